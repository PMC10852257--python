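"""Association rules from frequent itemsets: support, confidence, lift.

For a rule X => Y over N transactions,

    support(X => Y) = count(X u Y) / N
    confidence(X => Y) = count(X u Y) / count(X)
    lift(X => Y) = confidence(X => Y) / (count(Y) / N)

A lift of 1 marks statistical independence of antecedent and consequent;
above 1, a positive association.  Only single-item consequents are generated:
the analysis this package supports asks which climate-category combinations
imply the high-yield category, so every rule's consequent is one designated
item and the general multi-consequent enumeration is deliberately absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .fpgrowth import FrequentItemset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be nonempty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")


def generate_rules(itemsets: list[FrequentItemset], consequent_item: str,
                   n_transactions: int) -> list[AssociationRule]:
    """One rule (Z - {c}) => {c} per frequent itemset Z containing item c.

    ``itemsets`` must be downward-closed with exact counts (as returned by the
    miner), since confidence needs the antecedent's own count.  If the
    consequent item is not itself frequent no rule can clear the support
    threshold and an empty list is returned with a warning.
    """
    by_items = {s.items: s.support_count for s in itemsets}
    consequent = frozenset([consequent_item])
    if consequent not in by_items:
        log.warning("consequent %r is not frequent; no rules emitted",
                    consequent_item)
        return []
    consequent_support = by_items[consequent] / n_transactions
    out = []
    for s in itemsets:
        if consequent_item not in s.items or len(s.items) < 2:
            continue
        antecedent = s.items - consequent
        confidence = s.support_count / by_items[antecedent]
        out.append(AssociationRule(
            antecedent=antecedent,
            consequent=consequent,
            support=s.support_count / n_transactions,
            confidence=confidence,
            lift=confidence / consequent_support,
        ))
    return out


def filter_rules(rules: list[AssociationRule], min_confidence: float = 0.8,
                 min_lift: float = 1.0, min_antecedents: int = 3
                 ) -> list[AssociationRule]:
    """Keep rules with >= ``min_antecedents`` antecedent items and inclusive
    confidence/lift thresholds; input order is preserved."""
    if not 0 <= min_confidence <= 1:
        raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
    if min_lift < 0:
        raise ValueError(f"min_lift {min_lift} < 0")
    if min_antecedents < 1:
        raise ValueError(f"min_antecedents {min_antecedents} < 1")
    return [r for r in rules
            if len(r.antecedent) >= min_antecedents
            and r.confidence >= min_confidence
            and r.lift >= min_lift]


def _rank_key(rule: AssociationRule):
    return (-rule.confidence, -rule.lift, -rule.support,
            tuple(sorted(rule.antecedent)))


def rank_top_k(rules: list[AssociationRule], k: int) -> list[AssociationRule]:
    """The k most relevant rules: confidence, then lift, then support, all
    descending, with sorted antecedent labels as the deterministic tie-break."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return sorted(rules, key=_rank_key)[:k]


def write_rules_csv(rules: list[AssociationRule], path: str | Path) -> None:
    """Pipe-delimited ``antecedents|consequent|support|confidence|lift`` with
    ";"-joined sorted antecedents and three-decimal metrics."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("antecedents|consequent|support|confidence|lift\n")
        for r in rules:
            fh.write(f"{';'.join(sorted(r.antecedent))}"
                     f"|{';'.join(sorted(r.consequent))}"
                     f"|{r.support:.3f}|{r.confidence:.3f}|{r.lift:.3f}\n")


def format_report(zone: str, rules: list[AssociationRule]) -> str:
    """Human-readable per-zone rule listing."""
    lines = [f"Zone: {zone} — {len(rules)} rule(s)"]
    for i, r in enumerate(rules, 1):
        ant = " AND ".join(sorted(r.antecedent))
        (cons,) = r.consequent
        lines.append(f"  {i}. IF {ant} THEN {cons}"
                     f"  [support={r.support:.3f}, confidence={r.confidence:.3f},"
                     f" lift={r.lift:.3f}]")
    return "\n".join(lines) + "\n"
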