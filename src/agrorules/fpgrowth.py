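"""From-scratch frequent-itemset mining with an FP-tree.

The FP-tree compresses a transaction database into a prefix tree: items are
globally ordered by descending frequency (label-ascending on ties, so trees
are identical across runs and platforms), each transaction's frequent items
are inserted along that order, and overlapping transactions share prefix
nodes whose counts accumulate.  A header table keeps, per item, its total
support and the head of a linked chain threading every node carrying that
item.  Construction reads the transaction stream exactly twice: once to count
item frequencies, once to insert.

Mining proceeds bottom-up over the header (ascending frequency): for each
item, the prefix paths above its nodes — the conditional pattern base — are
reassembled into a conditional FP-tree and mined recursively with the item
appended to the suffix.  A tree that has degenerated to a single path is
enumerated combinatorially instead of recursed.  No candidate generation is
involved; every itemset is returned with its exact integer support count.

:func:`enumerate_bruteforce` is a deliberately independent levelwise Apriori
enumerator (candidate join + downward-closure prune + full DB scan per level)
kept as a cross-checking oracle for small inputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from .errors import EmptyInputError, OracleRefusedError

#: refuse brute-force enumeration beyond this many distinct frequent items
ORACLE_MAX_ITEMS = 25


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support_count: int
    support: float


class FPNode:
    __slots__ = ("item", "count", "parent", "children", "next_node")

    def __init__(self, item: str | None, count: int, parent: "FPNode | None"):
        self.item = item
        self.count = count
        self.parent = parent
        self.children: dict[str, FPNode] = {}
        self.next_node: FPNode | None = None

    def __repr__(self) -> str:  # debugging aid
        return f"FPNode({self.item!r}, {self.count})"


class _HeaderEntry:
    __slots__ = ("count", "head", "tail")

    def __init__(self, count: int):
        self.count = count
        self.head: FPNode | None = None
        self.tail: FPNode | None = None

    def append(self, node: FPNode) -> None:
        if self.head is None:
            self.head = self.tail = node
        else:
            self.tail.next_node = node
            self.tail = node

    def chain(self):
        node = self.head
        while node is not None:
            yield node
            node = node.next_node


class FPTree:
    """Prefix tree over frequency-ordered frequent items.

    ``header`` maps each frequent item to its support count and node chain, in
    frequency-descending (label-ascending on ties) order; ``rank`` gives each
    item's position in that order.
    """

    def __init__(self, item_counts: dict[str, int]):
        self.root = FPNode(None, 0, None)
        ordered = sorted(item_counts, key=lambda i: (-item_counts[i], i))
        self.header: dict[str, _HeaderEntry] = {
            item: _HeaderEntry(item_counts[item]) for item in ordered}
        self.rank: dict[str, int] = {item: r for r, item in enumerate(ordered)}
        self.n_transactions = 0

    def insert(self, items: list[str], count: int = 1) -> None:
        """Insert an already rank-sorted item list, sharing prefixes."""
        node = self.root
        for item in items:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, count, node)
                node.children[item] = child
                self.header[item].append(child)
            else:
                child.count += count
            node = child

    def is_empty(self) -> bool:
        return not self.root.children

    def single_path(self) -> list[FPNode] | None:
        """The root-to-leaf node list if the tree is one unbranched path."""
        path = []
        node = self.root
        while node.children:
            if len(node.children) > 1:
                return None
            (node,) = node.children.values()
            path.append(node)
        return path


def build_fptree(transactions, min_support_count: int) -> FPTree:
    """Two passes over ``transactions``: count item frequencies, then insert.

    Items with support below ``min_support_count`` are excluded from the tree
    entirely; each transaction's surviving items are inserted sorted by global
    frequency (descending, label-ascending ties).
    """
    if min_support_count < 1:
        raise ValueError(f"min_support_count must be >= 1, got {min_support_count}")
    counts: Counter[str] = Counter()
    n = 0
    for t in transactions:  # pass 1
        n += 1
        counts.update(set(t))
    if n == 0:
        raise EmptyInputError("no transactions")
    frequent = {i: c for i, c in counts.items() if c >= min_support_count}
    tree = FPTree(frequent)
    tree.n_transactions = n
    rank = tree.rank
    for t in transactions:  # pass 2
        kept = sorted((i for i in set(t) if i in rank), key=rank.__getitem__)
        if kept:
            tree.insert(kept)
    return tree


def _build_conditional(pattern_base: list[tuple[list[str], int]],
                       min_support_count: int) -> FPTree:
    counts: Counter[str] = Counter()
    for items, count in pattern_base:
        for item in items:
            counts[item] += count
    frequent = {i: c for i, c in counts.items() if c >= min_support_count}
    tree = FPTree(frequent)
    rank = tree.rank
    for items, count in pattern_base:
        kept = sorted((i for i in items if i in rank), key=rank.__getitem__)
        if kept:
            tree.insert(kept, count)
    return tree


def _mine(tree: FPTree, suffix: frozenset[str], min_support_count: int,
          out: list[tuple[frozenset[str], int]]) -> None:
    path = tree.single_path()
    if path is not None:
        # every nonempty combination of path nodes; the count is the deepest
        # included node's (counts are non-increasing down a single path)
        for r in range(1, len(path) + 1):
            for combo in combinations(path, r):
                out.append((suffix | {n.item for n in combo}, combo[-1].count))
        return
    for item in reversed(tree.header):  # ascending frequency
        entry = tree.header[item]
        itemset = suffix | {item}
        out.append((itemset, entry.count))
        base = []
        for node in entry.chain():
            prefix = []
            parent = node.parent
            while parent.item is not None:
                prefix.append(parent.item)
                parent = parent.parent
            if prefix:
                base.append((prefix, node.count))
        cond = _build_conditional(base, min_support_count)
        if not cond.is_empty():
            _mine(cond, itemset, min_support_count, out)


def mine_fptree(tree: FPTree, min_support_count: int) -> list[FrequentItemset]:
    """All itemsets with support count >= ``min_support_count``, exact counts.

    Fractional support is computed once here from the source transaction
    count; recursion carries integer counts only.
    """
    raw: list[tuple[frozenset[str], int]] = []
    _mine(tree, frozenset(), min_support_count, raw)
    n = tree.n_transactions
    return [FrequentItemset(items, count, count / n) for items, count in raw]


def enumerate_bruteforce(transactions, min_support_count: int
                         ) -> list[FrequentItemset]:
    """Levelwise Apriori enumeration; independent oracle for mine_fptree.

    Generates level-k candidates by joining level-(k-1) frequent sets, prunes
    any candidate with an infrequent subset (downward closure), then counts by
    scanning the database.  Refuses inputs with more than ``ORACLE_MAX_ITEMS``
    distinct frequent items.
    """
    if min_support_count < 1:
        raise ValueError(f"min_support_count must be >= 1, got {min_support_count}")
    db = [frozenset(t) for t in transactions]
    if not db:
        raise EmptyInputError("no transactions")
    n = len(db)
    counts: Counter[str] = Counter()
    for t in db:
        counts.update(t)
    level = {frozenset([i]): c for i, c in counts.items()
             if c >= min_support_count}
    if len(level) > ORACLE_MAX_ITEMS:
        raise OracleRefusedError(
            f"{len(level)} frequent items exceeds oracle guard {ORACLE_MAX_ITEMS}")
    results: list[FrequentItemset] = [
        FrequentItemset(s, c, c / n) for s, c in level.items()]
    while level:
        prev = list(level)
        candidates = set()
        for i, a in enumerate(prev):
            for b in prev[i + 1:]:
                union = a | b
                if len(union) == len(a) + 1:
                    if all(frozenset(union - {x}) in level for x in union):
                        candidates.add(union)
        level = {}
        for cand in candidates:
            c = sum(1 for t in db if cand <= t)
            if c >= min_support_count:
                level[cand] = c
        results.extend(FrequentItemset(s, c, c / n) for s, c in level.items())
    return results


def write_itemsets_csv(itemsets: list[FrequentItemset], path: str | Path) -> None:
    """Pipe-delimited rows ``items|support_count|support``, deterministic order."""
    ordered = sorted(itemsets,
                     key=lambda s: (-s.support_count, len(s.items),
                                    tuple(sorted(s.items))))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("items|support_count|support\n")
        for s in ordered:
            fh.write(f"{';'.join(sorted(s.items))}|{s.support_count}"
                     f"|{s.support:.6f}\n")
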