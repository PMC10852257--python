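"""Published climatological thresholds for Benin's three agro-ecological zones.

The cutpoints below are the mean +/- one standard deviation of 26 years
(1995-2020) of monthly climate observations at the Kandi (Sudanian), Save
(Sudano-Guinean) and Cotonou (Guinean) synoptic stations, plus the per-zone
monthly tomato yield.  They are the reference discretization grid for the
low/medium/high encoding and double as the calibration for the synthetic
generator.  Minimum humidity (Umin) has no published thresholds because it is
removed by the 80% correlation filter before discretization.

Units: Sun in hours, ET and RR in mm, temperatures in degrees C, humidity in
percent, yield in kg/ha.
"""

from .thresholds import ThresholdTable

SUDANIAN = ThresholdTable(
    zone="Sudanian",
    cuts={
        "Sun": (6.727, 9.157),
        "ET": (3.009, 6.585),
        "RR": (0.109, 0.323),
        "Tmax": (31.733, 37.793),
        "Tmin": (19.024, 25.120),
        "Umax": (52.850, 94.264),
        "Yield": (192.671, 689.989),
    },
)

SUDANO_GUINEAN = ThresholdTable(
    zone="Sudano-Guinean",
    cuts={
        "Sun": (4.664, 7.994),
        "ET": (2.387, 3.887),
        "RR": (4.504, 8.347),
        "Tmax": (31.079, 36.545),
        "Tmin": (21.968, 23.825),
        "Umax": (88.161, 95.710),
        "Yield": (208.159, 322.760),
    },
)

GUINEAN = ThresholdTable(
    zone="Guinean",
    cuts={
        "Sun": (4.664, 7.528),
        "ET": (1.971, 2.673),
        "RR": (1.331, 3.250),
        "Tmax": (29.214, 32.282),
        "Tmin": (24.424, 26.213),
        "Umax": (90.036, 93.962),
        "Yield": (1739.144, 3618.280),
    },
)

ZONE_THRESHOLDS = {t.zone: t for t in (SUDANIAN, SUDANO_GUINEAN, GUINEAN)}

#: synoptic station attached to each zone
STATIONS = {
    "Sudanian": "Kandi",
    "Sudano-Guinean": "Save",
    "Guinean": "Cotonou",
}
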