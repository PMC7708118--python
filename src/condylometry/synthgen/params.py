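"""Published group parameters used as simulator defaults.

Each grouping scheme carries, per group: the sample size, the per-variable
means and standard deviations of the six condylar measurands (or of their
deviation-side minus non-deviation-side differences for the symmetry
scheme), and the mean/SD of the grouping variable itself (menton deviation,
Wits appraisal, or the maxillomandibular ML-NL angle).

Units: millimetres for linear measures and Wits, degrees for inclinations
and ML-NL, percent for the condyle/mandible volume ratio.
"""

from __future__ import annotations

#: per-subject aggregate measurands (both sides averaged; ratio summed)
AGGREGATE_VARIABLES = (
    "c_depth", "c_width", "c_height", "c_incl_ap", "c_incl_ml", "ratio",
)

#: deviation-side minus non-deviation-side differences
DIFF_VARIABLES = tuple(f"diff_{v}" for v in AGGREGATE_VARIABLES)

SCHEMES = ("symmetry", "sagittal", "vertical")

#: grouping variable per scheme and the class intervals (closed brackets on
#: the printed bracketed intervals; strict elsewhere)
GROUPING_VARIABLE = {
    "symmetry": "me_msp",
    "sagittal": "wits",
    "vertical": "ml_nl",
}

# scheme -> group -> dict(n, means, sds, group_mean, group_sd)
# "means"/"sds" are ordered like DIFF_VARIABLES (symmetry) or
# AGGREGATE_VARIABLES (sagittal, vertical).
GROUP_PARAMETERS = {
    "symmetry": {
        "symmetric": {
            "n": 65,
            "means": (-0.1, 0.1, 0.1, 2.3, -0.4, 0.0),
            "sds": (1.2, 1.4, 1.3, 8.8, 7.8, 0.4),
            "group_mean": 0.8, "group_sd": 0.6,
        },
        "moderate": {
            "n": 22,
            "means": (0.1, 0.7, 0.8, 1.3, -1.7, 0.4),
            "sds": (1.0, 1.6, 1.4, 7.7, 10.1, 0.3),
            "group_mean": 2.9, "group_sd": 0.6,
        },
        "strong": {
            "n": 24,
            "means": (0.4, 0.6, 0.8, 1.0, -1.0, 0.5),
            "sds": (1.1, 2.1, 1.5, 9.7, 10.1, 0.5),
            "group_mean": 6.2, "group_sd": 1.9,
        },
    },
    "sagittal": {
        "I": {
            "n": 25,
            "means": (8.5, 19.8, 16.7, 56.9, 67.5, 5.8),
            "sds": (1.1, 2.2, 1.8, 6.8, 9.6, 1.1),
            "group_mean": -0.8, "group_sd": 1.2,
        },
        "II": {
            "n": 36,
            "means": (8.3, 19.2, 16.6, 53.9, 64.2, 5.6),
            "sds": (1.5, 2.8, 2.8, 8.4, 9.8, 1.2),
            "group_mean": 6.5, "group_sd": 2.9,
        },
        "III": {
            "n": 50,
            "means": (7.5, 20.2, 18.5, 60.9, 69.9, 6.6),
            "sds": (1.4, 2.5, 2.9, 7.4, 7.5, 1.3),
            "group_mean": -9.1, "group_sd": 4.3,
        },
    },
    "vertical": {
        "hypodivergent": {
            "n": 37,
            "means": (8.5, 20.5, 17.8, 55.0, 68.7, 6.4),
            "sds": (1.6, 2.4, 2.6, 7.9, 9.8, 1.2),
            "group_mean": 16.3, "group_sd": 4.1,
        },
        "neutral": {
            "n": 32,
            "means": (8.0, 20.3, 17.1, 58.3, 68.5, 6.3),
            "sds": (1.4, 2.3, 3.1, 8.8, 7.2, 1.3),
            "group_mean": 23.2, "group_sd": 1.8,
        },
        "hyperdivergent": {
            "n": 42,
            "means": (7.6, 18.9, 17.4, 59.6, 65.6, 5.7),
            "sds": (1.1, 2.6, 2.7, 7.4, 9.5, 1.3),
            "group_mean": 32.7, "group_sd": 4.3,
        },
    },
}

#: class intervals of the grouping-variable magnitude / value per group,
#: used to keep simulated grouping values consistent with the group label.
GROUP_INTERVALS = {
    "symmetry": {  # |Me-MSP| in mm
        "symmetric": (0.0, 2.0),
        "moderate": (2.0, 4.0),
        "strong": (4.0, None),
    },
    "sagittal": {  # Wits in mm
        "I": (-2.0, 2.0),
        "II": (2.0, None),
        "III": (None, -2.0),
    },
    "vertical": {  # ML-NL in degrees
        "neutral": (20.5, 26.5),
        "hypodivergent": (None, 20.5),
        "hyperdivergent": (26.5, None),
    },
}


def scheme_variables(scheme: str) -> tuple:
    """Variable names simulated for a scheme (Diff variables for symmetry)."""
    return DIFF_VARIABLES if scheme == "symmetry" else AGGREGATE_VARIABLES
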