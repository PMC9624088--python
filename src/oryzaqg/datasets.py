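"""Worked-example datasets from a published rice drought-selection field study.

Selection gradients (β ± SE), SNP-based G-matrices, predicted responses to
selection, breeding-line fitness ranks and multiple-testing constants for
Indica and Japonica varietal-group panels grown under wet and dry field
conditions.  XHS (xylem sap exudation) and LRO (leaf rolling) were scored
only under drought, so the wet-condition matrices cover six traits.

These tables serve as inputs for the breeder's-equation and ranking
machinery and as regression fixtures: feeding the published β and G into
:func:`oryzaqg.breeders.predict_response` reproduces the published direct,
indirect and total response cells to within the 3-decimal rounding of the
inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DRY_TRAITS = ["XHS", "WUE", "LOP", "TNR", "LRO", "SSC", "TGW", "DTF"]
WET_TRAITS = ["WUE", "LOP", "TNR", "SSC", "TGW", "DTF"]

# --- published marker counts and effective-test numbers -------------------
INDICA_N_LOCI = 424_105
JAPONICA_N_LOCI = 377_819
INDICA_MEFF = 38_822
JAPONICA_MEFF = 24_765
N_TRANSCRIPTS = 15_635

# --- selection gradients: (beta, se, p) per trait -------------------------
_GRADIENTS = {
    ("indica", "wet"): {
        "WUE": (-0.042, 0.033, 0.2003),
        "LOP": (-0.002, 0.033, 0.9428),
        "TNR": (0.157, 0.034, 0.0000),
        "SSC": (-0.067, 0.034, 0.0497),
        "TGW": (-0.085, 0.035, 0.0152),
        "DTF": (-0.206, 0.036, 0.0000),
    },
    ("indica", "dry"): {
        "XHS": (-0.181, 0.259, 0.4855),
        "WUE": (0.054, 0.259, 0.8357),
        "LOP": (-0.405, 0.268, 0.1331),
        "TNR": (0.065, 0.272, 0.8107),
        "LRO": (-0.392, 0.259, 0.1324),
        "SSC": (-0.228, 0.259, 0.3803),
        "TGW": (-0.271, 0.250, 0.2780),
        "DTF": (-1.476, 0.293, 0.0000),
    },
    ("japonica", "wet"): {
        "WUE": (-0.155, 0.076, 0.0433),
        "LOP": (0.072, 0.069, 0.3037),
        "TNR": (0.164, 0.071, 0.0213),
        "SSC": (0.034, 0.069, 0.6229),
        "TGW": (-0.285, 0.071, 0.0001),
        "DTF": (-0.130, 0.071, 0.0671),
    },
    ("japonica", "dry"): {
        "XHS": (0.058, 0.337, 0.8656),
        "WUE": (0.154, 0.344, 0.6575),
        "LOP": (0.113, 0.340, 0.7434),
        "TNR": (-0.334, 0.290, 0.2583),
        "LRO": (-0.484, 0.286, 0.1023),
        "SSC": (-0.358, 0.298, 0.2405),
        "TGW": (-0.290, 0.319, 0.3712),
        "DTF": (-1.335, 0.349, 0.0007),
    },
}

# --- G-matrices (heritabilities on the diagonal, covariances off) ---------
_G_MATRICES = {
    ("indica", "wet"): np.array([
        [0.746, -0.016, -0.182, 0.002, 0.169, -0.036],
        [-0.016, 0.117, -0.025, 0.065, -0.052, 0.029],
        [-0.182, -0.025, 0.897, 0.036, -0.207, 0.096],
        [0.002, 0.065, 0.036, 0.000, -0.051, 0.260],
        [0.169, -0.052, -0.207, -0.051, 0.799, -0.198],
        [-0.036, 0.029, 0.096, 0.260, -0.198, 0.751],
    ]),
    ("indica", "dry"): np.array([
        [0.000, -0.074, 0.000, 0.074, -0.063, 0.064, 0.057, 0.001],
        [-0.074, 0.833, -0.003, -0.119, 0.019, -0.071, 0.084, -0.120],
        [0.000, -0.003, 0.221, 0.057, -0.017, 0.063, -0.111, 0.111],
        [0.074, -0.119, 0.057, 0.078, 0.078, 0.031, 0.088, -0.007],
        [-0.063, 0.019, -0.017, 0.078, 0.439, -0.016, -0.126, 0.107],
        [0.064, -0.071, 0.063, 0.031, -0.016, 0.537, 0.088, 0.280],
        [0.057, 0.084, -0.111, 0.088, -0.126, 0.088, 0.443, -0.126],
        [0.001, -0.120, 0.111, -0.007, 0.107, 0.280, -0.126, 1.000],
    ]),
    ("japonica", "wet"): np.array([
        [0.844, -0.176, -0.438, -0.126, 0.211, 0.241],
        [-0.176, 0.316, 0.079, 0.020, -0.039, -0.056],
        [-0.438, 0.079, 0.235, 0.069, -0.092, -0.146],
        [-0.126, 0.020, 0.069, 0.000, -0.087, 0.139],
        [0.211, -0.039, -0.092, -0.087, 0.732, -0.140],
        [0.241, -0.056, -0.146, 0.139, -0.140, 0.664],
    ]),
    ("japonica", "dry"): np.array([
        [0.000, -0.069, -0.039, -0.056, 0.006, -0.022, -0.037, 0.222],
        [-0.069, 0.830, -0.020, -0.185, -0.060, -0.020, 0.103, -0.062],
        [-0.039, -0.020, 0.088, 0.002, 0.026, 0.016, -0.134, -0.111],
        [-0.056, -0.185, 0.002, 0.381, 0.177, 0.038, -0.158, -0.124],
        [0.006, -0.060, 0.026, 0.177, 0.603, -0.018, -0.201, -0.008],
        [-0.022, -0.020, 0.016, 0.038, -0.018, 0.238, -0.039, 0.144],
        [-0.037, 0.103, -0.134, -0.158, -0.201, -0.039, 0.509, -0.149],
        [0.222, -0.062, -0.111, -0.124, -0.008, 0.144, -0.149, 0.317],
    ]),
}

# --- published predicted responses (direct, indirect, total) --------------
_RESPONSES = {
    ("indica", "wet"): {
        "WUE": (-0.032, -0.036, -0.067),
        "LOP": (0.000, -0.009, -0.009),
        "TNR": (0.141, 0.003, 0.144),
        "SSC": (0.000, -0.044, -0.044),
        "TGW": (-0.068, 0.005, -0.063),
        "DTF": (-0.155, 0.016, -0.139),
    },
    ("indica", "dry"): {
        "XHS": (0.000, -0.005, -0.005),
        "WUE": (0.045, 0.170, 0.215),
        "LOP": (-0.089, -0.137, -0.226),
        "TNR": (0.005, -0.095, -0.089),
        "LRO": (-0.172, -0.095, -0.267),
        "SSC": (-0.122, -0.469, -0.592),
        "TGW": (-0.120, 0.260, 0.139),
        "DTF": (-1.476, -0.123, -1.599),
    },
    ("japonica", "wet"): {
        "WUE": (-0.131, -0.181, -0.311),
        "LOP": (0.023, 0.059, 0.082),
        "TNR": (0.039, 0.121, 0.160),
        "SSC": (0.000, 0.039, 0.039),
        "TGW": (-0.208, -0.035, -0.244),
        "DTF": (-0.086, -0.021, -0.107),
    },
    ("japonica", "dry"): {
        "XHS": (0.000, -0.276, -0.276),
        "WUE": (0.128, 0.145, 0.273),
        "LOP": (0.010, 0.162, 0.172),
        "TNR": (-0.127, 0.080, -0.047),
        "LRO": (-0.292, 0.010, -0.282),
        "SSC": (-0.085, -0.187, -0.272),
        "TGW": (-0.148, 0.362, 0.215),
        "DTF": (-0.423, 0.028, -0.395),
    },
}

# --- breeding-line fitness ranks relative to 114 further Indica accessions
_BREEDING_LINE_RANKS = [
    ("Sahbhagi Dhan", "RL", 13, 8),
    ("Sahod Ulan 1", "RL", 37, 19),
    ("BRRI dhan71", "RL", 36, 29),
    ("Katihan 3 (NSIC Rc27)", "UP", 42, 33),
    ("Katihan 1", "UP", 49, 26),
    ("Sukha Dhan 6", "RL", 30, 63),
    ("Sahod Ulan 12", "RL", 33, 61),
    ("Sahod Ulan 20", "RL", 44, 54),
    ("Sahod Ulan 5", "RL", 83, 47),
    ("Sahod Ulan 3", "RL", 34, 110),
    ("sister of CR Dhan 201", "UP", 125, 39),
    ("PSBRC_1", "UP", 102, 74),
    ("BPI 76", "IR", 43, 104),
    ("IR58", "IR", 89, 72),
    ("FL478", "IR", 113, 56),
    ("IR36", "IR", 75, 94),
    ("IR64", "IR", 99, 92),
    ("IR29", "IR", 96, 112),
]


def panel_traits(environment: str) -> list[str]:
    return list(DRY_TRAITS if environment == "dry" else WET_TRAITS)


def selection_gradients(panel: str, environment: str) -> pd.DataFrame:
    """Published β (±SE, p) for one panel × environment, per trait."""
    entries = _GRADIENTS[(panel, environment)]
    return pd.DataFrame.from_dict(
        {t: dict(zip(("beta", "se", "p"), v)) for t, v in entries.items()},
        orient="index",
    ).loc[panel_traits(environment)]


def g_matrix(panel: str, environment: str) -> pd.DataFrame:
    """Published SNP-based G-matrix for one panel × environment."""
    traits = panel_traits(environment)
    return pd.DataFrame(_G_MATRICES[(panel, environment)], index=traits, columns=traits)


def predicted_response(panel: str, environment: str) -> pd.DataFrame:
    """Published direct/indirect/total predicted responses (Δz)."""
    entries = _RESPONSES[(panel, environment)]
    return pd.DataFrame.from_dict(
        {t: dict(zip(("direct", "indirect", "total"), v)) for t, v in entries.items()},
        orient="index",
    ).loc[panel_traits(environment)]


def breeding_line_ranks() -> pd.DataFrame:
    """Published per-environment fitness ranks of 18 Indica breeding lines."""
    df = pd.DataFrame(
        _BREEDING_LINE_RANKS, columns=["accession", "ecosystem", "wet_rank", "dry_rank"]
    ).set_index("accession")
    return df
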