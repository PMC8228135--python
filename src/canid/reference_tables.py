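"""Published summary statistics for the wolf-like breed panels.

These are the reported per-breed ROH class summaries and the group-level
divergence matrix for the Czechoslovakian wolfdog (CWD), Saarloos wolfdog
(SWD), German Shepherd dog (GSD), Belgian Shepherd dog (BSD) and Grey
wolf (GW) panels, kept here as plain data so that internally recomputable
arithmetic (class shares, cumulative F_ROH reconstruction, row summaries)
can be checked without access to the underlying genotypes, which were
never publicly deposited.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DistanceMatrix

#: ROH length-class lower bounds in Mbp, ascending.
ROH_CLASS_LOWER_MBP = (0.0, 2.0, 4.0, 8.0, 16.0)
ROH_CLASS_LABELS = ("0-2", "2-4", "4-8", "8-16", ">16")

#: Per-breed ROH summaries: segment counts, mean segment length (Mbp),
#: reported class share (%), and reported group-mean F_ROH (%) per class,
#: in the class order above.  None marks an empty class.
ROH_CLASS_SUMMARY = {
    "CWD": {
        "n_animals": 30,
        "counts": (1868, 1110, 1088, 616, 227),
        "mean_length_mbp": (1.129, 2.893, 5.704, 10.817, 21.771),
        "share_pct": (38.053, 22.612, 22.163, 12.548, 4.624),
        "froh_pct": (35.010, 31.818, 26.958, 17.565, 7.480),
    },
    "GSD": {
        "n_animals": 56,
        "counts": (6071, 2669, 1787, 844, 211),
        "mean_length_mbp": (1.146, 2.853, 5.611, 10.777, 22.334),
        "share_pct": (52.418, 23.044, 15.429, 7.287, 1.822),
        "froh_pct": (31.141, 25.500, 19.327, 11.611, 4.458),
    },
    "BSD": {
        "n_animals": 31,
        "counts": (2231, 975, 735, 405, 137),
        "mean_length_mbp": (1.090, 2.854, 5.690, 10.966, 22.869),
        "share_pct": (49.766, 21.749, 16.395, 9.034, 3.056),
        "froh_pct": (24.857, 21.295, 17.219, 11.094, 4.905),
    },
    "GW": {
        "n_animals": 30,
        "counts": (1205, 192, 44, 6, None),
        "mean_length_mbp": (1.040, 2.685, 5.323, 9.727, None),
        "share_pct": (83.276, 13.269, 3.041, 0.415, None),
        "froh_pct": (8.508, 4.077, 1.898, 1.325, None),
    },
}

#: SNP-covered autosome length used in the reconstructions, in Mbp.  The
#: reported figure carries a 10x unit slip; this is the corrected value
#: under which the published F_ROH column is internally consistent.
AUTOSOME_LENGTH_MBP = 2199.534

GROUP_ORDER = ("CWD", "SWD", "GSD", "BSD", "GW")

#: Reported pairwise Weir-Cockerham F_ST between groups.
FST_MATRIX = {
    ("CWD", "SWD"): 0.290,
    ("CWD", "GSD"): 0.179,
    ("CWD", "BSD"): 0.273,
    ("CWD", "GW"): 0.319,
    ("SWD", "GSD"): 0.258,
    ("SWD", "BSD"): 0.284,
    ("SWD", "GW"): 0.346,
    ("GSD", "BSD"): 0.229,
    ("GSD", "GW"): 0.357,
    ("BSD", "GW"): 0.294,
}

#: Reported pairwise Nei genetic distances between groups.
NEI_MATRIX = {
    ("CWD", "SWD"): 0.151,
    ("CWD", "GSD"): 0.077,
    ("CWD", "BSD"): 0.148,
    ("CWD", "GW"): 0.169,
    ("SWD", "GSD"): 0.144,
    ("SWD", "BSD"): 0.194,
    ("SWD", "GW"): 0.214,
    ("GSD", "BSD"): 0.119,
    ("GSD", "GW"): 0.215,
    ("BSD", "GW"): 0.189,
}

#: QC accounting reported for the merged panel.
QC_COUNTS = {
    "n_markers_common": 153_733,
    "n_markers_pruned": 10_140,
    "n_markers_final": 143_593,
    "n_samples_in": 134,
    "n_samples_pruned": 3,
    "n_samples_final": 131,
}

#: Reported ROH-calling setup for the merged panel.
ROH_SETUP = {"alpha": 0.05, "min_snps_reported": 65, "n_snps": 143_593, "n_samples": 131}


def _as_distance_matrix(pairs: dict, method: str) -> DistanceMatrix:
    labels = list(GROUP_ORDER)
    n = len(labels)
    m = np.zeros((n, n))
    for (a, b), v in pairs.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(labels, m, method)


def published_fst_matrix() -> DistanceMatrix:
    return _as_distance_matrix(FST_MATRIX, "fst_wc")


def published_nei_matrix() -> DistanceMatrix:
    return _as_distance_matrix(NEI_MATRIX, "nei1972")
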