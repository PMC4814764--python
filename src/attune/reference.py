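"""Published per-child summary measures of the 12-child reference cohort.

The raw video recordings behind the reference study are not available,
so the per-child CRQA/LOS summary values printed in its report are
bundled here as validation inputs: arithmetic recompositions of these
columns (means, relative-difference scores, correlations) serve as
acceptance oracles for the pipeline's formulas.

NaN marks values the report left missing (one language score; the
tau_peak of the child whose RR_peak did not beat chance).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NA = float("nan")

#: Child characteristics (grade, age, school outcome scores).
CHILDREN = pd.DataFrame(
    {
        "child": range(1, 13),
        "grade": ["KG"] * 5 + ["1"] * 7,
        "age_months": [58, 55, 60, 58, 55, 64, 64, 69, 76, 69, 73, 71],
        "math_score": [5, 5, 2, 5, 5, 4, 5, 4, 4, 3, 4, 5],
        "language_score": [NA, 5, 3, 5, 4, 5, 5, 4, 4, 3, 4, 5],
        "avg_past_score": [
            2.65, 2.27, 0.77, 2.55, 2.45, 2.31, 2.56, 2.42, 2.27, 1.98, 2.75, 2.79,
        ],
    }
).set_index("child")

#: LOS-profile measures and whole-plot CRQA measures per child.
GLOBAL_MEASURES = pd.DataFrame(
    {
        "child": range(1, 13),
        "grade": ["KG"] * 5 + ["1"] * 7,
        "q_los": [0.46, 0.58, 0.91, 0.98, 1.31, 1.28, 0.48, 1.65, 0.90, 0.92, 1.78, 1.66],
        "rr_peak": [
            0.056, 0.089, 0.015, 0.076, 0.012, 0.034, 0.039, 0.034, 0.140, 0.053,
            0.021, 0.073,
        ],
        "tau_peak": [18, 16, NA, 2, 36, -1, -1, 0, 0, -1, -1, -1],
        "rr": [
            0.013, 0.019, 0.004, 0.011, 0.002, 0.010, 0.009, 0.006, 0.025, 0.016,
            0.002, 0.018,
        ],
        "lam_v": [
            0.986, 0.996, 0.968, 1.000, 0.893, 0.957, 0.979, 0.973, 0.992, 1.000,
            0.959, 1.000,
        ],
        "lam_h": [
            0.910, 0.885, 0.687, 0.885, 0.901, 0.701, 0.922, 0.624, 0.924, 0.789,
            0.632, 0.793,
        ],
        "tt_v": [5.2, 6.4, 4.3, 7.4, 3.2, 6.6, 5.8, 4.8, 6.3, 6.0, 5.4, 8.3],
        "tt_h": [3.4, 3.8, 2.6, 5.1, 3.1, 2.6, 4.0, 2.8, 5.1, 5.5, 2.7, 3.6],
        "maxl_v": [21, 19, 12, 26, 5, 16, 18, 12, 15, 25, 18, 24],
        "maxl_h": [7, 10, 3, 11, 6, 5, 12, 5, 15, 27, 3, 6],
    }
).set_index("child")

#: Sensorimotor-tier (levels 1-3) CRQA measures per child.
TIER_S_MEASURES = pd.DataFrame(
    {
        "child": range(1, 13),
        "grade": ["KG"] * 5 + ["1"] * 7,
        "pct_rr": [66.9, 29.3, 99.3, 7.2, 73.3, 95.6, 31.5, 73.9, 29.8, 60.3, 20.5, 19.8],
        "lam_v": [
            0.669, 0.289, 0.961, 0.072, 0.733, 0.915, 0.308, 0.721, 0.290, 0.603,
            0.192, 0.198,
        ],
        "lam_h": [
            0.595, 0.226, 0.687, 0.048, 0.672, 0.672, 0.248, 0.480, 0.267, 0.539,
            0.103, 0.161,
        ],
        "vh_lam": [
            0.074, 0.063, 0.273, 0.024, 0.061, 0.243, 0.059, 0.241, 0.023, 0.064,
            0.089, 0.037,
        ],
        "tt_v": [7.6, 8.3, 4.3, 6.0, 3.2, 6.7, 7.0, 4.3, 7.6, 5.1, 4.7, 5.0],
        "tt_h": [3.2, 2.5, 2.3, 3.2, 3.1, 2.6, 3.3, 2.7, 3.9, 5.4, 3.0, 3.3],
        "vh_tt": [0.41, 0.53, 0.31, 0.30, 0.01, 0.44, 0.37, 0.24, 0.32, -0.03, 0.22, 0.21],
        "maxl_v": [21, 19, 12, 6, 5, 16, 18, 8, 15, 10, 10, 9],
        "maxl_h": [7, 3, 3, 7, 6, 5, 5, 4, 15, 27, 3, 5],
        "vh_maxl": [0.50, 0.73, 0.60, -0.08, -0.09, 0.52, 0.57, 0.33, 0.00, -0.46, 0.54, 0.29],
    }
).set_index("child")

#: Representational-tier (levels 4-6) CRQA measures per child.
TIER_R_MEASURES = pd.DataFrame(
    {
        "child": range(1, 13),
        "grade": ["KG"] * 5 + ["1"] * 7,
        "pct_rr": [33.1, 70.7, 0.7, 92.8, 26.7, 4.4, 68.5, 26.1, 70.2, 39.7, 79.5, 80.2],
        "lam_v": [
            0.316, 0.707, 0.007, 0.928, 0.160, 0.042, 0.671, 0.252, 0.702, 0.397,
            0.767, 0.802,
        ],
        "lam_h": [
            0.315, 0.660, 0.000, 0.837, 0.229, 0.030, 0.674, 0.145, 0.657, 0.250,
            0.530, 0.632,
        ],
        "vh_lam": [
            0.002, 0.047, 0.007, 0.090, -0.069, 0.013, -0.003, 0.107, 0.045, 0.147,
            0.237, 0.170,
        ],
        "tt_v": [3.1, 5.8, 3.0, 7.5, 3.0, 4.8, 5.3, 7.0, 5.8, 8.2, 5.6, 9.8],
        "tt_h": [3.9, 4.7, 0.0, 5.3, 3.0, 4.0, 4.4, 3.3, 5.9, 5.7, 2.7, 3.7],
        "vh_tt": [-0.11, 0.11, 1.00, 0.17, 0.00, 0.09, 0.09, 0.35, -0.01, 0.18, 0.35, 0.45],
        "maxl_v": [5, 9, 3, 26, 3, 7, 11, 12, 10, 25, 18, 24],
        "maxl_h": [7, 10, 1, 11, 5, 4, 12, 5, 10, 8, 3, 6],
        "vh_maxl": [-0.17, -0.05, 0.50, 0.41, -0.25, 0.27, -0.04, 0.41, 0.00, 0.52, 0.71, 0.60],
    }
).set_index("child")


def grade_mask(df: pd.DataFrame, grade: str) -> np.ndarray:
    return (df["grade"] == grade).to_numpy()
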