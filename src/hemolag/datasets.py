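"""Reference tables for the 21-task aphasia battery.

Two small published tables ship with the package. ``battery_loadings()``
is the varimax-rotated loading pattern of 21 language/cognition tasks on
four orthogonal factors (phonology, semantics, executive, fluency) from a
66-patient chronic post-stroke aphasia cohort; it is the default ground
truth for the behavioural simulator.  ``example_factor_scores()`` holds
the regression-method factor scores of the 35-patient imaging subset and
exercises the +/-3 SD patient-exclusion rule (exactly two outlying
patients: one on fluency, one on semantics).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FACTOR_NAMES",
    "TASK_NAMES",
    "battery_loadings",
    "example_factor_scores",
]

FACTOR_NAMES = ["Phonology", "Semantics", "Executive", "Fluency"]

TASK_NAMES = [
    "Immediate Repetition - Non-words",
    "Delayed Repetition - Non-words",
    "Immediate Repetition - Words",
    "Delayed Repetition - Words",
    "64-Item Naming",
    "Boston Naming Test",
    "CAT Spoken Sentence Comprehension",
    "Forward Digit Span",
    "Backward Digit Span",
    "Spoken Word to Picture Matching",
    "Written Word to Picture Matching",
    "96 Synonym Judgement",
    "Camel and Cactus Test: Pictures",
    "Type/Token ratio",
    "Minimal Pairs - Non-words",
    "Minimal Pairs - Words",
    "Raven's Coloured Progressive Matrices",
    "Brixton Spatial Anticipation Test",
    "Words-Per-Minute",
    "Token",
    "Mean Length of Utterance in Morphemes",
]

# 21 tasks x 4 factors (phonology, semantics, executive, fluency)
_LOADINGS = np.array([
    [0.872, 0.073, 0.242, 0.154],
    [0.885, 0.042, 0.242, 0.154],
    [0.837, 0.225, 0.136, 0.196],
    [0.874, 0.238, 0.189, 0.213],
    [0.792, 0.454, 0.156, 0.135],
    [0.816, 0.402, 0.065, 0.116],
    [0.523, 0.467, 0.427, 0.133],
    [0.765, 0.233, 0.170, 0.085],
    [0.636, 0.161, 0.130, 0.302],
    [0.236, 0.809, 0.252, 0.122],
    [0.178, 0.721, 0.497, 0.147],
    [0.394, 0.677, 0.290, 0.323],
    [0.079, 0.700, 0.480, 0.274],
    [0.358, 0.729, -0.067, -0.083],
    [0.384, 0.072, 0.803, -0.072],
    [0.445, 0.180, 0.693, 0.077],
    [0.035, 0.268, 0.740, 0.179],
    [0.116, 0.176, 0.701, 0.240],
    [0.353, 0.103, 0.078, 0.755],
    [0.059, 0.030, 0.193, 0.876],
    [0.360, 0.268, 0.111, 0.799],
])

# 35 patients x 4 factors, regression-method scores
_FACTOR_SCORES = np.array([
    [1.14, -0.06, 0.95, 0.29],
    [-0.51, 0.93, 0.96, -1.06],
    [0.14, -1.32, 0.33, -0.92],
    [0.41, 0.48, -0.09, 0.30],
    [-0.03, 0.73, 0.12, -0.13],
    [-1.81, -0.09, 1.23, 2.40],
    [0.20, 0.59, -0.16, -0.98],
    [-0.77, 1.27, -0.39, -1.14],
    [-0.25, -0.01, 0.32, 3.91],
    [-0.43, 0.39, 0.50, -1.54],
    [1.15, -0.06, 0.30, 0.42],
    [1.26, 0.25, 0.43, 1.14],
    [-0.87, 0.97, 0.24, -0.39],
    [0.07, 0.09, 1.26, 0.62],
    [-1.56, -1.25, 1.86, -0.77],
    [-0.43, -0.04, 0.66, 1.42],
    [-1.45, 0.95, 1.03, -0.35],
    [0.12, 0.94, 0.18, -0.86],
    [-0.09, -3.88, -0.54, -0.83],
    [-1.07, 0.56, 0.25, 0.29],
    [0.44, 0.33, 1.14, -0.71],
    [0.53, 0.50, 0.23, -1.02],
    [-1.38, 0.42, -0.42, -0.25],
    [-0.27, 1.62, -1.09, 0.45],
    [-0.69, -1.18, -1.31, -0.49],
    [1.46, 0.31, 0.60, -0.47],
    [-0.09, -2.31, 1.34, -0.23],
    [-0.65, -0.69, -0.13, -1.73],
    [-0.23, -0.36, -2.27, -0.53],
    [0.59, 0.66, 0.92, -0.12],
    [0.86, 0.81, 0.01, -1.02],
    [-1.58, 0.25, 1.10, 0.80],
    [-1.15, -2.45, 1.29, -0.88],
    [-0.03, 0.43, -0.79, 1.86],
    [0.16, 0.18, -0.60, -1.17],
])


def battery_loadings(as_frame: bool = False) -> np.ndarray | pd.DataFrame:
    """Varimax-rotated loadings of the 21-task battery on four factors.

    Returns a copy; a DataFrame (task rows, factor columns) if ``as_frame``.
    """
    if as_frame:
        return pd.DataFrame(_LOADINGS.copy(), index=TASK_NAMES, columns=FACTOR_NAMES)
    return _LOADINGS.copy()


def example_factor_scores(as_frame: bool = False) -> np.ndarray | pd.DataFrame:
    """Factor scores of the 35-patient imaging subset (patients x 4)."""
    if as_frame:
        return pd.DataFrame(
            _FACTOR_SCORES.copy(),
            index=pd.RangeIndex(1, 36, name="patient_id"),
            columns=FACTOR_NAMES,
        )
    return _FACTOR_SCORES.copy()
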