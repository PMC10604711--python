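"""Published reference values for the LSAD measures.

Group-level descriptive statistics (mean, SD per pair and for the sum)
reported for a 150-patient Alzheimer's-dementia cohort versus 150 age- and
sex-matched non-demented controls, at depth coefficient c = 0.016.  They
are kept here for consistency checks — e.g. that the per-pair means add up
to the reported sum within the rounding of the printed components — and as
a scale reference for the synthetic generator.  They are not used by any
computation on user data.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "REFERENCE_DEPTH_COEFFICIENT",
    "AD_MEAN",
    "AD_SD",
    "CONTROL_MEAN",
    "CONTROL_SD",
    "AD_SUM",
    "CONTROL_SUM",
    "N_PER_GROUP",
]

REFERENCE_DEPTH_COEFFICIENT = 0.016
N_PER_GROUP = 150

# Per-pair group means/SDs, pair labels 1..29 in region order
# (face edge 1-8, eyebrows 9-13, nostrils 14-15, eyes 16-21, mouth 22-29).
AD_MEAN = np.array([
    0.71, 0.43, 0.47, 0.56, 0.57, 0.51, 0.41, 0.34,
    0.25, 0.17, 0.24, 0.30, 0.29,
    0.37, 0.44,
    0.12, 0.15, 0.13, 0.12, 0.32, 0.29,
    0.13, 0.31, 0.43, 0.33, 0.25, 0.82, 0.52, 0.36,
])
AD_SD = np.array([
    0.51, 0.30, 0.34, 0.37, 0.39, 0.33, 0.31, 0.35,
    0.19, 0.12, 0.18, 0.22, 0.20,
    0.23, 0.25,
    0.10, 0.12, 0.10, 0.07, 0.11, 0.11,
    0.09, 0.17, 0.23, 0.19, 0.16, 0.27, 0.15, 0.20,
])
CONTROL_MEAN = np.array([
    0.63, 0.40, 0.39, 0.46, 0.48, 0.44, 0.37, 0.25,
    0.22, 0.16, 0.22, 0.27, 0.25,
    0.31, 0.39,
    0.09, 0.11, 0.11, 0.10, 0.32, 0.28,
    0.11, 0.27, 0.37, 0.27, 0.21, 0.79, 0.55, 0.31,
])
CONTROL_SD = np.array([
    0.53, 0.37, 0.33, 0.37, 0.37, 0.32, 0.31, 0.24,
    0.15, 0.12, 0.18, 0.20, 0.18,
    0.22, 0.26,
    0.06, 0.09, 0.09, 0.07, 0.09, 0.08,
    0.08, 0.17, 0.23, 0.17, 0.15, 0.25, 0.13, 0.19,
])

# Reported "sum of LSAD" group means.
AD_SUM = 10.33
CONTROL_SUM = 9.14
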