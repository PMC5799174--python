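"""Published TMA cohort tables used as printed-input fixtures.

These are the cross-tabulations of CAV1 and ITGB1 score categories against
Gleason-score group and pathological tumour stage in the 435-patient
prostate-cancer TMA cohort, plus the benign/cancer score-category
distribution.  They are inputs to the statistical layer, not outputs of it.

Known printing discrepancies, handled here:

* The benign-column percentages in the category-distribution table were
  printed against the cancer total (435) rather than the benign total (401),
  e.g. 215 printed as 49.4%.  This package reports percentages over the
  column's own total.
* In the ITGB1 x stage table the <=pT2 row prints cells 55/101/19/8 (sum
  183) against a printed row total of 184 and a Negative column total of 91;
  Negative/<=pT2 = 56 satisfies both marginals and is stored here as the
  reconciled value.
"""

from __future__ import annotations

import numpy as np

GLEASON_GROUPS = ("<=6", "7", ">=8")
STAGE_GROUPS = ("<=pT2", "pT3<=")
SCORE_CATEGORIES = ("Negative", "Weak", "Moderate", "Strong")

# CAV1 score-category distribution, benign vs cancer areas
# (Negative, Weak, Moderate, Strong)
CAV1_BENIGN_COUNTS = np.array([215, 183, 0, 3])  # total 401
CAV1_CANCER_COUNTS = np.array([117, 207, 61, 50])  # total 435

# CAV1 category (columns) x Gleason group (rows); printed p = 0.075
CAV1_GLEASON = np.array(
    [
        [12, 45, 13, 10],  # Gleason <= 6   (n = 80)
        [57, 90, 36, 17],  # Gleason 7      (n = 200)
        [21, 23, 6, 7],    # Gleason >= 8   (n = 57)
    ]
)

# CAV1 category x stage group; printed p = 0.154
CAV1_STAGE = np.array(
    [
        [41, 89, 35, 17],  # <= pT2  (n = 182)
        [40, 57, 16, 16],  # pT3 <=  (n = 129)
    ]
)

# ITGB1 category x Gleason group; printed p = 0.331
ITGB1_GLEASON = np.array(
    [
        [22, 46, 11, 4],   # Gleason <= 6   (n = 83)
        [54, 114, 23, 7],  # Gleason 7      (n = 198)
        [25, 25, 5, 2],    # Gleason >= 8   (n = 57)
    ]
)

# ITGB1 category x stage group, reconciled (see module docstring);
# printed p = 0.698
ITGB1_STAGE = np.array(
    [
        [56, 101, 19, 8],  # <= pT2  (n = 184; Negative cell printed as 55)
        [35, 71, 18, 4],   # pT3 <=  (n = 128)
    ]
)

ITGB1_STAGE_AS_PRINTED = np.array([[55, 101, 19, 8], [35, 71, 18, 4]])
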