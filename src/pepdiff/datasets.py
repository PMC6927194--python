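"""Small bundled reference tables.

``load_qser1_summary`` returns the published per-treatment summary of log10
precursor intensity for peptides of the QSER1 gene symbol across 24 plasma
treatment groups (two of the 26 treatments had no QSER1 observations and are
omitted). Feeding it to :class:`pepdiff.intensity.IntensityAnova.from_summary`
reconstructs the published one-way ANOVA (treatment df 23, residual df 808)
and the Tukey-Kramer letter structure separating the breast-cancer groups
(treatments 5 and 6) from ovarian cancer (treatment 9).

``BREAST_TOTAL_MSMS``/``OVARIAN_TOTAL_MSMS`` are the published totals of
filtered (>= 1e4 counts) MS/MS spectra used to depth-correct the
breast-vs-ovarian frequency contrast.
"""

from __future__ import annotations

import pandas as pd

#: Total filtered MS/MS spectra in the breast-cancer samples.
BREAST_TOTAL_MSMS = 455_426
#: Total filtered MS/MS spectra in the ovarian-cancer plasma samples.
OVARIAN_TOTAL_MSMS = 498_616

# treatment_id, mean, sd, n, published Tukey-Kramer letters
_QSER1 = [
    (1, 5.072769, 0.302986, 21, "d"),
    (2, 4.593409, 0.511989, 67, "cde"),
    (3, 4.633497, 0.3285, 26, "bde"),
    (4, 4.056312, 0.161037, 33, "a"),
    (5, 5.918212, 0.760851, 25, "h"),
    (6, 5.717592, 0.763346, 18, "h"),
    (7, 4.837276, 0.216573, 8, "bdef"),
    (9, 4.542693, 0.65645, 141, "ceg"),
    (10, 4.600209, 0.640097, 66, "cde"),
    (11, 4.512103, 0.515631, 8, "acde"),
    (12, 4.029774, 0.0, 4, "acde"),
    (13, 4.452935, 0.491664, 50, "aceg"),
    (14, 4.12479, 0.351469, 35, "af"),
    (15, 4.419355, 0.198763, 53, "ace"),
    (16, 4.324212, 0.504538, 32, "ace"),
    (17, 4.928881, 0.947319, 22, "dg"),
    (18, 4.173403, 0.478339, 36, "ab"),
    (19, 4.740343, 0.428142, 58, "cde"),
    (20, 4.80151, 0.475907, 35, "de"),
    (21, 4.749583, 0.513686, 36, "cde"),
    (22, 4.755553, 0.517117, 25, "cde"),
    (23, 4.58392, 0.466147, 11, "acde"),
    (24, 3.736293, 0.0, 4, "abc"),
    (25, 4.881761, 0.953098, 18, "de"),
]


def load_qser1_summary() -> pd.DataFrame:
    """Published QSER1 per-treatment (mean, sd, n, letters) summary table."""
    return pd.DataFrame(_QSER1, columns=["treatment_id", "mean", "sd", "n",
                                         "published_letters"])
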