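"""Reference group statistics for the four diagnostic classes.

These are the published group means (and between-image SDs) of the six
measured parameters in the original development cohort of 40 consensus
biopsy images (10 per group), in pixel units at the reference acquisition
geometry.  They seed the synthetic-image presets and the default score
calibration.
"""

from __future__ import annotations

GRADES = ("NORMAL", "CIN1", "CIN2", "CIN3")

#: Group means of the six measured parameters, by grade.
#: A: epithelium area (px^2); N: mean nucleus area (px^2); V: mean zone of
#: influence area (px^2); D: differentiated-epithelium area (px^2);
#: Hst/HstU: total and upper nuclei chromaticism (inverted grey, 0-255).
GROUP_MEANS = {
    "NORMAL": {"A": 212018.0, "N": 173.9, "V": 1740.3, "D": 30136.3, "Hst": 19.1, "HstU": 7.3},
    "CIN1": {"A": 211203.0, "N": 239.1, "V": 995.5, "D": 75070.4, "Hst": 46.7, "HstU": 13.4},
    "CIN2": {"A": 193261.0, "N": 200.6, "V": 595.1, "D": 111642.0, "Hst": 59.5, "HstU": 15.6},
    "CIN3": {"A": 183499.0, "N": 206.7, "V": 442.3, "D": 157383.9, "Hst": 75.6, "HstU": 3.5},
}

#: Between-image standard deviations of the same parameters.
GROUP_SDS = {
    "NORMAL": {"A": 25165.0, "N": 33.8, "V": 277.5, "D": 4066.0, "Hst": 5.3, "HstU": 2.2},
    "CIN1": {"A": 19507.0, "N": 50.7, "V": 170.0, "D": 10032.7, "Hst": 8.2, "HstU": 3.0},
    "CIN2": {"A": 34755.0, "N": 41.5, "V": 114.8, "D": 27981.4, "Hst": 9.7, "HstU": 3.8},
    "CIN3": {"A": 36993.0, "N": 37.0, "V": 37.4, "D": 32505.0, "Hst": 15.2, "HstU": 2.5},
}

#: Published mean cervical score per grade; the calibration anchors.
SCORE_TARGETS = {"NORMAL": 27.0, "CIN1": 51.0, "CIN2": 78.0, "CIN3": 100.0}


def reference_ratios(grade: str) -> tuple[float, float, float]:
    """The (N/V, D/A, HstU/Hst) triple at the group means of ``grade``."""
    m = GROUP_MEANS[grade]
    return m["N"] / m["V"], m["D"] / m["A"], m["HstU"] / m["Hst"]
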