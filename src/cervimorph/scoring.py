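"""Discriminant ratios, the calibrated cervical score, grading and statistics.

Three ratios condense the six measured parameters: the nucleo-cytoplasmic
ratio N/V, the differentiation ratio DR = D/A and the upper-histogram ratio
HstR = HstU/Hst.  The cervical score is an affine combination of
(N/V, DR, 1 - HstR) calibrated so the four reference group-mean triples map
to the published group scores 27 / 51 / 78 / 100; (1 - HstR) enters because
HstR falls with grade.  The calibration is an exact solve of that 4x4
system, stored in plain floats so users can substitute their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .reference import GRADES, SCORE_TARGETS, reference_ratios

__all__ = [
    "FeatureVector",
    "RatioSet",
    "ScoreCalibration",
    "CervicalResult",
    "compute_ratios",
    "fit_calibration",
    "default_calibration",
    "cervical_score",
    "classify",
    "welch_ttest",
]


@dataclass
class FeatureVector:
    """The six measured parameters of one image (pixel units)."""

    A: float
    N: float | None
    V: float | None
    D: float
    Hst: float
    HstU: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.D < 0:
            raise ValueError("areas must be non-negative")
        if self.D > self.A:
            raise ValueError("differentiated area cannot exceed epithelium area")
        if self.N is not None and self.V is not None and self.N > self.V:
            warnings.warn(
                "mean nucleus area exceeds mean zone area; "
                "check segmentation", stacklevel=2,
            )


@dataclass
class RatioSet:
    nc_ratio: float  # N/V
    diff_ratio: float  # D/A
    hist_ratio: float  # HstU/Hst

    def as_regressors(self) -> np.ndarray:
        return np.array([self.nc_ratio, self.diff_ratio, 1.0 - self.hist_ratio])


@dataclass
class ScoreCalibration:
    """Affine map score = w . (N/V, DR, 1 - HstR) + offset."""

    weights: np.ndarray
    offset: float
    reference: dict[str, RatioSet] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"weights": list(map(float, self.weights)),
                "offset": float(self.offset)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreCalibration":
        return cls(np.asarray(d["weights"], dtype=float), float(d["offset"]))


@dataclass
class CervicalResult:
    ratios: RatioSet
    score: float
    grade: str


def compute_ratios(f: FeatureVector) -> RatioSet:
    """The three discriminant quotients of a feature vector."""
    if f.A <= 0:
        raise ValueError("epithelium area A must be positive")
    if f.V is None or f.V <= 0 or f.N is None:
        raise ValueError("nucleus/zone areas unavailable; cannot form N/V")
    hist_ratio = 0.0 if f.Hst <= 0 else f.HstU / f.Hst
    return RatioSet(f.N / f.V, f.D / f.A, hist_ratio)


def fit_calibration(
    reference: dict[str, RatioSet], targets: dict[str, float]
) -> ScoreCalibration:
    """Least-squares affine fit of group-mean ratio triples to target scores.

    With four groups and four unknowns this is an exact solve unless the
    reference triples are rank-deficient.
    """
    grades = [g for g in GRADES if g in reference]
    if len(grades) != len(reference) or len(grades) < 2:
        raise ValueError("reference must map known grade labels to RatioSets")
    X = np.array(
        [np.append(reference[g].as_regressors(), 1.0) for g in grades]
    )
    y = np.array([targets[g] for g in grades], dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # degenerate reference set: constant targets get a constant score
        if np.allclose(y, y[0]):
            return ScoreCalibration(np.zeros(3), float(y[0]), dict(reference))
        raise ValueError("reference ratio triples are rank-deficient")
    w, *_ = np.linalg.lstsq(X, y, rcond=None)
    return ScoreCalibration(w[:3], float(w[3]), dict(reference))


def default_calibration() -> ScoreCalibration:
    """Calibration fitted on the reference group-mean ratios vs 27/51/78/100."""
    reference = {
        g: RatioSet(*reference_ratios(g)) for g in GRADES
    }
    return fit_calibration(reference, SCORE_TARGETS)


def cervical_score(r: RatioSet, cal: ScoreCalibration | None = None) -> float:
    """Affine score of a ratio triple, clipped to [0, 120]."""
    if cal is None:
        cal = default_calibration()
    raw = float(cal.weights @ r.as_regressors() + cal.offset)
    return float(np.clip(raw, 0.0, 120.0))


def classify(score: float, targets: dict[str, float] = SCORE_TARGETS) -> str:
    """Grade whose calibrated reference score is nearest; ties go up-grade."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    best = None
    for g in GRADES:
        if g not in targets:
            continue
        d = abs(score - targets[g])
        if best is None or d <= best[0] + 1e-12:
            best = (d, g)  # later (higher) grade wins ties
    return best[1]


def welch_ttest(a, b) -> float:
    """Two-sided Welch t-test p-value (Welch-Satterthwaite df).

    Applied unconditionally — strictly more conservative than switching on
    an equal-variance pretest.  Two zero-variance samples with equal means
    give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def score_features(
    f: FeatureVector, cal: ScoreCalibration | None = None
) -> CervicalResult:
    """Ratios, score and grade for one feature vector."""
    r = compute_ratios(f)
    s = cervical_score(r, cal)
    return CervicalResult(ratios=r, score=s, grade=classify(s))
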