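"""Study-level evaluation: rubric scoring, rater agreement, learning curve.

The four-level quality rubric grades posture accuracy by angular deviation
bands (+-5/10/15 degrees), movement fluidity by boundary pauses and rhythm
variance, and force control by the substantial/insubstantial
differentiation index.  Inter-rater agreement uses Fleiss' kappa
(kappa = (P_o - P_e) / (1 - P_e)); the feedback-performance relationship
is the saturating logarithmic curve
P = P_max ln(1 + alpha F) / ln(1 + alpha F_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

__all__ = [
    "RubricResult",
    "RatingTable",
    "LearningCurveParams",
    "RubricThresholds",
    "rubric_score",
    "fleiss_kappa",
    "learning_curve",
    "LEVELS",
]

LEVELS = ("Excellent", "Good", "Fair", "NeedsImprovement")


@dataclass(frozen=True)
class RubricThresholds:
    """Configurable fluidity / force cutoffs (the posture bands are fixed).

    Fluidity: number of invalid pauses plus rhythm variance; force: the
    substantial/insubstantial differentiation index in [0, 1].
    """

    fluidity_pauses: tuple[int, int, int] = (0, 1, 3)          # Excellent/Good/Fair
    fluidity_rhythm_var: tuple[float, float, float] = (0.1, 0.25, 0.5)
    force_index: tuple[float, float, float] = (0.8, 0.6, 0.4)  # lower bounds


@dataclass(frozen=True)
class RubricResult:
    posture_level: str
    fluidity_level: str
    force_level: str
    composite_score: float

    def __post_init__(self) -> None:
        for lv in (self.posture_level, self.fluidity_level, self.force_level):
            if lv not in LEVELS:
                raise ValueError(f"unknown rubric level {lv!r}")


@dataclass(frozen=True)
class RatingTable:
    """Subjects x categories count table with a fixed rater count per subject."""

    counts: np.ndarray
    raters_per_subject: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("need >= 2 subjects and >= 2 categories")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if not np.all(c.sum(axis=1) == self.raters_per_subject):
            raise ValueError("each subject row must sum to raters_per_subject")
        if self.raters_per_subject < 2:
            raise ValueError("need >= 2 raters")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class LearningCurveParams:
    p_max: float
    f_max: float
    alpha_lc: float

    def __post_init__(self) -> None:
        if self.p_max <= 0 or self.f_max <= 0 or self.alpha_lc <= 0:
            raise ValueError("P_max, F_max and alpha must be positive")


def _band_level(value: float, bounds: tuple[float, float, float],
                lower_is_better: bool) -> str:
    if lower_is_better:
        for level, b in zip(LEVELS, bounds):
            if value <= b:
                return level
    else:
        for level, b in zip(LEVELS, bounds):
            if value >= b:
                return level
    return LEVELS[-1]


def rubric_score(
    posture_deviation_deg: float,
    fluidity_pauses: int,
    fluidity_rhythm_var: float,
    force_index: float,
    thresholds: RubricThresholds = RubricThresholds(),
) -> RubricResult:
    """Grade a performance on the four-level rubric.

    Posture uses the fixed +-5/10/15 degree deviation bands; fluidity is
    the stricter of the pause-count and rhythm-variance gradings; force is
    graded on the differentiation index.  The composite score is the mean
    of the three level ordinals mapped onto [0, 3] (0 = Excellent).
    """
    if posture_deviation_deg < 0:
        raise ValueError("posture deviation must be nonnegative")
    posture = _band_level(posture_deviation_deg, (5.0, 10.0, 15.0), True)
    f_pause = _band_level(fluidity_pauses, thresholds.fluidity_pauses, True)
    f_rhythm = _band_level(
        fluidity_rhythm_var, thresholds.fluidity_rhythm_var, True
    )
    fluidity = LEVELS[max(LEVELS.index(f_pause), LEVELS.index(f_rhythm))]
    force = _band_level(force_index, thresholds.force_index, False)
    ordinals = [LEVELS.index(x) for x in (posture, fluidity, force)]
    return RubricResult(
        posture_level=posture,
        fluidity_level=fluidity,
        force_level=force,
        composite_score=float(np.mean(ordinals)),
    )


def fleiss_kappa(table: RatingTable) -> float:
    """Fleiss' kappa = (P_o - P_e) / (1 - P_e) for a fixed-rater table.

    1 at perfect agreement (regardless of the marginal distribution);
    undefined (rejected) when every rating falls in one category, since
    chance agreement P_e is then 1.
    """
    counts = table.counts
    n = table.raters_per_subject
    p_cat = counts.sum(axis=0) / (counts.shape[0] * n)
    p_e = float(np.sum(p_cat**2))
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError(
            "kappa undefined: all ratings fall in a single category (P_e = 1)"
        )
    return float(_sm_fleiss_kappa(counts, method="fleiss"))


def learning_curve(feedback_count: float, params: LearningCurveParams) -> float:
    """P = P_max ln(1 + alpha F) / ln(1 + alpha F_max).

    Strictly increasing and concave in F with exact endpoints P(0) = 0 and
    P(F_max) = P_max.
    """
    f = float(feedback_count)
    if not 0.0 <= f <= params.f_max:
        raise ValueError(f"feedback count must lie in [0, {params.f_max}]")
    return float(
        params.p_max
        * np.log1p(params.alpha_lc * f)
        / np.log1p(params.alpha_lc * params.f_max)
    )
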