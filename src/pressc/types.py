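"""Core domain types shared across the pipeline.

Abundance matrices are plain :class:`pandas.DataFrame` objects (rows =
samples, columns = proteins, strictly positive RFU / concentration values);
sample metadata is a DataFrame with columns ``sample_id``, ``group``
(``case``/``control``) and ``outcome`` (``progressor``/``non_progressor``/
``not_applicable``).  The small record types below carry everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EffectSpec",
    "DiscoveryDesign",
    "ValidationDesign",
    "BaggingConfig",
    "IntervalObservation",
    "ICCoxFit",
    "CutpointResult",
    "TurnbullCurve",
    "GLRTResult",
]


@dataclass(frozen=True)
class EffectSpec:
    """A planted marker effect.

    Parameters
    ----------
    protein_id:
        Column name of the affected protein.
    log2_fc:
        Case-vs-control mean shift on the log2 abundance scale.
    log_hr:
        Log hazard ratio on progression per standard deviation of the
        (log2) marker.  Positive values are harmful (endostatin-like),
        negative values protective (bFGF-like).
    """

    protein_id: str
    log2_fc: float = 0.0
    log_hr: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.log2_fc) and math.isfinite(self.log_hr)):
            raise ValueError(f"non-finite effect for {self.protein_id!r}")


@dataclass(frozen=True)
class DiscoveryDesign:
    """Discovery-cohort dimensions.

    Defaults are the study conditions of the screen this package models:
    13 preclinical cases (7 of whom progress), 8 healthy controls, and a
    1306-protein aptamer panel.
    """

    n_cases: int = 13
    n_controls: int = 8
    n_proteins: int = 1306
    n_progressors: int = 7
    sigma: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_proteins) <= 0:
            raise ValueError("cohort dimensions must be positive")
        if not 0 <= self.n_progressors <= self.n_cases:
            raise ValueError("n_progressors must lie in [0, n_cases]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _default_visits() -> tuple[float, ...]:
    return (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class ValidationDesign:
    """Validation-cohort design: visit-based follow-up under a
    proportional-hazards event model.

    Defaults emulate the validation stage: 50 subjects followed on a yearly
    visit schedule over a 5-year horizon, with the baseline (null-covariate)
    hazard calibrated so the 5-year cumulative progression risk is 40%.
    """

    n_subjects: int = 50
    n_proteins: int = 9
    baseline_hazard: float = -math.log(0.6) / 5.0  # 40% 5-year risk
    visit_times: tuple[float, ...] = field(default_factory=_default_visits)
    horizon: float = 5.0
    weibull_shape: float = 1.0
    sigma: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_proteins) <= 0:
            raise ValueError("cohort dimensions must be positive")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ValueError("hazard parameters must be positive")
        v = tuple(float(t) for t in self.visit_times)
        if len(v) == 0:
            raise ValueError("empty visit schedule")
        if v[0] <= 0 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("visit_times must be strictly increasing and start > 0")
        if self.horizon < v[0]:
            raise ValueError("horizon precedes the first visit")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "visit_times", v)


@dataclass(frozen=True)
class BaggingConfig:
    """Configuration of the bagged median-threshold screen.

    ``n_resamples`` bootstrap draws per protein (default 100),
    ``n_permutations`` outcome-label permutations for the step-down maxT
    adjustment (default 10,000), fold-change filter at ``fc_threshold``
    on the log2 scale (default 0.585, i.e. |1.5|-fold), family-wise level
    ``alpha`` (default 0.05).
    """

    n_resamples: int = 100
    n_permutations: int = 10_000
    fc_threshold: float = 0.585
    alpha: float = 0.05
    seed: int = 0
    direction: str = "in_bag"  # or "fc_sign"
    reuse_bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_resamples <= 0 or self.n_permutations <= 0:
            raise ValueError("resample/permutation counts must be positive")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.direction not in ("in_bag", "fc_sign"):
            raise ValueError("direction must be 'in_bag' or 'fc_sign'")


@dataclass(frozen=True)
class IntervalObservation:
    """Censoring interval (L, R] for one subject, in years from blood draw.

    ``L`` is the last progression-free assessment, ``R`` the first
    assessment with definite disease; ``R = inf`` encodes right censoring.
    """

    sample_id: str
    L: float
    R: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.L) or self.L < 0:
            raise ValueError(f"{self.sample_id}: L must be finite and >= 0")
        if not self.L < self.R:
            raise ValueError(f"{self.sample_id}: requires L < R (got L={self.L}, R={self.R})")

    @property
    def right_censored(self) -> bool:
        return math.isinf(self.R)


def intervals_to_arrays(obs: Sequence[IntervalObservation]) -> tuple[np.ndarray, np.ndarray]:
    """Stack observations into (L, R) float arrays (R may contain inf)."""
    L = np.array([o.L for o in obs], dtype=float)
    R = np.array([o.R for o in obs], dtype=float)
    return L, R


@dataclass(frozen=True)
class ICCoxFit:
    """Interval-censored proportional-hazards fit for one covariate."""

    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p: float
    boxcox_lambda: float | None = None
    n_iter: int = 0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.hr <= hi):
            raise ValueError("CI must bracket the hazard ratio")
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass(frozen=True)
class CutpointResult:
    """Maximal-logrank cutpoint for a continuous covariate."""

    threshold: float
    direction: str  # "high_risk" | "low_risk"
    q_statistic: float
    p: float

    def __post_init__(self) -> None:
        if self.direction not in ("high_risk", "low_risk"):
            raise ValueError("direction must be 'high_risk' or 'low_risk'")
        if self.q_statistic < 0:
            raise ValueError("q_statistic must be >= 0")


@dataclass
class TurnbullCurve:
    """Nonparametric MLE of the survival function under interval censoring.

    ``intervals`` are the innermost (Turnbull) intervals (q_j, p_j] carrying
    probability ``masses``; ``survival[j]`` is S(t) just after p_j (the
    curve is a right-continuous step function dropping at right endpoints).
    A final open interval (q_m, inf) may carry residual mass for subjects
    who never fail within the observed range.
    """

    intervals: list[tuple[float, float]]
    masses: np.ndarray
    survival: np.ndarray

    def survival_at(self, times) -> np.ndarray:
        """S(t) = P(T > t), right-continuous, undefined-by-convention flat
        inside innermost intervals (mass counted once its interval closes)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        rights = np.array([p for _, p in self.intervals])
        out = np.empty(t.shape)
        for i, ti in enumerate(t):
            out[i] = self.masses[rights > ti].sum()
        return out

    def to_frame(self):
        """Long-format step curve: time 0 at S=1, then one row per drop."""
        import pandas as pd

        times = [0.0] + [p for _, p in self.intervals if np.isfinite(p)]
        surv = [1.0] + [s for (_, p), s in zip(self.intervals, self.survival) if np.isfinite(p)]
        return pd.DataFrame({"time": times, "survival": surv})


@dataclass(frozen=True)
class GLRTResult:
    """Generalized (interval-censored) logrank test result."""

    statistic: float
    p: float
    n_permutations_used: int
    exact: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
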