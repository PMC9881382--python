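"""Optimal cutpoint for a continuous covariate by the maximal logrank
statistic (Contal & O'Quigley).

The interval-censored observations are first reduced to right-censored
form (events at the interval midpoint, censoring at the last
progression-free time).  For every admissible split of the covariate the
logrank score S_c (sum of the at-beta=0 martingale residuals over the
high group) is computed; the estimated cutpoint maximizes |S_c| and its
significance uses the supremum-of-Brownian-bridge approximation

    q = max|S_c| / (s * sqrt(D - 1)),  p ~= 2 * sum_k (-1)^(k+1) exp(-2 k^2 q^2)

with s^2 = (1/(D-1)) * sum_{i=1..D} (1 - a_i)^2, a_i = sum_{j<=i} 1/(D-j+1)
over the D event ranks.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .types import CutpointResult, IntervalObservation, intervals_to_arrays

__all__ = ["to_right_censored", "logrank_scores", "contal_oquigley_cutpoint"]


def to_right_censored(
    obs: Sequence[IntervalObservation], conversion: str = "midpoint"
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point reduction of censoring intervals.

    ``midpoint``: events at (L+R)/2; ``right_endpoint``: events at R.
    Right-censored subjects are censored at L either way.
    Returns (time, event_indicator).
    """
    if conversion not in ("midpoint", "right_endpoint"):
        raise ValueError("conversion must be 'midpoint' or 'right_endpoint'")
    L, R = intervals_to_arrays(obs)
    event = np.isfinite(R)
    time = np.where(event, (L + R) / 2.0 if conversion == "midpoint" else R, L)
    return time, event.astype(bool)


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject logrank (martingale at beta=0) residuals
    w_i = delta_i - NelsonAalen(t_i), handling tied event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    # Nelson-Aalen cumulative hazard evaluated at each subject's time
    uniq = np.unique(t_sorted[event[order]])
    na = 0.0
    cumhaz_at = {}
    for t in uniq:
        d = float(((time == t) & event).sum())
        r = float((time >= t).sum())
        na += d / r
        cumhaz_at[t] = na
    # step value of NA at arbitrary t: last event time <= t
    w = np.empty(len(time))
    ev_times = np.array(sorted(cumhaz_at))
    ev_vals = np.array([cumhaz_at[t] for t in ev_times])
    for i, (t, d) in enumerate(zip(time, event)):
        j = np.searchsorted(ev_times, t, side="right") - 1
        ch = ev_vals[j] if j >= 0 else 0.0
        w[i] = (1.0 if d else 0.0) - ch
    return w


def contal_oquigley_cutpoint(
    covariate: Sequence[float] | np.ndarray,
    obs: Sequence[IntervalObservation],
    conversion: str = "midpoint",
    trim: tuple[float, float] = (0.10, 0.90),
) -> CutpointResult:
    """Maximal-logrank cutpoint with Contal-O'Quigley inference.

    Candidate thresholds are the unique covariate values between the
    ``trim`` quantiles (default 10th-90th percentile), each defining the
    split low = {x < c} vs high = {x >= c}.  ``direction`` is ``high_risk``
    when the high stratum has excess events (positive score sum).
    """
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(obs):
        raise ValueError("covariate length mismatch")
    if np.unique(x).size < 2:
        raise ValueError("covariate is constant; no cutpoint exists")

    time, event = to_right_censored(obs, conversion)
    D = int(event.sum())
    if D < 1:
        raise ValueError("no events after right-censored conversion")

    lo, hi = np.quantile(x, trim)
    # candidate thresholds: smallest value of a nonempty high group
    cands = [c for c in np.unique(x) if lo <= c <= hi and (x < c).any()]
    if not cands:
        raise ValueError("no admissible candidate cutpoint in the trimmed range")

    w = logrank_scores(time, event)
    scores = np.array([w[x >= c].sum() for c in cands])
    k = int(np.argmax(np.abs(scores)))
    s_max = scores[k]

    if D > 1:
        a = np.cumsum(1.0 / (D - np.arange(D)))
        s2 = float(np.sum((1.0 - a) ** 2) / (D - 1))
        q = abs(s_max) / math.sqrt(s2 * (D - 1)) if s2 > 0 else 0.0
    else:
        q = 0.0
    terms = np.array([(-1) ** (j + 1) * math.exp(-2 * j * j * q * q) for j in range(1, 101)])
    p = float(np.clip(2 * terms.sum(), 0.0, 1.0)) if q > 0 else 1.0

    return CutpointResult(
        threshold=float(cands[k]),
        direction="high_risk" if s_max > 0 else "low_risk",
        q_statistic=float(q),
        p=p,
    )
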