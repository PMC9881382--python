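"""Turnbull nonparametric MLE of the survival function for
interval-censored data, via the self-consistency (EM) iteration.

Probability mass can only live on the "innermost" intervals (q, p] whose
left endpoint is an observed L, whose right endpoint is an observed R, and
whose interior contains no other observation endpoint; right-censored
subjects (R = inf) contribute a terminal open interval so residual mass can
sit beyond the last follow-up.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .types import IntervalObservation, TurnbullCurve, intervals_to_arrays

__all__ = ["innermost_intervals", "turnbull_npmle"]


def innermost_intervals(L: np.ndarray, R: np.ndarray) -> list[tuple[float, float]]:
    """Turnbull innermost intervals from the pooled endpoint sets.

    Scans the sorted endpoints; an interval opens at each L and closes at
    the first R at or after it with no L in between.  At equal values an R
    is placed before an L, since (x, x] is empty for half-open intervals.
    """
    pts = [(float(l), 1) for l in L] + [(float(r), 0) for r in R]
    pts.sort(key=lambda t: (t[0], t[1]))  # at ties, R before L: (x, x] is empty
    out: list[tuple[float, float]] = []
    open_left: float | None = None
    for v, kind in pts:
        if kind == 1:
            open_left = v  # a later L supersedes (innermost = tightest)
        elif open_left is not None:
            out.append((open_left, v))
            open_left = None
    return out


def turnbull_npmle(
    obs: Sequence[IntervalObservation],
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> TurnbullCurve:
    """Self-consistency EM for the NPMLE of S(t) under interval censoring.

    Iterates p_j <- mean_i( a_ij p_j / sum_k a_ik p_k ) until the largest
    mass change is below ``tol`` (default 1e-8, cap 10,000 iterations).
    """
    if len(obs) == 0:
        raise ValueError("empty observation list")
    L, R = intervals_to_arrays(obs)
    ivals = innermost_intervals(L, R)
    q = np.array([a for a, _ in ivals])
    p = np.array([b for _, b in ivals])

    # a_ij = 1 iff innermost interval j lies inside (L_i, R_i]
    A = (q[None, :] >= L[:, None]) & (p[None, :] <= R[:, None])
    if not A.any(axis=1).all():
        raise ValueError("an observation contains no innermost interval")

    m = len(ivals)
    masses = np.full(m, 1.0 / m)
    for _ in range(max_iter):
        w = A * masses[None, :]
        w /= w.sum(axis=1, keepdims=True)
        new = w.mean(axis=0)
        delta = np.abs(new - masses).max()
        masses = new
        if delta < tol:
            break

    survival = 1.0 - np.cumsum(masses)
    survival = np.clip(survival, 0.0, 1.0)
    return TurnbullCurve(intervals=ivals, masses=masses, survival=survival)
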