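"""Box-Cox normalization of positive abundance values."""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.optimize import minimize_scalar
from scipy.stats import boxcox_llf

__all__ = ["boxcox_transform"]


def boxcox_transform(
    values, lam_bounds: tuple[float, float] = (-2.0, 2.0)
) -> tuple[np.ndarray, float]:
    """Power-transform ``values`` with lambda chosen by profile maximum
    likelihood on ``lam_bounds``.

    The transform is (x**lam - 1)/lam, log(x) at lam = 0.  If any value is
    non-positive a shift of ``1e-6 - min(x)`` is applied first.
    Returns ``(transformed, lambda)``.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    if x.size < 2:
        raise ValueError("need at least two values")
    if x.min() <= 0:
        x = x + (1e-6 - x.min())

    res = minimize_scalar(
        lambda lam: -boxcox_llf(lam, x), bounds=lam_bounds, method="bounded"
    )
    lam = float(res.x)
    return special.boxcox(x, lam), lam
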