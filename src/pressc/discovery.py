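"""Stage-1 screen: fold-change filter, bagged out-of-bag accuracy of
median-threshold classifiers, and step-down maxT permutation FWER control.

For each protein surviving the |log2 FC| >= 0.585 filter against healthy
controls, a univariate classifier is scored on the cases only: in each of
``n_resamples`` bootstrap draws the in-bag median RFU is the threshold, the
classification direction (above-median = progressor, or the reverse) is the
one with the higher in-bag accuracy, and accuracy is tallied on the
out-of-bag cases from the 2x2 table.  Family-wise significance of the mean
OOB accuracies is assessed with the Westfall-Young step-down maxT
permutation procedure over outcome-label permutations.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .types import BaggingConfig

__all__ = [
    "log_fold_change",
    "filter_by_fc",
    "bagging_accuracy",
    "stepdown_maxt",
    "run_discovery",
]


def log_fold_change(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Per-protein log2 fold change: mean log2 abundance over cases minus
    mean log2 abundance over controls (= log2 of the geometric-mean ratio).
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values not allowed at the discovery stage")
    if (vals <= 0).any():
        raise ValueError("non-positive abundance value encountered")
    meta = meta.set_index("sample_id").loc[matrix.index]
    is_case = (meta["group"] == "case").to_numpy()
    if is_case.sum() < 1 or (~is_case).sum() < 1:
        raise ValueError("need at least one case and one control")
    log2 = np.log2(vals)
    fc = log2[is_case].mean(axis=0) - log2[~is_case].mean(axis=0)
    return pd.Series(fc, index=matrix.columns, name="log2_fc")


def filter_by_fc(fc: pd.Series, threshold: float) -> pd.Index:
    """Proteins with |log2 FC| >= threshold (two-sided, inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return fc.index[np.abs(fc.to_numpy()) >= threshold]


def _bag_geometry(values: np.ndarray, boot_idx: np.ndarray):
    """Bootstrap geometry shared across label permutations.

    values : (n, K) case-level abundances; boot_idx : (B, n) in-bag draws.
    Returns in-bag count matrix C (B, n), OOB mask (B, n) and the
    above-median indicator (B, n, K) with the tie rule "equal to the median
    counts as at/below".
    """
    B, n = boot_idx.shape
    C = np.zeros((B, n))
    rows = np.repeat(np.arange(B), n)
    np.add.at(C, (rows, boot_idx.ravel()), 1.0)
    oob = C == 0
    med = np.median(values[boot_idx], axis=1)  # (B, K): multiplicity-weighted
    above = values[None, :, :] > med[:, None, :]
    return C, oob, above


def _oob_accuracy(
    values: np.ndarray,
    Y: np.ndarray,
    boot_idx: np.ndarray,
    direction: str = "in_bag",
    fc_sign: np.ndarray | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Mean OOB accuracy for every (labelling, protein) pair.

    values : (n, K); Y : (P, n) boolean progressor labels; boot_idx : (B, n).
    Returns (P, K).  Vectorized via the identity
    #correct = 2*sum(w*above*y) + sum(w) - sum(w*above) - sum(w*y)
    for weights w = in-bag counts (direction choice) or OOB mask (scoring);
    the opposite direction flips every prediction, so its accuracy is the
    complement.
    """
    n, K = values.shape
    P = Y.shape[0]
    C, oob, above = _bag_geometry(values, boot_idx)
    keep = oob.any(axis=1)
    if not keep.any():
        raise ValueError("every bootstrap resample had an empty out-of-bag set")
    C, oob, above = C[keep], oob[keep], above[keep]  # skip empty-OOB resamples
    B = C.shape[0]

    Cab = C[:, :, None] * above  # (B, n, K)
    Oab = oob[:, :, None] * above
    A1 = Cab.sum(axis=1)  # (B, K) in-bag above counts
    B1 = Oab.sum(axis=1)  # (B, K) OOB above counts
    Osz = oob.sum(axis=1)  # (B,), all > 0 after the skip above

    Yf = Y.astype(float)
    out = np.empty((P, K))
    for s in range(0, P, chunk):
        Yc = Yf[s : s + chunk]  # (p, n)
        T1 = np.einsum("pi,bik->pbk", Yc, Cab)  # in-bag above & progressor
        T2 = Yc @ C.T  # (p, B) in-bag progressor count
        U1 = np.einsum("pi,bik->pbk", Yc, Oab)
        U2 = Yc @ oob.T.astype(float)

        ib_above = (2 * T1 + n - A1[None] - T2[:, :, None]) / n
        if direction == "fc_sign":
            above_dir = np.broadcast_to(fc_sign[None, None, :] >= 0, ib_above.shape)
        else:
            above_dir = ib_above >= 0.5  # tie -> above-median predicts progressor

        oob_above = (2 * U1 + Osz[None, :, None] - B1[None] - U2[:, :, None]) / Osz[
            None, :, None
        ]
        acc = np.where(above_dir, oob_above, 1.0 - oob_above)
        out[s : s + chunk] = acc.mean(axis=1)
    return out


def bagging_accuracy(
    values: np.ndarray,
    outcome: np.ndarray,
    cfg: BaggingConfig | None = None,
    rng: np.random.Generator | None = None,
    bootstrap_indices: np.ndarray | None = None,
) -> float:
    """Bagged OOB accuracy of the median-threshold classifier for one protein.

    ``values`` are the case-level abundances, ``outcome`` the boolean
    progressor labels.  Resamples whose OOB set is empty are skipped.
    """
    cfg = cfg or BaggingConfig()
    values = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if values.size == 0:
        raise ValueError("empty values")
    if y.all() or not y.any():
        raise ValueError("outcome must contain both classes")
    if bootstrap_indices is None:
        rng = rng or np.random.default_rng(cfg.seed)
        bootstrap_indices = rng.integers(0, len(y), size=(cfg.n_resamples, len(y)))
    acc = _oob_accuracy(values[:, None], y[None, :], bootstrap_indices, cfg.direction)
    return float(acc[0, 0])


def _all_label_permutations(y: np.ndarray) -> np.ndarray:
    """All distinct relabellings preserving the progressor count."""
    from itertools import combinations

    n, k = len(y), int(y.sum())
    out = np.zeros((math.comb(n, k), n), dtype=bool)
    for r, idx in enumerate(combinations(range(n), k)):
        out[r, list(idx)] = True
    return out


def stepdown_maxt(
    case_matrix: pd.DataFrame,
    outcome: np.ndarray,
    cfg: BaggingConfig | None = None,
    permutations: np.ndarray | str | None = None,
    bootstrap_indices: np.ndarray | None = None,
    fc: pd.Series | None = None,
) -> pd.DataFrame:
    """Westfall-Young step-down maxT adjustment of bagged OOB accuracies.

    Labels are permuted across the cases only; by default the bootstrap
    index sets are drawn once and reused for every permutation
    (``cfg.reuse_bootstrap=False`` redraws them per permutation).
    ``permutations`` may be an explicit (P, n) boolean label array or
    ``"exhaustive"`` to enumerate all distinct labellings.

    Returns a DataFrame sorted by observed accuracy (descending) with
    columns ``protein_id, bag_accuracy, p_adj, significant``.
    """
    cfg = cfg or BaggingConfig()
    values = case_matrix.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=bool)
    n, K = values.shape
    if K < 1:
        raise ValueError("need at least one protein")
    if y.all() or not y.any():
        raise ValueError("outcome must contain both classes")
    if math.comb(n, int(y.sum())) < 2:
        raise ValueError("fewer than 2 distinct label permutations possible")

    rng = np.random.default_rng(cfg.seed)
    if bootstrap_indices is None:
        bootstrap_indices = rng.integers(0, n, size=(cfg.n_resamples, n))

    fc_sign = None
    if cfg.direction == "fc_sign":
        if fc is None:
            raise ValueError("direction='fc_sign' requires the fold-change vector")
        fc_sign = fc.loc[case_matrix.columns].to_numpy(dtype=float)

    if isinstance(permutations, str) and permutations == "exhaustive":
        Y = _all_label_permutations(y)
    elif permutations is not None:
        Y = np.asarray(permutations, dtype=bool)
    else:
        u = rng.random((cfg.n_permutations, n))
        Y = y[np.argsort(u, axis=1)]

    obs = _oob_accuracy(values, y[None, :], bootstrap_indices, cfg.direction, fc_sign)[0]
    if cfg.reuse_bootstrap:
        perm = _oob_accuracy(values, Y, bootstrap_indices, cfg.direction, fc_sign)
    else:
        perm = np.empty((Y.shape[0], K))
        for p in range(Y.shape[0]):
            bi = rng.integers(0, n, size=(cfg.n_resamples, n))
            perm[p] = _oob_accuracy(values, Y[p][None, :], bi, cfg.direction, fc_sign)[0]

    order = np.argsort(-obs, kind="stable")
    # successive maxima over the not-yet-rejected set (observed ordering)
    run_max = np.maximum.accumulate(perm[:, order][:, ::-1], axis=1)[:, ::-1]
    exceed = (run_max >= obs[order][None, :] - 1e-9).sum(axis=0)
    p_sorted = (1.0 + exceed) / (Y.shape[0] + 1.0)
    p_sorted = np.maximum.accumulate(p_sorted)  # enforce step-down monotonicity

    return pd.DataFrame(
        {
            "protein_id": case_matrix.columns[order],
            "bag_accuracy": obs[order],
            "p_adj": p_sorted,
            "significant": p_sorted <= cfg.alpha,
        }
    ).reset_index(drop=True)


def run_discovery(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    cfg: BaggingConfig | None = None,
    permutations: np.ndarray | str | None = None,
) -> pd.DataFrame:
    """Full stage-1 screen: FC filter vs controls, then bagging + maxT on
    the cases.  Returns the ranked discovery table (accuracy descending)
    with columns ``protein_id, log2_fc, bag_accuracy, p_adj, significant``.
    """
    cfg = cfg or BaggingConfig()
    fc = log_fold_change(matrix, meta)
    kept = filter_by_fc(fc, cfg.fc_threshold)
    cols = ["protein_id", "log2_fc", "bag_accuracy", "p_adj", "significant"]
    if len(kept) == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             zip(cols, [str, float, float, float, bool])})

    m = meta.set_index("sample_id").loc[matrix.index]
    is_case = (m["group"] == "case").to_numpy()
    y = (m.loc[is_case, "outcome"] == "progressor").to_numpy()
    case_matrix = matrix.loc[is_case, kept]
    table = stepdown_maxt(case_matrix, y, cfg, permutations=permutations, fc=fc)
    table.insert(1, "log2_fc", fc.loc[table["protein_id"]].to_numpy())
    return table[cols]
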