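"""Slow, loop-based reference implementations used as independent oracles.

Everything here is deliberately naive (explicit loops, no shared code with
the package internals beyond public dataclasses) so that agreement with the
vectorized implementations is evidence, not tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def oracle_bag_accuracy(values, y, boot_idx):
    """Mean OOB accuracy of the median-threshold classifier, by loops."""
    values = np.asarray(values, float)
    y = np.asarray(y, bool)
    n = len(y)
    accs = []
    for bag in boot_idx:
        oob = sorted(set(range(n)) - set(bag.tolist()))
        if not oob:
            continue
        med = np.median(values[bag])
        # direction above -> progressor, evaluated on the in-bag multiset
        correct_above = sum((values[i] > med) == y[i] for i in bag)
        acc_above = correct_above / len(bag)
        direction_above = acc_above >= 0.5  # tie -> above
        ncorr = 0
        for i in oob:
            pred = (values[i] > med) if direction_above else (values[i] <= med)
            ncorr += pred == y[i]
        accs.append(ncorr / len(oob))
    return float(np.mean(accs))


def oracle_westfall_young(values, y, boot_idx, label_perms, n_plus_one=True):
    """Step-down maxT adjusted p-values by explicit enumeration.

    ``values``: (n, K); ``label_perms``: (P, n) boolean labelings.
    Returns (order, p_adj) with proteins sorted by observed accuracy desc.
    """
    values = np.asarray(values, float)
    K = values.shape[1]
    obs = np.array([oracle_bag_accuracy(values[:, k], y, boot_idx) for k in range(K)])
    perm = np.array(
        [
            [oracle_bag_accuracy(values[:, k], lab, boot_idx) for k in range(K)]
            for lab in label_perms
        ]
    )  # (P, K)
    order = np.argsort(-obs, kind="stable")
    P = len(label_perms)
    p = np.empty(K)
    for r, k in enumerate(order):
        count = 0
        for b in range(P):
            if max(perm[b, order[r:]]) >= obs[k] - 1e-9:
                count += 1
        p[r] = (1 + count) / (P + 1)
    for r in range(1, K):
        p[r] = max(p[r], p[r - 1])
    return order, p


def oracle_npmle(obs, n_starts=5, seed=0):
    """Brute-force NPMLE: maximize the interval-censored likelihood over the
    probability simplex on independently-derived candidate intervals."""
    from scipy.optimize import minimize

    L = np.array([o.L for o in obs])
    R = np.array([o.R for o in obs])
    endpoints = sorted(set(L.tolist()) | set(R[np.isfinite(R)].tolist()))
    # candidate intervals: (l, r] with l in L-set, r in R-set, no endpoint inside
    cands = []
    rset = set(R.tolist())
    for l in sorted(set(L.tolist())):
        for r in sorted(rset):
            if r <= l:
                continue
            inside = [e for e in endpoints if l < e < r]
            if not inside:
                cands.append((l, r))
    A = np.array([[(ql >= li and qr <= ri) for (ql, qr) in cands] for li, ri in zip(L, R)], float)

    def nll(p):
        lik = A @ p
        if (lik <= 0).any():
            return 1e12
        return -np.log(lik).sum()

    m = len(cands)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = rng.dirichlet(np.ones(m)) if s else np.full(m, 1.0 / m)
        res = minimize(
            nll,
            x0,
            method="SLSQP",
            bounds=[(0, 1)] * m,
            constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1}],
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    return cands, np.maximum(best.x, 0.0)


def oracle_knn_impute(table, k=3):
    """All-pairs-distance kNN imputation by loops (z-scored shared columns)."""
    X = table.to_numpy(float).copy()
    n, p = X.shape
    obs = np.isfinite(X)
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    out = X.copy()
    for i in range(n):
        for c in range(p):
            if obs[i, c]:
                continue
            dists = []
            for j in range(n):
                if j == i or not obs[j, c]:
                    continue
                shared = [q for q in range(p) if obs[i, q] and obs[j, q]]
                if not shared:
                    continue
                d2 = sum((Z[i, q] - Z[j, q]) ** 2 for q in shared)
                dists.append((math.sqrt(d2), j))
            dists.sort(key=lambda t: (t[0], t[1]))
            nearest = [j for _, j in dists[:k]]
            out[i, c] = np.mean([X[j, c] for j in nearest])
    return out


def oracle_logrank_numerator(time, event, high):
    """Observed-minus-expected events in the high group, by loops."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    high = np.asarray(high, bool)
    U = 0.0
    for t in sorted(set(time[event].tolist())):
        at_risk = time >= t
        d = event & (time == t)
        U += d[high].sum() - d.sum() * at_risk[high].sum() / at_risk.sum()
    return U


def oracle_glrt_exact_p(u, group):
    """Exact permutation p for the centred-score statistic, by enumeration."""
    u = np.asarray(u, float)
    uc = u - u.mean()
    x = np.asarray(group, bool)
    n, n1 = len(u), int(x.sum())
    t_obs = abs(uc[x].sum())
    count = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(sum(uc[list(idx)])) >= t_obs - 1e-12:
            count += 1
    return count / total
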