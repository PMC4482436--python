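"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive pairwise distances,
full sign-flip enumeration, literal formula transcription) and shares no
code with the package's accelerated paths.
"""
from __future__ import annotations

import itertools

import numpy as np


def brute_knn_total_distance(X: np.ndarray, i: int, k: int) -> float:
    d = [np.sqrt(((X[i] - X[j]) ** 2).sum()) for j in range(len(X)) if j != i]
    return float(sum(sorted(d)[:k]))


def brute_alpha_mi(zf, zm, k, alpha, denominator="product", eps=1e-10):
    """Literal transcription of the kNN-graph alpha-MI with exhaustive search."""
    zf = np.asarray(zf, dtype=float)
    zm = np.asarray(zm, dtype=float)
    n, d = zf.shape
    zfm = np.concatenate([zf, zm], axis=1)

    def gammas(X):
        out = np.empty(n)
        for i in range(n):
            dists = sorted(
                np.sqrt(((X[i] - X[j]) ** 2).sum()) for j in range(n) if j != i
            )
            out[i] = sum(dists[:k])
        return np.maximum(out, eps)

    gf, gm, gfm = gammas(zf), gammas(zm), gammas(zfm)
    den = gf * gm if denominator == "product" else np.sqrt(gf * gm)
    gamma = d * (1.0 - alpha)
    s = float(np.sum((gfm / den) ** (2.0 * gamma)))
    return (np.log(s) - alpha * np.log(n)) / (alpha - 1.0)


def wilcoxon_exact_enumeration(x, y):
    """Exact two-sided signed-rank p-value by enumerating all sign flips.

    Drops zero differences, ranks |d| (average ranks on ties), computes
    W+ and, under the exchangeable-sign null, sums the probability of both
    tails: P(W+ <= min(W+, W-)) + P(W+ >= max(W+, W-)).
    """
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # average ranks for ties
    for v in np.unique(absd):
        m = absd == v
        ranks[m] = ranks[m].mean()
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= lo + 1e-12 or w >= hi - 1e-12:
            count += 1
    return count / 2 ** n


def directional_fd(fun, flat_params, direction, eps):
    """Central finite difference of ``fun`` along ``direction`` in place."""
    flat_params += eps * direction
    fp = fun()
    flat_params -= 2 * eps * direction
    fm = fun()
    flat_params += eps * direction
    return (fp - fm) / (2 * eps)
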