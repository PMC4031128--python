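"""Independent reference implementations used only by the test suite."""

from math import comb

import numpy as np


def nipals_pls2(X: np.ndarray, Y: np.ndarray, K: int,
                tol: float = 1e-12, max_iter: int = 5000):
    """Dense PLS2 via classical NIPALS iteration (regression mode).

    Returns (W, P, Q, T) with each direction vector sign-normalised so its
    largest-magnitude entry is positive. Independent of the package's
    SVD-based implementation.
    """
    Xk = X - X.mean(axis=0)
    Yk = Y.astype(float).copy()
    n, p = Xk.shape
    G = Yk.shape[1]
    W = np.zeros((p, K))
    P = np.zeros((p, K))
    Q = np.zeros((G, K))
    T = np.zeros((n, K))
    for k in range(K):
        u = Yk[:, int(np.argmax((Yk ** 2).sum(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = Xk.T @ u
            w /= np.linalg.norm(w)
            t = Xk @ w
            q = Yk.T @ t / (t @ t)
            u = Yk @ q / (q @ q)
            if np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        jmax = int(np.argmax(np.abs(w)))
        if w[jmax] < 0:
            w, t, q = -w, -t, -q
        q = Yk.T @ t / (t @ t)
        p_load = Xk.T @ t / (t @ t)
        W[:, k] = w
        P[:, k] = p_load
        Q[:, k] = q
        T[:, k] = t
        Xk = Xk - np.outer(t, p_load)
        Yk = Yk - np.outer(t, q)
    return W, P, Q, T


def expected_rarefied_richness(counts, depth: int) -> float:
    """Exact expected number of nonzero taxa after subsampling without
    replacement, by the hypergeometric absence probability per taxon."""
    counts = list(int(c) for c in counts)
    total = sum(counts)
    e = 0.0
    for c in counts:
        absent = comb(total - c, depth) / comb(total, depth) if total - c >= depth else 0.0
        e += 1.0 - absent
    return e


def pooled_ttest(a, b):
    """Closed-form pooled two-sample t statistic and two-sided p."""
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)
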