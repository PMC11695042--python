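"""Independent reference implementations used as oracles in the tests.

Everything here is written directly from the textbook definitions
(brute-force loops, closed forms) and deliberately shares no code with the
package internals it checks.
"""

from __future__ import annotations

import numpy as np


def nipals_pls1(X, y, n_components):
    """Standard orthogonal-scores NIPALS PLS1 on centred/scaled data.

    Returns (W, P, q) with unit-norm weight columns.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    Ws, Ps, qs = [], [], []
    for _ in range(n_components):
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = float(t @ t)
        p = X.T @ t / tt
        q = float(y @ t) / tt
        X = X - np.outer(t, p)
        y = y - t * q
        Ws.append(w)
        Ps.append(p)
        qs.append(q)
    return np.column_stack(Ws), np.column_stack(Ps), np.array(qs)


def nipals_pls1_predict(X_scaled, W, P, q):
    """Deflation-based prediction for the NIPALS model (scaled response)."""
    E = np.array(X_scaled, dtype=float)
    yhat = np.zeros(E.shape[0])
    for r in range(q.size):
        t = E @ W[:, r]
        E = E - np.outer(t, P[:, r])
        yhat = yhat + t * q[r]
    return yhat


def vip_single_block(X_scaled, y_scaled, n_components):
    """Standard single-block PLS VIP from the NIPALS fit."""
    X = np.array(X_scaled, dtype=float)
    y = np.array(y_scaled, dtype=float)
    p = X.shape[1]
    W, P, q = nipals_pls1(X, y, n_components)
    # recompute scores on the training data by deflation
    E = X.copy()
    ss = np.empty(n_components)
    for r in range(n_components):
        t = E @ W[:, r]
        E = E - np.outer(t, P[:, r])
        ss[r] = q[r] ** 2 * float(t @ t)
    vip = np.empty(p)
    for j in range(p):
        acc = 0.0
        for r in range(n_components):
            acc += ss[r] * (W[j, r] / np.linalg.norm(W[:, r])) ** 2
        vip[j] = np.sqrt(p * acc / ss.sum())
    return vip


def brute_total_within_ss(points, labels):
    """Double-loop within-cluster sum of squares; labels are 1-based."""
    points = np.asarray(points, dtype=float)
    total = 0.0
    for c in np.unique(labels):
        members = points[labels == c]
        mu = members.mean(axis=0)
        for row in members:
            total += float(np.sum((row - mu) ** 2))
    return total


def brute_silhouette(points, labels):
    """Pairwise-distance silhouette, straight from the definition."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    clusters = np.unique(labels)
    scores = []
    for i in range(n):
        own = labels[i]
        own_members = [j for j in range(n) if labels[j] == own and j != i]
        if not own_members:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in own_members])
        b = min(
            np.mean(
                [np.linalg.norm(points[i] - points[j]) for j in range(n) if labels[j] == c]
            )
            for c in clusters
            if c != own
        )
        m = max(a, b)
        scores.append(0.0 if m == 0 else (b - a) / m)
    return float(np.mean(scores))


def ols_coefficients(X, y):
    """Closed-form least squares via the normal equations."""
    X = np.asarray(X, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def mbpls_straightline(X, y, blocks, n_components):
    """Literal transcription of the multiblock component loop, step by step.

    Independent of the package implementation: plain loops, no shared
    helpers.  Returns a dict with every intermediate quantity per component.
    """
    E = np.array(X, dtype=float)
    f = np.array(y, dtype=float)
    n = E.shape[0]
    out = {"u": [], "s": [], "S": [], "w": [], "t": [], "p": [], "q": []}
    for _ in range(n_components):
        us, ss = [], []
        for idx in blocks:
            z = E[:, idx].T @ f
            u = z / np.linalg.norm(z)
            us.append(u)
            ss.append(E[:, idx] @ u)
        S = np.zeros((n, len(blocks)))
        for c, idx in enumerate(blocks):
            S[:, c] = ss[c] / len(idx)
        w = S.T @ f
        w = w / np.linalg.norm(w)
        t = S @ w
        tt = float(t @ t)
        p_r = E.T @ t / tt
        q_r = float(f @ t) / tt
        E = E - np.outer(t, p_r)
        f = f - t * q_r
        out["u"].append(us)
        out["s"].append(ss)
        out["S"].append(S)
        out["w"].append(w)
        out["t"].append(t)
        out["p"].append(p_r)
        out["q"].append(q_r)
    return out
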