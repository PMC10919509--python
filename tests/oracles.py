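"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the package's own implementations: the GLCM
oracle is a per-pixel double loop, the AUC oracle counts concordant pairs,
and the logistic-regression oracle is a plain Newton-Raphson iteration.
"""

from __future__ import annotations

import numpy as np

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(img, mask, L, d, theta, symmetric=True):
    """O(N) per-pixel pair counting with explicit loops."""
    levels = np.minimum((np.asarray(img, float) * L).astype(int), L - 1)
    dr, dc = ANGLE_OFFSETS[theta][0] * d, ANGLE_OFFSETS[theta][1] * d
    h, w = mask.shape
    counts = np.zeros((L, L))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def brute_force_auc(y_true, scores, positive_label):
    """Concordant-pair counting (ties count 1/2)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, float)
    pos = s[y == positive_label]
    neg = s[y != positive_label]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_fom(ref_edges, test_edges, alpha):
    """Double-loop nearest-reference-distance FOM."""
    ref = np.argwhere(np.asarray(ref_edges, bool))
    tst = np.argwhere(np.asarray(test_edges, bool))
    total = 0.0
    for t in tst:
        d2 = ((ref - t) ** 2).sum(axis=1).min()
        total += 1.0 / (1.0 + alpha * d2)
    return total / max(len(ref), len(tst))


def newton_logistic(X, y, iterations=50, tol=1e-10):
    """Maximum-likelihood logistic fit by Newton-Raphson.

    Returns (alpha, beta) for y in {0,1}.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    A = np.hstack([np.ones((X.shape[0], 1)), X])
    theta = np.zeros(A.shape[1])
    for _ in range(iterations):
        z = A @ theta
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        grad = A.T @ (y - p)
        W = p * (1 - p)
        H = (A * W[:, None]).T @ A + 1e-10 * np.eye(A.shape[1])
        step = np.linalg.solve(H, grad)
        theta = theta + step
        if np.abs(step).max() < tol:
            break
    return theta[0], theta[1:]


def two_class_lda_direction(X, y):
    """Closed-form Fisher direction Sw^{-1} (mu1 - mu0)."""
    X = np.asarray(X, float)
    classes = np.unique(y)
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Sw = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    return np.linalg.solve(Sw, mu1 - mu0)


def cosine(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
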