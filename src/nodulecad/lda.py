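"""Supervised linear dimensionality reduction (Fisher discriminant).

Solves the generalized eigenproblem Sb w = lambda Sw w for the projection
that maximizes between-class over within-class scatter, with optional
diagonal shrinkage of Sw for singular small-sample problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .errors import ValidationError


@dataclass
class LDAProjection:
    W: np.ndarray                 # (features, components)
    class_means: dict[str, np.ndarray]
    classes: list
    Sw: np.ndarray
    Sb: np.ndarray
    n_components: int
    eigenvalues: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "W": self.W.tolist(),
            "classes": [str(c) for c in self.classes],
            "class_means": {k: v.tolist() for k, v in self.class_means.items()},
            "n_components": self.n_components,
            "eigenvalues": self.eigenvalues.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LDAProjection":
        p = json.loads(Path(path).read_text())
        W = np.asarray(p["W"], float)
        d = W.shape[0]
        return cls(
            W=W,
            class_means={k: np.asarray(v, float) for k, v in p["class_means"].items()},
            classes=p["classes"],
            Sw=np.zeros((d, d)),
            Sb=np.zeros((d, d)),
            n_components=int(p["n_components"]),
            eigenvalues=np.asarray(p["eigenvalues"], float),
        )


def scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Within-class (Sw) and between-class (Sb) scatter, plus class means."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    mean = X.mean(axis=0)
    d = X.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    means = {}
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        means[str(c)] = mc
        dev = Xc - mc
        Sw += dev.T @ dev
        diff = (mc - mean)[:, None]
        Sb += Xc.shape[0] * (diff @ diff.T)
    return Sw, Sb, means


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    shrinkage: float = 1e-4,
) -> LDAProjection:
    """Fit the discriminant projection.

    ``Sw`` is regularized as (1-s)*Sw + s*diag(Sw). Columns of W are the
    top generalized eigenvectors, each with its first nonzero element made
    positive so the fit is deterministic.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("LDA requires at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValidationError(f"class {c!r} needs at least 2 samples")
    max_comp = classes.size - 1
    if n_components is None:
        n_components = max_comp
    if not (1 <= n_components <= max_comp):
        raise ValidationError(f"n_components must be in [1, {max_comp}]")

    Sw, Sb, means = scatter_matrices(X, y)
    s = float(shrinkage)
    Sw_reg = (1.0 - s) * Sw + s * np.diag(np.diag(Sw))
    if s > 0:
        # tiny ridge floor so constant features (zero diagonal) stay
        # invertible without influencing the solution direction
        Sw_reg = Sw_reg + 1e-12 * max(np.trace(Sw) / X.shape[1], 1.0) * np.eye(X.shape[1])
    try:
        evals, evecs = linalg.eigh(Sb, Sw_reg)
    except linalg.LinAlgError as exc:
        raise ValidationError(
            "within-class scatter is singular; increase the shrinkage parameter"
        ) from exc
    order = np.argsort(evals)[::-1][:n_components]
    W = evecs[:, order]
    evals = evals[order]
    # unit-norm columns: invariant to sample duplication (which rescales Sw)
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    # deterministic sign: first element with non-negligible magnitude positive
    for j in range(W.shape[1]):
        col = W[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * np.abs(col).max())[0]
        if nz.size and col[nz[0]] < 0:
            W[:, j] = -col
    return LDAProjection(
        W=W,
        class_means=means,
        classes=list(classes),
        Sw=Sw,
        Sb=Sb,
        n_components=n_components,
        eigenvalues=evals,
    )


def transform(p: LDAProjection, X: np.ndarray) -> np.ndarray:
    """Project X onto the fitted discriminant axes: X @ W."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != p.W.shape[0]:
        raise ValidationError(
            f"expected {p.W.shape[0]} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    return X @ p.W


def fisher_ratio(X: np.ndarray, y: np.ndarray, W: np.ndarray) -> float:
    """tr(W' Sb W) / tr(W' Sw W) — separation quality of a projection."""
    Sw, Sb, _ = scatter_matrices(X, y)
    num = float(np.trace(W.T @ Sb @ W))
    den = float(np.trace(W.T @ Sw @ W))
    return num / den if den > 0 else np.inf
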