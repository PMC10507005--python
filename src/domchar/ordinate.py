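"""Ordination of samples on Bray-Curtis dissimilarities, with permutation
fitting of compositional descriptors.

Principal coordinate analysis (PCoA, classical metric scaling) embeds the
samples from the dissimilarity matrix via Gower double centering and a
symmetric eigendecomposition; negative eigenvalues are reported rather than
corrected. Descriptors are then fitted post hoc as directions in the
ordination plane, with significance assessed by permuting the descriptor
across samples (vegan's envfit procedure, re-derived here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "OrdinationResult",
    "envfit",
    "EnvfitResult",
    "envfit_table",
]


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    total = float(np.sum(x + y))
    if total == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.sum(np.abs(x - y)) / total)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample columns."""
    samples = list(table.columns)
    x = table.to_numpy(float).T  # samples x formulas
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(x[i], x[j])
    return pd.DataFrame(d, index=samples, columns=samples)


@dataclass
class OrdinationResult:
    """Sample scores, eigenvalues and explained-variability proportions."""

    scores: pd.DataFrame          # samples x retained (positive) axes
    eigenvalues: np.ndarray       # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues, per retained axis
    fitted_vectors: pd.DataFrame | None = field(default=None)

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def pcoa(d: pd.DataFrame | np.ndarray) -> OrdinationResult:
    """Classical metric scaling of a symmetric dissimilarity matrix.

    Double-centers -d^2/2, eigendecomposes, and scales the eigenvectors of
    positive eigenvalues by sqrt(eigenvalue). Axis signs are fixed by making
    each axis's largest-magnitude coordinate positive, so results are
    deterministic. Explained proportions are taken over the positive
    eigenvalues only; negative eigenvalues are kept in ``eigenvalues`` for
    inspection.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        dm = d.to_numpy(float)
    else:
        dm = np.asarray(d, dtype=float)
        labels = [f"s{i}" for i in range(dm.shape[0])]
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    pos = eigval > tol
    scores = eigvec[:, pos] * np.sqrt(eigval[pos])
    # deterministic orientation
    for k in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, k])))
        if scores[i, k] < 0:
            scores[:, k] = -scores[:, k]
    pos_sum = eigval[pos].sum()
    proportion = eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=labels, columns=cols),
        eigenvalues=eigval,
        proportion_explained=proportion,
    )


@dataclass
class EnvfitResult:
    """One descriptor fitted as a direction in the ordination plane."""

    descriptor: str
    direction: np.ndarray     # unit vector over the fitted axes
    r2: float
    p_value: float
    significant: bool
    n_perm: int
    degenerate: bool = False


def _r2_against_scores(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """r^2 of y (columns) regressed on the orthonormalized centered scores."""
    yc = y - y.mean(axis=0, keepdims=True)
    ss_tot = (yc**2).sum(axis=0)
    proj = q.T @ yc
    ss_fit = (proj**2).sum(axis=0)
    return ss_fit / ss_tot


def envfit(
    result: OrdinationResult,
    descriptor: pd.Series | np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.1,
    n_axes: int = 2,
    rng: np.random.Generator | int | None = None,
    name: str = "descriptor",
) -> EnvfitResult:
    """Fit a per-sample descriptor to the first ``n_axes`` ordination axes.

    Least-squares regression of the descriptor on the axis scores gives r^2
    and the direction cosines; the permutation p-value is
    (1 + #{permuted r^2 >= observed}) / (1 + n_perm). A constant descriptor
    has no defined direction and returns a flagged null result.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(descriptor, pd.Series):
        y = descriptor.reindex(result.scores.index).to_numpy(float)
        name = descriptor.name or name
    else:
        y = np.asarray(descriptor, dtype=float)
    if y.shape[0] != result.scores.shape[0]:
        raise ValueError("descriptor length must match the number of samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("descriptor contains non-finite values")
    rng = np.random.default_rng(rng)

    k = min(n_axes, result.scores.shape[1])
    x = result.scores.to_numpy()[:, :k]
    xc = x - x.mean(axis=0, keepdims=True)
    if np.ptp(y) == 0:
        return EnvfitResult(
            descriptor=name, direction=np.zeros(k), r2=float("nan"),
            p_value=float("nan"), significant=False, n_perm=n_perm,
            degenerate=True,
        )
    q, _ = np.linalg.qr(xc)

    r2_obs = float(_r2_against_scores(q, y[:, None])[0])
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), xc]), y, rcond=None)
    direction = coef[1:]
    norm = np.linalg.norm(direction)
    if norm > 0:
        direction = direction / norm

    # one permutation per column, drawn via argsort of uniform noise
    perms = y[np.argsort(rng.random((n_perm, len(y))), axis=1)].T
    r2_perm = _r2_against_scores(q, perms)
    p = (1.0 + float((r2_perm >= r2_obs - 1e-12).sum())) / (1.0 + n_perm)
    return EnvfitResult(
        descriptor=name, direction=direction, r2=r2_obs, p_value=p,
        significant=p < alpha, n_perm=n_perm,
    )


def envfit_table(
    result: OrdinationResult,
    descriptors: pd.DataFrame,
    n_perm: int = 10_000,
    alpha: float = 0.1,
    n_axes: int = 2,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fit every descriptor column; one row per descriptor."""
    rng = np.random.default_rng(seed)
    rows = []
    for col in descriptors.columns:
        r = envfit(
            result, descriptors[col], n_perm=n_perm, alpha=alpha,
            n_axes=n_axes, rng=rng, name=col,
        )
        row = {"descriptor": col, "r2": r.r2, "p": r.p_value,
               "significant": r.significant}
        for k, v in enumerate(r.direction):
            row[f"d{'xy'[k] if k < 2 else k + 1}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("descriptor")
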