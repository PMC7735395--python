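"""Metric multidimensional scaling of a genetic distance matrix.

The embedding is initialized by classical (Torgerson) scaling and then
refined by SMACOF majorization, whose Guttman transform guarantees a
non-increasing raw-stress sequence.  Convergence is monitored on the
S-stress (formula 1, the normalized squared-distance stress) with a
default tolerance of 0.001 and at most 30 iterations; Kruskal stress-1
is reported alongside for comparability with other MDS software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .popgen import DistanceMatrix


@dataclass
class Embedding:
    labels: list
    coords: np.ndarray          # (n, dims)
    s_stress: float             # S-stress formula 1 at the final configuration
    kruskal_stress: float       # Kruskal stress-1 at the final configuration
    iterations: int
    converged: bool
    stress_sequence: np.ndarray  # majorized (normalized raw) stress per iteration

    def write_tsv(self, path) -> None:
        import pandas as pd

        cols = [f"dim{k + 1}" for k in range(self.coords.shape[1])]
        pd.DataFrame(self.coords, index=self.labels, columns=cols).to_csv(
            path, sep="\t", index_label="label"
        )


def _torgerson(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    lam = np.maximum(w[order], 0.0)
    return v[:, order] * np.sqrt(lam)


def _pdist_matrix(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _raw_stress(d: np.ndarray, delta: np.ndarray) -> float:
    num = ((d - delta) ** 2).sum()
    den = (delta**2).sum()
    return float(num / den) if den > 0 else 0.0


def _s_stress(d: np.ndarray, delta: np.ndarray) -> float:
    num = ((d**2 - delta**2) ** 2).sum()
    den = (delta**4).sum()
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def _kruskal(d: np.ndarray, delta: np.ndarray) -> float:
    den = (d**2).sum()
    return float(np.sqrt(((d - delta) ** 2).sum() / den)) if den > 0 else 0.0


def mds(
    D: DistanceMatrix,
    dims: int = 2,
    tol: float = 1e-3,
    max_iter: int = 30,
    seed: int | None = None,
    random_restart: bool = False,
) -> Embedding:
    """Embed ``D`` in ``dims`` dimensions (2 or 3) by stress majorization.

    Initialization is deterministic Torgerson scaling unless
    ``random_restart`` is set, in which case ``seed`` perturbs the start.
    Iteration stops when the decrease in S-stress falls below ``tol`` or
    after ``max_iter`` Guttman updates.
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    delta = np.asarray(D.values, dtype=float)
    n = delta.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} points for a {dims}-D embedding")

    X = _torgerson(delta, dims)
    if random_restart:
        rng = np.random.default_rng(seed)
        X = X + rng.normal(scale=delta.max() * 0.1 + 1e-12, size=X.shape)

    d = _pdist_matrix(X)
    stresses = [_raw_stress(d, delta)]
    s_prev = _s_stress(d, delta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, delta / d, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n  # Guttman transform
        d = _pdist_matrix(X)
        stresses.append(_raw_stress(d, delta))
        s_now = _s_stress(d, delta)
        if s_prev - s_now < tol:
            converged = True
            s_prev = s_now
            break
        s_prev = s_now

    return Embedding(
        labels=list(D.labels),
        coords=X - X.mean(axis=0),
        s_stress=_s_stress(d, delta),
        kruskal_stress=_kruskal(d, delta),
        iterations=it,
        converged=converged,
        stress_sequence=np.asarray(stresses),
    )


def procrustes_residual(X: np.ndarray, Y: np.ndarray) -> float:
    """RMS residual of Y onto X after optimal rotation/translation/scale."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    nx = np.linalg.norm(Xc)
    ny = np.linalg.norm(Yc)
    if nx == 0 or ny == 0:
        return float(np.linalg.norm(Xc - Yc))
    Xn, Yn = Xc / nx, Yc / ny
    u, s, vt = np.linalg.svd(Yn.T @ Xn)
    return float(np.sqrt(max(0.0, 1.0 - s.sum() ** 2)))
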