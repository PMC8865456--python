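"""Symmetric-KL similarity (KLS) connectivity matrices.

Edge weights between parcels are KLS(P, Q) = exp(-DKL(P, Q)) where

    DKL(P, Q) = integral of P log(P/Q) + Q log(Q/P) over the grid,

the symmetrized Kullback-Leibler divergence between the two parcels' PDFs,
discretized by the trapezoidal rule on the shared standardized grid.
Similar regional uptake distributions give weights near 1; diverging
distributions give weights near 0.  The matrix stays fully weighted - no
threshold or binarization is ever applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import DensityEstimate, StandardGrid, check_common_grid
from .exceptions import GridMismatchError, InputError

__all__ = ["ConnectivityMatrix", "symmetric_kl", "kls_similarity", "build_matrix"]

DEFAULT_EPSILON = 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted KLS matrix over the retained parcels.

    ``weights`` is bit-exactly symmetric with unit diagonal; the diagonal is
    excluded from every averaging operation downstream.  ``meta`` records
    the grid, the density floor epsilon and the subject id for provenance.
    """

    node_ids: np.ndarray
    weights: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.node_ids.size
        if self.weights.shape != (n, n):
            raise InputError("weights shape must match node count")
        if len(np.unique(self.node_ids)) != n:
            raise InputError("duplicate parcel ids")

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    def indices_of(self, ids) -> np.ndarray:
        lookup = {int(p): i for i, p in enumerate(self.node_ids)}
        try:
            return np.array([lookup[int(p)] for p in ids], dtype=int)
        except KeyError as e:
            raise InputError(f"parcel id {e.args[0]} not in matrix") from e

    def submatrix(self, ids) -> np.ndarray:
        idx = self.indices_of(ids)
        return self.weights[np.ix_(idx, idx)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_ids, columns=self.node_ids)


def _floor_and_renormalize(dens: np.ndarray, w: np.ndarray, epsilon: float) -> np.ndarray:
    """Floor densities at epsilon and renormalize the trapezoidal integral.

    Keeps every log ratio finite and every KLS weight strictly positive,
    matching an unthresholded weighted graph.
    """
    if epsilon <= 0:
        raise InputError("epsilon must be positive")
    d = np.maximum(dens, epsilon)
    return d / (d @ w)


def symmetric_kl(p: DensityEstimate, q: DensityEstimate, epsilon: float = DEFAULT_EPSILON) -> float:
    """Symmetrized KL divergence between two density estimates."""
    if p.grid != q.grid:
        raise GridMismatchError("P and Q must share the identical grid")
    w = p.grid.trapezoid_weights()
    pd_ = _floor_and_renormalize(p.densities, w, epsilon)
    qd = _floor_and_renormalize(q.densities, w, epsilon)
    integrand = pd_ * np.log(pd_ / qd) + qd * np.log(qd / pd_)
    return float(max(integrand @ w, 0.0))


def kls_similarity(divergence: float) -> float:
    """KLS weight exp(-DKL), in (0, 1], monotone decreasing in divergence."""
    if divergence < 0:
        raise InputError("divergence must be nonnegative")
    return float(np.exp(-divergence))


def build_matrix(
    estimates: list[DensityEstimate],
    epsilon: float = DEFAULT_EPSILON,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """Assemble the individual weighted KLS matrix from parcel PDFs.

    Every unordered pair is computed once; the divergence matrix is formed
    from commutative sums so symmetry holds bit-exactly.  Diagonal fixed
    at 1.
    """
    if len(estimates) < 2:
        raise InputError("need at least 2 density estimates")
    grid: StandardGrid = check_common_grid(estimates)
    ids = np.array([e.parcel_id for e in estimates], dtype=int)
    if np.unique(ids).size != ids.size:
        raise InputError("duplicate parcel ids among estimates")
    w = grid.trapezoid_weights()
    p = np.stack([e.densities for e in estimates])
    p = np.maximum(p, epsilon)
    p /= (p @ w)[:, None]
    logp = np.log(p)
    # D_ij = sum_k w_k (p_ik - p_jk)(log p_ik - log p_jk)
    #      = a_i + a_j - B_ij - B_ji with a_i = sum w p_i log p_i, B = (p*w) @ logp.T
    a = (p * logp) @ w
    b = (p * w) @ logp.T
    cross = b + b.T  # commutative sums keep every intermediate bit-symmetric
    d = (a[:, None] + a[None, :]) - cross
    d = np.maximum(d, 0.0)
    weights = np.exp(-d)
    np.fill_diagonal(weights, 1.0)
    meta = {
        "grid_lower": grid.lower,
        "grid_upper": grid.upper,
        "grid_points": grid.n_points,
        "epsilon": epsilon,
        "subject_id": subject_id,
    }
    return ConnectivityMatrix(ids, weights, meta)
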