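"""Fairlet decompositions as fixed-margin binary matrices.

A (1, t)-fairlet groups one minority (level-1) observation with exactly t
majority (level-2) observations; clustering fairlet *centers* instead of raw
observations guarantees every downstream cluster inherits the population's
1:t attribute ratio.  A decomposition is encoded by an ``N1 x N2`` binary
matrix ``B`` with row sums t and column sums 1: row i lists the level-2
members of fairlet i.  The optimal decomposition minimizes the transport
cost ``<B, L> = tr(B^T L)`` over this polytope, where ``L`` holds pairwise
discrepancies between minority and majority points — a minimum-cost-flow /
assignment problem whose linear-programming optimum is automatically binary
because transportation-polytope vertices are integral.

Posterior exploration of non-optimal decompositions uses a weighted
rectangular-loop Metropolis chain (checker-board 2x2 swaps), which is
reversible with respect to ``P(B) ∝ prod_ij omega_ij ** b_ij`` with
``omega_ij = exp(-lambda_f * l_ij)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datasets import InputError, LabeledDataset

__all__ = [
    "CostMatrix",
    "FairletAssignment",
    "FairletDecomposition",
    "WeightMatrix",
    "build_cost_matrix",
    "solve_optimal_fairlets",
    "fairlet_loss",
    "decompose",
    "weights_from_cost",
    "wrla_step",
    "wrla_chain",
]

METRICS = ("squared_euclidean", "manhattan")


class ConfigError(ValueError):
    """Raised for unsupported metric/temperature configuration."""


def pairwise_discrepancy(x: np.ndarray, y: np.ndarray, metric: str) -> np.ndarray:
    """Dense discrepancy matrix D(x_i, y_j) for the two supported metrics."""
    if metric == "squared_euclidean":
        diff = x[:, None, :] - y[None, :, :]
        return np.einsum("ijk,ijk->ij", diff, diff)
    if metric == "manhattan":
        return np.abs(x[:, None, :] - y[None, :, :]).sum(axis=2)
    raise ConfigError(f"unknown metric {metric!r}; choose one of {METRICS}")


@dataclass(frozen=True)
class CostMatrix:
    """N1 x N2 matrix of discrepancies between minority and majority points."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or (values < 0).any():
            raise InputError("cost matrix must be 2-D with nonnegative entries")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FairletAssignment:
    """Binary N1 x N2 matrix with row sums t and column sums 1."""

    b: np.ndarray
    t: int

    def __post_init__(self) -> None:
        b = np.asarray(self.b)
        if not np.isin(b, (0, 1)).all():
            raise InputError("assignment matrix must be binary")
        if not (b.sum(axis=1) == self.t).all():
            raise InputError(f"every row must sum to t={self.t}")
        if not (b.sum(axis=0) == 1).all():
            raise InputError("every column must sum to 1")
        object.__setattr__(self, "b", b.astype(np.uint8))


@dataclass(frozen=True)
class FairletDecomposition:
    """Fairlets as observation-index groups, plus their centers and loss."""

    fairlets: tuple[np.ndarray, ...]
    centers: np.ndarray
    loss: float


@dataclass(frozen=True)
class WeightMatrix:
    """Entrywise weights omega_ij = exp(-lambda_f * l_ij); log kept for stability."""

    values: np.ndarray
    log_values: np.ndarray


def build_cost_matrix(dataset: LabeledDataset, metric: str = "squared_euclidean") -> CostMatrix:
    """Discrepancies of every level-1 point to every level-2 point."""
    x1 = dataset.points[dataset.idx1]
    x2 = dataset.points[dataset.idx2]
    return CostMatrix(pairwise_discrepancy(x1, x2, metric), metric)


def solve_optimal_fairlets(cost: CostMatrix, t: int) -> FairletAssignment:
    """Minimum-cost (1, t)-decomposition via binary optimal transport.

    For t = 1 this is a minimum-cost perfect matching.  For t >= 2 each row
    is replicated t times and the resulting square assignment problem solved;
    the replicated optimum is exactly the transportation optimum because
    each copy of row i carries identical costs.
    """
    n1, n2 = cost.shape
    if t * n1 != n2:
        raise InputError(
            f"infeasible margins: t*N1 = {t}*{n1} != N2 = {n2}; a (1,{t})-"
            "fairlet decomposition requires an exact 1:t attribute ratio"
        )
    expanded = np.repeat(cost.values, t, axis=0)
    rows, cols = linear_sum_assignment(expanded)
    b = np.zeros((n1, n2), dtype=np.uint8)
    b[rows // t, cols] = 1
    return FairletAssignment(b, t)


def fairlet_loss(assignment: FairletAssignment, cost: CostMatrix) -> float:
    """Total within-fairlet discrepancy <B, L> = sum_ik b_ik l_ik."""
    if assignment.b.shape != cost.shape:
        raise InputError("assignment and cost matrix shapes differ")
    return float((assignment.b * cost.values).sum())


def decompose(
    assignment: FairletAssignment,
    dataset: LabeledDataset,
    cost: CostMatrix | None = None,
) -> FairletDecomposition:
    """Materialize fairlets and their centers from an assignment matrix.

    Fairlet i holds minority observation ``idx1[i]`` and the majority
    observations whose columns are active in row i; its center is the
    arithmetic mean of the t+1 member points.
    """
    idx1, idx2 = dataset.idx1, dataset.idx2
    fairlets = []
    centers = np.empty((len(idx1), dataset.d))
    for i in range(len(idx1)):
        members = np.concatenate(([idx1[i]], idx2[np.flatnonzero(assignment.b[i])]))
        fairlets.append(members)
        centers[i] = dataset.points[members].mean(axis=0)
    loss = fairlet_loss(assignment, cost) if cost is not None else float("nan")
    return FairletDecomposition(tuple(fairlets), centers, loss)


def fairlet_centers(b: np.ndarray, dataset: LabeledDataset) -> np.ndarray:
    """Vectorized fairlet centers for a feasible binary matrix."""
    x1 = dataset.points[dataset.idx1]
    x2 = dataset.points[dataset.idx2]
    t = b.sum(axis=1)[0]
    return (x1 + b @ x2) / (t + 1.0)


def weights_from_cost(cost: CostMatrix, lam_f: float) -> WeightMatrix:
    if lam_f <= 0:
        raise ConfigError("fairlet temperature lambda_f must be positive")
    log_values = -lam_f * cost.values
    return WeightMatrix(np.exp(log_values), log_values)


def wrla_step(
    assignment: FairletAssignment, weights: WeightMatrix, rng: np.random.Generator
) -> FairletAssignment:
    """One Metropolis checker-board swap on the fixed-margin polytope.

    Draws a uniform row pair and column pair; if the induced 2x2 submatrix is
    a checker-board, proposes the opposite checker-board and accepts with
    probability min{1, product of weights at entries turning 1 over product
    at entries turning 0}.  Non-checker-board proposals leave the state
    unchanged (counted as an iteration), keeping the proposal symmetric.
    """
    b = assignment.b.copy()
    _wrla_step_inplace(b, weights.log_values, rng)
    return FairletAssignment(b, assignment.t)


def _wrla_step_inplace(b: np.ndarray, log_w: np.ndarray, rng: np.random.Generator) -> bool:
    n1, n2 = b.shape
    if n1 < 2 or n2 < 2:
        return False
    i1, i2 = _pair(rng, n1)
    j1, j2 = _pair(rng, n2)
    s11, s12, s21, s22 = b[i1, j1], b[i1, j2], b[i2, j1], b[i2, j2]
    if s11 == s22 and s12 == s21 and s11 != s12:
        # checker-board: swap flips which diagonal holds the ones
        if s11 == 1:
            gain = log_w[i1, j2] + log_w[i2, j1] - log_w[i1, j1] - log_w[i2, j2]
        else:
            gain = log_w[i1, j1] + log_w[i2, j2] - log_w[i1, j2] - log_w[i2, j1]
        if gain >= 0 or rng.random() < np.exp(gain):
            b[i1, j1] = 1 - s11
            b[i2, j2] = 1 - s22
            b[i1, j2] = 1 - s12
            b[i2, j1] = 1 - s21
            return True
    return False


def _pair(rng: np.random.Generator, n: int) -> tuple[int, int]:
    a = int(rng.integers(n))
    c = int(rng.integers(n - 1))
    if c >= a:
        c += 1
    return a, c


def wrla_chain(
    b0: FairletAssignment,
    weights: WeightMatrix,
    n_steps: int,
    rng: np.random.Generator,
    thin: int = 1,
) -> list[FairletAssignment]:
    """Run the rectangular-loop chain, recording every ``thin``-th state."""
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    b = b0.b.copy()
    out = []
    for step in range(1, n_steps + 1):
        _wrla_step_inplace(b, weights.log_values, rng)
        if step % thin == 0:
            out.append(FairletAssignment(b.copy(), b0.t))
    return out
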