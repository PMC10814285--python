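"""Loss-based clustering of fairlet centers under a Gibbs posterior.

The clustering model is a product-partition Gibbs posterior: with a uniform
prior over partitions into exactly K blocks, the posterior over cluster
labels c is

    pi(c | u) ∝ exp(-lambda_c * Lc(c | u)),
    Lc(c | u) = sum_k sum_{i in C_k} D(u_i, u_(k)),

where u_(k) is the rule-defined center of cluster k.  Two loss families are
supported: squared Euclidean with arithmetic-mean centers (the k-means loss)
and Manhattan with componentwise-median centers (the k-medians loss, the L1
minimizer).  Because only cluster k's loss term depends on where unit i
goes, the full conditional of a single label is available in closed form and
a cyclic Gibbs sweep targets the Boltzmann law exactly.

MAP estimation uses Lloyd-style alternating minimization (assign to the
nearest center under D, recenter by the rule) with random restarts; each
iteration provably never increases the loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import InputError
from .fairlets import ConfigError, pairwise_discrepancy

__all__ = [
    "LossSpec",
    "ClusteringState",
    "cluster_loss",
    "gibbs_label_conditional",
    "gibbs_sweep",
    "map_clustering",
]

_CENTER_RULES = {"squared_euclidean": "mean", "manhattan": "componentwise_median"}


@dataclass(frozen=True)
class LossSpec:
    """Discrepancy family, its loss-minimizing center rule, and temperature."""

    discrepancy: str = "squared_euclidean"
    lam_c: float = 1.0

    def __post_init__(self) -> None:
        if self.discrepancy not in _CENTER_RULES:
            raise ConfigError(
                f"unknown discrepancy {self.discrepancy!r}; choose one of "
                f"{tuple(_CENTER_RULES)}"
            )
        if self.lam_c <= 0:
            raise ConfigError("clustering temperature lambda_c must be positive")

    @property
    def center_rule(self) -> str:
        return _CENTER_RULES[self.discrepancy]

    def center(self, points: np.ndarray) -> np.ndarray:
        if self.discrepancy == "squared_euclidean":
            return points.mean(axis=0)
        # lower componentwise median: deterministic L1 minimizer for even sizes
        srt = np.sort(points, axis=0)
        return srt[(points.shape[0] - 1) // 2]

    def point_loss(self, points: np.ndarray, center: np.ndarray) -> float:
        if self.discrepancy == "squared_euclidean":
            diff = points - center
            return float((diff * diff).sum())
        return float(np.abs(points - center).sum())


@dataclass(frozen=True)
class ClusteringState:
    """Labels in {1..K}, rule-consistent centers, and the current loss."""

    labels: np.ndarray
    centers: np.ndarray
    loss_value: float
    k: int

    @classmethod
    def from_labels(cls, u: np.ndarray, labels: np.ndarray, k: int, loss: LossSpec) -> "ClusteringState":
        labels = np.asarray(labels, dtype=int)
        if set(np.unique(labels).tolist()) != set(range(1, k + 1)):
            raise InputError(f"labels must use every cluster 1..{k}")
        centers = np.empty((k, u.shape[1]))
        total = 0.0
        for c in range(1, k + 1):
            members = u[labels == c]
            centers[c - 1] = loss.center(members)
            total += loss.point_loss(members, centers[c - 1])
        return cls(labels, centers, total, k)


def _block_loss(u: np.ndarray, loss: LossSpec) -> float:
    return loss.point_loss(u, loss.center(u))


def cluster_loss(u: np.ndarray, labels: np.ndarray, k: int, loss: LossSpec) -> float:
    """Total within-cluster discrepancy Lc, with centers recomputed per rule."""
    return ClusteringState.from_labels(u, labels, k, loss).loss_value


def gibbs_label_conditional(
    i: int, labels: np.ndarray, u: np.ndarray, k: int, loss: LossSpec
) -> np.ndarray:
    """Full conditional P(c_i = . | c_-i) as a length-K probability vector.

    For each candidate cluster the exponent is the increase in that
    cluster's loss term when unit i joins it (centers recomputed with and
    without i).  When unit i is a singleton it must stay put — the uniform
    prior has support only on partitions with exactly K blocks — so the
    conditional degenerates to its current label.
    """
    if k < 2:
        raise ConfigError("need K >= 2 clusters for label resampling")
    labels = np.asarray(labels, dtype=int)
    current = labels[i]
    if (labels == current).sum() == 1:
        out = np.zeros(k)
        out[current - 1] = 1.0
        return out
    mask = np.ones(len(labels), dtype=bool)
    mask[i] = False
    log_p = np.empty(k)
    for c in range(1, k + 1):
        others = u[mask & (labels == c)]
        with_i = np.vstack([others, u[i]])
        delta = _block_loss(with_i, loss) - (_block_loss(others, loss) if len(others) else 0.0)
        log_p[c - 1] = -loss.lam_c * delta
    log_p -= log_p.max()
    p = np.exp(log_p)
    return p / p.sum()


def gibbs_sweep(
    state: ClusteringState,
    u: np.ndarray,
    loss: LossSpec,
    rng: np.random.Generator,
    fixed_order: bool = True,
) -> ClusteringState:
    """One cyclic reallocation of every unit from its full conditional.

    Visits units sequentially (or in a fresh random permutation when
    ``fixed_order`` is off); centers and loss are rebuilt from the final
    labels so the returned state satisfies all invariants exactly.
    """
    labels = state.labels.copy()
    order = np.arange(len(labels))
    if not fixed_order:
        order = rng.permutation(order)
    for i in order:
        p = gibbs_label_conditional(int(i), labels, u, state.k, loss)
        labels[i] = 1 + rng.choice(state.k, p=p)
    return ClusteringState.from_labels(u, labels, state.k, loss)


def _lloyd(
    u: np.ndarray, k: int, loss: LossSpec, init_centers: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    centers = init_centers.copy()
    prev = np.inf
    labels = np.empty(len(u), dtype=int)
    for _ in range(max_iter):
        d = pairwise_discrepancy(u, centers, loss.discrepancy)
        labels = d.argmin(axis=1) + 1  # argmin takes the lowest index on ties
        # re-seed any empty cluster with the worst-fit point
        for c in range(1, k + 1):
            if not (labels == c).any():
                worst = int(d[np.arange(len(u)), labels - 1].argmax())
                labels[worst] = c
                d[worst, :] = np.inf
        total = 0.0
        for c in range(1, k + 1):
            members = u[labels == c]
            centers[c - 1] = loss.center(members)
            total += loss.point_loss(members, centers[c - 1])
        assert total <= prev + 1e-9, "Lloyd iteration increased the loss"
        if prev - total < 1e-12:
            break
        prev = total
    return labels, total


def map_clustering(
    u: np.ndarray,
    k: int,
    loss: LossSpec,
    n_restarts: int = 10,
    rng: np.random.Generator | None = None,
) -> ClusteringState:
    """Best Lloyd fixed point over random restarts (deterministic under seed)."""
    u = np.asarray(u, dtype=float)
    if len(u) < k:
        raise InputError(f"cannot form {k} nonempty clusters from {len(u)} units")
    rng = np.random.default_rng(0) if rng is None else rng
    best: tuple[np.ndarray, float] | None = None
    for _ in range(n_restarts):
        init = u[rng.choice(len(u), size=k, replace=False)]
        labels, total = _lloyd(u, k, loss, init)
        if best is None or total < best[1]:
            best = (labels, total)
    return ClusteringState.from_labels(u, best[0], k, loss)
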