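"""Joint Gibbs-posterior inference over fairlet decompositions and clusterings.

The target is the joint generalized-Bayes posterior

    pi(B, c) ∝ exp(-lambda_f * <B, L>) * exp(-lambda_c * Lc(c | u(B))),

where B ranges over (1, t)-fairlet decompositions (fixed-margin binary
matrices), u(B) are the induced fairlet centers, and c is a partition of the
centers into exactly K clusters.  Two samplers are provided:

* **MC-EM** — fixes B at the optimal-transport decomposition B' and samples
  only cluster labels; fast, ignores decomposition uncertainty.
* **full MCMC** — Metropolis-within-Gibbs: each outer iteration makes a
  batch of rectangular-loop (checker-board swap) proposals on B, each
  accepted with the *joint* Metropolis ratio — the entrywise-weight fairlet
  factor times the change in the clustering loss induced through the moved
  fairlet centers — then performs one Gibbs sweep on the labels.  Including
  the clustering factor in the acceptance ratio is what makes the B-update a
  valid conditional move for the joint posterior: a swap changes two fairlet
  centers and hence Lc even at fixed labels, so the weight-only ratio alone
  would not leave the joint law invariant.

Because every draw assigns whole fairlets to clusters, each sampled
observation-level clustering is *fair by construction*: cluster label
compositions are (n_k, t*n_k), so the balance of every draw is exactly 1/t.

Draw summaries follow the usual partition-MCMC toolkit: the pairwise
co-clustering matrix, the least-squares configuration (the stored draw whose
association matrix is closest to the co-clustering average, robust to label
switching), the MCMC maximum a posteriori draw, and per-observation
misclassification probabilities 1 - etabar[i, i*] anchored at each MAP
cluster's medioid i*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import InputError, LabeledDataset, balance_of_draws
from .fairlets import (
    ConfigError,
    CostMatrix,
    FairletAssignment,
    FairletDecomposition,
    _pair,
    build_cost_matrix,
    decompose,
    fairlet_centers,
    solve_optimal_fairlets,
    weights_from_cost,
    pairwise_discrepancy,
)
from .gibbs_clustering import ClusteringState, LossSpec, gibbs_sweep, map_clustering

__all__ = [
    "GibbsConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "log_joint",
    "run_mcem",
    "run_mcmc",
    "expand_labels",
    "coclustering",
    "dahl_least_squares",
    "misclassification_prob",
    "map_estimate",
    "summarize",
]


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler settings: temperatures, loss family, chain lengths, seed."""

    lam_f: float = 1.0
    lam_c: float = 1.0
    k: int = 2
    discrepancy: str = "squared_euclidean"
    mode: str = "mcmc"
    n_iterations: int = 1000
    burn_in: int = 200
    thin: int = 1
    wrla_inner_steps: int | None = None  # default: N1 proposals per outer iteration
    n_restarts: int = 10
    fixed_order: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("mcem", "mcmc"):
            raise ConfigError(f"mode must be 'mcem' or 'mcmc', got {self.mode!r}")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ConfigError("require 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.wrla_inner_steps is not None and self.wrla_inner_steps < 1:
            raise ConfigError("wrla_inner_steps must be >= 1")
        if self.k < 2:
            raise ConfigError("need K >= 2")

    @property
    def loss(self) -> LossSpec:
        return LossSpec(self.discrepancy, self.lam_c)


@dataclass
class PosteriorDraws:
    """Stored post-burn-in draws from the joint chain.

    ``partitions`` holds observation-level cluster labels in canonical form
    (clusters renumbered by first occurrence) so that draw equality and the
    least-squares objective are well defined under label switching.
    """

    partitions: np.ndarray  # (T, N) int
    fairlet_partitions: np.ndarray  # (T, m) int
    assignments: np.ndarray  # (T, N1, N2) uint8
    log_joint: np.ndarray  # (T,)
    fairlet_losses: np.ndarray  # (T,)
    clustering_losses: np.ndarray  # (T,)
    config: GibbsConfig
    attr_labels: np.ndarray
    points: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.partitions.shape[0]


@dataclass
class PosteriorSummary:
    """Co-clustering matrix and the point/uncertainty summaries derived from it."""

    coclustering: np.ndarray
    ls_partition: np.ndarray
    map_partition: np.ndarray
    misclassification: np.ndarray
    balance_per_draw: np.ndarray


def log_joint(
    assignment: FairletAssignment,
    cost: CostMatrix,
    state: ClusteringState,
    lam_f: float,
    lam_c: float,
) -> float:
    """Unnormalized log joint -lambda_f <B,L> - lambda_c Lc(c | u(B))."""
    lf = float((assignment.b * cost.values).sum())
    return -lam_f * lf - lam_c * state.loss_value


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters by order of first occurrence (label-switching-proof)."""
    labels = np.asarray(labels, dtype=int)
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, c in enumerate(labels):
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


def expand_labels(
    fairlet_labels: np.ndarray, decomposition: FairletDecomposition, n: int
) -> np.ndarray:
    """Lift a fairlet-level partition to observations: members inherit the label."""
    out = np.full(n, -1, dtype=int)
    for i, members in enumerate(decomposition.fairlets):
        out[members] = fairlet_labels[i]
    if (out < 0).any():
        raise RuntimeError("fairlet decomposition does not cover all observations")
    return out


def _joint_swap_step(
    b: np.ndarray,
    log_w: np.ndarray,
    u: np.ndarray,
    labels: np.ndarray,
    loss: LossSpec,
    x2: np.ndarray,
    t: int,
    rng: np.random.Generator,
) -> bool:
    """One checker-board swap on B accepted under the joint posterior.

    The proposal is the rectangular-loop move (uniform row pair, column
    pair; valid only on checker-board submatrices).  The acceptance ratio
    multiplies the entrywise-weight factor exp(-lambda_f * delta Lf) by
    exp(-lambda_c * delta Lc), where delta Lc is the clustering-loss change
    from the two fairlet centers the swap displaces (cluster labels held
    fixed).  Mutates ``b`` and ``u`` in place on acceptance.
    """
    n1, n2 = b.shape
    if n1 < 2 or n2 < 2:
        return False
    i1, i2 = _pair(rng, n1)
    j1, j2 = _pair(rng, n2)
    s11, s12, s21, s22 = b[i1, j1], b[i1, j2], b[i2, j1], b[i2, j2]
    if not (s11 == s22 and s12 == s21 and s11 != s12):
        return False
    if s11 == 1:  # row i1 trades column j1 for j2; row i2 the reverse
        lf_gain = log_w[i1, j2] + log_w[i2, j1] - log_w[i1, j1] - log_w[i2, j2]
        shift = (x2[j2] - x2[j1]) / (t + 1.0)
    else:
        lf_gain = log_w[i1, j1] + log_w[i2, j2] - log_w[i1, j2] - log_w[i2, j1]
        shift = (x2[j1] - x2[j2]) / (t + 1.0)
    u_new_i1 = u[i1] + shift
    u_new_i2 = u[i2] - shift
    delta_lc = 0.0
    for k in {int(labels[i1]), int(labels[i2])}:
        members = np.flatnonzero(labels == k)
        block = u[members]
        old = loss.point_loss(block, loss.center(block))
        block = block.copy()
        block[members == i1] = u_new_i1
        block[members == i2] = u_new_i2
        delta_lc += loss.point_loss(block, loss.center(block)) - old
    log_accept = lf_gain - loss.lam_c * delta_lc
    if log_accept >= 0 or rng.random() < np.exp(log_accept):
        b[i1, j1] = 1 - s11
        b[i2, j2] = 1 - s22
        b[i1, j2] = 1 - s12
        b[i2, j1] = 1 - s21
        u[i1] = u_new_i1
        u[i2] = u_new_i2
        return True
    return False


def _run_chain(dataset: LabeledDataset, config: GibbsConfig) -> PosteriorDraws:
    rng = np.random.default_rng(config.seed)
    t = dataset.t
    loss = config.loss
    cost = build_cost_matrix(dataset, config.discrepancy)
    b_opt = solve_optimal_fairlets(cost, t)
    weights = weights_from_cost(cost, config.lam_f)

    b = b_opt.b.copy()
    u = fairlet_centers(b, dataset)
    state = map_clustering(u, config.k, loss, config.n_restarts, rng)

    inner = config.wrla_inner_steps or dataset.n1
    sample_b = config.mode == "mcmc"

    n_stored = (config.n_iterations - config.burn_in) // config.thin
    m = dataset.n1
    partitions = np.empty((n_stored, dataset.n), dtype=int)
    fairlet_partitions = np.empty((n_stored, m), dtype=int)
    assignments = np.empty((n_stored, *b.shape), dtype=np.uint8)
    lj = np.empty(n_stored)
    lf_trace = np.empty(n_stored)
    lc_trace = np.empty(n_stored)

    stored = 0
    cost_vals = cost.values
    x2 = dataset.points[dataset.idx2]
    for it in range(1, config.n_iterations + 1):
        if sample_b:
            labels = state.labels
            for _ in range(inner):
                _joint_swap_step(b, weights.log_values, u, labels, loss, x2, t, rng)
            u = fairlet_centers(b, dataset)  # periodic exact recompute: float hygiene
            state = ClusteringState.from_labels(u, labels, config.k, loss)
        state = gibbs_sweep(state, u, loss, rng, config.fixed_order)
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            lf = float((b * cost_vals).sum())
            fl = canonical_labels(state.labels)
            decomp = decompose(FairletAssignment(b, t), dataset)
            partitions[stored] = expand_labels(fl, decomp, dataset.n)
            fairlet_partitions[stored] = fl
            assignments[stored] = b
            lf_trace[stored] = lf
            lc_trace[stored] = state.loss_value
            lj[stored] = -config.lam_f * lf - config.lam_c * state.loss_value
            stored += 1

    return PosteriorDraws(
        partitions[:stored],
        fairlet_partitions[:stored],
        assignments[:stored],
        lj[:stored],
        lf_trace[:stored],
        lc_trace[:stored],
        config,
        dataset.labels.copy(),
        dataset.points.copy(),
    )


def run_mcem(dataset: LabeledDataset, config: GibbsConfig) -> PosteriorDraws:
    """Sample cluster labels with the decomposition fixed at the OT optimum."""
    if config.mode != "mcem":
        config = replace(config, mode="mcem")
    return _run_chain(dataset, config)


def run_mcmc(dataset: LabeledDataset, config: GibbsConfig) -> PosteriorDraws:
    """Full Metropolis-within-Gibbs over (B, c), initialized at (B', MAP)."""
    if config.mode != "mcmc":
        config = replace(config, mode="mcmc")
    return _run_chain(dataset, config)


def coclustering(draws: PosteriorDraws | np.ndarray) -> np.ndarray:
    """etabar[i, j]: fraction of draws placing observations i and j together."""
    partitions = draws.partitions if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if partitions.shape[0] == 0:
        raise InputError("no draws to summarize")
    n = partitions.shape[1]
    eta = np.zeros((n, n))
    for s in partitions:
        onehot = (s[:, None] == np.unique(s)[None, :]).astype(float)
        eta += onehot @ onehot.T
    return eta / partitions.shape[0]


def dahl_least_squares(
    draws: PosteriorDraws | np.ndarray, eta: np.ndarray | None = None
) -> np.ndarray:
    """The stored draw whose association matrix is closest to etabar (squared error).

    Ties broken by earliest draw index; the result is always one of the
    stored draws, so structural properties of the draws (in particular their
    balance) carry over to the point estimate.
    """
    partitions = draws.partitions if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if eta is None:
        eta = coclustering(partitions)
    best_idx, best_val = 0, np.inf
    for idx, s in enumerate(partitions):
        assoc = (s[:, None] == s[None, :]).astype(float)
        val = float(((assoc - eta) ** 2).sum())
        if val < best_val - 1e-12:
            best_idx, best_val = idx, val
    return partitions[best_idx].copy()


def map_estimate(draws: PosteriorDraws) -> np.ndarray:
    """Stored draw with the highest log joint (MCMC approximation to the MAP)."""
    if draws.n_draws == 0:
        raise InputError("no draws to summarize")
    return draws.partitions[int(np.argmax(draws.log_joint))].copy()


def misclassification_prob(
    eta: np.ndarray,
    map_partition: np.ndarray,
    points: np.ndarray,
    discrepancy: str = "squared_euclidean",
) -> np.ndarray:
    """1 - etabar[i, i*], with i* the medioid of i's MAP cluster.

    The medioid is the cluster member minimizing total discrepancy to the
    other members, at observation level under the configured metric; it is
    its own anchor, so its misclassification probability is exactly 0.
    """
    map_partition = np.asarray(map_partition, dtype=int)
    out = np.empty(len(map_partition))
    for c in np.unique(map_partition):
        members = np.flatnonzero(map_partition == c)
        d = pairwise_discrepancy(points[members], points[members], discrepancy)
        medioid = members[int(d.sum(axis=1).argmin())]
        out[members] = 1.0 - eta[members, medioid]
    return out


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Compute all posterior summaries from the stored draws."""
    eta = coclustering(draws)
    ls = dahl_least_squares(draws, eta)
    map_part = map_estimate(draws)
    mis = misclassification_prob(eta, map_part, draws.points, draws.config.discrepancy)
    bal = balance_of_draws(list(draws.partitions), draws.attr_labels)
    return PosteriorSummary(eta, ls, map_part, mis, bal)
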