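# Methods

## Model

Data are N observations x_i ∈ R^d, each carrying a protected attribute with
two levels whose counts satisfy N₂ = t·N₁ for an integer t ≥ 1 (the level
with the smaller count is coded 1; ties are broken by sorted level order).
The target of inference is the joint Gibbs posterior

    π(B, C) ∝ exp{−λ_f ⟨B, L⟩} · ∏_k exp{−λ_c Σ_{i∈C_k} D(u_i, u_(k))}

with uniform priors on both layers: over the fixed-margin binary matrices B
(row sums t, column sums 1 — the convention under which the fairlets
partition all N observations) and over partitions C of the m = N₁ fairlet
centers into exactly K nonempty clusters. The fairlet cost matrix L holds
D(x_i, x_j) for minority row i against majority column j; fairlet centers
u(B) are arithmetic means of the t+1 member points. This is a belief update
in the generalized-Bayes sense: no data-generating model is assumed, the
losses play the role of a negative log-likelihood, and the temperatures
control how sharply the posterior concentrates at loss minimizers.

Two loss families are shipped, each paired with the center rule that
minimizes its within-cluster sum: squared Euclidean with means (k-means) and
Manhattan with componentwise medians (k-medians; the *lower* median is used
for even cluster sizes, which keeps the loss a deterministic function of
the partition). The fairlet matching metric defaults to the same D as the
clustering loss.

## Why every draw is fair

A draw assigns fairlets — not observations — to clusters, so a cluster with
n_k fairlets contains exactly n_k minority and t·n_k majority observations:
balance is 1/t identically, for the MAP, for Dahl's least-squares
configuration (always itself a stored draw), and for every other draw. The
package asserts this invariant on every run rather than assuming it.

## Sampling

**Optimal decomposition.** ⟨B, L⟩ is minimized by linear assignment
(`scipy.optimize.linear_sum_assignment`); for t ≥ 2 each row of L is
replicated t times, which is exact because transportation-polytope vertices
are integral and all t copies of a row carry identical costs.

**Label Gibbs sweep.** Only cluster k's loss term depends on where unit i
goes, so the full conditional is

    P(c_i = k | c_−i) ∝ exp{−λ_c [ Lc(C_{k,−i} ∪ {i}) − Lc(C_{k,−i}) ]}

with centers recomputed including/excluding i. Sweeps visit units
sequentially by default (random-scan is available). A unit that is currently
a singleton must stay put: the prior's support is partitions with exactly K
blocks, and restricting the move keeps the chain inside that support. The
conditional is validated against brute-force enumeration of the joint to
1e−10, and the sweep chain's long-run partition frequencies against the
enumerated Boltzmann law.

**Decomposition update.** The proposal is the rectangular-loop move: a
uniform row pair and column pair; if the induced 2×2 submatrix is a
checker-board, flip it to the opposite checker-board (margins are conserved
by construction; non-checker-board proposals count as iterations, keeping
the proposal symmetric). Within the joint sampler the acceptance ratio is
exp{−λ_f ΔLf − λ_c ΔLc}: a swap displaces exactly two fairlet centers, so
the clustering loss changes even at fixed labels, and omitting that term
leaves a chain whose stationary law measurably deviates from the joint
posterior (total variation ≈ 0.06 on a fully enumerable 6-point toy). With
the term included the empirical joint law matches enumeration to TV < 0.05.
The pure entrywise-weight chain — acceptance ∏ω(turning 1)/∏ω(turning 0)
with ω_ij = exp(−λ_f l_ij) — is kept as `fairlets.wrla_chain` for sampling
the fairlet posterior alone, and is validated by a chi-square
goodness-of-fit test against its enumerated stationary law.

**Schedules.** `mcem` fixes B at the transport optimum and sweeps labels
only (fast; ignores decomposition uncertainty). `mcmc` alternates
`wrla_inner_steps` swap proposals (default N₁ — one expected touch per row)
with one label sweep per outer iteration, initialized at the transport
optimum and a Lloyd MAP clustering. Chains run a fixed iteration budget
with burn-in and thinning from the configuration; there is no auto-stopping,
which keeps runs exactly reproducible from the manifest. Stored partitions
are canonicalized by first-occurrence relabeling so draw equality and the
least-squares objective are well defined under label switching.

**MAP optimization.** Lloyd-style alternating minimization under the chosen
D and center rule, from random restarts (default 10); ties in nearest-center
assignment break to the lowest cluster index, empty clusters are re-seeded
with the worst-fit point, and every iteration is asserted non-increasing.
Centers inside the samplers are periodically recomputed from scratch to
bound floating-point drift.

## Summaries

From T stored draws: the co-clustering matrix η̄ (fraction of draws placing
i and j together; symmetric, unit diagonal), Dahl's least-squares draw
s_LS = argmin_s Σ_ij (η_ij(s) − η̄_ij)² with ties to the earliest draw, the
highest-log-joint draw as the MCMC MAP, and misclassification probabilities
1 − η̄_{i,i★} where i★ is the medioid (member minimizing total discrepancy
to the other members, at observation level under the configured D) of i's
MAP cluster. Medioids score exactly 0 by construction. The joint MAP is
reported from the visited draws rather than from the two-step
decompose-then-cluster shortcut; at large temperatures the two coincide,
which is covered by a test.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| λ_f | 1.0 | fairlet temperature; larger concentrates B at the transport optimum (dimensionless; scales with the discrepancy units of L) |
| λ_c | 1.0 | clustering temperature; larger concentrates partitions at the loss minimizer |
| K | 2 | number of clusters, fixed in advance (a granularity choice, not an estimand) |
| discrepancy | squared_euclidean | pairs with mean centers; `manhattan` pairs with medians |
| n_iterations / burn_in / thin | 1000 / 200 / 1 | outer chain schedule |
| wrla_inner_steps | N₁ | swap proposals per outer iteration |
| n_restarts | 10 | Lloyd restarts for initialization and MAP baselines |

Principled temperature calibration (matching prior and posterior expected
loss) is deliberately out of scope; the defaults of 1 are sensible on
standardized features and both temperatures are plain configuration values.

## Synthetic benchmarks

Both generators emit 100 points in 2-D with attribute-by-cluster cell
counts (20, 30) / (30, 20) — 50 points per attribute level, so t = 1 — and
component means (4,4), (2,2) in cluster 1 and (10,10), (8,8) in cluster 2.
The *well-specified* design draws from isotropic Gaussians with covariance
4I; the *misspecified* design from bivariate Student-t with scale 3I and
ν = 2 degrees of freedom (infinite variance, so gross outliers occur), via
the scale-mixture construction μ + Z·√(ν/V), Z ~ N(0, S), V ~ χ²_ν, with
both parts driven by one seeded generator. Under perfect recovery of the
generating clusters the vanilla balance is min(20/30, 30/20)⁻¹-symmetric
= 2/3; the generating partition itself is *not* perfectly balanced, which
is exactly what the fair posterior corrects.

What the generators do not emulate: real datasets have non-Gaussian,
correlated, mixed-scale features, attribute ratios that are rarely exactly
integral, and more than two protected levels. Passing tests on these
designs demonstrate correctness of the machinery (exact fairness, correct
stationary laws, loss robustness), not clustering quality on real data.

## Problem sizes used in the validation suite

Enumeration-backed checks run on exhaustively enumerable instances: 3×3 and
4×4 matchings (t = 1), the 2×4 polytope at t = 2, partition spaces up to
m = 8 at K = 2, and a 6-point joint toy with 18 (B, C) states sampled for
2×10⁵ outer iterations. The stationary-law checks use 10⁵ thinned draws
(rectangular-loop chain) and 10⁵ sweeps (label chain). The robustness
comparison uses 20 replicates of the heavy-tailed design with 400-iteration
chains per loss. Full fits on the 100-point benchmarks use 600 iterations
with 100 burn-in, which the trace diagnostics show is ample for these small,
well-separated instances.

## Known limitations

* Two protected levels and exact 1:t ratios only; other inputs are rejected
  with explicit errors rather than approximated (the general multi-level
  balance formula is implemented, but no r > 2 inference is offered).
* K is fixed; no model-selection machinery.
* The least-squares and MAP summaries are restricted to visited draws; on
  multimodal posteriors with short chains they inherit MCMC error.
* Exact (perfect) sampling of decompositions is not provided; only MCMC.
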