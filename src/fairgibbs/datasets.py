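"""Core data containers, the balance criterion, synthetic benchmarks, and CSV I/O.

A :class:`LabeledDataset` couples an ``N x d`` feature matrix with a binary
protected attribute whose two levels occur in an exact ``1:t`` integer ratio.
The :func:`balance` function implements the standard fairness criterion for
clusterings: the minimum, over clusters and ordered pairs of attribute
levels, of the within-cluster count ratio.  A clustering with balance 1 keeps
every cluster exactly proportional to the population; balance 0 means some
cluster misses a level entirely.

Two seeded simulation designs are provided for benchmarking:

* a *well-specified* design — two clusters of isotropic bivariate Gaussians,
  with attribute-by-cluster cell counts (20, 30) / (30, 20);
* a *misspecified* design — the same layout with bivariate Student-t
  components at 2 degrees of freedom, whose variance does not exist, so
  gross outliers are expected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SyntheticSpec",
    "Partition",
    "balance",
    "balance_of_draws",
    "generate",
    "generate_well_specified",
    "generate_misspecified",
    "read_dataset",
    "write_dataset",
    "write_labels",
]


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


@dataclass(frozen=True)
class LabeledDataset:
    """Observations plus a two-level protected attribute.

    ``labels`` holds attribute codes in ``{1, 2}``, oriented so level 1 is
    the minority (or tied-first) level and ``N2 = t * N1`` for a positive
    integer ``t``.  ``level_names`` remembers the original level strings so
    round trips through CSV are lossless.
    """

    points: np.ndarray
    labels: np.ndarray
    level_names: tuple[str, str] = ("1", "2")

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if points.ndim != 2:
            raise InputError("points must be a 2-D array")
        if labels.shape != (points.shape[0],):
            raise InputError("labels length must match number of points")
        if not np.isfinite(points).all():
            raise InputError("points contain missing or non-finite values")
        levels = set(np.unique(labels).tolist())
        if not levels <= {1, 2} or len(levels) != 2:
            raise InputError(f"attribute codes must be exactly {{1, 2}}, got {sorted(levels)}")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    @property
    def idx1(self) -> np.ndarray:
        """Indices of level-1 (minority) observations."""
        return np.flatnonzero(self.labels == 1)

    @property
    def idx2(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 2)

    @property
    def n1(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.labels == 2).sum())

    @property
    def t(self) -> int:
        """The integer ratio N2 / N1; raises if the ratio is not integral."""
        n1, n2 = self.n1, self.n2
        if n2 % n1 != 0:
            raise InputError(
                f"attribute counts {n1}:{n2} are not in an exact 1:t integer "
                "ratio; fairlet decomposition is undefined for this dataset"
            )
        return n2 // n1

    @classmethod
    def from_levels(cls, points: np.ndarray, raw_labels: Sequence) -> "LabeledDataset":
        """Build from arbitrary two-level labels, orienting the minority level to code 1."""
        raw = np.asarray([str(v) for v in raw_labels])
        levels = sorted(set(raw.tolist()))
        if len(levels) != 2:
            raise InputError(
                f"protected attribute must have exactly 2 levels, got "
                f"{len(levels)}: {levels}"
            )
        counts = {lv: int((raw == lv).sum()) for lv in levels}
        # minority level coded 1; ties broken by sorted order
        first = min(levels, key=lambda lv: (counts[lv], levels.index(lv)))
        second = levels[1] if first == levels[0] else levels[0]
        codes = np.where(raw == first, 1, 2)
        return cls(np.asarray(points, dtype=float), codes, (first, second))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a two-cluster, two-attribute simulation design.

    ``counts[j, k]`` is the number of observations with attribute level
    ``j+1`` in cluster ``k+1``; ``means[j, k]`` the corresponding component
    mean.  ``family`` selects Gaussian or Student-t components (the latter
    with ``df`` degrees of freedom and the given scale matrix).
    """

    family: str
    counts: np.ndarray
    means: np.ndarray
    scale: np.ndarray
    df: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "student_t"):
            raise InputError(f"unknown family {self.family!r}")
        counts = np.asarray(self.counts, dtype=int)
        means = np.asarray(self.means, dtype=float)
        scale = np.asarray(self.scale, dtype=float)
        if counts.shape != (2, 2) or (counts <= 0).any():
            raise InputError("counts must be a 2x2 table of positive integers")
        if means.shape[:2] != (2, 2):
            raise InputError("means must be a 2x2 grid of component means")
        if not np.allclose(scale, scale.T) or np.linalg.eigvalsh(scale).min() <= 0:
            raise InputError("scale must be symmetric positive-definite")
        if self.family == "student_t":
            if self.df is None or self.df < 1:
                raise InputError("student_t family requires df >= 1")
        n1, n2 = counts[0].sum(), counts[1].sum()
        if max(n1, n2) % min(n1, n2) != 0:
            raise InputError("marginal attribute counts must be in a 1:t integer ratio")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "scale", scale)


@dataclass(frozen=True)
class Partition:
    """Cluster labels in ``{1..K}`` with every cluster nonempty."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(labels).tolist())
        if present != set(range(1, self.k + 1)):
            raise InputError(
                f"partition must use every cluster index 1..{self.k} at least "
                f"once; indices present: {sorted(present)}"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.labels.shape[0]


def balance(partition: Partition | np.ndarray, attr_labels: np.ndarray) -> float:
    """Minimum over clusters of the min pairwise ratio of attribute counts.

    Implements the general multi-level formula: for each cluster the minimum
    of ``|C_kj1| / |C_kj2|`` over ordered level pairs, then the minimum over
    clusters.  A cluster missing any globally-present level scores 0.
    """
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    attr = np.asarray(attr_labels)
    if labels.shape != attr.shape:
        raise InputError("partition and attribute labels must have equal length")
    levels = np.unique(attr)
    if levels.size < 2:
        raise InputError("need at least 2 attribute levels to compute balance")
    clusters, cluster_idx = np.unique(labels, return_inverse=True)
    counts = np.zeros((clusters.size, levels.size))
    level_idx = np.searchsorted(levels, attr)
    np.add.at(counts, (cluster_idx, level_idx), 1.0)
    if (counts == 0).any():
        return 0.0
    best = 1.0
    for j1 in range(levels.size):
        for j2 in range(levels.size):
            if j1 == j2:
                continue
            best = min(best, float((counts[:, j1] / counts[:, j2]).min()))
    return best


def balance_of_draws(draws: Sequence[np.ndarray], attr_labels: np.ndarray) -> np.ndarray:
    """Per-draw balance for a sequence of stored partitions."""
    if len(draws) == 0:
        raise InputError("empty draw sequence")
    return np.array([balance(np.asarray(s), attr_labels) for s in draws])


# ---------------------------------------------------------------------------
# Synthetic benchmarks

_LAYOUT_COUNTS = np.array([[20, 30], [30, 20]])  # rows: attribute level; cols: cluster
_LAYOUT_MEANS = np.array(
    [
        [[4.0, 4.0], [10.0, 10.0]],  # level 1 in cluster 1, cluster 2
        [[2.0, 2.0], [8.0, 8.0]],  # level 2 in cluster 1, cluster 2
    ]
)

WELL_SPECIFIED = SyntheticSpec(
    family="gaussian",
    counts=_LAYOUT_COUNTS,
    means=_LAYOUT_MEANS,
    scale=4.0 * np.eye(2),
)

MISSPECIFIED = SyntheticSpec(
    family="student_t",
    counts=_LAYOUT_COUNTS,
    means=_LAYOUT_MEANS,
    scale=3.0 * np.eye(2),
    df=2.0,
)


def generate(spec: SyntheticSpec, seed: int | None = None) -> tuple[LabeledDataset, Partition]:
    """Draw a dataset from a simulation design; returns the true partition too.

    Student-t components use the scale-mixture construction
    ``mu + Z * sqrt(df / V)`` with ``Z ~ N(0, S)`` and ``V ~ chi2(df)``,
    both driven by the same seeded generator.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chol = np.linalg.cholesky(spec.scale)
    blocks, attrs, true = [], [], []
    for k in range(2):  # cluster-major order
        for j in range(2):  # attribute level within cluster
            n = int(spec.counts[j, k])
            z = rng.standard_normal((n, 2)) @ chol.T
            if spec.family == "student_t":
                v = rng.chisquare(spec.df, size=n)
                z = z * np.sqrt(spec.df / v)[:, None]
            blocks.append(spec.means[j, k] + z)
            attrs.append(np.full(n, j + 1))
            true.append(np.full(n, k + 1))
    dataset = LabeledDataset(np.vstack(blocks), np.concatenate(attrs))
    return dataset, Partition(np.concatenate(true), 2)


def generate_well_specified(seed: int) -> tuple[LabeledDataset, Partition]:
    """Two isotropic Gaussian clusters, 100 points, balanced 50/50 attribute."""
    return generate(WELL_SPECIFIED, seed)


def generate_misspecified(seed: int) -> tuple[LabeledDataset, Partition]:
    """Heavy-tailed (Student-t, df=2) version of the two-cluster design."""
    return generate(MISSPECIFIED, seed)


# ---------------------------------------------------------------------------
# Tabular I/O

def read_dataset(path: str | Path, attribute_column: str) -> LabeledDataset:
    """Read a CSV with numeric feature columns plus one attribute column."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if attribute_column not in frame.columns:
        raise InputError(
            f"attribute column {attribute_column!r} not found; available "
            f"columns: {list(frame.columns)}"
        )
    feature_cols = [c for c in frame.columns if c not in (attribute_column, "true_cluster")]
    features = frame[feature_cols]
    numeric = features.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & features.notna()
    if bad.any().any() or features.isna().any().any():
        row = int(np.flatnonzero((bad | features.isna()).any(axis=1))[0])
        raise InputError(f"non-numeric or missing feature value at row {row}")
    return LabeledDataset.from_levels(numeric.to_numpy(float), frame[attribute_column])


def write_dataset(
    path: str | Path,
    dataset: LabeledDataset,
    true_partition: Partition | None = None,
    attribute_column: str = "attribute",
) -> None:
    frame = pd.DataFrame(
        dataset.points, columns=[f"x{i + 1}" for i in range(dataset.d)]
    )
    names = dict(zip((1, 2), dataset.level_names))
    frame[attribute_column] = [names[int(a)] for a in dataset.labels]
    if true_partition is not None:
        frame["true_cluster"] = true_partition.labels
    frame.to_csv(path, index=False, float_format="%.17g")


def write_labels(
    path: str | Path,
    partition: Partition,
    misclassification: np.ndarray | None = None,
    ls_labels: np.ndarray | None = None,
) -> None:
    """Write per-observation cluster labels (and uncertainty if supplied)."""
    out = pd.DataFrame({"observation": np.arange(partition.n), "map_label": partition.labels})
    if ls_labels is not None:
        out["ls_label"] = np.asarray(ls_labels, dtype=int)
    if misclassification is not None:
        out["misclassification"] = np.asarray(misclassification, dtype=float)
    out.to_csv(path, index=False)
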