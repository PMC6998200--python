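"""Frequency stratification of a spontaneous-reporting dataset.

The masking problem: over-reported drugs, ADRs and DECs inflate the expected
count of rarer combinations, depressing their observed-to-expected ratios so
that true signals fall below the IC_025 threshold.  The remedy implemented
here partitions the dataset into strata of similar reporting magnitude and
runs disproportionality *within* each stratum, in three nested levels:

1. cluster drugs by ln report frequency over the whole dataset;
2. within each drug cluster, cluster ADRs by their ln frequency recomputed
   inside that cluster;
3. within each resulting cluster, cluster DECs by their ln count.

Each level chooses its number of clusters k by counting the peaks of the
ln-frequency histogram (bin width 0.5 by default, origin at the scope's
minimum ln frequency) and then solves one-dimensional k-means *exactly* by
dynamic programming over the sorted values -- optimal 1-D clusters are
contiguous, so the global optimum is computable and the whole procedure is
deterministic.  Leaves carry dash-joined path labels ("2-1-3" = drug
cluster 2 -> ADR cluster 1 -> DEC cluster 3) and partition the records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DECCountTable, ReportSet, aggregate

LEVEL_ORDER: tuple[str, ...] = ("drug", "adr", "dec")


@dataclass(frozen=True)
class StratificationConfig:
    """Tuning knobs of the three-level frequency stratification.

    bin_width
        Histogram bin width on the natural-log scale used for peak counting.
    max_k
        Upper clamp on the peak count, guarding against noise-induced
        oversplitting of a ragged histogram.
    min_entities
        Scopes with fewer distinct entities than this are not split (k
        forced to 1); tiny strata cannot support a meaningful histogram.
    """

    bin_width: float = 0.5
    max_k: int = 5
    min_entities: int = 10

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.max_k < 1:
            raise ValueError("max_k must be >= 1")

    @property
    def level_order(self) -> tuple[str, ...]:
        return LEVEL_ORDER


@dataclass(frozen=True)
class ClusterAssignment:
    """1-based cluster labels ordered by ascending cluster centre (ln scale)."""

    labels: np.ndarray
    centers: np.ndarray

    @property
    def k(self) -> int:
        return len(self.centers)


def ln_frequencies(freqs: pd.Series) -> pd.Series:
    """Natural log of per-entity report frequencies (all frequencies >= 1)."""
    arr = freqs.to_numpy()
    if len(arr) and (arr < 1).any():
        raise ValueError("frequencies must be >= 1")
    return pd.Series(np.log(arr.astype(float)), index=freqs.index)


def histogram(values: Sequence[float], bin_width: float = 0.5,
              origin: float | None = None) -> np.ndarray:
    """Fixed-width bin counts; origin defaults to the minimum value.

    Bins are half-open ``[origin + i*w, origin + (i+1)*w)`` with the last
    bin closed on the right, so counts always sum to ``len(values)``.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("histogram requires at least one value")
    if origin is None:
        origin = float(v.min())
    n_bins = max(1, int(np.ceil((v.max() - origin) / bin_width)))
    idx = np.floor((v - origin) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def count_peaks(bin_counts: Sequence[int], max_k: int = 5) -> int:
    """Number of histogram modes, clamped to ``max_k``.

    A peak is a maximal run of equal counts strictly greater than both
    flanking counts (a boundary run need only exceed its single neighbour).
    A flat histogram has no such run and yields k = 1.
    """
    c = np.asarray(list(bin_counts), dtype=np.int64)
    if c.size == 0:
        raise ValueError("bin_counts must be non-empty")
    # compress equal-adjacent runs
    keep = np.ones(c.size, dtype=bool)
    keep[1:] = c[1:] != c[:-1]
    runs = c[keep]
    if runs.size == 1:
        return 1
    peaks = 0
    for i, h in enumerate(runs):
        left_ok = i == 0 or runs[i - 1] < h
        right_ok = i == runs.size - 1 or runs[i + 1] < h
        if left_ok and right_ok:
            peaks += 1
    return int(min(max(peaks, 1), max_k))


def _weighted_kmeans_dp(x: np.ndarray, w: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact weighted 1-D k-means on sorted distinct values.

    Returns (boundaries, centers): ``boundaries[j]`` is the first index of
    cluster j+1, centers are the weighted means.  O(k m^2) dynamic
    programme over contiguous segments, vectorized over split points.
    """
    m = x.size
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cwx = np.concatenate(([0.0], np.cumsum(w * x)))
    cwx2 = np.concatenate(([0.0], np.cumsum(w * x * x)))

    def seg_cost(a: np.ndarray, b: int) -> np.ndarray:
        # within-segment weighted SSE for segments [a, b), vectorized in a
        sw = cw[b] - cw[a]
        sx = cwx[b] - cwx[a]
        sx2 = cwx2[b] - cwx2[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            cost = sx2 - np.where(sw > 0, sx * sx / np.where(sw > 0, sw, 1.0), 0.0)
        return np.maximum(cost, 0.0)

    # D[j][i]: optimal cost of first i values in j clusters
    D = np.full((k + 1, m + 1), np.inf)
    back = np.zeros((k + 1, m + 1), dtype=int)
    D[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, m - (k - j) + 1):
            a = np.arange(j - 1, i)
            tot = D[j - 1, a] + seg_cost(a, i)
            best = int(np.argmin(tot))
            D[j, i] = tot[best]
            back[j, i] = a[best]
    # backtrack
    bounds = np.zeros(k, dtype=int)
    i = m
    for j in range(k, 0, -1):
        bounds[j - 1] = back[j, i]
        i = back[j, i]
    centers = np.empty(k)
    edges = np.concatenate((bounds, [m]))
    for j in range(k):
        a, b = edges[j], edges[j + 1]
        centers[j] = (cwx[b] - cwx[a]) / (cw[b] - cw[a])
    return bounds, centers


def kmeans_1d(values: Sequence[float], k: int) -> ClusterAssignment:
    """Globally optimal one-dimensional k-means.

    Minimizes the within-cluster sum of squared deviations exactly; labels
    are 1-based, renumbered by ascending cluster centre.  Ties (identical
    values) always share a cluster because optimal 1-D clusters are
    contiguous in sorted order.
    """
    v = np.asarray(list(values), dtype=float)
    uniq, inverse, counts = np.unique(v, return_inverse=True, return_counts=True)
    if k < 1 or k > uniq.size:
        raise ValueError(f"k={k} must be in 1..{uniq.size} (distinct values)")
    bounds, centers = _weighted_kmeans_dp(uniq, counts.astype(float), k)
    uniq_labels = np.searchsorted(np.append(bounds[1:], uniq.size),
                                  np.arange(uniq.size), side="right") + 1
    return ClusterAssignment(labels=uniq_labels[inverse], centers=centers)


@dataclass(frozen=True)
class StratumTree:
    """Three-level partition of a dataset's DEC counts.

    ``leaves`` maps a dash-joined path label to the sub-table of DEC counts
    whose records fall in that leaf; every DEC occurs in exactly one leaf
    (its drug fixes level 1, its ADR level 2, its count level 3) and leaf
    record counts sum to the dataset total.  ``metadata`` records one row
    per (level, entity) with the ln frequency and cluster label assigned.
    """

    leaves: dict[str, pd.Series]
    assignment: pd.Series  # DEC (drug, adr) -> path label
    metadata: pd.DataFrame  # level, path, entity_kind, entity_id, ln_frequency, cluster_label
    config: StratificationConfig

    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_sizes(self) -> pd.Series:
        """Record count per leaf."""
        return pd.Series({p: int(s.sum()) for p, s in self.leaves.items()}).sort_index()

    def total(self) -> int:
        return int(sum(s.sum() for s in self.leaves.values()))

    def to_frame(self) -> pd.DataFrame:
        return self.metadata.copy()

    def write_csv(self, path: str | Path) -> None:
        self.metadata.to_csv(path, index=False)


def _entity_frequencies(counts: pd.Series, key: str) -> pd.Series:
    if key == "drug":
        return counts.groupby(level="drug").sum()
    if key == "adr":
        return counts.groupby(level="adr").sum()
    if key == "dec":
        return counts
    raise ValueError(f"unknown stratification key: {key!r}")


def choose_k(lnf: pd.Series, config: StratificationConfig) -> int:
    """Peak-count rule for the number of clusters in one scope."""
    bins = histogram(lnf.to_numpy(), bin_width=config.bin_width)
    k = count_peaks(bins, max_k=config.max_k)
    if len(lnf) < max(k, config.min_entities):
        k = 1
    return min(k, int(pd.unique(lnf).size))


def stratify_level(counts: pd.Series, key: str,
                   config: StratificationConfig) -> tuple[pd.Series, ClusterAssignment, pd.Series]:
    """Cluster one scope by the ln frequency of `key` entities.

    Returns ``(labels_per_dec, assignment, ln_freqs)`` where
    ``labels_per_dec`` gives each DEC row of `counts` the cluster label of
    its key entity.
    """
    freqs = _entity_frequencies(counts, key)
    lnf = ln_frequencies(freqs)
    k = choose_k(lnf, config)
    asg = kmeans_1d(lnf.to_numpy(), k)
    entity_labels = pd.Series(asg.labels, index=freqs.index)
    if key == "drug":
        labels = counts.index.get_level_values("drug").map(entity_labels)
    elif key == "adr":
        labels = counts.index.get_level_values("adr").map(entity_labels)
    else:
        labels = entity_labels
    return pd.Series(np.asarray(labels), index=counts.index), asg, lnf


def stratify_hierarchical(data: ReportSet | DECCountTable,
                          config: StratificationConfig | None = None) -> StratumTree:
    """Build the drug -> ADR -> DEC stratum tree.

    ADR and DEC frequencies are recomputed within the parent cluster, not
    globally: each level smooths the frequency spread left by the previous
    one.  Leaves are labelled "i-j-l" with 1-based labels per level.
    """
    config = config or StratificationConfig()
    counts = (aggregate(data) if isinstance(data, ReportSet) else data).counts
    if counts.empty:
        raise ValueError("cannot stratify an empty dataset")

    meta_rows: list[tuple] = []
    leaves: dict[str, pd.Series] = {}

    def record_meta(level: int, path: str, kind: str, lnf: pd.Series,
                    labels: pd.Series) -> None:
        for ent, lab in labels.items():
            name = "|".join(ent) if isinstance(ent, tuple) else ent
            meta_rows.append((level, path, kind, name, float(lnf[ent]), int(lab)))

    def entity_label_series(counts_scope: pd.Series, key: str):
        labels, asg, lnf = stratify_level(counts_scope, key, config)
        freqs = _entity_frequencies(counts_scope, key)
        ent_labels = pd.Series(asg.labels, index=freqs.index)
        return labels, ent_labels, lnf

    drug_labels, drug_ent, drug_lnf = entity_label_series(counts, "drug")
    record_meta(1, "", "drug", drug_lnf, drug_ent)
    for i in sorted(drug_ent.unique()):
        sub1 = counts[drug_labels == i]
        adr_labels, adr_ent, adr_lnf = entity_label_series(sub1, "adr")
        record_meta(2, str(i), "adr", adr_lnf, adr_ent)
        for j in sorted(adr_ent.unique()):
            sub2 = sub1[adr_labels == j]
            dec_labels, dec_ent, dec_lnf = entity_label_series(sub2, "dec")
            record_meta(3, f"{i}-{j}", "dec", dec_lnf, dec_ent)
            for l in sorted(pd.unique(dec_labels)):
                path = f"{i}-{j}-{l}"
                leaves[path] = sub2[dec_labels == l]

    assignment = pd.concat(
        [pd.Series(path, index=s.index) for path, s in leaves.items()]
    ).reindex(counts.index)
    metadata = pd.DataFrame(
        meta_rows, columns=["level", "path", "entity_kind", "entity_id",
                            "ln_frequency", "cluster_label"])
    tree = StratumTree(leaves=leaves, assignment=assignment, metadata=metadata,
                       config=config)
    if tree.total() != int(counts.sum()):
        raise AssertionError("stratum leaves do not partition the records")
    return tree
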