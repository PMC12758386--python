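"""Arm composition matrix, bootstrap arm clustering, two-step block typing.

The composition matrix holds, per chromosome arm, the fraction of its
satellite units carrying each variant signature.  Arms are clustered
hierarchically on correlation distance with average linkage and plain
nonparametric bootstrap support over variant columns.  Higher-order block
types are derived by two-step k-means: variants are first grouped by their
across-arm frequency profiles, then fixed-width genomic blocks are clustered
by their composition over those variant groups; k for each step maximises
the mean silhouette score over a searched range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

DEFAULT_MIN_UNITS = 2000
DEFAULT_MIN_COUNT = 100


class EmptyMatrixError(ValueError):
    pass


def build_matrix(
    units_by_arm: dict[str, dict[str, int]],
    min_count: int = DEFAULT_MIN_COUNT,
    min_units: int = DEFAULT_MIN_UNITS,
) -> pd.DataFrame:
    """Arms x variant-signatures matrix of normalised counts.

    ``units_by_arm`` maps arm -> {signature: count}.  Arms with fewer than
    ``min_units`` total units are dropped; signatures with genome-wide count
    not strictly greater than ``min_count`` are dropped.  Cells are
    normalised by the arm's total (pre-filter) unit count, so rows sum to at
    most 1.
    """
    totals = {arm: sum(c.values()) for arm, c in units_by_arm.items()}
    kept_arms = [arm for arm, t in totals.items() if t >= min_units]
    if not kept_arms:
        raise EmptyMatrixError(
            f"no arm reaches min_units={min_units} "
            f"(max observed {max(totals.values(), default=0)})")
    genome_counts: dict[str, int] = {}
    for arm in kept_arms:
        for sig, c in units_by_arm[arm].items():
            genome_counts[sig] = genome_counts.get(sig, 0) + c
    kept_sigs = sorted(s for s, c in genome_counts.items() if c > min_count)
    if not kept_sigs:
        raise EmptyMatrixError(f"no signature exceeds min_count={min_count}")
    data = np.zeros((len(kept_arms), len(kept_sigs)))
    for i, arm in enumerate(kept_arms):
        for j, sig in enumerate(kept_sigs):
            data[i, j] = units_by_arm[arm].get(sig, 0) / totals[arm]
    return pd.DataFrame(data, index=kept_arms, columns=kept_sigs)


def correlation_distances(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson correlation distances between rows."""
    values = matrix.to_numpy(dtype=float)
    stds = values.std(axis=1)
    bad = np.flatnonzero(stds == 0)
    if bad.size:
        raise ValueError(
            f"correlation undefined for constant arm row(s): "
            f"{', '.join(matrix.index[i] for i in bad)}")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def _linkage_bipartitions(linkage: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    clusters: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    bipartitions = []
    for k, (a, b, _d, _c) in enumerate(linkage):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + k] = merged
        bipartitions.append(merged)
    return bipartitions


@dataclass
class ArmDendrogram:
    linkage: np.ndarray
    labels: list[str]
    support: dict[frozenset, float]  # percent of bootstrap replicates

    def bipartitions(self) -> list[frozenset]:
        return _linkage_bipartitions(self.linkage, self.labels)

    def to_newick(self) -> str:
        n = len(self.labels)
        names: dict[int, str] = {i: self.labels[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        bips = self.bipartitions()
        for k, (a, b, d, _c) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = d / 2 - heights[a]
            lb = d / 2 - heights[b]
            sup = self.support.get(bips[k], 0.0)
            names[n + k] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g}){sup:.0f}"
            heights[n + k] = d / 2
        return names[n + len(self.linkage) - 1] + ";"


def cluster_arms(
    matrix: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
) -> ArmDendrogram:
    """Average-linkage tree of arms on correlation distance with bootstrap.

    Support for every internal cluster is the percentage of ``n_boot``
    column-resampled replicates whose tree contains the same arm cluster.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 arms to cluster")
    labels = list(matrix.index)
    link = hierarchy.average(correlation_distances(matrix))
    observed = _linkage_bipartitions(link, labels)
    counts = {bip: 0 for bip in observed}
    rng = np.random.default_rng(seed)
    n_cols = matrix.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = matrix.iloc[:, cols]
        try:
            rep_link = hierarchy.average(correlation_distances(rep))
        except ValueError:
            continue
        rep_bips = set(_linkage_bipartitions(rep_link, labels))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    support = {bip: 100.0 * c / max(n_boot, 1) for bip, c in counts.items()}
    support[observed[-1]] = 100.0  # root cluster present in every tree
    return ArmDendrogram(linkage=link, labels=labels, support=support)


@dataclass
class BlockTypeAssignment:
    blocks: pd.DataFrame          # arm, start, end, n_units, block_type
    variant_cluster: dict[str, int]
    k_variants: int
    k_blocks: int
    silhouette_variants: dict[int, float]
    silhouette_blocks: dict[int, float]


def _best_kmeans(
    data: np.ndarray,
    k_range: tuple[int, int],
    n_init: int,
    seed: int,
) -> tuple[np.ndarray, int, dict[int, float]]:
    """k-means labels at the silhouette-optimal k in [k_range]."""
    n = data.shape[0]
    k_lo, k_hi = k_range
    if n <= k_lo:
        raise ValueError(
            f"only {n} items to cluster but smallest k is {k_lo}")
    scores: dict[int, float] = {}
    labels_at: dict[int, np.ndarray] = {}
    for k in range(k_lo, min(k_hi, n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(data)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(data, labels))
        labels_at[k] = labels
    if not scores:
        raise ValueError("silhouette undefined: k-means found a single cluster")
    best_k = max(scores, key=lambda k: (scores[k], -k))
    return labels_at[best_k], best_k, scores


def tile_blocks(
    cap_spans: dict[str, tuple[int, int]],
    block_width: int,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Non-overlapping blocks tiling each cap from its proximal edge.

    A trailing partial block is kept as its own block if it is at least
    ``min_fraction`` of the width, otherwise merged into its neighbour.
    """
    rows = []
    for arm, (cs, ce) in cap_spans.items():
        edges = list(range(cs, ce, block_width))
        spans = [(s, min(s + block_width, ce)) for s in edges]
        if len(spans) > 1 and (spans[-1][1] - spans[-1][0]) < min_fraction * block_width:
            last = spans.pop()
            spans[-1] = (spans[-1][0], last[1])
        for s, e in spans:
            rows.append((arm, s, e))
    return pd.DataFrame(rows, columns=["arm", "start", "end"])


def two_step_kmeans(
    matrix: pd.DataFrame,
    units: pd.DataFrame,
    cap_spans: dict[str, tuple[int, int]],
    block_width: int = 20_000,
    k_range: tuple[int, int] = (5, 20),
    n_init: int = 10,
    seed: int = 0,
) -> BlockTypeAssignment:
    """Two-step k-means block typing.

    Step 1 clusters variant signatures (columns of ``matrix``) by their
    across-arm frequency vectors.  Step 2 represents every genomic block by
    its unit composition over the step-1 variant clusters (fractions summing
    to 1) and clusters the blocks.  Both k are chosen by the silhouette
    score (Euclidean) over ``k_range``.  ``units`` must carry columns
    arm/start/end/signature.  Blocks without any unit carrying a retained
    signature are reported with block_type = -1 and excluded from step 2.
    """
    sig_vectors = matrix.to_numpy(dtype=float).T
    var_labels, k_var, sil_var = _best_kmeans(sig_vectors, k_range, n_init, seed)
    variant_cluster = {sig: int(lab) for sig, lab in zip(matrix.columns, var_labels)}

    blocks = tile_blocks(cap_spans, block_width)
    comp = np.zeros((len(blocks), k_var))
    n_units_per_block = np.zeros(len(blocks), dtype=int)
    units = units[units["signature"].isin(variant_cluster)]
    by_arm = {arm: sub.sort_values("start") for arm, sub in units.groupby("arm")}
    for i, row in enumerate(blocks.itertuples(index=False)):
        sub = by_arm.get(row.arm)
        if sub is None:
            continue
        sel = sub[(sub["start"] >= row.start) & (sub["start"] < row.end)]
        n_units_per_block[i] = len(sel)
        for sig in sel["signature"]:
            comp[i, variant_cluster[sig]] += 1
    covered = n_units_per_block > 0
    comp_frac = comp[covered] / comp[covered].sum(axis=1, keepdims=True)
    if covered.sum() <= k_range[0]:
        raise ValueError("too few blocks with units for the smallest k")
    blk_labels, k_blk, sil_blk = _best_kmeans(comp_frac, k_range, n_init, seed + 1)
    block_type = np.full(len(blocks), -1, dtype=int)
    block_type[covered] = blk_labels
    out = blocks.assign(n_units=n_units_per_block, block_type=block_type)
    return BlockTypeAssignment(
        blocks=out,
        variant_cluster=variant_cluster,
        k_variants=k_var,
        k_blocks=k_blk,
        silhouette_variants=sil_var,
        silhouette_blocks=sil_blk,
    )
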