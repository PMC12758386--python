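"""Spacer alignment, neighbor-joining trees and strict-clock calibration.

Spacer copies are near-identical (>90%) segmental-duplication paralogs, so a
center-star progressive alignment (center = copy with maximal mean pairwise
identity) is adequate; substitution-only input round-trips without gaps.
Trees are built by neighbor joining on Jukes-Cantor-corrected p-distances
with site-resampled bootstrap support, and time-calibrated under a strict
clock against fixed ape divergence times (human vs chimpanzee 6.4, gorilla
8.6, orangutan 15.2, siamang 19.5 MYA).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np

# human-vs-X divergence times (MYA) used for time recalibration
APE_CALIBRATION_AGES = {
    "chimpanzee": 6.4,
    "gorilla": 8.6,
    "orangutan": 15.2,
    "siamang": 19.5,
}

GAP = ord("-")


@dataclass
class SpacerAlignment:
    """A multiple sequence alignment of spacer copies."""

    names: list[str]
    seqs: list[str]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("aligned sequences must have equal length")
        if len(self.names) != len(self.seqs):
            raise ValueError("names/seqs length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def to_array(self) -> np.ndarray:
        return np.vstack([np.frombuffer(s.upper().encode(), dtype=np.uint8)
                          for s in self.seqs])

    def slice_columns(self, start: int, stop: int) -> "SpacerAlignment":
        return SpacerAlignment(self.names, [s[start:stop] for s in self.seqs],
                               self.classes)


def length_filter(seqs: dict[str, str], min_fraction: float = 0.90) -> dict[str, str]:
    """Keep copies longer than ``min_fraction`` of the modal full length."""
    lengths = [len(s) for s in seqs.values()]
    modal = max(sorted(set(lengths)), key=lambda l: (lengths.count(l), l))
    return {k: v for k, v in seqs.items() if len(v) > min_fraction * modal}


def _pairwise_cigar(a: str, b: str,
                    mismatch: int = 1, gap_open: int = 4,
                    gap_extend: int = 1) -> str:
    """Global affine-gap (Gotoh) alignment cigar of a vs b.

    Cost-minimising: match 0, mismatch 1, gap open 4, extend 1.  The stiff
    gap penalty keeps near-identical paralogs aligned column-to-column
    instead of absorbing substitution clusters into spurious indels.
    Ops: = match, X mismatch, I gap in b (a-only base), D gap in a.
    """
    if a == b:
        return f"{len(a)}=" if a else ""
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    la, lb = len(arr_a), len(arr_b)
    BIG = np.int32(1 << 28)
    # M: a[i] aligned to b[j]; X: gap in b (vertical); Y: gap in a (horizontal)
    M = np.full((la + 1, lb + 1), BIG, dtype=np.int32)
    X = np.full((la + 1, lb + 1), BIG, dtype=np.int32)
    Y = np.full((la + 1, lb + 1), BIG, dtype=np.int32)
    M[0, 0] = 0
    X[1:, 0] = gap_open + gap_extend * np.arange(1, la + 1, dtype=np.int32)
    Y[0, 1:] = gap_open + gap_extend * np.arange(1, lb + 1, dtype=np.int32)
    for i in range(1, la + 1):
        sub = np.where(arr_a[i - 1] == arr_b, 0, mismatch).astype(np.int32)
        prev_best = np.minimum(np.minimum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i] = np.minimum(np.minimum(M[i - 1], Y[i - 1]) + gap_open, X[i - 1]) \
            + gap_extend
        X[i, 0] = X[i - 1, 0] + gap_extend if i > 1 else gap_open + gap_extend
        # Y[i, j] = min over k < j of min(M, X)[i, k] + open + (j - k) extend
        base = np.minimum(M[i], X[i]) + gap_open
        shifted = base - gap_extend * np.arange(lb + 1, dtype=np.int32)
        Y[i, 1:] = (np.minimum.accumulate(shifted)[:-1]
                    + gap_extend * np.arange(1, lb + 1, dtype=np.int32))
        Y[i, 0] = BIG
    # traceback
    i, j = la, lb
    state = int(np.argmin([M[i, j], X[i, j], Y[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M: any optimal predecessor state works
            ops.append("=" if arr_a[i - 1] == arr_b[j - 1] else "X")
            i, j = i - 1, j - 1
            state = int(np.argmin([M[i, j], X[i, j], Y[i, j]]))
        elif state == 1:  # X: consume a[i-1], gap in b
            ops.append("I")
            came_open = min(M[i - 1, j], Y[i - 1, j]) + gap_open + gap_extend
            stay = X[i - 1, j] + gap_extend
            i -= 1
            if came_open <= stay:
                state = 0 if M[i, j] <= Y[i, j] else 2
            else:
                state = 1
        else:  # Y: consume b[j-1], gap in a
            ops.append("D")
            came_open = min(M[i, j - 1], X[i, j - 1]) + gap_open + gap_extend
            stay = Y[i, j - 1] + gap_extend
            j -= 1
            if came_open <= stay:
                state = 0 if M[i, j] <= X[i, j] else 1
            else:
                state = 2
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()
    # run-length encode
    cigar = []
    k = 0
    while k < len(ops):
        m = k
        while m < len(ops) and ops[m] == ops[k]:
            m += 1
        cigar.append(f"{m - k}{ops[k]}")
        k = m
    return "".join(cigar)


def align_spacers(
    seqs: dict[str, str],
    min_fraction: float = 0.90,
    classes: dict[str, str] | None = None,
) -> SpacerAlignment:
    """Center-star progressive alignment of spacer copies.

    The center is the copy with maximal mean pairwise identity; every other
    copy is pairwise-aligned to it and the gap patterns are merged.  Indel-
    free input of equal lengths aligns without opening gaps.
    """
    seqs = length_filter(seqs, min_fraction)
    if len(seqs) < 2:
        raise ValueError("need at least 2 spacer copies after length filter")
    names = sorted(seqs)
    strings = [seqs[n] for n in names]
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(strings[i], strings[j], mode="NW",
                            task="distance")["editDistance"]
            ident = 1.0 - d / max(len(strings[i]), len(strings[j]))
            dist[i, j] = dist[j, i] = 1.0 - ident
    center = int(np.argmin(dist.sum(axis=1)))
    c_seq = strings[center]
    Lc = len(c_seq)

    # per-sequence alignment to the center as (gaps-before-center-pos, rows)
    parsed: list[list[tuple[str, int]]] = []
    for i in range(n):
        if i == center:
            parsed.append([])
            continue
        cigar = _pairwise_cigar(c_seq, strings[i])
        parsed.append([(op, int(ln)) for ln, op in re.findall(r"(\d+)([=XID])", cigar)])

    # master gap profile: gaps[c] = max insert length before center position c
    gaps = np.zeros(Lc + 1, dtype=int)
    ins_per_seq: list[dict[int, int]] = []
    for i in range(n):
        ins: dict[int, int] = {}
        c = 0
        for op, ln in parsed[i]:
            if op in "=X":
                c += ln
            elif op == "I":  # center base unmatched (gap in sequence i)
                c += ln
            elif op == "D":  # sequence-i bases inserted before center pos c
                ins[c] = ins.get(c, 0) + ln
        ins_per_seq.append(ins)
        for c_pos, ln in ins.items():
            gaps[c_pos] = max(gaps[c_pos], ln)

    def build_center_row() -> str:
        out = []
        for c in range(Lc):
            out.append("-" * gaps[c])
            out.append(c_seq[c])
        out.append("-" * gaps[Lc])
        return "".join(out)

    def build_row(i: int) -> str:
        if i == center:
            return build_center_row()
        s = strings[i]
        out = []
        c = 0
        si = 0
        pending = 0  # insert length already consumed before center pos c

        def flush_gap(c_pos: int, used: int) -> None:
            out.append("-" * (gaps[c_pos] - used))

        for op, ln in parsed[i]:
            if op == "D":
                out.append(s[si:si + ln])
                si += ln
                pending += ln
            else:
                for _ in range(ln):
                    flush_gap(c, pending)
                    pending = 0
                    if op == "I":
                        out.append("-")
                    else:
                        out.append(s[si])
                        si += 1
                    c += 1
        flush_gap(Lc, pending)
        return "".join(out)

    rows = [build_row(i) for i in range(n)]
    for name, row in zip(names, rows):
        if row.replace("-", "") != seqs[name]:
            raise AssertionError("alignment does not round-trip input")
    return SpacerAlignment(names, rows, classes or {})


def _p_distances_from_array(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    valid = arr != GAP
    dist = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diff = (arr[i] != arr) & both
        with np.errstate(invalid="ignore"):
            dist[i] = diff.sum(axis=1) / both.sum(axis=1)
    np.fill_diagonal(dist, 0.0)
    return dist


def p_distance_matrix(alignment: SpacerAlignment) -> np.ndarray:
    """Pairwise p-distances over columns where both sequences are ungapped."""
    return _p_distances_from_array(alignment.to_array())


def _jc69_from_p(p: np.ndarray, names: list[str]) -> np.ndarray:
    sat = p >= 0.75
    np.fill_diagonal(sat, False)
    if sat.any():
        i, j = np.argwhere(sat)[0]
        raise ValueError(
            f"saturated distance (p >= 0.75) between {names[i]} and {names[j]}")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc69_matrix(alignment: SpacerAlignment) -> np.ndarray:
    """Jukes-Cantor-corrected distance matrix in substitutions/site."""
    return _jc69_from_p(p_distance_matrix(alignment), alignment.names)


def neighbor_joining(
    dist: np.ndarray,
    names: list[str],
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Classic neighbor joining; negative branch lengths are clamped to 0
    with the deficit transferred to the sibling branch."""
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(names)
    nodes = []
    for name in names:
        taxon = tns.get_taxon(name) or tns.new_taxon(name)
        nodes.append(dendropy.Node(taxon=taxon))
    d = dist.astype(float).copy()
    active = list(range(n))
    node_of = {i: nodes[i] for i in active}
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        child_i, child_j = node_of[i], node_of[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = li
        child_j.edge.length = lj
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        node_of[k] = parent
        active = [x for x in active if x not in (i, j)] + [k]
    i, j = active
    root = dendropy.Node()
    child_i, child_j = node_of[i], node_of[j]
    root.add_child(child_i)
    root.add_child(child_j)
    half = max(d[i, j], 0.0) / 2.0
    child_i.edge.length = half
    child_j.edge.length = half
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted splits, each as the side excluding the first taxon."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    all_set = frozenset(labels)
    splits: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(labels) - 1:
            splits.add(side)
    return splits


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds symmetric bipartition difference."""
    return len(tree_splits(tree_a) ^ tree_splits(tree_b))


@dataclass
class NJResult:
    tree: dendropy.Tree
    names: list[str]
    support: dict[frozenset, float]          # split -> percent of replicates
    bootstrap_trees: list[dendropy.Tree]
    distances: np.ndarray


def nj_tree(
    alignment: SpacerAlignment,
    n_boot: int = 1000,
    seed: int = 0,
    distance: str = "jc69",
) -> NJResult:
    """NJ tree with site-resampled bootstrap supports.

    ``distance`` is "jc69" (default) or "p" for the raw p-distance.
    """
    if len(alignment.names) < 4:
        raise ValueError("need at least 4 taxa for a meaningful topology")
    dist_fn = jc69_matrix if distance == "jc69" else p_distance_matrix
    dist = dist_fn(alignment)
    tns = dendropy.TaxonNamespace(alignment.names)
    tree = neighbor_joining(dist, alignment.names, tns)
    observed = tree_splits(tree)
    counts = {s: 0 for s in observed}
    rng = np.random.default_rng(seed)
    boot_trees = []
    L = alignment.n_columns
    arr = alignment.to_array()
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        p = _p_distances_from_array(arr[:, cols])
        try:
            rep_dist = (_jc69_from_p(p, alignment.names)
                        if distance == "jc69" else p)
        except ValueError:
            continue
        rep_tree = neighbor_joining(rep_dist, alignment.names, tns)
        boot_trees.append(rep_tree)
        for s in tree_splits(rep_tree) & counts.keys():
            counts[s] += 1
    denom = max(len(boot_trees), 1)
    support = {s: 100.0 * c / denom for s, c in counts.items()}
    return NJResult(tree=tree, names=alignment.names, support=support,
                    bootstrap_trees=boot_trees, distances=dist)


@dataclass
class CalibratedTree:
    tree: dendropy.Tree
    rate: float                                # substitutions/site/MY
    ages: dict[frozenset, float]               # clade (leaf set) -> age MYA
    age_ci: dict[frozenset, tuple[float, float]]
    calibrations: list[tuple[frozenset, float]]


def _root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    leaf = next(l for l in tree.leaf_node_iter() if l.taxon.label == outgroup)
    length = leaf.edge.length or 0.0
    tree.reroot_at_edge(leaf.edge, length1=length / 2, length2=length / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def _node_depths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Mean node-to-descendant-tip path length per clade (leaf-set keyed)."""
    depths: dict[frozenset, float] = {}
    info: dict[int, tuple[float, int, frozenset]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            info[id(node)] = (0.0, 1, frozenset([node.taxon.label]))
        else:
            total, count = 0.0, 0
            members: set[str] = set()
            for ch in node.child_nodes():
                t, c, mem = info[id(ch)]
                total += t + c * (ch.edge.length or 0.0)
                count += c
                members |= mem
            clade = frozenset(members)
            info[id(node)] = (total, count, clade)
            depths[clade] = total / count
    return depths


def calibrate(
    result: NJResult,
    calibrations: list[tuple[set[str] | frozenset, float]],
    outgroup: str,
    n_boot_ci: int = 100,
) -> CalibratedTree:
    """Strict-clock time calibration against fixed node ages.

    Each calibration is (leaf set, age in MYA); the calibrated node is the
    MRCA of the leaf set after outgroup rooting.  The global rate is the
    least-squares fit (through the origin) of calibrated node depths against
    their set ages; every node age is depth / rate.  Confidence intervals
    are 2.5/97.5 percentiles over the bootstrap trees (at most
    ``n_boot_ci`` of them).
    """
    cals = [(frozenset(taxa), float(age)) for taxa, age in calibrations]
    tip_labels = {n for n in result.names}
    missing = [sorted(t) for t, _ in cals if not set(t) <= tip_labels]
    if missing:
        raise ValueError(f"calibration taxa absent from tree: {missing}")

    def ages_for(tree: dendropy.Tree) -> tuple[dict[frozenset, float], float]:
        rooted = _root_on_outgroup(tree, outgroup)
        depths = _node_depths(rooted)

        def depth_of(taxa: frozenset) -> float:
            best = None
            for clade, dep in depths.items():
                if taxa <= clade and (best is None or len(clade) < len(best[0])):
                    best = (clade, dep)
            if best is None:
                raise ValueError(f"no clade contains calibration set {sorted(taxa)}")
            return best[1]

        d = np.array([depth_of(t) for t, _ in cals])
        a = np.array([age for _, age in cals])
        rate = float((d * a).sum() / (a * a).sum())
        if rate <= 0:
            raise ValueError("non-positive clock rate from calibration fit")
        ages = {clade: dep / rate for clade, dep in depths.items()}
        # enforce root-to-tip monotonicity (ages never increase tipward)
        rooted_nodes = list(rooted.postorder_internal_node_iter())
        clade_of: dict[int, frozenset] = {}
        for node in rooted_nodes:
            clade_of[id(node)] = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter())
        for node in rooted_nodes:
            clade = clade_of[id(node)]
            for ch in node.child_nodes():
                if not ch.is_leaf():
                    ages[clade] = max(ages[clade], ages[clade_of[id(ch)]])
        return ages, rate

    ages, rate = ages_for(result.tree)
    boot_ages: dict[frozenset, list[float]] = {c: [] for c in ages}
    for tree in result.bootstrap_trees[:n_boot_ci]:
        try:
            rep_ages, _ = ages_for(tree)
        except ValueError:
            continue
        for clade, age in rep_ages.items():
            if clade in boot_ages:
                boot_ages[clade].append(age)
    age_ci = {}
    for clade, samples in boot_ages.items():
        if samples:
            lo, hi = np.percentile(samples, [2.5, 97.5])
            age_ci[clade] = (float(lo), float(hi))
    rooted = _root_on_outgroup(result.tree, outgroup)
    return CalibratedTree(tree=rooted, rate=rate, ages=ages, age_ci=age_ci,
                          calibrations=cals)
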