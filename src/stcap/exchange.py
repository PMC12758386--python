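"""Detection and statistical testing of ectopic exchange between caps.

Nonallelic arms that underwent ectopic recombination share a recent
high-identity (>99.5%) segment whose proximal edge marks the exchange
breakpoint.  Pairwise arm alignment is seeded by rare shared k-mers,
chained by diagonal collinearity, and each chained block's identity is
recomputed exactly by (banded) global alignment.  Two statistical tests
probe spacer involvement: a breakpoint-shuffling permutation test of
breakpoint-to-spacer distance, and the half-alignment Robinson-Foulds shift
test, which compares the phylogenetic displacement of half-alignment trees
against a bootstrap-vs-consensus null.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import edlib
import numpy as np
import pandas as pd

from stcap.annotate import revcomp
from stcap.permutation import PermutationResult
from stcap.phylogeny import (
    SpacerAlignment,
    jc69_matrix,
    neighbor_joining,
    nj_tree,
    p_distance_matrix,
    robinson_foulds,
    tree_splits,
)


@dataclass(frozen=True)
class AlignmentBlock:
    query_arm: str
    q_start: int
    q_end: int
    target_arm: str
    t_start: int
    t_end: int
    identity: float
    orientation: str  # "+" or "-"

    @property
    def span(self) -> int:
        return self.q_end - self.q_start


@dataclass(frozen=True)
class ExchangeCandidate:
    arm_a: str
    arm_b: str
    breakpoint_a: int
    breakpoint_b: int
    span: int
    identity: float
    identity_class: str  # ">99.5%" or ">99.8%"


def _kmer_positions(seq: str, k: int, max_occ: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i:i + k], []).append(i)
    return {km: p for km, p in pos.items() if len(p) <= max_occ}


def _chain_anchors(
    anchors: list[tuple[int, int]],
    k: int,
    diag_band: int,
    chain_gap: int,
    min_anchors: int,
) -> list[tuple[int, int, int, int]]:
    """Group collinear anchors into (q_start, q_end, t_start, t_end) chains."""
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a[1] - a[0], a[0]))
    chains = []
    current = [anchors[0]]
    for q, t in anchors[1:]:
        pq, pt = current[-1]
        if abs((t - q) - (pt - pq)) <= diag_band and 0 <= q - pq <= chain_gap:
            current.append((q, t))
        else:
            chains.append(current)
            current = [(q, t)]
    chains.append(current)
    out = []
    for chain in chains:
        if len(chain) < min_anchors:
            continue
        qs = chain[0][0]
        qe = chain[-1][0] + k
        ts = min(t for _, t in chain)
        te = max(t for _, t in chain) + k
        out.append((qs, qe, ts, te))
    return out


def pairwise_identity(
    arm_a: str,
    arm_b: str,
    seq_a: str,
    seq_b: str,
    k: int = 21,
    max_occ: int = 5,
    diag_band: int = 100,
    chain_gap: int = 20_000,
    min_anchors: int = 3,
) -> list[AlignmentBlock]:
    """Collinear high-identity alignment blocks between two arms.

    Anchors are k-mers occurring at most ``max_occ`` times in each arm and
    shared between them; chains of anchors on a consistent diagonal become
    blocks whose identity is recomputed exactly by global alignment of the
    chained substrings (1 - edits / longer length).  The minus strand of
    ``arm_b`` is searched as well; minus-strand blocks report forward-strand
    target coordinates.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    idx_a = _kmer_positions(seq_a, k, max_occ)
    blocks: list[AlignmentBlock] = []
    for orientation in ("+", "-"):
        target = seq_b if orientation == "+" else revcomp(seq_b)
        idx_b = _kmer_positions(target, k, max_occ)
        anchors = []
        for km, qpos in idx_a.items():
            tpos = idx_b.get(km)
            if tpos is None:
                continue
            for q in qpos:
                for t in tpos:
                    anchors.append((q, t))
        for qs, qe, ts, te in _chain_anchors(anchors, k, diag_band,
                                             chain_gap, min_anchors):
            sub_q = seq_a[qs:qe]
            sub_t = target[ts:te]
            d = edlib.align(sub_q, sub_t, mode="NW", task="distance")["editDistance"]
            identity = 1.0 - d / max(len(sub_q), len(sub_t))
            if orientation == "-":
                ts, te = len(seq_b) - te, len(seq_b) - ts
            blocks.append(AlignmentBlock(arm_a, qs, qe, arm_b, ts, te,
                                         identity, orientation))
    blocks.sort(key=lambda b: (b.q_start, b.q_end))
    return blocks


def _refine_breakpoint(
    seq_a: str,
    seq_b: str,
    q_start: int,
    t_start: int,
    q_end: int,
    min_identity: float,
    window: int = 250,
) -> tuple[int, int]:
    """Trim the proximal edge of a merged region to the identity transition.

    Walks windows from the proximal edge along the shared diagonal and drops
    leading windows whose identity is at or below ``min_identity``; the
    breakpoint is the first window that clears it.  The edge is first
    extended proximally while full windows still clear the threshold, since
    anchor chains can start short of the true transition inside repeats.
    """
    def window_identity_at(off: int) -> float:
        a = seq_a[q_start + off:q_start + off + window]
        b = seq_b[t_start + off:t_start + off + window]
        if len(a) < window or len(b) < window:
            return -1.0
        d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        return 1.0 - d / window

    while q_start >= window and t_start >= window \
            and window_identity_at(-window) > min_identity:
        q_start -= window
        t_start -= window
    offset = 0
    while q_start + offset + window <= q_end:
        a = seq_a[q_start + offset:q_start + offset + window]
        b = seq_b[t_start + offset:t_start + offset + window]
        if not b:
            break
        d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        if 1.0 - d / max(len(a), len(b)) > min_identity:
            break
        offset += window
    return q_start + offset, t_start + offset


def _window_ident(seq_a: str, seq_b: str, q: int, t: int, w: int) -> float:
    a = seq_a[q:q + w]
    b = seq_b[t:t + w]
    if len(a) < w // 2 or len(b) < w // 2:
        return -1.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _high_identity_runs(
    seq_a: str,
    seq_b: str,
    q_lo: int,
    q_hi: int,
    diag: int,
    min_identity: float,
    window: int,
) -> list[tuple[int, int]]:
    """Maximal q-ranges along a diagonal whose windows clear min_identity.

    Single failing windows are bridged (at identity just above the
    threshold, individual windows fluctuate below it).
    """
    edges = list(range(q_lo, max(q_hi, q_lo + 1), window))
    passing = [_window_ident(seq_a, seq_b, q, q - diag, window) > min_identity
               for q in edges]
    runs = []
    i = 0
    while i < len(edges):
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(edges) and (
                passing[j + 1] or (j + 2 < len(edges) and passing[j + 2])):
            j += 1
        runs.append((edges[i], min(edges[j] + window, q_hi)))
        i = j + 1
    return runs


def detect_candidates(
    blocks: list[AlignmentBlock],
    min_identity: float = 0.995,
    min_span: int = 10_000,
    merge_gap: int = 5_000,
    min_block_span: int = 1_000,
    sequences: dict[str, str] | None = None,
    coarse_window: int = 1_000,
    refine_window: int = 250,
) -> list[ExchangeCandidate]:
    """Exchange candidates from nonallelic high-identity alignment.

    Blocks at least ``min_block_span`` long (shorter matches are satellite-
    repeat noise) from the same arm pair are clustered by alignment
    diagonal and q-proximity, so unrelated paralogous matches at other
    offsets never join an exchange region.  When ``sequences`` is given,
    each cluster is scanned along its diagonal for maximal runs of windows
    above ``min_identity`` — a chain may extend past the true exchange
    boundary through sub-threshold paralogy, so the run, not the chain,
    defines the candidate — and run edges are refined at ``refine_window``
    resolution.  Without sequences, whole blocks above ``min_identity`` are
    merged as-is.  A region spanning at least ``min_span`` becomes a
    candidate whose breakpoints are its proximal (lowest-coordinate) edges.
    Candidates are sorted by span, descending.
    """
    by_pair: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        if b.span >= min_block_span and (
                sequences is not None or b.identity > min_identity):
            by_pair.setdefault((b.query_arm, b.target_arm), []).append(b)
    candidates = []
    merge_diag = 500
    for (arm_a, arm_b), group in by_pair.items():
        group.sort(key=lambda b: (b.q_start - b.t_start, b.q_start))
        merged: list[list[AlignmentBlock]] = [[group[0]]]
        for b in group[1:]:
            prev = merged[-1][-1]
            same_diag = abs((b.q_start - b.t_start)
                            - (prev.q_start - prev.t_start)) <= merge_diag
            if same_diag and b.q_start - prev.q_end <= merge_gap:
                merged[-1].append(b)
            else:
                merged.append([b])
        for region in merged:
            core = max(region, key=lambda b: b.span)
            diag = core.q_start - core.t_start
            q_lo = min(b.q_start for b in region)
            q_hi = max(b.q_end for b in region)
            if sequences is not None:
                seq_a, seq_b = sequences[arm_a], sequences[arm_b]
                spans = _high_identity_runs(seq_a, seq_b, q_lo, q_hi, diag,
                                            min_identity, coarse_window)
            else:
                weights = np.array([b.span for b in region], dtype=float)
                idents = np.array([b.identity for b in region])
                if (weights * idents).sum() / weights.sum() <= min_identity:
                    continue
                spans = [(q_lo, q_hi)]
            for q_start, q_end in spans:
                t_start = q_start - diag
                if sequences is not None:
                    q_start, t_start = _refine_breakpoint(
                        seq_a, seq_b, q_start, t_start, q_end,
                        min_identity, window=refine_window)
                span = q_end - q_start
                if span < min_span:
                    continue
                if sequences is not None:
                    d = edlib.align(seq_a[q_start:q_end],
                                    seq_b[t_start:t_start + span],
                                    mode="NW", task="distance")["editDistance"]
                    identity = 1.0 - d / span
                else:
                    identity = float((weights * idents).sum() / weights.sum())
                if identity <= min_identity:
                    continue
                candidates.append(ExchangeCandidate(
                    arm_a=arm_a, arm_b=arm_b,
                    breakpoint_a=q_start, breakpoint_b=t_start,
                    span=span, identity=identity,
                    identity_class=">99.8%" if identity > 0.998 else ">99.5%",
                ))
    candidates.sort(key=lambda c: -c.span)
    return candidates


def _distance_to_spacers(pos: int, intervals: np.ndarray) -> int:
    """bp distance from a point to the nearest interval (0 if inside)."""
    best = None
    for s, e in intervals:
        if s <= pos < e:
            return 0
        d = s - pos if pos < s else pos - (e - 1)
        best = d if best is None else min(best, d)
    return best


def breakpoint_spacer_test(
    breakpoints: list[tuple[str, int]],
    spacers: pd.DataFrame,
    cap_spans: dict[str, tuple[int, int]],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of breakpoint proximity to SD spacers.

    Statistic: mean distance from each breakpoint to the nearest spacer bp
    on its own arm (0 inside a spacer).  Null: each breakpoint re-placed
    uniformly within its own cap span.  One-sided, smaller mean distance is
    more extreme (proximity hypothesis).  A one-sided rank-sum comparison of
    the observed per-breakpoint distances against the pooled null distances
    is reported in ``extra``.
    """
    if not breakpoints:
        raise ValueError("need at least one breakpoint")
    if spacers.empty:
        raise ValueError("empty spacer set")
    rng = np.random.default_rng(seed)
    by_arm = {arm: sub[["start", "end"]].to_numpy()
              for arm, sub in spacers.groupby("arm")}
    for arm, _pos in breakpoints:
        if arm not in by_arm:
            raise ValueError(f"no spacers on arm {arm}")

    def distances(points: list[tuple[str, int]]) -> np.ndarray:
        return np.array([_distance_to_spacers(p, by_arm[a]) for a, p in points],
                        dtype=float)

    obs_d = distances(breakpoints)
    observed = float(obs_d.mean())
    null = np.empty(n_perm)
    null_all = []
    for i in range(n_perm):
        placed = [(arm, int(rng.integers(*cap_spans[arm])))
                  for arm, _ in breakpoints]
        d = distances(placed)
        null[i] = d.mean()
        null_all.append(d)
    from scipy.stats import mannwhitneyu

    pooled = np.concatenate(null_all)
    try:
        rank_p = float(mannwhitneyu(obs_d, pooled, alternative="less").pvalue)
    except ValueError:  # all-identical values
        rank_p = 1.0
    return PermutationResult(
        observed=observed, null=null, direction="less",
        extra={"rank_sum_p": rank_p, "n_breakpoints": len(breakpoints)},
    )


@dataclass
class RFShiftResult:
    rf_first: int
    rf_second: int
    p_first: float
    p_second: float
    null: np.ndarray


def rf_shift_test(
    alignment: SpacerAlignment,
    n_boot: int = 1000,
    seed: int = 0,
    distance: str = "jc69",
) -> RFShiftResult:
    """Half-alignment Robinson-Foulds shift test for spacer recombination.

    The alignment is split at column ceil(L/2); trees are built (same NJ
    method as the spacer phylogeny) for the full alignment and each half.
    Observed statistics are RF(full, half_i).  The null is the RF distance
    between each full-alignment bootstrap tree and the majority-rule
    consensus of all bootstrap trees; p_i = (1 + #{null >= observed_i}) /
    (1 + n_boot).
    """
    if len(alignment.names) < 4:
        raise ValueError("need at least 4 taxa")
    L = alignment.n_columns
    half = -(-L // 2)  # ceil
    res = nj_tree(alignment, n_boot=n_boot, seed=seed, distance=distance)
    dist_fn = jc69_matrix if distance == "jc69" else p_distance_matrix
    tns = res.tree.taxon_namespace
    halves = []
    for part in (alignment.slice_columns(0, half),
                 alignment.slice_columns(half, L)):
        halves.append(neighbor_joining(dist_fn(part), part.names, tns))
    if not res.bootstrap_trees:
        raise ValueError("no usable bootstrap replicates")
    consensus = dendropy.TreeList(res.bootstrap_trees,
                                  taxon_namespace=tns).consensus(min_freq=0.5)
    null = np.array([robinson_foulds(consensus, bt)
                     for bt in res.bootstrap_trees], dtype=float)
    rf = [robinson_foulds(res.tree, h) for h in halves]
    p = [(1 + int((null >= r).sum())) / (1 + null.size) for r in rf]
    return RFShiftResult(rf_first=rf[0], rf_second=rf[1],
                         p_first=p[0], p_second=p[1], null=null)


def window_identity(
    blocks: list[AlignmentBlock],
    arm_length: int,
    window: int,
) -> pd.DataFrame:
    """Per-window identity of the query arm from alignment blocks.

    Identity per non-overlapping window is the coverage-weighted mean of
    block identities over the window; windows with no aligned bp are NA.
    """
    starts = np.arange(0, arm_length, window)
    ident = np.full(starts.size, np.nan)
    cover = np.zeros(starts.size)
    weight = np.zeros(starts.size)
    for b in blocks:
        first = b.q_start // window
        last = (b.q_end - 1) // window
        for w in range(first, min(last, starts.size - 1) + 1):
            ws, we = starts[w], min(starts[w] + window, arm_length)
            ov = min(b.q_end, we) - max(b.q_start, ws)
            if ov > 0:
                weight[w] += ov * b.identity
                cover[w] += ov
    mask = cover > 0
    ident[mask] = weight[mask] / cover[mask]
    return pd.DataFrame({"start": starts,
                         "end": np.minimum(starts + window, arm_length),
                         "identity": ident})


def allelic_identity_profile(
    hap1: dict[str, str],
    hap2: dict[str, str],
    window: int = 50_000,
    n_perm: int = 1000,
    seed: int = 0,
    **align_kwargs,
) -> tuple[pd.DataFrame, PermutationResult]:
    """Allelic vs nonallelic window identity and a two-sided label test.

    Arms present in both haplotype dicts under the same name are allelic
    pairs; every cross-name hap1-vs-hap2 combination is a nonallelic pair.
    Each pair is summarised by its mean window identity (NA windows
    excluded); the statistic is mean(allelic) - mean(nonallelic) and labels
    are permuted over pairs.
    """
    shared = sorted(set(hap1) & set(hap2))
    if not shared:
        raise ValueError("no shared arm names between haplotypes")
    for name in shared:
        if window > len(hap1[name]):
            raise ValueError(f"window larger than arm {name}")
    rows = []
    pair_means: list[tuple[str, float]] = []
    for qa in shared:
        for ta in shared:
            kind = "allelic" if qa == ta else "nonallelic"
            blocks = pairwise_identity(qa, ta, hap1[qa], hap2[ta], **align_kwargs)
            tab = window_identity(blocks, len(hap1[qa]), window)
            tab = tab.assign(query=qa, target=ta, kind=kind)
            rows.append(tab)
            vals = tab["identity"].dropna()
            if len(vals):
                pair_means.append((kind, float(vals.mean())))
    table = pd.concat(rows, ignore_index=True)
    labels = np.array([k for k, _ in pair_means])
    means = np.array([m for _, m in pair_means])
    if not (labels == "allelic").any() or not (labels == "nonallelic").any():
        raise ValueError("need both allelic and nonallelic aligned pairs")

    def stat(lab: np.ndarray) -> float:
        return float(means[lab == "allelic"].mean()
                     - means[lab == "nonallelic"].mean())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.permutation(labels)) for _ in range(n_perm)])
    result = PermutationResult(observed=observed, null=null,
                               direction="two-sided",
                               extra={"n_pairs": len(pair_means)})
    return table, result
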