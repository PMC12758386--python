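"""CpG methylation merging/profiling and euchromatin-boundary analyses.

CpG methylation is symmetric, so strand-specific modified/total read counts
are merged per CpG dinucleotide and sites with fewer than five reads are
dropped before fractional methylation is computed.  The euchromatin boundary
of a capped arm is the fixed-width window immediately proximal to the first
(cap-proximal) satellite unit; insertions are called from syntenic alignment
gaps and boundary enrichment of SDs/genes is assessed by an interval-
shuffling permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.stats import ranksums, spearmanr

from stcap.exchange import pairwise_identity
from stcap.permutation import PermutationResult

MIN_READS = 5


@dataclass
class MergeReport:
    n_input: int
    n_sites: int
    n_dropped_low_coverage: int
    n_skipped_non_cpg: int
    input_mod: int
    input_total: int
    merged_mod: int
    merged_total: int


def merge_cpg(
    calls: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    min_reads: int = MIN_READS,
) -> tuple[pd.DataFrame, MergeReport]:
    """Merge strand-specific CpG calls into per-CpG sites.

    ``calls`` columns: chrom, start, end, strand, n_mod, n_total.  Minus-
    strand records belong to the CpG whose plus-strand C is at start-1.
    When ``sequences`` is given, records not landing on a CpG dinucleotide
    are skipped with a warning and counted in the report.  Sites with merged
    coverage below ``min_reads`` are dropped; modified and total read counts
    are conserved before that filter (see the report).
    """
    df = calls.copy()
    df["pos"] = np.where(df["strand"] == "-", df["start"] - 1, df["start"])
    if sequences is not None:
        ok = np.ones(len(df), dtype=bool)
        for i, (chrom, pos) in enumerate(zip(df["chrom"], df["pos"])):
            seq = sequences.get(chrom, "")
            ok[i] = seq[pos:pos + 2].upper() == "CG"
        n_skipped = int((~ok).sum())
        if n_skipped:
            warnings.warn(f"skipped {n_skipped} calls not at a CpG dinucleotide")
        df = df[ok]
    else:
        n_skipped = 0
    merged = (df.groupby(["chrom", "pos"], as_index=False)
                .agg(n_mod=("n_mod", "sum"), n_total=("n_total", "sum")))
    kept = merged[merged["n_total"] >= min_reads].reset_index(drop=True)
    kept = kept.assign(fraction=kept["n_mod"] / kept["n_total"])
    report = MergeReport(
        n_input=len(calls),
        n_sites=len(kept),
        n_dropped_low_coverage=len(merged) - len(kept),
        n_skipped_non_cpg=n_skipped,
        input_mod=int(calls["n_mod"].sum()),
        input_total=int(calls["n_total"].sum()),
        merged_mod=int(merged["n_mod"].sum()),
        merged_total=int(merged["n_total"].sum()),
    )
    return kept, report


def derive_boundary_windows(
    units: pd.DataFrame,
    width: int,
    arm_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Boundary window per arm: ``width`` bp proximal to the first unit.

    Arms are q-style (cap runs to the arm end), so the window lies
    immediately upstream of the most proximal satellite unit, clipped at 0.
    """
    rows = []
    for arm, sub in units.groupby("arm"):
        anchor = int(sub["start"].min())
        rows.append((arm, max(0, anchor - width), anchor))
    return pd.DataFrame(rows, columns=["arm", "start", "end"])


def methylation_profile(
    sites: pd.DataFrame,
    windows: pd.DataFrame,
    bin_width: int = 1000,
) -> pd.DataFrame:
    """Binned mean +- SD methylation across boundary windows.

    Sites are binned by distance to the window's cap-proximal edge (window
    end); bins are aggregated over all windows.  Empty bins are NA.
    """
    width = int((windows["end"] - windows["start"]).max())
    edges = np.arange(0, width + bin_width, bin_width)
    values: list[list[float]] = [[] for _ in range(len(edges) - 1)]
    for row in windows.itertuples(index=False):
        sub = sites[(sites["chrom"] == row.arm)
                    & (sites["pos"] >= row.start) & (sites["pos"] < row.end)]
        dist = row.end - sub["pos"].to_numpy()  # bp proximal to the cap
        which = np.minimum(dist // bin_width, len(values) - 1)
        for b, f in zip(which, sub["fraction"]):
            values[int(b)].append(float(f))
    rows = []
    for i, vals in enumerate(values):
        arr = np.array(vals)
        rows.append((int(edges[i]), int(edges[i + 1]),
                     float(arr.mean()) if arr.size else np.nan,
                     float(arr.std()) if arr.size else np.nan,
                     arr.size))
    return pd.DataFrame(rows, columns=["dist_start", "dist_end",
                                       "mean", "sd", "n"])


def _sites_in(sites: pd.DataFrame, arm: str, start: int, end: int) -> pd.DataFrame:
    return sites[(sites["chrom"] == arm)
                 & (sites["pos"] >= start) & (sites["pos"] < end)]


def compare_feature_methylation(
    sites: pd.DataFrame,
    feature_sets: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-feature-class methylation and pairwise two-sided rank-sum tests.

    ``feature_sets`` maps class name (e.g. satellite / spacer / interstitial)
    to an interval table (arm, start, end).  Returns one row per ordered
    class pair with class means and the rank-sum p over per-site fractions.
    """
    fractions: dict[str, np.ndarray] = {}
    for name, df in feature_sets.items():
        vals = []
        for row in df.itertuples(index=False):
            vals.append(_sites_in(sites, row.arm, row.start, row.end)["fraction"])
        fractions[name] = (pd.concat(vals).to_numpy()
                           if vals else np.array([]))
    rows = []
    names = sorted(feature_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            fa, fb = fractions[a], fractions[b]
            if fa.size and fb.size:
                if np.ptp(np.concatenate([fa, fb])) == 0:
                    p = 1.0
                else:
                    p = float(ranksums(fa, fb).pvalue)
            else:
                p = np.nan
            rows.append((a, b,
                         float(fa.mean()) if fa.size else np.nan,
                         float(fb.mean()) if fb.size else np.nan,
                         p))
    return pd.DataFrame(rows, columns=["class_a", "class_b",
                                       "mean_a", "mean_b", "rank_sum_p"])


def spacer_length_methylation_corr(
    sites: pd.DataFrame,
    spacers: pd.DataFrame,
) -> tuple[float, float]:
    """Spearman correlation of spacer length vs mean spacer methylation."""
    lengths, means = [], []
    for row in spacers.itertuples(index=False):
        sub = _sites_in(sites, row.arm, row.start, row.end)
        if len(sub):
            lengths.append(row.end - row.start)
            means.append(float(sub["fraction"].mean()))
    if len(lengths) < 3:
        raise ValueError("need at least 3 spacers with methylation sites")
    rho, p = spearmanr(lengths, means)
    return float(rho), float(p)


def call_insertions(
    ape_arm: str,
    ape_seq: str,
    ref_seq: str,
    reference_arms: dict[str, str] | None = None,
    min_size: int = 50,
    min_source_identity: float = 0.90,
    min_chain_span: int = 1_000,
    min_chain_identity: float = 0.90,
    **align_kwargs,
) -> pd.DataFrame:
    """Insertions in an ape arm relative to its syntenic reference arm.

    The two arms are chained with :func:`pairwise_identity`; ape intervals
    covered by no chain and at least ``min_size`` bp are emitted as
    insertions.  Each insertion is re-aligned against ``reference_arms`` and
    attributed to the best-identity source above ``min_source_identity``,
    else "unplaced".  Output intervals are disjoint.
    """
    blocks = pairwise_identity(ape_arm, "ref", ape_seq, ref_seq, **align_kwargs)
    covered = sorted((b.q_start, b.q_end) for b in blocks
                     if b.span >= min_chain_span
                     and b.identity >= min_chain_identity)
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # only internal gaps count: uncovered sequence beyond the outermost
    # chains (e.g. anchor-free terminal satellite) is not a reliable call
    gaps = []
    for (s0, e0), (s1, e1) in zip(merged, merged[1:]):
        if s1 - e0 >= min_size:
            gaps.append((e0, s1))
    rows = []
    for s, e in gaps:
        insert = ape_seq[s:e]
        source = "unplaced"
        best = min_source_identity
        for name, seq in (reference_arms or {}).items():
            res = edlib.align(insert, seq, mode="HW", task="distance")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(insert)
            if ident >= best:
                best = ident
                source = name
        rows.append((ape_arm, s, e, e - s, source))
    return pd.DataFrame(rows, columns=["arm", "start", "end", "length", "source"])


def _density(features: pd.DataFrame, windows: pd.DataFrame) -> float:
    """Feature bp inside windows / total window bp."""
    win_by_arm = {arm: sub[["start", "end"]].to_numpy()
                  for arm, sub in windows.groupby("arm")}
    total_window = float((windows["end"] - windows["start"]).sum())
    inside = 0.0
    for row in features.itertuples(index=False):
        for ws, we in win_by_arm.get(row.arm, ()):
            inside += max(0, min(row.end, we) - max(row.start, ws))
    return inside / total_window


def boundary_enrichment_test(
    features: pd.DataFrame,
    windows: pd.DataFrame,
    genome_spans: dict[str, list[tuple[int, int]]],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[PermutationResult, float]:
    """One-sided permutation test of feature enrichment in boundary windows.

    Statistic: feature bp density inside the windows.  Null: every feature
    interval re-placed uniformly (length preserved, overlaps allowed) within
    the genome spans of its arm.  More extreme = null density >= observed.
    Also returns the fold difference, window density / genome-wide density.
    """
    if features.empty:
        raise ValueError("empty feature set")
    rng = np.random.default_rng(seed)
    observed = _density(features, windows)
    span_arrays = {arm: np.array(spans) for arm, spans in genome_spans.items()}
    span_totals = {arm: (arr[:, 1] - arr[:, 0]).sum()
                   for arm, arr in span_arrays.items()}

    def place(arm: str, length: int) -> tuple[int, int]:
        arr = span_arrays[arm]
        weights = np.maximum(arr[:, 1] - arr[:, 0] - length, 1)
        i = rng.choice(len(arr), p=weights / weights.sum())
        lo, hi = arr[i]
        s = int(rng.integers(lo, max(hi - length, lo + 1)))
        return s, s + length

    feats = list(features.itertuples(index=False))
    null = np.empty(n_perm)
    for it in range(n_perm):
        rows = []
        for f in feats:
            s, e = place(f.arm, f.end - f.start)
            rows.append((f.arm, s, e))
        null[it] = _density(pd.DataFrame(rows, columns=["arm", "start", "end"]),
                            windows)
    genome_bp = float(sum(span_totals.values()))
    feature_bp = float((features["end"] - features["start"]).sum())
    genome_density = feature_bp / genome_bp
    fold = observed / genome_density if genome_density > 0 else np.inf
    result = PermutationResult(observed=observed, null=null, direction="greater",
                               extra={"fold": float(fold)})
    return result, float(fold)
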