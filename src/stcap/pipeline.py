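"""End-to-end analysis of a (synthetic) cap genome.

Runs the full chain — unit detection, variant typing, arrays/spacers,
composition matrix, arm clustering, block typing, spacer phylogeny,
exchange detection and tests, methylation and boundary analyses — and
returns a flat summary of the headline numbers.  Used by the smoke tests
and the reproduction script; each stage is the same public function a user
would call directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from stcap import annotate as ann
from stcap import boundary as bnd
from stcap import composition as comp
from stcap import exchange as exch
from stcap import phylogeny as phylo
from stcap import simulate as sim


def annotate_genome(
    sequences: dict[str, str],
    consensus: ann.Consensus | None = None,
    max_gap: int = 5,
):
    """Detect units and derive arrays/spacers for every arm."""
    consensus = consensus or ann.Consensus()
    unit_rows, array_rows, spacer_rows = [], [], []
    cap_spans = {}
    for arm in sorted(sequences):
        units = ann.find_units(sequences[arm], consensus, arm=arm)
        if not units:
            continue
        span = (units[0].start, units[-1].end)
        cap_spans[arm] = span
        arrays, spacers = ann.derive_arrays_and_spacers(units, span, max_gap)
        unit_rows += [(arm, u.start, u.end, u.strand, u.variant_signature,
                       u.identity) for u in units]
        array_rows += [(arm, s, e, n) for s, e, n in arrays]
        spacer_rows += [(arm, s, e) for s, e in spacers]
    units = pd.DataFrame(unit_rows, columns=["arm", "start", "end", "strand",
                                             "signature", "identity"])
    arrays = pd.DataFrame(array_rows, columns=["arm", "start", "end", "n_units"])
    spacers = pd.DataFrame(spacer_rows, columns=["arm", "start", "end"])
    return units, arrays, spacers, cap_spans


def run_pipeline(
    config: sim.SimConfig | None = None,
    seed: int = 0,
    block_width: int = 2048,
    k_range: tuple[int, int] = (2, 10),
    n_boot_arms: int = 100,
    n_boot_tree: int = 100,
    n_perm: int = 500,
    min_units: int = 2000,
    min_count: int = 100,
    min_spacer_length: int = 1000,
) -> dict:
    """Simulate one cap genome and run every analysis stage on it."""
    rng = np.random.default_rng(seed)
    config = config or sim.SimConfig(seed=seed)
    sequences, truth = sim.simulate_cap_genome(config)
    arms = sorted(sequences)

    # plant one conversion-like ectopic exchange between the first two arms,
    # anchored at the spacer nearest each cap's midpoint so the exchanged
    # tail is long enough for the detector's span filter at any seed
    def _mid_spacer_breakpoint(arm: str) -> int:
        cs, ce = truth.cap_spans[arm]
        sub = truth.spacers[truth.spacers["arm"] == arm]
        mid = (cs + ce) // 2
        row = sub.iloc[(((sub["start"] + sub["end"]) // 2) - mid)
                       .abs().argmin()]
        return int((row["start"] + row["end"]) // 2)

    sequences, truth = sim.plant_exchange(
        sequences, truth, sim.ExchangeEvent(arms[0], arms[1]), rng,
        breakpoints=(_mid_spacer_breakpoint(arms[0]),
                     _mid_spacer_breakpoint(arms[1])))
    calls = sim.simulate_methylation(truth, sequences, config, rng)

    summary: dict = {"seed": seed, "n_arms": len(arms)}
    summary["genome_bp"] = int(sum(len(s) for s in sequences.values()))

    # --- satellite annotation ------------------------------------------------
    units, arrays, spacers, cap_spans = annotate_genome(sequences)
    summary["n_units_detected"] = len(units)
    summary["n_units_truth"] = len(truth.units)
    summary["unit_count_ratio"] = len(units) / max(len(truth.units), 1)

    # --- composition matrix, arm tree, block types ---------------------------
    by_arm = {arm: sub["signature"].value_counts().to_dict()
              for arm, sub in units.groupby("arm")}
    matrix = comp.build_matrix(by_arm, min_count=min_count, min_units=min_units)
    dendro = comp.cluster_arms(matrix, n_boot=n_boot_arms, seed=seed)
    summary["arm_tree_newick"] = dendro.to_newick()
    summary["arm_tree_mean_support"] = float(
        np.mean(list(dendro.support.values())))
    assign = comp.two_step_kmeans(matrix, units, cap_spans,
                                  block_width=block_width, k_range=k_range,
                                  seed=seed)
    summary["k_variant_clusters"] = assign.k_variants
    summary["k_block_types"] = assign.k_blocks
    blk = assign.blocks[assign.blocks["block_type"] >= 0]
    truth_map = {(r.arm, r.start): r.block_type
                 for r in truth.blocks.itertuples(index=False)}
    pred, true = [], []
    for r in blk.itertuples(index=False):
        key = (r.arm, r.start)
        if key in truth_map:
            pred.append(r.block_type)
            true.append(truth_map[key])
    summary["block_type_ari"] = (
        float(adjusted_rand_score(true, pred)) if pred else float("nan"))

    # --- spacer phylogeny ----------------------------------------------------
    spacer_seqs = {
        f"{r.arm}:{r.start}": sequences[r.arm][r.start:r.end]
        for r in spacers.itertuples(index=False)
        if r.end - r.start >= min_spacer_length}
    alignment = phylo.align_spacers(spacer_seqs)
    tree_res = phylo.nj_tree(alignment, n_boot=n_boot_tree, seed=seed)
    summary["n_spacers_in_tree"] = len(alignment.names)
    summary["spacer_tree_mean_support"] = float(
        np.mean(list(tree_res.support.values()))) if tree_res.support else 100.0

    # --- exchange detection and tests ----------------------------------------
    blocks = []
    for i, a in enumerate(arms):
        for b in arms[i + 1:]:
            blocks += exch.pairwise_identity(a, b, sequences[a], sequences[b])
    cands = exch.detect_candidates(blocks, min_span=4000, sequences=sequences)
    summary["n_exchange_candidates"] = len(cands)
    if cands:
        c = cands[0]
        bp_true = dict(truth.breakpoints)
        summary["breakpoint_error_bp"] = int(
            max(abs(c.breakpoint_a - bp_true.get(c.arm_a, c.breakpoint_a)),
                abs(c.breakpoint_b - bp_true.get(c.arm_b, c.breakpoint_b))))
        bp_test = exch.breakpoint_spacer_test(
            [(c.arm_a, c.breakpoint_a), (c.arm_b, c.breakpoint_b)],
            spacers, cap_spans, n_perm=n_perm, seed=seed)
        summary["breakpoint_spacer_p"] = float(bp_test.p)
        summary["breakpoint_spacer_observed_bp"] = float(bp_test.observed)
    rf = exch.rf_shift_test(alignment, n_boot=n_boot_tree, seed=seed)
    summary["rf_shift_p_first"] = float(rf.p_first)
    summary["rf_shift_p_second"] = float(rf.p_second)

    # --- methylation and boundary --------------------------------------------
    sites, report = bnd.merge_cpg(calls)
    summary["methylation_reads_conserved"] = float(
        report.merged_total == report.input_total)
    feature_means = bnd.compare_feature_methylation(
        sites, {"satellite": arrays[["arm", "start", "end"]],
                "spacer": spacers[["arm", "start", "end"]]})
    row = feature_means.iloc[0]
    sat = row["mean_a"] if row["class_a"] == "satellite" else row["mean_b"]
    spc = row["mean_b"] if row["class_b"] == "spacer" else row["mean_a"]
    summary["methylation_satellite_mean"] = float(sat)
    summary["methylation_spacer_mean"] = float(spc)
    windows = bnd.derive_boundary_windows(units, config.boundary_width)
    profile = bnd.methylation_profile(sites, windows,
                                      bin_width=max(config.boundary_width // 20,
                                                    250))
    summary["boundary_profile_bins"] = int(profile["n"].gt(0).sum())

    spans = {arm: [(0, truth.cap_spans[arm][0])] for arm in arms}
    sd = truth.features[truth.features["kind"] == "SD"]
    enr, fold = bnd.boundary_enrichment_test(sd, windows, spans,
                                             n_perm=n_perm, seed=seed)
    summary["sd_boundary_fold"] = float(fold)
    summary["sd_boundary_p"] = float(enr.p)

    # --- insertion calling ---------------------------------------------------
    ref = sequences[arms[2]]
    donor = sequences[arms[3]]
    ins_len = 5000
    pos = config.flank_length // 2
    ape = ref[:pos] + donor[1000:1000 + ins_len] + ref[pos:]
    ins = bnd.call_insertions(arms[2], ape, ref,
                              reference_arms={a: sequences[a]
                                              for a in arms if a != arms[2]})
    summary["n_insertions_called"] = len(ins)
    if len(ins):
        best = ins.iloc[(ins["start"] - pos).abs().argmin()]
        summary["insertion_length_error_bp"] = int(abs(best["length"] - ins_len))
        summary["insertion_source_correct"] = float(best["source"] == arms[3])
    return summary
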