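"""Exchange detection, breakpoint permutation test, RF-shift, identity profile."""

import numpy as np
import pandas as pd
import pytest

from stcap.annotate import revcomp
from stcap.exchange import (
    breakpoint_spacer_test,
    detect_candidates,
    pairwise_identity,
    rf_shift_test,
    allelic_identity_profile,
    window_identity,
)
from stcap.phylogeny import SpacerAlignment
from stcap.simulate import (
    ExchangeEvent,
    plant_exchange,
    random_clock_tree,
    random_dna,
    evolve_on_tree,
    simulate_cap_genome,
    SimConfig,
)

import dendropy


def _mutate_fraction(seq: str, frac: float, rng) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < frac
    arr[hit] = np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, int(hit.sum()))]
    return arr.tobytes().decode()


class TestPairwiseIdentity:
    def test_arm_vs_itself_full_identity(self, rng):
        seq = random_dna(20_000, rng)
        blocks = pairwise_identity("a", "a", seq, seq)
        main = max(blocks, key=lambda b: b.span)
        assert main.identity == 1.0
        assert main.span >= 0.99 * len(seq)
        assert main.orientation == "+"

    def test_planted_high_identity_segment(self, rng):
        shared = random_dna(10_000, rng)
        arm_a = random_dna(15_000, rng) + shared + random_dna(15_000, rng)
        noisy = _mutate_fraction(shared, 0.001, rng)
        arm_b = random_dna(12_000, rng) + noisy + random_dna(12_000, rng)
        blocks = pairwise_identity("a", "b", arm_a, arm_b)
        best = max(blocks, key=lambda b: b.span)
        assert best.span >= 0.95 * 10_000
        true_identity = np.mean([x == y for x, y in zip(shared, noisy)])
        assert abs(best.identity - true_identity) < 0.001

    def test_reverse_complement_flips_orientation(self, rng):
        seq_a = random_dna(8_000, rng)
        seq_b = seq_a[2000:6000]
        fwd = pairwise_identity("a", "b", seq_a, seq_b)
        rev = pairwise_identity("a", "b", seq_a, revcomp(seq_b))
        f = max(fwd, key=lambda b: b.span)
        r = max(rev, key=lambda b: b.span)
        assert f.orientation == "+" and r.orientation == "-"
        assert abs(r.t_start - (len(seq_b) - f.t_end)) <= 25
        assert abs(f.q_start - r.q_start) <= 25

    def test_no_shared_kmers_empty(self, rng):
        assert pairwise_identity("a", "b", "A" * 500, "C" * 500) == []


class TestDetectCandidates:
    def test_no_high_identity_blocks_empty(self, rng):
        seq_a = random_dna(30_000, rng)
        seq_b = _mutate_fraction(seq_a, 0.05, rng)  # ~95% identity
        blocks = pairwise_identity("a", "b", seq_a, seq_b)
        assert detect_candidates(blocks, min_span=1000) == []

    def test_planted_exchange_breakpoints_recovered(self, small_genome, rng):
        seqs, truth = small_genome
        arms = sorted(seqs)[:2]
        seqs2, truth2 = plant_exchange(seqs, truth, ExchangeEvent(*arms), rng)
        blocks = pairwise_identity(arms[0], arms[1],
                                   seqs2[arms[0]], seqs2[arms[1]])
        cands = detect_candidates(blocks, min_span=3000, sequences=seqs2)
        assert len(cands) >= 1
        c = cands[0]
        bp_true = dict(truth2.breakpoints)
        assert abs(c.breakpoint_a - bp_true[c.arm_a]) <= 300
        assert abs(c.breakpoint_b - bp_true[c.arm_b]) <= 300

    def test_sorted_by_span(self, small_genome, rng):
        seqs, truth = small_genome
        arms = sorted(seqs)
        seqs2, truth2 = plant_exchange(seqs, truth,
                                       ExchangeEvent(arms[0], arms[1]), rng)
        seqs2, truth2 = plant_exchange(seqs2, truth2,
                                       ExchangeEvent(arms[2], arms[3]), rng)
        blocks = []
        for i in (0, 2):
            blocks += pairwise_identity(arms[i], arms[i + 1],
                                        seqs2[arms[i]], seqs2[arms[i + 1]])
        cands = detect_candidates(blocks, min_span=2000, sequences=seqs2)
        spans = [c.span for c in cands]
        assert spans == sorted(spans, reverse=True)


def _spacer_layout(n_arms=3, cap=50_000, spacer_frac=0.10, n_spacers=5):
    rows = []
    cap_spans = {}
    width = int(cap * spacer_frac / n_spacers)
    for a in range(n_arms):
        arm = f"arm{a}"
        cap_spans[arm] = (0, cap)
        step = cap // n_spacers
        for i in range(n_spacers):
            s = i * step + (step - width) // 2
            rows.append((arm, s, s + width))
    return pd.DataFrame(rows, columns=["arm", "start", "end"]), cap_spans


class TestBreakpointSpacerTest:
    def test_inside_spacers_minimal_p(self, rng):
        spacers, cap_spans = _spacer_layout()
        bps = [("arm0", int(spacers.iloc[i]["start"]) + 5) for i in range(3)]
        res = breakpoint_spacer_test(bps, spacers, cap_spans,
                                     n_perm=199, seed=0)
        assert res.observed == 0.0
        minimal = (1 + int((res.null == 0).sum())) / (1 + res.n_perm)
        assert res.p == pytest.approx(minimal)

    def test_type_one_error_roughly_uniform(self):
        spacers, cap_spans = _spacer_layout()
        rng = np.random.default_rng(42)
        rejections = 0
        runs = 60
        for _ in range(runs):
            bps = [("arm0", int(rng.integers(0, 50_000))) for _ in range(5)]
            res = breakpoint_spacer_test(bps, spacers, cap_spans,
                                         n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        assert rejections / runs <= 0.15

    def test_power_on_planted_breakpoints(self):
        spacers, cap_spans = _spacer_layout(spacer_frac=0.10)
        arm0 = spacers[spacers["arm"] == "arm0"].reset_index(drop=True)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            bps = []
            for _ in range(5):
                row = arm0.iloc[int(rng.integers(len(arm0)))]
                bps.append(("arm0", int(rng.integers(row["start"], row["end"]))))
            res = breakpoint_spacer_test(bps, spacers, cap_spans,
                                         n_perm=199, seed=seed)
            hits += res.p <= 0.05
        assert hits >= 9

    def test_requires_breakpoints_and_spacers(self):
        spacers, cap_spans = _spacer_layout()
        with pytest.raises(ValueError):
            breakpoint_spacer_test([], spacers, cap_spans)
        with pytest.raises(ValueError):
            breakpoint_spacer_test([("arm0", 5)], spacers.iloc[0:0], cap_spans)

    def test_statistic_invariant_to_breakpoint_order(self):
        spacers, cap_spans = _spacer_layout()
        bps = [("arm0", 100), ("arm1", 30_000), ("arm2", 7_500)]
        a = breakpoint_spacer_test(bps, spacers, cap_spans, n_perm=99, seed=4)
        b = breakpoint_spacer_test(bps[::-1], spacers, cap_spans,
                                   n_perm=99, seed=4)
        assert a.observed == b.observed

    def test_p_never_zero(self):
        spacers, cap_spans = _spacer_layout()
        res = breakpoint_spacer_test([("arm0", 10)], spacers, cap_spans,
                                     n_perm=49, seed=1)
        assert res.p > 0


def _balanced(names, depth=0.06):
    a, b, c, d, e, f, g, h = names
    n = ("(((({a}:{x},{b}:{x}):{x},({c}:{x},{d}:{x}):{x}):{y},"
         "(({e}:{x},{f}:{x}):{x},({g}:{x},{h}:{x}):{x}):{y}));")
    return dendropy.Tree.get(
        data=n.format(a=a, b=b, c=c, d=d, e=e, f=f, g=g, h=h,
                      x=depth / 4, y=depth / 2),
        schema="newick")


class TestRFShift:
    def test_clean_alignment_maximal_p(self):
        tree = _balanced(list("abcdefgh"))
        rng = np.random.default_rng(0)
        seqs = evolve_on_tree(tree, random_dna(1500, rng), rng)
        aln = SpacerAlignment(sorted(seqs), [seqs[k] for k in sorted(seqs)])
        res = rf_shift_test(aln, n_boot=100, seed=0)
        assert res.rf_first == 0 and res.rf_second == 0
        assert res.p_first > 0.5 and res.p_second > 0.5

    def test_chimeric_alignment_rejected(self):
        names = list("abcdefgh")
        tree_a = _balanced(names)
        tree_b = _balanced([names[i] for i in (0, 4, 1, 5, 2, 6, 3, 7)])
        rng = np.random.default_rng(3)
        sa = evolve_on_tree(tree_a, random_dna(1000, rng), rng)
        sb = evolve_on_tree(tree_b, random_dna(1000, rng), rng)
        aln = SpacerAlignment(names, [sa[n] + sb[n] for n in names])
        res = rf_shift_test(aln, n_boot=200, seed=0)
        assert min(res.p_first, res.p_second) < 0.01

    def test_needs_four_taxa(self):
        aln = SpacerAlignment(["a", "b", "c"], ["ACGT", "ACGA", "ACGG"])
        with pytest.raises(ValueError):
            rf_shift_test(aln)


class TestAllelicIdentity:
    def test_identical_haplotypes_all_ones(self, rng):
        # arms share ancestry so nonallelic pairs still align
        root = random_dna(12_000, rng)
        arms = {f"chr{i}": _mutate_fraction(root, 0.03, rng) for i in range(2)}
        table, res = allelic_identity_profile(arms, dict(arms), window=3_000,
                                              n_perm=99, seed=0)
        allelic = table[(table["kind"] == "allelic")]
        covered = allelic["identity"].dropna()
        assert len(covered) > 0
        assert np.allclose(covered, 1.0)
        nonallelic = table[table["kind"] == "nonallelic"]["identity"].dropna()
        assert (nonallelic < 1.0).all()
        assert res.observed > 0

    def test_one_percent_divergence_recovered(self, rng):
        hap1 = {"chr1": random_dna(30_000, rng)}
        hap2 = {"chr1": _mutate_fraction(hap1["chr1"], 0.01 / 0.75, rng)}
        # mutation redraws uniformly: /0.75 makes the realised difference 1%
        blocks = pairwise_identity("chr1", "chr1", hap1["chr1"], hap2["chr1"],
                                   chain_gap=50_000)
        tab = window_identity(blocks, 30_000, 5_000)
        mean_ident = tab["identity"].dropna().mean()
        assert abs(mean_ident - 0.99) < 0.002

    def test_window_larger_than_arm_raises(self, rng):
        arms = {"chr1": random_dna(2_000, rng)}
        with pytest.raises(ValueError):
            allelic_identity_profile(arms, dict(arms), window=5_000)

    def test_null_permutation_p_in_range(self, rng):
        # allelic and nonallelic arms all equidistant from a common root:
        # the label test should not reject strongly
        root = random_dna(9_000, rng)
        hap1 = {f"c{i}": _mutate_fraction(root, 0.01, rng) for i in range(3)}
        hap2 = {f"c{i}": _mutate_fraction(root, 0.01, rng) for i in range(3)}
        _, res = allelic_identity_profile(hap1, hap2, window=3_000,
                                          n_perm=199, seed=1)
        assert 0 < res.p <= 1
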