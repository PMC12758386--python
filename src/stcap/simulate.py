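"""Synthetic subterminal cap genomes with full ground truth.

Each simulated chromosome arm is laid out as::

    euchromatic flank | array . spacer . array . spacer ... array  (terminal)

mirroring the cap architecture of African great ape q-arm telomeres: tandem
arrays of a 32 bp satellite unit interleaved with segmental-duplication
"spacer" copies, with the cap running to the end of the arm.  Everything that
downstream modules estimate is recorded as truth: unit intervals and variant
signatures, higher-order block labels, spacer intervals with their position
in a known duplication tree, planted ectopic-exchange breakpoints, per-CpG
methylation probabilities and boundary feature annotations.

Dimensions are desk-scale by default (2 kbp spacers rather than the real
32-34 kbp, 50 kbp boundary windows rather than 2 Mbp) and are all
configurable.  Spacer evolution is substitution-only (Jukes-Cantor events
along the configured tree) so that multiple sequence alignment of the copies
is column-true by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from stcap.annotate import PCHT_CONSENSUS, apply_signature

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def random_dna(n: int, rng: np.random.Generator) -> str:
    return _array_to_seq(_BASES[rng.integers(0, 4, n)])


def random_clock_tree(
    n_leaves: int,
    rng: np.random.Generator,
    depth: float = 0.05,
    prefix: str = "t",
) -> dendropy.Tree:
    """Random ultrametric (clock-like) tree with root depth ``depth`` subs/site.

    Topology and relative node times follow a Kingman coalescent; times are
    rescaled so the root sits at exactly ``depth``.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    taxa = dendropy.TaxonNamespace([f"{prefix}{i}" for i in range(n_leaves)])
    nodes = []
    for i in range(n_leaves):
        node = dendropy.Node(taxon=taxa[i])
        node.age_t = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.age_t = t
        parent.add_child(a)
        parent.add_child(b)
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    scale = depth / root.age_t
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (node.parent_node.age_t - node.age_t) * scale
    tree.is_rooted = True
    return tree


def evolve_on_tree(
    tree: dendropy.Tree,
    root_seq: str,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve ``root_seq`` along ``tree`` under Jukes-Cantor substitutions.

    Branch lengths are in expected substitutions/site.  Mutation events hit
    each site as a Poisson process and redraw the base uniformly from the
    four nucleotides, so the probability a site differs across a branch of
    length b is (3/4)(1 - exp(-4b/3)).  Returns leaf name -> sequence.
    """
    root_arr = _seq_to_array(root_seq)
    seqs: dict[str, str] = {}
    stack = [(tree.seed_node, root_arr)]
    while stack:
        node, arr = stack.pop()
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            if b < 0:
                raise ValueError("negative branch length")
            child_arr = arr.copy()
            if b > 0:
                hit = rng.random(child_arr.size) < -np.expm1(-4.0 * b / 3.0)
                child_arr[hit] = _BASES[rng.integers(0, 4, int(hit.sum()))]
            if child.is_leaf():
                seqs[child.taxon.label] = _array_to_seq(child_arr)
            else:
                stack.append((child, child_arr))
    return seqs


@dataclass(frozen=True)
class MethylationParams:
    """Beta-binomial CpG methylation model parameters.

    ``*_mean`` is the expected methylated fraction, ``*_conc`` the
    beta concentration (larger = less site-to-site spread); coverage per
    strand is Poisson with mean ``coverage_mean / 2``.
    """

    satellite_mean: float = 0.80
    satellite_conc: float = 50.0
    spacer_mean: float = 0.40
    spacer_conc: float = 50.0
    flank_mean: float = 0.70
    flank_conc: float = 50.0
    coverage_mean: float = 30.0


@dataclass(frozen=True)
class ExchangeEvent:
    """A planted ectopic exchange between two arms.

    ``mode='swap'`` exchanges the distal tails reciprocally; ``mode='copy'``
    replaces arm_a's tail with a copy of arm_b's tail (conversion-like,
    non-reciprocal).  Only the copy mode leaves the within-genome
    high-identity signature that the exchange detector looks for; a
    reciprocal swap of divergent tails leaves no shared sequence between
    the two product arms.
    """

    arm_a: str
    arm_b: str
    placement: str = "in_spacer"  # or "uniform"
    mode: str = "copy"            # or "swap"


@dataclass
class SimConfig:
    """Parameters of one synthetic cap genome.

    Structural sizes are in units/bp; the defaults generate ~6 arms of
    ~190 kbp each (~1.2 Mbp genome).  ``block_units`` satellite units form
    one higher-order block (64 x 32 bp = 2048 bp); arrays are whole numbers
    of blocks and the default spacer length equals one block so the block
    grid stays in phase across a cap.
    """

    seed: int = 0
    n_arms: int = 6
    blocks_per_array: tuple[int, int] = (3, 5)
    arrays_per_cap: tuple[int, int] = (12, 16)
    unit_consensus: str = PCHT_CONSENSUS
    block_units: int = 64
    n_block_types: int = 4
    signatures_per_group: int = 3
    within_group_weight: float = 0.85
    block_type_profiles: list[list[tuple[str, float]]] | None = None
    spacer_length: int = 2048
    spacer_tree: str | None = None  # newick; default random clock tree
    spacer_tree_depth: float = 0.05
    flank_length: int = 120_000
    boundary_width: int = 20_000
    boundary_fold: float = 5.0
    n_sd_features: int = 40
    n_gene_features: int = 30
    feature_length: int = 500
    exchange_events: list[ExchangeEvent] = field(default_factory=list)
    methylation: MethylationParams = field(default_factory=MethylationParams)

    def validate(self) -> None:
        import re as _re

        if not _re.fullmatch("[ACGT]+", self.unit_consensus.upper()):
            raise ValueError("unit consensus must be ACGT-only")
        for name in ("n_arms", "block_units", "spacer_length", "flank_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for rng_field in (self.blocks_per_array, self.arrays_per_cap):
            if rng_field[0] < 1 or rng_field[1] < rng_field[0]:
                raise ValueError("count ranges must be positive and ordered")
        if self.block_type_profiles is not None:
            if not self.block_type_profiles:
                raise ValueError("empty variant profile")
            for profile in self.block_type_profiles:
                if not profile:
                    raise ValueError("empty variant profile")
                total = sum(f for _, f in profile)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError("profile frequencies must sum to 1")


@dataclass
class SimTruth:
    """Ground truth for one simulated genome (BED-convention intervals)."""

    units: pd.DataFrame        # arm, start, end, signature, block_type
    arrays: pd.DataFrame       # arm, start, end, n_units
    spacers: pd.DataFrame      # arm, start, end, leaf
    blocks: pd.DataFrame       # arm, start, end, block_type
    features: pd.DataFrame     # arm, start, end, kind
    cap_spans: dict[str, tuple[int, int]]
    arm_lengths: dict[str, int]
    spacer_tree: str           # newick
    breakpoints: list[tuple[str, int]] = field(default_factory=list)
    methylation_prob: pd.DataFrame | None = None  # arm, pos, p_true
    block_type_profiles: list[list[tuple[str, float]]] | None = None

    def to_json_sidecar(self) -> str:
        payload = {
            "spacer_tree": self.spacer_tree,
            "cap_spans": {k: list(v) for k, v in self.cap_spans.items()},
            "arm_lengths": self.arm_lengths,
            "breakpoints": [list(bp) for bp in self.breakpoints],
        }
        return json.dumps(payload, indent=2)


def default_block_type_profiles(config: SimConfig, rng: np.random.Generator) -> list[list[tuple[str, float]]]:
    """One variant-signature profile per higher-order block type.

    ``n_block_types`` groups of single-substitution signatures at distinct
    consensus positions; block type t draws ``within_group_weight`` of its
    units from group t and spreads the rest uniformly over the other groups.
    """
    consensus = config.unit_consensus.upper()
    k = config.n_block_types
    m = config.signatures_per_group
    if k * m > len(consensus):
        raise ValueError("not enough consensus positions for distinct signatures")
    positions = rng.choice(len(consensus), size=k * m, replace=False)
    groups: list[list[str]] = []
    for g in range(k):
        sigs = []
        for j in range(m):
            pos = int(positions[g * m + j])
            ref = consensus[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            sigs.append(f"SUB{pos}{ref}>{alt}")
        groups.append(sigs)
    profiles: list[list[tuple[str, float]]] = []
    w_in = config.within_group_weight
    for t in range(k):
        profile: list[tuple[str, float]] = []
        for g in range(k):
            weight = w_in if g == t else (1.0 - w_in) / (k - 1) if k > 1 else 0.0
            for sig in groups[g]:
                profile.append((sig, weight / m))
        total = sum(f for _, f in profile)
        profiles.append([(s, f / total) for s, f in profile])
    return profiles


def _draw_block_units(profile, n_units, consensus, rng):
    sigs = [s for s, _ in profile]
    freqs = np.array([f for _, f in profile])
    idx = rng.choice(len(sigs), size=n_units, p=freqs / freqs.sum())
    seqs = [apply_signature(consensus, sigs[i]) for i in idx]
    return [sigs[i] for i in idx], seqs


def simulate_cap_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate arm sequences and full ground truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    consensus = config.unit_consensus.upper()
    profiles = config.block_type_profiles
    if profiles is None:
        profiles = default_block_type_profiles(config, rng)
    n_types = len(profiles)

    # arm block-type propensities differ so arm composition distinguishes arms
    arm_names = [f"sim.h1.chr{i + 1}q" for i in range(config.n_arms)]
    arm_type_props = rng.dirichlet(np.ones(n_types), size=config.n_arms)

    # spacer copies per arm decided first so the tree can cover all of them
    arrays_per_arm = rng.integers(config.arrays_per_cap[0],
                                  config.arrays_per_cap[1] + 1,
                                  size=config.n_arms)
    spacers_per_arm = arrays_per_arm - 1
    total_spacers = int(spacers_per_arm.sum())

    if config.spacer_tree is not None:
        tree = dendropy.Tree.get(data=config.spacer_tree, schema="newick")
        leaf_names = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(leaf_names) < total_spacers:
            raise ValueError(
                f"spacer tree has {len(leaf_names)} leaves but "
                f"{total_spacers} spacer copies are required")
    else:
        tree = random_clock_tree(max(total_spacers, 2), rng,
                                 depth=config.spacer_tree_depth, prefix="sp")
        leaf_names = [f"sp{i}" for i in range(max(total_spacers, 2))]
    root_spacer = random_dna(config.spacer_length, rng)
    spacer_seqs = evolve_on_tree(tree, root_spacer, rng)

    sequences: dict[str, str] = {}
    unit_rows, array_rows, spacer_rows, block_rows, feature_rows = [], [], [], [], []
    cap_spans: dict[str, tuple[int, int]] = {}
    arm_lengths: dict[str, int] = {}
    leaf_cursor = 0
    for a, arm in enumerate(arm_names):
        parts: list[str] = []
        pos = 0
        flank = random_dna(config.flank_length, rng)
        parts.append(flank)
        pos += config.flank_length
        cap_start = pos
        n_arrays = int(arrays_per_arm[a])
        for ai in range(n_arrays):
            n_blocks = int(rng.integers(config.blocks_per_array[0],
                                        config.blocks_per_array[1] + 1))
            array_start = pos
            n_units_total = 0
            for _b in range(n_blocks):
                btype = int(rng.choice(n_types, p=arm_type_props[a]))
                block_start = pos
                sigs, seqs = _draw_block_units(profiles[btype],
                                               config.block_units, consensus, rng)
                for sig, useq in zip(sigs, seqs):
                    unit_rows.append((arm, pos, pos + len(useq), sig, btype))
                    parts.append(useq)
                    pos += len(useq)
                n_units_total += config.block_units
                block_rows.append((arm, block_start, pos, btype))
            array_rows.append((arm, array_start, pos, n_units_total))
            if ai < n_arrays - 1:
                leaf = leaf_names[leaf_cursor]
                leaf_cursor += 1
                sp_seq = spacer_seqs[leaf]
                spacer_rows.append((arm, pos, pos + len(sp_seq), leaf))
                parts.append(sp_seq)
                pos += len(sp_seq)
        cap_spans[arm] = (cap_start, pos)
        arm_lengths[arm] = pos
        sequences[arm] = "".join(parts)

        # boundary features in the euchromatic flank; boundary_fold is the
        # target ratio of window density to flank-wide density
        window_start = cap_start - config.boundary_width
        w = config.boundary_width
        p_window = min(config.boundary_fold * w / config.flank_length, 1.0)
        for kind, n_feat in (("SD", config.n_sd_features // config.n_arms),
                             ("gene", config.n_gene_features // config.n_arms)):
            for _ in range(n_feat):
                flen = config.feature_length
                if rng.random() < p_window:
                    lo, hi = window_start, cap_start - flen
                else:
                    lo, hi = 0, window_start - flen
                s = int(rng.integers(lo, hi)) if hi > lo else lo
                feature_rows.append((arm, s, min(s + flen, cap_start), kind))

    truth = SimTruth(
        units=pd.DataFrame(unit_rows, columns=["arm", "start", "end", "signature", "block_type"]),
        arrays=pd.DataFrame(array_rows, columns=["arm", "start", "end", "n_units"]),
        spacers=pd.DataFrame(spacer_rows, columns=["arm", "start", "end", "leaf"]),
        blocks=pd.DataFrame(block_rows, columns=["arm", "start", "end", "block_type"]),
        features=pd.DataFrame(feature_rows, columns=["arm", "start", "end", "kind"]),
        cap_spans=cap_spans,
        arm_lengths=arm_lengths,
        spacer_tree=tree.as_string(schema="newick").strip(),
        block_type_profiles=profiles,
    )
    for event in config.exchange_events:
        sequences, truth = plant_exchange(sequences, truth, event, rng)
    return sequences, truth


def _cpg_positions(seq: str) -> np.ndarray:
    arr = _seq_to_array(seq)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def simulate_methylation(
    truth: SimTruth,
    sequences: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-strand bedMethyl-like calls for every CpG of every arm.

    Emits one row per strand per CpG (chrom, start, end, strand, n_mod,
    n_total).  The truth methylation probability per CpG is appended to
    ``truth.methylation_prob``.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    m = config.methylation
    rows = []
    prob_rows = []
    for arm, seq in sequences.items():
        pos = _cpg_positions(seq)
        if pos.size == 0:
            continue
        region_mean = np.full(pos.size, m.flank_mean)
        region_conc = np.full(pos.size, m.flank_conc)
        for df, mean, conc in ((truth.arrays, m.satellite_mean, m.satellite_conc),
                               (truth.spacers, m.spacer_mean, m.spacer_conc)):
            sub = df[df["arm"] == arm]
            for s, e in zip(sub["start"], sub["end"]):
                mask = (pos >= s) & (pos < e)
                region_mean[mask] = mean
                region_conc[mask] = conc
        with np.errstate(divide="ignore"):
            alpha = region_mean * region_conc
            beta = (1.0 - region_mean) * region_conc
        p_true = np.where(
            (region_mean <= 0) | (region_mean >= 1) | ~np.isfinite(region_conc),
            region_mean,
            rng.beta(np.clip(alpha, 1e-12, None), np.clip(beta, 1e-12, None)),
        )
        for strand, offset in (("+", 0), ("-", 1)):
            cov = rng.poisson(m.coverage_mean / 2.0, size=pos.size)
            mod = rng.binomial(cov, p_true)
            for p, c, md in zip(pos, cov, mod):
                rows.append((arm, int(p + offset), int(p + offset + 1), strand,
                             int(md), int(c)))
        for p, pt in zip(pos, p_true):
            prob_rows.append((arm, int(p), float(pt)))
    truth.methylation_prob = pd.DataFrame(prob_rows, columns=["arm", "pos", "p_true"])
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "n_mod", "n_total"])


def _remap_intervals(df: pd.DataFrame, arm_a: str, arm_b: str,
                     bp_a: int, bp_b: int) -> pd.DataFrame:
    """Swap interval coordinates distal to the breakpoints between two arms.

    Intervals spanning a breakpoint are split at it.
    """
    rows = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        arm, s, e = rec["arm"], rec["start"], rec["end"]
        if arm not in (arm_a, arm_b):
            rows.append(rec)
            continue
        bp_self, bp_other, other = (
            (bp_a, bp_b, arm_b) if arm == arm_a else (bp_b, bp_a, arm_a))
        pieces = []
        if s < bp_self:
            pieces.append((arm, s, min(e, bp_self)))
        if e > bp_self:
            ds, de = max(s, bp_self), e
            pieces.append((other, bp_other + (ds - bp_self), bp_other + (de - bp_self)))
        for parm, ps, pe in pieces:
            out = dict(rec)
            out["arm"], out["start"], out["end"] = parm, ps, pe
            rows.append(out)
    return pd.DataFrame(rows, columns=df.columns)


def _copy_intervals(df: pd.DataFrame, arm_a: str, arm_b: str,
                    bp_a: int, bp_b: int) -> pd.DataFrame:
    """Replace arm_a annotation distal to bp_a with a copy of arm_b's."""
    rows = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        arm, s, e = rec["arm"], rec["start"], rec["end"]
        if arm == arm_a:
            if s >= bp_a:
                continue
            if e > bp_a:
                rec = dict(rec)
                rec["end"] = bp_a
            rows.append(rec)
            continue
        rows.append(rec)
        if arm == arm_b and e > bp_b:
            dup = dict(rec)
            ds = max(s, bp_b)
            dup["arm"] = arm_a
            dup["start"] = bp_a + (ds - bp_b)
            dup["end"] = bp_a + (e - bp_b)
            rows.append(dup)
    return pd.DataFrame(rows, columns=df.columns)


def plant_exchange(
    sequences: dict[str, str],
    truth: SimTruth,
    event: ExchangeEvent,
    rng: np.random.Generator | None = None,
    breakpoints: tuple[int, int] | None = None,
) -> tuple[dict[str, str], SimTruth]:
    """Swap distal tails of two arms at breakpoints inside their caps.

    With ``placement='in_spacer'`` each breakpoint is placed strictly within
    a spacer interval of its arm; ``'uniform'`` places it uniformly in the
    cap span.  Explicit ``breakpoints`` override placement.
    """
    rng = rng or np.random.default_rng(0)
    for arm in (event.arm_a, event.arm_b):
        if arm not in sequences:
            raise ValueError(f"unknown arm {arm!r}")

    def _draw(arm: str) -> int:
        cs, ce = truth.cap_spans[arm]
        if event.placement == "in_spacer":
            sub = truth.spacers[truth.spacers["arm"] == arm]
            if sub.empty:
                raise ValueError(f"no spacers on {arm}")
            row = sub.iloc[int(rng.integers(len(sub)))]
            return int(rng.integers(row["start"] + 1, row["end"] - 1))
        return int(rng.integers(cs + 1, ce - 1))

    if breakpoints is not None:
        bp_a, bp_b = breakpoints
    else:
        bp_a, bp_b = _draw(event.arm_a), _draw(event.arm_b)
    for arm, bp in ((event.arm_a, bp_a), (event.arm_b, bp_b)):
        cs, ce = truth.cap_spans[arm]
        if not (cs <= bp < ce):
            raise ValueError(f"breakpoint {bp} outside cap span of {arm}")

    seq_a, seq_b = sequences[event.arm_a], sequences[event.arm_b]
    sequences = dict(sequences)
    sequences[event.arm_a] = seq_a[:bp_a] + seq_b[bp_b:]
    if event.mode == "swap":
        sequences[event.arm_b] = seq_b[:bp_b] + seq_a[bp_a:]
        remap = _remap_intervals
    elif event.mode == "copy":
        remap = _copy_intervals
    else:
        raise ValueError(f"unknown exchange mode {event.mode!r}")

    new_len_a = len(sequences[event.arm_a])
    new_len_b = len(sequences[event.arm_b])
    truth = replace(
        truth,
        units=remap(truth.units, event.arm_a, event.arm_b, bp_a, bp_b),
        arrays=remap(truth.arrays, event.arm_a, event.arm_b, bp_a, bp_b),
        spacers=remap(truth.spacers, event.arm_a, event.arm_b, bp_a, bp_b),
        blocks=remap(truth.blocks, event.arm_a, event.arm_b, bp_a, bp_b),
        cap_spans={**truth.cap_spans,
                   event.arm_a: (truth.cap_spans[event.arm_a][0], new_len_a),
                   event.arm_b: (truth.cap_spans[event.arm_b][0], new_len_b)},
        arm_lengths={**truth.arm_lengths,
                     event.arm_a: new_len_a, event.arm_b: new_len_b},
        breakpoints=truth.breakpoints + [(event.arm_a, bp_a), (event.arm_b, bp_b)],
    )
    return sequences, truth
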