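"""Satellite unit detection, variant typing and array/spacer derivation.

The subterminal satellite (pCht/StSat) is a 32 bp unit that occurs in long
tandem arrays.  Units are detected against a consensus by seeded semi-global
alignment: every alignment of the full consensus to a substring of the arm
with at most ``max_edits`` Levenshtein edits is a candidate hit, and
overlapping candidates are resolved greedily by identity, then leftmost
start.  A hit must retain strictly more than ``min_match_fraction`` of the
consensus positions (for the default 32-mer at 0.90 that means >28, i.e. at
least 29, matched positions, so at most 3 edits).

Each accepted unit carries a canonical *variant signature*: the ordered list
of differences from the consensus (substitutions, insertions, deletions in
consensus coordinates).  Signatures are the atoms of the higher-order
composition analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

# pCht/StSat consensus repeat unit of the African great ape subterminal caps.
PCHT_CONSENSUS = "gatatttccatgtttatacagatagcggtgta".upper()

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Consensus:
    """Satellite consensus and acceptance threshold.

    ``min_match_fraction`` is the fraction of consensus positions that must be
    retained (matched, strictly greater-than) for a hit to be accepted.
    """

    sequence: str = PCHT_CONSENSUS
    min_match_fraction: float = 0.90

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or not re.fullmatch("[ACGT]+", seq):
            raise ValueError("consensus must be non-empty and ACGT-only")
        if not (0.0 < self.min_match_fraction <= 1.0):
            raise ValueError("min_match_fraction must be in (0, 1]")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def min_matches(self) -> int:
        """Minimum number of retained consensus positions (strict > bound)."""
        return int(np.floor(self.min_match_fraction * len(self.sequence))) + 1

    @property
    def max_edits(self) -> int:
        """Maximum Levenshtein edits compatible with ``min_matches``."""
        return len(self.sequence) - self.min_matches


@dataclass(frozen=True)
class SatelliteUnit:
    """One detected occurrence of the consensus unit."""

    arm: str
    start: int
    end: int
    strand: str
    variant_signature: str
    identity: float

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _edits_from_cigar(cigar: str, consensus: str, observed: str) -> list[str]:
    """Canonical edit list (consensus coordinates) from an edlib NW cigar.

    The cigar is for align(query=consensus, target=observed): I consumes
    query only (consensus base deleted from the unit), D consumes target only
    (base inserted relative to the consensus).
    """
    edits: list[str] = []
    ci = 0  # consensus index
    oi = 0  # observed index
    for length, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(length)
        if op == "=":
            ci += n
            oi += n
        elif op == "X":
            for k in range(n):
                edits.append(f"SUB{ci + k}{consensus[ci + k]}>{observed[oi + k]}")
            ci += n
            oi += n
        elif op == "I":  # consensus base missing from observed unit
            for k in range(n):
                edits.append(f"DEL{ci + k}{consensus[ci + k]}>-")
            ci += n
        elif op == "D":  # extra base in observed unit, before consensus pos ci
            edits.append(f"INS{ci}->{observed[oi:oi + n]}")
            oi += n
    return edits


def signature_of(consensus: str, observed: str) -> str:
    """Canonical variant signature of ``observed`` against ``consensus``.

    Empty string iff the sequences are identical.  Edits are reported in
    ascending consensus position (the edlib alignment path is deterministic).
    """
    if observed == consensus:
        return ""
    res = edlib.align(consensus, observed, mode="NW", task="path")
    return ";".join(_edits_from_cigar(res["cigar"], consensus, observed))


def apply_signature(consensus: str, signature: str) -> str:
    """Inverse of :func:`signature_of`: build the unit sequence from edits."""
    if not signature:
        return consensus
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, str] = {}
    for edit in signature.split(";"):
        m = re.fullmatch(r"(SUB|DEL|INS)(\d+)(.*)>(.*)", edit)
        if not m:
            raise ValueError(f"malformed edit {edit!r}")
        cls, pos, _ref, alt = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        if cls == "SUB":
            subs[pos] = alt
        elif cls == "DEL":
            dels.add(pos)
        else:
            ins[pos] = ins.get(pos, "") + alt
    out: list[str] = []
    for i, base in enumerate(consensus):
        if i in ins:
            out.append(ins[i])
        if i in dels:
            continue
        out.append(subs.get(i, base))
    if len(consensus) in ins:
        out.append(ins[len(consensus)])
    return "".join(out)


def _seed_length(consensus_len: int, max_edits: int) -> int:
    # pigeonhole: any hit with <= max_edits edits contains an exact stretch of
    # at least floor((L - max_edits) / (max_edits + 1)) consensus bases
    return max(4, (consensus_len - max_edits) // (max_edits + 1))


def _candidate_ends(sequence: str, oriented: str, max_edits: int) -> set[int]:
    """End positions (exclusive) near exact seed matches of the consensus."""
    L = len(oriented)
    k = _seed_length(L, max_edits)
    seeds: dict[str, list[int]] = {}
    for o in range(L - k + 1):
        seeds.setdefault(oriented[o:o + k], []).append(o)
    n = len(sequence)
    ends: set[int] = set()
    for p in range(n - k + 1):
        offsets = seeds.get(sequence[p:p + k])
        if offsets is None:
            continue
        for o in offsets:
            centre = p - o + L
            for j in range(centre - max_edits, centre + max_edits + 1):
                if L - max_edits <= j <= n:
                    ends.add(j)
    return ends


def _best_hit_at_end(sequence: str, oriented: str, j: int, max_edits: int):
    """Best (edits, start) for an alignment of the full consensus ending at j.

    Window lengths within ``max_edits`` of the consensus length are exhaustive
    for hits with at most ``max_edits`` edits.  Ties on the edit count take
    the largest start (shortest window).
    """
    L = len(oriented)
    best_e, best_s = None, None
    for w in range(max(0, L - max_edits), L + max_edits + 1):
        s = j - w
        if s < 0:
            continue
        e = edlib.align(oriented, sequence[s:j], mode="NW", task="distance",
                        k=max_edits)["editDistance"]
        if e < 0:
            continue
        if best_e is None or e < best_e or (e == best_e and s > best_s):
            best_e, best_s = e, s
    return best_e, best_s


def resolve_overlaps(hits: list[tuple[int, int, int, str]]) -> list[tuple[int, int, int, str]]:
    """Greedy non-overlap resolution: identity desc (edits asc), leftmost.

    ``hits`` are (start, end, edits, strand); '+' wins exact ties.
    """
    order = sorted(hits, key=lambda h: (h[2], h[0], h[3] != "+", h[1]))
    taken: list[tuple[int, int]] = []
    accepted = []
    for s, e, d, strand in order:
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        accepted.append((s, e, d, strand))
    accepted.sort(key=lambda h: h[0])
    return accepted


def find_units(
    sequence: str,
    consensus: Consensus | None = None,
    arm: str = "",
    max_n_fraction: float = 0.10,
) -> list[SatelliteUnit]:
    """Detect all satellite units in ``sequence`` on both strands.

    Returns units sorted by start.  N bases never match; candidate hits with
    more than ``max_n_fraction`` N content are rejected.
    """
    consensus = consensus or Consensus()
    sequence = sequence.upper()
    if not sequence:
        return []
    if not re.fullmatch("[ACGTN]+", sequence):
        raise ValueError("sequence must be ACGT/N")
    L = len(consensus)
    max_e = consensus.max_edits
    hits: list[tuple[int, int, int, str]] = []
    for strand, oriented in (("+", consensus.sequence), ("-", revcomp(consensus.sequence))):
        for j in sorted(_candidate_ends(sequence, oriented, max_e)):
            e, s = _best_hit_at_end(sequence, oriented, j, max_e)
            if e is None or e > max_e:
                continue
            window = sequence[s:j]
            if window.count("N") > max_n_fraction * len(window):
                continue
            hits.append((s, j, e, strand))
    units = []
    for s, j, e, strand in resolve_overlaps(hits):
        observed = sequence[s:j] if strand == "+" else revcomp(sequence[s:j])
        units.append(SatelliteUnit(
            arm=arm, start=s, end=j, strand=strand,
            variant_signature=signature_of(consensus.sequence, observed),
            identity=1.0 - e / L,
        ))
    return units


def type_variants(units: list[SatelliteUnit]) -> dict[str, int]:
    """Count units per canonical variant signature."""
    counts: dict[str, int] = {}
    for u in units:
        counts[u.variant_signature] = counts.get(u.variant_signature, 0) + 1
    return counts


def derive_arrays_and_spacers(
    units: list[SatelliteUnit],
    cap_span: tuple[int, int],
    max_gap: int = 5,
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int]]]:
    """Merge units into maximal arrays and derive spacers by subtraction.

    Consecutive units with an inter-unit gap of at most ``max_gap`` bp join
    the same array.  Spacers are the cap span minus the arrays, so
    arrays + spacers tile the cap exactly.

    Returns ``(arrays, spacers)`` with arrays as (start, end, n_units) and
    spacers as (start, end).
    """
    cs, ce = cap_span
    if not (0 <= cs < ce):
        raise ValueError(f"malformed cap span {cap_span}")
    inside = sorted((u for u in units if cs <= u.start and u.end <= ce),
                    key=lambda u: u.start)
    arrays: list[tuple[int, int, int]] = []
    for u in inside:
        if arrays and u.start - arrays[-1][1] <= max_gap:
            s, _e, n = arrays[-1]
            arrays[-1] = (s, u.end, n + 1)
        else:
            arrays.append((u.start, u.end, 1))
    spacers: list[tuple[int, int]] = []
    cursor = cs
    for s, e, _n in arrays:
        if s > cursor:
            spacers.append((cursor, s))
        cursor = e
    if cursor < ce:
        spacers.append((cursor, ce))
    return arrays, spacers
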