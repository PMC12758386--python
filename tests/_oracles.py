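"""Independent brute-force oracles used to validate the implementations.

Everything here is written from the definitions, without reusing the package
code paths it checks (no edlib, no seeded search, no sklearn silhouette).
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def levenshtein(a: str, b: str) -> int:
    """Plain O(len(a) * len(b)) edit distance; N matches nothing."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            match = ca == cb and ca != "N"
            cur.append(min(prev[j - 1] + (0 if match else 1),
                           prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


def _semiglobal_end_distances(consensus: str, seq: str) -> np.ndarray:
    """For every end j, min edit distance of the full consensus against any
    window of ``seq`` ending at j (free start), vectorised over columns."""
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    row = np.zeros(n + 1, dtype=np.int32)
    idx = np.arange(n + 1, dtype=np.int32)
    for ch in consensus.encode():
        mism = np.ones(n, dtype=np.int32)
        mism[(s == ch) & (s != ord("N"))] = 0
        cand = np.minimum(row[:-1] + mism, row[1:] + 1)
        new = np.empty(n + 1, dtype=np.int32)
        new[0] = row[0] + 1
        new[1:] = cand
        # horizontal relaxation: new[j] = min_k<=j (new[k] + (j - k))
        new = np.minimum.accumulate(new - idx) + idx
        row = new
    return row  # row[j] = best distance for window ending at j


def _best_start_for_end(consensus: str, seq: str, j: int, max_e: int):
    """(best_e, largest start) over windows of length L +- max_e ending at j."""
    L = len(consensus)
    best = None
    for w in range(max(0, L - max_e), L + max_e + 1):
        s = j - w
        if s < 0:
            continue
        e = levenshtein(consensus, seq[s:j])
        if best is None or e < best[0] or (e == best[0] and s > best[1]):
            best = (e, s)
    return best


def oracle_find_units(sequence: str, consensus: str, max_edits: int):
    """Exhaustive unit scan: every end position on both strands, greedy
    non-overlap resolution by (edits asc, start asc, '+' first)."""
    sequence = sequence.upper()
    hits = []
    for strand, oriented in (("+", consensus), ("-", revcomp(consensus))):
        dists = _semiglobal_end_distances(oriented, sequence)
        for j in np.flatnonzero(dists <= max_edits):
            e, s = _best_start_for_end(oriented, sequence, int(j), max_edits)
            if e <= max_edits:
                window = sequence[s:int(j)]
                if window.count("N") > 0.10 * len(window):
                    continue
                hits.append((s, int(j), e, strand))
    hits.sort(key=lambda h: (h[2], h[0], h[3] != "+", h[1]))
    taken, accepted = [], []
    for s, j, e, strand in hits:
        if any(s < te and ts < j for ts, te in taken):
            continue
        taken.append((s, j))
        accepted.append((s, j, strand))
    return sorted(accepted)


def optimal_three_way_sp_cost(a: str, b: str, c: str) -> int:
    """Exact 3-way alignment under sum-of-pairs unit edit cost (cubic DP)."""
    la, lb, lc = len(a), len(b), len(c)
    D = np.full((la + 1, lb + 1, lc + 1), 1 << 30, dtype=np.int32)
    D[0, 0, 0] = 0
    for i in range(la + 1):
        for j in range(lb + 1):
            for k in range(lc + 1):
                cur = D[i, j, k]
                if cur >= 1 << 30:
                    continue
                if i < la and j < lb and k < lc:
                    cost = (a[i] != b[j]) + (a[i] != c[k]) + (b[j] != c[k])
                    D[i+1, j+1, k+1] = min(D[i+1, j+1, k+1], cur + cost)
                if i < la and j < lb:
                    D[i+1, j+1, k] = min(D[i+1, j+1, k], cur + (a[i] != b[j]) + 2)
                if i < la and k < lc:
                    D[i+1, j, k+1] = min(D[i+1, j, k+1], cur + (a[i] != c[k]) + 2)
                if j < lb and k < lc:
                    D[i, j+1, k+1] = min(D[i, j+1, k+1], cur + (b[j] != c[k]) + 2)
                if i < la:
                    D[i+1, j, k] = min(D[i+1, j, k], cur + 2)
                if j < lb:
                    D[i, j+1, k] = min(D[i, j+1, k], cur + 2)
                if k < lc:
                    D[i, j, k+1] = min(D[i, j, k+1], cur + 2)
    return int(D[la, lb, lc])


def sp_cost(rows: list[str]) -> int:
    """Sum-of-pairs unit cost of an MSA (sub 1, base-vs-gap 1, gap-gap 0)."""
    total = 0
    for x, y in itertools.combinations(rows, 2):
        for cx, cy in zip(x, y):
            if cx == "-" and cy == "-":
                continue
            total += (cx != cy)
    return total


def brute_silhouette(data: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score, O(n^2), straight from the definition."""
    n = len(data)
    d = np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = labels == labels[i]
        if same.sum() < 2:
            scores.append(0.0)
            continue
        a = d[i, same & (np.arange(n) != i)].mean()
        b = min(d[i, labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def evolve_pair_per_site(root: str, branch_lengths: tuple[float, float],
                         rng: np.random.Generator) -> tuple[str, str]:
    """Per-site Poisson-event simulation of two descendants of ``root``.

    Each event redraws the base uniformly from ACGT; event rate per site is
    4b/3 so that b equals the expected substitutions/site.
    """
    out = []
    for b in branch_lengths:
        seq = []
        for base in root:
            k = rng.poisson(4.0 * b / 3.0)
            cur = base
            for _ in range(k):
                cur = "ACGT"[rng.integers(0, 4)]
            seq.append(cur)
        out.append("".join(seq))
    return out[0], out[1]


def all_bipartitions(leaves: list[str]):
    """Every non-trivial bipartition, canonically as the side without the
    first leaf (so complements are not double-counted)."""
    rest = leaves[1:]
    for r in range(2, len(leaves) - 1):
        for combo in itertools.combinations(rest, r):
            yield frozenset(combo)


def rf_by_enumeration(splits_a: set, splits_b: set, leaves: list[str]) -> int:
    """RF distance by enumerating every possible bipartition."""
    count = 0
    for canon in all_bipartitions(leaves):
        count += (canon in splits_a) != (canon in splits_b)
    return count
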