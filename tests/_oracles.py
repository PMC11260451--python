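"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (enumeration, closed forms, direct
substring search) and shares no code with the package internals.
"""

from __future__ import annotations

from math import comb

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def soi_triple_loop(cell: set, ctdna: set, coculture: set) -> set:
    """Membership-test definition of SNVs of interest."""
    out = set()
    for key in cell | ctdna | coculture:
        if key in ctdna and key in coculture and key not in cell:
            out.add(key)
    return out


def venn_triple_loop(cell: set, ctdna: set, coculture: set) -> dict:
    out = {r: 0 for r in ("100", "010", "001", "110", "101", "011", "111")}
    for key in cell | ctdna | coculture:
        out[f"{int(key in cell)}{int(key in ctdna)}{int(key in coculture)}"] += 1
    return out


def max_cell_prefix(contig: str, cell_seqs: dict[str, str]) -> int:
    """Largest s such that contig[:s] occurs in the cell genome (either
    strand) — the exhaustive split-point oracle for a leading junction."""
    haystacks = [s for s in cell_seqs.values()] + [rc(s) for s in cell_seqs.values()]

    def occurs(prefix: str) -> bool:
        return any(prefix in h for h in haystacks)

    lo, hi = 0, len(contig)  # invariant: contig[:lo] occurs, contig[:hi+1] may not
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if occurs(contig[:mid]):
            lo = mid
        else:
            hi = mid - 1
    return lo


def min_cell_suffix_start(contig: str, cell_seqs: dict[str, str]) -> int:
    """Smallest s such that contig[s:] occurs in the cell genome (either
    strand) — the split-point oracle for a trailing junction."""
    haystacks = [s for s in cell_seqs.values()] + [rc(s) for s in cell_seqs.values()]

    def occurs(suffix: str) -> bool:
        return any(suffix in h for h in haystacks)

    lo, hi = 0, len(contig)
    while lo < hi:
        mid = (lo + hi) // 2
        if occurs(contig[mid:]):
            hi = mid
        else:
            lo = mid + 1
    return lo


def chi2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square for a 2x2 table, hand-expanded."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact conditional p by enumerating all tables with the
    observed margins and summing probabilities <= that of the observed
    table (hypergeometric null)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def binomial_bounds(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    half = z * (p * (1 - p) / n) ** 0.5
    return p - half, p + half
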