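"""Independent oracles used by the test suite.

Each function here recomputes a quantity by brute force (dynamic
programming, exhaustive enumeration, exact rational arithmetic) without
touching the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

NEG = float("-inf")


def sw_affine_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -5.0,
    gap_open: float = -1.0,
    gap_extend: float = -0.5,
) -> float:
    """Brute-force Gotoh local alignment score.

    The open penalty is charged on a gap's first symbol (length-1 gap
    costs ``gap_open``, length-2 costs ``gap_open + gap_extend``).
    Adjacent opposite-direction gaps each pay their own open penalty.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
            score = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = max(0.0, diag + score)
            best = max(best, M[i][j])
    return best


def harmonic_mean_exact(ranks: list[Fraction]) -> Fraction:
    """Exact rational harmonic mean."""
    return Fraction(len(ranks)) / sum(Fraction(1) / r for r in ranks)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed one (relative epsilon
    1e-7, the conventional guard for floating ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(
        pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7)
    )


def bh_adjust_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written out longhand."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p_values[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def spanning_kmers_enumerated(
    peptide: str, residues: set[int], size: int
) -> list[str]:
    """All length-``size`` substrings containing every 1-based residue."""
    out = []
    for start in range(1, len(peptide) - size + 2):
        end = start + size - 1
        if all(start <= r <= end for r in residues):
            out.append(peptide[start - 1 : end])
    return out


def spanning_kmer_count_closed_form(length: int, p: int, size: int) -> int:
    """Closed-form count for an adjacent breakpoint pair {p, p+1}."""
    count = min(p, length - size + 1) - max(1, p - size + 2) + 1
    return max(0, count)


def best_wt_by_enumeration(ase_key, catalogs, min_reads=1):
    """Brute-force WT pick: enumerate (junction, sample) pairs, max-count.

    ``catalogs`` is a list of dicts {(chrom, start, end): unique_reads}.
    Returns the winning key or None, using the documented tie-break
    (sample count, total reads, lexicographic key).
    """
    chrom, start, end = ase_key
    pairs = []
    for sample_idx, records in enumerate(catalogs):
        for key, reads in records.items():
            if key == ase_key or key[0] != chrom:
                continue
            if key[1] != start and key[2] != end:
                continue
            if reads >= min_reads:
                pairs.append((key, sample_idx, reads))
    if not pairs:
        return None
    by_key: dict = {}
    for key, sample_idx, reads in pairs:
        entry = by_key.setdefault(key, [set(), 0])
        entry[0].add(sample_idx)
        entry[1] += reads
    return min(
        by_key,
        key=lambda k: (-len(by_key[k][0]), -by_key[k][1], k[0], k[1], k[2]),
    )
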