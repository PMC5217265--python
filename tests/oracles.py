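"""Independent oracles: direct transcriptions of the textbook formulas and
brute-force enumerations, deliberately kept naive and separate from the
package's implementations."""

from __future__ import annotations

import math
from fractions import Fraction

from scipy import stats


def welch_oracle(x: list[float], y: list[float]) -> tuple[float, float, float]:
    """Welch t, Satterthwaite df, and two-sided p, straight from the
    formulas: t = (x1 - x2)/sqrt(s1^2/n1 + s2^2/n2)."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    s1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    q1, q2 = s1 / n1, s2 / n2
    t = (m1 - m2) / math.sqrt(q1 + q2)
    df = (q1 + q2) ** 2 / (q1**2 / (n1 - 1) + q2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration with
    exact rational probabilities (Fraction arithmetic throughout)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(k: int) -> Fraction:
        return Fraction(
            math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1)
        )

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(min(total, Fraction(1)))


def woolf_ci_oracle(
    a: float, b: float, c: float, d: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Woolf/Wald CI closed form on the (possibly corrected) cell counts."""
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return (
        or_point,
        math.exp(math.log(or_point) - z * se),
        math.exp(math.log(or_point) + z * se),
    )


def brute_force_blocks(track, min_snps, max_gap_bp, p_block):
    """All maximal contiguous subsequences satisfying the block criteria,
    found by testing every contiguous subsequence.

    track: list of (chrom, pos, snp_id, p) tuples sorted by (chrom, pos).
    Returns a list of (chrom, start_pos, end_pos, member snp_ids) tuples.
    """
    n = len(track)

    def qualifies(i: int, j: int) -> bool:  # members track[i..j] inclusive
        if j - i + 1 < min_snps:
            return False
        chrom = track[i][0]
        for k in range(i, j + 1):
            if track[k][0] != chrom or not track[k][3] < p_block:
                return False
        for k in range(i, j):
            if track[k + 1][1] - track[k][1] >= max_gap_bp:
                return False
        return True

    runs = [
        (i, j) for i in range(n) for j in range(i, n) if qualifies(i, j)
    ]
    maximal = [
        (i, j)
        for (i, j) in runs
        if not any((p <= i and j <= q and (p, q) != (i, j)) for (p, q) in runs)
    ]
    return [
        (
            track[i][0],
            track[i][1],
            track[j][1],
            tuple(track[k][2] for k in range(i, j + 1)),
        )
        for (i, j) in sorted(maximal)
    ]
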