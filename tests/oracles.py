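"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: rational arithmetic
for exact tails, quadratic scans for interval work, and a per-window
rescoring loop for PWM hits.
"""

from __future__ import annotations

import math
from fractions import Fraction

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


def binom_frac(n: int, k: int) -> Fraction:
    return Fraction(math.comb(n, k))


def hypergeom_upper_tail_frac(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) as a rational number."""
    total = binom_frac(N, n)
    acc = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        if n - kk <= N - K:
            acc += binom_frac(K, kk) * binom_frac(N - K, n - kk)
    return acc / total


def fisher_two_sided_frac(a: int, b: int, c: int, d: int) -> Fraction:
    """Sum of probabilities of all tables (same margins) <= observed."""
    N, K, n = a + b + c + d, a + b, a + c
    total = binom_frac(N, n)

    def pmf(x: int) -> Fraction:
        if not (0 <= x <= K and 0 <= n - x <= N - K):
            return Fraction(0)
        return binom_frac(K, x) * binom_frac(N - K, n - x) / total

    obs = pmf(a)
    return sum(
        (p for x in range(max(0, n + K - N), min(K, n) + 1) if (p := pmf(x)) <= obs),
        Fraction(0),
    )


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_scan(seq: str, probs, rel_threshold: float, background=None):
    """All (offset, strand, score, rel) hits by direct per-window rescoring."""
    bg = background or [0.25] * 4
    L = len(probs)
    lo = [[math.log2(probs[i][j] / bg[j]) for j in range(4)] for i in range(L)]
    lo_min = sum(min(row) for row in lo)
    lo_max = sum(max(row) for row in lo)
    span = lo_max - lo_min
    hits = []
    seq = seq.upper()
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        for strand in "+-":
            word = window if strand == "+" else revcomp(window)
            if any(b not in _BASES for b in word):
                continue
            score = sum(lo[i][_BASES.index(word[i])] for i in range(L))
            rel = (score - lo_min) / span if span > 0 else 1.0
            if rel >= rel_threshold - 1e-12:
                hits.append((off, strand, score, rel))
    return hits


def brute_intersect(a, b, min_overlap: int = 1):
    out = []
    for i, ia in enumerate(a):
        for j, ib in enumerate(b):
            if ia.chrom != ib.chrom:
                continue
            ov = min(ia.end, ib.end) - max(ia.start, ib.start)
            if ov >= min_overlap:
                out.append((i, j, ov))
    return sorted(out)


def brute_nearest_gene(summit: int, chrom: str, genes):
    """(gene_id, |distance|) of the nearest TSS on the chromosome, smallest
    gene_id winning ties; None when the chromosome has no gene."""
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        key = (abs(summit - g.tss), g.gene_id)
        if best is None or key < best:
            best = key
    return None if best is None else (best[1], best[0])
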