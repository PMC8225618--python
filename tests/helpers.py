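"""Independent brute-force oracles used to cross-check the implementations.

Each oracle is deliberately written from first principles (base-by-base
reference projection, exact-fraction hypergeometric enumeration, value-level
permutation enumeration) so that it shares no code path with the routines
it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def spans_junction_oracle(pos, cigar, chrom, sig, min_overhang):
    """Base-projection oracle for junction spanning.

    Projects every aligned base to its reference coordinate, collects the
    N-skipped intervals, and declares a span when some skip equals exactly
    the signature's intronic interval and the min_overhang reference
    positions on either side of the junction are all aligned.
    """
    if chrom != sig.chrom:
        return False
    aligned = set()
    skips = []
    ref = pos
    for length, op in cigar:
        if op in "M=X":
            for _ in range(length):
                aligned.add(ref)
                ref += 1
        elif op == "N":
            skips.append((ref, ref + length - 1))
            ref += length
        elif op == "D":
            ref += length
        # I, S, H, P consume no reference
    want = (sig.donor_end + 1, sig.acceptor_start - 1)
    if want not in skips:
        return False
    left = all(sig.donor_end - k in aligned for k in range(min_overhang))
    right = all(sig.acceptor_start + k in aligned for k in range(min_overhang))
    return left and right


def count_junction_reads_oracle(reads, model, min_overhang):
    """Per-read brute-force counting; first matching signature wins."""
    counts = {sig.transcript_id: 0 for sig in model.signatures}
    for read in reads:
        for sig in model.signatures:
            if spans_junction_oracle(read.pos, read.cigar, read.chrom, sig, min_overhang):
                counts[sig.transcript_id] += 1
                break
    return counts


def fisher_two_tailed_oracle(a, b, c, d):
    """Exact-fraction enumeration of all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k):
        if not (0 <= k <= r1 and 0 <= c1 - k <= r2):
            return None
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(0, c1 + 1):
        p = prob(k)
        if p is not None and p <= p_obs:
            total += p
    return float(total)


def mann_whitney_u_from_values(x, y):
    """U statistic of x computed pairwise from raw values (ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact p by enumerating group assignments of the raw values."""
    pooled = list(x) + list(y)
    nx = len(x)
    mu = nx * len(y) / 2.0
    obs = abs(mann_whitney_u_from_values(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = mann_whitney_u_from_values(chosen, rest)
        total += 1
        if abs(u - mu) >= obs - 1e-12:
            hits += 1
    return hits / total
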