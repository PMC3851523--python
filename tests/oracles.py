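"""Independent reference implementations used as test oracles.

Everything here is written as direct, naive computation — exact rational
enumeration for the hypergeometric tail, term-by-term series summation for
the Poisson tail, and per-pair experiment loops for the socio-affinity and
purification-enrichment scores — deliberately sharing no code with the
package's set/array implementations.
"""

import math
from fractions import Fraction


def hypergeom_upper_tail_exact(x, n_a, n_b, n_total, tail="gt"):
    """Exact P[H > x] (or >= x) by enumerating the hypergeometric support."""
    kmin = max(0, n_a + n_b - n_total)
    kmax = min(n_a, n_b)
    lo = x + 1 if tail == "gt" else x
    denom = math.comb(n_total, n_b)
    total = Fraction(0)
    for k in range(max(lo, kmin), kmax + 1):
        total += Fraction(math.comb(n_a, k) * math.comb(n_total - n_a, n_b - k), denom)
    return total


def poisson_upper_tail_series(x, lam, tail="gt"):
    """P[Poisson(lam) > x] (or >= x) by direct summation of the tail series."""
    lo = x + 1 if tail == "gt" else max(x, 0)
    term = math.exp(-lam)
    for k in range(1, lo + 1):
        term *= lam / k
    total, k = 0.0, lo
    while term > total * 1e-18 + 1e-320:
        total += term
        k += 1
        term *= lam / k
    return total


def _candidate_pairs_naive(sets, bait_of):
    pairs = set()
    for e, members in sets.items():
        for a in members:
            for b in members:
                if a < b:
                    pairs.add((a, b))
        bait = bait_of.get(e)
        if bait is not None:
            for p in members:
                if p != bait:
                    pairs.add((min(bait, p), max(bait, p)))
    return pairs


def sai_reference(sets, bait_of):
    """Naive socio-affinity score: explicit loops over experiments per pair."""
    exp_ids = list(sets)
    n = len(exp_ids)

    def freq(i):
        return sum(1 for e in exp_ids if i in sets[e]) / n

    def spoke(i, j):
        exps_j = [e for e in exp_ids if bait_of[e] == j]
        if not exps_j:
            return 0.0
        o = sum(1 for e in exps_j if i in sets[e])
        return math.log(o / (freq(i) * len(exps_j))) if o else 0.0

    def matrix_term(i, j):
        m = sum(
            1
            for e in exp_ids
            if i in sets[e] and j in sets[e] and bait_of[e] not in (i, j)
        )
        return math.log(m / (freq(i) * freq(j) * n)) if m else 0.0

    return {
        (a, b): spoke(a, b) + spoke(b, a) + matrix_term(a, b)
        for (a, b) in _candidate_pairs_naive(sets, bait_of)
    }


def pe_reference(sets, bait_of, r=0.3, n_pseudo=10):
    """Naive purification-enrichment score: per-pair loops over experiments."""
    exp_ids = list(sets)
    n = len(exp_ids)
    proteins = sorted({p for members in sets.values() for p in members})
    f0 = sum(
        sum(1 for e in exp_ids if p in sets[e]) for p in proteins
    ) / (len(proteins) * n)

    def freq(i):
        raw = sum(1 for e in exp_ids if i in sets[e])
        return min(max((raw + n_pseudo * f0) / (n + n_pseudo), 1e-9), 1 - 1e-9)

    def score(a, b):
        fa, fb = freq(a), freq(b)
        f_max = max(fa, fb)
        total = 0.0
        for e in exp_ids:
            bait = bait_of[e]
            in_a, in_b = a in sets[e], b in sets[e]
            if bait == b:
                total += math.log(r / fa) if in_a else math.log((1 - r) / (1 - fa))
            elif bait == a:
                total += math.log(r / fb) if in_b else math.log((1 - r) / (1 - fb))
            else:
                if in_a and in_b:
                    total += math.log(r * f_max / (fa * fb))
                elif in_a:
                    total += math.log((1 - r) / (1 - fb))
                elif in_b:
                    total += math.log((1 - r) / (1 - fa))
        return total

    return {
        (a, b): score(a, b) for (a, b) in _candidate_pairs_naive(sets, bait_of)
    }
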