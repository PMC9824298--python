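"""Independent brute-force oracles used only by the test suite.

Everything here is computed by enumeration or direct definition, never by
calling the implementation under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

# genotype codes: 0 = a/a, 1 = a/b, 2 = b/b


def hwe_probs(p: float) -> dict[int, float]:
    q = 1.0 - p
    return {0: p * p, 1: 2 * p * q, 2: q * q}


def gamete_probs(g: int) -> dict[int, float]:
    """Probability of transmitting allele index 0 (a) or 1 (b)."""
    return {0: {0: 1.0}, 1: {0: 0.5, 1: 0.5}, 2: {1: 1.0}}[g]


def transmission(o: int, m: int, f: int) -> float:
    """P(offspring genotype o | parent genotypes m, f)."""
    total = 0.0
    for am, pm in gamete_probs(m).items():
        for af, pf in gamete_probs(f).items():
            if am + af == o:
                total += pm * pf
    return total


def trio_compatible(m: int, f: int, o: int) -> bool:
    return transmission(o, m, f) > 0.0


def pair_compatible(c: int, o: int) -> bool:
    alleles = {0: {0}, 1: {0, 1}, 2: {1}}
    return bool(alleles[c] & alleles[o])


def exclusion_by_enumeration(p: float) -> tuple[float, float, float]:
    """Q1/Q2/Q3 by full enumeration of HWE parent/offspring configurations."""
    hw = hwe_probs(p)
    pe1 = pe2 = pe3 = 0.0
    for m, pm in hw.items():
        for f, pf in hw.items():
            for o in range(3):
                po = transmission(o, m, f)
                if po == 0.0:
                    continue
                w = pm * pf * po
                # Q1: mother known, random candidate as second parent
                pe1 += w * sum(pc for c, pc in hw.items() if not trio_compatible(m, c, o))
                # Q2: single candidate, other parent unknown
                pe2 += w * sum(pc for c, pc in hw.items() if not pair_compatible(c, o))
                # Q3: random parent pair
                pe3 += w * sum(
                    p1 * p2
                    for c1, p1 in hw.items()
                    for c2, p2 in hw.items()
                    if not trio_compatible(c1, c2, o)
                )
    return pe1, pe2, pe3


def mistyped_mismatch_rate(p: np.ndarray, error_rate: float) -> float:
    """Expected pair-mode mismatches of an offspring vs its true father
    when each offspring call is replaced by an HWE draw with prob e."""
    total = 0.0
    for pl in p:
        hw = hwe_probs(float(pl))
        incompat = sum(
            pf * pe_
            for f, pf in hw.items()
            for e_, pe_ in hw.items()
            if not pair_compatible(f, e_)
        )
        total += error_rate * incompat
    return total


def diversity_by_counts(n11: int, n12: int, n22: int) -> dict[str, float]:
    """Every diversity statistic straight from genotype counts."""
    n = n11 + n12 + n22
    p = (2 * n11 + n12) / (2 * n)
    q = 1 - p
    freqs = [x for x in (p, q) if x > 0]
    a2 = sum(x**2 for x in freqs)
    a4 = sum(x**4 for x in freqs)
    return {
        "maf": min(p, q),
        "na": len(freqs),
        "ne": 1.0 / a2,
        "shannon_i": -sum(x * np.log(x) for x in freqs),
        "ho": n12 / n,
        "he": (2 * n / (2 * n - 1)) * (1 - a2),
        "pic": 1 - a2 - (a2**2 - a4),
        "pi": 2 * a2**2 - a4,
    }


def smallest_distinguishing_subsets(calls: np.ndarray) -> list[tuple[int, ...]]:
    """All smallest column subsets separating every row pair.

    ``calls`` holds genotype codes with -1 for missing; missing never
    distinguishes.  Pairs that no column separates are ignored (they are
    unresolvable).  Returns [] only if zero columns suffice.
    """
    n, L = calls.shape
    pairs = list(combinations(range(n), 2))

    def separated(i, j, cols):
        return any(
            calls[i, c] != -1 and calls[j, c] != -1 and calls[i, c] != calls[j, c]
            for c in cols
        )

    resolvable = [ij for ij in pairs if separated(*ij, range(L))]
    for size in range(0, L + 1):
        hits = [
            sub
            for sub in combinations(range(L), size)
            if all(separated(i, j, sub) for i, j in resolvable)
        ]
        if hits:
            return hits
    return []
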