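"""Per-locus diversity statistics for biallelic SNP panels.

With allele frequencies p_i and power sums a_k = sum_i p_i^k:

* Ne (effective allele number) = 1 / a_2
* I (Shannon's information index) = -sum p_i ln p_i
* Ho (observed heterozygosity) = n_het / n_typed
* He (unbiased expected heterozygosity, Nei) = 2n/(2n-1) * (1 - a_2)
* PIC (Botstein) = 1 - a_2 - (a_2^2 - a_4)

The unbiased He factor matters: at p = 0.5 with n = 117 typed individuals
He = 0.5022, slightly above the uncorrected 2pq ceiling of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFreqs, GenotypeMatrix, allele_frequencies


class InsufficientDataError(ValueError):
    """Fewer than two typed individuals at a locus."""


@dataclass
class LocusDiversity:
    """The per-locus statistic bundle (one row of a diversity table)."""

    locus_id: str
    maf: float
    na: int
    ne: float
    shannon_i: float
    ho: float
    he: float
    pic: float
    pi: float | None = None
    pe1: float | None = None
    pe2: float | None = None
    pe3: float | None = None


def _power_sums(p: float) -> dict[int, float]:
    q = 1.0 - p
    return {k: p**k + q**k for k in (2, 3, 4, 5, 6)}


def shannon_index(p: float) -> float:
    terms = [x * np.log(x) for x in (p, 1.0 - p) if x > 0.0]
    return float(-sum(terms))


def pic_score(p: float) -> float:
    a = _power_sums(p)
    return 1.0 - a[2] - (a[2] ** 2 - a[4])


def effective_alleles(p: float) -> float:
    return 1.0 / _power_sums(p)[2]


def unbiased_he(p: float, n_typed: int) -> float:
    a2 = _power_sums(p)[2]
    return (2.0 * n_typed / (2.0 * n_typed - 1.0)) * (1.0 - a2)


def locus_stats(
    locus_id: str,
    p: float,
    genotype_counts: tuple[int, int, int],
) -> LocusDiversity:
    """Statistics for one locus from its allele_a frequency and the
    (n_11, n_12, n_22) genotype counts over typed individuals.

    Na counts alleles actually observed in the non-missing calls, so a
    locus fixed in the sample has Na = 1 even if declared biallelic.
    """
    n11, n12, n22 = genotype_counts
    n_typed = n11 + n12 + n22
    if n_typed < 2:
        raise InsufficientDataError(
            f"locus {locus_id}: need >= 2 typed individuals (got {n_typed})"
        )
    na = int(n11 + n12 > 0) + int(n22 + n12 > 0)
    return LocusDiversity(
        locus_id=locus_id,
        maf=min(p, 1.0 - p),
        na=na,
        ne=effective_alleles(p),
        shannon_i=shannon_index(p),
        ho=n12 / n_typed,
        he=unbiased_he(p, n_typed),
        pic=pic_score(p),
    )


def stats_from_frequency(locus_id: str, p: float, n_typed: int = 117) -> LocusDiversity:
    """Frequency-only statistic bundle (Ho unavailable, reported as NaN).

    Used when only published allele frequencies are in hand, e.g. to
    recompute a printed diversity table from its MAF column.
    """
    return LocusDiversity(
        locus_id=locus_id,
        maf=min(p, 1.0 - p),
        na=1 if p in (0.0, 1.0) else 2,
        ne=effective_alleles(p),
        shannon_i=shannon_index(p),
        ho=float("nan"),
        he=unbiased_he(p, n_typed),
        pic=pic_score(p),
    )


def panel_stats(g: GenotypeMatrix, freqs: AlleleFreqs | None = None) -> list[LocusDiversity]:
    """Per-locus statistics for every locus of a genotype matrix."""
    if freqs is None:
        freqs = allele_frequencies(g)
    out = []
    for j, lid in enumerate(g.locus_ids):
        col = g.codes[:, j]
        counts = (
            int((col == 0).sum()),
            int((col == 1).sum()),
            int((col == 2).sum()),
        )
        p, _ = freqs.for_locus(lid)
        out.append(locus_stats(lid, p, counts))
    return out


_COLUMNS = ["maf", "na", "ne", "shannon_i", "ho", "he", "pic", "pi"]


def stats_table(stats: list[LocusDiversity]) -> pd.DataFrame:
    """Diversity table, one row per locus, columns as in a published report."""
    rows = [
        {
            "name": s.locus_id,
            **{c: getattr(s, c) for c in _COLUMNS},
        }
        for s in stats
    ]
    return pd.DataFrame(rows).set_index("name")


def panel_summary(stats: list[LocusDiversity]) -> pd.DataFrame:
    """Min / max / mean per statistic over the panel (full precision)."""
    if not stats:
        raise ValueError("panel_summary needs at least one locus")
    tbl = stats_table(stats)
    return tbl.agg(["min", "max", "mean"])


def round_half_even(x: float, ndigits: int = 3) -> float:
    """Banker's rounding as used for report tables."""
    return float(np.round(x, ndigits))
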