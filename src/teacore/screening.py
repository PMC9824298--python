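"""Core-marker screening: the filter cascade and per-chromosome top-k choice.

A core marker must (1) have no missing calls across the panel, (2) have
MAF above a threshold (default 0.05), (3) when a reference genome is
supplied, have both 35-bp flanks perfectly conserved against it (so that
locus-specific primers can be designed directly), and (4) have a
computable PIC.  Survivors are ranked per chromosome by PIC (descending)
and the top k (default 3) retained — on a 15-chromosome genome that
yields an evenly spread 45-marker panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import LocusDiversity
from .genotypes import MISSING, GenotypeMatrix, LocusInfo

log = logging.getLogger(__name__)


@dataclass
class ScreeningCriteria:
    require_no_missing: bool = True
    maf_min: float = 0.05
    flank_len: int = 35
    require_flank_match: bool = True
    top_k_per_chrom: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.top_k_per_chrom < 1:
            raise ValueError("top_k_per_chrom must be >= 1")


def _get_sequence(reference, chrom: str) -> str | None:
    """Fetch a full chromosome sequence from a mapping or pyfaidx.Fasta."""
    try:
        seq = reference[chrom]
    except KeyError:
        return None
    return str(seq)


def flank_conserved(locus: LocusInfo, reference) -> bool:
    """True iff both 35-bp flanks match the reference exactly.

    Case-insensitive; any N in the flank or the reference window fails
    the check.  ``reference`` is any chrom -> sequence mapping (e.g. a
    ``pyfaidx.Fasta`` or a plain dict); coordinates are 1-based.
    """
    if locus.flank_up is None or locus.flank_down is None:
        raise ValueError(f"locus {locus.locus_id}: flanks are not set")
    if locus.chrom is None or locus.pos is None:
        raise ValueError(f"locus {locus.locus_id}: chrom/pos are not set")
    seq = _get_sequence(reference, locus.chrom)
    if seq is None:
        raise ValueError(f"locus {locus.locus_id}: chromosome {locus.chrom!r} not in reference")
    flank = len(locus.flank_up)
    if locus.pos - flank < 1 or locus.pos + flank > len(seq):
        raise ValueError(
            f"locus {locus.locus_id}: flank window outside {locus.chrom} "
            f"(pos {locus.pos}, length {len(seq)})"
        )
    ref_up = seq[locus.pos - 1 - flank : locus.pos - 1].upper()
    ref_down = seq[locus.pos : locus.pos + flank].upper()
    up, down = locus.flank_up.upper(), locus.flank_down.upper()
    if "N" in up + down + ref_up + ref_down:
        return False
    return ref_up == up and ref_down == down


def screen_core_markers(
    g: GenotypeMatrix,
    stats: Sequence[LocusDiversity],
    criteria: ScreeningCriteria | None = None,
    reference=None,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Run the filter cascade and pick the top-k loci per chromosome.

    ``stats`` must align one-to-one with ``g.loci``.  Returns
    ``(selected, ledger)`` where ``selected`` maps chromosome ->
    selected locus ids (PIC descending; ties by higher MAF then position
    ascending) and ``ledger`` records the fate of every locus.  Without a
    reference the flank criterion is skipped (with a warning) so the
    cascade runs on synthetic panels.
    """
    criteria = criteria or ScreeningCriteria()
    if len(stats) != g.n_loci or any(
        s.locus_id != l.locus_id for s, l in zip(stats, g.loci)
    ):
        raise ValueError("stats must align with the matrix loci")
    check_flanks = criteria.require_flank_match and reference is not None
    if criteria.require_flank_match and reference is None:
        log.warning("no reference genome supplied: flank-conservation criterion skipped")

    records = []
    for j, (locus, s) in enumerate(zip(g.loci, stats)):
        reasons = []
        if criteria.require_no_missing and (g.codes[:, j] == MISSING).any():
            reasons.append("missing_calls")
        if not (s.maf > criteria.maf_min):
            reasons.append("maf_below_threshold")
        if check_flanks and not flank_conserved(locus, reference):
            reasons.append("flank_not_conserved")
        if not np.isfinite(s.pic):
            reasons.append("pic_unavailable")
        records.append(
            {
                "locus_id": locus.locus_id,
                "chrom": locus.chrom or "unknown",
                "pos": locus.pos,
                "maf": s.maf,
                "pic": s.pic,
                "passed": not reasons,
                "rejection_reasons": ";".join(reasons),
            }
        )
    ledger = pd.DataFrame(records)

    selected: dict[str, list[str]] = {}
    for chrom, grp in ledger[ledger.passed].groupby("chrom", sort=True):
        grp = grp.sort_values(
            by=["pic", "maf", "pos"], ascending=[False, False, True], kind="mergesort"
        )
        chosen = grp.locus_id.head(criteria.top_k_per_chrom).tolist()
        if len(chosen) < criteria.top_k_per_chrom:
            log.warning(
                "chromosome %s: only %d of %d requested markers survive screening",
                chrom, len(chosen), criteria.top_k_per_chrom,
            )
        selected[chrom] = chosen
    for chrom in {l.chrom or "unknown" for l in g.loci} - set(selected):
        log.warning("chromosome %s: no markers survive screening", chrom)
        selected[chrom] = []
    return selected, ledger
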