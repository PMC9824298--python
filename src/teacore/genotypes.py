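"""Diploid biallelic SNP genotype panels.

The central container is :class:`GenotypeMatrix`: samples x loci diploid
calls in the unordered two-allele coding used throughout marker work on
clonal crops (``1/1``, ``1/2``, ``2/2``, with ``NA`` for missing; allele 1
is ``allele_a`` of the locus, allele 2 is ``allele_b``).  Readers and
writers cover a plain CSV genotype-table dialect and minimal biallelic
VCF v4.2; both round-trip every call including missing ones.

Internally calls are stored as an ``int8`` array counting copies of
``allele_b``: 0 = 1/1, 1 = 1/2, 2 = 2/2, -1 = missing.  Heterozygotes are
unordered ("2/1" is normalised to "1/2" at parse time and phase in VCF is
discarded); haploid or hemizygous calls are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_CALL_TO_CODE = {"1/1": 0, "1/2": 1, "2/1": 1, "2/2": 2, "NA": MISSING}
_CODE_TO_CALL = {0: "1/1", 1: "1/2", 2: "2/2", MISSING: "NA"}

_FLANK_RE = re.compile(r"^[ACGTNacgtn]*$")


class GenotypeError(ValueError):
    """Malformed genotype data (parse or invariant failure)."""


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one biallelic SNP locus.

    Coordinates are 1-based inclusive.  ``allele_a`` maps to code 1 and
    ``allele_b`` to code 2 in genotype calls.  Flanks, when present, are the
    35-nt sequences immediately up/downstream of the SNP site (used by the
    core-marker screening step to require perfect conservation against a
    reference genome).
    """

    locus_id: str
    chrom: str | None = None
    pos: int | None = None
    allele_a: str | None = None
    allele_b: str | None = None
    flank_up: str | None = None
    flank_down: str | None = None

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise GenotypeError("locus_id must be non-empty")
        if self.pos is not None and self.pos < 1:
            raise GenotypeError(f"locus {self.locus_id}: pos must be >= 1 (got {self.pos})")
        if self.allele_a is not None and self.allele_b is not None:
            if self.allele_a.upper() == self.allele_b.upper():
                raise GenotypeError(f"locus {self.locus_id}: alleles must differ")
        for name, flank in (("flank_up", self.flank_up), ("flank_down", self.flank_down)):
            if flank is None:
                continue
            if len(flank) != 35:
                raise GenotypeError(
                    f"locus {self.locus_id}: {name} must be exactly 35 nt (got {len(flank)})"
                )
            if not _FLANK_RE.match(flank):
                raise GenotypeError(f"locus {self.locus_id}: {name} has characters outside ACGTN")


class GenotypeMatrix:
    """Samples x loci grid of unordered diploid biallelic calls."""

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[LocusInfo],
        codes: np.ndarray,
    ) -> None:
        samples = list(samples)
        loci = list(loci)
        codes = np.asarray(codes, dtype=np.int8)
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise GenotypeError(f"duplicate sample ids: {dupes}")
        locus_ids = [l.locus_id for l in loci]
        if len(set(locus_ids)) != len(locus_ids):
            dupes = sorted({l for l in locus_ids if locus_ids.count(l) > 1})
            raise GenotypeError(f"duplicate locus ids: {dupes}")
        if codes.shape != (len(samples), len(loci)):
            raise GenotypeError(
                f"codes shape {codes.shape} does not match "
                f"{len(samples)} samples x {len(loci)} loci"
            )
        bad = ~np.isin(codes, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid genotype code {codes[i, j]} at sample {samples[i]!r}, "
                f"locus {locus_ids[j]!r}"
            )
        self.samples = samples
        self.loci = loci
        self.codes = codes
        self._sample_index = {s: i for i, s in enumerate(samples)}
        self._locus_index = {l: j for j, l in enumerate(locus_ids)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def sample_row(self, sample_id: str) -> np.ndarray:
        try:
            return self.codes[self._sample_index[sample_id]]
        except KeyError:
            raise GenotypeError(f"unknown sample id {sample_id!r}") from None

    def locus_column(self, locus_id: str) -> np.ndarray:
        try:
            return self.codes[:, self._locus_index[locus_id]]
        except KeyError:
            raise GenotypeError(f"unknown locus id {locus_id!r}") from None

    def locus(self, locus_id: str) -> LocusInfo:
        try:
            return self.loci[self._locus_index[locus_id]]
        except KeyError:
            raise GenotypeError(f"unknown locus id {locus_id!r}") from None

    def subset(
        self,
        samples: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([self._sample_index[s] for s in samples])
        )
        if loci is None:
            cols = np.arange(self.n_loci)
        else:
            for l in loci:
                if l not in self._locus_index:
                    raise GenotypeError(f"unknown locus id {l!r}")
            cols = np.array([self._locus_index[l] for l in loci])
        return GenotypeMatrix(
            [self.samples[i] for i in rows],
            [self.loci[j] for j in cols],
            self.codes[np.ix_(rows, cols)],
        )

    def to_frame(self) -> pd.DataFrame:
        """Calls as strings ('1/1'..'NA'), samples as index, loci as columns."""
        data = np.vectorize(_CODE_TO_CALL.get)(self.codes)
        return pd.DataFrame(data, index=self.samples, columns=self.locus_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class AlleleFreqs:
    """Per-locus allele_a frequency ``p`` and number of typed individuals.

    ``p`` is estimated from 2*n_typed allele draws; missing calls never
    enter the denominator.
    """

    locus_ids: list[str]
    p: np.ndarray
    n_typed: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n_typed = np.asarray(self.n_typed, dtype=int)
        if not (len(self.locus_ids) == len(self.p) == len(self.n_typed)):
            raise GenotypeError("AlleleFreqs fields must have equal length")
        if ((self.p < 0) | (self.p > 1)).any():
            raise GenotypeError("allele frequencies must lie in [0, 1]")
        self._index = {l: i for i, l in enumerate(self.locus_ids)}

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, self.q)

    def for_locus(self, locus_id: str) -> tuple[float, int]:
        i = self._index[locus_id]
        return float(self.p[i]), int(self.n_typed[i])


def allele_frequencies(g: GenotypeMatrix) -> AlleleFreqs:
    """Estimate allele_a frequencies per locus: p = (2*n11 + n12) / (2*n_typed)."""
    typed = g.codes != MISSING
    n_typed = typed.sum(axis=0)
    if (n_typed == 0).any():
        empty = [g.locus_ids[j] for j in np.flatnonzero(n_typed == 0)]
        raise GenotypeError(f"all calls missing at loci: {empty}")
    # codes count copies of allele_b, so allele_a copies = 2 - code (typed only)
    a_copies = np.where(typed, 2 - g.codes, 0).sum(axis=0)
    p = a_copies / (2.0 * n_typed)
    return AlleleFreqs(g.locus_ids, p, n_typed)


# -- CSV genotype tables ---------------------------------------------------


def read_genotype_csv(
    path: str | Path, loci: Sequence[LocusInfo] | None = None
) -> GenotypeMatrix:
    """Read the CSV genotype-table dialect.

    Header row ``sample,<locus_id>,...``; one row per sample; cells in
    {1/1, 1/2, 2/1, 2/2, NA}.  ``loci`` may supply full locus metadata
    (matched by id, in header order); otherwise bare ids are kept.
    """
    with open(path) as fh:
        raw_header = fh.readline().rstrip("\r\n").split(",")
    if len(raw_header) < 2:
        raise GenotypeError(f"{path}: expected a sample column plus at least one locus")
    raw_loci = raw_header[1:]
    if len(set(raw_loci)) != len(raw_loci):  # pandas would mangle duplicates
        dupes = sorted({l for l in raw_loci if raw_loci.count(l) > 1})
        raise GenotypeError(f"{path}: duplicate locus ids in header: {dupes}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = raw_header
    sample_col = df.columns[0]
    locus_ids = list(df.columns[1:])
    samples = df[sample_col].tolist()
    codes = np.full((len(samples), len(locus_ids)), MISSING, dtype=np.int8)
    for j, lid in enumerate(locus_ids):
        for i, cell in enumerate(df[lid]):
            cell = cell.strip()
            try:
                codes[i, j] = _CALL_TO_CODE[cell]
            except KeyError:
                raise GenotypeError(
                    f"{path}: malformed cell {cell!r} at sample {samples[i]!r}, "
                    f"locus {lid!r}"
                ) from None
    if loci is not None:
        by_id = {l.locus_id: l for l in loci}
        locus_infos = [by_id.get(lid, LocusInfo(lid)) for lid in locus_ids]
    else:
        locus_infos = [LocusInfo(lid) for lid in locus_ids]
    return GenotypeMatrix(samples, locus_infos, codes)


def write_genotype_csv(g: GenotypeMatrix, path: str | Path) -> None:
    df = g.to_frame()
    df.index.name = "sample"
    df.to_csv(path)


def write_fingerprint_table(
    g: GenotypeMatrix, panel: Sequence[str], path: str | Path
) -> None:
    """Emit the samples x panel genotype-code table used as a DNA fingerprint.

    Column order follows ``panel`` exactly; unknown locus ids raise.
    """
    write_genotype_csv(g.subset(loci=list(panel)), path)


# -- VCF -------------------------------------------------------------------

_GT_TO_CODE = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 1,
    (1, 1): 2,
    (None, None): MISSING,
}


def read_vcf(path: str | Path, on_invalid: str = "skip") -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF v4.2 file.

    GT 0/0, 0/1, 1/1, ./. map to 1/1, 1/2, 2/2, NA (phase discarded).
    Multi-allelic or indel records are skipped (``on_invalid='skip'``,
    default) or rejected (``'raise'``).  Haploid GT values are errors.
    """
    import pysam

    if on_invalid not in ("skip", "raise"):
        raise ValueError("on_invalid must be 'skip' or 'raise'")
    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise GenotypeError(f"{path}: VCF has no GT format definition")
        samples = list(vcf.header.samples)
        loci: list[LocusInfo] = []
        columns: list[np.ndarray] = []
        for rec in vcf:
            alts = rec.alts or ()
            invalid = (
                len(alts) != 1
                or len(rec.ref or "") != 1
                or len(alts[0]) != 1
                or (rec.ref or "").upper() not in "ACGT"
                or alts[0].upper() not in "ACGT"
            )
            if invalid:
                if on_invalid == "raise":
                    raise GenotypeError(
                        f"{path}: record {rec.chrom}:{rec.pos} is not a biallelic SNP"
                    )
                continue
            lid = rec.id or f"{rec.chrom}_{rec.pos}"
            col = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or len(gt) != 2:
                    raise GenotypeError(
                        f"{path}: non-diploid GT for sample {s!r} at {rec.chrom}:{rec.pos}"
                    )
                try:
                    col[i] = _GT_TO_CODE[tuple(gt)]
                except KeyError:
                    raise GenotypeError(
                        f"{path}: unsupported GT {gt} for sample {s!r} "
                        f"at {rec.chrom}:{rec.pos}"
                    ) from None
            loci.append(
                LocusInfo(lid, chrom=rec.chrom, pos=rec.pos, allele_a=rec.ref, allele_b=alts[0])
            )
            columns.append(col)
    if not loci:
        raise GenotypeError(f"{path}: no biallelic SNP records found")
    return GenotypeMatrix(samples, loci, np.column_stack(columns))


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes.

    Every locus must carry chrom, pos, and both alleles.
    """
    for l in g.loci:
        if l.chrom is None or l.pos is None or l.allele_a is None or l.allele_b is None:
            raise GenotypeError(
                f"locus {l.locus_id}: chrom/pos/alleles required to write VCF"
            )
    order = sorted(range(g.n_loci), key=lambda j: (_chrom_key(g.loci[j].chrom), g.loci[j].pos))
    contigs: dict[str, int] = {}
    for j in order:
        l = g.loci[j]
        contigs[l.chrom] = max(contigs.get(l.chrom, 0), l.pos + 1000)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={n}>" for c, n in contigs.items()]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples))
    for j in order:
        l = g.loci[j]
        gts = "\t".join(_CODE_TO_GT[int(c)] for c in g.codes[:, j])
        lines.append(
            f"{l.chrom}\t{l.pos}\t{l.locus_id}\t{l.allele_a}\t{l.allele_b}\t.\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _chrom_key(chrom: str) -> tuple:
    m = re.search(r"(\d+)$", chrom)
    return (0, int(m.group(1)), chrom) if m else (1, 0, chrom)
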