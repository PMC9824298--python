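"""Synthetic genotype panels with known truth.

Everything downstream of the data model — diversity statistics,
fingerprint selection, parentage assignment, screening, phylogeny — is
exercised on panels from these generators, which emulate a core-marker
panel for a clonal, self-incompatible diploid crop: ~45 unlinked biallelic
SNPs spread over 15 chromosomes, typed on ~117 cultivars, with minor
allele frequencies near 0.45-0.50.

Three generators:

* :func:`simulate_panel` — unstructured panel under Hardy-Weinberg
  equilibrium, per-locus MAF drawn uniformly from configured bounds.
* :func:`simulate_structured` — Balding-Nichols F-model divergence of a
  configurable number of subpopulations (stand-in for the Assam /
  Chinese / transitional grouping of cultivated tea).
* :func:`simulate_trios` — known parent-offspring families with an
  optional mistyping rate (each offspring call independently replaced by
  a fresh HWE draw), the ground truth for parentage-recovery tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, AlleleFreqs, GenotypeMatrix, LocusInfo

_NUCS = np.array(list("ACGT"))


@dataclass
class PanelSimConfig:
    """Panel dimensions and frequency model.

    Defaults mirror the published core panel: 117 diploid cultivars, 45
    loci on 15 chromosomes, per-locus MAF uniform on [0.447, 0.5] (the
    printed column range), no missing data.
    """

    n_samples: int = 117
    n_loci: int = 45
    maf_low: float = 0.447
    maf_high: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0
    n_chromosomes: int = 15

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 <= maf_low <= maf_high <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_samples < 1 or self.n_loci < 1 or self.n_chromosomes < 1:
            raise ValueError("counts must be positive")


@dataclass
class StructureSimConfig:
    """Balding-Nichols subpopulation divergence."""

    n_pops: int = 3
    fst: float = 0.1
    pop_sizes: list[int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")


@dataclass(frozen=True)
class TrioTruth:
    """Ground-truth pedigree record for one simulated family."""

    offspring_id: str
    mother_id: str | None
    father_id: str | None


def _sample_ids(n: int, prefix: str = "S") -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _make_loci(cfg: PanelSimConfig, rng: np.random.Generator) -> list[LocusInfo]:
    loci = []
    for j in range(cfg.n_loci):
        chrom = f"chr{j % cfg.n_chromosomes + 1}"
        rank = j // cfg.n_chromosomes
        pos = int((rank + 1) * 1_000_000 + rng.integers(1, 900_000))
        a, b = rng.choice(4, size=2, replace=False)
        flank_up = "".join(rng.choice(_NUCS, size=35))
        flank_down = "".join(rng.choice(_NUCS, size=35))
        loci.append(
            LocusInfo(
                f"L{j + 1:03d}",
                chrom=chrom,
                pos=pos,
                allele_a=str(_NUCS[a]),
                allele_b=str(_NUCS[b]),
                flank_up=flank_up,
                flank_down=flank_down,
            )
        )
    return loci


def _draw_hwe(p: np.ndarray, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Genotype codes (copies of allele_b) under HWE for allele_a freqs p."""
    u = rng.random((n_samples, len(p)))
    codes = np.full(u.shape, 2, dtype=np.int8)  # q^2 tail
    codes[u < p**2 + 2 * p * (1 - p)] = 1
    codes[u < p**2] = 0
    return codes


def _mask_missing(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        codes = codes.copy()
        codes[rng.random(codes.shape) < rate] = MISSING
    return codes


def simulate_panel(
    cfg: PanelSimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, AlleleFreqs]:
    """Unstructured HWE panel; returns the matrix and the true frequencies.

    allele_a is the major allele by construction (p = 1 - MAF).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, cfg.n_loci)
    p = 1.0 - maf
    loci = _make_loci(cfg, rng)
    codes = _mask_missing(_draw_hwe(p, cfg.n_samples, rng), cfg.missing_rate, rng)
    g = GenotypeMatrix(_sample_ids(cfg.n_samples), loci, codes)
    truth = AlleleFreqs([l.locus_id for l in loci], p, np.full(cfg.n_loci, cfg.n_samples))
    return g, truth


def simulate_structured(
    cfg: StructureSimConfig, base: PanelSimConfig
) -> tuple[GenotypeMatrix, list[str], dict]:
    """Structured panel under the Balding-Nichols model.

    Per locus an ancestral allele_a frequency p is drawn from the base MAF
    bounds; each subpopulation's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F)
    so that E[p_k] = p and Var[p_k] = F p (1-p).  fst = 0 degenerates to
    identical subpopulation frequencies.  Returns (matrix, per-sample
    population labels, truth dict with ancestral and per-pop frequencies).
    """
    rng = np.random.default_rng(base.seed)
    if cfg.pop_sizes is None:
        quo, rem = divmod(base.n_samples, cfg.n_pops)
        pop_sizes = [quo + (1 if k < rem else 0) for k in range(cfg.n_pops)]
    else:
        pop_sizes = list(cfg.pop_sizes)
        if sum(pop_sizes) != base.n_samples:
            raise ValueError("pop_sizes must sum to n_samples")
    maf = rng.uniform(base.maf_low, base.maf_high, base.n_loci)
    p_anc = 1.0 - maf
    if cfg.fst == 0.0:
        p_pops = np.tile(p_anc, (cfg.n_pops, 1))
    else:
        f = cfg.fst
        alpha = p_anc * (1 - f) / f
        beta = (1 - p_anc) * (1 - f) / f
        p_pops = rng.beta(alpha, beta, size=(cfg.n_pops, base.n_loci))
    loci = _make_loci(base, rng)
    pop_names = [f"pop{string.ascii_uppercase[k % 26]}" for k in range(cfg.n_pops)]
    blocks, labels = [], []
    for k, size in enumerate(pop_sizes):
        blocks.append(_draw_hwe(p_pops[k], size, rng))
        labels += [pop_names[k]] * size
    codes = _mask_missing(np.vstack(blocks), base.missing_rate, rng)
    g = GenotypeMatrix(_sample_ids(base.n_samples), loci, codes)
    truth = {"p_ancestral": p_anc, "p_pops": p_pops, "pop_names": pop_names}
    return g, labels, truth


def _breed(
    mothers: np.ndarray, fathers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One offspring genotype per (mother, father) row pair: one gamete each."""
    pa_m = (2 - mothers) / 2.0  # P(transmit allele_a)
    pa_f = (2 - fathers) / 2.0
    from_m = rng.random(mothers.shape) < pa_m
    from_f = rng.random(fathers.shape) < pa_f
    return (2 - from_m.astype(np.int8) - from_f.astype(np.int8)).astype(np.int8)


def simulate_trios(
    panel: PanelSimConfig, n_families: int, error_rate: float = 0.0
) -> tuple[GenotypeMatrix, list[TrioTruth]]:
    """Parent-offspring families with a known truth table.

    Parents are independent HWE draws; each offspring receives one allele
    from each parent uniformly at random; each offspring call is then
    independently replaced by a fresh HWE draw with probability
    ``error_rate`` (the mistyping model).  The emitted matrix holds
    mothers, fathers, then offspring; missingness from ``panel`` applies
    to every individual.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(panel.seed)
    maf = rng.uniform(panel.maf_low, panel.maf_high, panel.n_loci)
    p = 1.0 - maf
    loci = _make_loci(panel, rng)
    mothers = _draw_hwe(p, n_families, rng)
    fathers = _draw_hwe(p, n_families, rng)
    offspring = _breed(mothers, fathers, rng)
    if error_rate > 0:
        err = rng.random(offspring.shape) < error_rate
        offspring = np.where(err, _draw_hwe(p, n_families, rng), offspring)
    codes = _mask_missing(
        np.vstack([mothers, fathers, offspring]), panel.missing_rate, rng
    )
    width = max(3, len(str(n_families)))
    mids = [f"fam{i + 1:0{width}d}_mother" for i in range(n_families)]
    fids = [f"fam{i + 1:0{width}d}_father" for i in range(n_families)]
    oids = [f"fam{i + 1:0{width}d}_child" for i in range(n_families)]
    g = GenotypeMatrix(mids + fids + oids, loci, codes)
    truths = [TrioTruth(o, m, f) for o, m, f in zip(oids, mids, fids)]
    return g, truths
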