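"""End-to-end pipeline: simulate -> stats -> screen -> fingerprint ->
parentage -> tree, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, fingerprint, parentage, phylogeny, screening
from .genotypes import write_fingerprint_table, write_genotype_csv, write_vcf
from .simulate import PanelSimConfig, simulate_panel, simulate_trios

log = logging.getLogger(__name__)


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run.

    All randomness flows from ``seed``; per-stage blocks mirror the
    module config types.  Unknown keys are rejected up front.
    """

    out_dir: str = "results/run"
    seed: int = 0
    panel: PanelSimConfig = field(default_factory=PanelSimConfig)
    screening: screening.ScreeningCriteria = field(
        default_factory=lambda: screening.ScreeningCriteria(require_flank_match=False)
    )
    cervus: parentage.CervusSimConfig = field(default_factory=parentage.CervusSimConfig)
    fingerprint_strategy: str = "greedy"
    n_families: int = 10

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        nested = {
            "panel": PanelSimConfig,
            "screening": screening.ScreeningCriteria,
            "cervus": parentage.CervusSimConfig,
        }
        for key, sub_cls in nested.items():
            if key in data:
                data[key] = _from_dict(sub_cls, data[key])
        cfg = _from_dict(cls, data)
        # one seed drives every stage
        cfg.panel.seed = cfg.seed
        cfg.cervus.seed = cfg.seed + 1
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage on a simulated panel; returns the output directory.

    Artifacts: genotypes (CSV + VCF), diversity stats CSV, screening
    ledger CSV, fingerprint panel JSON + table CSV, parentage CSV,
    newick tree, and a manifest listing every file with its stage,
    parameters and checksum.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[tuple[str, Path]] = []

    def emit(stage: str, name: str) -> Path:
        path = out / name
        artifacts.append((stage, path))
        return path

    log.info("simulate: %d samples x %d loci (seed %d)", cfg.panel.n_samples, cfg.panel.n_loci, cfg.seed)
    g, truth = simulate_panel(cfg.panel)
    write_genotype_csv(g, emit("simulate", "genotypes.csv"))
    write_vcf(g, emit("simulate", "genotypes.vcf"))

    log.info("stats: per-locus diversity")
    stats = diversity.panel_stats(g)
    for s in stats:
        s.pi = float(fingerprint.locus_pi(1.0 - s.maf))
        tri = parentage.locus_exclusion(1.0 - s.maf)
        s.pe1, s.pe2, s.pe3 = tri.pe1, tri.pe2, tri.pe3
    tbl = diversity.stats_table(stats)
    tbl = pd.concat([tbl, tbl.mean(numeric_only=True).to_frame("Mean").T])
    tbl.index.name = "name"
    tbl.round(3).to_csv(emit("stats", "diversity.csv"))

    log.info("screen: filter cascade")
    selected, ledger = screening.screen_core_markers(g, stats, cfg.screening)
    ledger.to_csv(emit("screen", "screening_ledger.csv"), index=False)

    log.info("fingerprint: minimal discriminating panel (%s)", cfg.fingerprint_strategy)
    sel = fingerprint.select_min_panel(g, stats, strategy=cfg.fingerprint_strategy)
    emit("fingerprint", "fingerprint_panel.json").write_text(
        json.dumps(
            {
                "loci": sel.locus_ids,
                "cumulative_pi": sel.cumulative_pi,
                "distinguishes_all": sel.distinguishes_all,
                "duplicate_pairs": sel.duplicate_pairs,
                "seed": cfg.seed,
            },
            indent=2,
        )
    )
    if sel.locus_ids:
        write_fingerprint_table(g, sel.locus_ids, emit("fingerprint", "fingerprint_table.csv"))

    log.info("parentage: %d simulated families", cfg.n_families)
    trio_panel = PanelSimConfig(
        n_samples=cfg.panel.n_samples,
        n_loci=cfg.panel.n_loci,
        maf_low=cfg.panel.maf_low,
        maf_high=cfg.panel.maf_high,
        missing_rate=cfg.panel.missing_rate,
        seed=cfg.seed + 2,
        n_chromosomes=cfg.panel.n_chromosomes,
    )
    gt, truths = simulate_trios(trio_panel, cfg.n_families, cfg.cervus.error_rate)
    cervus = parentage.CervusSimConfig(**{**asdict(cfg.cervus), "n_candidates": cfg.n_families})
    assignments, critical = parentage.assign_parentage(
        gt,
        offspring_ids=[t.offspring_id for t in truths],
        candidate_ids=[t.father_id for t in truths],
        cfg=cervus,
        known_parents={t.offspring_id: t.mother_id for t in truths},
    )
    pd.DataFrame(
        [
            {
                "offspring": a.offspring_id,
                "candidate": a.candidate_id,
                "loci_compared": a.n_compared,
                "loci_mismatching": a.n_mismatch,
                "lod": round(a.lod, 2),
                "delta": round(a.delta, 2),
                "confidence": a.confidence,
                "true_father": next(t.father_id for t in truths if t.offspring_id == a.offspring_id),
            }
            for a in assignments
        ]
    ).to_csv(emit("parentage", "parentage.csv"), index=False)

    log.info("tree: allele-sharing distance + neighbor joining")
    dmat = phylogeny.allele_sharing_distance(g)
    pd.DataFrame(dmat.values, index=dmat.ids, columns=dmat.ids).to_csv(
        emit("tree", "distances.csv")
    )
    emit("tree", "tree.nwk").write_text(phylogeny.neighbor_joining(dmat) + "\n")

    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "critical_delta": critical,
        "files": [
            {"stage": stage, "file": p.name, "sha256": _sha256(p)} for stage, p in artifacts
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
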