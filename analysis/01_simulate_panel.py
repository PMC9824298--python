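"""Simulate the working genotype panel: 117 cultivars x 45 SNPs.

Emulates the study conditions of the published tea core-marker panel
(45 unlinked biallelic loci on 15 chromosomes, MAF in 0.447-0.50, no
missing data) plus 10 parent-offspring families with 1% mistyping for
the parentage stage.  Writes CSV + VCF + truth JSON under results/.
"""

import json
from dataclasses import asdict
from pathlib import Path

from teacore import (
    PanelSimConfig,
    simulate_panel,
    simulate_trios,
    write_genotype_csv,
    write_vcf,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = PanelSimConfig(seed=SEED)  # defaults mirror the published panel
    g, truth = simulate_panel(cfg)
    write_genotype_csv(g, OUT / "panel_genotypes.csv")
    write_vcf(g, OUT / "panel_genotypes.vcf")

    trio_cfg = PanelSimConfig(seed=SEED + 1)
    gt, trios = simulate_trios(trio_cfg, n_families=10, error_rate=0.01)
    write_genotype_csv(gt, OUT / "trio_genotypes.csv")

    (OUT / "panel_truth.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "p_true": dict(zip(truth.locus_ids, truth.p.tolist())),
                "trios": [asdict(t) for t in trios],
            },
            indent=2,
        )
    )
    print(f"panel: {g.n_samples} samples x {g.n_loci} loci -> {OUT / 'panel_genotypes.csv'}")
    print(f"trios: {len(trios)} families with 1% mistyping -> {OUT / 'trio_genotypes.csv'}")


if __name__ == "__main__":
    main()
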