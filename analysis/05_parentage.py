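"""Likelihood parentage verification on simulated families.

Runs the full assignment engine (LOD ranking + Monte-Carlo critical
delta) on 50 simulated trios genotyped at 45 loci with 1% mistyping,
mothers known, all true fathers among the candidates.  Reports the
fraction of true fathers recovered at 95% confidence and writes a
pedigree-verification table (offspring, candidate, mismatching loci,
LOD, confidence star).
"""

from pathlib import Path

import pandas as pd

from teacore import CervusSimConfig, PanelSimConfig, assign_parentage, simulate_trios

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel = PanelSimConfig(n_loci=45, maf_low=0.3, maf_high=0.5, seed=SEED)
    g, truths = simulate_trios(panel, n_families=50, error_rate=0.01)
    cfg = CervusSimConfig(
        n_candidates=50, n_offspring=1000, seed=SEED + 1, prop_parents_sampled=1.0
    )
    assignments, critical = assign_parentage(
        g,
        offspring_ids=[t.offspring_id for t in truths],
        candidate_ids=[t.father_id for t in truths],
        cfg=cfg,
        known_parents={t.offspring_id: t.mother_id for t in truths},
    )
    truth = {t.offspring_id: t.father_id for t in truths}
    rows = [
        {
            "offspring": a.offspring_id,
            "candidate_father": a.candidate_id,
            "loci_compared": a.n_compared,
            "loci_mismatching": a.n_mismatch,
            "lod": round(a.lod, 2),
            "delta": round(a.delta, 2),
            "confidence": "*" if a.confidence == "95%" else "",
            "is_true_father": a.candidate_id == truth[a.offspring_id],
        }
        for a in assignments
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "parentage_assignments.csv", index=False)
    recovered = (df.is_true_father & (df.confidence == "*")).sum()
    print(f"critical delta at 95% confidence: {critical:.3f}")
    print(f"true fathers recovered at 95% confidence: {recovered}/{len(truths)}")
    print(f"assignment table -> {OUT / 'parentage_assignments.csv'}")


if __name__ == "__main__":
    main()
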