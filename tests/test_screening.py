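"""Core-marker screening cascade and flank conservation."""

import numpy as np
import pytest

from teacore.diversity import panel_stats
from teacore.genotypes import MISSING, GenotypeMatrix, LocusInfo
from teacore.screening import ScreeningCriteria, flank_conserved, screen_core_markers
from teacore.simulate import PanelSimConfig, simulate_panel


def _reference_with_planted_flanks(loci):
    """Chromosome sequences in which every locus's flanks appear verbatim."""
    rng = np.random.default_rng(0)
    nucs = np.array(list("ACGT"))
    ref = {}
    for l in loci:
        length = l.pos + 40
        seq = list(rng.choice(nucs, size=length))
        seq[l.pos - 36 : l.pos - 1] = list(l.flank_up)
        seq[l.pos - 1] = l.allele_a
        seq[l.pos : l.pos + 35] = list(l.flank_down)
        prev = ref.get(l.chrom, "")
        joined = list(prev.ljust(length, "A"))
        joined[l.pos - 36 : l.pos + 35] = seq[l.pos - 36 : l.pos + 35]
        ref[l.chrom] = "".join(joined)
    return ref


class TestFlankConserved:
    def _locus(self, **kw):
        base = dict(
            chrom="chr1", pos=50,
            allele_a="A", allele_b="G",
            flank_up="ACGT" * 8 + "ACG", flank_down="TGCA" * 8 + "TGC",
        )
        base.update(kw)
        return LocusInfo("L1", **base)

    def _ref_for(self, locus):
        seq = ["C"] * 120
        seq[locus.pos - 36 : locus.pos - 1] = list(locus.flank_up)
        seq[locus.pos : locus.pos + 35] = list(locus.flank_down)
        return {locus.chrom: "".join(seq)}

    def test_verbatim_flanks_conserved(self):
        l = self._locus()
        assert flank_conserved(l, self._ref_for(l))

    def test_case_insensitive(self):
        l = self._locus()
        ref = {k: v.lower() for k, v in self._ref_for(l).items()}
        assert flank_conserved(l, ref)

    def test_single_substitution_fails(self):
        l = self._locus()
        ref = self._ref_for(l)
        seq = list(ref["chr1"])
        seq[l.pos - 36] = "T" if seq[l.pos - 36] != "T" else "A"
        assert not flank_conserved(l, {"chr1": "".join(seq)})

    def test_ambiguous_n_fails(self):
        l = self._locus(flank_up="N" + "ACGT" * 8 + "AC")
        ref = self._ref_for(l)
        assert not flank_conserved(l, ref)

    def test_absent_chromosome_is_error(self):
        l = self._locus()
        with pytest.raises(ValueError, match="chr1"):
            flank_conserved(l, {"chr2": "A" * 200})

    def test_window_out_of_range_is_error(self):
        l = self._locus(pos=10)
        with pytest.raises(ValueError, match="L1"):
            flank_conserved(l, {"chr1": "A" * 200})


class TestScreenCoreMarkers:
    def test_missing_call_excludes_locus(self):
        g, _ = simulate_panel(PanelSimConfig(n_samples=20, n_loci=6, seed=1))
        codes = g.codes.copy()
        codes[0, 2] = MISSING
        g2 = GenotypeMatrix(g.samples, g.loci, codes)
        stats = panel_stats(g2)
        criteria = ScreeningCriteria(require_flank_match=False)
        _, ledger = screen_core_markers(g2, stats, criteria)
        row = ledger.set_index("locus_id").loc[g.locus_ids[2]]
        assert not row.passed and "missing_calls" in row.rejection_reasons

    def test_maf_threshold_is_strict(self):
        # 0.04 excluded, 0.06 retained at the 0.05 threshold
        n = 50
        codes = np.zeros((n, 2), dtype=np.int8)
        codes[:4, 0] = 1   # maf 4/100 = 0.04
        codes[:6, 1] = 1   # maf 6/100 = 0.06
        g = GenotypeMatrix([f"s{i}" for i in range(n)], [LocusInfo("A"), LocusInfo("B")], codes)
        stats = panel_stats(g)
        criteria = ScreeningCriteria(require_flank_match=False)
        _, ledger = screen_core_markers(g, stats, criteria)
        fate = ledger.set_index("locus_id").passed
        assert not fate["A"] and fate["B"]

    def test_top_k_matches_sort_oracle(self):
        g, _ = simulate_panel(
            PanelSimConfig(n_samples=80, n_loci=10, maf_low=0.1, maf_high=0.5,
                           seed=11, n_chromosomes=2)
        )
        stats = panel_stats(g)
        criteria = ScreeningCriteria(require_flank_match=False, maf_min=0.0)
        selected, ledger = screen_core_markers(g, stats, criteria)
        by_id = {s.locus_id: s for s in stats}
        for chrom in selected:
            members = [l for l in g.loci if l.chrom == chrom]
            oracle = sorted(
                members,
                key=lambda l: (-by_id[l.locus_id].pic, -by_id[l.locus_id].maf, l.pos),
            )[:3]
            assert selected[chrom] == [l.locus_id for l in oracle]

    def test_output_size_bounded(self):
        g, _ = simulate_panel(PanelSimConfig(n_samples=117, n_loci=45, seed=0))
        stats = panel_stats(g)
        selected, _ = screen_core_markers(
            g, stats, ScreeningCriteria(require_flank_match=False)
        )
        total = sum(len(v) for v in selected.values())
        assert total <= 3 * 15
        # healthy panel: all 45 survive, 3 per chromosome on 15 chromosomes
        assert total == 45

    def test_flank_criterion_with_synthetic_reference(self):
        g, _ = simulate_panel(PanelSimConfig(n_samples=30, n_loci=6, seed=7, n_chromosomes=2))
        ref = _reference_with_planted_flanks(g.loci)
        # corrupt one locus's upstream flank in the reference
        bad = g.loci[0]
        seq = list(ref[bad.chrom])
        i = bad.pos - 36
        seq[i] = "A" if seq[i] != "A" else "C"
        ref[bad.chrom] = "".join(seq)
        stats = panel_stats(g)
        criteria = ScreeningCriteria(maf_min=0.0)
        _, ledger = screen_core_markers(g, stats, criteria, reference=ref)
        fate = ledger.set_index("locus_id")
        assert "flank_not_conserved" in fate.loc[bad.locus_id].rejection_reasons
        others = fate.drop(bad.locus_id)
        assert not others.rejection_reasons.str.contains("flank").any()

    def test_filters_are_a_pure_conjunction(self):
        g, _ = simulate_panel(PanelSimConfig(n_samples=40, n_loci=8, maf_low=0.0,
                                             maf_high=0.5, missing_rate=0.05, seed=3))
        stats = panel_stats(g)
        criteria = ScreeningCriteria(require_flank_match=False)
        _, ledger = screen_core_markers(g, stats, criteria)
        for _, row in ledger.iterrows():
            col = g.locus_column(row.locus_id)
            expect_missing = (col == MISSING).any()
            expect_maf = not (row.maf > criteria.maf_min)
            reasons = set(filter(None, row.rejection_reasons.split(";")))
            assert reasons == {
                r
                for r, hit in [
                    ("missing_calls", expect_missing),
                    ("maf_below_threshold", expect_maf),
                ]
                if hit
            }
            assert row.passed == (not reasons)
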