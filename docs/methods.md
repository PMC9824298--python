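# Methods

This note records the models, estimators, parameter choices and known
limitations behind `teacore`, in the order the pipeline runs them.

## Data model

Genotypes are unordered diploid biallelic calls (`1/1`, `1/2`, `2/2`,
`NA`), stored internally as the count of copies of the second allele
(0/1/2, −1 for missing). Heterozygote order and VCF phase are
discarded: the array-genotyping convention the panel was built for does
not record strand or parental origin. Haploid or hemizygous calls are
rejected rather than coerced — the package models diploid material
only. Allele frequencies are always estimated from 2·n_typed allele
draws with missing calls excluded from the denominator; a locus with no
typed calls is an error rather than a silent NaN.

Coordinates are 1-based inclusive (the convention of both VCF and the
published marker table); flank extraction converts internally.

## Synthetic panels

`simulate_panel` draws, per locus, a MAF uniform on
[`maf_low`, `maf_high`] and genotypes under Hardy–Weinberg equilibrium
(p², 2pq, q²), with loci assigned cyclically to `n_chromosomes`
chromosomes. Defaults (117 samples, 45 loci, 15 chromosomes, MAF on
[0.447, 0.5], no missing data) mirror the published core panel, whose
printed MAF column spans exactly that range on fully typed cultivars.
Loci are unlinked by construction — the real panel's nearest pair is
~6 Mb apart and the analysis treats all loci as independent — so
nothing here exercises linkage.

`simulate_structured` uses the Balding–Nichols model: an ancestral
frequency p per locus, and per-subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), so E[p_k] = p and Var[p_k] = F·p(1−p).
Any exchangeable F-model would serve; Balding–Nichols is standard, has
the Fst parameter directly, and its truth frequencies make moment
checks one line. It stands in for the Assam / Chinese / transitional
grouping of cultivated tea, which the original study inherited from
prior structure analyses (out of scope here).

`simulate_trios` draws parents under HWE, transmits one uniformly
chosen allele from each, and then — with probability `error_rate` per
call — replaces the offspring call with a fresh HWE draw. This
"replace with a population genotype" mistyping model is the simplest
one consistent with a Cervus-style mistyping rate and is used
consistently in both the generator and the likelihood, so
parentage-recovery tests are self-consistent. Real array errors are
not frequency-matched HWE draws (allele dropout biases toward
homozygotes), so recovery rates on real data may differ.

What the generators deliberately do not emulate: clonal duplicates,
relatedness among "unrelated" panel members (the real cultivar panel
mixes pedigree ties and shared ancestry), locus-specific missingness,
and genotyping batch effects. Passing tests therefore demonstrate
correctness of the machinery under the stated model, not performance
guarantees on arbitrary germplasm collections.

## Diversity statistics

All statistics are computed from allele frequencies (power sums
a_k = Σ p_i^k) and genotype counts:

| statistic | form | note |
|---|---|---|
| Ne | 1/a₂ | 2 at p = 0.5 |
| I | −Σ p_i ln p_i | ≤ ln 2 for biallelic loci |
| Ho | n_het / n_typed | direct count |
| He | 2n/(2n−1) · (1 − a₂) | Nei's unbiased estimator |
| PIC | 1 − a₂ − (a₂² − a₄) | Botstein's form, ≤ 0.375 |

He uses the unbiased small-sample factor because the published He
maximum (0.502 at n = 117) exceeds the uncorrected ceiling of 0.5 —
only the corrected form reproduces it (at p = 0.5, n = 117:
(234/233)·0.5 = 0.50215). Na counts alleles actually observed among
non-missing calls, so a locus fixed in the sample has Na = 1 even if
declared biallelic. Report tables round half-even to 3 decimals;
internal computation keeps full precision.

A caveat inherited from the source table: a few printed rows are not
internally consistent (statistics evidently computed from unrounded
frequencies before the MAF column was rounded), and multiplying 45
3-decimal-rounded MAFs compounds that rounding: the 45-locus PI product
is reproduced from the printed per-locus PI column (to 0.2 %), not from
the rounded MAF column (which lands ~7 % low).

## Fingerprinting

Single-locus PI = 2a₂² − a₄; panels multiply under the independence
assumption (no LD correction; the sibling-adjusted PIsibs is
deliberately not computed, matching the source analysis). Minimal-panel
selection offers two strategies. *Greedy* ranks loci by ascending PI
(ties: higher Ho, then locus id) and adds until every sample pair
differs somewhere — this mirrors the "take the lowest-PI markers"
practice and is the default. *Exhaustive* finds a true
smallest-cardinality distinguishing subset by breadth-first search over
subset sizes, permitted only up to 20 loci (the pair-cover problem is
NP-hard; 20 keeps worst cases around a million subsets). A missing call
never counts as distinguishing a pair: a fingerprint must not rely on
absent data. Samples with identical full profiles are reported as
duplicate pairs, not raised — detecting clones is a result, not an
error.

## Exclusion and likelihood parentage

Per-locus exclusion probabilities use the Jamieson–Taylor closed forms
(in a_k) for the three configurations Q1 (second parent tested, first
known), Q2 (lone candidate), Q3 (parent pair). They are validated in
the test suite against a full enumeration of HWE
mother × father × offspring × candidate configurations to 1e-10; at
p = 0.5 they give 0.1875 / 0.125 / 0.28125. Cumulative curves combine
as 1 − Π(1 − PE); with the shipped 45-marker frequencies the 40-locus
values round to 0.9997 / 0.9950 / 1.0.

The LOD for a candidate is Σ ln [P*(g_o | parents incl. candidate) /
P*(g_o | parents excl. candidate)] over loci typed in every compared
individual, where P* replaces each Mendelian transmission probability T
by (1−e)·T + e·P_HW(g_o). This is a deliberate simplification of the
full confusion-matrix error model used by Cervus — transparent, two
lines of algebra, and exact at e = 0 (where an incompatible candidate
gets −∞). With one parent known the denominator is the
mother-plus-random-father likelihood; with none it is the HWE genotype
probability.

Assignment uses delta (best minus second-best LOD). The critical delta
is calibrated by simulation: `n_offspring` synthetic offspring from the
pool's allele frequencies, true father present with probability
`prop_parents_sampled`, mistyping at `error_rate`, loci retained at
`prop_loci_typed`; the critical value is the smallest threshold at
which the fraction of correct best-candidate calls among calls
exceeding it reaches the confidence level. Defaults
(0.5 / 0.01 / 0.99, minimum 13 typed loci, 1000 offspring, 95 %)
follow the published analysis settings. **`prop_parents_sampled` must
describe the user's actual sampling completeness**: for a closed
pedigree pool where every true parent is among the candidates, set it
to 1.0 — leaving it at 0.5 calibrates against a half-absent world and
roughly doubles the critical delta, discarding perfectly good
assignments. The recovery experiment in `analysis/05_parentage.py`
(50 families, 45 loci, MAF ~ U(0.3, 0.5), 1 % mistyping, mothers known)
uses 1.0 for exactly that reason and recovers 49/50 true fathers at
95 % confidence. Ties (e.g. a candidate genotypically identical to the
true parent) give delta 0 and are never assigned with confidence.

## Screening

The core-marker cascade applies, in order but as a pure conjunction:
no missing calls; MAF strictly greater than the threshold (default
0.05); both 35-bp flanks exactly conserved against the reference
genome (case-insensitive, any N fails — "completely conserved" is read
strictly, since the flanks exist to anchor PCR primers); PIC
computable. Survivors are ranked per chromosome by PIC descending
(ties: higher MAF, then position) and the top k kept — 3 per
chromosome on a 15-chromosome genome yields the evenly spaced
45-marker layout. Without a reference the flank criterion is skipped
with a prominent warning so the cascade runs on synthetic panels.

## Distances and trees

Individuals are compared with the allele-sharing distance
d = 1 − shared/(2L) over co-typed loci (2/1/0 shared alleles per
locus). The source analysis applied Nei's distance — a population
measure — to individuals via PowerMarker; this package deviates
deliberately: allele sharing is well defined at the individual level,
and Nei's 1972 standard distance is offered separately for labelled
groups. A pair with zero co-typed loci is an error (their distance is
undefined, and silently imputing it would distort the tree).

Neighbor joining is the standard Saitou–Nei agglomeration:
Q_ij = (m−2)d_ij − r_i − r_j minimised with a lowest-index tie-break
(reproducible trees), branch lengths ½d_ij ± (r_i−r_j)/(2(m−2)),
negative lengths clamped to zero with the excess moved to the sister
edge, and a trifurcating root (the tree is unrooted). For additive
inputs the output path-length matrix equals the input exactly; the test
suite also cross-checks topologies against scikit-bio's independent NJ
implementation. No bootstrap support values are computed (none were
reported for the original tree).

## Problem sizes

Test and analysis runs are sized to be quick while keeping Monte-Carlo
error well inside the asserted tolerances: 50 families × 50 candidates
with 1000 calibration offspring for parentage recovery (seconds,
vectorised over a (1000, 50, 45) array); 2000 samples × 5 loci
(~2 × 10⁶ pairs) for the empirical match-probability check; 500 loci ×
3 populations for the Fst moment check; 60–90 samples × 200 loci for
tree-recovery checks. The published-panel recomputations are closed
form and instantaneous.

## Known limitations

* Independence of loci is assumed everywhere PI/PE multiply; linked
  panels need an LD-aware treatment this package does not provide.
* The mistyping model is shared between simulator and likelihood;
  structured genotyping error (dropout, null alleles) is not modelled.
* Exhaustive panel search is capped at 20 loci by design.
* No sibship reconstruction, joint pedigree inference, or
  population-assignment methods; parent/offspring directionality is
  metadata the caller supplies, the engine treats pairs symmetrically.
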