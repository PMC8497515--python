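# Methods

This note documents the models implemented in `codigest`, their
assumptions, the defaults and why, the synthetic-data generator's design,
and the numerical and statistical choices a maintainer should know about.

## Theoretical biomethane potential

All three BMP models operate on a validated `UltimateAnalysis`: TS as a
fraction of wet mass, VS as a fraction of TS, and C/H/N/S/O as mass
fractions of TS. Inputs are accepted on the conventional percent reporting
scales and converted once. Validation rejects negative values, elemental
sums above 100% of TS, and zero VS (per-VS quantities would be undefined).
The elemental sum may be below the VS fraction; the remainder is ash plus
unmeasured elements.

**Empirical formula.** Molar ratios C/12 : H/1 : O/16 : N/14 : S/32 (integer
atomic masses, the convention of the underlying formulas) are rescaled so
the sulfur subscript is 1. Sulfur-free compositions are normalized to
carbon instead, with an explicit warning rather than a silent mode switch.
Subscripts are reals; nearest-integer rounding is optional. Published
formula subscripts for field substrates are generally computed from
unrounded per-replicate measurements, so rounded printed means need not
reproduce them; no attempt is made to force such agreement.

**Buswell–Boyle stoichiometry.** For C_aH_bO_cN_dS_e the balanced digestion
reaction has

    water = a - b/4 - c/2 + 3d/4 + e/2
    ch4   = a/2 + b/8 - c/4 - 3d/8 - e/4
    co2   = a/2 - b/8 + c/4 + 3d/8 + e/4
    nh3   = d,  h2s = e

A negative CH4 coefficient means the composition is too oxidized to yield
methane and is a hard error. Atom conservation holds to machine precision
and is enforced by test against an element-counting oracle.
`bmp_buswell` uses the equivalent per-gram mass-fraction form
(C/24 + H/8 - O/64 - 3N/112 - S/128 mol CH4 per g TS) and the two routes are
verified against each other property-based.

**ThOD.** Oxidation basis C -> CO2, H -> H2O with nitrogen leaving as NH3
(consuming hydrogen, hence the -3N/56 term) and **sulfur not oxidized**.
Including sulfur oxidation shifts rounded values for S-bearing manures; the
sulfur-free basis is the convention that reproduces published manure ThOD
tables and is applied uniformly.

**Constants.** `BMPConstants` holds the molar volume (22,400 mL/mol at STP),
the COD-methane equivalence (350 mL CH4 per g O2), the methane energy
density (37.78 MJ/m3) and the Dulong coefficients
(337, 1419, 93, 23.26 kJ/kg per mass-percent). All are overridable via
configuration and every characterization output carries a provenance column
naming the constants used.

**Reporting bases.** Per-gram quantities are computed per g TS and divided
by VS/TS to express them per g VS. The Dulong-route BMP is the exception:
it is HHV (MJ per tonne TS) divided by the methane energy density with no
VS correction, because that is the arithmetic under which published manure
tables are internally consistent; the basis ambiguity (the column is
labelled per-VS) is deliberate and documented here rather than "fixed".

**Mixtures.** The additive mixture model is the VS-share-weighted mean of
component BMPs; the synergy index is observed/expected with values above 1
flagging synergy. Shares must sum to 1 (deviations up to 1e-6 are
renormalized with a warning).

## Functional prediction

The prediction stage is the standard copy-number-corrected linear model:
divide each OTU's abundance by its 16S copy number, then multiply by the
reference genome's KO copy counts. OTUs absent from the reference are
dropped with a logged estimate of the discarded abundance fraction (a
hard-fail mode exists). No nearest-sequenced-taxon index is computed — the
pipeline consumes a gene-content reference as input and never touches a
reference phylogeny.

Pathway aggregation sums member-KO abundances at hierarchy level 2 or 3. A
KO mapped to several pathways contributes fully to each (the KEGG
convention), so pathway totals can exceed KO totals; mass-conservation
tests therefore use single-mapped fixtures. Unmapped KOs are collected
under `Unclassified`. Tables are dense DataFrames; at the intended scale
(up to a few thousand features) sparsity buys nothing.

## Differential screening

`lefse_screen` normalizes samples to one million, tests each feature with a
tie-corrected Kruskal–Wallis (midranks; the statistic divided by
1 - Σ(t³-t)/(N³-N)), and computes a **deterministic effect score**:
log10 of the largest pairwise difference of class means on the per-million
scale, zero when that difference is under one per-million unit. This is an
explicit surrogate for the LEfSe tool's bootstrapped LDA score — it tracks
the same quantity (the magnitude of the between-class abundance shift on a
log10 scale) while being reproducible — and it keeps the conventional
thresholds meaningful: significant ⇔ p < 0.05 and score >= 2.0. The
bootstrap schedule and subclass Wilcoxon step of the original tool are
intentionally not replicated.

**Exact small-sample p-values.** For N <= 12 samples the Kruskal–Wallis
p-value is the exact tail P(H >= H_obs) over all distinct assignments of
the observed values to the class groups (e.g. 9!/(3!3!3!) = 1680 for the
3x3 design), because the chi-square approximation is poor there. Fully
separated groups of 3 attain p = 6/1680 ≈ 0.0036. Larger designs use the
chi-square tail with g-1 degrees of freedom; a Monte-Carlo permutation
variant serves as an independent check (median |Δp| < 0.01 at 10
samples/class). Enumeration is guarded at 500,000 assignments, beyond which
the chi-square tail is used.

Two structural facts about the 3-classes-of-3 design matter for
interpreting screen output and for fixture design:

* The exact p-distribution is discrete; `p < 0.05` corresponds to the
  49/1680 ≈ 2.9% tail. That is an **irreducible per-feature false-positive
  rate** for continuous exchangeable data — no noise scale changes a rank
  test.
* A feature enriched in *one* class while the other two classes are
  statistically identical cannot be reliably detected: the two null groups
  interleave at random and only 8 of their 20 rank arrangements push H past
  the 0.05 threshold. Reliable detection requires all three classes to
  separate, which is also what real multi-host communities show.

**Welch two-group comparisons** are computed on mean percentage proportions
with the Welch–Satterthwaite degrees of freedom, two-sided p-values, and a
95% confidence interval for the difference. Zero-variance degeneracies are
explicit: equal means give p = 1; unequal means give p = 0 with a
`degenerate` flag. No multiplicity correction is applied by default (the
convention for extended error-bar displays); Benjamini–Hochberg is
available and affects only the significance flag, not the reported raw p.

## Co-digestion advisor

The advisor is configuration, not inference, and says so in its output.
Significant screen hits are matched (case- and whitespace-insensitively,
never fuzzily) against a packaged pathway annotation tagging hydrolysis,
acidogenesis/acetogenesis and growth-support pathways; unmatched names are
reported, and the packaged list is deliberately partial and user-editable.
Emphasis weights are

    w_i ∝ BMP_i x (1 + tally_i / max(1, Σ tallies)),  Σ w_i = 1

chosen for two properties verified by tests: scale invariance in the BMPs
and monotonicity (raising a substrate's BMP or tally never lowers its
weight). A genus-role table supports role-coverage summaries and pathogen
alerts for genera with non-zero class means.

## Synthetic data

The generator exists so every stage has ground truth.

**Ultimate analyses** are drawn per field from normals truncated at zero
(honoring the mean/SD reporting convention directly; a lognormal would
decouple the printed parameters from the draw), with whole replicates
rejected while the elemental sum exceeds 100% of TS. Note the rejection
step selects against high-C draws, so for wide SDs the realized mean sits
slightly below the configured mean; tests account for this.

**Count tables** are Dirichlet-multinomial. A base composition is drawn
from a symmetric Dirichlet (or supplied explicitly for prescribed
fixtures); planted effects modify class base compositions on the
*proportion* scale (additive ppm shift or fold change, then
renormalization), so the truth is well defined at any sequencing depth;
each sample's composition is Dirichlet with parameter
`concentration x n_features x class_base` and counts are multinomial at the
configured depth. The concentration is therefore per-feature: a uniform
base with the default of 50 is a symmetric Dirichlet(50). With nothing
planted, classes are exchangeable by construction — the generator is its
own null. Depth can be exact (dispersion 0) or gamma-distributed with a
configured coefficient of variation.

**What the fixture emulates and what it does not.** The bundled
`make_reference_fixture` mirrors a 3-manure x 3-replicate design: reference
substrate compositions, a 12-pathway synthetic functional profile with four
target pathways (fructose and mannose; amino acid and nucleotide sugar;
phosphotransferase system; starch and sucrose metabolism) planted as a
three-level gradient — horse +10,000 ppm, pig +5,000 ppm, cow at base — and
matched OTU/gene-content/hierarchy inputs for end-to-end runs. The tiered
gradient is required by the rank-test structure above (one-class-only
enrichment is undetectable at 3 replicates) and matches the biology (all
three host communities differ, horse most enriched). The four target
pathways sit at low base abundance (0.2%) so the planted shifts dominate
them while the displaced mass (the compositional side effect of planting)
stays below replicate noise elsewhere; the pathway-level concentration of
450 encodes that aggregated functional profiles vary far less across
replicates than OTU tables. Calibration over 500 seeded tables: the four
planted pathways are recovered and assigned to horse in ~100% of tables;
the distribution of the total significant count is {4: ~53%, 5: ~36%,
6+: ~11%}. The extras are exactly the irreducible exact-test tail plus
compositional displacement, so "exactly four significant" is the modal
outcome, not a per-table guarantee — tests and the acceptance script assert
the modal count and per-table planted recovery, never per-table exact
counts. The generator does not emulate read-level errors, chimeras,
contamination, uneven library construction, or the heavy-tailed abundance
distributions of real OTU tables; passing tests demonstrate correctness of
the pipeline's arithmetic and calibration of its statistics under the
stated model, not field performance.

## Numerical and interface choices

* Tables are UTF-8 TSV in the classic orientation (features as rows,
  samples as columns), tolerating `#` comment blocks, a `#OTU ID` header
  cell and a trailing taxonomy column. Ragged rows fail with a line number.
* Feature ordering in screen output: effect descending, ties broken
  lexicographically by feature id, for byte-reproducible results.
* Pipeline runs write a manifest (SHA-256 of every input and output,
  constants, thresholds, seed, package version); identical configurations
  yield identical manifests.
* Exit codes: 0 success, 1 validation/parse error, 2 runtime failure.
* All randomness flows through `numpy.random.default_rng` seeded from
  configuration; fixed seeds give byte-identical outputs.

## Problem sizes used in tests and the acceptance script

Stoichiometry is verified on 1,000 random formulas; prediction against a
triple-loop oracle on 3x5x7 instances; the screen's planted-truth behavior
on 12-feature pathway tables over 12-150 seeds and its null false-positive
rate over 200 seeded 40-feature tables (8,000 feature-tests); the
chi-square/permutation agreement at 10 samples/class with 4,000 resamples.
These sizes give stable estimates (binomial standard errors below 0.3
percentage points for the false-positive rate) while keeping the full suite
and the acceptance script fast on a single CPU.

## Known limitations

* The effect score is a surrogate: it reproduces LEfSe's thresholds'
  *semantics*, not its numeric scores; rankings may differ from the Galaxy
  tool on the same data.
* The Dulong-route BMP inherits the TS/VS basis ambiguity described above.
* The advisor's weight rule is a transparent heuristic; it does not predict
  synergy magnitude and is not fitted to digestion outcomes.
* The packaged pathway and genus annotations are curated starting points,
  not exhaustive references.
* Laboratory BMP assay values are outside scope; the three models here are
  theoretical ceilings and are known to sit above or below assay results
  depending on substrate recalcitrance.
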