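# Methods

This note documents the statistical model behind `latentdoublet`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the procedure was
genuinely open.

## Problem and model

A *same-gene double mutation* (doublet) is a pair of somatic mutations at two
different protein positions of one gene observed in the same tumor.  The
package's premise is that individually weak ("latent") driver mutations can
combine, in cis, into a driver-strength oncogenic signal, so doublets that
co-occur more often than chance are candidate latent-driver pairs.

Mutations are identified by (gene, protein position) only: two tumors
mutated at the same residue count as carrying "the same" mutation even if the
mutant amino acids differ.  For a candidate pair the cohort is cross-
classified into a 2×2 table — a tumors carry both positions, b and c exactly
one, d = N − (a+b+c) neither, where N is the number of tumors with at least
one retained mutation.  Association is assessed with the two-sided Fisher
exact test (minimum-likelihood two-sidedness, the convention of standard
exact-test implementations) and corrected with Benjamini–Hochberg across the
*entire* candidate family of a run — all enumerated same-gene pairs, not only
those observed together and not per-gene.  Both choices are configurable in
`test_candidates` (`alternative=`, or post-hoc filtering), but the defaults
reflect that the discovery family is defined before seeing any table.

The odds ratio ad/bc classifies surviving doublets as co-occurring
(log₂ OR > 0) or mutually exclusive.  When b or c is zero the
Haldane–Anscombe 0.5 correction is added to every cell and the doublet is
flagged `or_corrected`; the correction affects only the reported OR, never
the p-value.

## Filters

Statistical significance is necessary but not sufficient; three per-carrier
plausibility filters follow.

* **Double nonsense.**  Two truncating mutations in one protein cannot
  cooperate; a doublet is removed when both components are nonsense in at
  least half of its carrier tumors.
* **Nonsense upstream.**  If the N-terminal component of a pair is nonsense,
  the downstream component sits on a degraded/truncated transcript — it is a
  passenger or on the other allele.  Removed when the configuration holds in
  at least half of the carriers.
* **VAF overlap.**  If VAF_i + VAF_j > 0.5 then (at ~2×VAF cell fraction per
  mutation) the implied fractions exceed 100% of the sequenced cells, which
  is impossible unless the two mutations share cells.  A doublet is retained
  when this overlap holds in at least 20% of its carrier records.  Raw VAF
  sums are used directly, not diploid-converted fractions.

Both nonsense filters use the same per-carrier ≥50% rule
(`carrier_fraction`, configurable).  An all-carrier variant can be obtained
with `carrier_fraction=1.0`; the default majority rule is the less aggressive
reading and is recorded here as a deliberate choice.  Filters only shrink
their input and the chain is idempotent; `prevalence_filter` finally splits
the surviving set into all significant doublets and those carried by ≥3
tumors (the set all downstream analyses use).

## Driver and latent labels

For each gene carrying a doublet, the *gene-mutant group* is the union of
carriers of the gene's positions that are themselves present in ≥3 tumors.
A component found in the driver catalog (matched by gene + position to stay
consistent with the position-collapsed mutation identity; exact-change
matching is available) is a known driver D, otherwise a potential latent
driver d.  Strength thresholds are strict: a driver is strong when its
frequency in the gene-mutant group exceeds 10%, a latent driver when it
exceeds 1%.  Doublets are DD/Dd/dd by the unordered label pair.

Chemical-class switches for missense changes use a three-class partition of
the 20 residues — Charged {D,E,K,R,H}, Polar {S,T,N,Q,C,Y}, Hydrophobic
{A,V,L,I,M,F,W,P,G} — passed as a swappable table, since class membership
conventions vary at the margins (H, C, G).  Cis/trans status is never phased
from reads; externally supplied per-carrier calls are reduced by majority
vote, ties → inconclusive, no calls → unknown.

## Hyper-mutation and the burden test

Per-sample counts of retained non-synonymous mutations define the burden
profile.  A sample is hyper-mutated when its count strictly exceeds
Q3 + 8×IQR; quartiles use linear interpolation of order statistics at
probability positions p·(n−1) (the numpy default).  Counts are taken after
the VAF filter; this is a documented choice, as is the `any_carrier`
exclusion mode (one hyper-mutated carrier suffices to drop a doublet).

The permutation burden test compares double-mutant tumors against the
remaining gene-mutant tumors on total non-synonymous counts with the
statistic T = μ(Double) − μ(Single).  Labels are shuffled B = 5000 times and
p = N_exceed/B where N_exceed counts permuted statistics *strictly greater*
than observed.  No add-one correction is applied, so p can be exactly 0; the
(N+1)/(B+1) alternative is reported alongside.  The null "Double burden ≤
Single burden" is rejected at p < 0.01.

## SBS96 contexts

Substitution contexts are 5′[ref>alt]3′ triplets.  Canonical form centers on
the pyrimidine strand: a purine-centered observation is reverse-complemented
(flanks swap and complement, ref and alt complement), giving 6 substitution
types × 16 flank combinations = 96 classes; the 192 raw labels quotient
exactly 2-to-1 onto them.  Two contexts are "the same" iff their canonical
forms coincide.  Contexts are consumed from an input column (real cohorts
would derive them from a reference genome, which is deliberately outside the
core); only missense components enter the summary.

## Preclinical comparison

Drug-response z-scores are called sensitive (z < −2), resistant (z > 2), or
gray (|z| ≤ 2, boundary inclusive); more negative means more sensitive —
the sign convention is configurable.  Scheme 1 selects a drug when *all*
single-mutant counterpart lines are gray and the double-mutant line is
significant, or when any single-mutant significant call flips sign in the
double-mutant line (any-line flip; the aggregation across multiple
counterpart lines was an open choice and is documented here).  Scheme 2
selects on significance in either side.  Selections, harbored mutations and
drug targets assemble into a typed networkx graph serialised as an edge list.

PDX tumor-volume curves are aligned to a 5-day grid by linear interpolation
between the nearest bracketing observations,
Vol_i = Vol_{i−1} + (t_i − t_{i−1})/(t_{i+1} − t_{i−1})·(Vol_{i+1} − Vol_{i−1}),
with on-grid observations passing through unchanged and no extrapolation.
Growth comparison is descriptive (volume deltas); no significance test is
attached.

## Synthetic cohorts

`generate_cohort` emulates the features of a pan-cancer cohort that this
pipeline is sensitive to:

* **Burden** — per-sample background mutation counts are negative-binomial
  (mean `background_rate` = 3 mutations/sample by default, dispersion 1.0 —
  i.e. geometric-tailed, matching the heavy-tailed burden of real cohorts);
  a `hyper_fraction` of samples has its mean multiplied by `hyper_multiplier`
  (default 10×).
* **VAF** — Beta(2,2) by default, so only ~4% of raw VAFs fall at or below
  the 0.125 filter; shapes are configurable to stress the filter.
* **Classes** — missense 0.80 / nonsense 0.12 / frameshift 0.08, roughly the
  non-synonymous class mix of exome cohorts.
* **Contexts** — uniform over the 96 canonical labels; a planted doublet can
  force one shared context on both components (context-biased mode for
  testing the SBS module).
* **Planted doublets** — joint and marginal carrier counts are hit *exactly*
  in the emitted records: background mutations never land on planted
  positions, and carrier sets are drawn without replacement.  The default
  planted condition used in validation is joint 30 with marginals 40/40 in
  2,000 samples.

What the generator does **not** emulate: mutational hotspot structure within
genes (background positions are uniform), correlation between burden and
tissue, sequence-determined context frequencies, clonal evolution or
subclonal VAF structure, and panel-vs-exome coverage differences.  Passing
tests therefore demonstrate the correctness of the statistical machinery and
its behaviour under controlled association structure — not calibration
against any real cohort's idiosyncrasies.

## Numerical choices and degenerate inputs

* VAF threshold is a strict `>`; thresholds at 10%/1% (strength), 50%
  (carrier fractions), 20% (overlap records) are strict or inclusive exactly
  as stated in their docstrings (strength strict; carrier fractions and the
  20% rule inclusive, "at least").
* A sample with two mutant residues at one position contributes once to the
  position's carriers with the maximum of its VAFs (alleles at one site in
  one clone are alternatives, not additive).
* Quartiles need ≥4 samples; fewer raise an error.  Empty groups raise
  errors in labeling and in the permutation test; an unknown gene yields an
  empty gene-mutant group with a warning.
* Patient deduplication breaks within-tier ties by lexicographically
  smallest barcode, for determinism.
* Monte-Carlo permutations vectorise B label shuffles via argsort of uniform
  randoms (exactly uniform over permutations); all randomness flows through
  `numpy.random.default_rng(seed)`.

## Validation problem sizes

The validation suite exercises: exhaustive Fisher-vs-enumeration agreement
over all 2×2 tables with N ≤ 16 plus a seeded random sample up to N = 60;
BH against the literal min-over-tail formula on vectors up to length 10⁴;
Monte-Carlo permutation p against exhaustive enumeration for groups of total
size ≤ 8; recovery power over 20 seeded cohorts of 2,000 samples and false-
discovery behaviour over 25 null cohorts of 1,000 samples.  These sizes were
chosen so the full suite runs comfortably on a laptop while keeping every
check statistically meaningful.

## Known limitations

* Cohort-scale counts from large consortium datasets are not reproducible at
  desk scale; on synthetic cohorts the pipeline reports its own audit counts.
* Catalog matching by position will mark a non-oncogenic change at a driver
  position as a known driver; use `exact`-change matching when the catalog
  provides full protein changes.
* The VAF-overlap filter assumes bulk sequencing of a single tumor sample;
  multi-region or liquid biopsies violate its premise.
* Cis/trans assignment relies entirely on external phasing information.
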