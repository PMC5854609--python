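# Methods

This note records the models, rules and numerical choices behind each
pipeline stage, the assumptions they rest on, and what the synthetic cohort
does and does not emulate.

## Candidate enumeration and the binding filter

Mutations enter at protein level with 1-based coordinates, matching labels
like `HHAT_L75F`; how a transcript isoform was chosen is outside the
package — one protein sequence per mutation is the caller's contract.
For a mutation at position *p* in a protein of length *N*, the enumerator
returns, per peptide length *L* ∈ {9, 10} by default, every length-*L*
window fully inside the protein that covers *p*, with the altered residue
substituted; the wild-type counterpart is the same window unsubstituted.
Windows truncated by a protein end are dropped, not padded — fixed-length
peptide predictors have no notion of a padded peptide, and a truncated
peptide is a different molecule. Windows containing `X` are excluded as
unsynthesizable and tallied. The window-count law
min(*p*, *L*, *N*−*p*+1, *N*−*L*+1) is property-tested against a
slide-every-window oracle.

The affinity filter keeps (peptide, allele) pairs with IC50 ≤ threshold
(inclusive at the default 500 nM — the bound is printed as "≤"), restricted
to the patient's own HLA-I alleles. Binding prediction itself is an input:
the package consumes an affinity table and never reimplements a predictor.
Because a cohort total can be read either as unique peptides or as
(peptide, allele) pairs, `predicted_load` reports both.

## ELISpot positivity

Positive ⇔ mean spots strictly greater than negative-control mean plus
`multiplier` (default 3) × SD of the negative control. Choices the rule
itself does not pin down:

* **Sample SD (n−1).** With triplicates the n−1 estimator is the
  conservative choice (larger SD, higher threshold).
* **Raw counts**, not background-subtracted ones, feed the rule.
* **sd = 0 negatives** degenerate the rule to mean > neg_mean; the strict
  inequality is kept, so an all-zero plate is never positive.
* PHA wells are a viability control: reported, excluded from calling.
* Conditions with fewer than two replicates get a call with a warning flag
  rather than an error, since screening plates are often imperfect.

## ICS polyfunctionality

Per-cell IFNγ/TNFα/IL-2 positivity tables from the stimulated and
unstimulated wells are decomposed over the 7 non-empty cytokine
combinations: unstimulated fraction subtracted from stimulated per
combination, negatives floored at zero, then renormalized over the 7. The
floor-then-renormalize order is a deliberate choice where background
handling was genuinely open; it guarantees a proper composition (sums to 1)
whenever anything survives subtraction, and an empty flag otherwise.

## Functional avidity (EC50)

The dose–response model is a four-parameter log-logistic on log10
concentration: r(x) = lower + (upper − lower) / (1 + 10^((logEC50 − x)·h)).
Fitting is a coarse grid over logEC50 (25 points spanning the dose range
±1 log) × Hill slope {0.3, 0.5, 1, 2, 4}, refined by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective). Responses are
normalized by the fitted upper asymptote, not the maximum observation, so a
single high outlier cannot set the scale. Series need ≥ 4 distinct
concentrations; a response range under 20% of the maximum flags the
estimate unreliable without fitting; an EC50 outside the spanned doses is
flagged extrapolated. The bootstrap CI resamples residuals (1,000 draws by
default, percentile method, seeded). Concentration units are opaque tags —
no µg/mL↔molar conversion is attempted because peptide masses are not part
of the data model; avidity comparisons are valid only within a unit system.
Group comparisons run on log10(EC50) with a two-tailed t-test, falling back
to Mann–Whitney when a Shapiro pre-check rejects normality at 0.05.

## Specific lysis

100 × (experimental − spontaneous) / (total − spontaneous), defined only
for total > spontaneous. Values outside [0, 100] occur with noisy release
counts and are returned flagged rather than clipped.

## TCR clonotypes

Reads are translated in reading frame 1 — amplicons are primer-anchored, so
a frame search is unnecessary; a 3-frame rescue flag exists for unanchored
input. Out-of-frame means length not divisible by 3 or a stop codon
anywhere in the translation; reads with non-ACGT characters are tallied
separately. Clonotype identity is (chain, full translated protein
sequence); V/J names are annotations (majority read vote within a pool),
never identity. The read floor (default 2) applies **after** pooling — the
stricter reading of the single-read exclusion rule, and the natural one
since pooling precedes abundance determination. Frequencies are computed
over retained reads. Ordering is descending count, then lexicographic
protein sequence, so outputs are deterministic. Read conservation
(retained + out-of-frame + invalid + sub-floor = input) is enforced by an
internal check and property-tested.

Tracking reports presence, frequency and dense rank of each specific
clonotype per bulk compartment. An absent clonotype is "excused" as
below-LOD only when the repertoire is too shallow for the configured LOD
fraction (1/total reads > lod_fraction); in a sufficiently deep repertoire
an absence stands as a real discordance. The default LOD fraction is 1e-5
(10 cells per million, 0.001%).

## Cohort statistics

A validated response = ELISpot positivity in ≥ 1 compartment **plus** ≥ 1
orthogonal assay (multimer/ICS); an ELISpot-only mode exists for
exploratory runs. Prevalence denominators come from the per-compartment
evaluation roster, never from the response list, because compartments are
evaluated in different patient subsets. Fisher's exact p-value is computed
from the conditional hypergeometric pmf with the point-probability
two-sided convention (sum of table probabilities ≤ observed, with a 1e-7
relative tie slack — the convention exact-test software uses for
floating-point ties); it is cross-checked in the tests against both a
log-factorial full enumeration and an independent library implementation.
The odds ratio is the conditional MLE. The load association is OLS with the
slope t-test, plus a seeded permutation p-value as a distribution-free
companion.

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes, at
desk scale:

* **Cohort**: 19 patients, mutation counts uniform on [10, 129] (a
  discretized lognormal with median ~69 is available — only the median and
  range of real cohorts are constrained, not the distribution), random
  proteins of 150–500 residues, 6 HLA alleles per patient from a pool of 12.
* **Toy affinity model**: per-(allele, length) position-specific residue
  scores; log-IC50 ~ Normal(log 12 µM, 1.22²), fixed once per seed and
  fully deterministic. The parameters were set analytically so that ~0.5%
  of (peptide, allele) pairs — a few percent of peptides across six
  alleles — pass 500 nM, reproducing the real-world proportion of a few
  hundred binders from ~20,000 candidate windows. It is an arbitrary
  scoring scheme with no binding biology; it exists to give the filter
  deterministic inputs.
* **ELISpot**: negative-binomial wells (mean 3, dispersion 5) — spot counts
  are overdispersed relative to Poisson; planted responders are shifted by
  +60 spots. Planted responses (6 PBL-responder patients of 19, 4 TIL of a
  14-patient tumor roster, 1–3 epitopes each, exactly one response shared
  between compartments) also receive orthogonal validations, ICS tables,
  one titration with a log-uniform EC50 in [1e-4, 1] µg/mL (9 ten-fold
  dilutions from 30 µg/mL, 10% multiplicative noise) and one killing triple
  with an exactly planted lysis fraction.
* **Repertoires**: three compartments (PBL, tumor, TIL) at 1e5 reads — a
  desk-scale stand-in for the 1e6–3e6 reads of deep repertoire sequencing;
  LOD-related checks scale with the configured depth. Background
  clonotypes follow a Zipf-like abundance profile, permuted per
  compartment; spikes plant the two discordance scenarios (tumor+TIL
  without blood; blood+tumor without expanded TIL), one ubiquitous clone,
  and a frequency ladder spanning 1e-6–1e-2 around the LOD. Synonymous
  nucleotide variants (rate 0.3), out-of-frame reads (5%) and single-read
  clonotypes (20 per compartment) are injected to exercise the
  corresponding filters.

What the generator does **not** emulate: real HLA-binding biology, antigen
processing, sequencing error profiles, UMI structure, V/J germline
alignment, or clonal lineage structure. Passing tests therefore demonstrate
that the pipeline's rules are implemented exactly and that planted signals
of realistic magnitude are recovered — not that the toy affinities or
repertoires are biologically faithful.

## Problem sizes and determinism

The default test and acceptance runs use the 19-patient cohort
(~1,000–1,300 mutations, ~20,000 candidate windows, ~150,000 scored
peptide–allele pairs) and 1e5-read repertoires; these sizes keep a full run
in seconds while preserving every statistical feature the checks rely on.
All randomness derives from one seed via independent seed sequences per
stage, so every output is reproducible byte for byte; no generator
parameter is tied to wall-clock time.

## Known limitations

* Class-II (CD4) epitopes and peptide lengths outside 8–11 are out of scope.
* The ELISpot rule assumes a shared negative control per plate group; plate
  effects and counting saturation are not modeled.
* EC50 estimates from 9-point single-replicate titrations carry ~10–30%
  relative error at 10% response noise; the bootstrap CI, not the point
  estimate, should be quoted near that regime.
* Clonotype frequencies are relative to retained (in-frame, ≥2-read)
  reads; comparisons to pipelines that divide by all reads need rescaling.
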