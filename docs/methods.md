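# Methods

`contambench` is a simulation-based benchmark for the two practical
problems of low-input (sub-nanogram) shotgun metagenomics: how much a
library-preparation kit distorts and contaminates the measured community,
and how well in silico decontamination recovers the true signal. Because
the ground truth of real sequencing data is unknowable, the benchmark
replaces it with a synthetic spike-in community whose composition is exact
by construction, and simulates everything downstream of taxonomic
classification at the count level.

## The mock community

The community mirrors a sequins-style synthetic standard: `n = 83`
artificial components assigned to 8 concentration tiers on a twofold molar
ladder (128-fold molar range), at least five components per tier, GC
contents drawn uniformly on [0.294, 0.7106] and lengths on [1929, 9120] bp.
Because shotgun reads sample bases rather than molecules, the expected read
share of a component is its *mass* fraction, proportional to
`molar_level x length_bp` and renormalized. A design is fully determined by
`(n_components, n_tiers, seed)` and validated against all structural
invariants on construction.

## The count simulator

One library is parameterized by kit, input mass (0.5–5000 pg; 0 pg is a
negative control), replicate, sequencing depth, and a seed derived from
`(master_seed, library_id)` via a 32-bit BLAKE2 hash, so libraries are
independently reproducible and no global RNG state exists.

Mass model, per library:

* **Designated (sequins) block** — total mass equals the input mass.
  Within the block, component weights are
  `mass_fraction x exp(b_gc (GC - 0.5) + b_len L_kb)`, with extra WGA
  coefficients added for amplified libraries (defaults: weak positive
  length bias `b_len = 0.05`/kb, low-GC preference `b_gc = -0.8`; WGA adds
  `+0.3`/kb and `-3.0`). Only directions are known from low-input
  experiments; magnitudes are configurable defaults.
* **Kit contaminants** — a kit-specific reagent pool. Total load is drawn
  from a median-preserving lognormal with medians
  {Son_Q 15.59, Son_N 2.32, End_N 0.05, End_Q 0.04, Tn5_V 0.01} pg and
  natural-log dispersion sigma = 1.0 (the dispersion across libraries is
  not documented anywhere; 1.0 makes a Son_Q-like kit span roughly 6–42 pg
  at the 16th–84th percentiles, i.e. heavy and highly variable at
  sub-nanogram inputs). The pool's genus composition is kit-specific
  (per-kit abundance centres, spread sigma = 1.5) with per-library
  variation (sigma = 0.6); a 30-genus core set is shared by all kits and a
  small number of genera are unique per kit.
* **Endogenous contaminants** — five genera residing in the template
  itself, with total mass a fixed fraction (default 0.001) of the input
  mass, so their contaminant-normalized abundance rises with input.

Counts are drawn **once** from a single multinomial over all taxa at the
configured depth. The designated/contaminant split is therefore exactly
mass-proportional in expectation, and GC/length bias only redistributes
reads within the designated block — which makes the spike-in mass
estimator (below) unbiased by construction rather than by accident.

Library complexity is modelled by resampling reads from a finite molecule
pool `M = total_mass x molecules_per_pg(mean length) x kit_recovery`, with
recovery factors ordered endonuclease > tagmentation > sonication. The
duplication rate is `1 - unique molecules / reads`, which reproduces the
qualitative input- and kit-dependence of library complexity without
fragment-level simulation. The pool uses the *total* DNA mass (input plus
contaminant) rather than input alone so that negative controls do not
degenerate to a single molecule. No read sequences are generated;
FASTQ-level simulation, alignment and classification are out of scope.

## Metrics

* **Total sum scaling** converts counts to relative abundances, optionally
  restricted to a provenance label.
* **Jensen-Shannon distance (JSD)** is the square root of the
  Jensen-Shannon divergence with base-2 logarithms (`0 log 0 := 0`, union
  support), so both divergence and distance lie in [0, 1] with 0 for
  identical profiles. Base 2 is the only base for which the stated [0, 1]
  range holds.
* **Fidelity** = 1 − JSD(measured, expected); two variants are exposed,
  against the full measured profile and against the designated-only
  profile. **Reproducibility** = 1 − JSD between replicates.
* **Conversion rate** = `Q_library x R_designated / (Q_input x 2^N_pcr)`,
  the fraction of input effectively converted to designated library at
  100% primer efficiency.
* **Abundance bias** is the per-component measured/reference abundance
  ratio; components with zero reference are skipped, never infinite. The
  length-bias regression fits OLS of the raw ratio on fragment length
  (matching a linear fit of ratios); a log-ratio option exists because the
  choice is not canonical.
* **Rarefaction** subsamples without replacement (multivariate
  hypergeometric), so zero taxa stay zero and counts never exceed their
  originals.

## Contaminant quantification and characterization

Because reads sample mass identically for designated and contaminating
DNA, absolute contaminant mass is `input x contaminant_reads /
designated_reads` — no length or GC correction, consistent with the
sampling model. Negative controls have no designated reads and are not
quantifiable by this route.

The endogenous screen regresses each genus's contaminant-normalized
abundance on log10 input (the dilution ladder is geometric; a raw-input
switch is provided), BH-corrects p-values within kit, and flags genera
with positive slope, adjusted p < 0.05 and R² > 0.55 in at least 4 kits.
All thresholds are arguments. Flagged genera are removed before all
downstream contamination analyses. Under the default five-kit conditions
the two heavy sonication-like kits often mask the endogenous trend with
load noise, so the default ≥4-kit rule is conservative; the screen's
sensitivity can be tuned via `min_kits`.

Core contaminants are genera whose contaminant-normalized abundance
exceeds 0.1% in at least half of a kit's libraries (dominant: 1%); shared
and kit-unique sets are plain set algebra over the per-kit cores. The
remaining-contaminant curve reports, for each abundance threshold, the
fraction of contaminating reads carried by taxa at or above that
threshold; thresholds compare against whole-library relative abundance by
default (contaminant-normalized as an option).

## Decontamination methods

* **Fold-over-NC**: the NC reference is the arithmetic mean relative
  abundance per taxon over ≥2 negative controls (absent = 0). A taxon is a
  true component iff its abundance is strictly greater than 5x (or 10x)
  its reference; exact ties and zero-abundance taxa are contaminants, and
  taxa absent from every NC are vacuously above threshold whenever present.
* **Frequency score**: on `x = ln input`, `y = ln frequency` over the
  positive samples where the taxon is present (≥3 required, else
  undefined), the contaminant model `y = -x + b` (slope fixed at −1,
  intercept by least squares) is compared with the constant model; the
  score is the CDF of an F(n−1, n−1) distribution at the SSR ratio. A
  perfectly inverse-scaling taxon scores 0, a constant one scores 1, and
  the score is invariant to rescaling all frequencies.
* **Prevalence score**: the one-sided hypergeometric tail probability of
  an NC presence count at least as extreme as observed in the 2x2
  presence table (presence = count > 0, with a configurable floor).
* **Classification**: contaminant iff score < threshold (strict, matching
  the sweep semantics), in frequency, prevalence, or either mode.
  Undefined scores never trigger a call; taxa never seen in a positive
  sample are called contaminants by convention (they carry no signal
  reads, so the convention cannot affect read-weighted metrics).

The score construction follows the published description of the
frequency/prevalence approach; only modes and thresholds are fixed by
convention elsewhere, so the internals above are this package's documented
choice and make results reproducible without any external implementation.

## Evaluation

Performance is read-weighted: TP = contaminating reads whose taxon is
called contaminant, FN = contaminating reads missed, TN = designated reads
kept, FP = designated reads removed; counts always conserve the library
depth. Precision and recall are reported as missing when undefined, never
coerced.

Threshold optimization sweeps 40 evenly spaced thresholds on [0.1, 0.5]
and selects the best recall among thresholds with zero false-positive
reads, ties toward the larger threshold. If full precision is unattainable
the best-precision-then-recall threshold is returned and flagged — an
explicitly marked extension, since the selection rule presumes full
precision is reachable. Grid points producing no contaminant call have
undefined precision and are treated as zero-FP candidates with zero
recall; they cannot beat any real candidate.

The decontaminated-profile distance removes called taxa, renormalizes, and
takes the JSD to the measured designated-only composition; removing every
read yields the maximal distance 1 with a warning.

PERMANOVA is one-factor: `SS_total = (1/N) sum_{i<j} d²`, within-group
sums weighted by group size, pseudo-F on (a−1, N−a) degrees of freedom,
and a permutation p-value with the add-one convention (so p ≥ 1/(perms+1)).
For N ≤ 8 an exact mode enumerates all N! label orders. R² is clipped to
[0, 1] against floating-point underflow.

## Problem sizes and numerical choices

The default pipeline simulates 5 kits x 5 inputs x 2 replicates + 2 NCs
per kit at 1e5 reads per library — deep enough that the smallest design
component receives tens of reads and read-weighted metrics are stable,
while a full run completes in seconds. Parameter-recovery checks use 1e6
reads where sampling error must sit well below the 5% recovery band, and
the decontamination case studies use 2e5. Mass-fraction sums are validated
to 1e-9; JS divergence is clipped to [0, 1] before the square root;
permutation-test comparisons use a 1e-12 tolerance on F to make ties
deterministic.

## What the simulation does and does not show

The generator reproduces the *structure* of a dilution-series benchmark:
mass-proportional sampling, kit-specific contaminant pools with realistic
load medians, input-proportional endogenous contamination, GC/length bias
directions, and finite-library duplication. It does not model unclassified
reads, classification errors, well-to-well cross-contamination, fragment-
level coverage stochasticity, or taxa present in both the template and the
reagents. Consequently, passing results demonstrate correctness of the
metrics and the relative behaviour of decontamination strategies under
known truth — e.g. that either-mode filtering restores lightly
contaminated libraries (JSD < 0.05) but cannot rescue heavily and variably
contaminated ones even at ≥95% read removal — not absolute performance on
any particular real dataset. In real data the fold-over-NC methods in
particular will lose precision whenever genuine community members also
occur in reagents, a situation the synthetic community cannot produce.
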