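# Methods

This note documents the models, conventions and numerical choices behind
`barcodegap`, and what the synthetic-data tests do and do not establish
about real data.

## Haplotype filtering

The delimitation window is the first 640 aligned sites (configurable
start offset). A sample is excluded if the window contains a fully
ambiguous call (N) or fewer than 640 resolved sites; gap characters
count as resolved columns, and haplotypes differing only by gaps are
kept distinct (a conservative choice — alignment gaps in COI are rare
and usually real indels or artifacts worth seeing). Haplotype ids are
assigned in first-seen sample order, so a table is reproducible for a
given input order. The same 640-nt window is the default sequence
length L used in expansion dating; any other L can be passed
explicitly and is always reported.

## NUMT screening

Two independent signals, each sufficient to flag a haplotype:

* **Stop codons.** The degapped sequence is scanned in all three frame
  offsets under NCBI translation table 5 (invertebrate mitochondrial;
  stops TAA/TAG). The reported frame is the one minimizing the stop
  count (ties to the smallest offset) — a functional COI fragment has an
  open frame; a pseudogene typically has stops everywhere. Flag when
  the minimum count is ≥ 1.
* **Transversion excess.** Transitions (A↔G, C↔T) and transversions are
  counted over resolved differing sites against the majority-rule
  consensus of the haplotype's single-linkage cluster (p-distance,
  threshold 2.7%), excluding the haplotype itself. A singleton cluster
  is compared against the nearest cluster carrying at least as many
  samples as the query — a pseudogene is rare relative to the barcode
  cluster it derives from, and without this rule an abundant source
  haplotype can be compared against its own derived contaminants and
  flagged backwards. Flag when ts/tv < 0.5 over ≥ 10 differences.
  The thresholds are deliberately demanding: under a COI-like
  transition bias (κ ≈ 8) the probability that a clean haplotype shows
  a transversion majority over ten or more sites is negligible, while
  pseudogenes divergent enough to distort delimitation (several
  percent) show it clearly. Both knobs are configurable and reported.

## Distance models

p, JC69, K2P and TN93 use their closed forms; sites with a gap, N or a
partial-ambiguity code in either sequence are excluded pair by pair.
A logarithm argument ≤ 0 (saturation) makes the pair non-estimable:
reported as missing, never silently infinite, and treated as ≥ threshold
(conservative split) during clustering.

The constrained GTR+I distance maximizes the pair likelihood

L(t) = Π_sites [ p_inv·π_x·δ(x,y) + (1 − p_inv)·π_x·(e^{Qt})_{xy} ]

over the branch length t (bounded scalar optimization on [1e-9, 10],
tolerance 1e-8), with Q a reversible rate matrix from six
exchangeabilities under equality constraints, normalized to one expected
substitution per unit t, and reports (1 − p_inv)·t substitutions/site.
Defaults:

* **Constraint classes** follow the jModelTest six-letter convention;
  TIM3 ties AC=CG and AT=GT and leaves the two transition classes free
  ("012032"). The mapping lives in config, not code, so it can be
  swapped without touching the likelihood.
* **Exchangeabilities** are estimated once per dataset by a
  method-of-moments count of substitution types over all haplotype
  pairs, pooled within tying classes and normalized to GT = 1. Crude
  but deterministic; the pairwise ML distance is dominated by t, not by
  modest exchangeability error.
* **p_inv** is the observed proportion of constant columns. Joint
  pairwise optimization of p_inv and t is unidentifiable from a single
  pair, so it is fixed dataset-wide. A consequence worth knowing: at
  large divergences the +I correction stretches distances well beyond
  JC69 (variable-site divergence is corrected on the non-invariant
  fraction only), so histogram break positions under `tim3i` sit higher
  than the raw-percent intuition suggests.

## Barcode gap and clustering

Histogram bins are half-open [k·w, (k+1)·w) with w = 0.25%, counted over
the strict upper triangle. A break is a maximal run of ≥ 3 consecutive
empty bins with occupied bins on both sides, reported with edges and
midpoint. Three, not two: with a few dozen haplotypes the within-species
distance cloud is quantized at ~1/640 per substitution and single
missing difference classes open 2-bin holes (measured: species recovery
over 40 seeded complexes rises from 35/40 to 38/40 when ignoring them),
while a true barcode gap spans ≥ 8 bins under every condition simulated
here. Clustering is single linkage with strict `< t` ("cut-off"
semantics); labels are the lexicographically smallest member id, making
partitions input-order invariant. The automatic threshold is the first
break's midpoint.

## Neutrality statistics and nulls

Definitions: k by pairwise deletion; π = k/L; S over columns with ≥ 2
resolved states; a singleton is a non-majority state carried by one
sequence (ties at a column resolved alphabetically, so counts are
deterministic); HD = n(1 − Σp²)/(n−1). Tajima's D uses the standard
1989 coefficients; Fu & Li's D* and F* use the corrected variance
coefficients (Simonsen, Churchill & Aquadro 1995), as DnaSP does — the
originally printed ones contain misprints. Fu's F_S takes θ̂ = k and
computes S′ = P(K ≥ K_obs) under the Ewens sampling distribution with a
log-space unsigned-Stirling recursion (stable beyond n = 170 where
factorials overflow); K_obs = 1 gives S′ = 1 exactly and is reported
missing. R2 uses U_i = singletons carried by sequence i.

Null distributions are simulated: Hudson coalescent genealogies with
mutations either multinomial on branch lengths (fixed S) or Poisson
(θ/2 per lineage per mutational-time unit). p-values follow each test's
convention — left-tailed for F_S and R2, two-tailed (doubled smaller
tail) for D, D*, F* — using Lancaster's **mid-p** (ties half-weighted).
Mid-p matters: conditioned on fixed S, D* is a function of the integer
singleton count alone and falls on ≤ S+1 atoms; inclusive-tie counting
makes the two-tailed test badly conservative (type-I ≈ 2% at nominal
5%), while mid-p restores ≈ 5% for all five statistics.

The exact test of differentiation computes the total conditional
probability (fixed margins) of tables as likely or less likely than
observed — by complete enumeration up to 10⁶ tables, else by
margin-preserving Monte-Carlo with a (hits+1)/(reps+1) estimate. Its
p-values are discrete with large atoms; the meaningful null property is
conservative validity, not continuous uniformity. AMOVA decomposes
squared Tamura–Nei distances (Excoffier-style, one or two levels) with
permutation p-values; populations of n = 1 are excluded with a warning,
and an all-identical dataset reports zero components with p = 1.
Population pooling (same putative species, pairwise exact-test p ≥ 0.05,
n ≥ 7) is an explicit, logged step.

## Mismatch model and dating

The sudden-expansion expectation is evaluated in exact incomplete-gamma
closed form from the pairwise coalescence-time density under the
two-epoch demography (hazard 1/θ₁ until τ, then 1/θ₀, Poisson(x)
differences). This equals the classical series expectation but is
stable for extreme parameters; it reduces to the stationary geometric
θ^i/(1+θ)^{i+1} at θ₀ = θ₁ and to the Poisson pulse e^{−τ}τ^i/i! as
θ₀ → 0, θ₁ → ∞ (both verified to ≤ 1e-5). For z = bτ beyond the range
of scipy's `gammaincc`, an asymptotic series supplies log Q(a, z).

The spatial-expansion expectation is an infinite-island "escape" model:
a sampled pair coalesces within its deme at rate 1/θ or separates at
pair rate M/θ until τ, after which all lineages coalesce panmictically
at rate 1/θ. It reduces to stationarity at M = 0 and has a matching
structured-coalescent simulator for the bootstrap. The published
analyses only exercise this model through its p-value, so it is flagged
experimental.

Fitting minimizes Σ(obs_rel − exp)² with L-BFGS-B from 8 seeded
Latin-hypercube starts; τ is bounded by twice the largest observed
difference class, θ₁ enters as 1/θ₁ ∈ (0, 2] so an effectively infinite
post-expansion size is reachable (θ₁ ≥ 10⁶ is reported as ∞), and
θ₀ > θ₁ is penalized. The parametric bootstrap resimulates n-sequence
coalescent samples under the fitted demography, refits each (3 starts),
and reports p_SSD and p_rg as the fraction of simulated statistics at
least as large as observed — large p means the expansion model is not
rejected. Known size behavior: on stationary data the false-rejection
rate of p_SSD at α = 0.05 is ≈ 10% for diverse samples (n = 40, θ = 8)
but rises toward 20% for small, low-diversity samples (n = 20, θ = 4),
where lumpy single-genealogy histograms get fitted by pseudo-expansion
curves whose bootstrap replicates are smoother.

Dating: u = (pairwise rate / 2)/10⁶ · L / (generations/year) per
sequence per generation; t_gen = τ/(2u); t_years = t_gen /
(generations/year). Defaults L = 640 (the delimitation window; the
published "abbreviated barcode" length is not stated, so L is always
echoed in the report), 13.5 generations/year, 6.5%/My pairwise.
τ = 6.74 with these defaults gives 162,019 ≈ 160,000 years BP.

A labeling ambiguity inherited from the source analyses: the population
table's τ column is described both as a mismatch expansion time and as
a "root age". This package always reports the mismatch-model τ.

## Synthetic-data generator

Time is in mutational units (pair coalescence rate 1/θ, mutation rate
1/2 per lineage-unit, so E[pairwise differences] = θ — verified against
msprime under the identical two-epoch demography). Sequences evolve
under a finite-site K2P kernel (default κ = 8) so distance corrections
and saturation are genuinely exercised; an infinite-sites mode (mutation
masks only) backs the statistic oracles. Root sequences are COI-like by
rejection: frame 0 open, frames 1–2 containing stops; mutations that
would create a frame-0 stop in a clean lineage are redrawn, mimicking
purifying selection and making the stop-codon screen informative.

Species ancestors are realized by UPGMA-decomposing the target
divergence matrix (triangle-inequality violations are rejected) and
mutating along each branch until the JC-corrected distance from the
parent reaches the branch target; realized tip-to-tip divergences land
within a few percent of target (multiple-hit non-additivity) and are
recorded in the truth record. Defaults emulate a cryptic complex
straddling an empirical barcode gap: K = 3 species, 10 samples each,
within-species θ = 3 (π ≈ 0.005 on 640 nt, inside the observed 0–0.011
range), between-species 5% and 12%. The expansion preset is one
population of 30 after a 100-fold stepwise expansion (τ = 5, θ₀ = 0.5,
θ₁ = 50). NUMT contaminants derive from the most abundant haplotype:
stop mode guarantees ≥ 1 stop in the best frame; transversion mode
plants ≥ 24 differences at ts/tv ≤ 1/6 (≈ 4% divergent, like real
borderline pseudogenes).

What the generator does **not** emulate: recombination, selection,
migration between species, heteroplasmy, sequencing error, alignment
error, and length variation among barcodes. Passing tests therefore
show the pipeline's logic is correct under the coalescent model it
assumes — not that real datasets satisfy those assumptions. Two
coalescent facts surfaced repeatedly in testing and are worth knowing
when interpreting real data: a single panmictic species occasionally
realizes a lineage deep enough (2–4%) to mimic a barcode gap, and the
genealogical dispersion of mean pairwise differences makes mismatch-τ
estimates intrinsically noisy (sd ≈ 1 at the expansion preset's
conditions), so per-population τ values should be read with wide
uncertainty.

## Problem sizes

Simulation-backed tests and the acceptance script use seeded, scaled
designs chosen to be statistically decisive for the property under
test: shared nulls of 6000–8000 replicates scored by 1500–2000 test
samples for calibration, 500 replicates for power signs, 100 fits for
τ recovery, 20 conditioned complexes for species recovery, and
parametric bootstraps of 40–500 where a p-value's granularity is all
that matters. The pipeline defaults mirror the published analysis
(16,000 null and bootstrap replicates); all counts are config-exposed.
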