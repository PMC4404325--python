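# barcodegap

DNA barcode-gap species delimitation and COI phylogeography, as a tested,
reusable Python pipeline. It is written for entomologists and molecular
ecologists working on cryptic species complexes — groups like the chilli
thrips *Scirtothrips dorsalis*, where a morphologically uniform "species"
hides multiple deeply divergent mitochondrial lineages — who need to go
from an aligned set of COI barcodes to putative species, per-population
diversity statistics, and dated demographic expansions, with every step
reproducible and testable against simulated ground truth.

## What it computes

**Haplotype filtering and collapsing.** Samples are retained when the
first 640 aligned sites are fully resolved (no N, no partial-ambiguity
codes); retained windows collapse to unique haplotypes with sample
multiplicities.

**NUMT screening.** Nuclear copies of mitochondrial genes masquerade as
barcodes. Haplotypes are flagged when no reading frame is free of stop
codons under the invertebrate mitochondrial code (translation table 5),
or when they show a transversion majority (ts/tv < 0.5 over ≥ 10
differences) against the majority-rule consensus of the most similar
established haplotype cluster — true COI evolution is strongly
transition-biased; pseudogenes are not.

**Model-corrected distances.** Pairwise distances under p, JC69, K2P,
TN93 closed forms, and a pairwise maximum-likelihood distance under a
constrained GTR+I model (default tying AC=CG and AT=GT with free
transitions — the TIM3 configuration — with empirical base frequencies
and the invariant-site proportion fixed at the constant-column fraction).

**Barcode gap and clustering.** All pairwise distances are binned at
0.25%; a "break" is a run of ≥ 3 consecutive empty bins flanked by
occupied ones. Haplotypes are clustered by single linkage below a
threshold (default: the first break's midpoint), giving the putative
species partition.

**Tree evaluation.** Putative species are checked for monophyly on a
support-annotated tree (unrooted bipartition semantics) with the
posterior clade probability of the defining edge; partitioning strategies
are compared with BF = 2(lnL₁ − lnL₀) + (P₁ − P₀)·ln(0.01), "at least
10" favoring the richer model; and putative species are merged when an
externally computed multispecies-coalescent speciation posterior falls
below a retention threshold (default 0.95).

**Population genetics.** Per population: n, segregating sites S,
singletons η_s, mean pairwise differences k, π = k/L, haplotype
diversity HD = n(1 − Σp²)/(n−1), Watterson's θ_W = S/a₁, Tajima's D,
Fu & Li's D\* and F\* (outgroup-free), Fu's F_S via the Ewens sampling
formula, and Ramos-Onsins & Rozas' R2 — each with p-values from seeded
neutral-coalescent null distributions (conditioned on S or θ). Plus the
exact test of population differentiation on haplotype contingency tables
(complete enumeration, Monte-Carlo fallback) and AMOVA with Φ statistics
under Tamura–Nei distances and permutation p-values.

**Mismatch distributions and dating.** The sudden-expansion model
(τ, θ₀, θ₁) is fitted to the pairwise-difference histogram by SSD
minimization, with parametric-bootstrap p-values for SSD and
Harpending's raggedness; a spatial-expansion variant (τ, θ, M) is
included. Fitted τ converts to calendar time via τ = 2ut with u built
from a pairwise divergence rate (default 6.5%/My), the sequence length,
and 13.5 generations per year.

**Synthetic data.** A Hudson coalescent generator produces species
complexes with target corrected divergences, constant-size or
sudden-expansion demographies, a COI-like K2P mutation kernel (open
reading frame maintained), and planted NUMT contaminants — each dataset
with a machine-readable truth record, so every stage of the pipeline is
testable end to end.

## Worked example

```bash
python analysis/01_simulate_datasets.py   # three seeded datasets + truth
python analysis/03_delimit_species.py     # distances -> gap -> species
python analysis/06_mismatch_dating.py     # expansion fit and dating
```

The delimitation step prints:

```
30 samples -> 16 unique haplotypes
proportion invariant sites used: 0.833
break: [1.75%, 6.75%], midpoint 4.25%
break: [10.00%, 18.00%], midpoint 14.00%
threshold 4.25% -> 3 putative species
  H001: 6 haplotypes, truth = ['speciesA']
  H007: 6 haplotypes, truth = ['speciesB']
  H013: 4 haplotypes, truth = ['speciesC']
```

The two breaks are the barcode gap: within-species distances stay below
1.75%, the two between-species tiers sit near 5% and 12% (stretched
upward by the +I correction), and clustering at the first midpoint
recovers the three planted species exactly. The dating step fits the
expansion population (true τ = 5, θ₀ = 0.5, θ₁ = 50, n = 30):

```
fitted: tau=6.21, theta0=1e-09, theta1=63.2
SSD=0.0048 (p=0.398), raggedness=0.0206 (p=0.302) [large p = expansion model not rejected]
dated expansion: 149,372 years before present

published-tau check: tau=6.74 on 640 nt -> 162,019 years BP (~160,000 expected)
```

i.e. the goodness-of-fit test retains the expansion model and the fitted
τ dates the growth to ~150 kyr BP; with a literature τ of 6.74 on the
same 640-nt window the clock gives ~160,000 years before present.

The same stages are exposed as a CLI (`barcodegap simulate | numt-screen |
distances | delimit | treecheck | popgen | mismatch | run`), with `run`
driving the whole workflow from a YAML config.

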