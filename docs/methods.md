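# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic admixed cohorts

**Ancestry mosaics.** Each haplotype is a Markov path along the genetic
map. Ancestry is drawn from the admixture proportions `p = (p_EUR, p_NAF,
p_SSA)` at the chromosome start; switch events arrive as a Poisson process
at rate `g` per Morgan, where `g` is the number of generations since a
single admixture pulse; at each switch the ancestry is redrawn from `p`.
After merging same-ancestry neighbours, the tract length of ancestry *k*
is exponential with mean `100/(g(1−p_k))` cM, and the ancestry-indicator
covariance between loci `d` Morgans apart decays exactly as `exp(−g·d)` —
the decay form the admixture-LD dating estimator fits. This memoryless
model was chosen over pedigree simulation because it is the tract-length
model implicit in LD-decay dating; empirically observed lognormal block
sizes arise from detection effects and are not imposed.

Defaults are the study conditions: `p = (0.75, 0.22, 0.03)`, `g = 15`,
22 autosomes with human-like relative lengths scaled to 3,000 Mb, uniform
1 cM/Mb unless a genetic map is supplied, and evenly spaced loci (default
1 per 20 kb).

**Allele frequencies.** Ancestry-specific frequencies follow the
Balding–Nichols construction: ancestral `p ~ U(0.05, 0.95)` per locus and
`f_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k)`. The divergence defaults
`F = (0.02, 0.03, 0.12)` were set once so that EUR–NAF differentiation is
small relative to either ancestry versus SSA (no published FST values
exist for the study's panels); the package only relies on that ordering.

**Signal injection.** A deviant region reassigns whole haplotype tracts
inside an interval (preserving contiguity, hence realistic dosage
autocorrelation) until the cohort-mean ancestry fraction reaches the
target; granularity is 1/(2n) per haplotype converted. ROH injection
copies haplotype A onto haplotype B (alleles and ancestry) within an
interval, creating a fully autozygous tract.

**What the generator does not model:** genotyping error, array
ascertainment, phasing error, LD within ancestral populations (loci are
exchangeable given the mosaic), and local-ancestry inference noise (truth
dosages are exact integers). Passing tests therefore demonstrate
correctness of the statistics and recovery machinery under the stated
model, not robustness to inference error on real array data.

## Quality control

Filter order is fixed: samples by call rate (≥0.95), then variants by
call rate (≥0.95), minor allele frequency (≥0.01) and the Hardy–Weinberg
*exact* conditional test (p ≥ 10⁻⁶; the exact test is used because the χ²
approximation is unreliable at the 10⁻⁶ tail). Missing genotypes are
excluded from all denominators. LD pruning is greedy within 50-SNP
windows sliding by 10: while any kept pair has genotype r² > 0.5, the
lower-MAF member is dropped (ties: the later variant). Four canonical
hg19 long-range-LD regions (chr5/6/8/11) are bundled for exclusion before
pruning.

## ROH calling

PLINK's sliding-window algorithm: a window of 50 consecutive SNPs —
truncated so it never spans more than 5,000 kb — is anchored at every SNP
and passes when it holds ≤1 heterozygous and ≤5 missing calls. A SNP is
ROH-eligible when ≥5% of the windows containing it pass. Maximal eligible
runs are segments if ≥500 kb long, ≤50 kb/SNP sparse, and free of
>1,000 kb internal gaps; bounds sit at the outermost eligible SNPs.
Window SNP count (50), hit fraction (0.05) and maximum gap (1,000 kb) are
PLINK defaults; they materially affect reproduction on external data and
are all configurable. Because eligibility is a windowed hit rate, segment
bounds can extend a few inter-SNP gaps beyond a true autozygous tract
(by-chance-homozygous flanking SNPs); boundary precision is on the order
of the window extent, as with PLINK itself. Segments are summarized in
six length categories (0.5–1, 1–2, 2–4, 4–8, 8–16, >16 Mb) and the
≤1.6/>1.6 Mb split; group differences use the two-sided rank-sum test
(exact for tie-free samples ≤25, otherwise normal approximation with tie
and continuity corrections) with Bonferroni-corrected thresholds.

## Ancestry blocks

Dosages round at 0.6/1.4 (<0.6 → 0, 0.6–1.4 → 1, >1.4 → 2); loci whose
rounded copies do not sum to 2 are ambiguous and excluded. Blocks are
maximal constant-level runs per ancestry, broken at chromosome ends,
ambiguous loci and centromere intervals (in-centromere SNPs are dropped).
A level-2 block is one homozygous block; haploid summaries weight lengths
by level, the reading adopted for expected-count comparisons since
unphased dosages cannot distinguish two haploid blocks from one
homozygous one. Expected haploid counts use `N_k = round(p_k·L/ℓ̄_k)`;
with the canonical mean lengths (13.05/8.46/7.48 Mb), proportions
(0.75/0.22/0.03) and L = 3,150 Mb this gives 181/82/13 (276 total).
Lognormal fits are moment MLEs on log lengths.

## Ancestry-deviation scan

Per ancestry, the per-locus cohort-mean fraction (mean dosage/2 over
non-missing individuals) is standardized by its genome-wide mean and
*empirical across-locus SD* (ddof 0), not a binomial SE: the empirical SD
absorbs mosaic autocorrelation and inference noise and maps |Z| > 3 onto
the two-sided normal tail 2.7×10⁻³. Individuals, not haplotypes, are the
averaging unit (dosages are unphased). Regions are maximal runs of
significant loci (gap tolerance default 0); the lead SNP is the max |Z|
with ties to the lowest position. A constant-ancestry column yields Z ≡ 0
with a warning. Diversity follow-up compares region per-SNP
heterozygosity and ROH-carrier counts against the genome-wide per-SNP
distributions by rank-sum, flagging at 0.05/m. On null cohorts the
per-locus |Z| > 3 rate sits near 2.7×10⁻³ (measured ~3×10⁻³), but called
*regions* can exceed their nominal count because neighbouring loci are
correlated — the false-positive guarantee is at locus level.

## Coalescent null

The demography is given in the ms dialect (times in 4N₀ generations,
sizes relative to N₀, migration in 4N₀m units; flags -t -r -I -n -g -ma
-es -ej -en -eM, `tbs` for per-replicate θ/ρ). The built-in
four-population island model places an isolated deme of Ne ≈ 497
(0.068·N₀ with N₀ = 7,310, used only for unit conversion) that receives a
90% European admixture pulse ~15 generations before sampling; 28
haplotypes are sampled. Simulation runs on msprime after exact unit
conversion; ms event semantics are preserved (`-ej` zeroes backward
migration out of the joined deme; a later `-eM` resets every off-diagonal
entry to x/(npop−1) counting split-created demes; equal-time events apply
in command order). Mutations are infinite-sites binary mutations on a
continuous coordinate. Locus parameters are randomized per replicate as
Normal(mean = estimate, variance = mean), truncated positive by
resampling. Replicates that come out monomorphic have no defined D and
are recorded at 0 (the neutral centre) so ensemble length stays fixed;
at the default θ ≈ 7.3 such replicates are rare.

Empirical p-values are `count/N` with zero counts floored at `1/N` and
flagged (`< 2×10⁻⁴` at N = 5,000). The D null uses the primary sample
only; for PBS nulls an option samples additional haplotypes from two
reference demes in the same simulation, since a PBS null needs all three
branches (the alternative — pairing simulated focal samples with fixed
real panels — is supported by passing allele-count tables directly).

## Selection statistics

Windows tile a region in non-overlapping 10-kb steps from the region
start. π uses per-site allele frequencies from unphased genotypes under
random union of gametes, `Σ 2p̂q̂·m/(m−1)` with per-site haplotype count
m (missing excluded); D uses n = 2×samples with Tajima's constants, NaN
when S = 0. Pairing haplotypes into homozygote-free diploids leaves S, π
and D exactly unchanged, which is the cross-module equivalence the tests
assert. FST is Hudson's ratio of averages (robust to rare variants and
the standard choice for PBS; the estimator identity is the main
reproduction risk for published PBS values since papers rarely name one).
PBS clamps FST at 1−10⁻⁹ before the log; small negative FST passes
through (negative branch). Bonferroni families are per statistic
(0.05/3 → 0.017 for a three-window D family; 0.05/21 → 2.4×10⁻³ for
seven-group pairwise ROH comparisons; 0.05/6 → 8×10⁻³ for six region
diversity tests).

## Admixture-LD dating

SNP weights are reference frequency contrasts `w_i = f_ref1 − f_ref2`;
every intra-chromosomal pair within [0.5, 30] cM contributes
`cov(g_i, g_j)·w_i·w_j` (genotype covariance across admixed individuals,
missing entries mean-imputed), averaged in 0.05-cM bins. Pairs below
0.5 cM are excluded (short-range LD contamination); the upper bound and
bin width follow the conventional defaults and are configurable — for
slow decays (g ≲ 8) widening the window to ~50 cM separates the affine
term better. The fit is bounded nonlinear least squares of
`A·exp(−n·d) + c` with A, n ≥ 0, bins weighted by √(pair count), initial
rate from a log-linear slope. SEs come from a leave-one-chromosome-out
jackknife on the binned per-chromosome partial sums (refit per deletion);
the detection pretest is the amplitude z-score A/SE_A ≥ 2 (replacing the
multi-panel pretest of the reference tool, whose machinery is out of
scope). Multiple reference pairs combine by inverse-variance weighting.
Years BP = generations × 33, with the interval `floor/ceil(n ∓ SE) × 33`.

With a free affine term the per-run estimator scatter at desk scale is
~0.3–1 generation; recovery experiments therefore average a few seeds
when asserting the <10% bias bound (measured mean bias ≲5% at
g ∈ {5, 15, 30} with 200 individuals, 2,000 Mb, 1 SNP/30 kb, five seeds
per g; the acceptance script runs the full study conditions — 200
individuals, 3,000 Mb, 1 SNP/20 kb — in one ~20 s pass).

## Problem sizes and determinism

Tests run at reduced sizes chosen for a single-CPU desk run: cohorts of
40–200 individuals, genomes of 120–2,000 Mb, null ensembles of 600–5,000
replicates; the constants above were fixed before the corresponding
assertions were first run. All randomness flows through
`numpy.random.default_rng` seeds (msprime seeds derived from them);
identical seeds give bit-identical cohorts and byte-identical pipeline
outputs.

## Known limitations

- Local-ancestry inference itself (ELAI/LAMP-LD-style HMMs) is out of
  scope: dosages are inputs, and truth dosages in simulations are exact.
- The ROH caller's printed-parameter reading is faithful to PLINK's
  windowed hit-rate algorithm, but external-data reproduction depends on
  defaults (window SNP count, hit fraction, max gap) the original
  analysis left implicit.
- PBS reproduction on published values additionally depends on which
  reference panels defined the branches; the interface accepts arbitrary
  allele-count tables for that reason.
- The dating estimator assumes a single pulse; continuous or multi-pulse
  admixture biases `n` toward an effective intermediate time.
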