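# Methods notes

## Scope and model

The package studies what a population-based GWA scan can resolve in a
highly inbred, strongly structured crop panel, and provides the scan
itself.  All inference rests on the single-random-effect mixed model
`y = Xb + u + e`, `u ~ N(0, σ²_g K)`, `e ~ N(0, σ²_e I)`.  After one
eigendecomposition of `K`, the REML (default) or ML criterion is a
one-dimensional profile likelihood in `δ = σ²_e/σ²_g`, optimised on a
100-point log grid over `[1e-5, 1e5]` and refined by bounded scalar search
in the bracketing interval; ties go to the smaller `δ`.  Degenerate flat
directions (e.g. `K = I`, where only `σ²_g(1+δ)` is identified) therefore
resolve deterministically, and the per-marker tests are invariant to where
in the flat region the optimiser lands.

### Kinship normalisation

`K` is the VanRaden genomic relationship matrix.  On fully inbred lines
its diagonal sits near 2 (no heterozygotes), and the conventional
pseudo-heritability `σ²_g/(σ²_g+σ²_e)` would systematically understate the
variance share of the random effect.  The spectral decomposition therefore
clamps negative eigenvalues (subsampled or compressed kinship can be
slightly indefinite; threshold `-1e-8·λ_max`) and rescales the spectrum to
unit mean.  Rescaling is absorbed by `σ²_g`, so p-values, effect
estimates, and the location of the likelihood optimum are unchanged; only
the variance-component scale is fixed so that pseudo-heritability is
comparable across kinship constructions.

### Compression (CMLM)

Candidate group counts run from 20 in steps of 20 up to the line count,
plus the uncompressed model, so compression can never be selected when it
fits worse than the plain mixed model.  Groups come from cutting a
complete-linkage dendrogram; the compressed kinship entry for groups A, B
is the mean of all line-level entries in the A×B block.  Because the
eigendecomposition at each level depends only on `(K, X)`, the sweep is
built once per panel and reused across traits and replicates — this is
what makes 40-replicate power grids desk-scale.

The clustering distance is the one the kinship itself induces,
`d_ij = K_ii + K_jj − 2K_ij`: it is exactly zero for genomically identical
lines and non-negative for PSD `K`.  The simpler monotone shift
`max(K) − K_ij` is available behind a flag (`distance="max_shift"`); it
ranks pairs the same way within a row but assigns identical lines a
nonzero merge height whenever some other line has a larger diagonal, which
we considered a defect for dendrogram interpretation.

### Marker tests (P3D)

Variance components are estimated once under the null of the selected
compression and frozen; each marker is then a one-column GLS addition,
computed in the rotated basis by projecting out the covariates (QR) and
applying a t-test with `n − q − 1` degrees of freedom.  With `K = I` this
reduces exactly to OLS (tested to 1e-6).  Markers collinear with the
covariates or constant are flagged `inestimable` and reported with p = 1
rather than dropped.  The allelic effect is the coefficient per
minor-allele copy — half the opposite-homozygote difference.

### Stepwise scan (MLMM)

Forward selection adds the minimum-p marker as a fixed cofactor and
re-estimates variance components each step (cheap: the kinship
eigendecomposition is reused; only the 1-D profile repeats).  Stopping:
remaining pseudo-heritability < 0.01 or 20 steps.  The floor applies only
after the first step — with a degenerate kinship the null pseudo-h² is
arbitrary and step 1 must still reduce to a single-locus scan.  Model size
is selected by extended BIC (γ = 1, penalty `s·log n + 2·log C(m, s)`);
the multiple-Bonferroni rule is available behind a flag, and a backward
elimination pass exists but is off by default.  Reported p-values are
computed in the selected model: add-one tests for non-cofactors, drop-one
tests for cofactors; both at-addition and in-model p-values are exported.
Remaining pseudo-heritability is non-increasing while genetic signal
remains; once it falls below ~0.05 the REML estimate sits near its
boundary and can wiggle at noise level between steps — a property of the
estimator, not of the selection.

## Synthetic panels

The generator emulates the study conditions rather than any one dataset:
defaults are 900 lines, 30,000 SNPs on 20 chromosomes (analysis drivers
and tests use 5,000-marker panels — the same line:marker geometry at
desk scale), three subpopulations at proportions 0.5/0.3/0.2, F_ST 0.15,
founder-segment length 20 markers, residual heterozygosity 1e-3 (about one
heterozygous call per 1,000 SNPs, as in inbred soybean).  Ancestral minor
frequencies are log-uniform on [0.02, 0.5] so the folded spectrum is
rare-skewed; subpopulation frequencies are Balding–Nichols draws; lines
copy founder haplotypes along chromosomes with per-marker switch
probability 1/20, giving geometrically decaying within-chromosome LD and
independence across chromosomes.

What it does **not** model: coalescent-exact LD, domestication bottlenecks
or selective sweeps, genotyping-array ascertainment bias, dominance,
epistasis, genotype-by-environment interaction, and linkage between a
causal variant and its marker (the sampled marker *is* the causal
variant).  Power estimates on synthetic panels are therefore qualitative
guides — ordering across architectures and heritabilities, an upper bound
flavor for false positives — not predictions for a specific germplasm
collection, whose longer LD blocks both help (proxy detection) and hurt
(LD echoes counted against the dual rule).

## Trait simulation

Genetic value `g_i = Σ_k effect_k · dosage_ik / 2`, so a heterozygote is
exactly intermediate and an effect of 1 spans the opposite homozygotes;
per-QTL effects sum to 1, making 1 the maximum total genotypic effect in
any simulation.  The linear effect law is `e_k = 2(n+1−k)/(n(n+1))` —
linearly declining toward but never reaching zero, summing to 1 for every
`n`, with maximum `2/(n+1)` (0.4 at n = 4).  Noise is
`N(0, Var(g)·(1−h²)/h²)` with the ddof-1 sample variance of the genetic
values, so realized heritability matches the target in expectation; the
choice of the empirical rather than a theoretical variance is a design
decision.  Same seed ⇒ bitwise identical trait; different seeds share the
genetic values and differ only in noise.

## Evaluation conventions

False negative: causal marker with CMLM `p ≥` threshold.  False positive:
non-causal marker with `p <` threshold under both CMLM and the selected
MLMM model.  The FP denominator is markers tested × replicate scans.
Quartile breakdowns restrict the causal set to the strongest `⌈n/4⌉`
(resp. `⌈3n/4⌉`) effects and are NA for uniform architectures.  Child
seeds per (condition, replicate) derive from the master seed by a fixed
affine counter, so any table cell reruns in isolation.

## Diversity statistics

Inbred-haplotype convention throughout: a homozygous genotype is its
haplotype.  `r²` is the squared Pearson correlation of dosage/2 over lines
homozygous at both markers; `D′` uses two-locus haplotype frequencies read
directly from those lines.  Residual heterozygotes are excluded pairwise.
Tajima's D windows are defined over **all** genotyped markers so
monomorphic sites occupy window slots; per site, heterozygous/missing
calls are excluded and pairwise diversity is `k(m−k)/C(m,2)` from the `m`
homozygous calls, with the constants using n = number of lines.  Windows
with `S = 0` or fewer than 4 lines give NA; a trailing short window is
emitted with its actual width and flagged.  No ascertainment-bias
correction is attempted; array-based marker panels inflate D upward, which
matters when interpreting locally negative values against that background.

## Heterozygote handling

Imputation fills missing calls with draws from the marker's homozygote
classes (never a heterozygote) — a deliberate stand-in for haplotype-aware
imputation, defensible at the MAF ≥ 0.05 markers used downstream.
Resolution (for the stepwise scan only) sends a het to the minor
homozygote with probability equal to the marker's minor-allele frequency.
This preserves expected allele frequency exactly only at MAF 0.5
(elsewhere the bias per marker is `h(2p−1)/2n` for `h` hets); at the
realistic ~1/1000 het rate this is negligible, minor and nonsystematic.

## Problem sizes and tolerances

Analysis drivers and acceptance runs use 900 × 5,000 panels with 5
replicates per grid condition, 10 null replicates, and 20 replicates per
heritability level — sizes chosen so the full suite re-runs in minutes
while keeping every per-condition estimate an average over independent
replicates.  Numerical tolerances: kinship symmetry 1e-10, OLS equivalence
1e-6, Tajima/LD brute-force agreement 1e-10, effect-sum 1e-12.  MAF
filtering is boundary-inclusive (exactly 0.05 is kept), applied after
imputation and after subsetting to a population's lines, with the minor
allele re-designated per panel (ties broken toward the lexicographically
greater allele so file round-trips are exact).
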