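# Methods

## Time grid

All tables live on an explicit window grid in hours after egg laying (hAEL),
labelled `h00-02` … `h18-24`. The default grid is 2 h windows from 0–12 hAEL
and 6 h windows for 12–18 and 18–24 hAEL. Quantities attached to a window are
treated as point measurements at the window midpoint (1, 3, 5, 7, 9, 11, 15,
21 hAEL); no within-window sampling convention is imposed by the data, so the
midpoint is used consistently for kinetics, half-life fits and plots. When a
coarse window must be compared with fine-grid coverage (the two 6 h windows
against 2 h total-RNA windows), the coarse value is the unweighted mean of the
fine windows that exactly tile it.

## Quantification

Reads are classified sequentially without double counting: 2S rRNA matches
are removed first, spike-in matches are tallied separately, and the remainder
is assigned with precedence abundant ncRNA > miRNA > transposon > other.
Matching is exact full-read substring containment in the reference set; this
is the desk-scale equivalent of zero-mismatch genome alignment and keeps the
classifier order-deterministic. Transposon reads of 21 nt count as siRNAs and
23–30 nt as piRNAs; 22 nt (and 18–20 nt) transposon reads carry no class
label and fall to "other", since only those two length classes are defined.
With a genome sequence set supplied, "other" means genome-matching but
category-less and everything else is "unmatched"; without one, all residual
reads are "other".

RPTS = count / spike-in count × 1000. When several spike-in oligos are used
the normalizer is the summed spike-in count. RPTS is invariant to joint
rescaling of counts and spike-ins and is additive over replicate pooling when
spike-ins are summed.

## Kinetic model and regression

The generative model is dM/dt = b·P(t) − a·M(t): production proportional to
transcription (upstream read density P) and first-order decay of the mature
species. The regression z ~ a·x + b·y + c is its window-pair discretization:
x = mature RPTS in the first window, y = upstream density in the second
window, z = mature difference (second − first). By default z is the raw
between-window difference, which is the operational definition used for the
mixed 2 h/6 h grid; `per_hour=True` divides z by the midpoint gap, which
makes the coefficients comparable across unequal windows and is the mode in
which the regression exactly inverts the discretized generator (see below).

Genes enter the regression only if they pass all of: first-window share of
summed RPTS ≤ 30% (maternally loaded genes violate the model's assumption of
embryo-autonomous synthesis), upstream density > 1 in at least one window,
mature level > 10 RPTS in at least five windows, and multi-mapping read
fraction ≤ 20%. All thresholds are configurable; these are the defaults.

Fits are ordinary least squares. Per-gene fits report the coefficient of
determination; the headline "pooled r²" is the squared Pearson correlation of
pooled per-gene predictions against observed z (a single pooled-plane fit is
also available). Rank-deficient designs are flagged, never silently fitted.
Prediction error rates are (predicted − observed) × window size × 100 /
mature level, with window size and mature level taken from the *second*
window of the pair (that is the window a pair is labelled by); points below
10 RPTS in that window are flagged and excluded by default.

## Synthetic kinetics: exact vs. discretized

`simulate_time_course` supports two integrators.

* `kinetics="exact"` integrates the ODE piecewise-analytically over the
  breakpoints of the piecewise-constant pulse schedule:
  M(t+Δ) = M e^{−aΔ} + (bP/a)(1 − e^{−aΔ}), with the linear limit b·P·Δ when
  a = 0. This is the reference trajectory; it matches a brute-force
  forward-Euler oracle at dt = 10⁻³ h to better than 0.1%.
* `kinetics="euler"` emits the window-step recurrence
  M_{k+1} = M_k + Δ_k (b P_{k+1} − a M_k) on the midpoint grid. This is the
  model the regression assumes, so per-hour regression on its noiseless
  output returns a = −a_g and b = b_g to machine precision — the canonical
  recovery test. The recurrence is only a meaningful discretization when
  a·Δ ≤ 1; on the mixed grid the 6 h steps violate this for fast-decaying
  genes, so recovery studies use a uniform 8 × 2 h grid, where a up to
  0.5 h⁻¹ stays stable. A step that would drive a level negative raises
  unless `clip_negative` is set.

Random parameterizations (`random_kinetics_config`) draw a ∈ [0.02, 0.5] h⁻¹
(half-lives of ~1.4 h to ~35 h, spanning rapidly degraded and stable
species), b ∈ [0.5, 2], and log-uniform expression scales of 5–500 RPTS.
`pulse_style="bursty"` gives each gene one or two transient transcription
pulses — the typical shape of pri-miRNA expression, which peaks in short
windows — while `"sustained"` gives mild (±20%) per-window variation around a
steady state, useful when strictly positive trajectories are needed for
arbitrary decay rates.

## Count noise

Counts are negative binomial with var = μ + φμ², φ = `nb_dispersion`
(Poisson at φ = 0), the standard overdispersion model for sequencing counts;
the data themselves do not pin down a noise law, so the choice is documented
here rather than asserted. Defaults: triplicate libraries, 10⁶-read depth
scale, 10⁴ expected spike-in reads, φ = 0.05 (≈22% biological CV). The
expected gene count is M_g × spike-in/1000, making RPTS an unbiased estimate
of M_g; this was verified by Monte-Carlo (200 Poisson replicates agree with
truth to <2%). The spike-in row has its own dispersion parameter defaulting
to 0 (Poisson): the spike-in is a fixed synthetic oligo dosed per RNA mass,
and giving it the biological CV would inject an unrealistically noisy
per-library normalization factor.

## Profile clustering and the cluster ANOVA

Profiles are row-standardized (mean 0, SD 1, ddof = 0; zero-variance rows
dropped with a warning) and clustered with Euclidean k-means (k = 4 by
default, best of 10 seeded restarts; within-cluster sum of squares reported
per k for elbow plots). Genes enter clustering when their maximum RPTS over
windows exceeds 50 — "expressed above 50 RPTS" is read as max-over-windows
and is configurable. For per-cluster charts, genes with all-window mean
RPTS < 5 are dropped and same-sequence paralogs are averaged into one
profile, since their reads cannot be attributed to a single locus.

For each genomic miRNA cluster and each consecutive window pair, per-replicate
change rates of the member genes are compared by one-way ANOVA; all
(cluster × pair) p-values are Benjamini–Hochberg adjusted together and
flagged at adjusted p < 0.01. Clusters with one member are skipped. A
degenerate all-equal cell is reported as F = 0, p = 1 rather than NaN.

## Half-lives

Least squares of ln(level) on midpoint time; λ = −slope, t½ = ln 2/λ.
Non-positive levels are dropped (no pseudocount by default — zeros in a decay
tail carry no log-scale information and a pseudocount would bias λ; a
configurable pseudocount is available upstream by adding it to the table).
Fewer than two positive points yields a flagged, undefined estimate; λ ≤ 0
(flat or rising series) reports t½ = +∞. The estimator is scale-invariant
and exact on noiseless exponentials; under 10% CV lognormal noise on an
8-point course the median of 500 replicate estimates is within 0.3% of a 3 h
truth (the test tolerance is 5%).

## 5′ nucleotide comparison

Mature miRNAs beginning with uridine bind the Argonaute MID pocket most
tightly and are expected to be better protected from decay, i.e. to show
higher (less negative) mature-level coefficients. Genes are split into 5′-U
vs other; group means/medians are reported and the difference is tested with
the one-tailed KS test (alternative: the 5′-U distribution is stochastically
larger). Individual per-gene coefficients are noisy — fits on seven points
routinely produce positive degradation coefficients — so only the group-level
comparison is meaningful.

## Target-site population genetics

Coordinates are 0-based half-open internally; SNP positions are 1-based on
input. UTR scanning is sense-strand only (minus-strand intervals are handled
by complementing alleles and reflecting coordinates). For every hexamer
window covering a SNP, a site is emitted when one allele spells the target
hexamer — the other allele is then automatically one of the 18 one-mismatch
variants. SNPs overlapping CDS intervals are discarded; genes with maximum
FPKM ≤ 0.1 are ignored; windows containing two SNPs are skipped as
ambiguous; duplicate hits from overlapping transcripts are deduplicated by
(gene, position, miRNA); missing haploid calls are excluded from both the
numerator and denominator of the target allele frequency.

Relative target avoidance per miRNA is the fraction of sites with target
allele frequency strictly below 0.1 in each gene class, and the ratio
zygotic/maternal (undefined, and flagged, when the maternal fraction is 0).
A site is a *derived* target site when the outgroup allele substituted into
its hexamer yields a non-target variant; its DAF is the target allele
frequency. DAF histograms use bins [0, 0.1), …, [0.9, 1.0].

The one-tailed two-sample KS statistic is the signed ECDF sup-difference in
the stated direction. The p-value is exact when n₁·n₂ ≤ 400 (configurable)
and the pooled values are tie-free: a lattice-path dynamic program counts,
in integer arithmetic, the label assignments whose running ECDF difference
never reaches the observed D — equivalent to full enumeration, and verified
against explicit enumeration of all 126 assignments at n₁ = 4, n₂ = 5.
Otherwise the one-sided asymptotic tail exp(−2D²n₁n₂/(n₁+n₂)) is used and
recorded in the result. On heavily tied data (allele frequencies from a
~200-line panel take ~200 distinct values) the test is conservative: the
null rejection rate at α = 0.05 measures ≈0.02–0.04 rather than 0.05. This
is inherent to KS on discrete data and affects the real analysis equally.

## SNP-panel generator

Each planted site gets its own synthetic gene: one ~200 nt UTR on its own
contig with the ancestral hexamer written into the reference sequence, a
panel of 205 haploid inbred-line calls, and one outgroup call. The derived
allele is the target hexamer with probability 0.5; its count i ∈ {1…n−1} is
drawn ∝ (1/i)·wⁱ — the neutral 1/i site-frequency spectrum tilted by a
selection weight w ∈ (0, 1] against the target allele (symmetrically
(1/i)·w^{n−i} when the derived allele is the non-target variant, i.e.
selection against retention of the ancestral target). w is a
phenomenological weight, not a population-genetic selection coefficient: the
claim being modeled is qualitative (selection left-shifts the target SFS).
The outgroup carries the ancestral allele, flipped to the derived allele
with probability 0.05 (divergence of the same order as close sibling
species), which exercises the mispolarization path. A configurable fraction
of sites can be overlapped by decoy CDS intervals to exercise the CDS
filter. Chi-square goodness of fit confirms the planted counts follow the
stated law at 10⁴ sites.

What the generator does *not* emulate: linkage between sites (every site is
independent), demography or background selection shaping the SFS, UTR
sequence composition biases, multi-SNP haplotypes, and alignment or
liftOver errors beyond the single divergence-flip probability. Passing
selection-detection tests therefore show the *inference machinery* is
correct and calibrated under the stated model, not that real panels meet
these assumptions.

## Determinism

All randomness flows from a single integer seed. Generators derive
independent child streams (`default_rng([seed, stream])`) per stage, so
identical seeds give byte-identical datasets, and adding replicates or sites
does not perturb other stages.

## Problem sizes in the validation suite

Recovery studies use 50 genes on a uniform 8 × 2 h grid (the discretized
generator's stable regime; see above); half-life recovery uses 500 replicate
8-point courses; selection detection uses 2000 planted sites per gene class
per miRNA and 200 runs per condition (power ≈ 1.0 at w = 0.6, neutral
rejection ≈ 0.02–0.04 at α = 0.05); variant enumeration is exhaustive over
all 4096 hexamers; KS exactness is checked against full 126-way enumeration.

## Known limitations

* The regression inherits the errors-in-variables problem of using measured
  mature levels as x: per-gene coefficient estimates are noisy and can take
  the "wrong" sign for individual genes, exactly as seen on real data; only
  aggregate statements are robust.
* The raw-difference z on the mixed grid conflates 2 h and 6 h pairs; the
  per-hour mode is preferred for inference, the raw mode for descriptive
  parity with the default convention.
* Exact KS p-values require tie-free data; tied inputs silently fall back to
  the (conservative) asymptotic form, with the method recorded.
* "Other" in read classification is only as meaningful as the supplied
  genome set; without one it is a residual category.
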