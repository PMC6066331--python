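# mirdyn

Analysis of microRNA expression dynamics across embryogenesis, built around a
time course of small-RNA libraries (2 h windows from 0–12 h after egg laying,
6 h windows to 24 h) and matched total-RNA coverage of primary miRNA loci.
The package is aimed at people studying post-transcriptional control of miRNA
abundance: it quantifies mature miRNAs on an absolute scale using spike-in
oligos, separates the contributions of transcription and decay with a simple
kinetic model, estimates mature-miRNA half-lives, tests whether members of a
polycistronic miRNA cluster change at different rates, and asks whether a
miRNA's stability leaves an evolutionary footprint at its seed-target sites in
3′UTRs of a sequenced inbred-line panel.

## The models

**Spike-in normalization (RPTS).** Read counts are divided by the library's
spike-in read count and scaled: RPTS = count / spike-in × 1000. Unlike
reads-per-million this is robust to global shifts in small-RNA composition.

**Production/degradation kinetics.** Mature miRNA abundance M(t) is modeled
as dM/dt = b·P(t) − a·M(t), with P(t) the transcription proxy (read density
immediately upstream of the hairpin). For each pair of consecutive windows
the model is fit as the multiple regression

    z ~ a·x + b·y + c

where x is the mature level in the first window, y the upstream density in
the second, and z the change in mature level. The coefficient on x estimates
(minus) the degradation rate; the coefficient on y the production efficiency.
Per-point prediction errors are expressed as
(predicted − observed) × window size × 100 / mature level (percent).

**Half-lives.** ln(level) is regressed on the window midpoint; the half-life
is ln 2 / λ with λ the fitted decay rate.

**Seed-target population genetics.** For a miRNA with seed s (mature
nucleotides 2–7), the 3′UTR target hexamer is the reverse complement of s.
A *polymorphic target site* is a UTR position where one allele spells the
target hexamer and the other one of its 18 one-mismatch variants. The target
allele frequency across the line panel, the fraction of sites below 0.1
(relative target avoidance, zygotic/maternal ratio), and derived allele
frequencies (polarized with an outgroup) quantify selection against target
sites, tested with a one-tailed two-sample Kolmogorov–Smirnov test whose
p-value is exact (full enumeration) for small samples.

A first-class synthetic-data generator (`mirdyn.simulate`) produces kinetic
time courses, negative-binomial count tables with spike-ins, and SNP panels
with planted target sites under a configurable selection weight w — the
derived-allele count i is drawn ∝ (1/i)·wⁱ — so every stage can be validated
against known ground truth.

## Worked example

```bash
mirdyn simulate --seed 1 --out demo --n-genes 50 --n-sites 500 --zygotic-weight 0.6
mirdyn run --config demo/config.yaml
mirdyn report --run-dir demo/results
```

On this dataset (seed 1, 50 genes, selection weight 0.6 against zygotic
target alleles) the run summary reports:

```
"regression_genes": 23,
"pooled_prediction_r2": 0.884,
"n_polymorphic_sites": 1000,
"daf_ks": {"D": 0.653, "p": 1.1e-47, "n_maternal": 250, "n_zygotic": 257}
```

23 genes pass the regression filters and their fitted planes predict the
observed change rates with pooled r² ≈ 0.88 — transcription plus first-order
decay explains most of the expression dynamics under sequencing noise. All
1000 planted polymorphic target sites are recovered from the UTR scan, and
the derived-allele-frequency distribution of zygotic genes is strongly
left-shifted relative to maternal genes (D = 0.65), detecting the planted
selection. Per-gene tables are written alongside: `kinetic_fits.tsv` (columns
`Coef_mature_Level`, `Coef_Updensity`, `intercept`, `r2`), `half_lives.tsv`,
`prediction_error_rates.tsv`, `cluster_anova.tsv`, `target_avoidance.tsv` and
`daf_histogram.tsv`. For example the fit for one fast-turnover gene:

```
gene        Coef_mature_Level  Coef_Updensity  intercept  r2     n_points
mir_sim004  -0.725             2.541           -9.189     0.984  7
```

i.e. an estimated degradation rate of ~0.73 h⁻¹ and production coefficient
~2.5 RPTS per density unit per hour.

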