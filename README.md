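# radml — reference-free RAD-seq SNP genotyping with a mixed Poisson/normal depth model

`radml` addresses a core problem of reduced-representation sequencing in
non-model organisms: calling SNPs **without a reference genome**. When RAD
reads are assembled de novo into clusters, reads from different copies of a
repeat collapse into a single *composite* cluster, and the sequence
differences between copies are then miscalled as heterozygous SNPs. `radml`
implements the **iML** caller, which detects composite clusters through their
read depth and diverts them into an explicit *undetermined* genotype
category, together with the classical ML and minor-allele-frequency (MAF)
threshold callers and a full simulation + evaluation harness.

It is a library first (everything is importable; see `examples/`) with a thin
`radml` CLI for shell use.

## The model

At mean per-locus coverage *C*, a unique locus's cluster depth *k* is
approximately Poisson(*C*); a cluster merging *i* repeat copies sits near
*iC*. Cluster depth therefore follows a mixture

&nbsp;&nbsp;Pr(*k* | *C*) = Σ<sub>1≤i≤M</sub> *a*<sub>i</sub> · f(*k* | *iC*),&nbsp;&nbsp;Σ *a*<sub>i</sub> = 1,

with f a Poisson pmf (simulated data) or a normal density with per-component
σ<sub>i</sub> (over-dispersed real libraries). All parameters are estimated
by EM with the component means tied to a single *C*; 1 − *a*<sub>1</sub>
estimates the composite-cluster fraction. Model families are ranked by a
one-sample Kolmogorov–Smirnov test and EM uncertainty is quantified by a
balanced bootstrap.

Given the rank-ordered nucleotide counts *n*<sub>1</sub> ≥ … ≥ *n*<sub>4</sub>
(*n* total) at a cluster position and sequencing error rate ε, iML scores
three categories:

- **homozygote** ∝ multinom(*n*; *n*<sub>1..4</sub>) · f₁(*n*) · (1 − 3ε/4)<sup>n₁</sup> (ε/4)<sup>n₂+n₃+n₄</sup>
- **heterozygote** ∝ multinom(*n*; *n*<sub>1..4</sub>) · f₁(*n*) · (1/2 − ε/4)<sup>n₁+n₂</sup> (ε/4)<sup>n₃+n₄</sup>
- **undetermined** ∝ Σ<sub>k≥2</sub> [*a*<sub>k</sub>/(1 − *a*<sub>1</sub>)] · f<sub>k</sub>(*n*)

where f<sub>k</sub> is the fitted depth model's k-th component. The category
with the largest posterior wins; clusters that are undetermined at a majority
of positions are flagged repeat-derived and excluded from the SNP list. The
ML baseline compares homozygote vs heterozygote with no depth factor; the
threshold rule calls a heterozygote iff *n*₂/(*n*₁+*n*₂) > 0.35.

## Worked example

`python examples/02_fit_depth_mixture.py` draws 20,000 cluster depths from a
three-component mixed Poisson (C = 30, weights 0.85/0.10/0.05) and refits it:

```
single Poisson: C=36.1
mixed  Poisson: C=30.02 weights=[0.847, 0.104, 0.049] (11 EM iterations)
estimated composite-cluster fraction 1-a1 = 0.153 (true 0.150)
depth threshold where P(composite) > 1/2: 47 reads
K-S single: statistic=0.2977 p=0
K-S mixed: statistic=0.0023 p=1
balanced bootstrap (B=100): C = 30.02 +/- 0.04, a1 = 0.847 +/- 0.003
```

The single Poisson is pulled right by the repeat tail and is firmly rejected,
while the mixture recovers C, the component weights, and hence the
composite-cluster fraction; the 47-read threshold is where a cluster becomes
more likely repeat-derived than unique.

`python examples/04_benchmark_callers.py` runs the full pipeline
(simulate → cluster → fit → call → score) on a 500 kb genome with 35% repeat
content:

```
   method  read_length  mean_depth  fpr_mean  fpr_sd  fnr_mean  fnr_sd  n
      iml           35      40.000     0.028   0.022     0.475   0.025  3
       ml           35      40.000     0.599   0.008     0.456   0.021  3
threshold           35      40.000     0.495   0.004     0.510   0.007  3
```

iML's false positive rate collapses (2.8% vs 60% for ML) because composite
clusters land in the undetermined category, at a sensitivity cost of ~2
points of FNR. (Both callers share a large FNR floor here: true SNPs hidden
inside composite clusters are unrecoverable for any single-sample de novo
caller, and ~30% of 35 bp reads carry at least one simulated error and drop
out of clustering.)

The other examples cover simulation/clustering (`01`) and single-site calling
(`03`); the `radml` CLI exposes the same steps as `simulate`, `qc`,
`cluster`, `fit-depth`, `call` and `evaluate` subcommands.

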