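# Methods

This note records the models implemented in `radml`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical and design decisions a maintainer should know about.

## Depth mixture model

Cluster depth is modelled as an M-component mixture whose i-th component has
mean i·C: Poisson(i·C) for the `mixed_poisson` family, Normal(i·C, σ_i) for
`mixed_normal`. A single C ties all component means; the normal family adds
one free σ per component to absorb the over-dispersion of real libraries
(uneven digestion, amplification bias). M defaults to 3 — in repeat-rich
genomes the 2- and 3-copy components carry almost all composite mass, and
higher components are rarely identifiable from a depth histogram.

**EM.** The E-step computes responsibilities P_j(d_t) over the unique depth
values (the likelihood depends on data only through the depth histogram, so
the fit collapses ties; this makes a 50,000-cluster fit take milliseconds).
The weight update is the mean responsibility. Two C updates are provided:

- `c_update="all"` (default): C ← Σ_t d_t / Σ_t Σ_j j·P_j(d_t), the exact
  maximizer of the complete-data log-likelihood with tied means. Every
  iteration is a true EM step, so the observed-data log-likelihood is
  non-decreasing (asserted in tests at 1e-10 relative tolerance).
- `c_update="component1"`: C ← Σ_t d_t P_1(d_t) / Σ_t P_1(d_t), the
  component-1-anchored estimator that appears in the original description of
  this method. It converges to essentially the same fixed point on all data
  we generate (|ΔC| < 0.1 at n = 30,000), but it is *not* an M-step of the
  tied-means mixture: near convergence the log-likelihood can decrease by
  ~1e-6 relative. We keep it selectable for fidelity but do not default to
  it, because monotone ascent is both a correctness check and a debugging
  anchor.

**Initialization.** C⁰ is the mode of the depth histogram after a window-5
box smoothing — the dominant component sits at the unique-locus depth and the
mode is robust to the heavy right tail that corrupts the mean. Weights start
at (0.90, 0.07, 0.03) for M = 3 (a weakly informative "mostly unique" prior
guess), a_1 = 0.9 with the remainder uniform otherwise. For `mixed_normal`,
σ_j⁰ = sqrt(j·C⁰) (Poisson-like scale); σ is floored at 1e-3 to prevent
collapse on degenerate data. Convergence requires every weight and C to move
≤ 1e-6 (the tolerance the method was published with); the cap is 10,000
iterations.

**Derived quantities.** 1 − a_1 estimates the composite-cluster fraction.
The composite posterior at depth k is Σ_{i≥2} a_i f_i(k) / Σ_i a_i f_i(k);
`repeat_depth_threshold` reports the smallest integer depth where it exceeds
1/2. That threshold is a diagnostic (the dashed line one would draw on a
depth histogram) — iML itself never hard-excludes at it, classification is
fully probabilistic.

**Goodness of fit.** Depths are integers, so the one-sample K-S statistic is
computed by comparing the ECDF and the mixture CDF at the same
right-continuous convention over the integer support, with the asymptotic
Kolmogorov p-value. The continuous-sample convention (scipy's default for a
callable CDF) degenerates under heavy ties — its D⁻ term reduces to the modal
pmf — and rejects *any* discrete model at large n. With the discrete-support
statistic the test is conservative (measured rejection rate 0.01 at nominal
0.05 under the true model, 200 seeds), which is acceptable for its only use
here: ranking candidate families, where the differences are many orders of
magnitude. No correction is made for estimated parameters.

**Balanced bootstrap.** B replicates are formed by pooling B copies of the
index set, shuffling once and splitting — each observation appears exactly B
times overall. Each replicate is refit with the same EM configuration; means
and SDs of C and the weights are reported. Failures in more than 20% of
replicates abort.

## Genotype callers

Sites are summarized as rank-ordered counts (ties broken A<C<G<T; the
homozygote formula only makes sense when n₁ is the majority base). All three
callers and the cluster-level driver are vectorized over positions and
computed in log space (gammaln for the multinomial coefficient, xlogy for the
ε → 0 limits, log-sum-exp for mixtures and normalization).

The undetermined score sums components k = 2..M of the fitted mixture with
conditional weights a_k/(1 − a_1). Because a published typeset leaves the
prior structure ambiguous, the default applies category priors a_1/2, a_1/2
and (1 − a_1) to homozygote/heterozygote/undetermined before normalization —
this makes the three categories a coherent partition of "unique locus split
evenly across zygosities vs composite", and the und term's weights then
reduce to Σ_{k≥2} a_k f_k(n). `category_priors=False` reproduces the raw
scores. Ties in the posterior arg-max resolve to undetermined (no SNP is
safer than a coin flip); the ML baseline, which has no third category,
resolves ties to homozygote for the same reason. A cluster whose positions
are undetermined at a strict majority is flagged repeat-derived and
contributes no SNPs. Note the per-position total n equals the cluster depth
at every position, so the undetermined decision is effectively cluster-level
— the majority rule just makes that explicit and robust.

The threshold caller uses strict inequality (minor fraction > 0.35), so
7/20 = 0.35 is a homozygote; this boundary is tested exhaustively against
exact rational arithmetic for all count vectors with n ≤ 20.

## Simulator

The simulator emulates single-end RAD sequencing of one diploid individual:

- tags of `read_length` bp are extracted from both flanks of every forward-
  strand motif occurrence (reverse-flank tags are reverse-complemented, so
  with a palindromic enzyme such as EcoRI both begin with the motif; tags
  running off a sequence end are dropped);
- every tag position becomes heterozygous independently with probability
  `snp_rate` (default 0.5%), the alternate base uniform over the other three;
- each allele is sequenced to Poisson(C/2) depth so a locus totals ~C,
  consistent with the site-level Poisson depth model (`per_allele_depth`
  overrides this if the per-allele mean itself should be C);
- substitution errors follow a linear ramp, zero at the first base and twice
  the mean at the last (mean preserved at `mean_error_rate`, default 1%),
  with the substituted base uniform over the alternatives.

Read IDs encode the truth locus, so evaluation is exact. The synthetic-genome
generator plants repeat families — each family one template with the enzyme
motif at its centre, copies mutated at `repeat_divergence` per base and
spliced into random background — plus, optionally, a motif-free background
with an exact number of planted unique sites, which pins the composite-
cluster fraction to family_count/(family_count + unique_sites) for the
calibration experiments.

Not emulated: indels, PCR duplicates, GC-coverage bias, restriction-site
polymorphism dropout, barcode structure, paired ends, quality-score
degradation (simulated FASTQ carries uniform Q40). Consequently, passing
benchmarks demonstrate the depth-mixture mechanism under Poisson coverage;
they do not certify performance under real-library dispersion — that is what
the `mixed_normal` family is for, and why K-S family selection precedes
calling on real data.

## Clustering

Exactly-matching reads form stacks; stacks below `min_depth=2` are discarded
(singletons are indistinguishable from error reads). Stacks whose consensuses
are within Hamming distance `max_distance=2` are merged as connected
components, iterated to a fixed point (the merged consensus can move closer
to another cluster; iteration makes the operation idempotent and
order-independent). Consensus ties break A<C<G<T. The classical exclusion of
clusters deeper than mean + 2 SD (population SD, computed once) is a separate
optional stage: the pipeline applies it to the ML and threshold baselines,
which have no other defence against repeats, and not to iML, whose
undetermined category supersedes it. Note that discarded singleton error
reads (~30% of 35 bp reads at 1% mean error) lower the *cluster* depth scale
to ~0.7·C relative to the raw per-locus coverage; the mixture estimates this
effective C from data, so nothing downstream depends on the nominal coverage.

## Evaluation

FPR = FP/(TP+FP) and FNR = FN/(FN+TP) — complements of call precision and
recall (an alternative per-site FPR denominator is available). Matching is
per position within a truth locus. A cluster resolves to a locus only when
all its member reads share one origin; a heterozygote call from a composite
cluster corresponds to no single-locus SNP and counts as a false positive,
and true SNPs inside composite clusters count as false negatives for every
caller. This is the reading under which "FPR reduction at ~1 point of FNR
cost" is the correct summary of what iML does; the alternative
majority-attribution policy (available as `composite_policy="majority"`)
would instead credit a caller with composite-cluster SNPs roughly in
proportion to 1/copy-number and blur exactly the distinction the benchmark
exists to measure.

## Problem sizes

Defaults were chosen at desk scale: the benchmark genome is 2 Mb with 35%
repeat content (≈1,700 tag loci, ≈70,000 reads per replicate, ten
replicates), EM recovery uses 50,000 depths, the composite-fraction
calibration ≈900 clusters, and the bootstrap B = 100 on 5,000 depths. These
sizes give sampling noise comfortably below the effects being measured
(e.g. binomial SE of a weight at n = 50,000 is ~0.002 against a 0.01
acceptance band) while a full run of the test suite or the acceptance script
completes in well under a minute each.

## Known limitations

- Single-sample calling only; no joint calling across individuals, no
  phasing, no per-base quality-aware ε.
- The mixture ties component means to integer multiples of one C; genuinely
  free component means (e.g. mixed libraries) are out of scope.
- Clustering truncates depths below 2 but the mixture is fitted untruncated,
  matching the original procedure; at C ≥ 8 the truncated mass is negligible.
- K-S p-values ignore parameter estimation, so they are comparative, not
  calibrated significance statements.
- The ML/threshold baselines inherit the 2-SD filter's weakness: a few
  extreme composite clusters inflate the SD until the filter excludes almost
  nothing, which is visible in their FPRs.
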