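# Methods

## Model

The package treats parent-of-origin inference as a per-chromosome
three-state decoding problem.  Informative positions — cytosines covered
≥ 3× in both parents with discordant binomial methylation calls — define
a marker set; methylation levels at those positions, restricted to
positions covered ≥ 3× in *every* sample, are the data.  Each fixed-width
bin contributes a feature vector per sample, a per-bin one-vs-rest
logistic regression converts it to state probabilities, and two rounds
of HMM decoding (forward–backward posteriors, then Viterbi over those
posteriors with a re-estimated transition matrix) produce the final map.

Assumptions worth stating explicitly:

* methylation at marker positions is inherited essentially intact within
  one generation (epimutation and trans-chromosomal effects are noise);
* a heterozygous locus shows the mid-parent methylation level — true on
  average for read-count-weighted levels over both alleles;
* recombination is rare at the bin scale, so adjacent bins usually share
  a state (what the transition matrices encode);
* pericentromeric bins are unreliable for classification and can be
  masked, leaving their state to the transition structure alone.

## Parameters

| parameter | default | notes |
|---|---|---|
| bin size | 50 kb | best-performing size in validation; 10–500 kb supported |
| min positions per bin | 3 | sparser bins merge forward into the next bin; a sparse terminal bin merges backward |
| min coverage | 3 reads | applied to parents (marker definition) and to every sample (feature space) |
| class weights (F2) | 0.25 / 0.5 / 0.25 | expected 1:2:1 segregation |
| class weights (F8 epiRIL) | 0.4961 / 0.0078 / 0.4961 | heterozygosity (1/2)^7; 127:2:127 |
| logistic regression | one-vs-rest, liblinear, C = 100 | see numerical choices |
| transition pseudo-count | 1 | keeps every transition possible |
| HMM initial distribution | uniform | no positional prior on the first bin |
| centromere mask | A. thaliana TAIR10 intervals | user-overridable; Chr4 carries two intervals around the knob |
| epiallele z-test margin | 0.25 | one-sided test for a > 25% level difference |
| bootstrap draws / cutoff | 2000 / 99th percentile | permutation null for Games–Howell statistics |
| parental-dominant tolerance | 0.10 | absolute level difference from a parent |

## Numerical choices

**Class weights are rescaled to mean 1.**  Weights enter liblinear as
per-sample weights, where only their ratio is meaningful but their scale
multiplies the data term of the penalized loss.  Fractional weights that
sum to 1 across three training vectors would shrink the fit toward the
intercept so strongly that a query identical to a parent's training
vector is classified mid-parent.  Rescaling to mean 1 preserves the
intended 1:2:1 (or 127:2:127) prior while keeping the effective
regularization at the solver default.

**Regularization strength C = 100.**  With only three (or, with
replicates, nine) training vectors the decision geometry is trivial and
overfitting is not a concern, but emission *confidence* matters: the
smoothing stages multiply per-bin odds against transition odds, and at
C = 1 the emissions are so flat that the chain prior dominates and the
map collapses to the heterozygous state.  Accuracy is flat over
C ∈ [30, 300]; 100 is used.

**HMM arithmetic.**  Forward–backward uses per-bin scaling, Viterbi
log-space; both are underflow-free beyond 10⁴ bins (tested).  Masked
bins use emission 1.0 in every state.  Argmax ties break toward the
lower state index (mother < mid-parent < father).

**Transition estimation** pools all classified non-parent sequences —
offspring, parental replicates and the mid-parent pseudo-sample —
literally; `transition_samples="offspring"` restricts to offspring
(measured difference: negligible).

**Exact multinomial test.**  The outcome space is enumerated (stars and
bars, vectorized log-pmf) up to 10⁶ outcomes — an F2 cohort of 20 over
crossover categories 0–6 plus ">6" is ~8.9×10⁵ — with p the total
probability of outcomes no more likely than observed (tolerance 1e-9 for
float ties).  Larger spaces fall back to 2×10⁵ seeded Monte-Carlo draws.

**Methylated-region retention.**  The one-sided z-test of a region's
level against 25%/n_generations is interpreted as: the most methylated
generation must exceed the level expected if a single-generation gain of
25% were diluted across the line.  The intent of the original rule is
ambiguous; this reading is flagged here so users can substitute their
own.

**Games–Howell statistic.**  Implemented as the Welch form
|x̄_a − x̄_b| / √(s²_a/n_a + s²_b/n_b); the studentized-range constant of
the textbook procedure cancels under the permutation null, which
compares the observed statistic to its own resampled distribution.
Resampling permutes the observed label multiset (group sizes preserved);
sampling with replacement is available as a flag.  A region yielding no
statistic for some pair (group < 2, or no variance) is unassessable and
removed, matching the removal rule of the procedure.  Regions where both
heterozygous comparisons are significant but the parental one is not
fall to "ambiguous" — the four listed rules do not cover this corner and
ambiguous is the closest semantics.

## The simulator

`synth_parents` scatters n positions uniformly over a chromosome; at
each, a randomly chosen parent is methylated with level ~ Beta(8, 2) and
the other unmethylated with level ~ Beta(2, 8).  Levels are stored as
counts (total 100) so they are exact; status flags are set by
construction, so every position is informative.  `simulate_offspring`
places k equally spaced potential breakpoints, draws each region's
genotype 1:2:1 (adjacent regions may repeat, so k potential breakpoints
yield 0–k crossovers), and draws each position's level uniformly from
[max(0, x − y), min(1, x + y)] around the genotype-expected level x.
Offspring counts use total 200 so mid-parent levels (odd multiples of
1/200) stay exact at y = 0.  Default conditions: 20 Mb, 20,000
positions, 20 offspring with 0–19 potential breakpoints, 25 iterations,
no centromere.  Bin-level truth is the majority genotype of a bin's
informative positions (ties to the lower state; empty bins take the
midpoint genotype).

What the simulator does *not* emulate: read sampling noise and coverage
variation, bisulfite conversion failure, context-specific methylation
dynamics, epimutation within the cohort, pericentromeric marker sparsity
and repetitiveness, and the bimodal near-0/1 levels of real CG sites
(parental levels here are beta-distributed).  Passing validation
therefore demonstrates the decoding machinery under controlled noise,
not performance on any particular organism's methylome.

## Known limitations

* **Emission ceiling without replicates.**  With exactly three training
  vectors the mid-parent vector is the parents' exact midpoint, so the
  three vectors are colinear and the MPV-vs-rest logistic subproblem is
  inseparable: homozygous bins cap at ~2:1 emission odds.  Consequently
  segments adjacent to a crossover can bleed by one bin, and even
  noiseless simulations score ~99.1%, not 100% — consistent with the
  validation design's reported optimum of 98.69% at ±30% error.
  Parental replicates break the colinearity and restore confident
  emissions.
* BH families are chosen where the procedure leaves them open:
  genome-wide (not per-context) for methylation-status calls, per-line
  for epiallele calls, across chromosomes for crossover tests, across
  bins for allele-frequency tests.
* The epiRIL marker restriction to gene-body-methylated CG sites is
  supported via a user-supplied position whitelist; the package does not
  ship a gene list.
* Candidate DMRs are an input (any external caller); only the downstream
  filters and tests are implemented here.
* Diploid, selfing-compatible designs only; no genetic-map distances or
  crossover interference.
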