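# Methods

## Problem and model

`purecall` calls somatic variants in tumors for which no clean germline
sample exists, by jointly modelling two or more samples of the *same*
patient that differ in tumor cell content — typically a tumor specimen
and histologically normal adjacent tissue that may itself carry
infiltrating tumor cells.  The discriminating signal is the allele
fraction: a germline heterozygous variant sits at an expected fraction
set by the local copy state and purity (0.5 in diploid regions,
regardless of purity), while a somatic variant's fraction scales with
the fraction of cells carrying it.  Two samples with different purities
therefore trace different, jointly informative fraction patterns.

Notation.  J samples, K clonal variant groups, G segments.  The model
parameters fitted by maximum (penalized) likelihood are:

* `f` — K×J matrix; `f[k, j]` is the fraction of cells in sample j that
  carry clone k's alterations (unitless, in [0, 1]).
* `C` — length-J positive depth-centering constants mapping
  unmatched-control coverage onto each tumor sample's coverage scale.
* `W` — length-J beta-binomial concentrations; `W → ∞` recovers the
  binomial, small `W` means overdispersed allele counts.

Each segment g carries a total copy number `N`, minor allele copy
number `M` (2M ≤ N) and the index of the clone with the alteration.

Expected allele fractions:

    phi_G = (f M + (1 − f)) / (f N + 2 (1 − f))                germline het
    phi_S = f M / (f N + 2(1 − f))                             somatic, minor allele, same clone
    phi_S = f (N − M) / (f N + 2(1 − f))                       somatic, major allele, same clone
    phi_S = f_kz / (f_kg N + 2 (1 − f_kg))                     somatic, other (copy-neutral) clone

Likelihoods: exon mean depths are Poisson around
`round((1/C)(N f + 2(1−f)) R_C)` with `R_C` the control mean depth;
allele counts are beta-binomial with shape `(W phi, W (1 − phi))`.
Segment-level penalty terms use binomial tails at database germline
positions: the probability of seeing at most the observed number of
heterozygous calls, and of seeing at least the observed number of
somatic calls at a baseline rate `rho`.  All likelihoods are computed
in log space; the beta-binomial is evaluated through log-gamma.

A Beta prior on the mean pairwise difference of each clone's sample
fractions (`Δf̄`, with a small `ε = 1e−3` so identical fractions remain
in-support) favors clones whose fractions differ across samples at
least as much as the configured expectation `f^π = (0.1, 0.7)`; the
Beta's second shape is chosen so its mode equals the prior difference.

## Classification

Read counts across samples are conditionally independent given the
genotype, so each candidate position's joint likelihood under
*somatic*, *germline heterozygous*, *homozygous A* and *other (BB)*
genotypes is a product of per-sample beta-binomial terms at the
respective expected fractions: `phi_S` at the maximum-likelihood
(clone, allele), `phi_G`, a residual error fraction `e_hom = 1e−3`, and
`1 − e_hom`.  We model the fourth, catch-all genotype as homozygous for
the variant allele: among the genotypes a biallelic site can take
beside AA, AB and somatic, BB is the one actually realized in data, and
placing its expected fraction between the het and somatic fractions
would absorb legitimate somatic calls.  Priors are Hardy–Weinberg in
the population B-allele frequency (alleles never observed in the
population panels get `1e−5` for SNVs, `1e−6` for indels), a somatic
prior `rho (1 + ω)` scaled by the hotspot observation count ω and gated
to zero when the population minor-allele frequency exceeds `2e−5`, and
a small constant `1e−4` for BB.  Posteriors are normalized by
log-sum-exp; labels require posterior ≥ 0.8 (configurable).

## Segmentation and copy number

Each sample's exon log2 depth ratios and common-het folded B-allele
fractions are segmented by recursive binary splitting with Welch-t
statistics and permutation p-values (199 permutations, split accepted
at p ≤ 0.01, minimum three points per side).  BAF series are folded at
0.5 so allele phase cannot create breakpoints.  Boundaries from all
samples and both data types are pooled, then pruned greedily: each
boundary's flanking segments are compared by Welch t-tests in all 2J
series, p-values combined by geometric mean (a series with fewer than
two observations on either side contributes p = 1), and the weakest
boundary removed (ties: leftmost) until all survivors fall below
`alpha_seg = 1e−5`.

Copy states are assigned per segment by exhaustive search over
N ∈ 0..8, M ∈ 0..⌊N/2⌋ and the clone index, maximizing a score that
averages the exon Poisson log-likelihoods and het beta-binomial
log-likelihoods within the segment (so long segments do not drown short
ones), weighted by copy-number priors
π(N=0..4, ≥5) = (0.01, 0.25, 0.3, 0.2, 0.15, 0.09) — the ≥5 mass
divided equally over 5..8 — and minor-copy priors
(0.25, 0.5, 0.25 over M=0, 1, ≥2).  Ties resolve to the smallest N,
then the largest M, then the lowest clone index, making assignment
deterministic and order-independent.  The sample-fraction-difference
prior enters the score only for copy-altered states: a copy-neutral
segment carries no alteration and hence no clone, and applying the
factor there lets the prior inflate some clone's fraction spread with
no data to oppose it (we observed exactly this failure mode — fitted
fractions drifting to the boundary on diploid data — before adopting
this rule).

## Fitting

Initialization: K = 2J + 1 clones — one main clone at `f^π`, J clones
clonal in one sample (0.05 elsewhere), J subclonal (half `f^π`, 0.01
elsewhere).  C maps the median tumor/control depth ratio to diploid;
W by method-of-moments on the allele-fraction overdispersion of
candidate hets (clamped to [10, 1e6]).

The objective is `Σ_g SLL_g + (1/Z) Σ_z log(π(Δf̄_kz) L_z) − J K λ`
with λ = 5 per degree of freedom.  Local optimization is Nelder–Mead on
transformed parameters (logit f, log W, log C), which enforces bounds
without constraints; the budget is 30 function evaluations per
parameter with loose tolerances (1e−3), adequate because every EM
iteration warm-starts from the previous optimum.  A macro-loop
alternates (1) re-centering — alternative C starting points at factors
0.5–2 — (2) adding clones, seeded by the best of 10 random trial
columns, accepted only on improvement, and (3) removing clones (the
best single-row deletion, re-optimized; segment clone indices are
remapped).  The loop stops after ξ = 3 consecutive macro-iterations
without a new maximum.  K is capped at 2J + 1 + 3.

The outer EM alternates copy-state assignment, joint classification and
parameter optimization, and stops when the call label vector repeats
between consecutive iterations (or after 20 iterations, returning the
best-scoring iterate with a warning).  All randomness flows from one
integer seed; identical seeds give byte-identical outputs.

## Quality filtering

A two-class quadratic discriminant scores each position per sample on
16 quality metrics (mapping/base qualities and their allele
differences, read-position, strand bias, soft-clipping, edit distance,
homopolymer context, control-panel behavior).  The metric set and the
training thresholds are this package's own defaults — they span the
artifact axes such filters must see, but they are not derived from any
published list and are fully configurable.  Training labels: PASS =
top quartile of mean standardized goodness with no metric in the bottom
decile; REJECT = bottom decile on ≥ 2 metrics.  A rule of "top quartile
on every metric simultaneously" degenerates as the metric count grows
(nothing qualifies at 16 weakly correlated metrics), hence the
composite.  The discriminant uses a trace-scaled covariance ridge
(1e−6) so constant or collinear metrics — which the A-allele-only
homozygous re-scoring produces by design — remain well-defined.
Per-sample PASS posteriors combine into a trust score (geometric mean
weighted by variant-supporting reads; invariant to weight rescaling);
positions at or below `T_pass = 0.8` are rejected.  SNVs and indels are
trained separately; homozygous calls are re-scored after classification
with difference metrics zeroed and B metrics replaced by their A
counterparts.

## Simulator

The simulator generates the study conditions used throughout the tests:
per site and sample, total depth ~ round(LogNormal) with the mean set
to the configured coverage times the purity-attenuated copy factor
`(N f + 2(1−f))/2` and σ = 0.5 on the log scale (an exome-like
dispersion; the value is a package default, configurable); variant
reads ~ Binomial(depth, phi) with phi from the expected-fraction
formulas.  Somatic variants are clonal (one clone at the sample
purities); germline sites are heterozygous.  Defaults are 1,000 somatic
and 10,000 germline sites per condition.  Non-diploid focal states are
placed on their own chromosome beside a diploid background chromosome
(copy alterations are focal in real genomes, and a genome in a single
altered state would leave C and N mutually unidentifiable).  Germline
sites are annotated as absent from population databases — the private
germline variant is the hard case; database-known hets are excluded
from somatic status by the frequency gate before any likelihood is
computed.  Quality metrics are emitted only on request (with an
optional planted artifact class); without them the trust filter is
neutral, isolating the statistical model.

What the simulator does not emulate: sequencing error in the alt count
(beyond the classifier's `e_hom`), mapping bias, FFPE damage,
multi-allelic sites, subclonal copy number, or correlated depth noise
along the genome.  Passing simulation tests therefore demonstrates the
statistical engine, not robustness to artifact-laden real data.

## Problem sizes and runtime choices

The bundled checks run the full pipeline at the stated condition sizes
(1,000 + 10,000 sites for the headline power claim; 200 + 2,000 per
cell for the power-surface comparisons; 100-replicate state-recovery
loops at 30 exons / 15 hets).  These sizes are the package's chosen
operating points for desk-scale reproduction; the pipeline itself has
no size limits.

## Known limitations

* One copy-number state per segment across samples; mixtures of altered
  states within a segment are not modelled.
* Segment boundaries and states are treated as known during
  classification; boundary uncertainty is not propagated.
* The somatic prior's sensitivity floor: very low-fraction subclonal
  variants are penalized by the large homozygous-reference prior.
* Single-sample (pooled) mode disables the sample-fraction-difference
  prior, which is undefined for J = 1.
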