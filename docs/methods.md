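# Methods

## The copying model

A target haplotype is reconstructed as a mosaic of a set of k donor
haplotypes. The hidden state at SNP l is the donor d ∈ {1..k} being
copied. The chain starts from the donor prior π (uniform by default);
across an inter-site genetic distance g (Morgans) it stays on the current
donor with probability exp(−Ne·g) and otherwise recombines to a donor
drawn afresh from π. Recombining back onto the same donor is allowed and
is *not* a segment boundary: expected chunk counts tally only transitions
that change donor identity (initial-state mass plus expected switch-in
transitions, computed from pairwise transition posteriors). The emission
probability is 1−Θ when the copied donor allele matches the target allele
and Θ when it mismatches; a missing allele on either side emits 1 (fully
uninformative).

Parameters, with units and defaults:

- **Ne** (dimensionless "recombination scaling constant"; default 267)
  multiplies Morgans, so it is the switch rate per Morgan. The default
  suits dense genome-wide human panels; it should be re-estimated whenever
  marker density or demography differs (the synthetic scenarios do).
- **Θ** (per-site miscopy/mutation probability; default 0.00043, valid
  range (0, 0.5)). A simple match/mismatch emission; no Watterson-style
  per-donor adjustment is attempted.
- **donor prior** (uniform by default). Group-level quantities aggregate
  haplotype-level expectations.

Forward–backward runs in linear space with per-site scaling; the log
scaling factors sum to the log-likelihood, and an exhaustive path-sum
oracle at L ≤ 4, k ≤ 3 agrees to ~1e-16 relative error. Per-site
posteriors integrate to expected copied sites; expected copied Morgans
weight each site by half its flanking inter-site intervals. A Viterbi path
is available as a debugging aid only; no downstream statistic uses it.

Zero inter-site genetic distances are floored at 1e-9 M when a map is
attached so transitions stay non-degenerate. Coordinates are 0-based
half-open internally, 1-based in VCF.

### EM estimation

(Ne, Θ) are estimated by expectation–maximization, independently for every
selected (population, chromosome) unit, each donor individual of the unit
painted leave-self-out against the full donor set. The E-step accumulates
expected mismatch emissions and expected recombination events; the M-step
sets Θ to the mismatch fraction and Ne to the root of
Σ_l (1 − exp(−Ne·g_l)) = E[switch intervals] (bracketed scalar solve; the
per-Morgan linearization is recovered in the sparse-switch limit). Final
parameters are arithmetic means over units; 10 iterations by default.
Parameter-recovery simulations (targets generated by the copying process
itself, Ne*=100, Θ*=0.01) recover both within a few percent.

## Donor clustering

Donor-vs-donor painting yields an individuals × individuals matrix X of
rounded expected chunk counts (self-column zero). Clusters of rows are
scored by the symmetric-Dirichlet marginal of their aggregated counts,
log B(x+β)/B(β) (per-row multinomial coefficients are partition-invariant
and omitted; including the *pooled* coefficient would spuriously reward
merges). β defaults to 1.0 and is configurable; the prior over partitions
is uniform on the number of clusters K (then uniform over partitions with
that K, via Stirling numbers of the second kind), with a flat alternative.

The posterior is explored by Metropolis–Hastings over set partitions with
three moves: single-individual reassignment (to any other cluster or a new
singleton), merge of a random cluster pair, and a uniform random binary
split, each with exact reverse-proposal correction. Likelihood deltas are
computed incrementally by rescoring only affected clusters (cross-checked
against from-scratch evaluation). Two independent chains run by default,
mirroring standard practice of extracting the best MAP state across runs;
desk-scale default is 50,000 iterations (the method's conventional run
length of millions is a config choice away). On 6-individual problems the
MAP matches exhaustive enumeration over all Bell(6)=203 partitions.

Columns of X are *not* re-aggregated by the evolving partition (fixed-
column approximation): this keeps the likelihood a proper product of
Dirichlet-multinomials and is the package's declared simplification
relative to full chunk-matrix re-aggregation.

Singleton clusters are removed from downstream donor sets. The cluster
tree is a greedy agglomeration merging the pair whose merge least
decreases the summed log marginal; heights record cumulative decreases.

## Mixture decomposition

The recipient target vector is the population mean of member individuals'
normalized copying vectors ("sites" weighting by default; "morgans"
available — the two coincide on uniform maps). The donor basis has one
column per non-singleton cluster, the mean member vector, optionally with
the own-cluster entry zeroed and renormalized.

The fit solves min ‖c − Cα‖₂ s.t. α ≥ 0 with the sum-to-one condition
imposed as a heavily weighted (λ=100) extra row of the least-squares
system before active-set NNLS, followed by exact renormalization; negative
numerical dust below 1e-12 is clamped first. The augmented system makes
the reported α effectively the simplex-constrained optimum — plain
renormalization of the unconstrained-sum solution can be visibly
suboptimal in fitted-vector norm when the target lies outside the basis
cone, and the implementation is held to a 0.001-step simplex grid search
within 1e-3.

**Surrogate masking**: masked coordinates are deleted from the target and
every basis column, all renormalized, before fitting; the masked clusters'
own columns remain available as components. Deletion+renormalization is
the default reading (zeroing without renormalization is the flag
alternative).

**Jackknife**: for each chromosome j the copying vectors are rebuilt from
the remaining chromosomes and the mixture refit; SE per cluster is
sqrt((n−1)/n · Σ_j (α_j − ᾱ)²), n = number of chromosomes (22 in the
reference configuration). Chromosomes are unweighted by default; SNP-count
weighting is a flag.

Individual-level decomposition applies the same fit per individual and
reports the population mean of individual solutions alongside the direct
population-level fit.

## Summaries

Cluster proportions aggregate through a cluster → region → continent map;
an unmapped cluster with positive weight is an error. Relative
within-continent composition renormalizes a continent's source proportions
to 1, excluding populations whose continent total is below `min_total`
(default 0.01 — populations with essentially no ancestry from a continent
carry no usable signal there, so their renormalized composition would be
noise).

Hierarchical clustering is Ward on Euclidean distances in the
squared-update ("ward.D2", as in SciPy) convention; populations are sorted
lexicographically first so merge ties break deterministically.

The bootstrap resamples *upstream of the fit*: each replicate rebuilds
every population of size n from n pseudo-individuals, each assembling, for
every chromosome, the painted chromosome of a member drawn uniformly with
replacement (both haplotypes of one member together by default;
independent haplotype resampling is a flag). Every replicate re-runs
mixture fit → continental aggregation → renormalization → Ward tree. The
consensus keeps clades recurring in strictly more than the support
threshold of replicates (default 0.8; "more than 80%" is a strict
inequality, verified at the exact 800/1000 boundary). Above 0.5 retained
clades are mutually compatible, so the consensus nests uniquely, possibly
multifurcating.

## Synthetic data: what it emulates and what it does not

Donor pools: per-population allele frequencies are Balding–Nichols beta
perturbations of shared ancestral frequencies (one divergence scalar F
controls donor distinguishability). Haplotypes optionally gain background
linkage through a within-population copying process (a few site-wise
founders, then mosaic copies at a switch rate per Morgan with a miscopy
probability) — without it, donor panels have no haplotype structure for a
copying HMM to exploit. Recipients are literal mosaics of donor
haplotypes: switch points are Poisson on the genetic map at rate
generations-per-Morgan, tract sources are i.i.d. from the admixture
proportions, and each tract copies one uniformly chosen donor haplotype
(per-site miscopy 0 by default). Ground-truth tracts tile each chromosome
exactly and are exported as TSV.

The reference scenario uses 22 chromosomes of 0.1 M carrying 1,000 SNPs,
20 donor haplotypes per population at F=0.15, background copying at
30/Morgan (miscopy 0.02, 4 founders), 20 recipients with α=(0.2, 0.3, 0.5)
admixed 20 generations ago. The 0.1-M chromosomes put ≈20 SNPs on an
average ancestry tract — the segment granularity of dense genome-wide
panels, scaled to desk size. The pipeline estimates its own (Ne, Θ) by EM
on one population × three chromosomes before painting, as the analysis
prescribes for unfamiliar marker densities. The surrogate variant adds a
fourth, independent, unadmixed population that is masked during fitting;
the generator has no shared-drift lineage model, so the surrogate's
"relatedness to an unsampled source" is played only by its masked role.

Not emulated: coalescent donor genealogies, mutation/genotyping error
models, phase-switch errors, unphased data, chromosome-length
heterogeneity, and realistic site-frequency spectra. Passing tests
therefore certify the inference machinery — likelihoods, estimators,
resampling — on data satisfying the model's assumptions, not robustness
to the violations real panels exhibit.

## Numerical and degenerate-input conventions

- Linear-space forward–backward with per-site scaling (not log-space);
  posteriors renormalized per site (≤1e-10 deviation checked).
- k=0 donors, empty donor sets after self-exclusion, empty EM subsets,
  single-chromosome jackknives, all-singleton partitions and zero-mass
  targets after masking all raise immediately with explicit messages.
- Call-rate filtering drops SNPs before samples (common practice; the
  order is otherwise unconstrained). Kinship pruning removes, from each
  pair above threshold, the member with more flagged pairs (ties: lower
  call rate, then lexicographic id) — a declared deterministic convention
  for the usual "remove one of each related pair" instruction, with the
  customary 0.0884 third-degree cutoff as default. Kinship coefficients
  are consumed from a table, never computed.
- MCMC non-convergence is reported via the trace, never raised.

## Known limitations

- The painting loops over sites in Python with vectorized donor axes;
  fine for ~10³–10⁴ sites × ~10² donors, not for biobank scale.
- The fixed-column chunk matrix and the simplified move set are
  approximations to full fineSTRUCTURE-style inference; hyperparameter
  (β) updates are not sampled.
- Copying vectors weight SNP count by default; genetic-length weighting
  is provided but the two differ on strongly non-uniform maps.
- The consensus operates on rooted clades (all trees share the Ward
  root); for the unrooted-bipartition reading this is equivalent up to
  the root split.
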