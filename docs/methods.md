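# Methods

## The model in brief

The pipeline treats a time-series expression study as a genes × conditions
matrix of replicate-averaged log2 signals and decomposes it by SVD,
`X = U diag(s) Vᵀ`. Each *eigensystem* k is the triple (eigenarray `U[:,k]`,
singular value `s[k]`, eigengene `V[:,k]`). Loadings are raw `U` entries —
the scale `s` cancels in every downstream use (correlations, signs, grouped
regression on a single eigensystem), and the unit-norm convention keeps
loadings comparable across systems of different size.

Conservation between two systems is a statement about eigenarrays: the
Pearson correlation of matched loading vectors over the genes the two
ANOVA-filtered datasets share. The test statistic is `t = r·√(d/(1−r²))`
with `d = n−2` degrees of freedom. At the sample sizes involved the
p-values underflow double precision, so the survival function is evaluated
in log space (`scipy.stats.t.logsf`); beyond the ~10⁻³²³ underflow of even
the log path, the tail switches to an arbitrary-precision evaluation of the
regularized incomplete beta representation, so a power of ten is always
reported. Whether `d` is n−2 or n changes none of the printed magnitudes at
these scales.

Matching is greedy one-to-one on |r|, which reproduces a dominant
one-to-one correspondence transparently; negative r sets a `sign_flip`
flag, since per-system SVD orientation is a gauge choice. The package's
convention orients each eigensystem so the largest-magnitude eigengene
entry is positive (ties broken by earliest condition), which makes outputs
reproducible but carries no biological meaning — "up" and "down" labels are
defined relative to it.

## Bayesian parent-set selection

Gene regulation within one conserved eigensystem's subspace is modelled as
a two-layer Bayesian network: binary composite-motif nodes, one binary
expression node (the sign of the gene's loading), all edges motif →
expression. Learning therefore reduces to scoring parent sets S:

* marginal likelihood: BDeu with equivalent sample size ESS (default 1);
  for q = 2^|S| parent configurations the pseudocounts are
  α_jc = ESS/(2q), and the likelihood factorises over configurations as a
  product of beta-function ratios;
* structure prior: ∝ κ^(Σ_{m∈S} size(m)), κ ∈ (0,1), where size(m) is the
  number of motif families in composite m;
* BN score: posterior(S) / posterior(∅), reported as log10.

Search is the two-step procedure: Step 1 scores every composite in the
universe (composites carried by ≥ 5 labelled genes; ties broken
lexicographically) as a singleton parent and keeps the top 120; Step 2
scores **every** subset of the pool of size ≤ 3 — with these defaults
~290 000 subsets, exact by construction. The hot path is a numba kernel
that accumulates single/pair/triple carrier counts from per-gene feature
lists and derives each subset's 2×2^k contingency table by
inclusion–exclusion, with log-gamma lookup tables; one full two-step search
over 2000 genes costs ~10 ms, which is what makes honest permutation nulls
affordable. A readable numpy implementation (`bde_score`) defines the
semantics and the kernel is tested against it.

**Penalty base κ = 0.1.** The prior's job is to stop the exact search from
decorating a true parent with lucky-noise composites. Because Step 2
searches a pool *pre-selected* for high marginal association, the relevant
noise scale is the maximum singleton gain over a universe of U ≈ 2000–3000
composites, roughly ½·χ²₁-quantile(1−1/U) ≈ 4–7 nats. κ = 0.1 prices one
extra motif family at 2.3 nats (a spurious triple at 6.9), matching that
scale; with a weaker penalty (e.g. κ = 0.5) the optimal set almost always
contains noise riders at realistic sample sizes. κ is exposed in
`BDeConfig`; q-value calibration does not depend on it because observed and
permuted searches use the same score.

**Permutation q-values.** For each of n_perm label permutations the full
two-step search is rerun (Step-1 pool re-selected under the permuted
labels) and the optimal BN score recorded; q(s) is the fraction of
permutation optima ≥ s. This is exceedance against a *max* null, so q is
automatically monotone in s and controls the family-wise error of "any
feature at q < α" at ~α, which the suite verifies empirically (the
fraction of pure-null datasets with any feature at q < 0.05 sits inside
the 99% binomial band around 0.05 at 200 datasets). Permutation streams
are keyed by (seed, permutation index).

**Cross-system validation.** Step-2 candidate pools for the observed runs
are the union of both systems' Step-1 selections, so any feature selected
on either system is scorable on both. The top ≤ 10 training features with
q < 0.05 are scored on the test system and assigned q-values from the
*test system's own* permutation null — the more stringent of the two
defensible conventions, and the one that lets a feature be significant in
one system only. Permutation nulls themselves use each system's own
two-step pools; the union applies to observed scoring only.

## Grouped weighted regression

Single-gene loadings are heavy-tailed, so inference uses group means:
genes grouped by exact integer count (no binning; singleton groups keep
weight 1 and an undefined SD), response = group mean loading, weights =
group sizes. Because group-mean variance is σ²/n_g, weighting by n_g is
exactly the right generalised-least-squares correction, and the
Goldfeld–Quandt test (lower/upper thirds of the count-ordered data, middle
excluded, one-sided F) documents the heteroskedasticity that motivates it.
Shapiro–Wilk on √w-scaled residuals is reported, never used as a gate.
Eligibility mirrors the counting semantics: motif-count regressors use
only genes with ≥ 1 CNS; CNS-count (and bivariate) regressions include
zero-CNS genes. The path analysis fits edges loading~CNS, loading~motif,
motif~CNS (univariate) and loading~CNS+motif (bivariate); a mediated
effect appears as a strong univariate CNS edge that collapses in the
bivariate fit.

Where a check asks whether a fitted slope is consistent with a planted
value or with zero, the package uses the fit's own t distribution
(df = groups − parameters): the 95% CI for "recovered", the t test at the
5% level for "no effect". With 5–12 groups the ±2·SE Gaussian shorthand
has only 88–93% coverage, so the exact small-sample form is the
defensible reading.

## The synthetic-data generator

`synthdata.simulate` emulates the data regime of a two-system rat brain
injury comparison: system A with 5 conditions (sham + 4 post-insult times),
system B with 2×5 treatment/control conditions, 3 replicates each,
~2000–2600 genes per system with ~30% overlap, and three planted shared
eigensystems.

Construction details that matter:

* **Exactly orthonormal planted eigenarrays with identical shared rows.**
  The shared gene block and each system-specific block are orthonormalised
  separately (QR) and scaled by √c and √(1−c) with
  c = n_shared/(n_shared + mean specific size), so each system's stacked
  loading matrix is exactly orthonormal while shared genes carry identical
  loadings. Eigensystem 1 is built magnitude-like — all-positive eigenarray,
  constant-in-time eigengene — so it *is* the baseline-expression component
  and the noise-free SVD recovers the planted singular values exactly
  (an additive offset outside the planted system would break that).
* **Default singular values (800, 60, 45)** at the ~2000-gene scale give a
  baseline of ~8 log2 units and per-gene responses up to ~2 log2 units
  (few-fold changes), with eigensystems 2–3 far enough above the
  replicate-noise floor (noise_sd 0.2 log2 units, a typical array
  replicate SD) that conserved eigenarrays correlate at |r| ≳ 0.97 across
  systems — clean but not trivial recovery.
* **Cis tables.** CNS count per gene ~ Poisson(2); families per CNS
  ~ 1+Poisson(2) over a 30-family alphabet; instances per conserved family
  per CNS ~ 1+Poisson(1.5) on each species track, the intensity implied by
  the emulated alignment database's census (~1.6 M rat instances over
  ~49 k CNSs, two thirds conserved); 20% decoy single-species instances
  exercise the conservation filter. The CNS-per-gene rate and family
  alphabet are scaled down (real censuses run ~5 CNSs/gene over 151
  families) to keep the composite universe in the low thousands; this
  shrinks counts and feature support, so planted effects are set at
  magnitudes recoverable at this scale.
* **Planted effects act on true loadings before expression synthesis**, so
  SVD re-estimation noise propagates honestly. Sign features resample the
  loading sign of carrier genes with the configured positive-sign odds
  (one draw per gene, shared across systems when planted in both). Count
  effects add β·count (default β 0.02 loading units per count — roughly one
  baseline loading SD per 1–2 instances). The antagonist pair (A, S)
  combines a count effect of A suppressed in S-carriers with a constant
  −0.015 loading offset for S-carriers; the offset gives S its marginal
  down-association (as the blocker's repressive role implies) while
  keeping the S-stratum slope on A-counts exactly zero and
  homoskedastic. True loadings are deliberately *not* re-orthonormalised
  after planting (that would rescale β); the orthonormal base eigenarrays
  are stored alongside them in the ground truth.

What the generator does **not** emulate: probe-level noise models and MAS5
internals (signals are lognormal around the planted mean), array batch
effects, real genomic sequence or alignment (coordinates are decorative),
correlated motif co-occurrence beyond shared CNS membership, and
expression-level (rather than sign/loading-level) regulatory mechanisms.
Passing tests therefore demonstrate that the *statistics* behave as
designed under the assumed data regime, not that the biology of any real
dataset will be as clean.

## Problem sizes used by scripts/acceptance.py

Anchor quantities are analytic (n = 737 common genes). Pipeline-level
quantities: one paired dataset of 2×2000 genes for conservation and
robustness; 60 null datasets × 200 permutations for q-value calibration;
10 seeds × 200 permutations for planted-feature recovery and
cross-validation; 10 seeds for the antagonist checks; 20 seeds for slope
recovery; 200 replicates for Goldfeld–Quandt calibration. The statistical
validation suite under `tests/` runs the same checks at larger counts
(200 null datasets, 20–40 recovery seeds). All seeds derive from the
`--seed` argument.

## Known limitations

* Exhaustive Step-2 search is exponential in `max_parents`; the
  implementation caps parents at 3 and pool sizes near 120 (≈3·10⁵
  subsets), which matches the method's design but cannot explore larger
  parent sets.
* The expression node is the *sign* of a loading; magnitude information
  enters only through the regression module.
* Zero loadings are excluded from labelling; with continuous data they are
  measure-zero but synthetic edge cases may drop genes.
* Greedy eigenarray matching can mis-pair eigensystems whose singular
  values nearly tie under heavy noise; the match report's full correlation
  grid is written so such cases are visible.
* q-values are computed per system and per eigensystem with no additional
  global correction, mirroring the per-model multiplicity accounting of
  the study design it implements.
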