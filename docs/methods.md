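# Methods

`sympnet` implements the contemporaneous symptom-network workflow used in
cross-sectional patient-reported-outcome studies: ordinal severity items are
summarized, clustered by exploratory factor analysis, modeled as a regularized
Gaussian graphical model, characterized by centrality and bridge indices,
stress-tested by bootstrap, and compared between subgroups by permutation.
This note records the models, the parameters that matter, and the design
choices made where the methodology is genuinely open.

## Data model

The pipeline input is an n × p matrix of integer severities on a 0–10 scale
(p ≥ 2 symptoms) plus categorical covariates. Rows with any missing symptom
item are excluded at load time and counted. Symptoms with occurrence
prevalence below a threshold (default 20%, strict comparison) are dropped
before clustering and network estimation: items endorsed by very few
participants carry almost no rank information and destabilize every
downstream estimate.

## Synthetic cohort generator

Every stage is testable without external data because the generator draws
cohorts from a fully specified latent Gaussian graphical model:

1. **Planted precision matrix.** Unit diagonal; each requested within-cluster
   or bridge partial correlation r contributes an off-diagonal entry −r;
   everything else is exactly zero. If the matrix is not positive definite it
   is repaired by eigenvalue clipping (floor 1e−8) and rescaling to unit
   diagonal; if the repair moves any requested partial correlation by more
   than 1e−6 the offending edges are reported as an error rather than
   silently altered.
2. **Latent draws.** Multivariate normal with the correlation matrix implied
   by the precision; covariate levels are drawn independently per covariate
   (binary by prevalence, or multinomial for ordinal covariates) and shift
   latent means per symptom, linearly in the coded level.
3. **Ordinal mapping.** A single latent variable drives both occurrence and
   severity: severity is 0 below the (1 − prevalence)-quantile of the
   *marginal* standard normal, and the upper tail is cut into
   `severity_max` equal-probability bins giving severities 1..10. This
   preserves the monotone latent–severity link that a Spearman-based network
   model assumes, and makes covariate shifts alter observed prevalence and
   severity jointly, as they would in practice. Prevalence 0 and 1 are exact
   (all-zero / never-zero columns), not errors.

The default `study_like_config()` encodes the reference cohort the package
emulates: n = 249; 19 symptoms with the published occurrence fractions (two of
them — drowsiness at 12.4% and cough-with-blood at 15.3% — below the
prevalence filter); four clusters (respiratory, gastrointestinal, emotional,
neuro-perceptual); within-cluster partial correlations 0.18; bridges
sadness–fatigue 0.40, sadness–cough 0.25, sadness–nausea 0.22, ranked after
the reference study's strongest reported associations; and covariate latent
shifts sized so the regression screen reproducibly flags gender, smoking
history and education as network confounders. For the published sadness row,
whose occurrence count and printed percentage disagree, the count-derived
value (203/249) is used.

**What the generator does not emulate.** Real severity distributions are
strongly right-skewed; equal-probability bins are symmetric on the latent
scale, so synthetic total scores run higher (≈63 ± 26 versus ≈31 ± 16 in the
reference cohort). Covariates are independent of one another by default (no
gender × smoking structure), and there is no item-specific measurement error
beyond discretization. Passing tests therefore demonstrate recovery of
*planted rank structure* under ordinal thresholding — not calibration to any
particular real severity histogram.

## Symptom clusters

Exploratory factor analysis in its classical survey form: eigendecomposition
of the Pearson correlation matrix of raw scores (a config switch allows
Spearman; Pearson is the default because the rank-based machinery is reserved
for the network stage), retention of components with eigenvalue > 1, varimax
rotation, and assignment of each symptom to the factor carrying its largest
absolute rotated loading provided |loading| > 0.5; symptoms failing the gate
are listed unassigned, and factors with fewer than two assigned symptoms
raise a report warning. Varimax iterates pairwise planar rotations with
Kaiser normalization (on by default) until the raw varimax criterion changes
by < 1e−10 or 1000 sweeps; factor sign is fixed by forcing each factor's
largest-|loading| entry positive. Sampling adequacy: KMO from the anti-image
partial correlations of the scaled inverse correlation matrix, and Bartlett's
sphericity test χ² = −(n − 1 − (2p+5)/6)·ln det R with p(p−1)/2 df.

## Network estimation

Edges are partial correlations from an L1-penalized precision matrix:

- **Input:** Spearman rank correlations (average ranks for ties), the
  standard choice for ordinal severities; if the matrix is not positive
  definite it is repaired by eigenvalue clipping and rescaling, with a
  metadata flag.
- **Solver:** graphical lasso by block coordinate descent over the working
  covariance, penalty on off-diagonal entries only, convergence when the
  largest parameter change in a sweep is below 1e−6 (error after 10,000
  sweeps). At λ = 0 the solver converges to the plain inverse; this is the
  oracle anchor of the test suite. The core is numba-compiled so bootstrap
  and permutation loops run thousands of re-estimations per minute.
- **Selection:** λ path of 100 log-spaced values (20 inside resampling
  loops) from λ_max = max |off-diagonal correlation| down to 0.01·λ_max;
  EBIC(λ) = −2ℓ(Ω̂) + E·log n + 4·E·γ·log p with
  ℓ = (n/2)(log det Ω̂ − tr(S Ω̂)) and E the edge count; default γ = 0.5.
  The likelihood is that of the *penalized* estimate — no refitting.

A consequence worth knowing: with strong true edges the EBIC minimum drifts
to small λ because reducing shrinkage bias on strong edges buys more
likelihood than the per-edge penalty costs, so a few small spurious edges
enter and specificity plateaus around 0.75–0.85 even at n = 2000. This is a
property of penalized-likelihood EBIC selection generally, not of this
implementation (the solver matches an independent implementation to 5e−4 and
the exact inverse at λ = 0 to 1e−6). The support-recovery benchmark is
therefore run in the boundary-signal regime (planted |pcor| = 0.1 at
n = 2000, |pcor|·√n ≈ 4.5), where selection rather than shrinkage decides the
graph; there sensitivity and specificity both exceed 0.9.

Covariates (binary 0/1; education as ordinal 0/1/2) enter the Spearman matrix
directly as extra nodes, yielding the covariate-adjusted network; subgroup
comparisons use symptom-only networks by default (config-exposed).

## Node indices

- **Strength:** sum of absolute incident edge weights.
- **Closeness:** inverse of the summed shortest-path distance (edge length
  1/|w|), computed within a node's connected component and multiplied by
  (component size − 1)/(p − 1) to penalize isolation; a flag switches to the
  inverse-average convention, which multiplies every value by the constant
  (p − 1) and leaves rankings unchanged. Isolated nodes score 0.
- **Betweenness:** standard Brandes accumulation, fractional credit for tied
  shortest paths, unnormalized.
- **Bridge strength:** sum of absolute weights to symptom nodes in *other*
  clusters; covariate nodes carry no bridge value and do not contribute.
- **Predictability:** R² of each node's OLS regression on its network
  neighbors. This deliberately simplifies the mixed-graphical-model nodewise
  fit to a Gaussian linear one — ordinal severities are treated as
  continuous — which is accurate in the latent-linear regime the generator
  defines (it matches the precision-matrix identity R² = 1 − 1/(ω_ii σ_ii)
  within 0.02 at large n) but is an approximation for real data.

## Stability and accuracy

Nonparametric row-resampling bootstrap (default B = 1000; the pipeline
default uses 250 for desk-scale runtime) yields percentile CIs per edge —
percentile rather than BCa, the convention of the field's stability tooling.
Because the lasso shrinks edges toward zero, nominal 95% intervals cover
*true* generator weights at roughly 88–99%, not 95%; the suite asserts that
band rather than pretending exactness. Case-dropping bootstrap re-estimates
the network on subsamples of size n(1−q) for q = 0.05..0.75 (step 0.05) and
records the Pearson correlation with the full-sample centrality vector; the
CS coefficient is the largest q such that every tested q′ ≤ q keeps at least
95% of replicates at correlation ≥ 0.7 (0.25 acceptable, > 0.5 ideal, by the
standard interpretation). Pairwise bootstrap difference tests flag pairs
whose difference CI excludes zero, with no multiplicity correction
(exploratory, as conventional) and a 1e−5 floor so solver-level numerical
asymmetries are never reported as differences. All resampling derives
per-replicate RNGs from a single seed, so results are identical for any
worker count.

## Between-group comparison

The permutation network comparison test estimates both group networks with
identical settings and computes M (largest absolute edge difference), S
(absolute difference of global strengths, each edge counted once), and
per-edge differences E. Group labels are permuted over pooled rows
preserving group sizes, both networks re-estimated per permutation, and
two-tailed p-values computed with the add-one rule
p = (1 + #{perm ≥ obs})/(1 + n_perm), which cannot return zero. Edge
p-values are Benjamini–Hochberg adjusted across the edges nonzero in either
observed network (an `all` option tests every pair). The two groups are
ordered canonically (by size, then a content digest) before pooling, making
every statistic and p-value exactly invariant under swapping the arguments.
Default n_perm = 1000; simulation at the suite's scale (200 replicates,
n_perm = 200) puts the M-test's type-I error at ≈0.05.

## Problem sizes used by the shipped checks

Unit and property tests run at n = 150–2000 with p = 6 fixtures and the
n = 249, p = 19 study-like cohort; the acceptance script runs the full
pipeline at n = 249 (case-dropping B = 100, NCT n_perm = 500), the recovery
benchmark at n = 2000 × 20 seeds, and the permutation-size simulation at 100
replicates × 200 permutations. These sizes are the package's own desk-scale
defaults; every one is a config knob.

## Known limitations

- Exact reproduction of the reference study's numbers requires its deposited
  participant-level file; without it the suite verifies the same quantity
  surface on synthetic cohorts under design-implied assertions.
- Polychoric correlations are not implemented; Spearman on 0–10 scores
  attenuates latent associations when zero-inflation is heavy.
- Predictability is Gaussian-OLS, not a mixed graphical model.
- No survey weighting, imputation, oblique rotation, temporal or directed
  networks.
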