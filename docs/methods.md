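# Methods

## Problem and approach

`netla` asks a localization question about machine-learning models fit on
functional connectomes: given a model that predicts a phenotype (here,
chronological age) from all edges of a parcellated resting-state
functional-connectivity (rsFC) matrix, *which network blocks* — the edge
sets within one functional network or between a pair of networks — carry
the association? Rather than refitting a model per block (whose accuracy
mostly reflects feature count), the package fits one connectome-wide model
and then performs enrichment-style inference on its edge-level weight map.

The pipeline is:

1. **Edges.** With `P` parcels there are `E = P(P-1)/2` edges (lower
   triangle of the correlation matrix, row-major order). Edge values are
   Fisher-z transformed Pearson correlations `z(r) = atanh(r)` between
   parcel time courses; `|r|` is clipped at `1 - 1e-7` so degenerate
   perfect correlations stay finite.
2. **Edge-level weight maps**, one scalar per edge, from any of four
   estimation methods: marginal Pearson correlation with age (`pearson`);
   linear support vector regression on the k marginally strongest edges
   (`pearson_fs_lsvr`); LSVR on all edges, raw weights (`lsvr`); or the
   Haufe-inverted LSVR (`lsvr_inverted`), i.e. the sample covariance of
   each edge with the model's predicted age. The inversion converts the
   backward (decoder) model into an interpretable forward pattern: for any
   linear model the activation pattern is `a ∝ Σ_x w`, realized here as
   `a_e = cov(x_e, ŷ)` with `1/(n-1)` normalization. Raw decoder weights
   can load heavily on suppressor features that carry no outcome-related
   signal; the inverted pattern sends those to zero.
3. **Resampled fitting.** Models are fit over J repetitions of an
   80/20 train/test split, either ignoring family structure (RS1) or
   assigning whole families to one side only (RS2). The LSVR's L2 penalty
   parameter is tuned per repetition by 5-fold inner cross-validation
   (family-grouped under RS2) minimizing mean validation MSE, ties going to
   the smaller (more regularized) value. Features are z-scored with
   training-set statistics only; accuracy is summarized by Pearson r, MAE
   and MSE (1/n) on the held-out set, and weight maps are averaged across
   repetitions before enrichment.
4. **Enrichment.** The mean weight map is Z-scored across edges,
   thresholded at `|Z| > 2` and binarized; per block a 1-df chi-square
   compares the observed strong-edge count against the uniform expectation
   from the margins (no continuity correction; a hypergeometric upper-tail
   test is the alternative). Family-wise error over the `B = N(N+1)/2`
   blocks is controlled by an age-shuffling permutation null with the
   max-statistic rule and add-one p values,
   `p = (1 + #{max null chi2 >= observed}) / (J_perm + 1)`.
   Functional networks are never shuffled, preserving the covariance
   structure of the data.
5. **Reliability and comparison.** Cross-day reliability of block calls is
   the Matthews correlation coefficient of the two days' significance
   masks (defined 0 when a marginal is empty); edge-level stability is the
   overlap percentage (fraction of per-repetition thresholded masks in
   which an edge is strong, over both days); predicted-age reliability is
   ICC(2,1) (two-way random effects, absolute agreement, single measure)
   computed from the two cross-day models' predictions; and models are
   compared with the corrected resampled t-test, whose variance term
   `(1/J + n_test/n_train)·var(d)` accounts for overlapping resamples,
   with Bonferroni adjustment across comparisons (alpha/6 = 0.00833 for
   all pairs of four methods).

The individual-block counter-analysis (`block_analysis`) fits one model
per block and contrasts its test-r distribution against a permuted-age
null (summarized by an add-one p on the mean observed r, and by Cohen's d
with pooled n-1 SD) and against models on equally many randomly drawn
edges from outside the significant blocks. The latter null is the
decisive one: block models typically do not beat size-matched random
feature sets, which is why whole-connectome enrichment is preferred for
biological interpretation.

## Synthetic cohorts

Restricted in-vivo data are not required: `netla.synthetic` generates
family-structured, two-day cohorts with planted block-level age effects.
The additive model for subject `s`, edge `e`, day `d` is

    x[s,e,d] = mu[e] + beta[block(e)]·age_std[s] + u[family(s)] + v[s]
               + eps[s,e] + w[s,e,d]

with independent zero-mean Gaussians: family intercept `u` (SD
`family_sd`), subject intercept `v` (`subject_sd`) — both scalars shared
across edges and days — a subject-by-edge component `eps` stable across
days (`edge_sd`), and day-specific noise `w` (`day_sd`). The per-day noise
SD around the age effect is the quadrature sum of the four components;
splitting the edge-level noise into a stable and a day-specific part makes
test-retest reliability tunable through `day_sd` alone. An optional
per-block family effect (`per_block_family_effect`) gives each family a
block-wise connectome signature, emulating heritability; the scalar
intercept alone spans a single direction in edge space and cannot support
family-identity memorization.

Ages cluster within families: a family mean is drawn uniformly over the
configured range (default 22–35 years) and members deviate by
N(0, 1.5 y), clipped to the range. This mirrors young-adult twin/sibling
cohorts, where family members are close in age, and it is the mechanism
by which family-ignorant resampling (RS1) leaks information: a model that
partially memorizes a family's connectome signature can read a test
subject's age off a training sibling. With fully independent ages
(`within_family_age_sd = inf`) the shared variance is pure noise and the
RS1/RS2 gap vanishes.

Defaults: `family_sd = subject_sd = day_sd = edge_sd = 0.1` (z(r) units;
per-edge, per-day noise SD = 0.2, half of the subject-level variance shared
within families), baseline mean 0.25, 100 families of 1–3 members. The
helper `beta_for_target_r` converts a target edge-age correlation into the
block slope via `r = beta/sqrt(beta^2 + s^2)` with `s` the total noise SD.

What the generator deliberately omits: spatial autocorrelation between
parcels, nonlinear age effects, motion or scanner confounds, and
heavy-tailed noise. Passing tests therefore demonstrate the statistical
machinery (calibration, recovery, directional effects) under a clean
linear-Gaussian connectome, not robustness to real acquisition artifacts.

## Numerical and design choices

- **Edge order** is fixed to lower-triangle row-major (`e = i(i-1)/2 + j`,
  `j < i`); network blocks are enumerated `(1,1), (1,2), …, (N,N)` with
  `a <= b`. An "unspecified" network is an ordinary network in block
  enumeration (13 networks -> 91 blocks).
- **LSVR**: scikit-learn `LinearSVR`, epsilon-insensitive loss with fixed
  `epsilon = 0.1`; only the L2 penalty parameter is tuned, over a
   7-point logarithmic grid `1e-4 … 1e2`. Feature standardization uses
  train statistics (inner-train statistics inside the inner CV). Grid and
  standardization are package defaults, documented here because no
  canonical values exist.
- **Permutation null fits**: one model fit per permutation, on a
  family-grouped 80% subsample with all ages shuffled, so null maps carry
  sampling variability comparable to a single observed fit
  (`perm_inner_reps` raises the per-permutation averaging to mirror
  observed-map averaging at proportional cost). LSVR null fits reuse the
  penalty chosen on the observed data unless `tune_each_permutation` is
  set; re-tuning inside every permutation multiplies cost ~36-fold for no
  observed change in calibration.
- **Feature-selected maps** are Z-scored over selected edges only;
  unselected edges are never strong. k-best ties break to the lower edge
  id. Zero-variance edges keep weight 0 rather than being dropped,
  preserving `E` for map alignment.
- **Degenerate inputs**: constant weight maps, constant ages, zero total
  variance in ICC, and zero pooled SD in Cohen's d raise errors;
  `K = 0` (no strong edges) yields chi2 = 0, p = 1; an MCC with an empty
  marginal is defined as 0.
- **Repetition seeds** are counter-based (`default_rng([master, j])`), so
  any repetition or permutation can be reproduced in isolation and results
  are invariant to how work is batched.
- **Cross-day ICC pairing**: the two days' resampling draws are
  independent, so per repetition only subjects in both test sets receive
  one prediction from each day's model; those pairs are pooled over
  repetitions into a single ICC(2,1).

## Problem sizes

Statistical checks run at reduced but honest scale, chosen so the full
suite completes on one CPU in minutes: calibration and recovery cohorts
use P=60 parcels in 6 networks (1,770 edges, 21 blocks) with ~300 subjects
in 150 two-member families (100 null replicates x 200 permutations for
family-wise error calibration; 50 replicates for planted-block recovery);
directional model comparisons use P=30 (435 edges) with 180 subjects and
50 repetitions. The corresponding full-size configuration (`scale: full`,
333 parcels, 13 networks, 1,000 repetitions and permutations) is the same
code path.

## Known limitations

- Accuracy of the `pearson` method is undefined (it is a forward
  association map, not a predictor); its entries feed enrichment only.
- The corrected resampled t-test uses the nominal 80/20 counts even when
  family grouping perturbs exact split sizes; the correction factor is a
  first-order approximation.
- The permutation FWER is exchangeability-based: it assumes ages are
  exchangeable across subjects under the null, which family-structured
  ages violate mildly (ages are shuffled across, not within, families).
- Blocks with very few edges yield coarse chi-square statistics; the
  hypergeometric alternative is exact but one-sided (enrichment only).
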