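# Methods

## Model

MT-SCCAR couples, per imaging modality m, a sparse canonical correlation
analysis (SCCA) between a genotype matrix `X` (n subjects × p SNPs) and an
imaging QT matrix `Y_m` (n × q ROIs) with a linear regression of the
imaging projection `Y_m v_m` onto each cognitive score `z_c`:

```
min_{U,V}  Σ_m Σ_c ||Y_m v_m − z_c||² + Σ_m ||X u_m − Y_m v_m||²
           + λ_v1 ||V||_{2,1} + λ_v2 ||V||_{1,1}
           + λ_u1 ||U||_{2,1} + λ_u2 ||U||_{1,1} + λ_u3 ||U||_G
s.t.       ||X u_m||² = ||Y_m v_m||² = 1  ∀ m.
```

Assumptions worth making explicit:

- Associations are **linear and low-rank**: each task seeks one canonical
  direction pair; disease heterogeneity beyond a single latent axis is not
  modeled.
- Columns of `X` and every `Y_m` are **standardized** (mean 0, sd 1,
  ddof=1) and cognitive scores mean-centered before fitting: the
  unit-variance projection constraints and cross-view products presume
  comparable column scales. `assemble_dataset`/the generator do this by
  default; `scale=False` switches it off.
- The L2,1 coupling on `V` (and `U`) requires all modalities to share the
  same ROI dimension q with aligned rows; datasets with differing q per
  modality are rejected.
- The regression term deliberately breaks the sign gauge of (u_m, v_m):
  without it the objective is invariant to jointly flipping a column pair's
  sign; supervision anchors the sign to the cognitive scores.

## Optimization

Each norm is handled by iterative reweighting: `|w|` is majorized by
`w²/(2(|w_prev|+ε)) + const`, giving diagonal weight matrices

- `D_v1[i] = 1/(2(||V_{i,:}||₂+ε))`, `D_v2^{(m)}[i] = 1/(2(|v_im|+ε))`,
- `D_u1`, `D_u2` analogously on `U`, and
- `D_u3[i] = 1/(2(||U_{g_k,:}||_F+ε))` for `i ∈ g_k` (constant within each
  SNP group).

With diagonals frozen, the v half-step of task m solves

```
((γ_v + 2) G_m + λ_v1 D_v1 + λ_v2 D_v2^{(m)}) v = Σ_c Y_m'z_c + Y_m'X u_m
```

and the u half-step solves

```
((γ_u + 1) G + λ_u1 D_u1 + λ_u2 D_u2^{(m)} + λ_u3 D_u3) u = X'Y_m v_m,
```

followed in each case by rescaling onto the unit-variance constraint. The
γ terms are the constraint multipliers (fixed to 1; they mainly set the
weight amplitude) and are excluded from the reported objective value, which
tracks the modeled loss and penalties only.

### Curvature choice (`cov_mode`)

`G`/`G_m` is the curvature matrix of the smooth part. Two options are
implemented:

- `"identity"` (default): `G = I`. For standardized columns the Gram
  matrix has unit diagonal, and replacing it by the identity is the
  customary simplification in this family of constrained SCCA solvers; the
  half-steps become diagonal (closed-form), which is fast and — more
  importantly — spreads shrinkage evenly across correlated features.
- `"exact"`: the full Gram matrices `X'X`, `Y_m'Y_m`, solved as symmetric
  positive-definite systems (never by forming an inverse).

The default matters scientifically. When the latent signal is strong, the
columns carrying it are highly collinear, and the exact-curvature fixed
point concentrates weight on a few representatives of the collinear block —
the classic lasso-on-correlated-features behavior, amplified by the
reweighting. On the reference synthetic design this caps the sign-aligned
correlation between estimated and true loadings near 0.7 regardless of λ,
while the identity-curvature solver recovers the loadings nearly perfectly
(correlation ≈ 0.99, support F1 = 1.0 at λ = 0.1). An SVD benchmark
(top right-singular vector, correlation ≈ 0.95) confirms the data support
the higher figure. Both modes satisfy their own fixed-weight surrogate
stationarity conditions exactly; the test suite checks the exact mode
against independent dense solves.

### Regression curvature (`regression_hessian`)

The gradient of `Σ_c ||Y v − z_c||²` contributes `C·Y'Yv`, but the standard
update rule for this model carries the term once, giving the aggregate
`(γ_v+2)G` above. Both behaviors are available: `"printed"` (default,
curvature entered once) and `"derived"` (`(γ_v+1+C)G`). With the default
single cognitive score the two coincide.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `lambda_u1`, `lambda_v1` | 0.1 | cross-task L2,1 sparsity weight |
| `lambda_u2`, `lambda_v2` | 0.1 | element-wise L1,1 sparsity weight |
| `lambda_u3` | 0 | SNP group-lasso weight; requires a group map |
| `gamma_u`, `gamma_v` | 1 | constraint multipliers (amplitude control) |
| `eps` | 1e-6 | smoothing inside every reweighting denominator |
| `max_iter` | 200 | iteration cap |
| `tol` | 1e-5 | max-abs weight-change stopping threshold (both U and V) |

All λ are dimensionless (data are standardized). The 0.1 defaults are the
values a nested five-fold grid search over `{10⁻³,…,10³}` selects on the
reference synthetic design at unit noise; they are a starting point, and
real analyses should re-tune with `nested_grid_search` (mean inner-fold
testing CCC, averaged over tasks and inner folds, is the selection
criterion; per-fold selections and the full grid trace are returned).
`lambda_u3` defaults to off because the group penalty is only meaningful
with gene/LD-block information; supplying an empty group map gives tagSNP
mode (every SNP its own group), in which the group penalty coincides with
the L2,1 row penalty.

Initialization is deterministic by default (constant vectors rescaled onto
the constraints), so identical inputs give bit-identical fits; a seeded
random initialization is available. Convergence is judged on the
post-normalization weight changes; the objective trace is recorded for
diagnostics but monotone decrease is not asserted — the rescaling step can
break monotonicity of the surrogate descent.

## Synthetic data generator

The generator emulates a three-stage disease course driving all views
through one latent vector `l`: subjects split into three equal classes with
latent centers −5, 0, 5 (unit within-class sd); then

```
X = l u' + E,   Y_m = l v_m' + E,   c = l + e,
```

all noise entries iid `N(0, σ²)` with σ² swept over 1..10. Loading vectors
carry one contiguous nonzero block covering 20 % of their length, with
magnitudes uniform in [0.5, 1] and a single random sign per block; supports
are recorded so recovery (sign-aligned correlation, support F1 at a 10 %
of-max magnitude threshold) is well defined. Default dimensions are n=90,
p=100, q=90, M=2, one cognitive score.

What the generator does **not** emulate: discrete 0/1/2 genotype values,
allele-frequency spectra and linkage disequilibrium, spatial correlation
among ROIs, covariate effects, or missingness. Passing recovery tests on
this design therefore demonstrates correctness of the estimator under the
stated latent-factor model, not performance on real genotype/imaging data.

A companion group-structure generator partitions SNP indices into
contiguous blocks either aligned with the true support (the signal block is
one group) or deliberately misaligned, for positive and negative tests of
the group penalty.

## Evaluation protocol

- CCC is the Pearson correlation of `X u_m` and `Y_m v_m`; a zero-variance
  projection is an error (degenerate weights), never silently 0.
- Cross-validation folds are stratified by class label when labels exist
  (synthetic data) and plain shuffled K-fold otherwise; scaling parameters
  are learned on training folds and applied to test folds.
- The noise sweep fixes the penalty weights (defaults) across noise levels
  and reuses one set of ground-truth loadings per replicate so only the
  noise level varies; failed fits are recorded as missing cells.
- Top-feature tables rank by absolute canonical weight, either per task
  (top ROIs per modality) or after averaging absolute weights across tasks
  (top SNPs); ties break by feature id, deterministically.

Problem sizes used by the test suite and `scripts/acceptance.py`: recovery
is averaged over 10 simulation seeds; the noise sweep runs 10 replicates ×
10 noise levels × 5 folds; the high-noise model comparison uses 60
replicates at σ² = 10, because the supervised model's advantage there is
small (≈ 3×10⁻⁴ CCC) and more replicates are needed to resolve it above
Monte-Carlo error. At this noise range both models remain close to the CCC
ceiling; their separation grows at noise variances beyond 10 and at larger
penalty weights.

## Numerical and degenerate-input choices

- `ε = 1e-6` guards every reweighting denominator; a zero row yields a
  finite (large) weight rather than an infinite one.
- Exact-mode systems are solved with an SPD factorization; a singular
  system raises a numerical error advising larger penalties or ε.
- Non-finite iterates abort with the iteration index.
- Zero-variance data columns, duplicate ids, conflicting group
  assignments, rank-deficient covariates and misaligned subjects are hard
  errors at load/validation time.
- Covariate adjustment (least-squares residualization on an intercept plus
  covariates) is applied to the full matrix before any train/test split;
  with cross-validated evaluation this leaks a small amount of covariate
  information across folds — acceptable for nuisance covariates such as
  age and sex, but worth noting.

## Limitations

- One canonical component pair per task; no deflation for further
  components.
- The CCC ceiling of the synthetic design is high even at σ² = 10, so
  model differences there are small; conclusions about relative robustness
  at extreme noise rest on the documented replicate counts.
- The three-view (genotype–imaging–cognition) symmetric SCCA alternative
  and downstream classification/regression analyses are out of scope.
- No GPU or out-of-core support; dense in-memory linear algebra only.
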