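# mtsccar

Supervised multi-task sparse canonical correlation analysis with regression
guidance (MT-SCCAR) for brain imaging genetics.

## The problem

Imaging-genetics studies ask which genetic variants (SNPs, additively coded
0/1/2) are associated with which imaging quantitative traits (QTs — e.g.
per-ROI gray-matter density from MRI and SUVR from amyloid/FDG PET), and
whether those associations track disease severity as measured by cognitive
scores (MMSE, ADAS-Cog, ...). Plain two-view sparse CCA handles one imaging
modality at a time and ignores the cognitive outcome. MT-SCCAR treats each
imaging modality as one learning task sharing the genotype view, and steers
the imaging projections toward the cognitive scores with a multi-task
linear regression term, so the selected SNP–ROI patterns are both
cross-modal and clinically relevant.

## The model

Given genotypes `X ∈ R^{n×p}`, imaging QTs `Y_m ∈ R^{n×q}` for modalities
`m = 1..M`, and cognitive scores `z_c ∈ R^n`, MT-SCCAR solves

```
min_{U,V}  Σ_m Σ_c ||Y_m v_m − z_c||²  +  Σ_m ||X u_m − Y_m v_m||²
           + λ_v1 ||V||_{2,1} + λ_v2 ||V||_{1,1}
           + λ_u1 ||U||_{2,1} + λ_u2 ||U||_{1,1} + λ_u3 ||U||_G
s.t.       ||X u_m||² = 1,  ||Y_m v_m||² = 1   for every task m,
```

where column `u_m` (`v_m`) holds the SNP (ROI) canonical weights of task m.
The L2,1 norms couple tasks (a feature is kept or dropped jointly across
modalities), the L1,1 norms give element-wise sparsity, and `||U||_G` is a
group-lasso penalty over SNP groups (genes or LD blocks; singleton groups =
tagSNP mode). Setting the regression term to zero yields the unsupervised
MTSCCA baseline.

The solver alternates iteratively-reweighted half-steps: each non-smooth
norm is majorized by a quadratic with diagonal weights `1/(2(|w|+ε))`
recomputed from the previous iterate, each half-step reduces to a linear
solve, and each weight column is rescaled onto its unit-variance projection
constraint. Iteration stops when `max|Δu| ≤ 1e-5` and `max|Δv| ≤ 1e-5`.
Performance is measured by the canonical correlation coefficient
(CCC = Pearson corr of `X u_m` and `Y_m v_m`), with penalty weights tuned
by nested five-fold cross-validation over `{10⁻³, …, 10³}`.

## Worked example

Simulate the reference synthetic design (90 subjects in three latent
classes with centers −5/0/5, 100 SNPs, two 90-ROI modalities, unit noise),
fit, and rank ROIs:

```
$ mtsccar simulate --outdir demo --seed 1
simulated n=90 p=100 q=90 M=2 sigma2=1.0 seed=1 -> demo

$ mtsccar fit --outdir demo/fit --genotypes demo/genotypes.tsv \
    --modality demo/modality1.tsv --modality demo/modality2.tsv \
    --cognitive demo/cognitive.tsv
fit converged after 37 iterations; training CCC per task: 0.9953, 0.9953

$ mtsccar evaluate --weights demo/fit/qt_weights.tsv --top-k 5 --outdir demo/eval
task  rank feature   weight
mod1     1  roi021 0.007176
mod1     2  roi012 0.007155
...
```

The fit converges in 37 iterations under the `1e-5` weight-change rule; the
per-task training CCC of 0.995 says the genotype and imaging projections of
each modality are almost perfectly correlated at unit noise. The ranked
table lists each modality's ROIs by absolute canonical weight — on this
synthetic dataset the top entries fall inside the true signal block
recorded in `demo/truth.json`. Real studies swap the simulated TSVs for a
genotype matrix (TSV or PLINK `.raw`), per-modality ROI tables, a cognitive
score table, and optionally covariates (`--covariates`, residualized out of
the QTs) and a SNP group map (`--groups`, enabling `--lambda-u3`).

`mtsccar cv` runs the nested grid search, and `mtsccar sweep` reproduces
the noise-robustness experiment (testing CCC under noise variances 1..10
for MT-SCCAR and the MTSCCA ablation).

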