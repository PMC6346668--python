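# cddnet

Copula directional dependence (CDD) networks for multivariate time
series, designed for fMRI region-of-interest (ROI) signals.

Functional connectivity measures such as correlation are undirected, and
lag-based directed measures (Granger causality, VAR coefficients) are
unreliable at fMRI sampling rates: subsampling a VAR(1) by a factor `L`
turns its coefficient matrix into `A^L`, which can reverse every
cause-effect arrow.  CDD takes a different route: it reads direction from
the *asymmetry of the joint distribution* of two signals, which survives
subsampling.  For copula-scale variables `(U, V)` (each series mapped
through its empirical CDF) the directional dependence is

    rho2_{U->V} = Var( E[V | U] ) / Var(V),        Var(V) = 1/12,

the share of `V`'s variance explained by regressing on `U` on the copula
scale, modeled by a logit-link beta regression
`logit(mu_t) = beta0 + beta1 u_t`, `V_t ~ Beta(mu_t kappa, (1-mu_t) kappa)`.
The sign of `delta = rho2_{U->V} - rho2_{V->U}` defines the inferred
direction; an ordinary nonparametric bootstrap (100 replicates, basic 95%
CI) decides whether the direction is significant.  A whole-brain analysis
estimates all directed pairs, Fisher-transforms the scores
(`z = atanh(rho2)`), fits a half-normal-null mixture, and prunes edges
with local FDR >= 0.2; degree centralities of the pruned digraph and the
CDD strengths feed nonparametric group tests (Kruskal-Wallis, quantile
ANOVA, robust two-way ANOVA on medians).

The package also ships the two validation simulators for the method: an
asymmetric copula (product of two Plackett copulas with powered
arguments) pushed through a Gaussian-HRF BOLD measurement model, and a
three-region subsampled VAR(1) with independent / correlated-normal /
asymmetric-copula noise.  See `docs/methods.md` for the full model
descriptions and numerical choices.

## Worked example

Direction recovery on the subsampled VAR with asymmetric-copula noise -
the setting where lag-based inference points the wrong way:

```python
import cddnet as c

spec = c.VARSpec(
    A=c.cyclic_var_matrix(),            # influences 2->1, 3->2, 1->3
    noise_model="asymmetric",
    copula_spec=c.AsymCopulaSpec(theta1=5000, theta2=5, alpha=0.7, beta=0.3),
    n=10000, L=5,                       # 1-in-5 subsampling, as in fMRI
)
y = c.simulate_var(spec, seed=5)
res = c.bootstrap_direction(y[:, 0], y[:, 1], n_boot=100, seed=7)
print(f"rho2 y1->y2 = {res.rho2_uv:.3f}")
print(f"rho2 y2->y1 = {res.rho2_vu:.3f}")
print(f"delta = {res.delta:+.4f}  (95% CI {res.ci_lower:+.4f} .. {res.ci_upper:+.4f})")
```

prints

```
rho2 y1->y2 = 0.139
rho2 y2->y1 = 0.149
delta = -0.0099  (95% CI -0.0215 .. +0.0018)
```

Both directional dependences are around 0.14-0.16 (the pair is
correlated at about 0.42), and `delta < 0` points to `y2 -> y1`: the
direction carried by the noise asymmetry, not the one a lag-based model
would infer from the subsampled data.  Across repeated simulations the
sign is negative in roughly three quarters of datasets; the bootstrap CI
quantifies how decisive any single dataset is (here it is suggestive but
not significant at 95%).

The same machinery scales to a full region set:

```sh
cddnet simulate-var --model 3 --n 10000 -L 5 --seed 1 --out series.csv
cddnet estimate --in series.csv --nboot 100 --seed 1 --out cdd.csv
cddnet network --in cdd.csv --fdr-threshold 0.2 --out edges.tsv --degrees degrees.csv
cddnet run --in my_roi_series.csv --out-dir results/   # full pipeline
```

`cddnet roi-extract` reduces a preprocessed 4-D NIfTI volume to an ROI
series table by averaging 5x5x5-voxel cubes at MNI coordinates (a
14-region bilateral cortical table is built in), and
`cddnet groupstats` runs the nonparametric group-difference tests given
per-participant outcomes and a design table.

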