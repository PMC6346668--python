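"""Nonparametric group-difference tests for network and dependence outcomes.

Degree centralities and dependence strengths across participants are
skewed and heavily tied, so group comparisons use rank- and quantile-based
procedures:

* Kruskal-Wallis rank-sum test (one factor);
* one-way quantile ANOVA: Harrell-Davis quantile estimates compared with a
  centered percentile-bootstrap null, robust to ties;
* robust two-way ANOVA on cell medians with McKean-Schrader standard
  errors and Johansen-type chi-square statistics for the two main effects
  and their interaction;
* Pearson chi-square test of independence for the design table.

No multiple-comparison correction is applied by default (every p-value is
reported); an optional Benjamini-Hochberg adjustment is available in the
batch runner.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kruskal_wallis",
    "harrell_davis",
    "quantile_anova",
    "median_two_way_anova",
    "chi_square_independence",
    "batch_group_tests",
]


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    levels = pd.unique(labels)
    groups = [values[labels == lev] for lev in levels]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    return levels, groups


def kruskal_wallis(outcome, factor):
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df."""
    _, groups = _split_groups(outcome, factor)
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        raise ValueError("all values identical: rank test is untestable")
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def harrell_davis(x, q: float = 0.5) -> float:
    """Harrell-Davis estimator: a smooth, beta-weighted average of order stats."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    a, b = (n + 1) * q, (n + 1) * (1 - q)
    grid = np.arange(n + 1) / n
    w = np.diff(stats.beta.cdf(grid, a, b))
    return float(w @ x)


def quantile_anova(
    outcome,
    factor,
    q: float = 0.5,
    n_boot: int = 2000,
    seed: int | None = None,
):
    """One-way quantile ANOVA with a percentile-bootstrap null.

    The observed statistic is the size-weighted dispersion of the
    Harrell-Davis group quantiles around their weighted mean; the null
    distribution is obtained by resampling within groups and centering each
    bootstrap quantile at its observed value (so the resampled statistic
    reflects no quantile differences).  Returns the bootstrap p-value.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    _, groups = _split_groups(outcome, factor)
    if any(len(g) < 5 for g in groups):
        raise ValueError("each group must have at least 5 observations")
    rng = np.random.default_rng(seed)

    sizes = np.array([len(g) for g in groups], dtype=float)
    wts = sizes / sizes.sum()
    qhat = np.array([harrell_davis(g, q) for g in groups])

    def dispersion(est: np.ndarray) -> float:
        center = float(wts @ est)
        return float(np.sum(sizes * (est - center) ** 2))

    t_obs = dispersion(qhat)

    t_null = np.empty(n_boot)
    boot_q = np.empty((n_boot, len(groups)))
    for j, g in enumerate(groups):
        n = len(g)
        a, b = (n + 1) * q, (n + 1) * (1 - q)
        w = np.diff(stats.beta.cdf(np.arange(n + 1) / n, a, b))
        samples = rng.choice(g, size=(n_boot, n), replace=True)
        samples.sort(axis=1)
        boot_q[:, j] = samples @ w
    centered = boot_q - qhat  # deviations: quantile-difference signal removed
    for bidx in range(n_boot):
        t_null[bidx] = dispersion(centered[bidx])
    p = (1.0 + np.sum(t_null >= t_obs)) / (n_boot + 1.0)
    return float(p)


def _mckean_schrader_var(x: np.ndarray) -> float:
    """Squared McKean-Schrader standard error of the sample median."""
    y = np.sort(x)
    n = len(y)
    z995 = stats.norm.ppf(0.995)
    av = int(round((n + 1) / 2 - z995 * np.sqrt(n / 4)))
    av = max(av, 1)
    top = n - av + 1
    return float(((y[top - 1] - y[av - 1]) / (2 * z995)) ** 2)


def _diff_matrix(k: int) -> np.ndarray:
    d = np.zeros((k - 1, k))
    d[np.arange(k - 1), np.arange(k - 1)] = 1.0
    d[np.arange(k - 1), np.arange(1, k)] = -1.0
    return d


def median_two_way_anova(outcome, factor_a, factor_b):
    """Robust two-way ANOVA on cell medians.

    Cell medians with McKean-Schrader squared standard errors enter
    Johansen-type quadratic forms for the row effect, the column effect and
    the interaction, each referred to its asymptotic chi-square null.
    Returns ``(p_a, p_b, p_interaction)``.
    """
    outcome = np.asarray(outcome, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (len(outcome) == len(factor_a) == len(factor_b)):
        raise ValueError("outcome and factors must have equal length")
    lev_a = pd.unique(factor_a)
    lev_b = pd.unique(factor_b)
    J, K = len(lev_a), len(lev_b)
    if J < 2 or K < 2:
        raise ValueError("both factors need at least two levels")

    med = np.zeros((J, K))
    var = np.zeros((J, K))
    for j, a in enumerate(lev_a):
        for k, b in enumerate(lev_b):
            cell = outcome[(factor_a == a) & (factor_b == b)]
            if len(cell) < 5:
                raise ValueError(f"cell ({a!r}, {b!r}) has fewer than 5 observations")
            med[j, k] = np.median(cell)
            var[j, k] = _mckean_schrader_var(cell)

    theta = med.ravel()
    v = np.diag(var.ravel())
    ones_j = np.full((1, J), 1.0 / J)
    ones_k = np.full((1, K), 1.0 / K)
    dj, dk = _diff_matrix(J), _diff_matrix(K)

    def quad_p(contrast: np.ndarray, df: int) -> float:
        est = contrast @ theta
        cov = contrast @ v @ contrast.T
        stat = float(est @ np.linalg.solve(cov, est))
        return float(stats.chi2.sf(stat, df))

    p_a = quad_p(np.kron(dj, ones_k), J - 1)
    p_b = quad_p(np.kron(ones_j, dk), K - 1)
    p_ab = quad_p(np.kron(dj, dk), (J - 1) * (K - 1))
    return p_a, p_b, p_ab


def chi_square_independence(table):
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.round(table)) or np.any(table < 0):
            raise ValueError("table must hold nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total: independence test undefined")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def batch_group_tests(
    outcomes: pd.DataFrame,
    design: pd.DataFrame,
    tests=("kw", "qanova", "med2way"),
    factors=("age_group", "gender"),
    n_boot: int = 2000,
    seed: int | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """One row of p-values per outcome column, for each test x factor.

    ``outcomes`` has one column per node/edge statistic and one row per
    participant; ``design`` carries the factor columns.  All p-values are
    reported (no correction) unless ``bh_adjust`` adds Benjamini-Hochberg
    adjusted columns.
    """
    if len(outcomes) != len(design):
        raise ValueError("outcomes and design must have one row per participant")
    ss = np.random.SeedSequence(seed)
    rows = []
    for name in outcomes.columns:
        vals = outcomes[name].to_numpy(dtype=float)
        row: dict = {"outcome": name}
        if "kw" in tests:
            for fac in factors:
                try:
                    _, _, p = kruskal_wallis(vals, design[fac].to_numpy())
                except ValueError:
                    p = np.nan
                row[f"kw_{fac}"] = p
        if "qanova" in tests:
            for fac in factors:
                child = ss.spawn(1)[0]
                try:
                    p = quantile_anova(
                        vals, design[fac].to_numpy(), n_boot=n_boot, seed=child
                    )
                except ValueError:
                    p = np.nan
                row[f"qanova_{fac}"] = p
        if "med2way" in tests and len(factors) == 2:
            try:
                pa, pb, pab = median_two_way_anova(
                    vals, design[factors[0]].to_numpy(), design[factors[1]].to_numpy()
                )
            except ValueError:
                pa = pb = pab = np.nan
            row[f"med2way_{factors[0]}"] = pa
            row[f"med2way_{factors[1]}"] = pb
            row["med2way_interaction"] = pab
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        for col in out.columns:
            if col == "outcome":
                continue
            p = out[col].to_numpy(dtype=float)
            mask = np.isfinite(p)
            adj = np.full_like(p, np.nan)
            if mask.any():
                adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
            out[f"{col}_bh"] = adj
    return out
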