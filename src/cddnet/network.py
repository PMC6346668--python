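"""Directed connectivity networks pruned by a local false discovery rate.

Every directed dependence rho2_{U->V} is Fisher z-transformed
(z = atanh(rho2), nonnegative) and the collection of scores over all
ordered region pairs is modeled as a two-group mixture

    f(z) = eta * f0(z; sigma) + (1 - eta) * fA(z),

where the null component f0 is a half-normal with scale sigma (the
sampling distribution of the transformed score when the true dependence is
zero).  sigma is estimated by censored maximum likelihood on the central
body of scores, eta from the null mass at the censoring cutoff, and the
mixture density f by a Grenander (monotone) estimator.  The local FDR of
an edge is eta * f0(z) / f(z), capped at one; edges with fdr >= 0.2 (the
default threshold) are pruned from the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FDRFit",
    "ConnectivityNetwork",
    "fisher_z",
    "fit_local_fdr",
    "build_network",
    "degree_table",
    "write_edge_list",
    "write_graphml",
]

#: density assigned to exactly tied scores (zero-width Grenander segments)
_TIE_DENSITY = 1e12


def fisher_z(rho2):
    """Fisher z-transform atanh(rho2) of a dependence score in [0, 1)."""
    rho2 = np.asarray(rho2, dtype=float)
    if np.any((rho2 < 0) | (rho2 >= 1)):
        raise ValueError("fisher_z requires values in [0, 1)")
    out = np.arctanh(rho2)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class FDRFit:
    """Fitted two-group mixture over transformed dependence scores.

    ``eta`` is the null proportion, ``sigma`` the half-normal null scale,
    ``fdr_scores`` the per-edge local FDR (monotone non-increasing in z,
    capped at one).  ``f_grid``/``f_hat`` tabulate the Grenander mixture
    density estimate.
    """

    eta: float
    sigma: float
    cutoff: float
    z_values: np.ndarray
    fdr_scores: np.ndarray
    f_grid: np.ndarray
    f_hat: np.ndarray


def _halfnormal_logpdf(z: np.ndarray, sigma: float) -> np.ndarray:
    return np.log(2.0) + stats.norm.logpdf(z, scale=sigma)


def _halfnormal_pdf(z, sigma: float):
    return 2.0 * stats.norm.pdf(z, scale=sigma)


def _halfnormal_cdf(z, sigma: float):
    return special.erf(np.asarray(z) / (sigma * np.sqrt(2.0)))


def _censored_sigma(z: np.ndarray, cutoff: float) -> float:
    """ML scale of a half-normal truncated to [0, cutoff], from z <= cutoff."""
    body = z[z <= cutoff]
    body = body[body > 0]
    if len(body) < 5:
        body = z[z > 0]
    scale0 = np.sqrt(np.mean(body**2))

    def negll(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        ll = np.sum(_halfnormal_logpdf(body, sigma))
        ll -= len(body) * np.log(max(_halfnormal_cdf(cutoff, sigma), 1e-300))
        return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(np.log(scale0) - 5, np.log(scale0) + 5), method="bounded"
    )
    return float(np.exp(res.x))


def _grenander(z: np.ndarray):
    """Grenander estimator of a non-increasing density on [0, inf).

    Returns ``(knots, heights)``: the density equals ``heights[i]`` on the
    interval ``(knots[i], knots[i+1]]``.  Exactly tied scores would give a
    zero-width segment with infinite slope; those are represented by a large
    finite density.
    """
    n = len(z)
    zu, cnt = np.unique(z, return_counts=True)
    if zu[0] == 0.0:
        # exact zeros would make a zero-width first step; nudge them
        zu = zu.copy()
        zu[0] = 1e-12 if len(zu) == 1 else min(1e-12, zu[1] / 2)
    x = np.concatenate([[0.0], zu])
    w = np.concatenate([[0.0], cnt / n])
    # least concave majorant of the cumulative points via a slope hull
    hull_x = [x[0]]
    hull_f = [0.0]
    cum = 0.0
    for xi, wi in zip(x[1:], w[1:]):
        cum += wi
        hull_x.append(xi)
        hull_f.append(cum)
        # pool while slopes increase (concavity violated)
        while len(hull_x) >= 3:
            s1 = _slope(hull_x[-3], hull_f[-3], hull_x[-2], hull_f[-2])
            s2 = _slope(hull_x[-2], hull_f[-2], hull_x[-1], hull_f[-1])
            if s2 > s1:
                del hull_x[-2], hull_f[-2]
            else:
                break
    knots = np.asarray(hull_x)
    heights = np.array(
        [_slope(hull_x[i], hull_f[i], hull_x[i + 1], hull_f[i + 1]) for i in range(len(hull_x) - 1)]
    )
    return knots, heights


def _slope(x0, f0, x1, f1) -> float:
    dx = x1 - x0
    if dx <= 0:
        return _TIE_DENSITY
    return min((f1 - f0) / dx, _TIE_DENSITY)


def _grenander_eval(knots: np.ndarray, heights: np.ndarray, q: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(knots, q, side="left") - 1
    idx = np.clip(idx, 0, len(heights) - 1)
    return heights[idx]


def _kernel_density(z: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Boundary-corrected (reflected) Gaussian kernel density on [0, inf)."""
    kde = stats.gaussian_kde(np.concatenate([z, -z]))
    return 2.0 * kde(q)


def fit_local_fdr(z_values) -> FDRFit:
    """Fit the half-normal-null mixture and per-score local FDR.

    Requires at least 20 nonnegative scores.  The null scale sigma is
    estimated by censored ML below the 75th percentile of the scores, then
    refined once with the cutoff moved to 2.5 sigma (a point enclosing
    ~99% of null mass); eta is the fraction of observed mass below the
    cutoff relative to the null mass there.  The mixture density uses the
    Grenander monotone estimator (reflected kernel estimate when n < 50),
    and the fdr curve is regularized to be non-increasing in z by a running
    maximum taken from the largest score downward, which only raises
    scores and so never un-prunes an edge.
    """
    z = np.asarray(z_values, dtype=float)
    if z.ndim != 1 or len(z) < 20:
        raise ValueError("need at least 20 scores")
    if np.any(z < 0):
        raise ValueError("scores must be nonnegative")
    if np.all(z == 0):
        raise ValueError("all scores are zero: degenerate fit")

    cutoff = float(np.quantile(z, 0.75))
    if cutoff <= 0:
        cutoff = float(np.max(z)) * 0.5
    sigma = _censored_sigma(z, cutoff)
    cutoff = float(min(2.5 * sigma, np.max(z)))
    sigma = _censored_sigma(z, cutoff)

    frac_below = float(np.mean(z <= cutoff))
    null_mass = float(_halfnormal_cdf(cutoff, sigma))
    eta = float(min(1.0, frac_below / max(null_mass, 1e-12)))

    if len(z) >= 50:
        knots, heights = _grenander(z)
        f_at_z = _grenander_eval(knots, heights, z)
        grid = np.linspace(0.0, float(np.max(z)), 201)
        f_grid = _grenander_eval(knots, heights, grid)
    else:
        f_at_z = _kernel_density(z, z)
        grid = np.linspace(0.0, float(np.max(z)), 201)
        f_grid = _kernel_density(z, grid)

    raw = eta * _halfnormal_pdf(z, sigma) / np.maximum(f_at_z, 1e-300)
    raw = np.minimum(raw, 1.0)
    order = np.argsort(z, kind="stable")
    mono_sorted = np.maximum.accumulate(raw[order][::-1])[::-1]
    fdr = np.empty_like(raw)
    fdr[order] = mono_sorted

    return FDRFit(
        eta=eta,
        sigma=sigma,
        cutoff=cutoff,
        z_values=z,
        fdr_scores=fdr,
        f_grid=grid,
        f_hat=f_grid,
    )


# ---------------------------------------------------------------------------
# network construction


@dataclass
class ConnectivityNetwork:
    """Directed graph over regions with CDD weights and pruning metadata.

    ``edges`` has one row per directed (ordered) region pair with columns
    ``source, target, rho2, z, fdr, kept, dominant, direction_significant``;
    ``graph`` contains only the kept edges.
    """

    graph: nx.DiGraph
    edges: pd.DataFrame
    fdr_fit: FDRFit
    fdr_threshold: float

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


def build_network(
    cdd_matrix: pd.DataFrame,
    pair_results: pd.DataFrame | None = None,
    fdr_threshold: float = 0.2,
) -> ConnectivityNetwork:
    """Prune a matrix of directed dependences into a connectivity network.

    ``cdd_matrix`` is square and labeled, with entry (i, j) holding
    rho2_{i->j} (the diagonal is ignored).  One mixture fit is made over all
    directed entries and edges with local fdr >= ``fdr_threshold`` are
    removed.  For each unordered pair, the direction with the larger
    dependence is flagged ``dominant``; if ``pair_results`` (the output of
    :func:`cddnet.cdd.estimate_all_pairs` with bootstrap columns) is given,
    the dominant direction is marked significant when the basic bootstrap
    CI for the difference excludes zero.
    """
    if not (0.0 < fdr_threshold < 1.0):
        raise ValueError("fdr_threshold must lie in (0, 1)")
    mat = cdd_matrix.astype(float)
    if list(mat.index) != list(mat.columns):
        raise ValueError("cdd_matrix must be square with matching labels")
    labels = list(mat.columns)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two regions")

    sources, targets, rho2 = [], [], []
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            val = mat.iat[i, j]
            if not np.isfinite(val):
                raise ValueError(f"missing dependence value for {a}->{b}")
            sources.append(a)
            targets.append(b)
            rho2.append(val)
    rho2 = np.asarray(rho2)
    z = fisher_z(rho2)
    fit = fit_local_fdr(z)
    kept = fit.fdr_scores < fdr_threshold

    edges = pd.DataFrame(
        {
            "source": sources,
            "target": targets,
            "rho2": rho2,
            "z": z,
            "fdr": fit.fdr_scores,
            "kept": kept,
        }
    )

    # dominant direction per unordered pair (larger rho2 wins; ties keep both)
    fwd = edges.set_index(["source", "target"])["rho2"]
    dominant = [
        r >= fwd.loc[(t, s)] for s, t, r in zip(edges.source, edges.target, edges.rho2)
    ]
    edges["dominant"] = dominant

    signif = np.zeros(len(edges), dtype=bool)
    if pair_results is not None and {"lb", "ub"}.issubset(pair_results.columns):
        ci = {}
        for row in pair_results.itertuples(index=False):
            excl = np.isfinite(row.lb) and np.isfinite(row.ub) and (row.lb > 0 or row.ub < 0)
            ci[(row.region_u, row.region_v)] = excl
            ci[(row.region_v, row.region_u)] = excl
        signif = np.array(
            [
                dom and ci.get((s, t), False)
                for s, t, dom in zip(edges.source, edges.target, edges.dominant)
            ]
        )
    edges["direction_significant"] = signif

    graph = nx.DiGraph()
    graph.add_nodes_from(labels)
    for row in edges.itertuples(index=False):
        if row.kept:
            graph.add_edge(
                row.source,
                row.target,
                rho2=float(row.rho2),
                fdr=float(row.fdr),
                direction_significant=bool(row.direction_significant),
            )
    return ConnectivityNetwork(
        graph=graph, edges=edges, fdr_fit=fit, fdr_threshold=fdr_threshold
    )


def degree_table(network: ConnectivityNetwork) -> pd.DataFrame:
    """Per-node in-, out- and total degree over the kept edges."""
    g = network.graph
    rows = [
        {
            "node": node,
            "in_degree": g.in_degree(node),
            "out_degree": g.out_degree(node),
            "total_degree": g.in_degree(node) + g.out_degree(node),
        }
        for node in g.nodes
    ]
    return pd.DataFrame(rows)


def write_edge_list(network: ConnectivityNetwork, path) -> None:
    """Write the full directed edge table as TSV."""
    network.edges.to_csv(path, sep="\t", index=False)


def write_graphml(network: ConnectivityNetwork, path) -> None:
    """Export the pruned graph (kept edges only) as GraphML."""
    nx.write_graphml(network.graph, path)
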