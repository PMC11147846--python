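"""Graph-centrality reproduction analysis.

FC matrices are thresholded at a significance level on the correlation
coefficients (two-sided t test with T_effective - 2 degrees of freedom),
negative surviving edges are removed, and degree, eigenvector and PageRank
centralities are computed per node. The question asked here: how much of
the variance in individual subjects' node centralities is explained by the
cross-validated *training-average* centralities — i.e. does a predictor
need to know anything about the subject to reproduce FC network structure?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .core import Cohort, ConnectivityMatrix, FoldAssignment

MEASURES = ("degree", "eigenvector", "pagerank")


@dataclass(frozen=True)
class CentralityConfig:
    """alpha = 0.0001 on the edge correlation coefficients is the
    conventional threshold for FC graph analyses; T_effective is the scan
    length the null distribution assumes (1200 ~ one concatenated
    resting-state session)."""

    alpha: float = 0.0001
    T_effective: int = 1200
    binarize_degree: bool = True
    pagerank_damping: float = 0.85
    two_sided: bool = True

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.T_effective < 4:
            raise ValueError("T_effective must be at least 4")


def critical_r(alpha: float, T_effective: int, two_sided: bool = True) -> float:
    """Critical |r| for a Pearson correlation test at level alpha with
    df = T_effective - 2, via inversion of t = r sqrt(df / (1 - r^2))."""
    df = T_effective - 2
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    t = stats.t.ppf(q, df)
    return float(t / np.sqrt(df + t**2))


def threshold_fc(fc, cfg: CentralityConfig | None = None) -> np.ndarray:
    """Zero out edges that fail the significance threshold, then remove
    surviving negative edges. Returns a plain array (no longer a valid
    correlation matrix). Warns if no edge survives."""
    cfg = cfg or CentralityConfig()
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    r_crit = critical_r(cfg.alpha, cfg.T_effective, cfg.two_sided)
    out = v.copy()
    out[np.abs(out) < r_crit] = 0.0
    out[out < 0] = 0.0
    np.fill_diagonal(out, 0.0)
    if not out.any():
        warnings.warn("no edge survived the significance threshold (empty graph)")
    return out


def centralities(thresholded: np.ndarray, cfg: CentralityConfig | None = None) -> dict:
    """Degree, eigenvector and PageRank centrality per node.

    Degree is computed on the binarized graph by default (edge presence);
    eigenvector and PageRank use the surviving positive weights. On a
    disconnected graph, eigenvector centrality is computed on the largest
    connected component with zeros elsewhere (flagged by a warning);
    PageRank is defined on any graph and sums to 1 before rescaling.
    """
    cfg = cfg or CentralityConfig()
    W = np.asarray(thresholded, dtype=float)
    p = W.shape[0]
    out = {}
    adj = (W > 0).astype(float)
    out["degree"] = adj.sum(axis=1) if cfg.binarize_degree else W.sum(axis=1)

    G = nx.from_numpy_array(W)
    if W.any():
        components = list(nx.connected_components(G))
        giant = max(components, key=len)
        ev = np.zeros(p)
        if len(components) > 1:
            warnings.warn(
                "graph is disconnected; eigenvector centrality computed on "
                "the largest component, zeros elsewhere"
            )
        sub = G.subgraph(giant)
        if len(giant) == 2:
            # leading eigenvector of a single weighted edge: uniform on the
            # two endpoints (unit L2 norm, matching the numpy routine)
            for node in giant:
                ev[node] = 1.0 / np.sqrt(2.0)
        elif len(giant) > 2:
            evc = nx.eigenvector_centrality_numpy(sub, weight="weight")
            for node, val in evc.items():
                ev[node] = val
        out["eigenvector"] = ev
        pr = nx.pagerank(G, alpha=cfg.pagerank_damping, weight="weight")
        out["pagerank"] = np.array([pr[i] for i in range(p)])
    else:
        out["eigenvector"] = np.zeros(p)
        out["pagerank"] = np.full(p, 1.0 / p)  # PageRank of the empty graph
    return out


def standardize_centralities(values: np.ndarray) -> np.ndarray:
    """z-score across the full concatenation, then map linearly onto
    [-1, 1] (min -> -1, max -> 1). Order-preserving; errors on constants."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("centrality values are constant; standardization undefined")
    z = (v - v.mean()) / v.std()
    return -1.0 + 2.0 * (z - z.min()) / np.ptp(z)


def subject_centralities(cohort: Cohort, cfg: CentralityConfig | None = None) -> dict:
    """Each subject's node centralities from their thresholded eFC; returns
    {measure: (n_subjects, p) array}."""
    cfg = cfg or CentralityConfig()
    per = {m: [] for m in MEASURES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in cohort:
            c = centralities(threshold_fc(s.efc, cfg), cfg)
            for m in MEASURES:
                per[m].append(c[m])
    return {m: np.vstack(v) for m, v in per.items()}


def centrality_variance_explained(
    cohort: Cohort, folds: FoldAssignment, cfg: CentralityConfig | None = None
) -> dict:
    """Variance in individual node centralities explained by the
    cross-validated training-average centralities.

    Per measure: each validation subject's predicted node centralities are
    the per-node means over that fold's training subjects; empirical and
    predicted values are concatenated over all subjects and nodes,
    standardized (z-score then [-1, 1] rescale — a monotone linear map, so
    it does not affect the correlation), and the squared Pearson
    correlation is reported.
    """
    cfg = cfg or CentralityConfig()
    emp = subject_centralities(cohort, cfg)
    out = {}
    for m in MEASURES:
        E = emp[m]
        P = np.empty_like(E)
        for f, train, val in folds.folds():
            P[val] = E[train].mean(axis=0)
        e = standardize_centralities(E.ravel())
        q = standardize_centralities(P.ravel())
        out[m] = float(np.corrcoef(e, q)[0, 1] ** 2)
    return out
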