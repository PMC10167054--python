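"""Functional/effective connectivity and weighted graph metrics.

Functional connectivity (FC) is the Pearson correlation between channel
or region HbO2 time courses over the concatenated task blocks (window
selectable). Effective connectivity (EC) is pairwise Granger causality
between region means: for each ordered pair the F-statistic of the lagged
source terms in the full vs. reduced autoregression, with the lag order
chosen by BIC. Graph metrics follow weighted brain-network practice:
negative weights zeroed, weights normalized to [0, 1], Onnela weighted
clustering (cube-root triangle intensity), and local/global efficiency
from shortest paths on distance = 1/weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .fnirs import HemoSignal, REGIONS

__all__ = [
    "ConnectivityMatrix",
    "GraphMetrics",
    "functional_connectivity",
    "effective_connectivity",
    "pairwise_granger",
    "graph_metrics",
    "compare_matrices",
    "fisher_z",
]


@dataclass
class ConnectivityMatrix:
    """Square connectivity matrix with p-values and an FDR significance mask."""

    values: np.ndarray
    nodes: list[str]
    kind: str  # "functional" | "effective"
    pvals: np.ndarray
    qvals: np.ndarray
    mask: np.ndarray  # True where the estimate is defined and FDR-significant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.nodes, columns=self.nodes)


@dataclass
class GraphMetrics:
    """Weighted network summary of an FC matrix."""

    clustering: np.ndarray  # per node
    local_efficiency: np.ndarray  # per node
    global_efficiency: float
    nodes: list[str]
    region_clustering: dict[str, float] = field(default_factory=dict)
    region_local_efficiency: dict[str, float] = field(default_factory=dict)


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def _pearson_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix of columns with two-sided p-values from the t
    transform; constant columns yield NaN."""
    n, k = X.shape
    sd = X.std(axis=0)
    ok = sd > 0
    r = np.full((k, k), np.nan)
    if ok.sum() >= 1:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, np.nan)
    return r, p


def _fdr_mask(p: np.ndarray, q: float, symmetric: bool) -> tuple[np.ndarray, np.ndarray]:
    """BH correction over the off-diagonal family; returns (qvals, mask)."""
    k = p.shape[0]
    if symmetric:
        iu = np.triu_indices(k, 1)
        fam = p[iu]
    else:
        off = ~np.eye(k, dtype=bool)
        fam = p[off]
    qvals = np.full_like(p, np.nan)
    mask = np.zeros_like(p, dtype=bool)
    finite = np.isfinite(fam)
    if finite.any():
        rej = np.zeros(fam.size, dtype=bool)
        qv = np.full(fam.size, np.nan)
        rej[finite], qv[finite], *_ = multipletests(fam[finite], alpha=q, method="fdr_bh")
        if symmetric:
            qvals[iu] = qv
            mask[iu] = rej
            qvals.T[iu] = qv
            mask.T[iu] = rej
        else:
            qvals[off] = qv
            mask[off] = rej
    return qvals, mask


def functional_connectivity(
    hemo: HemoSignal,
    scope: str = "channel",
    window: str = "task",
    q: float = 0.05,
) -> ConnectivityMatrix:
    """Pearson FC between node time courses over the chosen window.

    ``scope`` is ``channel`` (valid channels) or ``region`` (mean of each
    region's valid channels); ``window`` is ``task`` (concatenated task
    blocks), ``rest``, ``relaxation`` or ``session``.
    """
    if scope == "channel":
        X = hemo.hbo2
        nodes = [e["name"] for e in hemo.layout]
        node_valid = hemo.valid.copy()
    elif scope == "region":
        X, nodes = hemo.region_means()
        node_valid = np.ones(len(nodes), dtype=bool)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if node_valid.sum() < 2 and scope == "channel":
        raise ValueError("need at least 2 valid nodes")

    if window != "session":
        sel = hemo.timeline.mask(window, hemo.rate)[: X.shape[0]]
        if not sel.any():
            raise ValueError(f"timeline has no {window!r} samples")
        X = X[sel]

    r, p = _pearson_matrix(X)
    # invalid channels masked, never dropped: NaN rows/columns
    if scope == "channel" and not node_valid.all():
        r[~node_valid, :] = np.nan
        r[:, ~node_valid] = np.nan
        p[~node_valid, :] = np.nan
        p[:, ~node_valid] = np.nan
    qvals, mask = _fdr_mask(p, q, symmetric=True)
    return ConnectivityMatrix(values=r, nodes=nodes, kind="functional",
                              pvals=p, qvals=qvals, mask=mask)


# ---------------------------------------------------------------------------
# Granger causality


def _lag_design(y: np.ndarray, x: np.ndarray | None, p: int) -> tuple[np.ndarray, np.ndarray]:
    n = y.size
    rows = n - p
    cols = [np.ones(rows)]
    for lag in range(1, p + 1):
        cols.append(y[p - lag : n - lag])
    if x is not None:
        for lag in range(1, p + 1):
            cols.append(x[p - lag : n - lag])
    return np.column_stack(cols), y[p:]


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _bic_order(y: np.ndarray, x: np.ndarray, max_lag: int) -> int:
    """Lag order of the full bivariate model by BIC, fit on a common
    sample so orders are comparable.

    Selecting on the reduced (own-lags) model would ignore pure
    cross-lag structure entirely (a white target driven only by lagged
    source would get order 1 regardless of the true lag)."""
    n = y.size
    best_p, best_bic = 1, np.inf
    for p in range(1, max_lag + 1):
        rows = n - max_lag
        cols = [np.ones(rows)]
        for lag in range(1, p + 1):
            cols.append(y[max_lag - lag : n - lag])
        for lag in range(1, p + 1):
            cols.append(x[max_lag - lag : n - lag])
        X = np.column_stack(cols)
        rss = _ols_rss(X, y[max_lag:])
        bic = rows * np.log(max(rss / rows, 1e-300)) + (2 * p + 1) * np.log(rows)
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


def pairwise_granger(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[float, float, int]:
    """Granger causality x -> y: F-statistic, p-value and the BIC-chosen lag.

    F compares the full model (own + source lags) against the reduced
    own-lags autoregression of y, at the order minimizing the full
    model's BIC (bounded by ``max_lag``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if y.size < 10 * max_lag:
        raise ValueError("series shorter than 10 x max_lag")
    p = _bic_order(y, x, max_lag)
    Xr, yr = _lag_design(y, None, p)
    Xf, _ = _lag_design(y, x, p)
    rss_r = _ols_rss(Xr, yr)
    rss_f = _ols_rss(Xf, yr)
    df_denom = yr.size - (2 * p + 1)
    if df_denom <= 0:
        raise ValueError("not enough samples for the chosen lag order")
    F = max((rss_r - rss_f) / p, 0.0) / max(rss_f / df_denom, 1e-300)
    pval = float(stats.f.sf(F, p, df_denom))
    return float(F), pval, p


def effective_connectivity(
    region_series: np.ndarray,
    nodes: list[str] | None = None,
    max_lag: int = 5,
    q: float = 0.05,
    decimate: int = 1,
    confounds: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Directed region EC by pairwise Granger causality.

    ``region_series`` is (n_samples, n_regions). The series are made
    stationary before fitting: mean and linear trend are removed, as are
    any ``confounds`` columns (e.g. the task-evoked regressor, whose
    shared deterministic response would otherwise masquerade as
    causality). Band-limited series oversampled relative to their content
    should be decimated (``decimate`` keeps every k-th sample) - at the
    native rate the lag columns are near-collinear and the F-test
    degenerates. The diagonal (self-pairs) is undefined (NaN). Values are
    F-statistics; the mask marks FDR-significant directed edges.
    """
    X = np.asarray(region_series, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two region series")
    nodes = list(nodes) if nodes is not None else list(REGIONS[: X.shape[1]])
    n = X.shape[0]
    design = [np.ones(n), np.linspace(-1, 1, n)]
    if confounds is not None:
        C = np.atleast_2d(np.asarray(confounds, dtype=float))
        if C.shape[0] != n:
            C = C.T
        design += [C[:, j] for j in range(C.shape[1])]
    D = np.column_stack(design)
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    X = X - D @ beta
    if decimate > 1:
        X = X[::decimate]
    k = X.shape[1]
    F = np.full((k, k), np.nan)
    P = np.full((k, k), np.nan)
    for src in range(k):
        for dst in range(k):
            if src == dst:
                continue
            F[src, dst], P[src, dst], _ = pairwise_granger(X[:, src], X[:, dst], max_lag)
    qvals, mask = _fdr_mask(P, q, symmetric=False)
    return ConnectivityMatrix(values=F, nodes=nodes, kind="effective",
                              pvals=P, qvals=qvals, mask=mask)


# ---------------------------------------------------------------------------
# graph metrics


def _prepare_weights(fc_values: np.ndarray, valid: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    W = np.array(fc_values, dtype=float)
    k = W.shape[0]
    if valid is None:
        valid = ~np.all(np.isnan(W + np.eye(k)), axis=0)
    W = np.nan_to_num(W, nan=0.0)
    W[W < 0] = 0.0
    np.fill_diagonal(W, 0.0)
    W[~valid, :] = 0.0
    W[:, ~valid] = 0.0
    return W, np.asarray(valid, dtype=bool)


def _efficiency(W: np.ndarray) -> float:
    """Mean inverse shortest-path length on distance = 1/weight; 0 for
    graphs with fewer than 2 nodes."""
    k = W.shape[0]
    if k < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(D, 0.0)
    sp = shortest_path(D, method="D", directed=False)
    off = ~np.eye(k, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(sp[off]) & (sp[off] > 0), 1.0 / sp[off], 0.0)
    return float(inv.mean())


def graph_metrics(
    fc: ConnectivityMatrix | np.ndarray,
    nodes: list[str] | None = None,
    valid: np.ndarray | None = None,
    region_of: list[str] | None = None,
) -> GraphMetrics:
    """Weighted clustering, node-local efficiency and global efficiency.

    Weights: FC values with negatives zeroed, zero diagonal, normalized by
    the maximum weight. Clustering is Onnela's cube-root triangle
    intensity; local efficiency is the efficiency of each node's
    neighborhood subgraph; global efficiency uses shortest paths on
    distance = 1/weight. With weights in [0, 1] all metrics lie in [0, 1].
    """
    if isinstance(fc, ConnectivityMatrix):
        values = fc.values
        nodes = nodes or fc.nodes
    else:
        values = np.asarray(fc, dtype=float)
        nodes = nodes or [f"n{i}" for i in range(values.shape[0])]
    W, valid = _prepare_weights(values, valid)
    if W.max() <= 0:
        raise ValueError("empty graph: no positive weights")
    Wn = W / W.max()
    k = Wn.shape[0]

    # Onnela weighted clustering
    W3 = np.cbrt(Wn)
    tri = np.diagonal(W3 @ W3 @ W3)
    deg = (Wn > 0).sum(axis=1)
    denom = deg * (deg - 1)
    clustering = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)

    local_eff = np.zeros(k)
    for i in range(k):
        nbrs = np.flatnonzero(Wn[i] > 0)
        if nbrs.size >= 2:
            local_eff[i] = _efficiency(Wn[np.ix_(nbrs, nbrs)])

    global_eff = _efficiency(Wn)

    region_c: dict[str, float] = {}
    region_e: dict[str, float] = {}
    if region_of is not None:
        regions = np.asarray(region_of)
        for r in dict.fromkeys(region_of):
            sel = (regions == r) & valid
            if sel.any():
                region_c[r] = float(clustering[sel].mean())
                region_e[r] = float(local_eff[sel].mean())
    return GraphMetrics(
        clustering=clustering,
        local_efficiency=local_eff,
        global_efficiency=global_eff,
        nodes=list(nodes),
        region_clustering=region_c,
        region_local_efficiency=region_e,
    )


# ---------------------------------------------------------------------------
# group comparison of matrices


def compare_matrices(
    group_a: list[np.ndarray | ConnectivityMatrix],
    group_b: list[np.ndarray | ConnectivityMatrix],
    paired: bool = True,
    q: float = 0.05,
    nodes: list[str] | None = None,
) -> pd.DataFrame:
    """Edge-wise comparison of two groups of symmetric FC matrices.

    Correlations are Fisher-z transformed; each upper-triangle edge gets a
    paired or independent t-test, BH-FDR corrected over the edge family.
    The ``tier`` column encodes the two significance bands (2: p < 0.01,
    1: 0.01 <= p < 0.05, 0 otherwise); ``significant`` is the FDR verdict.
    """

    def stack(group):
        mats = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m) for m in group]
        return np.stack([fisher_z(m) for m in mats])

    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 matrices per group")
    A, B = stack(group_a), stack(group_b)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("mismatched node sets")
    if paired and A.shape[0] != B.shape[0]:
        raise ValueError("paired comparison requires equal group sizes")
    k = A.shape[1]
    if isinstance(group_a[0], ConnectivityMatrix):
        nodes = nodes or group_a[0].nodes
    nodes = nodes or [f"n{i}" for i in range(k)]
    iu, ju = np.triu_indices(k, 1)
    rows = []
    for i, j in zip(iu, ju):
        a, b = A[:, i, j], B[:, i, j]
        ok = np.isfinite(a) & np.isfinite(b) if paired else None
        if paired:
            a, b = a[ok], b[ok]
            if a.size < 2:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_rel(b, a)
        else:
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if min(a.size, b.size) < 2:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(b, a)
        rows.append({"nodeA": nodes[i], "nodeB": nodes[j], "t": float(t), "p": float(p),
                     "delta_z": float(np.nanmean(b) - np.nanmean(a))})
    df = pd.DataFrame(rows)
    finite = df["p"].notna().to_numpy()
    qv = np.full(len(df), np.nan)
    rej = np.zeros(len(df), dtype=bool)
    if finite.any():
        rej[finite], qv[finite], *_ = multipletests(df.loc[finite, "p"], alpha=q, method="fdr_bh")
    df["q"] = qv
    df["significant"] = rej
    df["tier"] = np.select([df["p"] < 0.01, df["p"] < 0.05], [2, 1], default=0)
    df.loc[~finite, "tier"] = 0
    return df
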