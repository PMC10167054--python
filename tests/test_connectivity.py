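import numpy as np
import pytest

from corticoflow.connectivity import (
    compare_matrices,
    effective_connectivity,
    functional_connectivity,
    graph_metrics,
    pairwise_granger,
)
from corticoflow.fnirs import HemoSignal, default_layout
from corticoflow.protocol import Timeline

from _oracles import brute_graph_metrics


def _hemo(hbo2, rate=11.0, valid=None):
    n, n_ch = hbo2.shape
    tl = Timeline.from_records([{"label": "task", "start_s": 0.0, "end_s": n / rate}])
    return HemoSignal(
        hbo2=hbo2, hbr=-0.3 * hbo2, rate=rate, layout=default_layout()[:n_ch],
        timeline=tl, valid=np.ones(n_ch, bool) if valid is None else valid,
    )


# ---------------------------------------------------------------------------
# functional connectivity


def test_fc_diagonal_and_identical_series(rng):
    x = rng.standard_normal(500)
    hbo2 = np.column_stack([x, x, rng.standard_normal(500)])
    fc = functional_connectivity(_hemo(hbo2), scope="channel")
    assert np.allclose(np.diag(fc.values), 1.0)
    assert fc.values[0, 1] == pytest.approx(1.0)
    assert fc.pvals[0, 1] < 1e-10
    assert np.allclose(fc.values, fc.values.T, equal_nan=True)
    finite = fc.values[np.isfinite(fc.values)]
    assert np.all(finite >= -1) and np.all(finite <= 1)


def test_fc_masks_invalid_channels(rng):
    hbo2 = rng.standard_normal((400, 5))
    valid = np.ones(5, bool)
    valid[2] = False
    fc = functional_connectivity(_hemo(hbo2, valid=valid), scope="channel")
    assert np.all(np.isnan(fc.values[2, :])) and np.all(np.isnan(fc.values[:, 2]))
    assert np.isfinite(fc.values[0, 1])


def test_fc_constant_series_undefined(rng):
    hbo2 = np.column_stack([np.full(300, 2.0), rng.standard_normal(300)])
    fc = functional_connectivity(_hemo(hbo2), scope="channel")
    assert np.isnan(fc.values[0, 1])
    assert not fc.mask[0, 1]


def test_fc_window_selection(rng):
    n = 660
    hbo2 = rng.standard_normal((n, 3))
    tl = Timeline.from_records(
        [
            {"label": "relaxation", "start_s": 0.0, "end_s": 20.0},
            {"label": "task", "start_s": 20.0, "end_s": 40.0},
            {"label": "rest", "start_s": 40.0, "end_s": 60.0},
        ]
    )
    hemo = HemoSignal(hbo2=hbo2, hbr=-0.3 * hbo2, rate=11.0, layout=default_layout()[:3],
                      timeline=tl, valid=np.ones(3, bool))
    task_fc = functional_connectivity(hemo, scope="channel", window="task")
    sel = tl.mask("task", 11.0)
    want = np.corrcoef(hbo2[sel], rowvar=False)
    np.testing.assert_allclose(task_fc.values, want, atol=1e-12)
    with pytest.raises(ValueError):
        functional_connectivity(hemo, scope="channel", window="nap")


# ---------------------------------------------------------------------------
# Granger causality


def test_granger_matches_statsmodels(rng):
    """Dual route: our F-test equals statsmodels' ssr_ftest at the same lag."""
    from statsmodels.tsa.stattools import grangercausalitytests

    n = 400
    x = rng.standard_normal(n)
    y = np.zeros(n)
    for t in range(1, n):
        y[t] = 0.5 * x[t - 1] + 0.3 * y[t - 1] + rng.standard_normal()
    F, p, lag = pairwise_granger(x, y, max_lag=1)
    res = grangercausalitytests(np.column_stack([y, x]), maxlag=[1])
    F_sm, p_sm, *_ = res[1][0]["ssr_ftest"]
    assert F == pytest.approx(F_sm, rel=1e-9)
    assert p == pytest.approx(p_sm, rel=1e-9)


def test_granger_detects_programmed_direction(rng):
    n = 600
    x = rng.standard_normal(n)
    y = np.zeros(n)
    for t in range(2, n):
        y[t] = 0.6 * x[t - 2] + rng.standard_normal()
    F_xy, p_xy, _ = pairwise_granger(x, y, max_lag=5)
    F_yx, p_yx, _ = pairwise_granger(y, x, max_lag=5)
    assert p_xy < 1e-6 and F_xy > F_yx


def test_granger_input_validation(rng):
    with pytest.raises(ValueError):
        pairwise_granger(rng.standard_normal(30), rng.standard_normal(30), max_lag=5)
    with pytest.raises(ValueError):
        pairwise_granger(rng.standard_normal(100), rng.standard_normal(100), max_lag=0)


def test_effective_connectivity_shape_and_self_pairs(rng):
    X = rng.standard_normal((400, 4))
    ec = effective_connectivity(X, nodes=list("abcd"), max_lag=3)
    assert ec.kind == "effective"
    assert np.all(np.isnan(np.diag(ec.values)))
    off = ~np.eye(4, dtype=bool)
    assert np.all(np.isfinite(ec.values[off]))


def test_effective_connectivity_confound_removal(rng):
    """A shared deterministic component is not reported as causality once
    supplied as a confound."""
    n = 600
    shared = np.sin(2 * np.pi * np.arange(n) / 90)
    X = np.column_stack(
        [shared + 0.3 * rng.standard_normal(n), np.roll(shared, 7) + 0.3 * rng.standard_normal(n)]
    )
    with_conf = effective_connectivity(
        X, nodes=["a", "b"], max_lag=12, confounds=np.column_stack([shared, np.roll(shared, 7)])
    )
    assert not with_conf.mask.any()


# ---------------------------------------------------------------------------
# graph metrics


def test_complete_graph_closed_form():
    K5 = np.ones((5, 5)) - np.eye(5)
    gm = graph_metrics(K5)
    np.testing.assert_allclose(gm.clustering, 1.0)
    np.testing.assert_allclose(gm.local_efficiency, 1.0)
    assert gm.global_efficiency == pytest.approx(1.0)


def test_star_graph_center_has_no_triangles():
    star = np.zeros((5, 5))
    star[0, 1:] = star[1:, 0] = 1.0
    gm = graph_metrics(star)
    assert gm.clustering[0] == 0.0
    assert gm.local_efficiency[0] == 0.0
    # leaves reach each other through the center: d = 2
    assert gm.global_efficiency == pytest.approx((8 * 1 + 12 * 0.5) / 20)


def test_random_weighted_graphs_match_bruteforce(rng):
    """Clustering, local and global efficiency agree with exhaustive
    enumeration to 1e-12 on random graphs of up to 8 nodes."""
    for _ in range(20):
        k = int(rng.integers(4, 9))
        W = rng.uniform(-0.3, 1.0, (k, k))
        W = (W + W.T) / 2
        W[rng.uniform(size=(k, k)) < 0.3] = 0.0
        W = np.maximum(W, W.T)
        np.fill_diagonal(W, 0.0)
        if W.max() <= 0:
            continue
        gm = graph_metrics(W)
        bc, bl, bg = brute_graph_metrics(W)
        np.testing.assert_allclose(gm.clustering, bc, atol=1e-12)
        np.testing.assert_allclose(gm.local_efficiency, bl, atol=1e-12)
        assert gm.global_efficiency == pytest.approx(bg, abs=1e-12)


def test_weighted_clustering_matches_networkx(rng):
    """Independent cross-check against networkx's Onnela clustering."""
    import networkx as nx

    k = 7
    W = rng.uniform(0, 1, (k, k))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    gm = graph_metrics(W)
    G = nx.from_numpy_array(W)
    nx_c = nx.clustering(G, weight="weight")
    np.testing.assert_allclose(gm.clustering, [nx_c[i] for i in range(k)], atol=1e-12)


def test_metrics_bounded_and_regions_aggregated(rng):
    W = np.abs(rng.standard_normal((10, 10)))
    W = (W + W.T) / 2
    regions = ["A"] * 5 + ["B"] * 5
    gm = graph_metrics(W, region_of=regions)
    assert np.all((gm.clustering >= 0) & (gm.clustering <= 1))
    assert np.all((gm.local_efficiency >= 0) & (gm.local_efficiency <= 1))
    assert 0 <= gm.global_efficiency <= 1
    assert gm.region_clustering["A"] == pytest.approx(gm.clustering[:5].mean())


def test_empty_graph_rejected():
    with pytest.raises(ValueError, match="empty graph"):
        graph_metrics(np.zeros((4, 4)) - 1.0)


# ---------------------------------------------------------------------------
# matrix comparison


def test_compare_matrices_flags_programmed_difference(rng):
    base = [np.eye(4) + 0.0 for _ in range(10)]
    shifted = []
    for _ in range(10):
        m = np.eye(4).copy()
        m[0, 1] = m[1, 0] = 0.6 + 0.05 * rng.standard_normal()
        shifted.append(m)
    for m in base:
        m[0, 1] = m[1, 0] = 0.05 * rng.standard_normal()
    df = compare_matrices(base, shifted, paired=True)
    row = df[(df.nodeA == "n0") & (df.nodeB == "n1")].iloc[0]
    assert row.significant and row.tier == 2 and row.delta_z > 0
    others = df[~((df.nodeA == "n0") & (df.nodeB == "n1"))]
    assert not others.significant.any()


def test_compare_matrices_input_validation(rng):
    mats3 = [np.eye(3) for _ in range(3)]
    mats4 = [np.eye(4) for _ in range(3)]
    with pytest.raises(ValueError, match="at least 2"):
        compare_matrices(mats3[:1], mats3)
    with pytest.raises(ValueError, match="mismatched"):
        compare_matrices(mats3, mats4)
    with pytest.raises(ValueError, match="equal group sizes"):
        compare_matrices(mats3, mats3 + [np.eye(3)], paired=True)
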