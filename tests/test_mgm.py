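"""Mixed graphical model: encoding, nodewise fits, edge aggregation."""

import numpy as np
import pandas as pd
import pytest

from dietnet import mgm
from dietnet.mgm import MGMSpec, NodeSpec, aggregate_edges, encode_design, nodewise_fit

from conftest import chain_gaussian_table, mrf_spec, planted_mixed_mrf


@pytest.fixture(scope="module")
def toy_mixed_table():
    rng = np.random.default_rng(0)
    n = 400
    x = rng.standard_normal(n)
    return pd.DataFrame({
        "x": x,
        "y": 0.5 * x + rng.standard_normal(n),
        "k": rng.choice(["a", "b", "c"], size=n),
    })


@pytest.fixture(scope="module")
def toy_spec():
    return MGMSpec((
        NodeSpec("x", "continuous"),
        NodeSpec("y", "continuous"),
        NodeSpec("k", "categorical", ("a", "b", "c")),
    ))


def test_encode_design_indicators_sum_to_one(toy_mixed_table, toy_spec):
    d = encode_design(toy_mixed_table, toy_spec)
    ind = d.X[[f"k={lv}" for lv in ("a", "b", "c")]]
    assert (ind.sum(axis=1) == 1.0).all()
    assert d.X["x"].mean() == pytest.approx(0.0, abs=1e-12)
    assert d.X["x"].std(ddof=1) == pytest.approx(1.0)


def test_encode_design_column_map_partitions_columns(toy_mixed_table, toy_spec):
    d = encode_design(toy_mixed_table, toy_spec)
    seen = [c for node in toy_spec.names for c in d.col_map[node]]
    assert sorted(seen) == sorted(d.X.columns)
    assert len(seen) == len(set(seen))


def test_unobserved_level_dropped_with_warning(toy_mixed_table):
    spec = MGMSpec((
        NodeSpec("x", "continuous"),
        NodeSpec("y", "continuous"),
        NodeSpec("k", "categorical", ("a", "b", "c", "ghost")),
    ))
    with pytest.warns(UserWarning, match="ghost"):
        d = encode_design(toy_mixed_table, spec)
    assert "k=ghost" not in d.X.columns


def test_independent_node_gets_zero_coefficients():
    rng = np.random.default_rng(1)
    n = 2000
    tab = pd.DataFrame({
        "a": rng.standard_normal(n),
        "b": rng.standard_normal(n),
        "c": rng.standard_normal(n),
    })
    spec = MGMSpec(tuple(NodeSpec(c, "continuous") for c in "abc"))
    d = encode_design(tab, spec)
    fit = nodewise_fit("a", d, spec)
    assert np.all(fit.coef.to_numpy() == 0.0)


def test_single_strong_predictor_selected():
    rng = np.random.default_rng(2)
    n = 2000
    x = rng.standard_normal(n)
    tab = pd.DataFrame({
        "x": x,
        "y": 0.5 * x + rng.standard_normal(n),
        "z": rng.standard_normal(n),
    })
    spec = MGMSpec(tuple(NodeSpec(c, "continuous") for c in ("x", "y", "z")))
    d = encode_design(tab, spec)
    fit = nodewise_fit("y", d, spec)
    coefs = fit.coef.iloc[0]
    assert abs(coefs["x"]) > 0
    assert coefs["z"] == 0.0


def test_gamma_increases_sparsity(toy_mixed_table, toy_spec):
    d = encode_design(toy_mixed_table, toy_spec)
    nz = {}
    for g in (0.0, 0.5):
        fit = nodewise_fit("y", d, toy_spec, gamma=g)
        nz[g] = int(np.count_nonzero(fit.coef.to_numpy()))
    assert nz[0.5] <= nz[0.0]


def _make_fit(node, kind, coef_df):
    return mgm.NodewiseFit(node=node, kind=kind, coef=coef_df,
                           intercept=np.zeros(len(coef_df)),
                           selected_lambda=0.1, lambda_path=np.array([0.1]),
                           ebic_trace=np.array([0.0]),
                           predict_cols=list(coef_df.columns))


def test_and_rule_drops_one_sided_edges_and_or_keeps_them():
    spec = MGMSpec((NodeSpec("u", "continuous"), NodeSpec("v", "continuous")))
    design = type("D", (), {"col_map": {"u": ["u"], "v": ["v"]}})()
    fits_one_sided = {
        "u": _make_fit("u", "continuous", pd.DataFrame([[0.4]], index=["coef"], columns=["v"])),
        "v": _make_fit("v", "continuous", pd.DataFrame([[0.0]], index=["coef"], columns=["u"])),
    }
    net_and = aggregate_edges(fits_one_sided, spec, design, gamma=0.5, rule="AND")
    net_or = aggregate_edges(fits_one_sided, spec, design, gamma=0.5, rule="OR")
    assert net_and.weight[0, 1] == 0.0
    assert net_or.weight[0, 1] > 0.0


def test_edge_weight_is_mean_of_absolute_coefficients():
    spec = MGMSpec((NodeSpec("u", "continuous"), NodeSpec("v", "continuous")))
    design = type("D", (), {"col_map": {"u": ["u"], "v": ["v"]}})()
    fits = {
        "u": _make_fit("u", "continuous", pd.DataFrame([[0.4]], index=["coef"], columns=["v"])),
        "v": _make_fit("v", "continuous", pd.DataFrame([[0.2]], index=["coef"], columns=["u"])),
    }
    net = aggregate_edges(fits, spec, design, gamma=0.5)
    assert net.weight[0, 1] == pytest.approx(0.3)
    assert net.sign[0, 1] == 1


def test_disagreeing_signs_are_undeterminable():
    spec = MGMSpec((NodeSpec("u", "continuous"), NodeSpec("v", "continuous")))
    design = type("D", (), {"col_map": {"u": ["u"], "v": ["v"]}})()
    fits = {
        "u": _make_fit("u", "continuous", pd.DataFrame([[-0.4]], index=["coef"], columns=["v"])),
        "v": _make_fit("v", "continuous", pd.DataFrame([[0.2]], index=["coef"], columns=["u"])),
    }
    net = aggregate_edges(fits, spec, design, gamma=0.5)
    assert net.weight[0, 1] > 0
    assert net.sign[0, 1] == 0


def test_and_edges_subset_of_or_edges(toy_mixed_table, toy_spec):
    net_and = mgm.fit_mgm(toy_mixed_table, toy_spec, rule="AND")
    net_or = mgm.fit_mgm(toy_mixed_table, toy_spec, rule="OR")
    assert net_and.edge_set() <= net_or.edge_set()


def test_fully_independent_cohort_gives_empty_network():
    rng = np.random.default_rng(33)
    n = 1000
    tab = pd.DataFrame({f"v{i}": rng.standard_normal(n) for i in range(6)})
    for i in range(4):
        tab[f"k{i}"] = rng.choice(["a", "b"], size=n)
    spec = MGMSpec(
        tuple(NodeSpec(f"v{i}", "continuous") for i in range(6))
        + tuple(NodeSpec(f"k{i}", "categorical", ("a", "b")) for i in range(4))
    )
    net = mgm.fit_mgm(tab, spec)
    assert len(net.edge_set()) == 0


def test_weight_matrix_symmetric_and_nonnegative(toy_mixed_table, toy_spec):
    net = mgm.fit_mgm(toy_mixed_table, toy_spec)
    assert np.allclose(net.weight, net.weight.T)
    assert (net.weight >= 0).all()
    assert np.all(np.diag(net.weight) == 0)
    assert np.all((net.weight > 0) | (net.sign == 0))


def test_permuting_node_order_permutes_network(toy_mixed_table, toy_spec):
    net1 = mgm.fit_mgm(toy_mixed_table, toy_spec)
    perm_spec = MGMSpec(tuple(reversed(toy_spec.nodes)))
    net2 = mgm.fit_mgm(toy_mixed_table, perm_spec)
    r = net1.names[::-1]
    reordered = pd.DataFrame(net2.weight, index=net2.names, columns=net2.names)
    reordered = reordered.loc[net1.names, net1.names].to_numpy()
    assert np.allclose(reordered, net1.weight, atol=1e-6)


def test_predictability_zero_predictor_categorical_is_modal_frequency():
    rng = np.random.default_rng(5)
    n = 1500
    tab = pd.DataFrame({
        "k": rng.choice(["a", "b"], size=n, p=[0.7, 0.3]),
        "x": rng.standard_normal(n),
    })
    spec = MGMSpec((NodeSpec("k", "categorical", ("a", "b")), NodeSpec("x", "continuous")))
    net = mgm.fit_mgm(tab, spec)
    modal = (tab["k"] == "a").mean()
    assert net.predictability["k"] == pytest.approx(modal, abs=1e-9)


def test_predictability_near_one_for_deterministic_node():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(1000)
    tab = pd.DataFrame({"x": x, "y": 2.0 * x + 1e-3 * rng.standard_normal(1000)})
    spec = MGMSpec((NodeSpec("x", "continuous"), NodeSpec("y", "continuous")))
    net = mgm.fit_mgm(tab, spec)
    assert net.predictability["y"] > 0.99


def test_classification_rate_close_to_bayes_rate():
    """Planted logistic dependence: achievable accuracy is the Bayes rate
    E[max(p, 1-p)], estimated by Monte Carlo from the true model."""
    rng = np.random.default_rng(9)
    n = 5000
    x = rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(-(0.3 + 1.5 * x)))
    y = np.where(rng.uniform(size=n) < p, "b", "a")
    tab = pd.DataFrame({"x": x, "k": y})
    spec = MGMSpec((NodeSpec("x", "continuous"), NodeSpec("k", "categorical", ("a", "b"))))
    net = mgm.fit_mgm(tab, spec)
    bayes = np.mean(np.maximum(p, 1 - p))
    assert net.predictability["k"] == pytest.approx(bayes, abs=0.03)


def test_planted_mixed_network_recovery_single_seed():
    mrf = planted_mixed_mrf()
    spec = mrf_spec(mrf)
    tab = pd.DataFrame(mrf.sample(2000, np.random.default_rng(17)))
    net = mgm.fit_mgm(tab, spec)
    true = mrf.edges()
    est = net.edge_set()
    assert len(est & true) / len(true) >= 0.85
    npairs = len(spec.names) * (len(spec.names) - 1) // 2
    assert len(est - true) / (npairs - len(true)) <= 0.05
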