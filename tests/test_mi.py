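"""Adaptive-partitioning MI, permutation null, thresholding, DPI, top-k."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import procoex as px
from procoex.errors import CalibrationError, InputError
from procoex.mi import CHI2_CRIT, MIN_POINTS, null_mi_samples


# ------------------------------------------------------------------ oracle
def brute_apmi(x, y, chi2_crit=CHI2_CRIT, min_points=MIN_POINTS):
    """Independent plain-recursion implementation of the same estimator."""
    n_total = len(x)
    pts = list(zip(x, y))

    def rec(cell, x0, x1, y0, y1):
        n = len(cell)
        if n == 0:
            return 0.0
        xm, ym = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        quads = {
            (0, 0): [p for p in cell if p[0] <= xm and p[1] <= ym],
            (0, 1): [p for p in cell if p[0] <= xm and p[1] > ym],
            (1, 0): [p for p in cell if p[0] > xm and p[1] <= ym],
            (1, 1): [p for p in cell if p[0] > xm and p[1] > ym],
        }
        e = n / 4.0
        chi2 = sum((len(q) - e) ** 2 / e for q in quads.values())
        if n >= min_points and chi2 > chi2_crit:
            return (
                rec(quads[(0, 0)], x0, xm, y0, ym)
                + rec(quads[(0, 1)], x0, xm, ym, y1)
                + rec(quads[(1, 0)], xm, x1, y0, ym)
                + rec(quads[(1, 1)], xm, x1, ym, y1)
            )
        p = n / n_total
        return p * math.log(p / ((x1 - x0) * (y1 - y0)))

    return max(rec(pts, 0.0, 1.0, 0.0, 1.0), 0.0)


def _ranked_pair(rng, n):
    x = (rng.permutation(n) + 1) / n
    y = (rng.permutation(n) + 1) / n
    return x, y


# ------------------------------------------------------- copula transform
def test_copula_rank_arithmetic():
    df = pd.DataFrame([[3.0, 1.0, 2.0]], index=["G1"], columns=list("abc"))
    out = px.copula_rank_transform(df, seed=0)
    assert out.loc["G1"].tolist() == [1.0, 1 / 3, 2 / 3]


def test_copula_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    row = rng.standard_normal(50)
    df = pd.DataFrame([row, np.exp(row)], index=["G1", "G2"])
    out = px.copula_rank_transform(df, seed=1)
    assert np.array_equal(out.loc["G1"], out.loc["G2"])


def test_copula_constant_row_valid_and_reproducible():
    df = pd.DataFrame([[5.0, 5.0, 5.0]], index=["G1"])
    a = px.copula_rank_transform(df, seed=3)
    b = px.copula_rank_transform(df, seed=3)
    assert sorted(a.loc["G1"]) == [1 / 3, 2 / 3, 1.0]
    assert a.equals(b)


def test_copula_rows_are_rank_permutations():
    cfg = px.SyntheticConfig(n_proteins=20, n_tumor=10, n_healthy=3,
                             n_modules=2, missing_rate=0.0, seed=2)
    m, _ = px.generate_dataset(cfg)
    out = px.copula_rank_transform(m, seed=4)
    n = m.n_samples
    expect = np.arange(1, n + 1) / n
    for _, row in out.iterrows():
        assert np.array_equal(np.sort(row.to_numpy()), expect)


# ------------------------------------------------------------------- apmi
def test_apmi_balanced_four_points_is_zero():
    pts = [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)]
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    assert px.apmi(x, y) == 0.0


def test_apmi_length_mismatch():
    with pytest.raises(InputError):
        px.apmi([0.5, 1.0], [0.5, 0.75, 1.0])


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("n", [8, 16, 32])
def test_apmi_matches_brute_recursion(seed, n):
    rng = np.random.default_rng(seed)
    x, y = _ranked_pair(rng, n)
    # correlated variant too: y follows x's order with a few swaps
    assert px.apmi(x, y) == pytest.approx(brute_apmi(x, y), abs=1e-12)
    y2 = np.sort(y)[np.argsort(np.argsort(x + rng.normal(0, 0.2, n)))]
    assert px.apmi(x, y2) == pytest.approx(brute_apmi(x, y2), abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(8, 64))
def test_apmi_symmetric(seed, n):
    rng = np.random.default_rng(seed)
    x, y = _ranked_pair(rng, n)
    assert px.apmi(x, y) == pytest.approx(px.apmi(y, x), abs=1e-12)


def test_apmi_gaussian_oracle_rho09():
    rng = np.random.default_rng(42)
    z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=5000)
    ranked = px.copula_rank_transform(pd.DataFrame(z.T), seed=0)
    mi = px.apmi(ranked.iloc[0], ranked.iloc[1])
    assert mi == pytest.approx(-0.5 * math.log(1 - 0.81), abs=0.1)


# -------------------------------------------------------------- null model
@pytest.fixture(scope="module")
def small_null():
    rng = np.random.default_rng(10)
    ranked = px.copula_rank_transform(
        pd.DataFrame(rng.standard_normal((40, 100))), seed=11
    )
    return ranked, px.calibrate_null(ranked, n_perm=20_000, seed=12)


def test_null_inversion_identity(small_null):
    _, null = small_null
    assert null.p_of_mi(null.mi_at_p(1e-8)) == pytest.approx(1e-8, rel=1e-9)


def test_null_zero_mi_has_p_one(small_null):
    _, null = small_null
    assert null.p_of_mi(0.0) == 1.0


def test_null_slope_negative_and_deterministic(small_null):
    ranked, null = small_null
    assert null.slope < 0
    again = px.calibrate_null(ranked, n_perm=20_000, seed=12)
    assert again.slope == null.slope and again.intercept == null.intercept


def test_null_p_monotone_nonincreasing(small_null):
    _, null = small_null
    xs = np.linspace(0.0, 1.0, 4001)
    ps = null.p_of_mi(xs)
    assert (np.diff(ps) <= 1e-15).all()


def test_null_degenerate_fit_raises():
    rng = np.random.default_rng(13)
    ranked = px.copula_rank_transform(
        pd.DataFrame(rng.standard_normal((10, 100))), seed=14
    )
    with pytest.raises(CalibrationError):
        px.calibrate_null(ranked, n_perm=200, seed=15)


# ---------------------------------------------------------- infer_network
def test_independent_proteins_give_no_edges(small_null):
    ranked, null = small_null
    net = px.infer_network(ranked, null, p_thresh=1e-8)
    # 780 pairs x 1e-8 expected edges under the calibrated null
    assert net.n_edges <= 2
    assert net.n_nodes == 40


def test_vacuous_threshold_gives_complete_graph(small_null):
    ranked, null = small_null
    sub = ranked.iloc[:12]
    net = px.infer_network(sub, null, p_thresh=1.1)
    assert net.n_edges == 12 * 11 // 2


def test_planted_modules_dominate_edge_density(planted_session):
    net = planted_session["net"]
    truth = planted_session["truth"]
    mod = truth.module_labels()
    same = (mod.loc[net.edges["protein_a"]].to_numpy()
            == mod.loc[net.edges["protein_b"]].to_numpy())
    n_within_pairs = sum(c * (c - 1) // 2 for c in mod.value_counts())
    n_total_pairs = len(mod) * (len(mod) - 1) // 2
    density_within = same.sum() / n_within_pairs
    n_between = (~same).sum()
    density_between = n_between / (n_total_pairs - n_within_pairs)
    assert density_within > 10 * max(density_between, 1e-12)


def test_null_model_json_roundtrip(small_null):
    _, null = small_null
    back = px.NullModel.from_dict(null.to_dict())
    assert back.p_of_mi(0.2) == null.p_of_mi(0.2)


# -------------------------------------------------------------------- DPI
def _net(edge_list):
    return px.Network(pd.DataFrame(edge_list, columns=["protein_a", "protein_b", "mi"]))


def test_dpi_removes_weakest_triangle_edge():
    net = _net([("A", "B", 3.0), ("B", "C", 2.0), ("A", "C", 1.0)])
    out = px.apply_dpi(net)
    assert out.edge_set() == {("A", "B"), ("B", "C")}


def test_dpi_ties_survive_at_zero_tolerance():
    net = _net([("A", "B", 2.0), ("B", "C", 2.0), ("A", "C", 2.0)])
    assert px.apply_dpi(net).n_edges == 3


def brute_dpi(net, tolerance=0.0):
    """Triangle-enumeration oracle for DPI."""
    mi = {
        frozenset((a, b)): w
        for a, b, w in zip(net.edges["protein_a"], net.edges["protein_b"], net.edges["mi"])
    }
    nodes = net.nodes
    doomed = set()
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            for c in nodes:
                tri = [frozenset((a, b)), frozenset((a, c)), frozenset((b, c))]
                if c in (a, b) or not all(t in mi for t in tri):
                    continue
                for t in tri:
                    others = [mi[o] for o in tri if o != t]
                    if mi[t] < min(others) * (1 - tolerance):
                        doomed.add(t)
    return {t for t in mi if t not in doomed}


def test_dpi_matches_brute_force_on_random_graph():
    rng = np.random.default_rng(21)
    nodes = [f"N{i:02d}" for i in range(20)]
    rows = []
    for i in range(20):
        for j in range(i + 1, 20):
            if rng.random() < 0.3:
                rows.append((nodes[i], nodes[j], float(rng.random())))
    net = _net(rows)
    out = px.apply_dpi(net)
    assert {frozenset(e) for e in out.edge_set()} == brute_dpi(net)
    # subset of input, idempotent at tolerance 0
    assert out.edge_set() <= net.edge_set()
    assert px.apply_dpi(out).edge_set() == out.edge_set()


# ------------------------------------------------------------------ top-k
def test_top_k_tie_handling():
    net = _net([("A", "B", 5.0), ("A", "C", 4.0), ("A", "D", 3.0),
                ("B", "C", 3.0), ("B", "D", 2.0)])
    assert px.top_k_edges(net, k=10).n_edges == 5  # k >= |E| -> identity
    assert px.top_k_edges(net, k=4).n_edges == 4
    assert px.top_k_edges(net, k=3).n_edges == 4  # ties at the k-th kept
    assert px.top_k_edges(net, k=1).edges["mi"].tolist() == [5.0]
    with pytest.raises(InputError):
        px.top_k_edges(net, k=0)


def test_top_k_preserves_node_set():
    net = px.Network(
        pd.DataFrame([("A", "B", 5.0), ("C", "D", 1.0)],
                     columns=["protein_a", "protein_b", "mi"]),
        nodes=["A", "B", "C", "D", "E"],
    )
    out = px.top_k_edges(net, k=1)
    assert out.nodes == ["A", "B", "C", "D", "E"]
    assert out.n_edges == 1
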