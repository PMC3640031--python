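"""Similarity matrices, UPGMA dendrograms and permutation group tests."""

import numpy as np
import pandas as pd
import pytest

from _oracles import pearson_by_formula, upgma_by_scipy
from brulechip.fingerprint import (
    multi_site_report,
    permutation_group_test,
    similarity_matrix,
    upgma,
)
from brulechip.model import FingerprintSet
from brulechip.simulate import SimulationConfig, simulate_fingerprints


def _fps(lanes: dict, design: pd.DataFrame, grid=None) -> FingerprintSet:
    n = len(next(iter(lanes.values())))
    grid = grid if grid is not None else np.linspace(0, 1, n)
    df = pd.DataFrame(lanes, index=pd.Index(grid, name="position"))
    return FingerprintSet(df, design)


def _design(samples, groups, sites=None):
    return pd.DataFrame(
        {"group": groups, "site": sites or ["S1"] * len(samples), "pool": 1},
        index=pd.Index(samples, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------


def test_duplicate_lanes_are_100_similar():
    x = [1.0, 5.0, 2.0, 8.0]
    d = _design(["a", "b"], ["IN", "OUT"])
    sim = similarity_matrix(_fps({"a": x, "b": x}, d))
    assert sim.loc["a", "b"] == pytest.approx(100.0)
    assert np.allclose(np.diag(sim), 100.0)


def test_reflected_lane_is_minus_100():
    x = np.array([1.0, 5.0, 2.0, 8.0])
    y = x.max() + x.min() - x  # reflection about the midrange, stays nonnegative
    d = _design(["a", "b"], ["IN", "OUT"])
    sim = similarity_matrix(_fps({"a": x, "b": y}, d))
    assert sim.loc["a", "b"] == pytest.approx(-100.0)


def test_similarity_matches_direct_formula_oracle():
    rng = np.random.default_rng(40)
    d = _design(["a", "b", "c", "e"], ["IN", "IN", "OUT", "OUT"])
    for _ in range(100):
        lanes = {s: rng.uniform(0, 10, 12) for s in d.index}
        fps = _fps(lanes, d)
        sim = similarity_matrix(fps)
        norm = {s: np.asarray(v) / np.sum(v) for s, v in lanes.items()}
        for s1 in d.index:
            for s2 in d.index:
                if s1 != s2:
                    assert sim.loc[s1, s2] == pytest.approx(
                        100 * pearson_by_formula(norm[s1], norm[s2])
                    )


def test_zero_variance_lane_error_names_lane():
    d = _design(["a", "flatliner"], ["IN", "OUT"])
    with pytest.raises(ValueError, match="flatliner"):
        similarity_matrix(_fps({"a": [1.0, 2.0, 3.0], "flatliner": [2.0, 2.0, 2.0]}, d))


def test_affine_lane_rescale_leaves_similarity_unchanged():
    rng = np.random.default_rng(41)
    d = _design(["a", "b", "c"], ["IN", "IN", "OUT"])
    lanes = {s: rng.uniform(0, 10, 15) for s in d.index}
    sim1 = similarity_matrix(_fps(lanes, d))
    lanes["b"] = 5.0 * np.asarray(lanes["b"])
    sim2 = similarity_matrix(_fps(lanes, d))
    assert np.allclose(sim1, sim2)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def _sim_df(vals, labels):
    return pd.DataFrame(vals, index=labels, columns=labels, dtype=float)


def test_identical_lanes_merge_first_at_height_zero():
    S = _sim_df([[100, 100, 50], [100, 100, 50], [50, 50, 100]], ["a", "b", "c"])
    tree = upgma(S)
    assert tree.merges[0] == (("a",), ("b",), 0.0)


def test_three_leaf_toy_topology_and_heights():
    S = _sim_df([[100, 90, 50], [90, 100, 50], [50, 50, 100]], ["A", "B", "C"])
    tree = upgma(S)
    assert tree.merges[0] == (("A",), ("B",), pytest.approx(10.0))
    assert tree.merges[1][2] == pytest.approx(50.0)
    assert tree.newick == "((A:10,B:10):40,C:50);"


def test_upgma_matches_scipy_average_linkage():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(4, 8))
        labels = [f"L{i}" for i in range(n)]
        r = rng.uniform(-0.5, 0.99, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        S = _sim_df(100 * r, labels)
        tree = upgma(S)
        mine = {(frozenset(a) | frozenset(b)): h for a, b, h in tree.merges}
        for members, h in upgma_by_scipy(S):
            assert members in mine
            assert mine[members] == pytest.approx(h)


def test_upgma_heights_are_ultrametric():
    rng = np.random.default_rng(43)
    r = rng.uniform(0, 0.9, (7, 7))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    tree = upgma(_sim_df(100 * r, list("abcdefg")))
    heights = [h for _, _, h in tree.merges]
    assert all(h2 >= h1 - 1e-9 for h1, h2 in zip(heights, heights[1:]))


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def _block_similarity(groups, within=95.0, between=75.0):
    g = np.asarray(groups)
    S = np.where(g[:, None] == g[None, :], within, between)
    np.fill_diagonal(S, 100.0)
    labels = [f"s{i}" for i in range(len(groups))]
    return pd.DataFrame(S, index=labels, columns=labels), pd.Series(g, index=labels)


def test_block_structure_reaches_enumeration_minimum():
    sim, labels = _block_similarity(["IN", "IN", "OUT", "OUT"])
    res = permutation_group_test(sim, labels, n_perm=1000)
    assert res.exact and res.n_perm == 6  # C(4,2) labellings
    assert res.d == pytest.approx(20.0)
    # observed + complementary labelling share the maximal d
    assert res.p == pytest.approx(2 / 6)


def test_d_by_hand_on_2v2_toy():
    labels = pd.Series(["IN", "IN", "OUT", "OUT"], index=["a", "b", "c", "d"])
    S = pd.DataFrame(
        [
            [100, 90, 70, 60],
            [90, 100, 50, 80],
            [70, 50, 100, 85],
            [60, 80, 85, 100],
        ],
        index=labels.index, columns=labels.index, dtype=float,
    )
    # within pairs: ab=90, cd=85 -> mean 87.5; between: ac,ad,bc,bd = 70,60,50,80 -> 65
    res = permutation_group_test(S, labels, n_perm=10)
    assert res.d == pytest.approx(87.5 - 65.0)
    # swapping the roles of within and between negates d
    swapped = permutation_group_test(S, labels.map({"IN": "OUT", "OUT": "IN"}), n_perm=10)
    assert swapped.d == pytest.approx(res.d)  # label swap is a symmetry...
    sw, sb = 87.5, 65.0
    assert -(sb - sw) == pytest.approx(res.d)  # ...and the definition is antisymmetric


def test_fixed_seed_reproducible_and_p_bounded():
    cfg = SimulationConfig(seed=44, n_shifted_bands=5)
    fps, _ = simulate_fingerprints(cfg)
    sim = similarity_matrix(fps)
    design = fps.design
    r1 = permutation_group_test(sim, design["group"], n_perm=200, seed=7, strata=design["site"])
    r2 = permutation_group_test(sim, design["group"], n_perm=200, seed=7, strata=design["site"])
    assert r1.p == r2.p
    assert r1.p >= 1 / 201


def test_exact_p_matches_montecarlo_estimate():
    rng = np.random.default_rng(45)
    labels = pd.Series(["IN"] * 4 + ["OUT"] * 4, index=[f"s{i}" for i in range(8)])
    r = rng.uniform(0.3, 0.9, (8, 8))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    sim = pd.DataFrame(100 * r, index=labels.index, columns=labels.index)
    exact = permutation_group_test(sim, labels, n_perm=1000)
    assert exact.exact and exact.n_perm == 70
    mc = permutation_group_test(sim, labels, n_perm=10_000, seed=3, force_random=True)
    assert not mc.exact
    se = np.sqrt(exact.p * (1 - exact.p) / 10_000)
    assert abs(mc.p - exact.p) <= 3 * max(se, 1e-3)


# ---------------------------------------------------------------------------
# Multi-site report
# ---------------------------------------------------------------------------


def test_single_site_total_equals_site_row():
    cfg = SimulationConfig(seed=46, n_sites=1, lanes_per_group=4, n_shifted_bands=4)
    fps, _ = simulate_fingerprints(cfg)
    rep = multi_site_report(fps, n_perm=100, seed=1).set_index("scope")
    assert rep.loc["S1", "d"] == pytest.approx(rep.loc["Total", "d"])
    assert rep.loc["S1", "p"] == pytest.approx(rep.loc["Total", "p"])  # both exact
    assert "Among sites" not in rep.index


def test_site_with_single_group_marked_untestable():
    cfg = SimulationConfig(seed=47, n_sites=2, lanes_per_group=3)
    fps, _ = simulate_fingerprints(cfg)
    design = fps.design.copy()
    design.loc[design["site"] == "S2", "group"] = "IN"  # degenerate site
    fps2 = FingerprintSet(fps.lanes, design)
    rep = multi_site_report(fps2, n_perm=50, seed=1).set_index("scope")
    assert "untestable" in rep.loc["S2", "note"]
    assert np.isnan(rep.loc["S2", "p"])


def test_planted_shift_starred_at_all_sites():
    cfg = SimulationConfig(seed=48, n_shifted_bands=12, shift_in_prob=1.0,
                           shift_out_prob=0.0, band_presence_prob=1.0)
    fps, _ = simulate_fingerprints(cfg)
    rep = multi_site_report(fps, n_perm=999, seed=2).set_index("scope")
    for site in ("S1", "S2", "S3", "S4", "Total"):
        assert rep.loc[site, "significant"], site
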