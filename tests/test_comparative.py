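import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_body, make_point_mass
from hullmass import (
    PhyloTree,
    StylopodialModel,
    aicc,
    ancestral_states,
    fit_allometry,
    normalize_com,
    phylomorphospace,
    spearman_rho,
    stylopodial_mass,
)
from hullmass.comparative import ComparativeError
from hullmass.skeleton_io import SegmentClass, SegmentMesh, SkeletonManifest
from hullmass.synthetic_data import box_vertices, random_tree, simulate_brownian


def _manifest(glenoid=(2.0, 0.0, 0.5)):
    return SkeletonManifest(
        taxon="test",
        segments=[
            SegmentMesh(SegmentClass("torso"), "midline", box_vertices((0, 0, 0), (1, 1, 1)))
        ],
        acetabulum=np.zeros(3),
        glenoid=np.array(glenoid, dtype=float),
    )


# ---------------------------------------------------------------------------
# COM normalisation


def test_com_at_acetabulum_and_glenoid_map_to_zero_and_one():
    manifest = _manifest()
    at_acet = make_body([make_point_mass("torso", 10.0, (0.0, 0.0, 0.0))])
    rec = normalize_com(at_acet, manifest)
    assert rec.com_ap_ga == pytest.approx(0.0)
    at_glen = make_body([make_point_mass("torso", 10.0, (2.0, 0.0, 0.5))])
    rec = normalize_com(at_glen, manifest)
    assert rec.com_ap_ga == pytest.approx(1.0)
    assert rec.com_dv_ga == pytest.approx(1.0)


def test_mass_cube_root_normalisation():
    manifest = _manifest()
    body = make_body([make_point_mass("torso", 1000.0, (0.5, 0.0, 0.2))])
    rec = normalize_com(body, manifest)
    assert rec.com_ap_m13 == pytest.approx(0.05)
    assert rec.com_dv_m13 == pytest.approx(0.02)


def test_dv_degenerate_taxa_flagged():
    manifest = _manifest(glenoid=(2.0, 0.0, 0.0))
    body = make_body([make_point_mass("torso", 10.0, (1.0, 0.0, 0.3))])
    rec = normalize_com(body, manifest)
    assert rec.dv_degenerate
    assert np.isnan(rec.com_dv_ga)
    assert np.isfinite(rec.com_dv_m13)


def test_normalize_com_translation_invariant():
    # body frame is re-origined at the acetabulum, so rigid translation of
    # everything changes nothing
    manifest = _manifest()
    body = make_body([make_point_mass("torso", 10.0, (1.0, 0.0, 0.25))])
    shifted_manifest = _manifest()
    offset = np.array([3.0, -1.0, 2.0])
    shifted_manifest.acetabulum = shifted_manifest.acetabulum + offset
    shifted_manifest.glenoid = shifted_manifest.glenoid + offset
    shifted_body = make_body([make_point_mass("torso", 10.0, offset + (1.0, 0.0, 0.25))])
    a = normalize_com(body, manifest)
    b = normalize_com(shifted_body, shifted_manifest)
    assert a.com_ap_ga == pytest.approx(b.com_ap_ga)
    assert a.com_dv_ga == pytest.approx(b.com_dv_ga)


# ---------------------------------------------------------------------------
# stylopodial masses


def test_stylopodial_sanity_case_and_bounds():
    model = StylopodialModel("bipedal", slope=1.0, intercept=0.0, mppe=0.25)
    mass, lo, hi = stylopodial_mass(10.0, model)
    assert mass == pytest.approx(10.0)
    assert (lo, hi) == (pytest.approx(7.5), pytest.approx(12.5))


def test_stylopodial_power_law_doubling():
    model = StylopodialModel("quadrupedal", slope=2.73, intercept=-1.1)
    m1, *_ = stylopodial_mass(123.0, model)
    m2, *_ = stylopodial_mass(246.0, model)
    assert m2 / m1 == pytest.approx(2.0 ** 2.73, rel=1e-12)


def test_stylopodial_log_space_oracle():
    model = StylopodialModel("bipedal", slope=2.749, intercept=-0.683)
    c = 534.0
    mass, *_ = stylopodial_mass(c, model)
    # independent arithmetic route
    expected = 10.0 ** (-0.683) * c ** 2.749
    assert mass == pytest.approx(expected, rel=1e-12)


def test_stylopodial_requires_coefficients():
    with pytest.raises(ComparativeError, match="coefficients"):
        stylopodial_mass(100.0, None)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_and_reversed():
    x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
    assert spearman_rho(x, x) == pytest.approx(1.0)
    assert spearman_rho(x, -x) == pytest.approx(-1.0)


def test_spearman_ties_match_midrank_oracle():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert spearman_rho(x, y) == pytest.approx(expected, rel=1e-12)


def test_spearman_constant_vector_flagged():
    with pytest.warns(UserWarning, match="constant"):
        assert np.isnan(spearman_rho(np.ones(5), np.arange(5.0)))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_spearman_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = spearman_rho(x, y)
    assert spearman_rho(np.exp(x), y) == pytest.approx(base, rel=1e-12)
    assert spearman_rho(x, y ** 3) == pytest.approx(base, rel=1e-12)


# ---------------------------------------------------------------------------
# regression


def test_exact_line_recovered_with_unit_r2():
    x = np.linspace(0.0, 3.0, 10)
    res = fit_allometry(2.0 * x + 1.0, x, method="ols")
    assert res.slope == pytest.approx(2.0, abs=1e-12)
    assert res.intercept == pytest.approx(1.0, abs=1e-12)
    assert res.adj_r2 == pytest.approx(1.0)


def test_pgls_equals_ols_on_star_phylogeny():
    n = 12
    newick = "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");"
    tree = PhyloTree.from_newick(newick)
    rng = np.random.default_rng(7)
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n) * 0.2
    pgls = fit_allometry(y, x, tree=tree, method="pgls", taxa=tree.taxa)
    ols = fit_allometry(y, x, method="ols")
    assert pgls.slope == pytest.approx(ols.slope, abs=1e-9)
    assert pgls.intercept == pytest.approx(ols.intercept, abs=1e-9)
    assert pgls.slope_se == pytest.approx(ols.slope_se, rel=1e-9)


def test_pgls_matches_statsmodels_gls_oracle():
    import statsmodels.api as sm

    tree = random_tree(20, seed=11)
    rng = np.random.default_rng(3)
    x = simulate_brownian(tree, 1.0, 0.0, seed=rng)
    y = 0.8 * x + simulate_brownian(tree, 0.05, 0.0, seed=rng)
    ours = fit_allometry(y, x, tree=tree, method="pgls")
    C = tree.tip_covariance()
    oracle = sm.GLS(y, sm.add_constant(x), sigma=C).fit()
    assert ours.intercept == pytest.approx(oracle.params[0], rel=1e-9)
    assert ours.slope == pytest.approx(oracle.params[1], rel=1e-9)
    assert ours.slope_se == pytest.approx(oracle.bse[1], rel=1e-6)
    ci = oracle.conf_int()[1]
    assert ours.slope_ci == pytest.approx(tuple(ci), rel=1e-6)


def test_isometry_verdicts():
    x = np.linspace(0.0, 3.0, 20)
    rng = np.random.default_rng(0)
    noise = rng.normal(size=20) * 0.01
    iso = fit_allometry(x / 3.0 + noise, x, method="ols", iso_slope=1.0 / 3.0)
    assert iso.verdict == "isometry-within-CI"
    pos = fit_allometry(0.5 * x + noise, x, method="ols", iso_slope=1.0 / 3.0)
    assert pos.verdict == "positive"
    neg = fit_allometry(0.2 * x + noise, x, method="ols", iso_slope=1.0 / 3.0)
    assert neg.verdict == "negative"


def test_constant_predictor_rejected():
    with pytest.raises(ComparativeError, match="singular"):
        fit_allometry(np.arange(5.0), np.ones(5), method="ols")


# ---------------------------------------------------------------------------
# AICc


def test_aicc_closed_form_and_aic_limit():
    assert aicc(0.0, 2, 10) == pytest.approx(4.0 + 12.0 / 7.0)
    assert aicc(-3.0, 3, 10 ** 9) == pytest.approx(6.0 + 6.0, abs=1e-6)  # AIC limit
    with pytest.raises(ComparativeError):
        aicc(0.0, 3, 4)


def test_better_model_wins_aicc_on_simulated_data():
    # y depends on x; an intercept-only "fit" must lose in >= 95% of replicates
    rng = np.random.default_rng(12)
    wins = 0
    n = 30
    for _ in range(200):
        x = rng.normal(size=n)
        y = 1.0 + 0.8 * x + rng.normal(size=n) * 0.5
        full = fit_allometry(y, x, method="ols")
        # null model: slope forced ~0 by regressing on pure noise predictor
        resid = y - y.mean()
        ll_null = -0.5 * n * (np.log(2 * np.pi * np.mean(resid ** 2)) + 1.0)
        if full.aicc < aicc(ll_null, 2, n):
            wins += 1
    assert wins >= 190


# ---------------------------------------------------------------------------
# ancestral states & phylomorphospace


def test_two_tip_root_is_mean():
    tree = PhyloTree.from_newick("(a:1.0,b:1.0);")
    anc = ancestral_states(tree, {"a": 2.0, "b": 6.0})
    assert len(anc) == 1
    assert anc.iloc[0] == pytest.approx(4.0)


def test_constant_tips_give_constant_ancestors():
    tree = random_tree(10, seed=2)
    anc = ancestral_states(tree, np.full(10, 3.7))
    assert np.allclose(anc.to_numpy(), 3.7, atol=1e-10)


def test_ancestral_states_match_reroot_gls_oracle():
    # oracle: reroot the tree at each internal node; the Brownian ML state
    # there is the GLS mean of the tips under the rerooted covariance
    tree = random_tree(16, seed=5)
    y = simulate_brownian(tree, 1.0, 3.0, seed=7)
    anc = ancestral_states(tree, y)

    dt = tree.as_dendropy()
    for idx, nd in enumerate(dt.preorder_node_iter()):
        if not nd.is_leaf():
            nd.label = nd.label or f"node{idx}"
    for lbl in tree.internal_labels:
        t2 = copy.deepcopy(dt)
        node = next(nd for nd in t2.preorder_node_iter() if nd.label == lbl)
        if t2.seed_node is not node:
            t2.reroot_at_node(node, update_bipartitions=False)
        rerooted = PhyloTree(t2)
        order = rerooted.reorder(tree.taxa)
        C = rerooted.tip_covariance()[np.ix_(order, order)]
        ones = np.ones(len(y))
        mu = (ones @ np.linalg.solve(C, y)) / (ones @ np.linalg.solve(C, ones))
        assert anc[lbl] == pytest.approx(mu, abs=1e-8)


def test_ancestral_reconstruction_is_linear_in_tips():
    tree = random_tree(12, seed=9)
    y = simulate_brownian(tree, 1.0, 0.0, seed=1)
    a, b = 2.5, -1.0
    lhs = ancestral_states(tree, a * y + b)
    rhs = a * ancestral_states(tree, y) + b
    assert np.allclose(lhs.to_numpy(), rhs.to_numpy(), atol=1e-10)


def test_zero_length_terminal_branch_epsilon_warning():
    tree = PhyloTree.from_newick("((a:0.0,b:1.0):1.0,c:2.0);")
    with pytest.warns(UserWarning, match="epsilon"):
        anc = ancestral_states(tree, {"a": 1.0, "b": 2.0, "c": 3.0})
    assert np.all(np.isfinite(anc.to_numpy()))


def test_phylomorphospace_counts_and_order_invariance():
    tree = random_tree(8, seed=4)
    rng = np.random.default_rng(0)
    tx = {t: float(v) for t, v in zip(tree.taxa, rng.normal(size=8))}
    ty = {t: float(v) for t, v in zip(tree.taxa, rng.normal(size=8))}
    coords, edges = phylomorphospace(tree, tx, ty)
    n_internal = len(tree.internal_labels)
    assert len(coords) == 8 + n_internal
    assert len(edges) == len(coords) - 1  # rooted tree: every non-root has one edge
    # permuting dict insertion order changes nothing
    tx2 = dict(reversed(list(tx.items())))
    coords2, _ = phylomorphospace(tree, tx2, ty)
    assert np.allclose(coords["x"].to_numpy(), coords2["x"].to_numpy())


def test_two_tip_phylomorphospace_root_at_means():
    tree = PhyloTree.from_newick("(a:1.0,b:1.0);")
    coords, edges = phylomorphospace(tree, {"a": 0.0, "b": 2.0}, {"a": 1.0, "b": 5.0})
    assert len(coords) == 3
    assert len(edges) == 2
    root = coords[~coords["is_tip"]].iloc[0]
    assert root["x"] == pytest.approx(1.0)
    assert root["y"] == pytest.approx(3.0)
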