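"""RRPP linear models, phenotype vectors, Mantel and disparity tests,
cross-checked against closed forms and independent implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphodim.shape_stats import (
    compare_vectors_across_spaces,
    disparity_ancova,
    distance_correlation_2d3d,
    mantel,
    pairwise_vectors,
    rrpp_fit,
)


def _one_way_data(rng, n_per=10, k=3, delta=0.8):
    y = np.concatenate([rng.normal(delta * g, 1.0, n_per) for g in range(k)])
    data = pd.DataFrame({"g": np.repeat([f"g{j}" for j in range(k)], n_per)})
    return y, data


# ----------------------------------------------------------------------
# rrpp_fit
# ----------------------------------------------------------------------

def test_univariate_one_way_f_matches_scipy(rng):
    y, data = _one_way_data(rng)
    fit = rrpp_fit(y, data, ["g"], n_perm=99, seed=0)
    groups = [y[data.g == lvl] for lvl in data.g.unique()]
    f_ref, _ = stats.f_oneway(*groups)
    assert fit.table.loc["g", "F"] == pytest.approx(f_ref, rel=1e-10)


def test_permutation_p_close_to_parametric_for_gaussian_data(rng):
    y, data = _one_way_data(rng, n_per=12, k=2, delta=0.9)
    fit = rrpp_fit(y, data, ["g"], n_perm=9999, seed=2)
    f = fit.table.loc["g", "F"]
    p_param = stats.f.sf(f, 1, len(y) - 2)
    assert fit.table.loc["g", "p_perm"] == pytest.approx(p_param, abs=0.02)


def test_type2_ss_matches_statsmodels(rng):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    n = 40
    df = pd.DataFrame({
        "g": np.tile(["a", "b", "c", "d"], n // 4),
        "x": rng.normal(size=n),
    })
    df["y"] = (df.g.map({"a": 0, "b": 1, "c": -1, "d": 2})
               + 0.7 * df.x + rng.normal(size=n))
    fit = rrpp_fit(df.y.to_numpy(), df[["g", "x"]], ["g", "x", "g:x"],
                   n_perm=99, seed=0)
    ref = sm.stats.anova_lm(ols("y ~ C(g) * x", data=df).fit(), typ=2)
    assert fit.table.loc["g", "SS"] == pytest.approx(
        ref.loc["C(g)", "sum_sq"], rel=1e-8)
    assert fit.table.loc["x", "SS"] == pytest.approx(
        ref.loc["x", "sum_sq"], rel=1e-8)
    assert fit.table.loc["g:x", "SS"] == pytest.approx(
        ref.loc["C(g):x", "sum_sq"], rel=1e-8)
    assert fit.table.loc["g", "F"] == pytest.approx(
        ref.loc["C(g)", "F"], rel=1e-8)


def test_multivariate_one_way_matches_skbio_permanova(rng):
    # for Euclidean distances, the one-way PERMANOVA pseudo-F equals the
    # multivariate OLS F
    from skbio.stats.distance import DistanceMatrix, permanova
    y = rng.normal(size=(24, 5))
    y[12:] += 0.6
    data = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12})
    fit = rrpp_fit(y, data, ["g"], n_perm=99, seed=0)
    dm = DistanceMatrix(
        np.sqrt(((y[:, None] - y[None]) ** 2).sum(-1)),
        ids=[str(i) for i in range(24)])
    res = permanova(dm, grouping=data.g.to_numpy(), permutations=99)
    assert fit.table.loc["g", "F"] == pytest.approx(
        res["test statistic"], rel=1e-8)


def test_saturated_design_r2_one_and_min_p(rng):
    # exact watershed effect, zero residual variance within groups
    means = {"a": 1.0, "b": -2.0, "c": 0.5}
    data = pd.DataFrame({"g": list("aabbcc") * 2, "h": ["x", "y"] * 6})
    y = data.g.map(means).to_numpy()
    fit = rrpp_fit(y, data, ["g"], n_perm=199, seed=1)
    assert fit.table.loc["g", "R2"] == pytest.approx(1.0, abs=1e-10)
    assert fit.table.loc["g", "p_perm"] == pytest.approx(1 / 200)


def test_type2_ss_invariant_to_term_order(rng):
    n = 36
    df = pd.DataFrame({
        "g": rng.choice(["a", "b", "c"], n),
        "x": rng.normal(size=n),
    })
    y = rng.normal(size=(n, 4))
    f1 = rrpp_fit(y, df, ["g", "x"], n_perm=99, seed=0)
    f2 = rrpp_fit(y, df, ["x", "g"], n_perm=99, seed=0)
    for t in ("g", "x"):
        assert f1.table.loc[t, "SS"] == pytest.approx(
            f2.table.loc[t, "SS"], rel=1e-10)


def test_ss_partition_in_balanced_design(rng):
    # Type II SS sum to the model SS when factors are orthogonal (balanced)
    data = pd.DataFrame({
        "g": np.repeat(["a", "b", "c"], 8),
        "h": np.tile(["x", "y"], 12),
    })
    y = rng.normal(size=(24, 3))
    fit = rrpp_fit(y, data, ["g", "h"], n_perm=99, seed=0)
    t = fit.table
    assert t.loc["g", "SS"] + t.loc["h", "SS"] + t.loc["Residual", "SS"] \
        == pytest.approx(t.loc["Total", "SS"], rel=1e-8)
    assert ((t["R2"].dropna() >= 0) & (t["R2"].dropna() <= 1 + 1e-12)).all()


def test_rank_deficient_design_raises(rng):
    df = pd.DataFrame({"g": ["a", "a", "b", "b"],
                       "h": ["x", "x", "y", "y"]})  # h aliased with g
    y = rng.normal(size=4)
    with pytest.raises(ValueError, match="alias"):
        rrpp_fit(y, df, ["g", "h"], n_perm=99, seed=0)


def test_permutations_reproducible(rng):
    y, data = _one_way_data(rng)
    t1 = rrpp_fit(y, data, ["g"], n_perm=199, seed=42).table
    t2 = rrpp_fit(y, data, ["g"], n_perm=199, seed=42).table
    pd.testing.assert_frame_equal(t1, t2)


# ----------------------------------------------------------------------
# vectors
# ----------------------------------------------------------------------

def _slope_fixture(slopes, n_per=8, noise=0.0, seed=0):
    """Groups with prescribed slope vectors of y on x."""
    rng = np.random.default_rng(seed)
    rows, ys = [], []
    for g, slope in slopes.items():
        x = np.linspace(-1, 1, n_per)
        y = np.outer(x, slope) + rng.normal(size=(n_per, len(slope))) * noise
        ys.append(y)
        rows += [{"g": g, "x": xi} for xi in x]
    data = pd.DataFrame(rows)
    return np.vstack(ys), data


def test_pairwise_vector_angles_closed_forms():
    y, data = _slope_fixture({"a": [1, 0], "b": [0, 1], "c": [1, 1],
                              "d": [2, 0]})
    fit = rrpp_fit(y, data, ["g", "x", "g:x"], n_perm=99, seed=0)
    vc = pairwise_vectors(fit, "g", "x", n_perm=99, seed=0)
    assert vc.angles.loc["a", "b"] == pytest.approx(90.0, abs=1e-8)
    assert vc.angles.loc["a", "c"] == pytest.approx(45.0, abs=1e-10)
    assert vc.angles.loc["a", "d"] == pytest.approx(0.0, abs=1e-6)
    assert vc.magnitude_diff.loc["a", "d"] == pytest.approx(1.0, abs=1e-8)
    assert np.allclose(np.diag(vc.angles), 0)
    a = vc.angles.to_numpy()
    assert ((a >= 0) & (a <= 180)).all()


def test_pairwise_vectors_match_exported_coefficients():
    # angles recomputed directly from the slope vectors the object exports
    y, data = _slope_fixture({"a": [1, 0.2, 0], "b": [0.5, 1, -0.3]},
                             noise=0.05, seed=3)
    fit = rrpp_fit(y, data, ["g", "x", "g:x"], n_perm=99, seed=0)
    vc = pairwise_vectors(fit, "g", "x", n_perm=199, seed=0)
    u = vc.vectors.loc["a"].to_numpy()
    v = vc.vectors.loc["b"].to_numpy()
    ang = np.degrees(np.arccos(
        u @ v / (np.linalg.norm(u) * np.linalg.norm(v))))
    assert vc.angles.loc["a", "b"] == pytest.approx(ang, abs=1e-10)


def test_pairwise_requires_interaction_term():
    y, data = _slope_fixture({"a": [1, 0], "b": [0, 1]})
    fit = rrpp_fit(y, data, ["g", "x"], n_perm=99, seed=0)
    with pytest.raises(ValueError, match="interaction"):
        pairwise_vectors(fit, "g", "x")


def test_angle_scale_invariance_magnitude_not():
    y, data = _slope_fixture({"a": [1, 0], "b": [3, 0]})
    fit = rrpp_fit(y, data, ["g", "x", "g:x"], n_perm=99, seed=0)
    vc = pairwise_vectors(fit, "g", "x", n_perm=99, seed=0)
    assert vc.angles.loc["a", "b"] == pytest.approx(0.0, abs=1e-6)
    assert vc.magnitude_diff.loc["a", "b"] == pytest.approx(2.0, abs=1e-8)


def test_cross_space_vectors_identical_sets_give_zero_angle():
    y, data = _slope_fixture({"2d": [1, 0.5, -0.2], "3d": [1, 0.5, -0.2]})
    data = data.rename(columns={"g": "space"})
    data["w"] = "ws1"
    fit = rrpp_fit(y, data, ["space", "x", "space:x"], n_perm=99, seed=0)
    out = compare_vectors_across_spaces(fit, "x", dim="space", within="w",
                                        n_perm=99, seed=0)
    assert out["overall"].angles.iloc[0, 1] == pytest.approx(0.0, abs=1e-6)
    assert out["per_group"].iloc[0]["angle_deg"] == pytest.approx(
        0.0, abs=1e-6)


# ----------------------------------------------------------------------
# mantel
# ----------------------------------------------------------------------

def _rand_dist(rng, n=12):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return d


def test_mantel_identity_and_affine_invariance(rng):
    d1 = _rand_dist(rng)
    r, _ = mantel(d1, d1, n_perm=99, seed=0)
    assert r == pytest.approx(1.0, abs=1e-12)
    d2 = 2 * d1 + 3
    np.fill_diagonal(d2, 0)
    r2, _ = mantel(d1, d2, n_perm=99, seed=0)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_mantel_matches_skbio(rng):
    from skbio.stats.distance import mantel as skbio_mantel
    d1, d2 = _rand_dist(rng, 15), _rand_dist(rng, 15)
    r, p = mantel(d1, d2, n_perm=999, seed=0)
    r_ref, p_ref, _ = skbio_mantel(d1, d2, method="pearson",
                                   permutations=999,
                                   alternative="greater")
    assert r == pytest.approx(r_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=0.08)


def test_mantel_rejects_asymmetric(rng):
    d = _rand_dist(rng)
    bad = d.copy()
    bad[0, 1] += 1
    with pytest.raises(ValueError, match="symmetric"):
        mantel(d, bad, n_perm=99)


def test_mantel_null_calibration(rng):
    ps = []
    for s in range(20):
        r = np.random.default_rng(s)
        _, p = mantel(_rand_dist(r, 20), _rand_dist(r, 20),
                      n_perm=99, seed=s)
        ps.append(p)
    ps = np.array(ps)
    assert (ps < 0.05).mean() <= 0.2
    assert 0.2 < ps.mean() < 0.8


# ----------------------------------------------------------------------
# distance correlations and disparity
# ----------------------------------------------------------------------

class _FakeAligned:
    def __init__(self, coords, consensus):
        self.coords = coords
        self.consensus = consensus


def test_distance_correlation_log_linearity(rng):
    consensus = np.zeros((4, 2))
    d = rng.uniform(0.5, 2.0, 20)
    c2 = np.zeros((20, 4, 2))
    c3 = np.zeros((20, 4, 2))
    c2[:, 0, 0] = d          # distance d from consensus
    c3[:, 0, 0] = d ** 3     # monotone nonlinear relation
    r, _ = distance_correlation_2d3d(_FakeAligned(c2, consensus),
                                     _FakeAligned(c3, consensus))
    assert r == pytest.approx(1.0, abs=1e-10)


def test_disparity_ancova_closed_forms(rng):
    n = 36
    # covariate orthogonal to the factor (same values in every watershed)
    data = pd.DataFrame({
        "watershed": np.repeat(["a", "b", "c"], n // 3),
        "cov": np.tile(np.linspace(-1, 1, n // 3), 3),
    })
    dist = 0.5 + 2.0 * data["cov"].to_numpy()  # exact linear relation
    fit = disparity_ancova(dist, data, "cov", n_perm=99, seed=0)
    assert fit.table.loc["cov", "R2"] == pytest.approx(1.0, abs=1e-10)
    # matches classical ANCOVA F on noisy data
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    df = data.copy()
    df["y"] = dist + rng.normal(size=n)
    fit2 = disparity_ancova(df.y.to_numpy(), data, "cov", n_perm=99, seed=0)
    ref = sm.stats.anova_lm(
        ols("y ~ C(watershed) + cov", data=df).fit(), typ=2)
    assert fit2.table.loc["cov", "F"] == pytest.approx(
        ref.loc["cov", "F"], rel=1e-8)
    assert fit2.table.loc["watershed", "F"] == pytest.approx(
        ref.loc["C(watershed)", "F"], rel=1e-8)
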