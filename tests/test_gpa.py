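"""Procrustes machinery: sizes, alignment, distances, TPS, symmetry,
side averaging, allometry and tangent PCA."""

import math

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator
from scipy.spatial import procrustes as scipy_procrustes

from morphodim import gpa, simulate
from morphodim.gpa import (
    allometry_residuals,
    centroid_size,
    gpa_align,
    procrustes_distance,
    side_average,
    symmetry_decompose,
    tangent_pca,
    tps_interpolate_missing,
    tps_warp,
)
from morphodim.io import LandmarkDataset

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _rot2(theta):
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


# ----------------------------------------------------------------------
# centroid size
# ----------------------------------------------------------------------

def test_centroid_size_closed_forms():
    assert centroid_size(SQUARE) == pytest.approx(math.sqrt(2), abs=1e-12)
    assert centroid_size(3 * SQUARE) == pytest.approx(3 * math.sqrt(2),
                                                      abs=1e-12)
    rotated = SQUARE @ _rot2(math.radians(37)).T + [4.2, -1.1]
    assert centroid_size(rotated) == pytest.approx(math.sqrt(2), abs=1e-12)


def test_centroid_size_rejects_missing():
    bad = SQUARE.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="interpolat"):
        centroid_size(bad)


# ----------------------------------------------------------------------
# GPA
# ----------------------------------------------------------------------

def test_gpa_similarity_copies_collapse(rng):
    base = rng.normal(size=(16, 3))
    configs = [base]
    for _ in range(7):
        rot = simulate._random_rotation(rng)
        s = rng.uniform(0.5, 2.0)
        configs.append(s * base @ rot.T + rng.uniform(-5, 5, 3))
    aligned = gpa_align(np.stack(configs))
    n = len(configs)
    dmax = max(
        procrustes_distance(aligned.coords[i], aligned.coords[j])
        for i in range(n) for j in range(i + 1, n))
    assert dmax < 1e-8


def test_gpa_invariants_and_idempotence(rng):
    base = simulate.bilateral_template(simulate.TEMPLATE_LEFT)
    coords = np.empty((10, 16, 3))
    for i in range(10):
        c = base + rng.normal(size=(16, 3)) * 0.1
        coords[i] = c @ simulate._random_rotation(rng).T + rng.uniform(-5, 5, 3)
    aligned = gpa_align(coords)
    # unit centroid size, centred at origin
    for c in aligned.coords:
        assert abs(centroid_size(c) - 1) < 1e-8
        assert np.abs(c.mean(axis=0)).max() < 1e-8
    # consensus is the coordinate-wise mean
    np.testing.assert_allclose(aligned.consensus,
                               aligned.coords.mean(axis=0), atol=1e-10)
    again = gpa_align(aligned.coords)
    assert np.abs(again.coords - aligned.coords).max() < 1e-8


def test_gpa_converges_quickly_on_realistic_configs(rng):
    # 50 specimens with realistic shape dispersion around a template,
    # in random digitization frames
    coords = np.empty((50, 16, 3))
    base = simulate.bilateral_template(simulate.TEMPLATE_LEFT)
    for i in range(50):
        c = base + rng.normal(size=(16, 3)) * 0.1
        coords[i] = c @ simulate._random_rotation(rng).T + rng.uniform(-5, 5, 3)
    aligned = gpa_align(coords, tol=1e-10)
    assert aligned.converged
    assert aligned.iterations < 20


def test_gpa_converges_eventually_on_dispersed_random_configs(rng):
    # maximally dispersed shapes converge slowly but surely under the
    # alternating rotation/consensus update
    coords = rng.normal(size=(20, 16, 3))
    aligned = gpa_align(coords, tol=1e-8, max_iter=1000)
    assert aligned.converged


def test_gpa_objective_nonincreasing(rng):
    # summed squared distance to consensus cannot grow across re-alignment
    coords = rng.normal(size=(12, 6, 2))
    with pytest.warns(RuntimeWarning):
        aligned = gpa_align(coords, max_iter=1)
    obj1 = ((aligned.coords - aligned.coords.mean(0)) ** 2).sum()
    aligned2 = gpa_align(coords, max_iter=50)
    obj2 = ((aligned2.coords - aligned2.coords.mean(0)) ** 2).sum()
    assert obj2 <= obj1 + 1e-12


# ----------------------------------------------------------------------
# Procrustes distance
# ----------------------------------------------------------------------

def test_procrustes_distance_basic(rng):
    a = rng.normal(size=(5, 2))
    assert procrustes_distance(a, a) == 0.0
    b = a @ _rot2(1.1).T + [3, 4]
    assert procrustes_distance(a, b, mode="full_ols") < 1e-12
    with pytest.raises(ValueError, match="mismatch"):
        procrustes_distance(a, a[:4])


def test_procrustes_distance_matches_rotation_grid_oracle():
    a = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    b = np.array([[0.0, 0.0], [1.2, 0.1], [-0.2, 0.8]])
    a0 = (a - a.mean(0)) / centroid_size(a)
    b0 = (b - b.mean(0)) / centroid_size(b)
    thetas = np.arange(0, 2 * math.pi, 1e-5)
    c, s = np.cos(thetas), np.sin(thetas)
    # rotate b0 by every grid angle; distance at the best one
    d2 = np.zeros_like(thetas)
    for i in range(3):
        rx = c * b0[i, 0] - s * b0[i, 1]
        ry = s * b0[i, 0] + c * b0[i, 1]
        d2 += (rx - a0[i, 0]) ** 2 + (ry - a0[i, 1]) ** 2
    oracle = math.sqrt(d2.min())
    ours = procrustes_distance(a, b, mode="full_ols")
    assert ours == pytest.approx(oracle, abs=1e-8)


def test_procrustes_distance_agrees_with_scipy(rng):
    # scipy's full Procrustes disparity is sin^2(rho); our partial
    # Procrustes distance is sqrt(2 - 2 cos(rho)).  Both determine rho, so
    # they must agree through that identity when the optimal transform is
    # a proper rotation.
    a = rng.normal(size=(7, 2))
    b_rot = a @ _rot2(0.4).T * 1.3 + 0.05 * rng.normal(size=(7, 2))
    _, _, disparity = scipy_procrustes(a, b_rot)
    d = procrustes_distance(a, b_rot, "full_ols")
    cos_rho = 1 - d ** 2 / 2
    assert 1 - cos_rho ** 2 == pytest.approx(disparity, rel=1e-9)


# ----------------------------------------------------------------------
# TPS
# ----------------------------------------------------------------------

def _mini_dataset(coords, metadata=None):
    n, k, d = coords.shape
    import pandas as pd
    md = pd.DataFrame({
        "watershed": ["w"] * n, "habitat": ["lake"] * n, "sex": ["M"] * n,
    }, index=pd.Index([f"s{i}" for i in range(n)], name="specimen_id"))
    return LandmarkDataset(coords=coords,
                           specimen_ids=[f"s{i}" for i in range(n)],
                           landmark_names=[f"lm{j}" for j in range(k)],
                           sides=[""] * k, metadata=md)


def test_tps_exact_recovery_of_reference_copy(rng):
    base = rng.normal(size=(10, 3))
    coords = np.stack([base, base, base.copy()])
    coords[2, 4] = np.nan
    ds = _mini_dataset(coords)
    out = tps_interpolate_missing(ds)
    assert np.linalg.norm(out.coords[2, 4] - base[4]) < 1e-6
    assert not out.missing_mask.any()


def test_tps_reproduces_affine_maps_exactly(rng):
    base = rng.normal(size=(9, 3))
    aff = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
    warped = base @ aff + [0.3, -0.2, 0.1]
    out = tps_warp(base[:8], warped[:8], base[8])
    np.testing.assert_allclose(out[0], warped[8], atol=1e-9)


def test_tps_matches_independent_rbf_solver(rng):
    # smooth nonlinear warp in 3D: our solver vs scipy's RBF interpolant
    # with the same r kernel
    src = rng.normal(size=(12, 3))
    dst = src + 0.2 * np.sin(src[:, [1, 2, 0]])
    query = rng.normal(size=(5, 3))
    ours = tps_warp(src, dst, query)
    ref = RBFInterpolator(src, dst, kernel="linear", degree=1)(query)
    np.testing.assert_allclose(ours, ref, atol=1e-8)


def test_tps_unrecoverable_landmark_errors(rng):
    base = rng.normal(size=(6, 3))
    coords = np.stack([base, base])
    coords[:, 2] = np.nan
    ds = _mini_dataset(coords)
    with pytest.raises(ValueError, match="unrecoverable"):
        tps_interpolate_missing(ds)


# ----------------------------------------------------------------------
# symmetry
# ----------------------------------------------------------------------

def _bilateral_dataset(coords):
    import pandas as pd
    n = coords.shape[0]
    k = coords.shape[1] // 2
    names = [f"lm{j}" for j in range(k)] * 2
    sides = ["L"] * k + ["R"] * k
    return LandmarkDataset(coords=coords,
                           specimen_ids=[f"s{i}" for i in range(n)],
                           landmark_names=names, sides=sides)


def test_symmetry_null_case(rng):
    left = rng.normal(size=(8, 3))
    coords = np.stack([simulate.bilateral_template(
        left + 0.0) for _ in range(12)])
    # tiny symmetric perturbations only (mirrored to both sides)
    for i in range(12):
        pert = simulate._mirror_left_pattern(rng.normal(size=(8, 3)) * 0.01)
        coords[i] += pert
    rep = symmetry_decompose(_bilateral_dataset(coords), n_perm=199, seed=0)
    assert rep.r2_directional < 1e-6
    assert rep.p_directional > 0.5


def test_symmetry_recovers_directional_offset():
    rng = np.random.default_rng(7)
    left = simulate.TEMPLATE_LEFT
    da = rng.normal(size=(8, 3))
    da *= 0.15 / np.linalg.norm(da)
    coords = np.empty((30, 16, 3))
    for i in range(30):
        c = simulate.bilateral_template(left).copy()
        c[:8] += da / 2
        c[8:] -= simulate._mirror_left_pattern(da)[8:] / 2
        c += rng.normal(size=(16, 3)) * 0.01
        coords[i] = c
    rep = symmetry_decompose(_bilateral_dataset(coords), n_perm=199, seed=1)
    assert rep.p_directional < 0.05
    # directional component matches the injected asymmetry after removing
    # the similarity components superimposition cannot estimate
    true_full = np.zeros((16, 3))
    true_full[:8] = da / 2
    true_full[8:] = -simulate._mirror_left_pattern(da)[8:] / 2
    ref = simulate.bilateral_template(left)
    true_t = gpa.similarity_tangent_project(true_full, ref).ravel()
    est = rep.directional.ravel()
    cos = est @ true_t / (np.linalg.norm(est) * np.linalg.norm(true_t))
    assert cos > 0.95


def test_symmetry_side_permutation_destroys_significance():
    # randomly swapping side labels turns directional into fluctuating
    # asymmetry; p-values should look uniform across generator seeds
    ps = []
    for seed in range(15):
        rng = np.random.default_rng(seed)
        da = rng.normal(size=(8, 3))
        da *= 0.1 / np.linalg.norm(da)
        coords = np.empty((20, 16, 3))
        for i in range(20):
            c = simulate.bilateral_template(simulate.TEMPLATE_LEFT).copy()
            c[:8] += da / 2
            c[8:] -= simulate._mirror_left_pattern(da)[8:] / 2
            c += rng.normal(size=(16, 3)) * 0.01
            if rng.random() < 0.5:  # side-label swap
                c = np.vstack([c[8:], c[:8]])
                c[:, 2] *= -1
            coords[i] = c
        rep = symmetry_decompose(_bilateral_dataset(coords), n_perm=99,
                                 seed=seed)
        ps.append(rep.p_directional)
    ps = np.array(ps)
    assert (ps < 0.05).mean() <= 0.25
    assert 0.2 < ps.mean() < 0.8


def test_symmetry_partition_matches_balanced_anova_oracle(sim_default):
    # SS partition agrees with the classical balanced two-way formulas
    # computed directly from group means, independent of the QR machinery
    _, ds, _ = sim_default
    from morphodim import dimension
    oriented = ds.copy()
    for i in range(ds.n_specimens):
        oriented.coords[i] = dimension.orient_midsagittal(
            ds.coords[i], ds.pairs)
    rep = symmetry_decompose(oriented, n_perm=99, seed=0)
    n = ds.n_specimens
    aligned = gpa_align(np.concatenate([
        oriented.coords,
        np.stack([gpa._mirror_relabel(c, ds.pairs)
                  for c in oriented.coords])]))
    y = aligned.flat()
    grand = y.mean(axis=0)
    side_means = np.stack([y[:n].mean(axis=0), y[n:].mean(axis=0)])
    ind_means = (y[:n] + y[n:]) / 2
    ss_total = ((y - grand) ** 2).sum()
    ss_side = n * ((side_means - grand) ** 2).sum()
    ss_ind = 2 * ((ind_means - grand) ** 2).sum()
    ss_res = ss_total - ss_side - ss_ind
    assert rep.r2_directional == pytest.approx(ss_side / ss_total, rel=1e-6)
    assert rep.r2_fluctuating == pytest.approx(ss_res / ss_total, rel=1e-6)


def test_symmetry_refuses_small_n_perm(sim_default):
    _, ds, _ = sim_default
    with pytest.raises(ValueError, match="n_perm"):
        symmetry_decompose(ds, n_perm=50)


# ----------------------------------------------------------------------
# side averaging
# ----------------------------------------------------------------------

def test_side_average_symmetric_equals_left():
    coords = simulate.bilateral_template(simulate.TEMPLATE_LEFT)[None]
    out = side_average(_bilateral_dataset(coords))
    np.testing.assert_allclose(out.coords[0], simulate.TEMPLATE_LEFT,
                               atol=1e-12)


def test_side_average_midpoint_and_swap_invariance(rng):
    base = simulate.bilateral_template(simulate.TEMPLATE_LEFT)
    eps = rng.normal(size=(8, 3)) * 0.05
    c = base.copy()
    c[:8] += eps  # left = mirrored right + eps
    out = side_average(_bilateral_dataset(c[None]))
    np.testing.assert_allclose(out.coords[0], c[:8] - eps / 2, atol=1e-12)
    # swapping the side labels (and mirroring) leaves the average unchanged
    swapped = np.vstack([c[8:], c[:8]])
    swapped[:, 2] *= -1
    out2 = side_average(_bilateral_dataset(swapped[None]))
    sw = out2.coords[0].copy()
    sw[:, 2] *= -1
    assert (np.allclose(out2.coords[0], out.coords[0], atol=1e-9)
            or np.allclose(sw, out.coords[0], atol=1e-9))


# ----------------------------------------------------------------------
# allometry + PCA
# ----------------------------------------------------------------------

def test_allometry_residuals_properties(rng):
    coords = rng.normal(size=(20, 6, 2))
    aligned = gpa_align(coords)
    res = allometry_residuals(aligned)
    x = np.log10(aligned.centroid_sizes)
    xc = x - x.mean()
    slopes = xc @ res.flat() / (xc @ xc)
    assert np.abs(slopes).max() < 1e-10  # exact orthogonality


def test_allometry_equal_sizes_passthrough(rng):
    coords = rng.normal(size=(8, 5, 2))
    aligned = gpa_align(coords)
    aligned.centroid_sizes = np.ones(8) * 3.3
    with pytest.warns(RuntimeWarning, match="zero variance"):
        res = allometry_residuals(aligned)
    y = aligned.flat()
    np.testing.assert_allclose(res.flat(), y - y.mean(axis=0), atol=1e-12)


def test_allometry_slope_recovery():
    rng = np.random.default_rng(3)
    k, d, n = 6, 2, 120
    consensus = rng.normal(size=(k, d))
    consensus -= consensus.mean(0)
    consensus /= centroid_size(consensus)
    beta = rng.normal(size=k * d) * 0.02
    logs = rng.normal(0.8, 0.2, size=n)
    shapes = consensus.ravel()[None] + np.outer(logs, beta) \
        + rng.normal(size=(n, k * d)) * 0.002
    aligned = gpa_align(shapes.reshape(n, k, d))
    aligned.centroid_sizes = 10.0 ** logs  # sizes carried separately
    res = allometry_residuals(aligned, log_size=True)
    beta_t = gpa.similarity_tangent_project(
        beta.reshape(k, d), consensus).ravel()
    cos = res.slope @ beta_t / (np.linalg.norm(res.slope)
                                * np.linalg.norm(beta_t))
    assert cos > 0.95


def test_tangent_pca_invariants(rng):
    coords = rng.normal(size=(15, 5, 3))
    aligned = gpa_align(coords)
    pca = tangent_pca(aligned)
    assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
    gram = pca.axes @ pca.axes.T
    np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
    np.testing.assert_allclose(pca.reconstruct(), aligned.flat(), atol=1e-8)


def test_tangent_pca_collinear_data(rng):
    direction = rng.normal(size=10)
    y = np.outer(np.linspace(-1, 1, 9), direction)
    pca = tangent_pca(y.reshape(9, 5, 2) + 0.0)
    assert pca.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)


def test_tangent_pca_requires_three(rng):
    with pytest.raises(ValueError):
        tangent_pca(gpa_align(rng.normal(size=(2, 4, 2))))
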