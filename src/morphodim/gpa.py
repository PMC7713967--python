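"""Core shape machinery.

Generalized Procrustes analysis (partial Procrustes: every configuration is
centred and scaled to unit centroid size, rotations fitted by orthogonal
least squares against an iteratively updated consensus), Procrustes
distances, tangent-space PCA, thin-plate-spline interpolation of missing
landmarks, bilateral (object) symmetry decomposition, side averaging and
allometry correction.

Conventions follow mainstream geometric-morphometrics practice: unit
centroid-size scaling, no post-hoc cos(rho) rescaling, reflections
disallowed during alignment unless explicitly requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LandmarkDataset, StructuralError

__all__ = [
    "AlignedSample",
    "PcaResult",
    "SymmetryReport",
    "centroid_size",
    "gpa_align",
    "procrustes_distance",
    "optimal_rotation",
    "tps_interpolate_missing",
    "symmetry_decompose",
    "side_average",
    "allometry_residuals",
    "tangent_pca",
]

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass
class AlignedSample:
    """Procrustes-superimposed configurations.

    ``coords`` are the aligned ``(N, K, D)`` shapes, each centred at the
    origin with centroid size 1; ``centroid_sizes`` are the pre-scaling
    sizes; ``consensus`` is the coordinate-wise mean shape.
    """

    coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int = 0
    converged: bool = True
    log: list[str] = field(default_factory=list)
    specimen_ids: list[str] | None = None

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    def flat(self) -> np.ndarray:
        """Vectorized (N, K*D) view of the aligned coordinates."""
        n = self.coords.shape[0]
        return self.coords.reshape(n, -1)


@dataclass
class PcaResult:
    """Tangent-space PCA of vectorized aligned coordinates."""

    scores: np.ndarray            # (N, m)
    axes: np.ndarray              # (m, K*D), rows orthonormal
    variance_fractions: np.ndarray
    center: np.ndarray            # (K*D,)

    def reconstruct(self) -> np.ndarray:
        return self.center + self.scores @ self.axes


@dataclass
class SymmetryReport:
    """Object-symmetry decomposition of a bilateral sample."""

    directional: np.ndarray       # (K, D) mean (original - mirrored)/2
    r2_directional: float
    r2_fluctuating: float
    p_directional: float
    p_fluctuating: float          # NaN: untestable with one digitization
    table: pd.DataFrame
    n_perm: int
    seed: int | None


# ----------------------------------------------------------------------
# basic geometry
# ----------------------------------------------------------------------

def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid.

    Invariant to rotation and translation; scales linearly under isotropic
    scaling.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 3:
        raise ValueError("config must be (K>=3, D)")
    if np.isnan(config).any():
        raise ValueError(
            "config contains missing coordinates; interpolate first "
            "(see tps_interpolate_missing)"
        )
    centred = config - config.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum()))


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centred = config - config.mean(axis=0)
    cs = np.sqrt((centred ** 2).sum())
    if cs == 0:
        raise ValueError("degenerate configuration with zero centroid size")
    return centred / cs, float(cs)


def optimal_rotation(a: np.ndarray, b: np.ndarray,
                     allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimising ||a R - b||_F over orthogonal (det=+1) R.

    Solved by SVD (Kabsch); with ``allow_reflection`` the full orthogonal
    group is searched.
    """
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def gpa_align(
    data: LandmarkDataset | np.ndarray,
    allow_reflection: bool = False,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> AlignedSample:
    """Generalized Procrustes alignment of N configurations.

    Iteratively rotates each unit-size centred configuration onto the
    current consensus and re-estimates the consensus until the summed
    squared consensus displacement falls below ``tol``.
    """
    if isinstance(data, LandmarkDataset):
        if data.has_missing():
            raise ValueError("dataset has missing landmarks; interpolate first")
        coords = data.coords
        ids = list(data.specimen_ids)
    else:
        coords = np.asarray(data, dtype=float)
        ids = None
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("need an (N>=2, K, D) coordinate array")

    n = coords.shape[0]
    log: list[str] = []
    aligned = np.empty_like(coords, dtype=float)
    sizes = np.empty(n)
    for i in range(n):
        aligned[i], sizes[i] = _center_scale(coords[i])
        sv = np.linalg.svd(aligned[i], compute_uv=False)
        if sv[-1] < 1e-12 and coords.shape[2] > 1:
            log.append(f"configuration {i} is degenerate (rank-deficient); "
                       "rotation falls back to the SVD solution")

    consensus, _ = _center_scale(aligned.mean(axis=0))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(
                aligned[i], consensus, allow_reflection)
        new_consensus, _ = _center_scale(aligned.mean(axis=0))
        shift = ((new_consensus - consensus) ** 2).sum()
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus shift {shift:.3e})", RuntimeWarning)
        log.append("non-convergence")
    # the unit-size consensus drives the iteration; the reported consensus
    # is the plain coordinate-wise mean of the aligned configurations
    return AlignedSample(coords=aligned, centroid_sizes=sizes,
                         consensus=aligned.mean(axis=0), iterations=it,
                         converged=converged, log=log, specimen_ids=ids)


def procrustes_distance(a: np.ndarray, b: np.ndarray,
                        mode: str = "aligned_euclidean") -> float:
    """Distance between two landmark configurations.

    ``aligned_euclidean``: root summed squared coordinate differences of
    already-superimposed shapes.  ``full_ols``: the same after centring,
    scaling to unit centroid size and optimally rotating ``b`` onto ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mode == "aligned_euclidean":
        return float(np.sqrt(((a - b) ** 2).sum()))
    if mode == "full_ols":
        a0, _ = _center_scale(a)
        b0, _ = _center_scale(b)
        b0 = b0 @ optimal_rotation(b0, a0)
        return float(np.sqrt(((a0 - b0) ** 2).sum()))
    raise ValueError(f"unknown mode {mode!r}")


# ----------------------------------------------------------------------
# thin plate splines
# ----------------------------------------------------------------------

def _tps_kernel(r: np.ndarray, ndim: int) -> np.ndarray:
    if ndim == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r * r * np.log(r), 0.0)
        return out
    return -r


def tps_warp(src: np.ndarray, dst: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Thin-plate-spline interpolant taking ``src`` to ``dst``, at ``query``.

    Kernel U(r) = r^2 log r in 2D, U(r) = -r in 3D.  Exactly interpolates
    the source landmarks and reproduces affine maps exactly.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    query = np.atleast_2d(np.asarray(query, dtype=float))
    n, d = src.shape
    r = np.linalg.norm(src[:, None] - src[None], axis=2)
    k = _tps_kernel(r, d)
    p = np.hstack([np.ones((n, 1)), src])
    sys_mat = np.zeros((n + d + 1, n + d + 1))
    sys_mat[:n, :n] = k
    sys_mat[:n, n:] = p
    sys_mat[n:, :n] = p.T
    rhs = np.zeros((n + d + 1, d))
    rhs[:n] = dst
    sol = np.linalg.solve(sys_mat, rhs)
    w, a = sol[:n], sol[n:]
    rq = np.linalg.norm(query[:, None] - src[None], axis=2)
    kq = _tps_kernel(rq, d)
    pq = np.hstack([np.ones((query.shape[0], 1)), query])
    return kq @ w + pq @ a


def tps_interpolate_missing(dataset: LandmarkDataset) -> LandmarkDataset:
    """Fill missing landmarks from a within-population TPS reference.

    For each population (watershed x habitat), complete specimens are
    Procrustes-aligned and their consensus taken as the reference.  Each
    incomplete specimen is superimposed on the reference using its observed
    landmarks (full similarity fit); the reference's missing-landmark
    positions are warped into the specimen through a TPS fitted on the
    observed landmarks, then mapped back to the specimen's original frame.
    """
    if not dataset.has_missing():
        return dataset.copy()
    if dataset.metadata is None:
        raise ValueError("metadata (watershed/habitat) required to form "
                         "population references")
    out = dataset.copy()
    md = dataset.metadata.loc[dataset.specimen_ids]
    pops = md["watershed"].astype(str) + "|" + md["habitat"].astype(str)
    for pop in pops.unique():
        rows = np.flatnonzero((pops == pop).to_numpy())
        mask = dataset.missing_mask[rows]
        if not mask.any():
            continue
        complete = rows[~mask.any(axis=1)]
        if mask.all(axis=0).any():
            bad = np.flatnonzero(mask.all(axis=0))
            raise ValueError(
                f"landmark(s) {bad.tolist()} missing in every specimen of "
                f"population {pop!r}: unrecoverable"
            )
        if len(complete) == 0:
            raise ValueError(f"population {pop!r} has no complete specimen")
        if len(complete) == 1:
            reference = dataset.coords[complete[0]]
            reference = reference - reference.mean(axis=0)
        else:
            reference = gpa_align(dataset.coords[complete]).consensus
        for i in rows[mask.any(axis=1)]:
            obs = ~dataset.missing_mask[i]
            miss = dataset.missing_mask[i]
            spec_obs = dataset.coords[i][obs]
            ref_obs = reference[obs]
            # full similarity superimposition of the specimen onto the
            # reference using observed landmarks: x -> s * (x - mu) @ R + nu
            mu = spec_obs.mean(axis=0)
            nu = ref_obs.mean(axis=0)
            xc = spec_obs - mu
            yc = ref_obs - nu
            rot = optimal_rotation(xc, yc)
            s = float((xc @ rot * yc).sum() / (xc ** 2).sum())
            spec_in_ref = s * xc @ rot + nu
            warped = tps_warp(ref_obs, spec_in_ref, reference[miss])
            # invert the similarity to return to the specimen frame
            filled = (warped - nu) @ rot.T / s + mu
            out.coords[i][miss] = filled
            out.missing_mask[i][miss] = False
    return out


# ----------------------------------------------------------------------
# bilateral symmetry
# ----------------------------------------------------------------------

def _mirror_relabel(coords: np.ndarray, pairs: list[tuple[int, int]],
                    reflect: bool = True) -> np.ndarray:
    """Swap paired landmarks, reflecting across the last coordinate axis.

    With ``reflect=False`` only the relabelling is applied — appropriate
    for lateral-view 2D projections, where the midsagittal mirror acts as
    the identity on the projected coordinates.
    """
    ref = coords.copy()
    if reflect:
        ref[..., -1] *= -1
    out = ref.copy()
    for li, ri in pairs:
        out[..., li, :] = ref[..., ri, :]
        out[..., ri, :] = ref[..., li, :]
    return out


def symmetry_decompose(
    dataset: LandmarkDataset,
    n_perm: int = 999,
    seed: int | None = None,
    reflect: bool | None = None,
) -> SymmetryReport:
    """Object-symmetry analysis of a bilateral landmark sample.

    Each specimen and its relabelled mirror image enter a joint GPA; shape
    variation is then partitioned into symmetric (individual), directional
    (side) and fluctuating (individual x side) components by a Procrustes
    ANOVA, with the side effect tested by residual-randomization
    permutation against the individual-only model.

    With a single digitization per side the fluctuating component is the
    residual and carries no permutation test (p reported as NaN).

    ``reflect`` controls the mirror: True reflects across the last axis
    (3D data); False relabels only (lateral 2D projections).  Default:
    reflect for 3D, relabel-only for 2D.
    """
    if n_perm < 99:
        raise ValueError("n_perm < 99 gives unstable p-values; refusing")
    pairs = dataset.pairs
    if not pairs:
        raise StructuralError("bilateral pairing required")
    if dataset.has_missing():
        raise ValueError("interpolate missing landmarks first")
    from .shape_stats import rrpp_fit  # deferred: avoids import cycle

    if reflect is None:
        reflect = dataset.ndim_coords == 3
    coords = dataset.coords
    mirrored = np.stack([_mirror_relabel(c, pairs, reflect) for c in coords])
    n = coords.shape[0]
    both = np.concatenate([coords, mirrored])
    aligned = gpa_align(both)
    y = aligned.flat()
    data = pd.DataFrame({
        "ind": pd.Categorical([f"s{i}" for i in range(n)] * 2),
        "side": pd.Categorical(["orig"] * n + ["mirror"] * n),
    })
    fit = rrpp_fit(y, data, ["ind", "side"], n_perm=n_perm, seed=seed)
    tab = fit.table
    ss_total = tab.loc["Total", "SS"]
    directional = (aligned.coords[:n] - aligned.coords[n:]).mean(axis=0) / 2
    return SymmetryReport(
        directional=directional,
        r2_directional=float(tab.loc["side", "R2"]),
        r2_fluctuating=float(tab.loc["Residual", "SS"] / ss_total),
        p_directional=float(tab.loc["side", "p_perm"]),
        p_fluctuating=float("nan"),
        table=tab,
        n_perm=n_perm,
        seed=seed,
    )


def side_average(dataset: LandmarkDataset) -> LandmarkDataset:
    """Average bilateral landmark pairs into a one-sided configuration.

    Expects midsagittally oriented coordinates (mirror plane at Z=0 for 3D
    data; see :func:`morphodim.dimension.orient_midsagittal`).  The right
    side is reflected into the left side's orientation and the pair
    averaged.  2D lateral projections are averaged directly, since Z-drop
    projection commutes with the mirror.
    """
    pairs = dataset.pairs
    if not pairs:
        raise StructuralError("bilateral pairing required")
    if dataset.has_missing():
        raise ValueError("interpolate missing landmarks first")
    d = dataset.ndim_coords
    left_idx = [li for li, _ in pairs]
    right_idx = [ri for _, ri in pairs]
    left = dataset.coords[:, left_idx, :]
    right = dataset.coords[:, right_idx, :].copy()
    if d == 3:
        right[..., 2] *= -1
    avg = (left + right) / 2
    return LandmarkDataset(
        coords=avg,
        specimen_ids=list(dataset.specimen_ids),
        landmark_names=[dataset.landmark_names[i] for i in left_idx],
        sides=[""] * len(pairs),
        metadata=dataset.metadata,
    )


# ----------------------------------------------------------------------
# allometry and PCA
# ----------------------------------------------------------------------

@dataclass
class AllometryResult:
    """Size-corrected shapes: residuals of shape on (log) centroid size."""

    coords: np.ndarray            # consensus + residuals, (N, K, D)
    residuals: np.ndarray         # (N, K, D)
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    slope: np.ndarray             # (K*D,) shape change per unit predictor
    log_size: bool
    specimen_ids: list[str] | None = None

    def flat(self) -> np.ndarray:
        return self.residuals.reshape(self.residuals.shape[0], -1)


def allometry_residuals(aligned: AlignedSample,
                        log_size: bool = True) -> AllometryResult:
    """Regress vectorized aligned shapes on (log10) centroid size.

    Returns residual shapes plus the consensus so residual "shapes" remain
    plottable; residuals are exactly orthogonal to the size predictor.
    """
    y = aligned.flat()
    size = np.log10(aligned.centroid_sizes) if log_size else aligned.centroid_sizes
    if np.ptp(size) == 0:
        warnings.warn("zero variance in centroid size; passing through "
                      "centred shapes", RuntimeWarning)
        resid = y - y.mean(axis=0)
        slope = np.zeros(y.shape[1])
    else:
        x = np.column_stack([np.ones_like(size), size])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        slope = beta[1]
    k, d = aligned.consensus.shape
    resid3 = resid.reshape(-1, k, d)
    return AllometryResult(
        coords=aligned.consensus[None] + resid3,
        residuals=resid3,
        consensus=aligned.consensus,
        centroid_sizes=aligned.centroid_sizes,
        slope=slope,
        log_size=log_size,
        specimen_ids=aligned.specimen_ids,
    )


def similarity_tangent_project(pattern: np.ndarray,
                               reference: np.ndarray) -> np.ndarray:
    """Remove the similarity-transform components of a shape displacement.

    Projects a K x D displacement pattern orthogonal to the subspace
    spanned, at ``reference``, by translations, the scaling direction and
    the infinitesimal rotation generators.  Superimposition estimates
    shape effects only up to this projection, so generator effect vectors
    must be projected before being compared with fitted coefficients.
    """
    ref = np.asarray(reference, dtype=float)
    k, d = ref.shape
    ref = ref - ref.mean(axis=0)
    basis = []
    for j in range(d):
        t = np.zeros((k, d))
        t[:, j] = 1.0
        basis.append(t.ravel())
    basis.append(ref.ravel())
    for a in range(d):
        for b in range(a + 1, d):
            g = np.zeros((d, d))
            g[a, b], g[b, a] = 1.0, -1.0
            basis.append((ref @ g).ravel())
    q, _ = np.linalg.qr(np.array(basis).T)
    v = np.asarray(pattern, dtype=float).ravel()
    return (v - q @ (q.T @ v)).reshape(k, d)


def tangent_pca(aligned: AlignedSample | AllometryResult) -> PcaResult:
    """Covariance PCA of vectorized aligned coordinates about their mean."""
    if isinstance(aligned, np.ndarray):
        y = aligned.reshape(aligned.shape[0], -1)
    else:
        y = aligned.flat()
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 specimens for a tangent PCA")
    center = y.mean(axis=0)
    yc = y - center
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    m = min(n - 1, y.shape[1])
    u, s, vt = u[:, :m], s[:m], vt[:m]
    var = s ** 2
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    return PcaResult(scores=u * s, axes=vt,
                     variance_fractions=fractions, center=center)
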