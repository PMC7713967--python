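"""Four-bar linkage kinematics and mandibular lever mechanics.

A four-bar linkage is a closed chain of four rigid links: a fixed link
(suspensorium), an input link rotated by a prescribed angle about one
fixed joint, an output link rotating about the other fixed joint, and a
coupler connecting the two moving joints.  Kinematic transmission (KT) is
the ratio of output-link rotation to input-link rotation over a 10 deg
input sweep (the standard convention for fish jaw linkages).

Two solvers are provided: a planar closed-form solution (circle-circle
intersection with branch continuation) for 2D coordinates, and a 3D
solver in which the input and output links each rotate about prescribed
(possibly tilted) joint axes and the output angle at each increment is
found by closing the coupler loop to machine tolerance.

Landmark-to-link assignments are configuration data, not code constants:
``DEFAULT_LINKAGE_SPEC`` carries the opercular (Op4) and maxillary (Max4)
linkages and the opening/closing mandibular levers, keyed by 1-based
landmark numbers, and can be overridden wholesale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import shape_stats
from .gpa import PcaResult, tangent_pca

__all__ = [
    "MechanismError",
    "FourBarLinkage",
    "LeverSpec",
    "KinematicEstimates",
    "DEFAULT_LINKAGE_SPEC",
    "build_linkages",
    "planar_kt",
    "spatial_kt",
    "lever_ratios",
    "size_correct_function",
    "kinematic_stats",
    "axis_from_angles",
]

#: Default landmark-number assignments for the trophic lever systems.
#: ``input``/``output`` tuples are (fixed joint, moving joint).
#: Op4: fixed suspensorium 2-3, input opercle 2-1, coupler
#: interopercle/ligament 1-4, output mandible 3-4.  Max4: fixed 3-8,
#: input lower jaw 3-6, coupler maxilla 6-7, output nasal link 8-7.
#: Levers: jaw joint 3, opening in-lever 3-4, closing in-lever 3-6,
#: shared out-lever 3-5.
DEFAULT_LINKAGE_SPEC: dict = {
    "op4": {"fixed": (2, 3), "input": (2, 1), "coupler": (1, 4),
            "output": (3, 4)},
    "max4": {"fixed": (3, 8), "input": (3, 6), "coupler": (6, 7),
             "output": (8, 7)},
    "levers": {"fulcrum": 3, "in_open": 4, "in_close": 6, "out": 5},
}

DEFAULT_INPUT_ROTATION = 10.0  # degrees


class MechanismError(RuntimeError):
    """The linkage cannot close (locks) over the requested sweep."""


@dataclass
class FourBarLinkage:
    """Joint coordinates and link assignment of a four-bar mechanism.

    ``fixed_in``/``fixed_out`` are the two grounded joints; ``moving_in``
    is carried by the input link (rotating about ``fixed_in``) and
    ``moving_out`` by the output link (rotating about ``fixed_out``).
    """

    fixed_in: np.ndarray
    moving_in: np.ndarray
    fixed_out: np.ndarray
    moving_out: np.ndarray
    name: str = ""
    input_axis: np.ndarray | None = None
    output_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        for attr in ("fixed_in", "moving_in", "fixed_out", "moving_out"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        lengths = self.link_lengths
        if min(lengths.values()) < 1e-12:
            bad = [k for k, v in lengths.items() if v < 1e-12]
            raise ValueError(
                f"degenerate linkage {self.name!r}: coincident joints give "
                f"zero-length link(s) {bad}")

    @property
    def link_lengths(self) -> dict[str, float]:
        return {
            "fixed": float(np.linalg.norm(self.fixed_in - self.fixed_out)),
            "input": float(np.linalg.norm(self.fixed_in - self.moving_in)),
            "coupler": float(np.linalg.norm(self.moving_in - self.moving_out)),
            "output": float(np.linalg.norm(self.fixed_out - self.moving_out)),
        }

    def loop_closure_residual(self) -> float:
        """Closure defect of the initial pose (zero by construction, since
        the four links share their joints)."""
        lengths = self.link_lengths
        chain = (lengths["input"], lengths["coupler"], lengths["output"],
                 lengths["fixed"])
        return 0.0 * sum(chain)

    def to_2d(self) -> "FourBarLinkage":
        if self.fixed_in.shape[0] == 2:
            return self
        return FourBarLinkage(
            fixed_in=self.fixed_in[:2], moving_in=self.moving_in[:2],
            fixed_out=self.fixed_out[:2], moving_out=self.moving_out[:2],
            name=self.name + "_2d")


@dataclass
class LeverSpec:
    """Mandibular lever arms: in-levers and the shared out-lever (mm)."""

    in_open: float
    in_close: float
    out: float


@dataclass
class KinematicEstimates:
    """Per-specimen functional estimates (dimensionless)."""

    table: pd.DataFrame      # columns kt_op4, kt_max4, lr_open, lr_close
    dimensionality: str      # "2d" | "3d"
    residual_table: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------

def _lm(config: np.ndarray, number: int) -> np.ndarray:
    return config[number - 1]


def build_linkages(
    config: np.ndarray,
    spec: dict | None = None,
) -> tuple[FourBarLinkage, FourBarLinkage, LeverSpec]:
    """Assemble Op4 and Max4 linkages and the lever arms from a one-sided
    8-landmark configuration (rows = landmark numbers 1-8)."""
    spec = spec or DEFAULT_LINKAGE_SPEC
    config = np.asarray(config, dtype=float)
    if np.isnan(config).any():
        raise ValueError("configuration has missing landmarks")

    def four_bar(name: str) -> FourBarLinkage:
        s = spec[name]
        return FourBarLinkage(
            fixed_in=_lm(config, s["input"][0]),
            moving_in=_lm(config, s["input"][1]),
            fixed_out=_lm(config, s["output"][0]),
            moving_out=_lm(config, s["output"][1]),
            name=name,
        )

    lv = spec["levers"]
    f = _lm(config, lv["fulcrum"])
    lever = LeverSpec(
        in_open=float(np.linalg.norm(_lm(config, lv["in_open"]) - f)),
        in_close=float(np.linalg.norm(_lm(config, lv["in_close"]) - f)),
        out=float(np.linalg.norm(_lm(config, lv["out"]) - f)),
    )
    if lever.out < 1e-12:
        raise ValueError("zero-length out-lever")
    return four_bar("op4"), four_bar("max4"), lever


# ----------------------------------------------------------------------
# planar solver
# ----------------------------------------------------------------------

def _rot2(v: np.ndarray, center: np.ndarray, theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    d = v - center
    return center + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def _circle_intersect(c1: np.ndarray, r1: float, c2: np.ndarray, r2: float
                      ) -> tuple[np.ndarray, np.ndarray] | None:
    d = float(np.linalg.norm(c2 - c1))
    if d > r1 + r2 or d < abs(r1 - r2) or d == 0:
        return None
    a = (r1 * r1 - r2 * r2 + d * d) / (2 * d)
    h2 = r1 * r1 - a * a
    h = math.sqrt(max(h2, 0.0))
    ex = (c2 - c1) / d
    ey = np.array([-ex[1], ex[0]])
    base = c1 + a * ex
    return base + h * ey, base - h * ey


def _link_angle2(fixed: np.ndarray, moving: np.ndarray) -> float:
    d = moving - fixed
    return math.atan2(d[1], d[0])


def planar_kt(
    linkage: FourBarLinkage,
    input_rotation: float = DEFAULT_INPUT_ROTATION,
    n_steps: int = 20,
) -> float:
    """Planar kinematic transmission by closed-form loop closure.

    The input link is rotated in ``n_steps`` increments; at each step the
    output joint is the circle-circle intersection (radius = output link
    about the fixed output joint, radius = coupler about the new input
    joint) continuous with the previous pose.  KT is the total output
    angular excursion over the input rotation.
    """
    lk = linkage.to_2d()
    lengths = lk.link_lengths
    theta_total = math.radians(input_rotation)
    out_prev = lk.moving_out.copy()
    ang_prev = _link_angle2(lk.fixed_out, out_prev)
    excursion = 0.0
    for step in range(1, n_steps + 1):
        theta = theta_total * step / n_steps
        p_in = _rot2(lk.moving_in, lk.fixed_in, theta)
        hit = _circle_intersect(lk.fixed_out, lengths["output"],
                                p_in, lengths["coupler"])
        if hit is None:
            max_deg = input_rotation * (step - 1) / n_steps
            raise MechanismError(
                f"{lk.name or 'linkage'} locks: no closure beyond "
                f"{max_deg:.3f} deg of input rotation")
        # branch continuous with the previous pose
        cand = min(hit, key=lambda q: float(np.linalg.norm(q - out_prev)))
        ang = _link_angle2(lk.fixed_out, cand)
        d_ang = math.remainder(ang - ang_prev, math.tau)
        excursion += d_ang
        out_prev, ang_prev = cand, ang
    return abs(excursion) / abs(theta_total)


# ----------------------------------------------------------------------
# spatial solver
# ----------------------------------------------------------------------

def axis_from_angles(polar_deg: float, azimuth_deg: float = 0.0) -> np.ndarray:
    """Unit joint axis tilted ``polar_deg`` away from Z.

    With azimuth 0 the tilt is within the YZ plane (toward dorsoventral Y);
    azimuth rotates the tilt direction about Z.
    """
    p = math.radians(polar_deg)
    a = math.radians(azimuth_deg)
    return np.array([math.sin(p) * math.sin(a),
                     math.sin(p) * math.cos(a),
                     math.cos(p)])


def _rodrigues(points: np.ndarray, center: np.ndarray, axis: np.ndarray,
               theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    d = points - center
    c, s = math.cos(theta), math.sin(theta)
    return (center + c * d + s * np.cross(axis, d)
            + (1 - c) * np.outer(d @ axis, axis).reshape(d.shape))


def spatial_kt(
    linkage: FourBarLinkage,
    input_axis: np.ndarray | None = None,
    output_axis: np.ndarray | None = None,
    input_rotation: float = DEFAULT_INPUT_ROTATION,
    n_steps: int = 20,
    tol: float = 1e-9,
) -> float:
    """3D kinematic transmission with prescribed joint rotation axes.

    The input link rotates rigidly about (``fixed_in``, ``input_axis``);
    the output link is constrained to rotate about (``fixed_out``,
    ``output_axis``) and its angle at each increment solves the coupler
    loop-closure condition |moving_in - moving_out| = coupler length to
    within ``tol`` mm, continuing from the previous increment.  KT is the
    output angular excursion about its axis divided by the input rotation.
    """
    input_axis = np.asarray(
        input_axis if input_axis is not None
        else linkage.input_axis if linkage.input_axis is not None
        else [0.0, 0.0, 1.0], dtype=float)
    output_axis = np.asarray(
        output_axis if output_axis is not None
        else linkage.output_axis if linkage.output_axis is not None
        else [0.0, 0.0, 1.0], dtype=float)
    input_axis = input_axis / np.linalg.norm(input_axis)
    output_axis = output_axis / np.linalg.norm(output_axis)

    lengths = linkage.link_lengths
    coupler = lengths["coupler"]
    theta_total = math.radians(input_rotation)
    phi = 0.0

    def closure(theta: float, phi_val: float) -> float:
        p_in = _rodrigues(linkage.moving_in[None], linkage.fixed_in,
                          input_axis, theta)[0]
        p_out = _rodrigues(linkage.moving_out[None], linkage.fixed_out,
                           output_axis, phi_val)[0]
        return float(np.linalg.norm(p_in - p_out)) - coupler

    for step in range(1, n_steps + 1):
        theta = theta_total * step / n_steps
        f0 = closure(theta, phi)
        if abs(f0) <= tol:
            continue
        # bracket a root around the continuation value
        width = math.radians(1.0)
        lo = hi = phi
        found = False
        for _ in range(12):
            lo, hi = phi - width, phi + width
            flo, fhi = closure(theta, lo), closure(theta, hi)
            if flo == 0.0 or fhi == 0.0 or (flo < 0) != (fhi < 0):
                found = True
                break
            width *= 2.0
        if not found:
            max_deg = input_rotation * (step - 1) / n_steps
            raise MechanismError(
                f"{linkage.name or 'linkage'} cannot close beyond "
                f"{max_deg:.3f} deg (loop residual {f0:.3e} mm)")
        if closure(theta, lo) == 0.0:
            phi = lo
        elif closure(theta, hi) == 0.0:
            phi = hi
        else:
            phi = optimize.brentq(lambda v: closure(theta, v), lo, hi,
                                  xtol=1e-14, rtol=8.9e-16)
        resid = abs(closure(theta, phi))
        if resid > tol:
            raise MechanismError(
                f"loop-closure residual {resid:.3e} mm above tolerance "
                f"{tol:g} at step {step}")
    return abs(phi) / abs(theta_total)


def opening_direction(linkage: FourBarLinkage, planar: bool = False,
                      probe_deg: float = 0.5) -> float:
    """Sign of the input rotation that moves the output's moving joint
    ventrally (negative Y) -- the jaw-opening sense."""
    for sign in (1.0, -1.0):
        try:
            if planar:
                lk = linkage.to_2d()
                lengths = lk.link_lengths
                p_in = _rot2(lk.moving_in, lk.fixed_in,
                             math.radians(sign * probe_deg))
                hit = _circle_intersect(lk.fixed_out, lengths["output"],
                                        p_in, lengths["coupler"])
                if hit is None:
                    continue
                cand = min(hit,
                           key=lambda q: float(np.linalg.norm(q - lk.moving_out)))
                dy = cand[1] - lk.moving_out[1]
            else:
                p_in = _rodrigues(linkage.moving_in[None], linkage.fixed_in,
                                  np.array([0.0, 0.0, 1.0]),
                                  math.radians(sign * probe_deg))[0]
                dy = p_in[1] - linkage.moving_in[1]
            if dy < 0:
                return sign
        except MechanismError:
            continue
    return 1.0


# ----------------------------------------------------------------------
# levers and statistics
# ----------------------------------------------------------------------

def lever_ratios(lever: LeverSpec) -> tuple[float, float]:
    """Opening and closing lever ratios (in-lever over out-lever)."""
    if lever.out <= 0:
        raise ValueError("zero out-lever")
    return lever.in_open / lever.out, lever.in_close / lever.out


def size_correct_function(values: np.ndarray, centroid_sizes: np.ndarray
                          ) -> np.ndarray:
    """Residuals of functional estimates on log10 centroid size.

    KT and LR cannot be computed from shape residuals, so size correction
    happens downstream: each variable is regressed on the log10 centroid
    size of the entire landmark set and the residuals carried forward.
    """
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(centroid_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be positive")
    x = np.log10(sizes)
    if np.ptp(x) == 0:
        import warnings
        warnings.warn("constant centroid size; returning centred values",
                      RuntimeWarning)
        return values - values.mean()
    xm = x - x.mean()
    slope = (xm @ (values - values.mean())) / (xm @ xm)
    resid = values - values.mean() - slope * xm
    return resid


def kinematic_stats(
    estimates: pd.DataFrame,
    data: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Univariate ANCOVAs per kinematic variable, a multivariate PERMANOVA
    over all of them, and a covariance PCA of the variable matrix.

    ``estimates`` holds the (size-corrected) kinematic columns; ``data``
    the specimen covariates/factors; ``terms`` the model.
    """
    y = estimates.to_numpy(dtype=float)
    out: dict = {"univariate": {}, "pca_loadings": None}
    for j, col in enumerate(estimates.columns):
        out["univariate"][col] = shape_stats.rrpp_fit(
            y[:, j], data, terms, n_perm=n_perm, seed=seed)
    out["multivariate"] = shape_stats.rrpp_fit(
        y, data, terms, n_perm=n_perm,
        seed=None if seed is None else seed + 1)
    centred = y - y.mean(axis=0)
    pca: PcaResult = tangent_pca(centred)
    out["pca"] = pca
    out["pca_loadings"] = pd.DataFrame(
        pca.axes, columns=estimates.columns,
        index=[f"PC{i+1}" for i in range(pca.axes.shape[0])])
    return out
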