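"""Synthetic bilateral landmark data and diet compositions.

The generator emulates a replicated lake-stream design: six watersheds,
each with a parapatric lake and stream population of about five fish.
Every specimen is a stylized 8-landmark (per side) trophic-lever
configuration built from a bilaterally symmetric template plus

* a shared habitat/diet effect vector (direction partly in the Z/width
  dimension, controlled by ``habitat_effect_z_fraction``) scaled by the
  population's diet score,
* a random symmetric watershed effect and a watershed x habitat
  interaction,
* allometric shape change along log10 centroid size (lognormal sizes),
* a consistent directional-asymmetry offset plus per-specimen fluctuating
  asymmetry, and
* independent landmark noise,

after which each specimen is rigidly rotated and translated into a random
digitization frame.  Diet compositions are drawn from habitat-specific
Dirichlet distributions.  Every drawn effect is kept in a truth record so
parameter recovery can be tested end to end.  A single master seed
deterministically derives all sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diet import DietTable
from .io import DEFAULT_LANDMARK_NAMES, LandmarkDataset

__all__ = [
    "SimulationConfig",
    "TEMPLATE_LEFT",
    "bilateral_template",
    "simulate_landmarks",
    "simulate_diet",
    "true_habitat_contrast",
]

#: Stylized left-side trophic landmark template (mm): X anterior, Y dorsal,
#: Z lateral (left positive).  Plausible proportions for a small fish head;
#: no anatomical claim beyond positive link lengths and feasible linkages.
TEMPLATE_LEFT = np.array([
    [-3.0, -2.5, 1.6],   # 1 opercle ventral tip
    [-3.5,  2.0, 1.8],   # 2 opercular-hyomandibular joint
    [ 0.0,  0.0, 1.5],   # 3 articular-quadrate joint
    [ 0.8, -0.8, 1.4],   # 4 interopercle-ligament insertion
    [ 4.0, -0.5, 0.8],   # 5 anterior tooth tip
    [ 1.0,  0.8, 1.3],   # 6 articular dorsal tip
    [ 3.5,  1.2, 1.0],   # 7 maxilla anterior tip
    [ 1.5,  2.5, 1.2],   # 8 lateral ethmoid-lacrimal joint
])

PREY_CATEGORIES = (
    "copepods", "ostracods", "cladocerans", "chironomids",
    "ceratopogonids", "clams", "caddisflies", "amphipods",
    "mites", "plecopterans", "empidids", "other",
)

# lake diets lean on zooplankton (copepods, cladocerans, caddisflies);
# stream diets on benthic prey (chironomids, ostracods, clams, amphipods,
# empidids).  The shifts are mild on purpose: individual gut contents of
# parapatric pairs overlap heavily even when population means separate.
LAKE_ALPHA = (2.4, 1.5, 2.4, 2.5, 1.0, 1.0, 1.4, 1.5, 0.8, 0.8, 1.0, 1.2)
STREAM_ALPHA = (2.0, 1.78, 2.0, 2.78, 1.0, 1.28, 1.0, 1.78, 0.8, 0.8, 1.28, 1.2)


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the generator.

    Norms are Frobenius norms of the full bilateral 16x3 displacement
    pattern in mm; SDs are per-coordinate in mm.
    """

    n_watersheds: int = 6
    n_per_population: int = 5
    template: np.ndarray = field(
        default_factory=lambda: TEMPLATE_LEFT.copy())
    habitat_effect_norm: float = 0.2
    habitat_effect_z_fraction: float = 0.5
    habitat_effect_vector: np.ndarray | None = None  # overrides the draw
    watershed_sd: float = 0.08
    interaction_sd: float = 0.04
    allometry_norm: float = 0.15       # shape change per unit log10 size
    size_log10_sd: float = 0.08
    directional_asymmetry: float = 0.04
    fluctuating_sd: float = 0.02
    noise_sd: float = 0.05
    diet_score_sd: float = 0.2
    n_fish_per_pop_diet: int = 15
    lake_alpha: tuple = LAKE_ALPHA
    stream_alpha: tuple = STREAM_ALPHA
    prey_categories: tuple = PREY_CATEGORIES
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if self.template.shape != (8, 3):
            raise ValueError("template must be (8, 3) left-side landmarks")
        if np.linalg.matrix_rank(self.template - self.template.mean(0)) < 2:
            raise ValueError("degenerate template")
        for name in ("watershed_sd", "interaction_sd", "fluctuating_sd",
                     "noise_sd", "size_log10_sd", "diet_score_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.habitat_effect_z_fraction <= 1:
            raise ValueError("habitat_effect_z_fraction must be in [0, 1]")
        if min(self.lake_alpha) <= 0 or min(self.stream_alpha) <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


def bilateral_template(left: np.ndarray) -> np.ndarray:
    """(16, 3) bilateral configuration: left block then mirrored right."""
    right = left.copy()
    right[:, 2] *= -1
    return np.vstack([left, right])


def _mirror_left_pattern(delta_left: np.ndarray) -> np.ndarray:
    """Symmetric bilateral displacement from a left-side (8, 3) pattern."""
    return bilateral_template(delta_left)


def _split_z_direction(rng: np.random.Generator, z_fraction: float
                       ) -> np.ndarray:
    """Unit left-side (8,3) direction with a set fraction of squared norm
    in the Z coordinates."""
    xy = rng.standard_normal((8, 2))
    xy /= np.linalg.norm(xy)
    z = rng.standard_normal(8)
    z /= np.linalg.norm(z)
    out = np.zeros((8, 3))
    out[:, :2] = np.sqrt(1 - z_fraction) * xy
    out[:, 2] = np.sqrt(z_fraction) * z
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def simulate_landmarks(config: SimulationConfig
                       ) -> tuple[LandmarkDataset, dict]:
    """Draw a 3D bilateral landmark dataset plus its truth record."""
    ss = np.random.SeedSequence(config.seed)
    ss_effects, ss_scores, ss_specimens = ss.spawn(3)
    rng = np.random.default_rng(ss_effects)

    template16 = bilateral_template(config.template)
    base_cs = np.sqrt(((template16 - template16.mean(0)) ** 2).sum())

    # habitat/diet effect: symmetric bilateral pattern with a controlled
    # width (Z) component; norm is of the full 16x3 pattern
    if config.habitat_effect_vector is not None:
        habitat_effect = np.asarray(config.habitat_effect_vector, float)
        if habitat_effect.shape != (16, 3):
            raise ValueError("habitat_effect_vector must be (16, 3)")
    else:
        direction = _split_z_direction(rng, config.habitat_effect_z_fraction)
        habitat_effect = _mirror_left_pattern(direction)
        norm = np.linalg.norm(habitat_effect)
        habitat_effect *= (config.habitat_effect_norm / norm
                           if norm > 0 else 0.0)

    watersheds = [f"ws{i+1}" for i in range(config.n_watersheds)]
    watershed_effects = {
        w: _mirror_left_pattern(
            rng.standard_normal((8, 3)) * config.watershed_sd)
        for w in watersheds
    }
    interaction_effects = {
        (w, h): _mirror_left_pattern(
            rng.standard_normal((8, 3)) * config.interaction_sd)
        for w in watersheds for h in ("lake", "stream")
    }
    allometry = _mirror_left_pattern(rng.standard_normal((8, 3)))
    a_norm = np.linalg.norm(allometry)
    allometry *= config.allometry_norm / a_norm if a_norm > 0 else 0.0
    da_left = rng.standard_normal((8, 3))
    da_left *= config.directional_asymmetry / np.linalg.norm(da_left) \
        if config.directional_asymmetry > 0 else 0.0

    score_rng = np.random.default_rng(ss_scores)
    pop_scores = {}
    for w in watersheds:
        for h in ("lake", "stream"):
            center = -1.0 if h == "lake" else 1.0
            pop_scores[(w, h)] = float(
                center + score_rng.normal(0, config.diet_score_sd))

    n_total = config.n_watersheds * 2 * config.n_per_population
    spec_seeds = ss_specimens.spawn(n_total)
    coords = np.empty((n_total, 16, 3))
    ids, meta_rows = [], []
    sizes = np.empty(n_total)
    sexes = ("M", "F", "U")
    i = 0
    for w in watersheds:
        for h in ("lake", "stream"):
            for j in range(config.n_per_population):
                srng = np.random.default_rng(spec_seeds[i])
                shape = (template16
                         + watershed_effects[w]
                         + pop_scores[(w, h)] * habitat_effect
                         + interaction_effects[(w, h)])
                log_size = srng.normal(np.log10(base_cs),
                                       config.size_log10_sd)
                shape = shape + (log_size - np.log10(base_cs)) * allometry
                # side-signed directional asymmetry
                shape[:8] += da_left / 2
                shape[8:] -= _mirror_left_pattern(da_left)[8:] / 2
                # fluctuating asymmetry + digitization noise (asymmetric)
                shape = shape + srng.standard_normal((16, 3)) * \
                    config.fluctuating_sd
                shape = shape + srng.standard_normal((16, 3)) * \
                    config.noise_sd
                # set centroid size, then a random digitization frame
                cs = np.sqrt(((shape - shape.mean(0)) ** 2).sum())
                shape = shape * (10.0 ** log_size / cs)
                rot = _random_rotation(srng)
                shift = srng.uniform(-20, 20, size=3)
                coords[i] = shape @ rot.T + shift
                sizes[i] = 10.0 ** log_size
                sid = f"{w}-{h}-{j+1:02d}"
                ids.append(sid)
                meta_rows.append({"specimen_id": sid, "watershed": w,
                                  "habitat": h, "sex": sexes[j % 3]})
                i += 1

    metadata = pd.DataFrame(meta_rows).set_index("specimen_id")
    names = list(DEFAULT_LANDMARK_NAMES) * 2
    side_labels = ["L"] * 8 + ["R"] * 8
    dataset = LandmarkDataset(coords=coords, specimen_ids=ids,
                              landmark_names=names, sides=side_labels,
                              metadata=metadata)
    truth = {
        "habitat_effect": habitat_effect,
        "watershed_effects": watershed_effects,
        "interaction_effects": interaction_effects,
        "allometry": allometry,
        "directional_asymmetry_left": da_left,
        "pop_scores": pop_scores,
        "sizes": sizes,
        "template": template16,
        "config": {k: v for k, v in asdict(config).items()
                   if np.isscalar(v)},
    }
    return dataset, truth


def simulate_diet(config: SimulationConfig) -> DietTable:
    """Draw per-fish diet compositions from habitat-specific Dirichlets."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])
    rows, habs, pops, ids = [], [], [], []
    for wi in range(config.n_watersheds):
        w = f"ws{wi+1}"
        for h in ("lake", "stream"):
            alpha = np.asarray(
                config.lake_alpha if h == "lake" else config.stream_alpha,
                dtype=float)
            draws = rng.dirichlet(alpha, size=config.n_fish_per_pop_diet)
            for f in range(config.n_fish_per_pop_diet):
                rows.append(draws[f])
                habs.append(h)
                pops.append(f"{w}-{h}")
                ids.append(f"{w}-{h}-diet{f+1:02d}")
    proportions = pd.DataFrame(rows, index=ids,
                               columns=list(config.prey_categories))
    return DietTable(proportions=proportions,
                     habitat=pd.Series(habs, index=ids),
                     population=pd.Series(pops, index=ids))


def true_habitat_contrast(truth: dict) -> np.ndarray:
    """Noise-free stream-vs-lake mean contrast, side-averaged (8, 3).

    This is the generator's habitat-effect pattern expressed in the
    one-sided space the pipeline analyses (left block of the symmetric
    bilateral pattern), per unit diet score.
    """
    return truth["habitat_effect"][:8]
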