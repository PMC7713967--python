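"""2D datasets from 3D landmarks, and the joint 2D-3D common shape space.

The lateral-view 2D dataset is produced by rotating each specimen so its
midsagittal plane (the best-fit mirror plane through the midpoints of the
left-right landmark pairs) lies at Z=0, then dropping the Z column.  The
common shape space embeds 2D shapes at Z=0 and jointly superimposes the
centroid-size residual shapes of both dimensionalities, so that each
specimen appears twice and 2D-3D distortion can be measured directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gpa
from .io import LandmarkDataset, StructuralError

__all__ = [
    "CommonSpaceSample",
    "orient_midsagittal",
    "project_to_2d",
    "project_dataset",
    "build_common_space",
    "paired_2d3d_distances",
]


# ----------------------------------------------------------------------
# midsagittal orientation
# ----------------------------------------------------------------------

def _mirror_plane(config: np.ndarray, pairs: list[tuple[int, int]]
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through left-right pair midpoints.

    Returns (centroid, unit normal, rms residual).  The normal is signed
    toward the left side (mean of left-minus-right coordinates), so that
    left landmarks get positive Z after orientation.
    """
    left = config[[li for li, _ in pairs]]
    right = config[[ri for _, ri in pairs]]
    mids = (left + right) / 2
    c = mids.mean(axis=0)
    centred = mids - c
    if np.allclose(centred, 0):
        raise ValueError("degenerate pair midpoints (all coincident)")
    _, sv, vt = np.linalg.svd(centred, full_matrices=True)
    normal = vt[-1]
    lr = (left - right).mean(axis=0)
    if normal @ lr < 0:
        normal = -normal
    rms = float(np.sqrt((((centred @ normal)) ** 2).mean()))
    return c, normal, rms


def orient_midsagittal(
    config: np.ndarray,
    pairs: list[tuple[int, int]],
    anterior_landmark: int = 4,
) -> np.ndarray:
    """Rotate/translate a bilateral 3D configuration to a canonical frame.

    The best-fit mirror plane is mapped to Z=0 (left side at positive Z),
    the X axis is the anterior-posterior extent (first in-plane principal
    axis of the pair midpoints), signed so that ``anterior_landmark``
    (default: the anterior tooth tip, landmark 5, index 4) lies anterior
    (positive X).  Deterministic; idempotent up to numerical precision.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[1] != 3:
        raise ValueError("config must be (K, 3)")
    if not pairs:
        raise StructuralError("bilateral pairing required")
    c, normal, _ = _mirror_plane(config, pairs)
    mids = (config[[li for li, _ in pairs]]
            + config[[ri for _, ri in pairs]]) / 2 - c
    in_plane = mids - np.outer(mids @ normal, normal)
    _, _, vt = np.linalg.svd(in_plane, full_matrices=False)
    x_axis = vt[0]
    x_axis -= (x_axis @ normal) * normal
    x_axis /= np.linalg.norm(x_axis)
    # anterior landmark on the positive-X side of the midpoint centroid
    ant = config[anterior_landmark] - c
    if ant @ x_axis < 0:
        x_axis = -x_axis
    y_axis = np.cross(normal, x_axis)
    rot = np.column_stack([x_axis, y_axis, normal])
    return (config - c) @ rot


def project_to_2d(config: np.ndarray, pairs: list[tuple[int, int]] | None = None,
                  tol: float = 1e-6) -> np.ndarray:
    """Drop the Z column of a midsagittally oriented configuration."""
    config = np.asarray(config, dtype=float)
    if config.shape[1] == 2:
        return config.copy()
    if pairs:
        # if oriented, pair midpoints sit near Z=0 up to the asymmetric
        # part of the shape (the plane-fit rms residual)
        _, _, rms = _mirror_plane(config, pairs)
        scale = np.abs(config).max() or 1.0
        mids = (config[[li for li, _ in pairs]]
                + config[[ri for _, ri in pairs]]) / 2
        if np.abs(mids[:, 2]).max() > tol * scale + 10 * rms:
            warnings.warn("configuration does not appear midsagittally "
                          "oriented; Z-drop may not be a lateral view",
                          RuntimeWarning)
    return config[:, :2].copy()


def project_dataset(dataset: LandmarkDataset, orient: bool = True,
                    anterior_landmark: int | None = None) -> LandmarkDataset:
    """Orient every specimen midsagittally and drop Z, keeping metadata.

    For bilateral datasets the mirror plane comes from the landmark pairs;
    one-sided datasets are assumed already oriented.
    """
    if dataset.ndim_coords == 2:
        return dataset.copy()
    pairs = dataset.pairs
    coords2 = np.empty(dataset.coords.shape[:2] + (2,))
    for i in range(dataset.n_specimens):
        cfg = dataset.coords[i]
        if orient and pairs:
            kwargs = {}
            if anterior_landmark is not None:
                kwargs["anterior_landmark"] = anterior_landmark
            cfg = orient_midsagittal(cfg, pairs, **kwargs)
        coords2[i] = cfg[:, :2]
    return LandmarkDataset(
        coords=coords2,
        specimen_ids=list(dataset.specimen_ids),
        landmark_names=list(dataset.landmark_names),
        sides=list(dataset.sides),
        metadata=dataset.metadata,
    )


# ----------------------------------------------------------------------
# common 2D-3D shape space
# ----------------------------------------------------------------------

@dataclass
class CommonSpaceSample:
    """Jointly superimposed 2D and 3D representations of the same specimens.

    ``aligned.coords`` holds 2N configurations (2D entries embedded at
    Z=0 before the joint superimposition); ``provenance`` flags each entry
    ``from_2d`` or ``from_3d``; ``pairing`` maps specimen id to its
    (2d index, 3d index).
    """

    aligned: gpa.AlignedSample
    provenance: np.ndarray
    pairing: dict[str, tuple[int, int]]
    specimen_ids: list[str]

    @property
    def coords(self) -> np.ndarray:
        return self.aligned.coords

    def frame(self, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-entry metadata frame (specimen, space) for model fitting."""
        df = pd.DataFrame({
            "specimen_id": self.specimen_ids * 2
            if len(self.specimen_ids) * 2 == len(self.provenance)
            else list(self.specimen_ids),
            "space": self.provenance,
        })
        if metadata is not None:
            df = df.join(metadata, on="specimen_id")
        return df


def build_common_space(
    dataset3d: LandmarkDataset,
    dataset2d: LandmarkDataset,
    add_consensus: bool = True,
) -> CommonSpaceSample:
    """Joint superimposition of centroid-size residual 2D and 3D shapes.

    Within each dimensionality: GPA, regression of shape on log10 centroid
    size, residuals taken (centring each set about its consensus).  With
    ``add_consensus`` each dimensionality's consensus is added back so the
    joint GPA operates on shape-like configurations; 2D shapes are then
    embedded at Z=0 and all 2N configurations superimposed together.
    """
    if dataset3d.specimen_ids != dataset2d.specimen_ids:
        missing = set(dataset3d.specimen_ids) ^ set(dataset2d.specimen_ids)
        raise ValueError(f"specimen sets differ (or order differs): "
                         f"{sorted(missing) or 'order mismatch'}")
    if dataset3d.landmark_names != dataset2d.landmark_names:
        raise ValueError("landmark names differ between datasets")

    reps = []
    for ds in (dataset2d, dataset3d):
        aligned = gpa.gpa_align(ds)
        allo = gpa.allometry_residuals(aligned)
        shapes = allo.residuals + (allo.consensus[None] if add_consensus else 0)
        reps.append(shapes)
    shapes2d, shapes3d = reps
    n, k = shapes3d.shape[:2]
    if shapes2d.shape[2] == shapes3d.shape[2]:
        emb2d = shapes2d  # e.g. 3D data entered as both sets
    else:
        emb2d = np.concatenate([shapes2d, np.zeros((n, k, 1))], axis=2)
    joint = np.concatenate([emb2d, shapes3d])
    aligned = gpa.gpa_align(joint)
    ids = list(dataset3d.specimen_ids)
    aligned.specimen_ids = ids * 2
    provenance = np.array(["from_2d"] * n + ["from_3d"] * n)
    pairing = {sid: (i, n + i) for i, sid in enumerate(ids)}
    return CommonSpaceSample(aligned=aligned, provenance=provenance,
                             pairing=pairing, specimen_ids=ids)


def paired_2d3d_distances(common: CommonSpaceSample) -> pd.Series:
    """Per-specimen Procrustes distance between its 2D and 3D entries."""
    vals = {}
    for sid, (i2, i3) in common.pairing.items():
        vals[sid] = gpa.procrustes_distance(
            common.coords[i2], common.coords[i3], mode="aligned_euclidean")
    return pd.Series(vals, name="dist_2d3d").loc[common.specimen_ids]
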