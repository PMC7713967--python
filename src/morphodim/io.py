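"""Landmark dataset container and file I/O.

The canonical on-disk form is a long-format CSV with one row per landmark
(``specimen_id, landmark, side, x, y[, z]``) plus a separate metadata CSV
keyed by ``specimen_id``.  TPS (``LM=``/``LM3=`` blocks with ``ID=`` keys)
and NTS (labelled coordinate matrix) dialects are supported and map into
the same in-memory container.

Missing landmarks are encoded as ``NA`` cells on disk and as NaN rows in
memory, mirrored by an explicit boolean ``missing_mask`` so that
missingness survives round-trips instead of being silently dropped.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "StructuralError",
    "MetadataError",
    "LandmarkDataset",
    "DEFAULT_LANDMARK_NAMES",
    "read_landmarks",
    "write_landmarks",
    "read_metadata",
    "write_metadata",
]

HABITATS = ("lake", "stream")
SEXES = ("M", "F", "U")

#: Anatomical landmark names, numbered 1-8 on each side of the head.
DEFAULT_LANDMARK_NAMES = (
    "opercle_ventral_tip",            # 1
    "opercular_hyomandibular_joint",  # 2
    "articular_quadrate_joint",       # 3
    "interopercle_ligament_insertion",  # 4
    "anterior_tooth_tip",             # 5
    "articular_dorsal_tip",           # 6
    "maxilla_anterior_tip",           # 7
    "lateral_ethmoid_lacrimal_joint",  # 8
)


class DatasetError(ValueError):
    """Base class for landmark-dataset validation failures."""


class StructuralError(DatasetError):
    """Ragged or inconsistent coordinate structure."""


class MetadataError(DatasetError):
    """Invalid or missing specimen metadata."""


@dataclass
class LandmarkDataset:
    """A set of specimens sharing one landmark scheme.

    Attributes
    ----------
    coords
        ``(N, K, D)`` array of landmark coordinates in mm; NaN where missing.
    specimen_ids
        Length-``N`` specimen identifiers (unique).
    landmark_names
        Length-``K`` landmark names.
    sides
        Length-``K`` side labels, each ``"L"``, ``"R"`` or ``""`` (unsided).
    metadata
        Optional data frame indexed by specimen id with at least
        ``watershed``, ``habitat`` and ``sex`` columns.
    missing_mask
        ``(N, K)`` boolean array; True where a landmark is missing.
    """

    coords: np.ndarray
    specimen_ids: list[str]
    landmark_names: list[str]
    sides: list[str]
    metadata: pd.DataFrame | None = None
    missing_mask: np.ndarray | None = None
    _pairs: list[tuple[int, int]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise StructuralError(
                f"coords must be (N, K, D), got shape {self.coords.shape}"
            )
        n, k, d = self.coords.shape
        if d not in (2, 3):
            raise StructuralError(f"dimensionality must be 2 or 3, got {d}")
        if len(self.specimen_ids) != n:
            raise StructuralError("specimen_ids length does not match coords")
        if len(set(self.specimen_ids)) != n:
            raise StructuralError("specimen ids are not unique")
        if len(self.landmark_names) != k or len(self.sides) != k:
            raise StructuralError("landmark_names/sides length does not match K")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.coords).any(axis=2)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (n, k):
                raise StructuralError("missing_mask must be (N, K)")
        if self.metadata is not None:
            self._validate_metadata()

    # ------------------------------------------------------------------
    def _validate_metadata(self) -> None:
        md = self.metadata
        missing = set(self.specimen_ids) - set(md.index.astype(str))
        if missing:
            raise MetadataError(f"metadata missing specimens: {sorted(missing)}")
        for col in ("watershed", "habitat"):
            if col not in md.columns:
                raise MetadataError(f"metadata lacks required column '{col}'")
        bad_hab = set(md.loc[self.specimen_ids, "habitat"]) - set(HABITATS)
        if bad_hab:
            raise MetadataError(f"unknown habitat token(s): {sorted(bad_hab)}")
        if md.loc[self.specimen_ids, "watershed"].isna().any():
            raise MetadataError("watershed token missing for some specimens")
        if "sex" in md.columns:
            bad_sex = set(md.loc[self.specimen_ids, "sex"].dropna()) - set(SEXES)
            if bad_sex:
                raise MetadataError(f"unknown sex token(s): {sorted(bad_sex)}")

    # ------------------------------------------------------------------
    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def ndim_coords(self) -> int:
        return self.coords.shape[2]

    @property
    def is_bilateral(self) -> bool:
        return bool(self.pairs)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Left/right landmark index pairs, matched by landmark name.

        A bijection between sided landmarks: every ``L`` landmark must have
        exactly one same-named ``R`` partner (and vice versa).  Returns an
        empty list for one-sided datasets.
        """
        if self._pairs is not None:
            return self._pairs
        left = {n: i for i, (n, s) in
                enumerate(zip(self.landmark_names, self.sides)) if s == "L"}
        right = {n: i for i, (n, s) in
                 enumerate(zip(self.landmark_names, self.sides)) if s == "R"}
        if not left and not right:
            self._pairs = []
        elif set(left) != set(right):
            raise StructuralError(
                "bilateral pairing is not a bijection: unmatched landmarks "
                f"{sorted(set(left) ^ set(right))}"
            )
        else:
            self._pairs = [(left[n], right[n]) for n in left]
        return self._pairs

    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def subset_landmarks(self, indices: Sequence[int]) -> "LandmarkDataset":
        idx = list(indices)
        return LandmarkDataset(
            coords=self.coords[:, idx, :].copy(),
            specimen_ids=list(self.specimen_ids),
            landmark_names=[self.landmark_names[i] for i in idx],
            sides=[self.sides[i] for i in idx],
            metadata=self.metadata,
            missing_mask=self.missing_mask[:, idx].copy(),
        )

    def copy(self) -> "LandmarkDataset":
        return replace(
            self,
            coords=self.coords.copy(),
            specimen_ids=list(self.specimen_ids),
            landmark_names=list(self.landmark_names),
            sides=list(self.sides),
            missing_mask=self.missing_mask.copy(),
            _pairs=None,
        )

    def equals(self, other: "LandmarkDataset", atol: float = 0.0) -> bool:
        return (
            self.specimen_ids == other.specimen_ids
            and self.landmark_names == other.landmark_names
            and self.sides == other.sides
            and self.coords.shape == other.coords.shape
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.allclose(
                np.nan_to_num(self.coords), np.nan_to_num(other.coords),
                atol=atol, rtol=0.0,
            )
        )


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # >= 9 significant digits round-trip


def read_landmarks(
    path: str | Path,
    format: str = "csv",
    *,
    landmark_names: Sequence[str] | None = None,
    sides: Sequence[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> LandmarkDataset:
    """Read a landmark dataset from ``csv``, ``tps`` or ``nts``.

    TPS and NTS files do not carry landmark names or side labels; supply
    them through ``landmark_names``/``sides`` or generic names are used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        ds = _read_csv(path)
    elif format == "tps":
        ds = _read_tps(path)
    elif format == "nts":
        ds = _read_nts(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if landmark_names is not None:
        if len(landmark_names) != ds.n_landmarks:
            raise StructuralError("landmark_names length mismatch")
        ds.landmark_names = list(landmark_names)
    if sides is not None:
        if len(sides) != ds.n_landmarks:
            raise StructuralError("sides length mismatch")
        ds.sides = list(sides)
        ds._pairs = None
    if metadata is not None:
        ds.metadata = metadata
        ds._validate_metadata()
    return ds


def write_landmarks(dataset: LandmarkDataset, path: str | Path,
                    format: str = "csv") -> Path:
    """Write a dataset; round-trips bit-for-bit at >= 9 significant digits."""
    if dataset.n_specimens == 0:
        raise DatasetError("refusing to write an empty dataset")
    path = Path(path)
    if format == "csv":
        _write_csv(dataset, path)
    elif format == "tps":
        _write_tps(dataset, path)
    elif format == "nts":
        _write_nts(dataset, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _read_csv(path: Path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen_id": str, "landmark": str,
                                  "side": str}, keep_default_na=True)
    required = {"specimen_id", "landmark", "side", "x", "y"}
    if not required.issubset(df.columns):
        raise StructuralError(
            f"CSV must have columns {sorted(required)}; got {list(df.columns)}"
        )
    ndim = 3 if "z" in df.columns else 2
    df["side"] = df["side"].fillna("")
    # specimens keyed by ID; file row order within a specimen defines landmark
    # order, which must agree across specimens.
    ids = list(dict.fromkeys(df["specimen_id"]))
    key0 = None
    blocks, masks = [], []
    for sid in ids:
        sub = df[df["specimen_id"] == sid]
        key = list(zip(sub["landmark"], sub["side"]))
        if key0 is None:
            key0 = key
        elif key != key0:
            raise StructuralError(
                f"specimen {sid!r} has landmark rows {len(key)} != "
                f"{len(key0)} or a different landmark order"
            )
        xyz = sub[["x", "y", "z"][:ndim]].to_numpy(dtype=float)
        blocks.append(xyz)
        masks.append(np.isnan(xyz).any(axis=1))
    coords = np.stack(blocks)
    return LandmarkDataset(
        coords=coords,
        specimen_ids=ids,
        landmark_names=[k[0] for k in key0],
        sides=[k[1] for k in key0],
        missing_mask=np.stack(masks),
    )


def _write_csv(dataset: LandmarkDataset, path: Path) -> None:
    ndim = dataset.ndim_coords
    cols = ["x", "y", "z"][:ndim]
    rows = []
    for i, sid in enumerate(dataset.specimen_ids):
        for j in range(dataset.n_landmarks):
            row = {"specimen_id": sid,
                   "landmark": dataset.landmark_names[j],
                   "side": dataset.sides[j]}
            if dataset.missing_mask[i, j]:
                row.update({c: "NA" for c in cols})
            else:
                row.update({c: _FLOAT_FMT % dataset.coords[i, j, k]
                            for k, c in enumerate(cols)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA")


def _read_tps(path: Path) -> LandmarkDataset:
    blocks: list[tuple[str, np.ndarray]] = []
    cur: list[list[float]] | None = None
    cur_id: str | None = None
    expect = 0
    ndim = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                if cur is not None:
                    blocks.append((cur_id or f"spec{len(blocks)+1}",
                                   np.array(cur)))
                this_dim = 3 if upper.startswith("LM3=") else 2
                if ndim is None:
                    ndim = this_dim
                elif ndim != this_dim:
                    raise StructuralError("mixed LM=/LM3= blocks in TPS file")
                expect = int(line.split("=", 1)[1])
                cur, cur_id = [], None
            elif upper.startswith("ID="):
                cur_id = line.split("=", 1)[1].strip()
            elif "=" in line and line[:2].isalpha():
                continue  # SCALE=, IMAGE= etc. ignored
            else:
                vals = [np.nan if v.upper() == "NA" else float(v)
                        for v in line.split()]
                if cur is None:
                    raise StructuralError("coordinate line before LM= header")
                cur.append(vals)
    if cur is not None:
        blocks.append((cur_id or f"spec{len(blocks)+1}", np.array(cur)))
    if not blocks:
        raise StructuralError("no LM= blocks found in TPS file")
    k0 = blocks[0][1].shape
    for sid, arr in blocks:
        if arr.shape != k0:
            raise StructuralError(
                f"specimen {sid!r} has {arr.shape[0]} landmarks, "
                f"expected {k0[0]}"
            )
    if expect and k0[0] != expect:
        raise StructuralError(
            f"LM= header says {expect} landmarks, block has {k0[0]}"
        )
    coords = np.stack([arr for _, arr in blocks])
    k = coords.shape[1]
    return LandmarkDataset(
        coords=coords,
        specimen_ids=[sid for sid, _ in blocks],
        landmark_names=[f"lm{j+1:02d}" for j in range(k)],
        sides=[""] * k,
    )


def _write_tps(dataset: LandmarkDataset, path: Path) -> None:
    tag = "LM3" if dataset.ndim_coords == 3 else "LM"
    with open(path, "w") as fh:
        for i, sid in enumerate(dataset.specimen_ids):
            fh.write(f"{tag}={dataset.n_landmarks}\n")
            for j in range(dataset.n_landmarks):
                if dataset.missing_mask[i, j]:
                    fh.write(" ".join(["NA"] * dataset.ndim_coords) + "\n")
                else:
                    fh.write(" ".join(
                        _FLOAT_FMT % v for v in dataset.coords[i, j]) + "\n")
            fh.write(f"ID={sid}\n")


def _read_nts(path: Path) -> LandmarkDataset:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith('"')]
    header = lines[0].split()
    n = int(header[1].rstrip("Ll"))
    labelled = header[1].upper().endswith("L")
    ncol = int(header[2])
    has_missing = len(header) > 3 and header[3] == "1"
    miss_code = header[4] if has_missing else None
    ndim = 3
    for tok in header:
        if tok.lower().startswith("dim="):
            ndim = int(tok.split("=", 1)[1])
    body = lines[1:]
    if labelled:
        ids = body[0].split()
        body = body[1:]
    else:
        ids = [f"spec{i+1}" for i in range(n)]
    vals: list[float] = []
    for ln in body:
        for tok in ln.split():
            if (miss_code is not None and tok == miss_code) or tok.upper() == "NA":
                vals.append(np.nan)
            else:
                vals.append(float(tok))
    if len(vals) != n * ncol:
        raise StructuralError(
            f"NTS matrix has {len(vals)} values, expected {n}x{ncol}"
        )
    if ncol % ndim:
        raise StructuralError("NTS column count not divisible by dim")
    coords = np.array(vals).reshape(n, ncol // ndim, ndim)
    k = coords.shape[1]
    return LandmarkDataset(
        coords=coords,
        specimen_ids=ids,
        landmark_names=[f"lm{j+1:02d}" for j in range(k)],
        sides=[""] * k,
    )


def _write_nts(dataset: LandmarkDataset, path: Path) -> None:
    n, k, d = dataset.coords.shape
    has_missing = dataset.has_missing()
    head = f"1 {n}L {k * d} {'1 -999' if has_missing else '0'} dim={d}"
    with open(path, "w") as fh:
        fh.write(head + "\n")
        fh.write(" ".join(dataset.specimen_ids) + "\n")
        flat = dataset.coords.reshape(n, k * d)
        mask = np.repeat(dataset.missing_mask, d, axis=1)
        for i in range(n):
            toks = ["-999" if m else _FLOAT_FMT % v
                    for v, m in zip(flat[i], mask[i])]
            fh.write(" ".join(toks) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, dtype=str).set_index("specimen_id")
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    metadata.to_csv(path, index_label="specimen_id")
    return path
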