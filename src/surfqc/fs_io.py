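"""Readers and writers for the neuroimaging and tabular formats the QC pipeline touches.

Volumes are MGZ or NIfTI-1 (via nibabel), surfaces are FreeSurfer binary
triangle files, cohort tables and rating exports are headered CSV. All
coordinates are world millimetres; the volume affine (0-based voxel index ->
world mm) is the single source of voxel/world truth. Surface files carrying a
FreeSurfer volume-geometry block have the c_ras translation applied at load so
surfaces and volume share one world frame.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    DimensionalityError,
    FormatError,
    IntegrityError,
    SchemaError,
    UniquenessError,
    VocabularyError,
)

HEMISPHERES = ("lh", "rh")
SURFACE_LAYERS = ("white", "pial")

#: the four-level rating vocabulary, ordered best to worst
RATING_CATEGORIES = ("good", "minor_error", "visible_motion", "bad")

RATINGS_COLUMNS = ("image_hash", "rater_id", "category", "deliberation_ms", "timestamp")


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class VolumeImage:
    """A 3-D intensity grid with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume must be 3-D, got shape {self.data.shape}"
            )
        if any(s < 8 for s in self.data.shape):
            raise IntegrityError(f"grid dimensions must be >= 8 per axis, got {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise IntegrityError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise IntegrityError("affine is singular")

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Millimetres per voxel step along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm (..., 3) to fractional voxel indices."""
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class TriMesh:
    """A triangle mesh in world millimetres."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise IntegrityError("vertices must be N x 3")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise IntegrityError("faces must be M x 3")
        n = len(self.vertices)
        if n < 4 or len(self.faces) < 4:
            raise IntegrityError("mesh needs >= 4 vertices and >= 4 faces")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= n:
            raise IntegrityError(
                f"face indices must lie in [0, {n}); found range "
                f"[{self.faces.min()}, {self.faces.max()}]"
            )
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise IntegrityError("a face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


@dataclass
class SubjectBundle:
    """One participant: a T1 volume plus the four cortical boundary meshes.

    ``surfaces`` maps (hemisphere, layer) -> TriMesh for hemisphere in
    {lh, rh} and layer in {white, pial}. All geometry shares the volume's
    world frame.
    """

    subject_id: str
    t1: VolumeImage
    surfaces: Mapping[tuple[str, str], TriMesh]

    def __post_init__(self) -> None:
        missing = [
            (h, l)
            for h in HEMISPHERES
            for l in SURFACE_LAYERS
            if (h, l) not in self.surfaces
        ]
        if missing:
            raise IntegrityError(f"subject {self.subject_id} missing surfaces: {missing}")


@dataclass
class LoadReport:
    """Row accounting for a tabular load: input = retained + dropped, always."""

    n_input: int
    n_retained: int
    n_dropped: int
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class CohortSchema:
    """Column-role mapping for a cohort CSV.

    ``region_columns`` maps phenotype ('CT', 'SA', 'CV') to the region columns
    holding it. When omitted, columns prefixed ``CT_`` / ``SA_`` / ``CV_`` are
    auto-detected. ``qc_metrics`` lists quality columns (e.g. fsqc, euler).
    """

    subject_id: str = "subject_id"
    age: str = "age"
    sex: str = "sex"
    diagnosis: str = "diagnosis"
    site: str = "site"
    qc_metrics: Sequence[str] = ()
    region_columns: Mapping[str, Sequence[str]] | None = None


class CohortTable:
    """Participant-level analysis substrate: demographics, QC metrics, regions.

    Thin wrapper over a pandas DataFrame with a validated schema. Region
    phenotype columns follow the ``<PHENOTYPE>_<region>`` naming convention.
    Missing region values are retained as NaN; analyses drop row-wise per
    region and report the n actually used.
    """

    PHENOTYPES = ("CT", "SA", "CV")

    def __init__(self, df: pd.DataFrame, schema: CohortSchema | None = None):
        self.schema = schema or CohortSchema()
        self.df = df.reset_index(drop=True)
        s = self.schema
        required = [s.subject_id, s.age, s.site]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing required columns: {missing}")
        if self.df[s.subject_id].duplicated().any():
            dups = self.df.loc[self.df[s.subject_id].duplicated(), s.subject_id].tolist()
            raise UniquenessError(f"duplicate subject_id values: {dups[:5]}")
        ages = self.df[s.age]
        if (ages <= 0).any():
            raise IntegrityError("age must be > 0 for all participants")
        if self.df[s.site].nunique() < 1:
            raise IntegrityError("site must have >= 1 level")

    def __len__(self) -> int:
        return len(self.df)

    def region_columns(self, phenotype: str) -> list[str]:
        """Region columns for a phenotype, from schema or by prefix."""
        if phenotype not in self.PHENOTYPES:
            raise SchemaError(f"unknown phenotype {phenotype!r}; expected one of {self.PHENOTYPES}")
        rc = self.schema.region_columns
        if rc is not None and phenotype in rc:
            return list(rc[phenotype])
        prefix = phenotype + "_"
        return [c for c in self.df.columns if c.startswith(prefix)]

    @property
    def n_sites(self) -> int:
        return self.df[self.schema.site].nunique()

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.df.loc[np.asarray(mask, bool)].copy(), self.schema)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def read_volume(path: str | os.PathLike) -> VolumeImage:
    """Read an MGZ or NIfTI-1 volume; intensities and affine pass through unchanged."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of parse errors
        size = os.path.getsize(path)
        raise FormatError(
            f"could not read {path!r} as MGZ/NIfTI (file is {size} bytes; "
            f"parse failed at or before byte {size}): {exc}"
        ) from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise DimensionalityError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    return VolumeImage(data=data, affine=np.asarray(img.affine))


def write_volume(vol: VolumeImage, path: str | os.PathLike) -> None:
    """Write MGZ (.mgz/.mgh) or NIfTI-1 (.nii/.nii.gz) according to extension."""
    path = os.fspath(path)
    if path.endswith((".mgz", ".mgh")):
        # MGH only stores uint8/int16/int32/float32
        data = vol.data
        if data.dtype not in (np.uint8, np.int16, np.int32, np.float32):
            data = data.astype(np.float32)
        img = nib.MGHImage(data, vol.affine)
    elif path.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(vol.data, vol.affine)
    else:
        raise FormatError(f"unsupported volume extension for {path!r}")
    nib.save(img, path)


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------


def read_surface(path: str | os.PathLike) -> TriMesh:
    """Read a FreeSurfer binary triangle surface into world mm.

    If the file carries a volume-geometry block, its c_ras translation is
    added so the mesh lands in the volume's world (scanner RAS) frame.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, faces, volume_info = nib.freesurfer.read_geometry(
                path, read_metadata=True
            )
    except ValueError as exc:
        raise FormatError(f"{path!r} is not a FreeSurfer triangle surface: {exc}") from exc
    coords = np.asarray(coords, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    cras = volume_info.get("cras") if volume_info else None
    if cras is not None:
        coords = coords + np.asarray(cras, dtype=float)
    if len(faces) and (faces.min() < 0 or faces.max() >= len(coords)):
        raise IntegrityError(
            f"{path!r}: face index out of range [0, {len(coords)})"
        )
    return TriMesh(vertices=coords, faces=faces)


def write_surface(mesh: TriMesh, path: str | os.PathLike) -> None:
    """Write a FreeSurfer binary triangle surface (no volume-geometry block)."""
    nib.freesurfer.write_geometry(
        os.fspath(path),
        np.asarray(mesh.vertices, dtype=np.float32),
        np.asarray(mesh.faces, dtype=np.int32),
    )


# ---------------------------------------------------------------------------
# Subject directories (FreeSurfer-style layout)
# ---------------------------------------------------------------------------


def write_subject(bundle: SubjectBundle, subjects_dir: str | os.PathLike) -> str:
    """Write a bundle as ``<subjects_dir>/<id>/{mri/T1.mgz, surf/?h.{white,pial}}``."""
    root = os.path.join(os.fspath(subjects_dir), bundle.subject_id)
    os.makedirs(os.path.join(root, "mri"), exist_ok=True)
    os.makedirs(os.path.join(root, "surf"), exist_ok=True)
    write_volume(bundle.t1, os.path.join(root, "mri", "T1.mgz"))
    for (hemi, layer), mesh in bundle.surfaces.items():
        write_surface(mesh, os.path.join(root, "surf", f"{hemi}.{layer}"))
    return root


def read_subject(subjects_dir: str | os.PathLike, subject_id: str) -> SubjectBundle:
    """Read a FreeSurfer-style subject directory back into a bundle."""
    root = os.path.join(os.fspath(subjects_dir), subject_id)
    t1 = read_volume(os.path.join(root, "mri", "T1.mgz"))
    surfaces = {
        (h, l): read_surface(os.path.join(root, "surf", f"{h}.{l}"))
        for h in HEMISPHERES
        for l in SURFACE_LAYERS
    }
    return SubjectBundle(subject_id=subject_id, t1=t1, surfaces=surfaces)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


def read_cohort_table(
    path: str | os.PathLike, schema: CohortSchema | None = None
) -> tuple[CohortTable, LoadReport]:
    """Load a cohort CSV, dropping (and counting) rows with unparseable required fields."""
    schema = schema or CohortSchema()
    raw = pd.read_csv(path, dtype={schema.subject_id: str, schema.site: str})
    required = [schema.subject_id, schema.age, schema.site]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"cohort file missing required roles/columns: {missing}")
    n_input = len(raw)
    drop_reasons: dict[str, int] = {}

    age = pd.to_numeric(raw[schema.age], errors="coerce")
    bad_age = age.isna() | (age <= 0)
    if bad_age.any():
        drop_reasons["unparseable_or_nonpositive_age"] = int(bad_age.sum())
    bad_id = raw[schema.subject_id].isna()
    if bad_id.any():
        drop_reasons["missing_subject_id"] = int(bad_id.sum())
    bad_site = raw[schema.site].isna()
    if bad_site.any():
        drop_reasons["missing_site"] = int(bad_site.sum())
    keep = ~(bad_age | bad_id | bad_site)
    df = raw.loc[keep].copy()
    df[schema.age] = age.loc[keep]
    for col in (schema.sex, schema.diagnosis):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    # region + QC columns become numeric, NaN where unparseable (retained, flagged)
    role_cols = {schema.subject_id, schema.site, schema.age, schema.sex, schema.diagnosis}
    for col in df.columns:
        if col not in role_cols:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    table = CohortTable(df, schema)
    report = LoadReport(
        n_input=n_input,
        n_retained=len(df),
        n_dropped=n_input - len(df),
        drop_reasons=drop_reasons,
    )
    return table, report


# ---------------------------------------------------------------------------
# Ratings tables
# ---------------------------------------------------------------------------


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the five-column ratings contract; returns the validated frame."""
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ratings table missing columns: {missing}")
    bad = ~df["category"].isin(RATING_CATEGORIES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise VocabularyError(
            f"unknown rating category {df['category'].iloc[row]!r} at row {row}; "
            f"allowed: {RATING_CATEGORIES}"
        )
    if df.duplicated(subset=["image_hash", "rater_id"]).any():
        dup = df.loc[df.duplicated(subset=["image_hash", "rater_id"]), ["image_hash", "rater_id"]]
        raise UniquenessError(
            f"duplicate (image_hash, rater_id) pairs, e.g. {dup.iloc[0].tolist()}"
        )
    times = pd.to_numeric(df["deliberation_ms"], errors="raise")
    if (times < 0).any():
        raise IntegrityError("deliberation_ms must be >= 0")
    out = df.copy()
    out["deliberation_ms"] = times
    return out[list(RATINGS_COLUMNS)]


def read_ratings(path: str | os.PathLike) -> pd.DataFrame:
    """Read a rating-session CSV export (image_hash, rater_id, category, deliberation_ms, timestamp)."""
    return validate_ratings(pd.read_csv(path, dtype={"image_hash": str, "rater_id": str}))


def write_ratings(table: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_ratings(table).to_csv(path, index=False)
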