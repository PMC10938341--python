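"""Snapshot generation: brain-cropped slice views with surface contours, anonymized for rating.

The pipeline per subject is

    brain_bounding_box -> select_slice_planes -> (extract_slice_image,
    slice_contours per surface) -> render_snapshot -> anonymize_and_shuffle

Slice positions are fixed fractions of the per-subject brain bounding box
(default 3 axial + 3 coronal at {0.30, 0.50, 0.70} and 4 sagittal at
{0.25, 0.40, 0.60, 0.75}, which keeps the sagittal views off the midline and
gives two views per hemisphere, for 10 images per participant). Contours are
the exact intersection of each triangle mesh with the slice plane, chained
into polylines. Output filenames are salted-MD5 hashes and the presentation
order is a seeded uniform shuffle pooled across subjects, so raters cannot
associate images from the same participant or site.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import shutil
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import line as _bresenham_line

from .errors import CollisionError, ConfigError, ThresholdError
from .fs_io import HEMISPHERES, SURFACE_LAYERS, SubjectBundle, TriMesh, VolumeImage

AXES = {"sagittal": 0, "coronal": 1, "axial": 2}

DEFAULT_FRACTIONS: dict[str, tuple[float, ...]] = {
    "axial": (0.30, 0.50, 0.70),
    "coronal": (0.30, 0.50, 0.70),
    "sagittal": (0.25, 0.40, 0.60, 0.75),
}


# ---------------------------------------------------------------------------
# Planes and plumbing types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlicePlane:
    """An axis-aligned slicing plane in world mm.

    ``axis`` names the anatomical view; the plane is normal to the
    corresponding world axis at ``world_coordinate``. ``basis`` holds the two
    orthonormal in-plane direction vectors; in-plane 2-D coordinates of a
    world point w are (w . basis[0], w . basis[1]).
    """

    axis: str
    world_coordinate: float
    basis: tuple[tuple[float, float, float], tuple[float, float, float]]

    @property
    def normal_axis(self) -> int:
        return AXES[self.axis]

    @property
    def normal(self) -> np.ndarray:
        n = np.zeros(3)
        n[self.normal_axis] = 1.0
        return n

    def to_plane_2d(self, points: np.ndarray) -> np.ndarray:
        """Project world points (..., 3) to in-plane 2-D mm."""
        b = np.asarray(self.basis)
        return np.asarray(points, float) @ b.T

    def plane_to_world(self, uv: np.ndarray) -> np.ndarray:
        b = np.asarray(self.basis)
        uv = np.asarray(uv, float)
        out = uv @ b
        out[..., self.normal_axis] += self.world_coordinate
        return out


def _plane_for_axis(axis: str, coordinate: float) -> SlicePlane:
    k = AXES[axis]
    in_plane = [i for i in range(3) if i != k]
    basis = []
    for i in in_plane:
        v = [0.0, 0.0, 0.0]
        v[i] = 1.0
        basis.append(tuple(v))
    return SlicePlane(axis=axis, world_coordinate=float(coordinate), basis=(basis[0], basis[1]))


@dataclass
class Polyline:
    """An ordered contour in plane coordinates (mm)."""

    points: np.ndarray
    closed: bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if len(self.points) < 2:
            raise ConfigError("polyline needs >= 2 points")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SnapshotConfig:
    """Slice-selection and rendering configuration.

    ``counts`` gives per-view slice counts (axial, coronal, sagittal); the
    default (3, 3, 4) yields the standard 10 images. Non-default counts use
    evenly spaced fractions over the same interior band, keeping even sagittal
    counts off the midline.
    """

    counts: tuple[int, int, int] = (3, 3, 4)
    fractions: Mapping[str, Sequence[float]] | None = None
    intensity_fraction: float = 0.1
    pixel_size: float = 1.0
    chain_tol: float = 1e-6
    interpolation: str = "nearest"  # or "linear"

    def fractions_for(self, axis: str) -> tuple[float, ...]:
        if self.fractions is not None and axis in self.fractions:
            fr = tuple(float(f) for f in self.fractions[axis])
        else:
            count = self.counts[("axial", "coronal", "sagittal").index(axis)]
            if count < 1:
                raise ConfigError(f"slice count for {axis} must be >= 1, got {count}")
            if count == len(DEFAULT_FRACTIONS[axis]):
                fr = DEFAULT_FRACTIONS[axis]
            elif count == 1:
                fr = (0.5,) if axis != "sagittal" else (0.3,)
            else:
                lo, hi = (0.25, 0.75) if axis == "sagittal" else (0.30, 0.70)
                vals = np.linspace(lo, hi, count)
                if axis == "sagittal":
                    # keep sagittal views off the interhemispheric midline
                    vals = np.where(np.isclose(vals, 0.5), 0.57, vals)
                fr = tuple(float(v) for v in vals)
        if any(not (0.0 < f < 1.0) for f in fr):
            raise ConfigError(f"slice fractions must lie in (0, 1), got {fr}")
        return fr


# ---------------------------------------------------------------------------
# Bounding box and plane selection
# ---------------------------------------------------------------------------


def brain_bounding_box(volume: VolumeImage, intensity_fraction: float = 0.1) -> np.ndarray:
    """Tightest world-mm box containing all voxels brighter than a max-intensity fraction.

    Returns a (2, 3) array of (lower, upper) world coordinates. Raises
    :class:`ThresholdError` when no voxel passes (e.g. constant-zero volume).
    """
    data = np.asarray(volume.data, float)
    vmax = data.max()
    mask = data > intensity_fraction * vmax
    if not mask.any():
        raise ThresholdError(
            f"no voxel exceeds {intensity_fraction} x max intensity ({vmax})"
        )
    idx = np.nonzero(mask)
    lo_ijk = np.array([a.min() for a in idx], float)
    hi_ijk = np.array([a.max() for a in idx], float)
    # transform the 8 corners of the index box; world box is their AABB
    corners = np.array(
        [[i, j, k] for i in (lo_ijk[0], hi_ijk[0]) for j in (lo_ijk[1], hi_ijk[1]) for k in (lo_ijk[2], hi_ijk[2])]
    )
    world = volume.voxel_to_world(corners)
    return np.vstack([world.min(axis=0), world.max(axis=0)])


def select_slice_planes(box: np.ndarray, config: SnapshotConfig | None = None) -> list[SlicePlane]:
    """Slice planes at fixed fractions of the brain box: default 3 axial, 3 coronal, 4 sagittal."""
    config = config or SnapshotConfig()
    box = np.asarray(box, float)
    extent = box[1] - box[0]
    if np.any(extent <= 0):
        raise ConfigError(f"degenerate bounding box, extent {extent}")
    planes: list[SlicePlane] = []
    for axis in ("axial", "coronal", "sagittal"):
        k = AXES[axis]
        for frac in config.fractions_for(axis):
            coord = box[0, k] + frac * extent[k]
            planes.append(_plane_for_axis(axis, coord))
    return planes


# ---------------------------------------------------------------------------
# Mesh / plane intersection
# ---------------------------------------------------------------------------

_EPS_ON_PLANE = 1e-9  # vertices exactly on the plane are nudged to +1e-9 mm


def _signed_distances(mesh: TriMesh, plane: SlicePlane) -> np.ndarray:
    d = mesh.vertices[:, plane.normal_axis] - plane.world_coordinate
    d = np.where(np.abs(d) < _EPS_ON_PLANE, _EPS_ON_PLANE, d)
    return d


def _edge_crossings(mesh: TriMesh, plane: SlicePlane):
    """Per straddling triangle, the two crossing edges keyed by sorted vertex pair.

    Intersection points are computed once per edge (with the edge's endpoints
    in index order), so the two triangles sharing an edge get bit-identical
    endpoints and chaining can match exactly.
    """
    d = _signed_distances(mesh, plane)
    f = mesh.faces
    sides = d[f] > 0
    straddle = ~(sides.all(axis=1) | (~sides).all(axis=1))
    segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
    point_of: dict[tuple[int, int], np.ndarray] = {}
    for tri in f[straddle]:
        keys = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if (d[a] > 0) != (d[b] > 0):
                i, j = (a, b) if a < b else (b, a)
                key = (int(i), int(j))
                if key not in point_of:
                    t = d[i] / (d[i] - d[j])
                    point_of[key] = mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i])
                keys.append(key)
        if len(keys) == 2:
            segments.append((keys[0], keys[1]))
    return segments, point_of


def slice_contours(mesh: TriMesh, plane: SlicePlane, tol: float = 1e-6) -> list[Polyline]:
    """Intersect a triangle mesh with a plane and chain segments into maximal polylines.

    Each triangle whose vertices straddle the plane contributes the segment
    obtained by linear interpolation of signed vertex distances along its two
    crossing edges. Segments are chained through their shared mesh edges
    (exact arithmetic identity, no fuzzy matching); a polyline is closed when
    the chain returns to its starting edge. For a closed mesh and a plane
    through no vertex every polyline is closed. Returns [] when the plane
    misses the mesh.
    """
    if tol <= 0:
        raise ConfigError("chaining tolerance must be > 0")
    lo, hi = mesh.bounds()
    k = plane.normal_axis
    if plane.world_coordinate < lo[k] - tol or plane.world_coordinate > hi[k] + tol:
        return []
    segments, point_of = _edge_crossings(mesh, plane)
    if not segments:
        return []

    # adjacency: edge key -> indices of segments touching it
    touch: dict[tuple[int, int], list[int]] = {}
    for s_idx, (ka, kb) in enumerate(segments):
        touch.setdefault(ka, []).append(s_idx)
        touch.setdefault(kb, []).append(s_idx)

    used = np.zeros(len(segments), dtype=bool)
    polylines: list[Polyline] = []
    for start in range(len(segments)):
        if used[start]:
            continue
        # walk forward from the start segment
        chain = [segments[start][0], segments[start][1]]
        used[start] = True
        for end in (1, 0):  # extend at tail, then at head
            while True:
                tip = chain[-1] if end == 1 else chain[0]
                nxt = [i for i in touch.get(tip, ()) if not used[i]]
                if not nxt:
                    break
                s = segments[nxt[0]]
                used[nxt[0]] = True
                other = s[1] if s[0] == tip else s[0]
                if end == 1:
                    chain.append(other)
                else:
                    chain.insert(0, other)
            if chain[0] == chain[-1]:
                break  # cycle closed; no head extension needed
        closed = chain[0] == chain[-1] and len(chain) > 2
        pts3d = np.array([point_of[key] for key in chain])
        pts2d = plane.to_plane_2d(pts3d)
        polylines.append(Polyline(points=pts2d, closed=closed))
    return polylines


# ---------------------------------------------------------------------------
# Slice image extraction
# ---------------------------------------------------------------------------


@dataclass
class PlaneFrame:
    """Mapping between plane mm coordinates and pixel indices of a slice image."""

    u_min: float
    v_min: float
    pixel_size: float
    shape: tuple[int, int]  # (n_v rows, n_u cols)

    def to_pixels(self, uv: np.ndarray) -> np.ndarray:
        """Plane mm -> fractional (col, row) pixel coordinates."""
        uv = np.asarray(uv, float)
        cols = (uv[..., 0] - self.u_min) / self.pixel_size
        rows = (uv[..., 1] - self.v_min) / self.pixel_size
        return np.stack([cols, rows], axis=-1)


@dataclass
class SliceImage:
    """A 2-D intensity sample of the volume on a plane, with its coordinate frame."""

    data: np.ndarray  # (n_v, n_u)
    frame: PlaneFrame
    empty: bool


def extract_slice_image(
    volume: VolumeImage,
    plane: SlicePlane,
    pixel_size: float = 1.0,
    interpolation: str = "nearest",
) -> SliceImage:
    """Sample the volume on the plane over the volume's in-plane footprint.

    Nearest-neighbour lookup by default so raw-intensity artifacts (ringing)
    survive into the rating image; ``interpolation='linear'`` switches to
    trilinear.
    """
    if pixel_size <= 0:
        raise ConfigError("pixel_size must be > 0")
    shape = np.array(volume.data.shape)
    corners_ijk = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)]
    )
    world = volume.voxel_to_world(corners_ijk)
    uv = plane.to_plane_2d(world)
    u_min, v_min = uv.min(axis=0)
    u_max, v_max = uv.max(axis=0)
    n_u = max(int(np.floor((u_max - u_min) / pixel_size)) + 1, 1)
    n_v = max(int(np.floor((v_max - v_min) / pixel_size)) + 1, 1)
    us = u_min + pixel_size * np.arange(n_u)
    vs = v_min + pixel_size * np.arange(n_v)
    uu, vv = np.meshgrid(us, vs)  # rows over v, cols over u
    pts = plane.plane_to_world(np.stack([uu.ravel(), vv.ravel()], axis=-1))
    ijk = volume.world_to_voxel(pts)
    grid = np.zeros(uu.size, dtype=float)
    if interpolation == "nearest":
        idx = np.rint(ijk).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        if inside.any():
            ii = idx[inside]
            grid[inside] = volume.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    elif interpolation == "linear":
        from scipy.ndimage import map_coordinates

        inside = np.all((ijk >= -0.5) & (ijk <= shape - 0.5), axis=1)
        grid = map_coordinates(
            np.asarray(volume.data, float), ijk.T, order=1, mode="constant", cval=0.0
        )
        grid[~inside] = 0.0
    else:
        raise ConfigError(f"unknown interpolation {interpolation!r}")
    k = plane.normal_axis
    lo, hi = world[:, k].min(), world[:, k].max()
    empty = not (lo <= plane.world_coordinate <= hi) or not inside.any()
    frame = PlaneFrame(u_min=float(u_min), v_min=float(v_min), pixel_size=pixel_size, shape=(n_v, n_u))
    return SliceImage(data=grid.reshape(n_v, n_u), frame=frame, empty=empty)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass
class RenderStyle:
    """Contour colours per surface layer; greyscale window percentile for the underlay."""

    layer_colors: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: {"white": (255, 230, 40), "pial": (255, 60, 60)}
    )
    window_percentile: float = 99.5
    upscale: int = 2  # integer pixel replication for crisper contours


def render_snapshot(
    slice_image: SliceImage,
    contour_sets: Mapping[str, Sequence[Polyline]],
    path: str | os.PathLike,
    style: RenderStyle | None = None,
) -> None:
    """Rasterize the greyscale slice with coloured surface contours to a PNG.

    Deterministic: identical inputs and style produce byte-identical files
    (PIL writes no timestamps). The image row order puts larger v (anterior /
    superior) at the top.
    """
    style = style or RenderStyle()
    data = np.asarray(slice_image.data, float)
    hi = np.percentile(data, style.window_percentile) if data.size else 1.0
    hi = hi if hi > 0 else 1.0
    grey = np.clip(data / hi * 255.0, 0, 255).astype(np.uint8)
    s = max(int(style.upscale), 1)
    if s > 1:
        grey = np.repeat(np.repeat(grey, s, axis=0), s, axis=1)
    rgb = np.stack([grey] * 3, axis=-1)
    n_rows, n_cols = rgb.shape[:2]
    for layer, polylines in contour_sets.items():
        color = np.array(style.layer_colors.get(layer, (0, 255, 0)), dtype=np.uint8)
        for pl in polylines:
            px = slice_image.frame.to_pixels(pl.points) * s
            px = np.rint(px).astype(int)
            for (c0, r0), (c1, r1) in zip(px[:-1], px[1:]):
                rr, cc = _bresenham_line(r0, c0, r1, c1)
                ok = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
                rgb[rr[ok], cc[ok]] = color
    Image.fromarray(rgb[::-1]).save(os.fspath(path), format="PNG")


# ---------------------------------------------------------------------------
# Per-subject generation and anonymization
# ---------------------------------------------------------------------------


def generate_subject_snapshots(
    bundle: SubjectBundle,
    out_dir: str | os.PathLike,
    config: SnapshotConfig | None = None,
    style: RenderStyle | None = None,
) -> pd.DataFrame:
    """Generate the subject's snapshot set (default 10 images) and return manifest rows.

    Each image overlays the contours of all four surfaces (lh/rh x
    white/pial) on the T1 slice. Rows record subject, view, slice position,
    filename and whether any contour was drawn (planes missing the brain are
    flagged, not dropped).
    """
    config = config or SnapshotConfig()
    os.makedirs(out_dir, exist_ok=True)
    box = brain_bounding_box(bundle.t1, config.intensity_fraction)
    planes = select_slice_planes(box, config)
    rows = []
    counters: dict[str, int] = {}
    for plane in planes:
        i = counters.get(plane.axis, 0)
        counters[plane.axis] = i + 1
        img = extract_slice_image(bundle.t1, plane, config.pixel_size, config.interpolation)
        contour_sets: dict[str, list[Polyline]] = {"white": [], "pial": []}
        for (hemi, layer), mesh in bundle.surfaces.items():
            contour_sets[layer].extend(slice_contours(mesh, plane, config.chain_tol))
        fname = f"{bundle.subject_id}_{plane.axis}_{i:02d}.png"
        render_snapshot(img, contour_sets, os.path.join(out_dir, fname), style)
        n_contours = sum(len(v) for v in contour_sets.values())
        rows.append(
            {
                "subject_id": bundle.subject_id,
                "axis": plane.axis,
                "slice_index": i,
                "world_coordinate": plane.world_coordinate,
                "filename": fname,
                "n_contours": n_contours,
                "no_contours": n_contours == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SnapshotManifest:
    """Anonymization record: per image, the salted-MD5 hash and shuffle position.

    The original->hash mapping is a bijection kept for de-anonymization; the
    salt and the shuffle seed are stored so a session can be reproduced or
    audited.
    """

    rows: pd.DataFrame
    seed: int
    salt: str

    def deanonymize(self, image_hash: str) -> str:
        m = self.rows.loc[self.rows["image_hash"] == image_hash, "filename"]
        if m.empty:
            raise KeyError(image_hash)
        return str(m.iloc[0])

    def subject_of(self, image_hash: str) -> str:
        m = self.rows.loc[self.rows["image_hash"] == image_hash, "subject_id"]
        if m.empty:
            raise KeyError(image_hash)
        return str(m.iloc[0])

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": self.seed,
            "salt": self.salt,
            "rows": self.rows.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SnapshotManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(rows=pd.DataFrame(payload["rows"]), seed=payload["seed"], salt=payload["salt"])

    def to_csv(self, path: str | os.PathLike) -> None:
        self.rows.to_csv(path, index=False)


def anonymize_and_shuffle(
    manifest_rows: pd.DataFrame, seed: int, salt: str = ""
) -> SnapshotManifest:
    """Rename images to salted MD5 hashes and assign a seeded uniform shuffle order.

    Images are pooled across subjects (and sites) before shuffling so rating
    order carries no subject structure. Raises :class:`CollisionError` on a
    hash collision (reporting the colliding names) rather than silently
    merging images.
    """
    rows = manifest_rows.copy().reset_index(drop=True)
    if rows["filename"].duplicated().any():
        dups = rows.loc[rows["filename"].duplicated(), "filename"].tolist()
        raise CollisionError(f"duplicate input filenames: {dups[:5]}")
    hashes = [
        hashlib.md5((salt + name).encode("utf-8")).hexdigest() for name in rows["filename"]
    ]
    seen: dict[str, str] = {}
    for name, h in zip(rows["filename"], hashes):
        if h in seen:
            raise CollisionError(f"MD5 collision between {seen[h]!r} and {name!r}")
        seen[h] = name
    rows["image_hash"] = hashes
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    positions = np.empty(len(rows), dtype=int)
    positions[order] = np.arange(1, len(rows) + 1)
    rows["shuffle_position"] = positions
    return SnapshotManifest(rows=rows, seed=int(seed), salt=salt)


def apply_anonymization(
    manifest: SnapshotManifest, src_dir: str | os.PathLike, dst_dir: str | os.PathLike
) -> None:
    """Copy snapshot files to their hashed names (keeps the originals intact)."""
    os.makedirs(dst_dir, exist_ok=True)
    for _, row in manifest.rows.iterrows():
        shutil.copyfile(
            os.path.join(os.fspath(src_dir), row["filename"]),
            os.path.join(os.fspath(dst_dir), row["image_hash"] + ".png"),
        )
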