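"""Phantom subjects and simulated cohorts with exported ground truth.

Two generators make every stage of the pipeline testable without any data
download:

* :func:`make_phantom_subject` builds a two-hemisphere ellipsoid "brain"
  (CSF background, grey-matter shell, white-matter core) with matching pial
  and white boundary meshes, optional ripple artifact emulating the periodic
  intensity modulation of head motion, optional topological handles, and
  analytic ellipse cross-sections as ground truth for the contouring stage.

* :func:`simulate_cohort` draws a multi-site cohort in which image quality is
  worse in younger and diagnosed participants, sites carry random
  intercepts, and each region's morphometry responds to observed quality
  with region-specific slopes of both signs. The returned ground-truth table
  stores every coefficient together with the partial correlation it implies
  for the regional analysis model, so parameter-recovery tests have an exact
  target.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError
from .fs_io import CohortSchema, CohortTable, SubjectBundle, TriMesh, VolumeImage
from .snapshot import SlicePlane, SnapshotConfig, brain_bounding_box, select_slice_planes

# ---------------------------------------------------------------------------
# Mesh primitives
# ---------------------------------------------------------------------------


def make_icosphere(
    subdivisions: int = 2, radius: float = 1.0, center: Sequence[float] = (0.0, 0.0, 0.0)
) -> TriMesh:
    """Geodesic sphere: icosahedron with each triangle 4-split ``subdivisions`` times.

    Subdivision k has 2 + 10 * 4^k vertices and 20 * 4^k faces.
    """
    if subdivisions < 0:
        raise ConfigError("subdivisions must be >= 0")
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        vlist = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def _mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                m = vlist[a] + vlist[b]
                m = m / np.linalg.norm(m)
                midpoint[key] = len(vlist)
                vlist.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = _mid(a, b), _mid(b, c), _mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return TriMesh(vertices=verts * radius + np.asarray(center, float), faces=faces)


def make_torus(R: float = 30.0, r: float = 10.0, m: int = 48, n: int = 24) -> TriMesh:
    """Torus on an m x n vertex grid: V = mn, E = 3mn, F = 2mn, chi = 0."""
    if not (R > r > 0):
        raise ConfigError("need R > r > 0")
    if m < 3 or n < 3:
        raise ConfigError("need m, n >= 3")
    u = 2 * np.pi * np.arange(m) / m
    v = 2 * np.pi * np.arange(n) / n
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (R + r * np.cos(vv)) * np.cos(uu)
    y = (R + r * np.cos(vv)) * np.sin(uu)
    z = r * np.sin(vv)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    faces = []
    for i in range(m):
        for j in range(n):
            a = i * n + j
            b = ((i + 1) % m) * n + j
            c = ((i + 1) % m) * n + (j + 1) % n
            d = i * n + (j + 1) % n
            faces += [[a, b, c], [a, c, d]]
    return TriMesh(vertices=verts, faces=np.array(faces, dtype=np.int64))


def add_handle(mesh: TriMesh, seed: int = 0) -> TriMesh:
    """Attach a handle: remove two disjoint faces and stitch a tube between them.

    The two removed triangles' boundary loops are bridged with six new
    triangles (no new vertices): dV = 0, dE = +6, dF = +4, so the Euler
    characteristic drops by exactly 2 (genus + 1). The donor faces are chosen
    seeded and far apart so the bridge introduces no pre-existing edges.
    """
    if mesh.n_faces < 8:
        raise GeometryError("mesh too small to attach a handle")
    rng = np.random.default_rng(seed)
    faces = mesh.faces
    centroids = mesh.vertices[faces].mean(axis=1)
    existing = set(map(tuple, np.sort(np.vstack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1)))
    order = rng.permutation(mesh.n_faces)
    for fa in order:
        va = set(faces[fa])
        # candidate partners sorted by distance, farthest first
        d = np.linalg.norm(centroids - centroids[fa], axis=1)
        for fb in np.argsort(-d):
            if fb == fa or va & set(faces[fb]):
                continue
            a = faces[fa]
            b = faces[fb]
            # orient loop b to minimise twist: match each a-vertex to nearest b-vertex
            best = min(
                (tuple(np.roll(b[::step], k)) for step in (1, -1) for k in range(3)),
                key=lambda perm: sum(
                    np.linalg.norm(mesh.vertices[a[i]] - mesh.vertices[perm[i]])
                    for i in range(3)
                ),
            )
            b = np.array(best)
            bridge = np.array(
                [
                    [a[0], a[1], b[0]], [a[1], b[1], b[0]],
                    [a[1], a[2], b[1]], [a[2], b[2], b[1]],
                    [a[2], a[0], b[2]], [a[0], b[0], b[2]],
                ],
                dtype=np.int64,
            )
            new_edges = set(map(tuple, np.sort(np.vstack(
                [bridge[:, [0, 1]], bridge[:, [1, 2]], bridge[:, [2, 0]]]), axis=1)))
            cross = {e for e in new_edges if len({e[0], e[1]} & va) == 1}
            if cross & existing:
                continue  # a bridge edge already exists; try another partner
            keep = np.ones(mesh.n_faces, bool)
            keep[[fa, fb]] = False
            return TriMesh(
                vertices=mesh.vertices.copy(),
                faces=np.vstack([faces[keep], bridge]),
            )
    raise GeometryError("could not find disjoint donor faces for a handle")


# ---------------------------------------------------------------------------
# Phantom subject
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Two-hemisphere ellipsoid phantom parameters (world mm, intensities a.u.)."""

    shape: tuple[int, int, int] = (80, 96, 80)
    voxel_size: float = 2.0
    outer_semiaxes: tuple[float, float, float] = (30.0, 70.0, 55.0)
    hemisphere_offset: float = 34.0  # |x| of each hemisphere centre
    inner_scale: float = 0.75
    intensities: tuple[float, float, float] = (20.0, 90.0, 150.0)  # CSF, GM, WM
    ripple_amplitude: float = 0.0  # fraction of local intensity
    ripple_frequency: float = 0.1  # cycles per mm
    ripple_axis: int = 1
    handles_per_hemisphere: int = 0
    noise_sd: float = 0.0
    subdivisions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ripple_amplitude < 1):
            raise ConfigError("ripple amplitude fraction must be in [0, 1)")
        if self.inner_scale >= 1 or self.inner_scale <= 0:
            raise ConfigError("inner surface must be strictly inside the outer")
        if len(set(self.intensities)) != 3:
            raise ConfigError("tissue intensities must be distinct")


@dataclass
class EllipseSection:
    """Analytic cross-section of one hemisphere surface on one slice plane."""

    hemisphere: str
    layer: str
    plane_axis: str
    world_coordinate: float
    center_2d: tuple[float, float]
    semiaxes_2d: tuple[float, float]

    def points(self, n: int = 256) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.stack(
            [
                self.center_2d[0] + self.semiaxes_2d[0] * np.cos(t),
                self.center_2d[1] + self.semiaxes_2d[1] * np.sin(t),
            ],
            axis=1,
        )


@dataclass
class PhantomSubject:
    bundle: SubjectBundle
    planes: list[SlicePlane]
    ellipses: list[EllipseSection]
    config: PhantomConfig


def _hemisphere_centers(config: PhantomConfig) -> dict[str, np.ndarray]:
    return {
        "lh": np.array([-config.hemisphere_offset, 0.0, 0.0]),
        "rh": np.array([config.hemisphere_offset, 0.0, 0.0]),
    }


def make_phantom_subject(
    config: PhantomConfig | None = None, subject_id: str = "phantom"
) -> PhantomSubject:
    """Build the phantom bundle plus analytic contour ground truth.

    The volume is CSF background with a GM shell between the inner
    (white-like) and outer (pial-like) ellipsoids of each hemisphere and a WM
    core; the meshes are subdivided ellipsoids at the two tissue boundaries.
    The optional ripple multiplies intensities by 1 + A sin(2 pi f x_axis).
    Ground truth lists the in-plane ellipse of every hemisphere surface on
    every default slice plane.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    shape = np.array(config.shape)
    vox = config.voxel_size
    offset = -(shape - 1) / 2 * vox
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = offset

    i, j, k = np.indices(shape, dtype=float, sparse=True)
    x = i * vox + offset[0]
    y = j * vox + offset[1]
    z = k * vox + offset[2]

    csf, gm, wm = config.intensities
    data = np.full(tuple(shape), float(csf))
    out_ax = np.asarray(config.outer_semiaxes, float)
    in_ax = out_ax * config.inner_scale
    centers = _hemisphere_centers(config)
    for c in centers.values():
        rho_out = ((x - c[0]) / out_ax[0]) ** 2 + ((y - c[1]) / out_ax[1]) ** 2 + (
            (z - c[2]) / out_ax[2]
        ) ** 2
        rho_in = ((x - c[0]) / in_ax[0]) ** 2 + ((y - c[1]) / in_ax[1]) ** 2 + (
            (z - c[2]) / in_ax[2]
        ) ** 2
        data[rho_out <= 1] = gm
        data[rho_in <= 1] = wm
    if config.ripple_amplitude > 0:
        coord = (x, y, z)[config.ripple_axis]
        ripple = 1 + config.ripple_amplitude * np.sin(
            2 * np.pi * config.ripple_frequency * coord
        )
        data = data * ripple
    if config.noise_sd > 0:
        data = data + rng.normal(0, config.noise_sd, size=data.shape)
    volume = VolumeImage(data=data, affine=affine)

    surfaces: dict[tuple[str, str], TriMesh] = {}
    for hemi, c in centers.items():
        for layer, ax in (("pial", out_ax), ("white", in_ax)):
            unit = make_icosphere(config.subdivisions, 1.0, (0, 0, 0))
            mesh = TriMesh(vertices=unit.vertices * ax + c, faces=unit.faces)
            for h in range(config.handles_per_hemisphere):
                mesh = add_handle(mesh, seed=int(rng.integers(0, 2**31 - 1)))
            surfaces[(hemi, layer)] = mesh
    bundle = SubjectBundle(subject_id=subject_id, t1=volume, surfaces=surfaces)

    box = brain_bounding_box(volume, 0.1)
    planes = select_slice_planes(box, SnapshotConfig())
    ellipses: list[EllipseSection] = []
    for plane in planes:
        kk = plane.normal_axis
        in_plane = [a for a in range(3) if a != kk]
        for hemi, c in centers.items():
            for layer, ax in (("pial", out_ax), ("white", in_ax)):
                off = plane.world_coordinate - c[kk]
                if abs(off) >= ax[kk]:
                    continue
                shrink = np.sqrt(1 - (off / ax[kk]) ** 2)
                ellipses.append(
                    EllipseSection(
                        hemisphere=hemi,
                        layer=layer,
                        plane_axis=plane.axis,
                        world_coordinate=plane.world_coordinate,
                        center_2d=(c[in_plane[0]], c[in_plane[1]]),
                        semiaxes_2d=(ax[in_plane[0]] * shrink, ax[in_plane[1]] * shrink),
                    )
                )
    return PhantomSubject(bundle=bundle, planes=planes, ellipses=ellipses, config=config)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSimParams:
    """Generative parameters for the simulated multi-site cohort.

    Latent quality q for participant i at site s:

        q_i = beta_age (age_i - mean age) + beta_dx dx_i + u_s + N(0, quality_noise_sd)

    with u_s ~ N(0, site_sd). beta_age < 0 makes quality worse (larger q) in
    younger participants; beta_dx > 0 makes it worse in cases. Observed
    scores: FSQC = clip(fsqc_mu + q, 1, 4) and Euler =
    round(exp(euler_a + euler_b q + noise)), the log-linear link giving the
    heavy right skew characteristic of defect counts.

    Regions: value = m_r + gamma_age,r age + gamma_sex,r sex + delta_r dx +
    lambda_r g(FSQC) + w_s + N(0, residual_sd), where g is centred FSQC
    (``quality_effect_mode='linear'``) or the centred hinge
    max(FSQC - tail_knot, 0) (``'tail'``, concentrating the quality effect in
    the worst images). Per-region lambdas are specified directly
    (``quality_slopes``) or derived from ``target_partial_r`` so the implied
    regional partial correlation equals the target; when neither is given a
    mixture with negative, zero and positive entries is drawn.
    """

    n: int = 2000
    n_sites: int = 10
    site_sd: float = 0.15
    site_sd_region: float = 0.05
    age_range: tuple[float, float] = (6.0, 30.0)
    case_fraction: float = 0.5
    beta_age: float = -0.02
    beta_dx: float = 0.15
    quality_noise_sd: float = 0.5
    fsqc_mu: float = 1.9
    euler_a: float = 4.6
    euler_b: float = 0.6
    euler_noise_sd: float = 0.35
    n_regions: int = 360
    phenotypes: tuple[str, ...] = ("CT",)
    region_baseline: tuple[float, float] = (2.5, 0.3)  # mean, sd of m_r
    age_slope: tuple[float, float] = (-0.01, 0.005)  # mean, sd of gamma_age
    sex_effect_sd: float = 0.03
    residual_sd: float = 0.15
    target_partial_r: np.ndarray | Sequence[float] | None = None
    quality_slopes: np.ndarray | Sequence[float] | None = None
    delta_dx: float | np.ndarray | Sequence[float] = 0.0
    quality_effect_mode: Literal["linear", "tail"] = "linear"
    tail_knot: float = 2.5
    include_extra_metrics: bool = True
    include_globals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("site_sd", "site_sd_region", "quality_noise_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.case_fraction <= 1):
            raise ConfigError("case_fraction must be a probability")
        if self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise ConfigError("age_range must be positive and increasing")


def _default_target_partial_r(n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Mixture of region effects: mostly negative, some null, some positive."""
    kinds = rng.choice(3, size=n_regions, p=(0.45, 0.35, 0.20))
    r = np.zeros(n_regions)
    r[kinds == 0] = rng.uniform(-0.45, -0.05, (kinds == 0).sum())
    r[kinds == 2] = rng.uniform(0.05, 0.35, (kinds == 2).sum())
    return r


def _draw_participants(params: CohortSimParams, rng: np.random.Generator):
    n = params.n
    site = rng.integers(0, params.n_sites, n)
    age = rng.uniform(*params.age_range, n)
    sex = rng.integers(0, 2, n).astype(float)
    dx = (rng.random(n) < params.case_fraction).astype(float)
    u_site = rng.normal(0, params.site_sd, params.n_sites)
    mean_age = np.mean(params.age_range)
    q = (
        params.beta_age * (age - mean_age)
        + params.beta_dx * dx
        + u_site[site]
        + rng.normal(0, params.quality_noise_sd, n)
    )
    fsqc = np.clip(params.fsqc_mu + q, 1.0, 4.0)
    euler = np.rint(
        np.exp(params.euler_a + params.euler_b * q + rng.normal(0, params.euler_noise_sd, n))
    )
    euler = np.maximum(euler, 0.0)
    return site, age, sex, dx, q, fsqc, euler


def _analysis_residual_moments(params: CohortSimParams, n_aux: int = 60_000):
    """Second moments of FSQC, g(FSQC) and diagnosis residualized on the
    regional-analysis covariates (age, age^2, sex, site), from a large
    auxiliary draw. Used to translate slopes into implied partial r exactly
    under the data-generating process (clipping included)."""
    aux = CohortSimParams(**{**params.__dict__, "n": n_aux, "n_regions": 1,
                             "target_partial_r": None, "quality_slopes": None})
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA0E]))
    site, age, sex, dx, q, fsqc, _ = _draw_participants(aux, rng)
    if params.quality_effect_mode == "tail":
        g = np.maximum(fsqc - params.tail_knot, 0.0)
    else:
        g = fsqc
    age_c = age - age.mean()
    Z = np.column_stack(
        [np.ones(n_aux), age_c, age_c**2, sex]
        + [(site == s).astype(float) for s in range(1, params.n_sites)]
    )

    def _resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
        return v - Z @ beta

    rF, rg, rd = _resid(fsqc - fsqc.mean()), _resid(g - g.mean()), _resid(dx)
    return {
        "v_F": rF.var(),
        "v_g": rg.var(),
        "v_d": rd.var(),
        "c_gF": float(np.mean(rg * rF)),
        "c_dF": float(np.mean(rd * rF)),
        "c_gd": float(np.mean(rg * rd)),
    }


def implied_partial_r(
    lambdas: np.ndarray, deltas: np.ndarray, sigma: float, moments: dict
) -> np.ndarray:
    """Partial r between FSQC and region value, adjusted for age, age^2, sex, site.

    With region residual = lambda resid(g) + delta resid(dx) + eps the partial
    correlation with resid(FSQC) is closed-form in the residual moments.
    """
    cov = lambdas * moments["c_gF"] + deltas * moments["c_dF"]
    var_y = (
        lambdas**2 * moments["v_g"]
        + deltas**2 * moments["v_d"]
        + 2 * lambdas * deltas * moments["c_gd"]
        + sigma**2
    )
    denom = np.sqrt(var_y * moments["v_F"])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def lambda_for_partial_r(target_r: np.ndarray, sigma: float, moments: dict) -> np.ndarray:
    """Quality slope giving a target partial r (linear mode, delta = 0)."""
    target_r = np.asarray(target_r, float)
    if np.any(np.abs(target_r) >= 1):
        raise ConfigError("target partial r must lie in (-1, 1)")
    sd_F = np.sqrt(moments["v_F"])
    return target_r / np.sqrt(1 - target_r**2) * sigma / sd_F


def simulate_cohort(
    params: CohortSimParams | None = None,
) -> tuple[CohortTable, pd.DataFrame]:
    """Draw the cohort and its ground truth.

    Returns ``(cohort, ground_truth)`` where the ground-truth frame has one
    row per (phenotype, region) with every generative coefficient and the
    implied partial correlation for the regional analysis model.
    """
    params = params or CohortSimParams()
    ss = np.random.SeedSequence(params.seed)
    rng_regions, rng_part = (np.random.default_rng(s) for s in ss.spawn(2))

    # region-level coefficients first (independent of n)
    n_r = params.n_regions
    m_r = rng_regions.normal(*params.region_baseline, n_r)
    g_age = rng_regions.normal(*params.age_slope, n_r)
    g_sex = rng_regions.normal(0, params.sex_effect_sd, n_r)
    delta = np.broadcast_to(np.asarray(params.delta_dx, float), (n_r,)).copy()

    moments = _analysis_residual_moments(params)
    if params.quality_slopes is not None:
        lambdas = np.asarray(params.quality_slopes, float)
        target = np.full(n_r, np.nan)
    else:
        if params.target_partial_r is not None:
            target = np.asarray(params.target_partial_r, float)
        else:
            target = _default_target_partial_r(n_r, rng_regions)
        lambdas = lambda_for_partial_r(target, params.residual_sd, moments)
    if len(lambdas) != n_r:
        raise ConfigError("quality slope vector length must equal n_regions")

    site, age, sex, dx, q, fsqc, euler = _draw_participants(params, rng_part)
    n = params.n
    if params.quality_effect_mode == "tail":
        g = np.maximum(fsqc - params.tail_knot, 0.0)
    else:
        g = fsqc
    g_c = g - g.mean()
    w_site = rng_part.normal(0, params.site_sd_region, params.n_sites)

    data = {
        "subject_id": [f"sub{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "diagnosis": dx,
        "site": [f"site{s:02d}" for s in site],
        "fsqc": fsqc,
        "euler": euler,
    }
    if params.include_extra_metrics:
        data["motion_qc"] = np.clip(2.0 + 0.9 * q + rng_part.normal(0, 0.45, n), 1, 5)
        data["pondrai_qc"] = np.clip(2.0 + 0.8 * q + rng_part.normal(0, 0.5, n), 1, 5)
        # higher values = better quality (certainty of a "good" call)
        data["qoala_t"] = np.clip(70 - 18 * q + rng_part.normal(0, 12, n), 0, 100)
    if params.include_globals:
        # weak but detectable quality effects on the global measures
        data["TBV"] = 1.15e6 + rng_part.normal(0, 1.0e5, n) - 3.0e4 * q
        data["cGMV"] = 6.0e5 + rng_part.normal(0, 6.0e4, n) - 2.0e4 * q
        data["sGMV"] = 6.0e4 + rng_part.normal(0, 7.0e3, n) - 1.8e3 * q
        data["WMV"] = 4.5e5 + rng_part.normal(0, 5.0e4, n) - 1.2e4 * q
        data["ventricles"] = 1.5e4 + rng_part.normal(0, 5.0e3, n) + 1.4e3 * q
        data["meanCT"] = 2.6 + rng_part.normal(0, 0.08, n) - 0.04 * q

    truth_rows = []
    scale = {"CT": 1.0, "SA": 250.0, "CV": 600.0}
    for pheno in params.phenotypes:
        sc = scale.get(pheno, 1.0)
        eps = rng_part.normal(0, params.residual_sd, (n, n_r))
        values = (
            m_r[None, :]
            + g_age[None, :] * age[:, None]
            + g_sex[None, :] * sex[:, None]
            + delta[None, :] * dx[:, None]
            + lambdas[None, :] * g_c[:, None]
            + w_site[site][:, None]
            + eps
        ) * sc
        implied = implied_partial_r(lambdas, delta, params.residual_sd, moments)
        for r in range(n_r):
            name = f"{pheno}_region{r:03d}"
            data[name] = values[:, r]
            truth_rows.append(
                {
                    "region": name,
                    "phenotype": pheno,
                    "baseline": m_r[r] * sc,
                    "gamma_age": g_age[r] * sc,
                    "gamma_sex": g_sex[r] * sc,
                    "delta_dx": delta[r] * sc,
                    "lambda_quality": lambdas[r] * sc,
                    "target_partial_r": target[r],
                    "implied_partial_r": implied[r],
                }
            )

    schema = CohortSchema(qc_metrics=("fsqc", "euler"))
    cohort = CohortTable(pd.DataFrame(data), schema)
    return cohort, pd.DataFrame(truth_rows)


def simulate_rater_scores(
    n_participants: int = 50,
    n_raters: int = 6,
    truth_sd: float = 0.6,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Participants x raters score grid: shared latent quality plus rater noise.

    A convenience generator for reliability statistics: every rater observes
    the same latent score (clipped to [1, 4]) through independent noise.
    """
    rng = np.random.default_rng(seed)
    truth = np.clip(rng.normal(1.8, truth_sd, n_participants), 1, 4)
    scores = np.clip(
        truth[:, None] + rng.normal(0, noise_sd, (n_participants, n_raters)), 1, 4
    )
    return pd.DataFrame(
        scores,
        index=[f"sub{i:03d}" for i in range(n_participants)],
        columns=[f"rater{j}" for j in range(n_raters)],
    )
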