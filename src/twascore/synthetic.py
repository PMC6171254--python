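"""Synthetic aneurysm cases: pulsatile wall-shear fields and dome images.

Patient CFD results and intraoperative photographs are not shippable, so
this module fabricates cases with the statistical structure the method
assumes: a spherical aneurysm dome whose "thin-walled" patch carries

* a wall-shear-stress deficit (low WSS) over the cardiac cycle,
* partial flow reversal (elevated oscillatory shear index), and
* a reddish (+a* in CIELAB) shift in a rendered dome image,

all co-located and recorded as ground truth.  The cardiac cycle is a
two-harmonic raised-cosine flow-like waveform (systolic peak, diastolic
trough); spatial texture is multiplicative log-normal jitter.  Everything
is driven by one explicit seed.

The patch profile is a cosine-squared bump peaked at the patch centre, so
the planted WSS minimum and redness maximum are point-like rather than a
plateau; the ground-truth masks are the profile's upper half (weight > 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import trimesh
from skimage import color as _skcolor

from .colorimetry import RegionAnnotation
from .fields import SacMask, WallFieldSeries
from .mesh import SurfaceMesh

__all__ = [
    "SyntheticCaseConfig",
    "GroundTruth",
    "DomeProjection",
    "SyntheticCase",
    "SyntheticCohort",
    "cardiac_waveform",
    "make_case",
    "make_cohort",
]


def cardiac_waveform(phase: np.ndarray) -> np.ndarray:
    """Flow-like modulation over one cycle, phase in [0, 1).

    q(s) = 0.82 + 0.55 cos(2 pi s) + 0.18 cos(4 pi s): systolic peak 1.55
    at s = 0, diastolic trough ~0.43 near s = 0.63; strictly positive.
    """
    s = np.asarray(phase, dtype=float)
    return 0.82 + 0.55 * np.cos(2 * np.pi * s) + 0.18 * np.cos(4 * np.pi * s)


#: cycle phase of the waveform minimum (diastole), located once on a fine grid
_phase_grid = np.linspace(0.0, 1.0, 4001)
_DIASTOLE_PHASE = float(_phase_grid[np.argmin(cardiac_waveform(_phase_grid))])
del _phase_grid


@dataclass(frozen=True)
class SyntheticCaseConfig:
    """All knobs of one synthetic case; defaults are the study conditions.

    The WSS deficit 0.2 mirrors the observed more/less-dangerous WSS ratio
    (~0.34/1.76 Pa); the reversal fraction 0.15 yields patch OSI near the
    observed ~0.07; pressure carries no planted effect.
    """

    seed: int = 0
    # geometry (mm)
    mesh_subdivisions: int = 3
    dome_radius: float = 2.55          # half the ~5.1 mm mean aneurysm size
    neck_z: float = 0.0                # sac = faces with centroid z above this
    patch_center: tuple[float, float, float] = (0.35, 0.25, 0.90)
    patch_angle: float = 0.5           # angular half-width of the bump (rad)
    # hemodynamics
    wss_base: float = 1.8              # Pa, healthy-wall scale
    wss_deficit: float = 0.2           # multiplicative WSS factor at patch centre
    reversal_fraction: float = 0.15    # fraction of cycle reversed inside patch
    background_reversal_fraction: float = 0.10  # ditto, outside the patch
    spatial_jitter_sd: float = 0.08    # log-normal sigma of per-face texture
    n_times: int = 32
    period: float = 0.9                # s, ~67 bpm
    flow_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    pulsatile: bool = True             # False = constant (flat) waveform
    # pressure (Pa)
    pressure_mean: float = 15750.0
    pressure_noise_sd: float = 5.0
    # image
    image_size: int = 200
    image_lab: tuple[float, float, float] = (52.0, 24.0, 22.0)  # vessel wall
    patch_a_shift: float = 15.0        # +a* (redness) at patch centre
    patch_l_shift: float = -3.0        # slight darkening of the thin wall
    image_noise_sd: float = 1.5        # Lab-channel Gaussian noise
    background_lab: tuple[float, float, float] = (20.0, 6.0, 4.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.wss_deficit < 1.0:
            raise ValueError("wss_deficit must lie in (0, 1)")
        for name in ("reversal_fraction", "background_reversal_fraction"):
            if not 0.0 <= getattr(self, name) <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5]")
        if self.n_times < 8:
            raise ValueError("need at least 8 time samples per cycle")
        if not (self.dome_radius > 0 and self.patch_angle > 0 and self.period > 0):
            raise ValueError("geometry/period parameters must be positive")
        if self.image_size < 32:
            raise ValueError("image_size too small to render a dome")


@dataclass(frozen=True)
class DomeProjection:
    """Orthographic dome-to-image mapping (view along -z, image y down)."""

    cx: float
    cy: float
    radius_px: float
    dome_radius: float

    def direction_to_pixel(self, direction: np.ndarray) -> tuple[float, float]:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return self.cx + d[0] * self.radius_px, self.cy - d[1] * self.radius_px

    def pixel_to_direction(self, x: float, y: float) -> Optional[np.ndarray]:
        nx = (x - self.cx) / self.radius_px
        ny = -(y - self.cy) / self.radius_px
        r2 = nx * nx + ny * ny
        if r2 > 1.0:
            return None
        return np.array([nx, ny, np.sqrt(1.0 - r2)])

    def pixel_to_point(self, x: float, y: float) -> Optional[np.ndarray]:
        """3D point (mm) on the visible dome surface under the pixel."""
        d = self.pixel_to_direction(x, y)
        return None if d is None else self.dome_radius * d


@dataclass(frozen=True)
class GroundTruth:
    """Where the planted thin-walled area actually is."""

    twa_face_mask: np.ndarray    # (M,) bool
    twa_pixel_mask: np.ndarray   # (H, W) bool
    annotations: tuple[RegionAnnotation, ...]

    def __post_init__(self) -> None:
        if not self.twa_face_mask.any() or not self.twa_pixel_mask.any():
            raise ValueError("planted TWA masks must be nonempty")


@dataclass(frozen=True)
class SyntheticCase:
    case_id: str
    config: SyntheticCaseConfig
    series: WallFieldSeries
    sac_mask: SacMask
    image: np.ndarray            # (H, W, 3) uint8 sRGB
    projection: DomeProjection
    ground_truth: GroundTruth


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _patch_weight(cos_angle: np.ndarray, patch_angle: float) -> np.ndarray:
    """Cosine-squared bump: 1 at the centre, 0 beyond patch_angle."""
    theta = np.arccos(np.clip(cos_angle, -1.0, 1.0))
    w = np.cos(np.pi * theta / (2.0 * patch_angle)) ** 2
    return np.where(theta < patch_angle, w, 0.0)


def _tangent_field(normals: np.ndarray, flow_dir: np.ndarray) -> np.ndarray:
    """Unit tangents: the flow direction projected onto each face plane."""
    proj = flow_dir - (normals @ flow_dir)[:, None] * normals
    norms = np.linalg.norm(proj, axis=1)
    bad = norms < 1e-8
    if bad.any():
        # faces whose normal is (anti)parallel to the flow: any perpendicular
        alt = np.cross(normals[bad], [0.0, 0.0, 1.0])
        alt_n = np.linalg.norm(alt, axis=1)
        still = alt_n < 1e-8
        alt[still] = np.cross(normals[bad][still], [0.0, 1.0, 0.0])
        proj[bad] = alt
        norms[bad] = np.linalg.norm(alt, axis=1)
    return proj / norms[:, None]


def _reversal_window(phases: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean per-sample mask: the cycle fraction centred on diastole."""
    if fraction <= 0:
        return np.zeros(phases.size, dtype=bool)
    d = np.abs(phases - _DIASTOLE_PHASE)
    d = np.minimum(d, 1.0 - d)  # circular distance in phase
    return d <= fraction / 2.0 + 1e-12


def make_case(config: SyntheticCaseConfig, case_id: str = "case") -> SyntheticCase:
    """Build one deterministic synthetic case from its config."""
    rng = np.random.default_rng(config.seed)
    sphere = trimesh.creation.icosphere(
        subdivisions=config.mesh_subdivisions, radius=config.dome_radius
    )
    mesh = SurfaceMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces))
    centroids = mesh.face_centroids
    cdirs = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    sac = SacMask(centroids[:, 2] > config.neck_z)

    patch_dir = _unit(config.patch_center)
    w_face = _patch_weight(cdirs @ patch_dir, config.patch_angle)
    deficit_factor = 1.0 - (1.0 - config.wss_deficit) * w_face
    jitter = rng.lognormal(mean=0.0, sigma=config.spatial_jitter_sd, size=mesh.n_faces)
    tangents = _tangent_field(mesh.face_normals, _unit(config.flow_direction))

    T = config.n_times
    phases = np.arange(T) / T
    times = phases * config.period
    q = cardiac_waveform(phases) if config.pulsatile else np.ones(T)

    in_patch = w_face > 0.5
    rev_patch = _reversal_window(phases, config.reversal_fraction)
    rev_bg = _reversal_window(phases, config.background_reversal_fraction)
    sign = np.ones((T, mesh.n_faces))
    sign[np.ix_(rev_patch, in_patch)] = -1.0
    sign[np.ix_(rev_bg, ~in_patch)] = -1.0

    magnitude = config.wss_base * jitter * deficit_factor  # (M,)
    wss = (q[:, None] * sign * magnitude[None, :])[:, :, None] * tangents[None, :, :]
    pressure = config.pressure_mean + rng.normal(
        0.0, config.pressure_noise_sd, size=(T, mesh.n_faces)
    )
    series = WallFieldSeries(
        mesh=mesh, times=times, wss_vectors=wss, pressure=pressure,
        period=config.period,
    )

    image, projection, twa_pixel_mask = _render_dome(config, patch_dir, rng)
    annotations = _make_annotations(config, patch_dir, projection)
    gt = GroundTruth(
        twa_face_mask=in_patch & sac.member,
        twa_pixel_mask=twa_pixel_mask,
        annotations=annotations,
    )
    return SyntheticCase(case_id, config, series, sac, image, projection, gt)


def _render_dome(
    config: SyntheticCaseConfig, patch_dir: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, DomeProjection, np.ndarray]:
    """Lambertian-shaded hemisphere with a +a* patch, encoded to sRGB."""
    n = config.image_size
    proj = DomeProjection(
        cx=(n - 1) / 2.0, cy=(n - 1) / 2.0,
        radius_px=0.42 * n, dome_radius=config.dome_radius,
    )
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    nx = (xx - proj.cx) / proj.radius_px
    ny = -(yy - proj.cy) / proj.radius_px
    r2 = nx * nx + ny * ny
    on_dome = r2 <= 1.0
    nz = np.sqrt(np.clip(1.0 - r2, 0.0, None))

    # gentle Lambertian modulation: the operating field is quite evenly lit,
    # and redness, not shading, must carry the thin-wall signal
    light = _unit((0.3, 0.3, 0.9))
    shade = 0.55 + 0.45 * np.clip(
        nx * light[0] + ny * light[1] + nz * light[2], 0.0, None
    )
    cosang = nx * patch_dir[0] + ny * patch_dir[1] + nz * patch_dir[2]
    w_pix = np.where(on_dome, _patch_weight(cosang, config.patch_angle), 0.0)

    L0, a0, b0 = config.image_lab
    lab = np.empty((n, n, 3))
    lab[..., 0] = L0 * (0.7 + 0.3 * shade) + w_pix * config.patch_l_shift
    lab[..., 1] = a0 + w_pix * config.patch_a_shift
    lab[..., 2] = b0
    bg = np.asarray(config.background_lab)
    lab[~on_dome] = bg
    lab += rng.normal(0.0, config.image_noise_sd, size=lab.shape)
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)

    rgb = np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)
    image = (rgb * 255.0 + 0.5).astype(np.uint8)
    return image, proj, (w_pix > 0.5)


def _make_annotations(
    config: SyntheticCaseConfig, patch_dir: np.ndarray, proj: DomeProjection
) -> tuple[RegionAnnotation, ...]:
    """Reference / more-dangerous / less-dangerous circles plus the dome ROI.

    The reference sits a quarter-turn in azimuth from the patch, the
    less-dangerous region diametrically opposite in azimuth; both are
    outside the patch support for the default geometry.
    """
    px, py, pz = patch_dir
    ref_dir = _unit((-py, px, pz))
    less_dir = _unit((-px, -py, pz))
    r_px = 0.06 * config.image_size

    def circ(d, role):
        x, y = proj.direction_to_pixel(d)
        return RegionAnnotation(cx=x, cy=y, radius=r_px, role=role)

    return (
        circ(ref_dir, "reference"),
        circ(patch_dir, "more_dangerous"),
        circ(less_dir, "less_dangerous"),
        RegionAnnotation(
            cx=proj.cx, cy=proj.cy, radius=0.85 * proj.radius_px, role="roi"
        ),
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class SyntheticCohort:
    cases: tuple[SyntheticCase, ...]
    samples: "object" = None  # long-format pandas DataFrame, set by make_cohort
    wide: "object" = None     # per-case normalized values at both sites

    def __len__(self) -> int:
        return len(self.cases)


def _jittered_config(
    base: SyntheticCaseConfig, rng: np.random.Generator
) -> SyntheticCaseConfig:
    """Per-case anatomical and effect-size variation around the base config.

    Multiplicative jitter on (1 - deficit) and on the reversal fractions
    preserves null effects: a near-1 deficit stays near 1.
    """
    z = rng.normal(size=8)
    azimuth = rng.uniform(0.0, 2.0 * np.pi)
    patch_z = rng.uniform(0.55, 0.95)
    rho = np.sqrt(1.0 - patch_z**2)
    center = (rho * np.cos(azimuth), rho * np.sin(azimuth), patch_z)
    deficit = 1.0 - np.clip(
        (1.0 - base.wss_deficit) * np.exp(0.2 * z[0]), 0.02, 0.98
    )
    return replace(
        base,
        seed=int(rng.integers(2**31)),
        dome_radius=float(base.dome_radius * np.exp(0.12 * z[1])),
        patch_center=tuple(center),
        patch_angle=float(np.clip(base.patch_angle * np.exp(0.15 * z[2]), 0.25, 0.9)),
        wss_base=float(base.wss_base * np.exp(0.25 * z[3])),
        wss_deficit=float(deficit),
        reversal_fraction=float(
            np.clip(base.reversal_fraction * np.exp(0.35 * z[4]), 0.0, 0.5)
        ),
        background_reversal_fraction=float(
            np.clip(base.background_reversal_fraction * np.exp(0.35 * z[5]), 0.0, 0.5)
        ),
        pressure_mean=float(base.pressure_mean + 700.0 * z[6]),
        patch_a_shift=float(np.clip(base.patch_a_shift * np.exp(0.2 * z[7]), 0.0, 40.0)),
    )


def make_cohort(
    n_cases: int,
    base_config: Optional[SyntheticCaseConfig] = None,
    seed: int = 0,
) -> SyntheticCohort:
    """A cohort of jittered cases with paired per-site hemodynamic samples.

    Site values mimic the clinical readout: every hemodynamic parameter is
    evaluated on the surface at the more-dangerous (planted-patch centre)
    and less-dangerous ground-truth sites, as small patch means.
    """
    import pandas as pd

    if n_cases < 2:
        raise ValueError("a cohort needs at least 2 cases")
    base = base_config or SyntheticCaseConfig()
    rng = np.random.default_rng(seed)
    cases, long_rows, wide_rows = [], [], []
    for i in range(n_cases):
        cfg = _jittered_config(base, rng)
        case = make_case(cfg, case_id=f"case{i:02d}")
        cases.append(case)
        vals = _site_samples(case)
        wide_rows.append({"case_id": case.case_id, **vals["wide"]})
        for hp, (v_more, v_less) in vals["long"].items():
            long_rows.append(
                {"case_id": case.case_id, "hp_kind": hp,
                 "region": "more_dangerous", "value": v_more}
            )
            long_rows.append(
                {"case_id": case.case_id, "hp_kind": hp,
                 "region": "less_dangerous", "value": v_less}
            )
    return SyntheticCohort(
        cases=tuple(cases),
        samples=pd.DataFrame(long_rows),
        wide=pd.DataFrame(wide_rows),
    )


def _site_samples(case: SyntheticCase, site_radius: float = 0.4) -> dict:
    """Patch-mean hemodynamic values at the two ground-truth sites."""
    from . import hemodynamics as hemo

    cfg = case.config
    mesh = case.series.mesh
    patch_dir = _unit(cfg.patch_center)
    less_dir = _unit((-patch_dir[0], -patch_dir[1], patch_dir[2]))

    dia = hemo.default_diastolic_index(case.series, case.sac_mask)
    wss_dia = hemo.wss_magnitude_at(case.series, dia)
    extremes = hemo.sac_extremes(wss_dia, case.sac_mask)
    wssn = hemo.wss_norm(wss_dia, extremes)
    osi = hemo.compute_osi(case.series)
    osin = hemo.osi_norm(osi)
    pressure_mean = case.series.pressure.mean(axis=0)

    def at(direction, values):
        point = cfg.dome_radius * direction
        d = np.linalg.norm(mesh.face_centroids - point, axis=1)
        nearby = d <= max(site_radius, d.min() + 1e-9)
        return float(
            np.average(values[nearby], weights=mesh.face_areas[nearby])
        )

    long = {
        "pressure": (at(patch_dir, pressure_mean), at(less_dir, pressure_mean)),
        "wss": (at(patch_dir, wss_dia.values), at(less_dir, wss_dia.values)),
        "osi": (at(patch_dir, osi.values), at(less_dir, osi.values)),
        "wss_norm": (at(patch_dir, wssn.values), at(less_dir, wssn.values)),
        "osi_norm": (at(patch_dir, osin.values), at(less_dir, osin.values)),
    }
    wide = {
        "wssn_more": long["wss_norm"][0],
        "osin_more": long["osi_norm"][0],
        "wssn_less": long["wss_norm"][1],
        "osin_less": long["osi_norm"][1],
    }
    return {"long": long, "wide": wide}
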