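"""Normalized hemodynamic parameters on an aneurysm surface.

Wall shear stress (WSS) is the tangential viscous traction on the vessel
wall, tau = mu * du/dn.  The oscillatory shear index (OSI)

    OSI = 1/2 * (1 - |integral wss dt| / integral |wss| dt)

measures how much the WSS vector changes direction over one cardiac cycle:
0 for unidirectional shear, 0.5 for full symmetric reversal.  Because low
WSS and high OSI both mark wall-degrading flow, each is mapped onto [0, 1]
and blended into the combined hemodynamic parameter

    CHP = w1 * WSSnorm + w2 * OSInorm,     w1 + w2 = 1.

WSSnorm solves the quartic "ellipse" relation

    (WSSnorm - 1)^4 + ((WSS - WSSmax) / (WSSmax - WSSmin))^4 = 1

whose [0, 1] branch is WSSnorm = 1 - (1 - u^4)^(1/4) with
u = (WSS - WSSmax)/(WSSmax - WSSmin); it runs from 1 at the sac minimum to
0 at the sac maximum, deliberately emphasizing the low-WSS end.  OSInorm is
simply 2 * OSI.  The extremes WSSmin/WSSmax are taken over the sac faces at
the diastolic (low-flow) instant.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .fields import PeakRegion, SacExtremes, SacMask, ScalarField, WallFieldSeries, Weighting

__all__ = [
    "wss_from_gradient",
    "wss_magnitude_at",
    "default_diastolic_index",
    "compute_osi",
    "sac_extremes",
    "wss_norm",
    "osi_norm",
    "chp",
    "peak_region",
]

#: Faces whose cycle-integrated |WSS| falls below this are treated as no-flow.
ZERO_FLOW_TOL = 1e-12


def wss_from_gradient(viscosity: float, wall_shear_rate) -> np.ndarray | float:
    """WSS magnitude (Pa) from dynamic viscosity (Pa*s) and wall shear rate (1/s)."""
    rate = np.asarray(wall_shear_rate, dtype=float)
    if not viscosity > 0:
        raise ValueError("viscosity must be positive")
    if np.any(rate < 0):
        raise ValueError("wall shear rate must be non-negative")
    out = viscosity * rate
    return float(out) if out.ndim == 0 else out


def wss_magnitude_at(series: WallFieldSeries, time_index: int) -> ScalarField:
    """Per-face Euclidean norm of the WSS vector at one sampled instant."""
    idx = int(time_index)
    if not 0 <= idx < series.n_times:
        raise IndexError(f"time index {idx} out of range [0, {series.n_times})")
    mag = np.linalg.norm(series.wss_vectors[idx], axis=1)
    return ScalarField(mag, "wss_magnitude")


def default_diastolic_index(series: WallFieldSeries, mask: SacMask) -> int:
    """Diastolic instant = sample minimizing the sac-area-weighted mean |WSS|.

    Diastole is the low-flow phase of the cycle; absent an explicit flow
    waveform this is the natural surrogate, and it is overridable via
    ``WallFieldSeries.diastolic_index``.
    """
    sac = mask.indices
    w = series.mesh.face_areas[sac]
    mags = np.linalg.norm(series.wss_vectors[:, sac, :], axis=2)  # (T, S)
    sac_mean = mags @ w / w.sum()
    return int(np.argmin(sac_mean))


def _cycle_grid(series: WallFieldSeries) -> tuple[np.ndarray, np.ndarray]:
    """Times and per-time sample index for periodic trapezoidal quadrature.

    If the stored samples do not reach the full period, the wrap interval
    from the final sample back to the first (one period later) is appended,
    reusing the first sample's values.
    """
    t = series.times
    idx = np.arange(t.size)
    period = series.cycle_duration
    span = t[-1] - t[0]
    if period - span > 1e-12 * max(period, 1.0):
        t = np.append(t, t[0] + period)
        idx = np.append(idx, 0)
    return t, idx


def compute_osi(series: WallFieldSeries) -> ScalarField:
    """Oscillatory shear index per face over one cardiac cycle.

    Both integrals use the trapezoidal rule on the sample grid with periodic
    closure.  Faces with (numerically) no flow over the whole cycle get
    OSI = 0: without flow there is nothing to oscillate.
    """
    t, idx = _cycle_grid(series)
    vecs = series.wss_vectors[idx]          # (T', M, 3)
    mags = np.linalg.norm(vecs, axis=2)     # (T', M)
    int_vec = np.trapezoid(vecs, x=t, axis=0)     # (M, 3)
    int_mag = np.trapezoid(mags, x=t, axis=0)     # (M,)
    norm_int_vec = np.linalg.norm(int_vec, axis=1)

    osi = np.zeros(series.mesh.n_faces)
    flowing = int_mag > ZERO_FLOW_TOL
    osi[flowing] = 0.5 * (1.0 - norm_int_vec[flowing] / int_mag[flowing])
    # |integral of a vector| <= integral of |vector| analytically; clip the
    # quadrature round-off.
    np.clip(osi, 0.0, 0.5, out=osi)
    return ScalarField(osi, "osi")


def sac_extremes(field: ScalarField, mask: SacMask) -> SacExtremes:
    """Min and max WSS magnitude restricted to the sac faces."""
    if field.kind != "wss_magnitude":
        raise ValueError("sac extremes are defined on a wss_magnitude field")
    if len(field) != len(mask):
        raise ValueError("field and mask face counts differ")
    vals = field.values[mask.member]
    return SacExtremes(float(vals.min()), float(vals.max()))


def wss_norm(field: ScalarField, extremes: SacExtremes) -> ScalarField:
    """Normalized WSS via the quartic ellipse relation; 1 at WSSmin, 0 at WSSmax.

    Values outside the sac range (possible when evaluating off-sac faces)
    are clamped onto it, so the output always lies in [0, 1].
    """
    if field.kind != "wss_magnitude":
        raise ValueError("wss_norm expects a wss_magnitude field")
    u = (field.values - extremes.wss_max) / extremes.span
    np.clip(u, -1.0, 0.0, out=u)
    out = 1.0 - (1.0 - u**4) ** 0.25
    return ScalarField(out, "wss_norm")


def osi_norm(field: ScalarField) -> ScalarField:
    """Doubled OSI, stretching [0, 0.5] onto [0, 1]."""
    if field.kind != "osi":
        raise ValueError("osi_norm expects an osi field")
    return ScalarField(np.clip(2.0 * field.values, 0.0, 1.0), "osi_norm")


def chp(wssn: ScalarField, osin: ScalarField, w: Weighting) -> ScalarField:
    """Combined hemodynamic parameter: w1*WSSnorm + w2*OSInorm, face-wise."""
    if wssn.kind != "wss_norm" or osin.kind != "osi_norm":
        raise ValueError("chp expects (wss_norm, osi_norm) fields")
    if len(wssn) != len(osin):
        raise ValueError("fields live on different meshes (face counts differ)")
    vals = w.w1 * wssn.values + w.w2 * osin.values
    return ScalarField(np.clip(vals, 0.0, 1.0), "chp")


def peak_region(
    field: ScalarField,
    mask: SacMask,
    mesh,
    patch_radius: float = 0.5,
    mode: str = "max",
) -> PeakRegion:
    """Locate the sac patch with the extreme area-weighted mean field value.

    Each sac face seeds a candidate patch: all sac faces whose centroid lies
    within ``patch_radius`` mm of the seed centroid (Euclidean distance as a
    geodesic proxy on these smooth sacs).  The patch with the largest
    (``mode='max'``) or smallest (``'min'``) area-weighted mean wins; ties
    break toward the lowest seed face index.
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    if patch_radius < 0:
        raise ValueError("patch_radius must be >= 0")
    if len(field) != len(mask):
        raise ValueError("field and mask face counts differ")
    sac = mask.indices
    cent = mesh.face_centroids[sac]
    areas = mesh.face_areas[sac]
    vals = field.values[sac]

    if patch_radius == 0:
        means = vals
        neighbors = [[i] for i in range(sac.size)]
    else:
        tree = cKDTree(cent)
        neighbors = tree.query_ball_point(cent, r=patch_radius)
        means = np.empty(sac.size)
        for i, nb in enumerate(neighbors):
            nb = np.asarray(nb)
            means[i] = np.average(vals[nb], weights=areas[nb])

    # lowest-face-index tie-break; near-ties within round-off count as ties
    extreme = means.max() if mode == "max" else means.min()
    tol = 1e-12 * max(1.0, abs(extreme))
    tied = means >= extreme - tol if mode == "max" else means <= extreme + tol
    best = int(np.flatnonzero(tied)[0])  # sac order == face order
    patch = np.sort(sac[np.asarray(neighbors[best], dtype=np.int64)])
    return PeakRegion(
        seed_face=int(sac[best]),
        patch_faces=patch,
        patch_mean=float(means[best]),
        patch_radius=float(patch_radius),
    )
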