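"""Field containers: pulsatile wall-shear series, sac mask, per-face scalars.

A :class:`WallFieldSeries` carries the wall shear stress (WSS) vector on every
face of a surface mesh at each sampled instant of one cardiac cycle, plus an
optional wall pressure.  The oscillatory shear index and all normalized
hemodynamic parameters are derived from it (see :mod:`twascore.hemodynamics`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mesh import SurfaceMesh

__all__ = [
    "WallFieldSeries",
    "SacMask",
    "ScalarField",
    "SacExtremes",
    "Weighting",
    "PeakRegion",
    "SCALAR_KINDS",
]

#: Recognized per-face scalar kinds and their admissible ranges.
SCALAR_KINDS = {
    "wss_magnitude": (0.0, np.inf),
    "pressure": (-np.inf, np.inf),  # gauge pressure may be negative
    "osi": (0.0, 0.5),
    "wss_norm": (0.0, 1.0),
    "osi_norm": (0.0, 1.0),
    "chp": (0.0, 1.0),
}

_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class ScalarField:
    """One finite value per mesh face, tagged with what it measures."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("ScalarField values must be 1-D (one per face)")
        if not np.isfinite(v).all():
            raise ValueError("ScalarField values must be finite")
        if self.kind not in SCALAR_KINDS:
            raise ValueError(f"unknown scalar kind {self.kind!r}")
        lo, hi = SCALAR_KINDS[self.kind]
        if v.size and (v.min() < lo - _RANGE_TOL or v.max() > hi + _RANGE_TOL):
            raise ValueError(
                f"{self.kind} values outside [{lo}, {hi}]: "
                f"range [{v.min():g}, {v.max():g}]"
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SacMask:
    """Per-face flag, true for faces in the aneurysm sac above its neck."""

    member: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.member, dtype=bool)
        if m.ndim != 1:
            raise ValueError("sac mask must be 1-D")
        if not m.any():
            raise ValueError("sac mask selects no faces")
        object.__setattr__(self, "member", m)

    def __len__(self) -> int:
        return self.member.size

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.member)


@dataclass(frozen=True)
class WallFieldSeries:
    """Per-face WSS vectors sampled over one cardiac cycle.

    Parameters
    ----------
    mesh : SurfaceMesh
    times : (T,) strictly increasing sample times in seconds.
    wss_vectors : (T, M, 3) WSS vector in Pa at each time, each face.
    pressure : optional (T, M) wall pressure in Pa.
    period : optional cycle duration in seconds.  If omitted the samples are
        taken to bracket exactly one cycle, i.e. ``times[-1] - times[0]`` is
        the period and the endpoints share the same cardiac phase.  If given
        and larger than the sampled span, cycle integrals close periodically
        by pairing the final sample with the first.
    diastolic_index : optional time index of the diastolic (low-flow) instant;
        if unset, downstream code derives it from the sac-averaged WSS.
    """

    mesh: SurfaceMesh
    times: np.ndarray
    wss_vectors: np.ndarray
    pressure: Optional[np.ndarray] = None
    period: Optional[float] = None
    diastolic_index: Optional[int] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.wss_vectors, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("need at least 3 time samples over the cycle")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if w.shape != (t.size, self.mesh.n_faces, 3):
            raise ValueError(
                f"wss_vectors shape {w.shape} != (T={t.size}, M={self.mesh.n_faces}, 3)"
            )
        if not np.isfinite(w).all():
            raise ValueError("wss_vectors must be finite")
        span = t[-1] - t[0]
        if self.period is not None:
            if not self.period > 0:
                raise ValueError("period must be positive")
            if span > self.period * (1 + 1e-9):
                raise ValueError("time samples span more than one period")
        if self.pressure is not None:
            p = np.asarray(self.pressure, dtype=float)
            if p.shape != (t.size, self.mesh.n_faces):
                raise ValueError("pressure shape must be (T, M)")
            if not np.isfinite(p).all():
                raise ValueError("pressure must be finite")
            object.__setattr__(self, "pressure", p)
        if self.diastolic_index is not None:
            if not 0 <= int(self.diastolic_index) < t.size:
                raise ValueError("diastolic_index out of range")
            object.__setattr__(self, "diastolic_index", int(self.diastolic_index))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wss_vectors", w)

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def cycle_duration(self) -> float:
        return float(self.period) if self.period is not None else float(
            self.times[-1] - self.times[0]
        )


@dataclass(frozen=True)
class SacExtremes:
    """Minimum and maximum WSS magnitude over the sac at the diastolic time."""

    wss_min: float
    wss_max: float

    DEGENERATE_TOL = 1e-12  # Pa

    def __post_init__(self) -> None:
        if not (np.isfinite(self.wss_min) and np.isfinite(self.wss_max)):
            raise ValueError("extremes must be finite")
        if self.wss_max - self.wss_min <= self.DEGENERATE_TOL:
            raise ValueError(
                "degenerate WSS range: wss_max must exceed wss_min "
                f"(got {self.wss_min!r}, {self.wss_max!r}); normalization undefined"
            )

    @property
    def span(self) -> float:
        return self.wss_max - self.wss_min


@dataclass(frozen=True)
class Weighting:
    """Convex weights of WSSnorm (w1) and OSInorm (w2); w1 + w2 = 1."""

    w1: float
    w2: float

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_w1(cls, w1: float) -> "Weighting":
        return cls(float(w1), 1.0 - float(w1))


@dataclass(frozen=True)
class PeakRegion:
    """A patch of faces around the extreme of a scalar field."""

    seed_face: int
    patch_faces: np.ndarray
    patch_mean: float
    patch_radius: float

    def __post_init__(self) -> None:
        pf = np.asarray(self.patch_faces, dtype=np.int64)
        if self.seed_face not in pf:
            raise ValueError("seed_face must belong to patch_faces")
        object.__setattr__(self, "patch_faces", pf)
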