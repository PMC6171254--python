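"""Triangulated surface container for vessel + aneurysm geometry.

The mesh is the already-reconstructed luminal surface (e.g. segmented from
angiography); all hemodynamic fields in this package live on its faces.
Units are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurfaceMesh"]


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangle mesh with per-face geometry derived lazily.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex positions in mm.
    faces : (M, 3) int array
        Triangles as 0-based vertex index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be an (M, 3) array of vertex triples")
        if v.shape[0] < 3 or f.shape[0] < 1:
            raise ValueError("mesh needs at least 3 vertices and 1 face")
        if not np.isfinite(v).all():
            raise ValueError("vertices must be finite")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if not (self.face_areas > 0).all():
            raise ValueError("every face must have positive area")

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def _corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v, f = self.vertices, self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    @property
    def face_areas(self) -> np.ndarray:
        """Per-face area in mm^2."""
        if "areas" not in self._cache:
            a, b, c = self._corners()
            cross = np.cross(b - a, c - a)
            self._cache["areas"] = 0.5 * np.linalg.norm(cross, axis=1)
        return self._cache["areas"]

    @property
    def face_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            a, b, c = self._corners()
            self._cache["centroids"] = (a + b + c) / 3.0
        return self._cache["centroids"]

    @property
    def face_normals(self) -> np.ndarray:
        """Unit normals, orientation as given by the winding order."""
        if "normals" not in self._cache:
            a, b, c = self._corners()
            cross = np.cross(b - a, c - a)
            self._cache["normals"] = cross / np.linalg.norm(cross, axis=1, keepdims=True)
        return self._cache["normals"]
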