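"""Triangle surface meshes and per-vertex (nodal) maps.

The endocardial surface is represented as a triangle mesh in world mm.
Voltage, activation-time and scar information live on mesh vertices as
nodal maps, mirroring how electroanatomic mapping platforms colour their
chamber shells.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class MeshError(ValueError):
    """Raised for invalid mesh topology or inconsistent nodal data."""


@dataclass
class SurfaceMesh:
    """Triangle mesh: vertices in world mm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (M, 3)")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise MeshError("face indices out of range")
        areas = self._face_areas()
        if np.any(areas <= 1e-12):
            raise MeshError(f"{int(np.sum(areas <= 1e-12))} zero-area faces")
        if self.n_components() != 1:
            raise MeshError("vertex-edge graph is not connected")

    def _face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as (E, 2) sorted index pairs."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def adjacency(self):
        """Sparse symmetric vertex adjacency matrix."""
        e = self.edges()
        n = self.n_vertices
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()

    def n_components(self) -> int:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        n = len(self.vertices)
        adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return int(ncomp)

    def transformed(self, transform) -> "SurfaceMesh":
        return SurfaceMesh(transform.apply(self.vertices), self.faces.copy())

    def save(self, path) -> None:
        tm = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        tm.export(str(path))

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


@dataclass
class NodeScalarMap:
    """Per-vertex scalar values with a per-vertex known (Dirichlet) flag.

    ``known`` marks vertices whose value was measured directly; the rest are
    either NaN (pre-interpolation) or interpolated.
    """

    values: np.ndarray
    known: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.known = np.asarray(self.known, dtype=bool)
        if self.values.ndim != 1 or self.values.shape != self.known.shape:
            raise MeshError("values and known must be equal-length 1D arrays")
        if not np.all(np.isfinite(self.values[self.known])):
            raise MeshError("known values must be finite")

    @property
    def n_known(self) -> int:
        return int(self.known.sum())

    @classmethod
    def empty(cls, n: int) -> "NodeScalarMap":
        return cls(np.full(n, np.nan), np.zeros(n, dtype=bool))


@dataclass
class NodeBinaryMap:
    """Per-vertex binary label; 1 = scar / abnormal, 0 = normal."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 1:
            raise MeshError("labels must be 1D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise MeshError(f"labels must be in {{0, 1}}, found {uniq}")
        self.labels = arr.astype(np.uint8)

    def __len__(self) -> int:
        return len(self.labels)

    def count(self) -> int:
        return int(self.labels.sum())
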