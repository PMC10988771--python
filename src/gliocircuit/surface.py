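"""Spherical surface meshes and per-vertex maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError


@dataclass
class SurfaceMesh:
    """Triangulated mesh: ``vertices`` (n, 3) float and ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise FormatError("mesh vertices must be finite")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise FormatError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def vertex_adjacency(self) -> list:
        """Adjacency lists over the mesh edge graph (used for contiguity checks)."""
        adj = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.faces:
            adj[a].update((b, c))
            adj[b].update((a, c))
            adj[c].update((a, b))
        return [sorted(s) for s in adj]


def validate_labels(mesh: SurfaceMesh, labels: np.ndarray) -> np.ndarray:
    """Per-vertex integer parcel labels; 0 means unassigned/medial wall."""
    labels = np.asarray(labels, dtype=np.int64).ravel()
    if len(labels) != mesh.n_vertices:
        raise FormatError(
            f"labels length {len(labels)} != vertex count {mesh.n_vertices}"
        )
    if labels.min(initial=0) < 0:
        raise FormatError("labels must be non-negative integers")
    return labels


@dataclass
class SurfaceMap:
    """One scalar per mesh vertex plus a validity mask (False = masked out)."""

    values: np.ndarray
    valid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool).ravel()
        if self.valid.shape != self.values.shape:
            raise FormatError("validity mask must match value vector length")

    def __len__(self) -> int:
        return len(self.values)
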