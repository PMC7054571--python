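"""Core in-memory containers for cortical surface data.

All coordinates are millimetres in surface RAS (+X right, +Y anterior,
+Z superior), the frame FreeSurfer stores its surfaces in.  Curvature
fields follow the FreeSurfer sign convention: negative mean curvature =
locally convex = gyral; positive = concave = sulcal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError


@dataclass
class TriangleSurface:
    """Triangle mesh of one hemisphere's white or pial surface.

    Parameters
    ----------
    coords : (N, 3) float array
        Vertex coordinates in mm, surface RAS.
    faces : (M, 3) int array
        Vertex indices of each triangle.
    hemisphere : {"left", "right"}
    surface_kind : {"white", "pial", "synthetic"}
    """

    coords: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"
    surface_kind: str = "synthetic"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.validate()

    @property
    def n_vertices(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def validate(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ConsistencyError("coords must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ConsistencyError("faces must be (M, 3)")
        n, m = self.coords.shape[0], self.faces.shape[0]
        if n < 3 or m < 1:
            raise ConsistencyError(f"surface too small: N={n}, M={m}")
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ConsistencyError(
                f"face index out of range [0, {n}): "
                f"min={self.faces.min()}, max={self.faces.max()}"
            )
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            raise ConsistencyError(
                f"{int(degenerate.sum())} faces repeat a vertex"
            )


@dataclass
class VertexScalarField:
    """Per-vertex scalar (mean curvature in 1/mm, thickness in mm, or generic)."""

    values: np.ndarray
    kind: str = "generic"  # {mean_curvature, thickness, generic}
    surface_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        self.validate()

    def __len__(self) -> int:
        return int(self.values.shape[0])

    def validate(self) -> None:
        if self.kind == "thickness" and np.any(self.values < 0):
            raise ConsistencyError("thickness fields must be non-negative")

    def check_length(self, n: int) -> None:
        if len(self) != n:
            raise ConsistencyError(
                f"scalar field has {len(self)} values, surface has {n} vertices"
            )


@dataclass
class CorticalParcellation:
    """Per-vertex ROI assignment with a named ROI table (Destrieux-style).

    ``vertex_roi`` holds the ROI id for every vertex, with −1 marking
    unassigned ("unknown") vertices.  Every non-negative id must appear in
    ``roi_table``, which maps id → (name, (R, G, B)).
    """

    vertex_roi: np.ndarray
    roi_table: dict[int, tuple[str, tuple[int, int, int]]]

    def __post_init__(self) -> None:
        self.vertex_roi = np.asarray(self.vertex_roi, dtype=np.int64).ravel()
        self.validate()

    @property
    def n_vertices(self) -> int:
        return int(self.vertex_roi.shape[0])

    def validate(self) -> None:
        used = np.unique(self.vertex_roi)
        missing = [int(i) for i in used if i >= 0 and i not in self.roi_table]
        if missing:
            raise ConsistencyError(f"ROI ids without table entry: {missing}")
        names = [name for name, _ in self.roi_table.values()]
        if len(names) != len(set(names)):
            raise ConsistencyError("duplicate ROI names in table")

    def roi_id(self, name: str) -> int | None:
        """Look up a ROI id by its (case-sensitive) name; None if absent."""
        for rid, (roi_name, _) in self.roi_table.items():
            if roi_name == name:
                return rid
        return None

    def vertices_of(self, roi_id: int) -> np.ndarray:
        return np.flatnonzero(self.vertex_roi == roi_id)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.roi_table.values()]


@dataclass
class SurfaceLabel:
    """A subset of surface vertices — the pipeline's output currency.

    Mirrors FreeSurfer's ASCII label format: sorted unique vertex indices,
    each with its mm coordinates (copied from the reference surface) and a
    per-vertex statistic value (0 by default).
    """

    vertices: np.ndarray
    coords: np.ndarray
    stat_value: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "label"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64).ravel()
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if self.stat_value is None:
            self.stat_value = np.zeros(len(self.vertices))
        self.stat_value = np.asarray(self.stat_value, dtype=np.float64).ravel()
        self.validate()

    def __len__(self) -> int:
        return int(self.vertices.shape[0])

    def validate(self) -> None:
        if len(self.vertices) and np.any(np.diff(self.vertices) <= 0):
            raise ConsistencyError("label vertices must be strictly increasing")
        if len(self.vertices) and self.vertices[0] < 0:
            raise ConsistencyError("label vertex indices must be non-negative")
        if self.coords.shape[0] != len(self.vertices):
            raise ConsistencyError("label coords row count != vertex count")
        if self.stat_value.shape[0] != len(self.vertices):
            raise ConsistencyError("label stat count != vertex count")

    @classmethod
    def from_vertices(
        cls,
        vertices: np.ndarray,
        surface: TriangleSurface,
        name: str = "label",
        stat_value: np.ndarray | None = None,
    ) -> "SurfaceLabel":
        """Build a label from a vertex set, copying coordinates from *surface*."""
        idx = np.unique(np.asarray(vertices, dtype=np.int64))
        if len(idx) and (idx[0] < 0 or idx[-1] >= surface.n_vertices):
            raise ConsistencyError("label vertex outside surface range")
        return cls(
            vertices=idx,
            coords=surface.coords[idx],
            stat_value=stat_value,
            name=name,
        )
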