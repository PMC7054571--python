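"""Readers and writers for the FreeSurfer on-disk formats the pipeline touches.

Four formats are supported, all big-endian 32-bit:

* binary triangle surface (magic ``0xFF 0xFF 0xFE``) — white/pial geometry;
* "new-format" per-vertex scalar (magic ``0xFF 0xFF 0xFF``) — curvature,
  thickness;
* annotation with embedded version-2 colour table (colour packing
  ``R + 256·G + 65536·B``);
* ASCII label (``#!ascii`` header, one ``index x y z stat`` row per vertex).

Surface geometry and annotations are parsed through ``nibabel.freesurfer``;
the scalar and label formats are handled directly so that truncation and
count mismatches raise instead of being silently ignored.  Legacy quad
surfaces and old two-byte scalar files are rejected: all FreeSurfer ≥v5
output uses the new formats.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import nibabel.freesurfer.io as fsio

from .errors import ConsistencyError, FormatError
from .types import CorticalParcellation, SurfaceLabel, TriangleSurface, VertexScalarField

TRIANGLE_MAGIC = b"\xff\xff\xfe"
SCALAR_MAGIC = b"\xff\xff\xff"

# Fixed creation stamp so writes are byte-deterministic across runs.
_CREATE_STAMP = "created by tash"


def _check_magic(path: Path, expected: bytes, format_name: str) -> None:
    with open(path, "rb") as f:
        magic = f.read(3)
    if magic != expected:
        raise FormatError(
            f"{path}: not a FreeSurfer {format_name} file: expected magic "
            f"{expected.hex()} but found {magic.hex()}"
        )


def read_surface(path: str | Path, hemisphere: str = "left",
                 surface_kind: str = "white") -> TriangleSurface:
    """Read a FreeSurfer binary triangle surface.

    Raises :class:`FormatError` naming the magic found if the file is not in
    the triangle format, and ``IOError``/:class:`FormatError` on truncation.
    """
    path = Path(path)
    _check_magic(path, TRIANGLE_MAGIC, "triangle surface")
    try:
        coords, faces = fsio.read_geometry(str(path))
    except (ValueError, struct.error) as exc:  # truncated payload
        raise IOError(f"{path}: truncated or corrupt surface file: {exc}") from exc
    return TriangleSurface(
        coords=np.asarray(coords, dtype=np.float64),
        faces=np.asarray(faces, dtype=np.int64),
        hemisphere=hemisphere,
        surface_kind=surface_kind,
    )


def write_surface(surface: TriangleSurface, path: str | Path) -> None:
    """Write a triangle surface; ``read_surface`` round-trips it exactly
    (coordinates at float32 precision)."""
    surface.validate()
    fsio.write_geometry(
        str(path),
        surface.coords.astype(np.float32),
        surface.faces.astype(np.int32),
        create_stamp=_CREATE_STAMP,
    )


def read_scalar_field(path: str | Path, expected_n: int,
                      kind: str = "generic") -> VertexScalarField:
    """Read a new-format per-vertex scalar file ("curv"/"thickness").

    The stored vertex count must equal *expected_n* and the values-per-vertex
    field must be 1; anything else raises.
    """
    path = Path(path)
    _check_magic(path, SCALAR_MAGIC, "scalar (curv)")
    with open(path, "rb") as f:
        f.read(3)
        header = f.read(12)
        if len(header) < 12:
            raise IOError(f"{path}: truncated scalar header")
        vnum, _fnum, vals_per_vertex = struct.unpack(">iii", header)
        if vals_per_vertex != 1:
            raise FormatError(
                f"{path}: unsupported scalar file with {vals_per_vertex} "
                "values per vertex (only 1 supported)"
            )
        values = np.fromfile(f, dtype=">f4", count=vnum)
    if values.shape[0] != vnum:
        raise IOError(
            f"{path}: truncated payload: header promises {vnum} values, "
            f"file holds {values.shape[0]}"
        )
    if vnum != expected_n:
        raise ConsistencyError(
            f"{path}: stores {vnum} vertices but surface has {expected_n}"
        )
    return VertexScalarField(values=values.astype(np.float64), kind=kind)


def write_scalar_field(field: VertexScalarField, path: str | Path) -> None:
    """Write a per-vertex scalar in the new ("curv") format."""
    field.validate()
    with open(path, "wb") as f:
        f.write(SCALAR_MAGIC)
        f.write(struct.pack(">iii", len(field), 0, 1))
        f.write(field.values.astype(">f4").tobytes())


def _pack_rgb(rgb: np.ndarray) -> np.ndarray:
    return rgb[:, 0] + 256 * rgb[:, 1] + 65536 * rgb[:, 2]


def read_annotation(path: str | Path) -> CorticalParcellation:
    """Read a FreeSurfer annotation with an embedded (version-2) colour table.

    Each vertex whose packed colour matches a colour-table entry receives
    that entry's ROI id; unmatched or zero-coloured vertices become −1.
    """
    path = Path(path)
    try:
        raw_labels, ctab, names = fsio.read_annot(str(path), orig_ids=True)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse annotation: {exc}") from exc
    if ctab is None or len(names) == 0:
        raise FormatError(f"{path}: annotation has no embedded colour table")
    names = [n.decode() if isinstance(n, bytes) else str(n) for n in names]
    if len(names) != len(set(names)):
        raise ConsistencyError(f"{path}: duplicate ROI names in colour table")
    rgb = np.asarray(ctab[:, :3], dtype=np.int64)
    packed = _pack_rgb(rgb)
    vertex_roi = np.full(raw_labels.shape[0], -1, dtype=np.int64)
    roi_table: dict[int, tuple[str, tuple[int, int, int]]] = {}
    for rid, (name, code) in enumerate(zip(names, packed)):
        roi_table[rid] = (name, tuple(int(c) for c in rgb[rid]))
        if code == 0:
            continue  # zero-coloured = "unknown": stays −1
        vertex_roi[raw_labels == code] = rid
    return CorticalParcellation(vertex_roi=vertex_roi, roi_table=roi_table)


def write_annotation(parc: CorticalParcellation, path: str | Path) -> None:
    """Write a parcellation as an annotation readable by ``read_annotation``.

    Unassigned vertices (−1) are stored with packed colour 0 so they round-trip
    back to −1.  Only what the synthetic fixtures need; not a general-purpose
    annotation writer.
    """
    parc.validate()
    ids = sorted(parc.roi_table)
    names = ["Unknown"] + [parc.roi_table[i][0] for i in ids]
    rgb = np.zeros((len(names), 3), dtype=np.int64)
    for row, rid in enumerate(ids, start=1):
        rgb[row] = parc.roi_table[rid][1]
    if np.any(_pack_rgb(rgb[1:]) == 0):
        raise ConsistencyError("ROI colours must pack to a non-zero code")
    ctab = np.zeros((len(names), 5), dtype=np.int64)
    ctab[:, :3] = rgb
    # labels indexed into the ctab rows; −1 maps to the Unknown row
    index_of = {rid: row for row, rid in enumerate(ids, start=1)}
    labels = np.zeros(parc.n_vertices, dtype=np.int64)
    for rid, row in index_of.items():
        labels[parc.vertex_roi == rid] = row
    fsio.write_annot(str(path), labels, ctab,
                     [n.encode() for n in names], fill_ctab=True)


def read_label(path: str | Path) -> SurfaceLabel:
    """Read a FreeSurfer ASCII label file."""
    path = Path(path)
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#!ascii"):
            raise FormatError(f"{path}: missing '#!ascii' label header")
        try:
            count = int(f.readline().split()[0])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: unreadable vertex-count line") from exc
        rows = [line.split() for line in f if line.strip()]
    if len(rows) != count:
        raise ConsistencyError(
            f"{path}: count line says {count} vertices, file has {len(rows)} rows"
        )
    if count == 0:
        return SurfaceLabel(
            vertices=np.empty(0, dtype=np.int64),
            coords=np.empty((0, 3)),
            name=path.stem,
        )
    data = np.array(rows, dtype=np.float64)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    return SurfaceLabel(
        vertices=data[:, 0].astype(np.int64),
        coords=data[:, 1:4],
        stat_value=data[:, 4],
        name=path.stem,
    )


def write_label(label: SurfaceLabel, path: str | Path) -> None:
    """Write a label in FreeSurfer's ASCII format (ascending vertex order)."""
    label.validate()
    with open(path, "w") as f:
        f.write(f"#!ascii label {label.name}\n")
        f.write(f"{len(label)}\n")
        for v, (x, y, z), s in zip(label.vertices, label.coords, label.stat_value):
            f.write(f"{v}  {x:.6f}  {y:.6f}  {z:.6f} {s:.10f}\n")
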