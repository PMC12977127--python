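"""Readers and writers for every external representation the toolkit touches.

Supported formats
-----------------
Surfaces
    FreeSurfer binary surface, GIFTI (``.surf.gii``), PLY.
Per-vertex labels
    FreeSurfer ``.annot`` (24-bit RGB color packing) and plain CSV
    (``vertex_id,label_id``).
Volumes
    NIfTI-1 (``.nii`` / ``.nii.gz``) and MGZ/MGH.  Integer label volumes stay
    integer; the voxel-center-to-world affine round-trips bit-exactly.
Displacement fields
    Vector NIfTI with shape (X, Y, Z, 1, 3), displacements in world mm.
Color lookup tables
    FreeSurfer-style text (``id name R G B A``).

Voxel indices are 0-based and the affine maps voxel centers to world mm.
"""

from __future__ import annotations

import os
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .errors import (AffineError, DimensionalityError, FormatError,
                     LabelLookupError, UnsupportedGeometryError)
from .types import DisplacementField, LabelTable, LabeledSurface, LabelVolume, Volume

__all__ = [
    "read_surface", "write_surface",
    "read_vertex_labels", "write_vertex_labels",
    "read_volume", "write_volume",
    "read_displacement_field", "write_displacement_field",
    "read_label_table", "write_label_table",
]

SURFACE_FORMATS = ("freesurfer", "gifti", "ply")


def _guess_surface_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".gii"):
        return "gifti"
    if p.endswith(".ply"):
        return "ply"
    return "freesurfer"


def read_surface(path, format: Optional[str] = None) -> LabeledSurface:
    """Read a triangular surface mesh (geometry only), preserving vertex order.

    Vertices are returned in world mm; faces as 0-based index triples.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _guess_surface_format(path)
    if fmt not in SURFACE_FORMATS:
        raise FormatError(f"unknown surface format {fmt!r}")
    if fmt == "freesurfer":
        try:
            verts, faces = nib.freesurfer.read_geometry(str(path))
        except Exception as e:  # noqa: BLE001 - re-raise with context
            raise FormatError(f"not a FreeSurfer binary surface: {path}: {e}") from e
    elif fmt == "gifti":
        img = nib.load(str(path))
        verts = faces = None
        for da in img.darrays:
            if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = da.data
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = da.data
        if verts is None or faces is None:
            raise FormatError(f"GIFTI file lacks pointset/triangle arrays: {path}")
    else:  # ply
        mesh = trimesh.load_mesh(str(path), process=False)
        if not isinstance(mesh, trimesh.Trimesh):
            raise FormatError(f"PLY did not contain a single triangle mesh: {path}")
        verts, faces = np.asarray(mesh.vertices), np.asarray(mesh.faces)
    faces = np.asarray(faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise UnsupportedGeometryError(
            f"non-triangular faces (shape {faces.shape}) in {path}")
    return LabeledSurface(np.asarray(verts, dtype=np.float64),
                          faces.astype(np.int64))


def write_surface(surface: LabeledSurface, path, format: Optional[str] = None) -> None:
    fmt = format or _guess_surface_format(path)
    if fmt == "freesurfer":
        nib.freesurfer.write_geometry(str(path), surface.vertices, surface.faces)
    elif fmt == "gifti":
        gda = nib.gifti.GiftiDataArray
        img = nib.gifti.GiftiImage(darrays=[
            gda(surface.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"),
            gda(surface.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, str(path))
    elif fmt == "ply":
        mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
        mesh.export(str(path))
    else:
        raise FormatError(f"unknown surface format {fmt!r}")


# ---------------------------------------------------------------------------
# per-vertex labels

def _guess_label_format(path: str) -> str:
    p = str(path).lower()
    return "annot" if p.endswith(".annot") else "csv"


def write_vertex_labels(labels: np.ndarray, table: LabelTable, path,
                        format: Optional[str] = None) -> None:
    """Write per-vertex labels with their color table.

    The ``.annot`` dialect stores colors and names only; rows are written in
    ascending label-id order so the (id, name, color) triples can be
    recovered on read.  CSV stores ids directly (``vertex_id,label_id``) with
    a companion ``<path>.lut.txt`` color table.
    """
    fmt = format or _guess_label_format(path)
    labels = np.asarray(labels, dtype=np.int64)
    if fmt == "csv":
        pd.DataFrame({"vertex_id": np.arange(len(labels)),
                      "label_id": labels}).to_csv(path, index=False)
        write_label_table(table, str(path) + ".lut.txt")
    elif fmt == "annot":
        entries = sorted(table.entries, key=lambda e: e[0])
        ids = [e[0] for e in entries]
        names = [e[1] for e in entries]
        ctab = np.zeros((len(entries), 5), dtype=np.int64)
        for r, (_, _, (red, green, blue)) in enumerate(entries):
            ctab[r, :4] = (red, green, blue, 0)
        id_to_row = {i: r for r, i in enumerate(ids)}
        try:
            rows = np.array([id_to_row[int(l)] for l in labels])
        except KeyError as e:
            raise LabelLookupError(f"label id {e} not in table") from e
        nib.freesurfer.write_annot(str(path), rows, ctab, names, fill_ctab=True)
    else:
        raise FormatError(f"unknown label format {fmt!r}")


def read_vertex_labels(path, format: Optional[str] = None,
                       table: Optional[LabelTable] = None
                       ) -> Tuple[np.ndarray, LabelTable]:
    """Read per-vertex labels, mapping colors/ids through a color table.

    For ``.annot``, labels are mapped to stable integer ids: if ``table`` is
    given, each annotation color is looked up in it (an unknown color raises
    :class:`LabelLookupError` naming the color); otherwise ids are assigned
    from the row order of the embedded color table, matching the ascending-id
    convention used by :func:`write_vertex_labels`.
    """
    fmt = format or _guess_label_format(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        labels = df.sort_values("vertex_id")["label_id"].to_numpy(dtype=np.int64)
        lut_path = str(path) + ".lut.txt"
        if table is None and os.path.exists(lut_path):
            table = read_label_table(lut_path)
        if table is None:
            present = np.unique(labels)
            entries = [(0, "background", (0, 0, 0))]
            entries += [(int(i), f"label_{int(i)}", (int(i) % 256, 0, 0))
                        for i in present if i != 0]
            table = LabelTable(entries)
        return labels, table
    if fmt == "annot":
        rows, ctab, names = nib.freesurfer.read_annot(str(path))
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in names]
        colors = [tuple(int(c) for c in ctab[r, :3]) for r in range(len(names))]
        if table is not None:
            color_to_id = {table.color_of(i): i for i in table.ids}
            row_ids = []
            for c in colors:
                if c not in color_to_id:
                    raise LabelLookupError(
                        f"annotation color RGB{c} has no entry in the label table")
                row_ids.append(color_to_id[c])
            row_ids = np.array(row_ids, dtype=np.int64)
        else:
            row_ids = np.arange(len(names), dtype=np.int64)
            table = LabelTable([(int(row_ids[r]), names[r], colors[r])
                                for r in range(len(names))])
        if np.any(rows < 0):
            raise LabelLookupError(
                "annotation contains colors absent from its own color table")
        return row_ids[rows], table
    raise FormatError(f"unknown label format {fmt!r}")


# ---------------------------------------------------------------------------
# volumes

def _as_int_dtype(arr: np.ndarray) -> np.ndarray:
    if arr.min() >= np.iinfo(np.int32).min and arr.max() <= np.iinfo(np.int32).max:
        return arr.astype(np.int32)
    return arr.astype(np.int64)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1 or MGZ (by extension), preserving the affine."""
    arr = volume.array
    if np.issubdtype(arr.dtype, np.integer):
        arr = _as_int_dtype(arr)
    else:
        arr = arr.astype(np.float32)
    p = str(path).lower()
    if p.endswith((".mgz", ".mgh")):
        img = nib.MGHImage(arr, volume.affine)
    else:
        img = nib.Nifti1Image(arr, volume.affine)
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    """Read a NIfTI-1 or MGZ volume.

    Returns a :class:`LabelVolume` when the on-disk dtype is integer, else a
    float :class:`Volume`.  4-D inputs raise :class:`DimensionalityError`.
    """
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise DimensionalityError(
            f"expected a 3-D volume, got shape {arr.shape} in {path}")
    affine = img.affine
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise AffineError(f"singular affine in {path}")
    if np.issubdtype(arr.dtype, np.integer):
        return LabelVolume(arr, affine)
    return Volume(arr, affine)


# ---------------------------------------------------------------------------
# displacement fields

def write_displacement_field(field: DisplacementField, path) -> None:
    """Vector NIfTI with shape (X, Y, Z, 1, 3); displacements in world mm."""
    data = field.vectors[:, :, :, np.newaxis, :].astype(np.float32)
    img = nib.Nifti1Image(data, field.affine)
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_displacement_field(path) -> DisplacementField:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 5 and arr.shape[3] == 1:
        arr = arr[:, :, :, 0, :]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise DimensionalityError(
            f"expected a (X,Y,Z,1,3) or (X,Y,Z,3) vector image, got {arr.shape}")
    return DisplacementField(arr.astype(np.float64), img.affine)


# ---------------------------------------------------------------------------
# color lookup tables

def write_label_table(table: LabelTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id name R G B A\n")
        for i, name, (r, g, b) in sorted(table.entries, key=lambda e: e[0]):
            fh.write(f"{i} {name} {r} {g} {b} 0\n")


def read_label_table(path) -> LabelTable:
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"malformed LUT line: {line!r}")
            i, name = int(parts[0]), parts[1]
            r, g, b = (int(x) for x in parts[2:5])
            entries.append((i, name, (r, g, b)))
    return LabelTable(entries)
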