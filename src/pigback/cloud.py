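"""Point-cloud container and PLY / feature-table input-output.

Conventions used throughout the package:

* coordinates are metres, ``z`` is height above the floor plane (increasing
  upward; the depth camera sits conceptually 2.5 m overhead);
* a cloud is an unordered set of points — every downstream algorithm is
  order-invariant up to documented determinism rules;
* optional per-point labels tag the synthetic ground truth
  (``pig_torso``, ``pig_head``, ``pig_tail``, ``floor``, ``outlier_large``,
  ``outlier_small``, ``unknown``); real recordings carry no labels.

PLY support is deliberately small: element ``vertex`` with ``x, y, z``
properties, ASCII or binary little-endian. Big-endian files are rejected
with a clear error rather than half-supported.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SchemaError

LABELS = (
    "unknown",
    "floor",
    "pig_torso",
    "pig_head",
    "pig_tail",
    "outlier_large",
    "outlier_small",
)

PIG_LABELS = ("pig_torso", "pig_head", "pig_tail")

#: CSV schema of the back-feature table (optionally followed by actual_weight).
FEATURE_COLUMNS = (
    "envelope_volume",
    "envelope_area",
    "projection_area",
    "shoulder_width",
    "belly_width",
    "hip_width",
)

# PLY scalar types we can parse. Values: (struct format char, numpy dtype).
_PLY_TYPES = {
    "float": ("f", np.float32),
    "float32": ("f", np.float32),
    "double": ("d", np.float64),
    "float64": ("d", np.float64),
    "char": ("b", np.int8),
    "int8": ("b", np.int8),
    "uchar": ("B", np.uint8),
    "uint8": ("B", np.uint8),
    "short": ("h", np.int16),
    "int16": ("h", np.int16),
    "ushort": ("H", np.uint16),
    "uint16": ("H", np.uint16),
    "int": ("i", np.int32),
    "int32": ("i", np.int32),
    "uint": ("I", np.uint32),
    "uint32": ("I", np.uint32),
}


class PointCloud:
    """An unordered set of 3D points in metres with optional labels.

    Parameters
    ----------
    points : array-like of shape (n, 3)
        Cartesian coordinates. Must be finite.
    labels : sequence of str, optional
        One tag per point, drawn from :data:`LABELS`.
    """

    __slots__ = ("points", "labels")

    def __init__(self, points, labels=None):
        pts = np.asarray(points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ParameterError(f"points must have shape (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ParameterError("point coordinates must all be finite")
        self.points = pts
        if labels is not None:
            lab = np.asarray(labels, dtype="U13")
            if lab.shape != (len(pts),):
                raise ParameterError(
                    f"labels length {lab.shape} does not match {len(pts)} points"
                )
            bad = set(np.unique(lab)) - set(LABELS)
            if bad:
                raise ParameterError(f"unknown labels: {sorted(bad)}")
            self.labels = lab
        else:
            self.labels = None

    def __len__(self) -> int:
        return len(self.points)

    def __repr__(self) -> str:
        tag = "labeled" if self.labels is not None else "unlabeled"
        return f"PointCloud({len(self)} points, {tag})"

    def select(self, mask) -> "PointCloud":
        """Subset by boolean mask or index array, preserving point order."""
        mask = np.asarray(mask)
        labels = self.labels[mask] if self.labels is not None else None
        return PointCloud(self.points[mask], labels)

    def label_counts(self) -> dict:
        if self.labels is None:
            return {}
        vals, counts = np.unique(self.labels, return_counts=True)
        return {str(v): int(c) for v, c in zip(vals, counts)}


@dataclass
class SceneGroundTruth:
    """Ground truth attached to a synthetic scene (stand-in for scale readings)."""

    true_weight: float  # kg
    body_length: float  # m
    body_width: float  # m
    body_height: float  # m
    label_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.true_weight <= 0:
            raise ParameterError("true_weight must be positive")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SceneGroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

def _parse_ply_header(fh):
    """Parse the header of an open binary file, return (fmt, elements, offset).

    ``elements`` is a list of (name, count, [(prop_name, type_str), ...]).
    List properties are recorded as (name, ("list", count_type, item_type)).
    """
    magic = fh.readline().strip()
    if magic != b"ply":
        raise FormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements = []
    while True:
        raw = fh.readline()
        if not raw:
            raise FormatError("unexpected end of file inside PLY header")
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        parts = line.split()
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if not elements:
                raise FormatError("PLY property outside any element")
            if parts[1] == "list":
                elements[-1][2].append((parts[4], ("list", parts[2], parts[3])))
            else:
                elements[-1][2].append((parts[2], parts[1]))
        elif parts[0] == "end_header":
            break
        else:
            raise FormatError(f"unrecognized PLY header line: {line!r}")
    if fmt is None:
        raise FormatError("PLY header has no 'format' line")
    if fmt == "binary_big_endian":
        raise FormatError(
            "big-endian PLY is not supported; re-export as ascii or "
            "binary_little_endian"
        )
    if fmt not in ("ascii", "binary_little_endian"):
        raise FormatError(f"unsupported PLY format {fmt!r}")
    return fmt, elements


def read_ply(path) -> PointCloud:
    """Read the vertex element of an ASCII or binary little-endian PLY file.

    Extra vertex properties (colors, normals, ...) are ignored; only the
    ``x``, ``y``, ``z`` coordinates are returned, in file order.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements = _parse_ply_header(fh)
        names = [e[0] for e in elements]
        if "vertex" not in names:
            raise FormatError("PLY file has no 'vertex' element")
        vi = names.index("vertex")
        _, n_vertex, props = elements[vi]
        prop_names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in prop_names:
                raise FormatError(f"PLY vertex element is missing property '{axis}'")
        if any(isinstance(t, tuple) for _, t in props):
            raise FormatError("list properties on the vertex element are unsupported")

        if fmt == "ascii":
            rows = np.zeros((n_vertex, 3))
            cols = [prop_names.index(a) for a in "xyz"]
            # honor declared precision: float32 columns round-trip exactly
            casts = [np.dtype(_PLY_TYPES[props[c][1]][1]).type for c in cols]
            for i in range(n_vertex):
                line = fh.readline()
                if not line:
                    raise FormatError("PLY file truncated inside vertex data")
                vals = line.split()
                if len(vals) < len(prop_names):
                    raise FormatError(f"vertex row {i} has too few values")
                rows[i] = [cast(float(vals[c])) for c, cast in zip(cols, casts)]
            return PointCloud(rows)

        # binary little-endian; elements before "vertex" must be skippable
        for name, count, eprops in elements[:vi]:
            if any(isinstance(t, tuple) for _, t in eprops):
                raise FormatError(
                    f"cannot skip element '{name}' with list properties "
                    "preceding the vertex element in a binary PLY"
                )
            row = sum(struct.calcsize(_PLY_TYPES[t][0]) for _, t in eprops)
            fh.seek(count * row, 1)
        dtype = np.dtype([(p, np.dtype(_PLY_TYPES[t][1]).newbyteorder("<"))
                          for p, t in props])
        buf = fh.read(n_vertex * dtype.itemsize)
        if len(buf) < n_vertex * dtype.itemsize:
            raise FormatError("PLY file truncated inside vertex data")
        rec = np.frombuffer(buf, dtype=dtype, count=n_vertex)
        return PointCloud(np.column_stack([rec["x"], rec["y"], rec["z"]]))


def write_ply(cloud: PointCloud, path, format: str = "ascii") -> None:
    """Write a cloud as PLY with float32 x, y, z vertex properties."""
    if format not in ("ascii", "binary"):
        raise ParameterError(f"format must be 'ascii' or 'binary', got {format!r}")
    fmt_name = "ascii" if format == "ascii" else "binary_little_endian"
    pts = cloud.points.astype(np.float32)
    header = (
        "ply\n"
        f"format {fmt_name} 1.0\n"
        f"element vertex {len(pts)}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if format == "ascii":
            for x, y, z in pts:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n".encode("ascii"))
        else:
            fh.write(np.ascontiguousarray(pts, dtype="<f4").tobytes())


# ---------------------------------------------------------------------------
# Feature tables (six back parameters, optional paired weight)
# ---------------------------------------------------------------------------

def read_feature_table(path):
    """Read a back-feature CSV into a list of (BackFeatures, weight-or-None).

    The header must carry ``id`` plus the six feature columns; a trailing
    ``actual_weight`` column is optional. Decimal separator is the dot,
    independent of locale.
    """
    from .features import BackFeatures  # local import to avoid a cycle

    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"feature table {path} is empty or has no header") from exc
    for col in ("id",) + FEATURE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"feature table is missing required column '{col}'")
    has_weight = "actual_weight" in df.columns
    out = []
    for i, row in df.iterrows():
        try:
            feats = BackFeatures(*(float(row[c]) for c in FEATURE_COLUMNS))
            weight = float(row["actual_weight"]) if has_weight else None
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric cell in feature table row {i}") from exc
        out.append((feats, weight))
    return out


def write_feature_table(records, path, ids: Sequence | None = None) -> None:
    """Write (BackFeatures, weight-or-None) records in the CSV schema."""
    rows = []
    any_weight = any(w is not None for _, w in records)
    for i, (feats, weight) in enumerate(records):
        row = {"id": ids[i] if ids is not None else f"{i + 1:03d}"}
        row.update({c: getattr(feats, c) for c in FEATURE_COLUMNS})
        if any_weight:
            row["actual_weight"] = weight
        rows.append(row)
    cols = ["id", *FEATURE_COLUMNS] + (["actual_weight"] if any_weight else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
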