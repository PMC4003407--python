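"""Dendrite medial axes and spine marker tables.

A dendritic segment is represented by its *medial axis* -- an ordered 3D
polyline manually traced through the middle of the dendritic shaft -- and a
table of *spine records*, one per dendritic spine, each carrying the spine's
insertion point on the shaft plus its morphometric marks (length and volume).
All coordinates are micrometres (μm); volumes are μm³.

Axes are read from SWC (the community interchange format for traced
neurites, restricted here to a single unbranched path) or from a plain
3-column CSV.  Spine tables are CSV with a fixed schema
``spine_id,x,y,z,length_um,volume_um3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MedialAxis",
    "SpineRecord",
    "MorphologyError",
    "read_axis_swc",
    "read_axis_csv",
    "write_axis_csv",
    "read_spine_table",
    "write_spine_table",
]

#: significant digits used when writing CSV floats; chosen so that
#: write -> read -> write is byte-identical.
FLOAT_FORMAT = "%.6g"


class MorphologyError(ValueError):
    """Invalid morphology input (malformed file, degenerate geometry)."""


@dataclass(frozen=True)
class MedialAxis:
    """Ordered polyline through the dendritic shaft, with arc length.

    Attributes
    ----------
    points : ndarray, shape (n, 3)
        Vertex coordinates in μm, ordered root (soma end) to tip.
    cum_s : ndarray, shape (n,)
        Cumulative arc length at each vertex; ``cum_s[0] == 0`` and
        ``cum_s[i] - cum_s[i-1]`` is the Euclidean length of segment i.
    """

    points: np.ndarray
    cum_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise MorphologyError("degenerate axis: need >= 2 three-dimensional points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            i = int(np.argmax(seg == 0.0)) + 1
            raise MorphologyError(f"duplicate consecutive vertices at row {i}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "cum_s", np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def total_length(self) -> float:
        """Total arc length of the axis in μm."""
        return float(self.cum_s[-1])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class SpineRecord:
    """One dendritic spine: insertion point plus morphometric marks."""

    spine_id: str
    insertion: tuple[float, float, float]
    length_um: float
    volume_um3: float

    def __post_init__(self) -> None:
        if self.length_um < 0:
            raise MorphologyError(f"spine {self.spine_id!r}: negative length {self.length_um}")
        if self.volume_um3 < 0:
            raise MorphologyError(f"spine {self.spine_id!r}: negative volume {self.volume_um3}")
        object.__setattr__(self, "insertion", tuple(float(c) for c in self.insertion))


# ---------------------------------------------------------------------------
# SWC

def read_axis_swc(path) -> MedialAxis:
    """Read an unbranched SWC file as a medial axis.

    The standard 7-column SWC layout (``id type x y z radius parent``) is
    expected.  The path is reconstructed by following parent pointers from
    the single root, so the file's row order is not trusted.  The radius
    column is ignored; coordinates are taken as μm.

    Raises
    ------
    MorphologyError
        If any node has two children ("axis must be unbranched"), if fewer
        than two nodes are present ("degenerate axis"), or on a malformed
        line (reported with its line number).
    """
    nodes: dict[int, np.ndarray] = {}
    parent: dict[int, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise MorphologyError(f"malformed SWC line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                nid = int(cols[0])
                xyz = np.array([float(cols[2]), float(cols[3]), float(cols[4])])
                par = int(cols[6])
            except ValueError as exc:
                raise MorphologyError(f"malformed SWC line {lineno}: {exc}") from None
            if nid in nodes:
                raise MorphologyError(f"malformed SWC line {lineno}: duplicate node id {nid}")
            nodes[nid] = xyz
            parent[nid] = par

    if len(nodes) < 2:
        raise MorphologyError("degenerate axis: SWC file has fewer than 2 nodes")

    children: dict[int, list[int]] = {}
    roots = []
    for nid, par in parent.items():
        if par == -1:
            roots.append(nid)
        else:
            if par not in nodes:
                raise MorphologyError(f"SWC node {nid} references missing parent {par}")
            children.setdefault(par, []).append(nid)
    if len(roots) != 1:
        raise MorphologyError(f"axis must be a single path: found {len(roots)} root nodes")
    for nid, kids in children.items():
        if len(kids) > 1:
            raise MorphologyError("axis must be unbranched")

    order = [roots[0]]
    while order[-1] in children:
        order.append(children[order[-1]][0])
    if len(order) != len(nodes):
        raise MorphologyError("axis must be a single path: disconnected nodes present")
    return MedialAxis(np.array([nodes[n] for n in order]))


# ---------------------------------------------------------------------------
# CSV axes

def read_axis_csv(path) -> MedialAxis:
    """Read a medial axis from a CSV with columns x,y,z (header required)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise MorphologyError("degenerate axis: empty file") from None
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise MorphologyError(f"axis CSV missing column {col!r}")
    sub = df[["x", "y", "z"]]
    bad = sub.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0, 0]) + 1
        raise MorphologyError(f"non-numeric coordinate at axis row {row}")
    if len(df) < 2:
        raise MorphologyError("degenerate axis: need >= 2 vertices")
    return MedialAxis(sub.to_numpy(dtype=float))


def write_axis_csv(axis: MedialAxis, path) -> None:
    df = pd.DataFrame(axis.points, columns=["x", "y", "z"])
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Spine tables

SPINE_COLUMNS = ["spine_id", "x", "y", "z", "length_um", "volume_um3"]


def read_spine_table(path) -> list[SpineRecord]:
    """Read spine records from CSV; order preserved, ids must be unique."""
    try:
        df = pd.read_csv(path, dtype={"spine_id": str})
    except pd.errors.EmptyDataError:
        raise MorphologyError("empty spine table") from None
    for col in SPINE_COLUMNS:
        if col not in df.columns:
            raise MorphologyError(f"spine table missing column {col!r}")
    dup = df["spine_id"].duplicated()
    if dup.any():
        raise MorphologyError(f"duplicate spine_id {df['spine_id'][dup].iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SpineRecord(
                spine_id=str(row.spine_id),
                insertion=(float(row.x), float(row.y), float(row.z)),
                length_um=float(row.length_um),
                volume_um3=float(row.volume_um3),
            )
        )
    return records


def write_spine_table(spines: list[SpineRecord], path) -> None:
    df = pd.DataFrame(
        {
            "spine_id": [s.spine_id for s in spines],
            "x": [s.insertion[0] for s in spines],
            "y": [s.insertion[1] for s in spines],
            "z": [s.insertion[2] for s in spines],
            "length_um": [s.length_um for s in spines],
            "volume_um3": [s.volume_um3 for s in spines],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
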