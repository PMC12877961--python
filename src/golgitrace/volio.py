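"""Readers, writers and coordinate conventions for volumes, SWC trees and markers.

Conventions used throughout the package:

* volumes are stored ``(z, y, x)`` slice-major with physical voxel spacing
  ``(dz, dy, dx)`` in micrometres;
* voxel indices are 0-based, physical coordinates are voxel *centres* in μm
  with the origin at index ``(0, 0, 0)``, so ``x = ix * dx`` etc.;
* SWC files keep the standard ``x y z`` column order and physical μm units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "StructureError",
    "Volume",
    "SWCTree",
    "Marker",
    "MarkerSet",
    "MARKER_KINDS",
    "read_volume",
    "write_volume",
    "convert_to_8bit",
    "read_swc",
    "write_swc",
    "read_markers",
    "write_markers",
    "index_to_physical",
    "physical_to_index",
]


class FormatError(ValueError):
    """An on-disk artefact cannot be parsed into a domain object."""


class StructureError(ValueError):
    """An SWC record set violates the tree invariants."""


# ---------------------------------------------------------------------------
# Volume
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Volume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    grid : ndarray, shape (nz, ny, nx)
        Intensity grid, slice-major ``(z, y, x)``.
    spacing : tuple of float
        ``(dz, dy, dx)`` voxel spacing in μm; all components positive.
    bit_depth : int
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    polarity : str
        ``"bright"`` when signal is brighter than background (the usual
        case for Golgi-type contrast), ``"dark"`` otherwise.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    bit_depth: int
    polarity: str = "bright"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if grid.ndim != 3:
            raise ValueError(f"volume grid must be 3D, got ndim={grid.ndim}")
        if any(d < 1 for d in grid.shape):
            raise ValueError(f"all grid dimensions must be >= 1, got {grid.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.polarity not in ("bright", "dark"):
            raise ValueError(f"polarity must be 'bright' or 'dark', got {self.polarity!r}")
        lim = 2 ** self.bit_depth - 1
        if grid.size and (grid.min() < 0 or grid.max() > lim):
            raise ValueError(f"intensities outside [0, {lim}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in μm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def max_intensity(self) -> float:
        return float(self.grid.max())


_TIFF_SUFFIXES = (".tif", ".tiff")


def read_volume(path: str | Path, spacing: Sequence[float]) -> Volume:
    """Read a multi-page TIFF or a directory of equally sized 2D TIFF slices.

    Slices in a directory are stacked in lexicographic filename order as z.
    Bit depth is inferred from the sample type; anything other than unsigned
    8/16-bit raises :class:`FormatError` rather than silently truncating.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
        )
        if not files:
            raise FormatError(f"no TIFF slices found in directory {path}")
        slices = []
        for f in files:
            arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise FormatError(f"slice {f} is not 2D (shape {arr.shape})")
            slices.append(arr)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise FormatError(f"slices in {path} have unequal shapes: {sorted(shapes)}")
        grid = np.stack(slices, axis=0)
    else:
        if not path.exists():
            raise FormatError(f"volume path does not exist: {path}")
        grid = tifffile.imread(path)
        if grid.ndim == 2:
            grid = grid[None]
        if grid.ndim != 3:
            raise FormatError(f"{path}: expected a 2D/3D TIFF, got shape {grid.shape}")
    if grid.dtype == np.uint8:
        bit_depth = 8
    elif grid.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(f"unsupported sample type {grid.dtype}; expected uint8/uint16")
    return Volume(grid=grid, spacing=tuple(spacing), bit_depth=bit_depth)


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF, re-readable to an identical grid."""
    path = Path(path)
    dtype = np.uint8 if vol.bit_depth == 8 else np.uint16
    try:
        # explicit photometric keeps 3-slice stacks from being guessed as RGB
        tifffile.imwrite(
            path, np.ascontiguousarray(vol.grid.astype(dtype)),
            photometric="minisblack",
        )
    except OSError as exc:  # unwritable path
        raise FormatError(f"cannot write volume to {path}: {exc}") from exc
    return path


def convert_to_8bit(
    vol: Volume,
    mode: str = "minmax",
    lo: float | None = None,
    hi: float | None = None,
) -> Volume:
    """Linearly rescale a 16-bit volume onto [0, 255].

    ``mode="minmax"`` maps the global min/max of the grid onto 0/255; a
    degenerate (constant) range maps to all zeros, signalling no contrast.
    ``mode="fixed"`` maps the caller-supplied ``[lo, hi]`` instead, clipping
    outside values.  Rounding is half-up.
    """
    if vol.bit_depth != 16:
        raise ValueError("convert_to_8bit expects a 16-bit volume")
    g = vol.grid.astype(np.float64)
    if mode == "minmax":
        lo, hi = float(g.min()), float(g.max())
        if hi <= lo:
            out = np.zeros_like(g)
            return Volume(out.astype(np.uint8), vol.spacing, 8, vol.polarity)
    elif mode == "fixed":
        if lo is None or hi is None:
            raise ValueError("fixed mode requires lo and hi")
        if lo >= hi:
            raise ValueError(f"fixed range requires lo < hi, got lo={lo}, hi={hi}")
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'minmax' or 'fixed'")
    scaled = np.clip((g - lo) / (hi - lo), 0.0, 1.0) * 255.0
    out = np.floor(scaled + 0.5).astype(np.uint8)  # round half-up
    return Volume(out, vol.spacing, 8, vol.polarity)


# ---------------------------------------------------------------------------
# SWC trees
# ---------------------------------------------------------------------------

SWC_COLUMNS = ("id", "stype", "x", "y", "z", "radius", "parent")


@dataclass(frozen=True)
class SWCTree:
    """A rooted, typed neuron tree with standard SWC semantics.

    ``nodes`` is a DataFrame with columns ``id, stype, x, y, z, radius,
    parent`` (coordinates and radii in μm; ``parent == -1`` marks the single
    root).  Structure types follow the SWC standard: 1 soma, 2 axon,
    3 basal dendrite, 4 apical dendrite.
    """

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.nodes.reset_index(drop=True)
        object.__setattr__(self, "nodes", df)
        _validate_swc(df)

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent"] == -1, "id"].iloc[0])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def parent_map(self) -> dict[int, int]:
        return dict(zip(self.nodes["id"].astype(int), self.nodes["parent"].astype(int)))

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(i): [] for i in self.nodes["id"]}
        for nid, pid in zip(self.nodes["id"].astype(int), self.nodes["parent"].astype(int)):
            if pid != -1:
                out[pid].append(nid)
        return out

    def positions(self) -> dict[int, np.ndarray]:
        return {
            int(r.id): np.array([r.x, r.y, r.z], dtype=float)
            for r in self.nodes.itertuples()
        }

    def node_position(self, node_id: int) -> np.ndarray:
        row = self.nodes.loc[self.nodes["id"] == node_id]
        if row.empty:
            raise KeyError(f"no node with id {node_id}")
        return row[["x", "y", "z"]].to_numpy(dtype=float)[0]

    def soma_position(self) -> np.ndarray:
        return self.node_position(self.root_id)


def _validate_swc(df: pd.DataFrame) -> None:
    missing = set(SWC_COLUMNS) - set(df.columns)
    if missing:
        raise StructureError(f"SWC table missing columns {sorted(missing)}")
    if df.empty:
        raise StructureError("SWC tree must contain at least one node")
    ids = df["id"].astype(int)
    if (ids <= 0).any():
        bad = int(ids[ids <= 0].iloc[0])
        raise StructureError(f"non-positive node id {bad}")
    if ids.duplicated().any():
        dup = int(ids[ids.duplicated()].iloc[0])
        raise StructureError(f"duplicate node id {dup}")
    if (df["radius"].astype(float) < 0).any():
        bad = df.loc[df["radius"] < 0].iloc[0]
        raise StructureError(f"negative radius on node {int(bad['id'])}")
    parents = df["parent"].astype(int)
    roots = ids[parents == -1]
    if len(roots) != 1:
        raise StructureError(f"expected exactly one root (parent=-1), found {len(roots)}")
    idset = set(ids)
    for nid, pid in zip(ids, parents):
        if pid != -1 and pid not in idset:
            raise StructureError(f"node {nid} references missing parent {pid}")
    # connectivity (and hence acyclicity of the parent-pointer graph)
    children: dict[int, list[int]] = {int(i): [] for i in ids}
    for nid, pid in zip(ids, parents):
        if pid != -1:
            children[int(pid)].append(int(nid))
    root = int(roots.iloc[0])
    seen = {root}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) != len(ids):
        orphan = sorted(set(map(int, ids)) - seen)[0]
        raise StructureError(
            f"node {orphan} is not reachable from the root (cycle or disconnected record)"
        )


def read_swc(path: str | Path) -> SWCTree:
    """Parse a whitespace-delimited 7-column SWC file ('#' lines are comments)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                records.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable record: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no SWC records found")
    df = pd.DataFrame(records, columns=list(SWC_COLUMNS))
    return SWCTree(df)


def write_swc(tree: SWCTree, path: str | Path, comment: str | None = None) -> Path:
    """Write a tree as standard SWC; floats carry 4 decimal places."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for r in tree.nodes.itertuples():
            fh.write(
                f"{int(r.id)} {int(r.stype)} {r.x:.4f} {r.y:.4f} {r.z:.4f} "
                f"{r.radius:.4f} {int(r.parent)}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

MARKER_KINDS = ("soma_seed", "branch_terminal", "eraser_sphere", "eraser_box")


@dataclass(frozen=True)
class Marker:
    """A manual annotation in physical μm coordinates.

    ``param`` is the radius for ``eraser_sphere`` and the ``(ex, ey, ez)``
    edge extent for ``eraser_box``; unused otherwise.
    """

    kind: str
    position: tuple[float, float, float]  # (x, y, z) μm
    param: float | tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise FormatError(f"unknown marker kind {self.kind!r}")
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))
        if self.kind == "eraser_sphere":
            if self.param is None or float(self.param) <= 0:  # type: ignore[arg-type]
                raise FormatError("eraser_sphere requires a positive radius param")
            object.__setattr__(self, "param", float(self.param))  # type: ignore[arg-type]
        elif self.kind == "eraser_box":
            if self.param is None:
                raise FormatError("eraser_box requires an extent param 'ex;ey;ez'")
            ext = tuple(float(v) for v in self.param)  # type: ignore[union-attr]
            if len(ext) != 3 or any(e <= 0 for e in ext):
                raise FormatError("eraser_box extent must be three positive values")
            object.__setattr__(self, "param", ext)


@dataclass(frozen=True)
class MarkerSet:
    """Soma-seed, branch-terminal and eraser annotations for one task."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))

    def __len__(self) -> int:
        return len(self.markers)

    def of_kind(self, *kinds: str) -> tuple[Marker, ...]:
        return tuple(m for m in self.markers if m.kind in kinds)

    @property
    def terminals(self) -> tuple[Marker, ...]:
        return self.of_kind("branch_terminal")

    @property
    def erasers(self) -> tuple[Marker, ...]:
        return self.of_kind("eraser_sphere", "eraser_box")

    def single_soma(self) -> Marker:
        """The unique soma seed; raises if the task has zero or several."""
        somas = self.of_kind("soma_seed")
        if len(somas) != 1:
            raise FormatError(
                f"single-neuron task requires exactly one soma_seed marker, found {len(somas)}"
            )
        return somas[0]


def read_markers(path: str | Path, require_soma: bool = False) -> MarkerSet:
    """Read a marker CSV with header ``x,y,z,kind[,param]`` (positions in μm)."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for needed in ("x", "y", "z", "kind"):
        if needed not in cols:
            raise FormatError(f"{path}: marker CSV missing column {needed!r}")
    markers = []
    for row in df.itertuples():
        kind = str(row.kind).strip()
        raw_param = getattr(row, "param", None)
        param: float | tuple[float, float, float] | None = None
        if raw_param is not None and not (isinstance(raw_param, float) and math.isnan(raw_param)):
            if kind == "eraser_box":
                param = tuple(float(v) for v in str(raw_param).split(";"))  # type: ignore[assignment]
            elif kind == "eraser_sphere":
                param = float(raw_param)
        markers.append(Marker(kind=kind, position=(row.x, row.y, row.z), param=param))
    ms = MarkerSet(tuple(markers))
    if require_soma:
        ms.single_soma()
    return ms


def write_markers(markers: MarkerSet, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for m in markers.markers:
        if m.kind == "eraser_box":
            param = ";".join(f"{v:g}" for v in m.param)  # type: ignore[union-attr]
        elif m.kind == "eraser_sphere":
            param = f"{m.param:g}"
        else:
            param = ""
        x, y, z = m.position
        rows.append({"x": x, "y": y, "z": z, "kind": m.kind, "param": param})
    pd.DataFrame(rows, columns=["x", "y", "z", "kind", "param"]).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def index_to_physical(
    idx: Sequence[int], spacing: Sequence[float]
) -> tuple[float, float, float]:
    """Voxel index ``(iz, iy, ix)`` → physical ``(x, y, z)`` μm (voxel centres)."""
    iz, iy, ix = idx
    dz, dy, dx = spacing
    return (ix * dx, iy * dy, iz * dz)


def physical_to_index(
    pos: Sequence[float],
    spacing: Sequence[float],
    shape: Sequence[int] | None = None,
) -> tuple[int, int, int]:
    """Physical ``(x, y, z)`` μm → nearest voxel index ``(iz, iy, ix)``.

    With ``shape`` given, an index outside the grid raises ``IndexError``.
    """
    x, y, z = (float(v) for v in pos)
    dz, dy, dx = spacing
    idx = (
        int(math.floor(z / dz + 0.5)),
        int(math.floor(y / dy + 0.5)),
        int(math.floor(x / dx + 0.5)),
    )
    if shape is not None:
        if any(i < 0 or i >= n for i, n in zip(idx, shape)):
            raise IndexError(
                f"physical point {pos} maps to voxel {idx}, outside grid {tuple(shape)}"
            )
    return idx
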