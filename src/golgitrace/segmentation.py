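"""Background denoising and single-neuron extraction.

Densely labelled Golgi-type volumes carry a textured tissue background plus
non-specific vessel and glia signal.  The extraction strategy is: global
intensity threshold → connected-component labelling → removal of components
below a physical-volume floor (default 1000 μm³) → selection of the component
holding the soma seed → optional manual eraser edits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volio import MarkerSet, Volume, physical_to_index

__all__ = [
    "BinaryMask",
    "Labeling",
    "SeedError",
    "threshold_volume",
    "evaluate_thresholds",
    "label_components",
    "filter_small_components",
    "select_neuron",
    "apply_edits",
]


class SeedError(ValueError):
    """No foreground voxel lies within snapping range of a seed point."""


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground mask sharing the source volume's geometry."""

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if grid.ndim != 3:
            raise ValueError("mask grid must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class Labeling:
    """Integer component map plus a per-component summary table.

    ``components`` columns: ``label, voxel_count, volume_um3, z0, z1, y0,
    y1, x0, x1`` (half-open bounding boxes).  Labels run 1..K with no gaps;
    ``volume_um3 = voxel_count * dz*dy*dx``.
    """

    label_grid: np.ndarray
    components: pd.DataFrame
    spacing: tuple[float, float, float]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def mask_of(self, labels: Sequence[int]) -> BinaryMask:
        k = int(self.label_grid.max())
        lut = np.zeros(k + 1, dtype=bool)
        lut[np.asarray(list(labels), dtype=int)] = True
        return BinaryMask(lut[self.label_grid], self.spacing)


_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


def threshold_volume(vol: Volume, T: float, polarity: str | None = None) -> BinaryMask:
    """Binarise a volume at intensity ``T``.

    Bright-foreground polarity keeps voxels with intensity ≥ T; dark
    polarity keeps intensity ≤ T.  ``T`` must lie within the dynamic range.
    """
    lim = 2 ** vol.bit_depth - 1
    if not (0 <= T <= lim):
        raise ValueError(f"threshold {T} outside dynamic range [0, {lim}]")
    polarity = polarity or vol.polarity
    if polarity == "bright":
        grid = vol.grid >= T
    elif polarity == "dark":
        grid = vol.grid <= T
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return BinaryMask(grid, vol.spacing)


def label_components(mask: BinaryMask, connectivity: int = 26) -> Labeling:
    """Label connected foreground under 6/18/26 adjacency.

    Two true voxels share a label iff they are connected under the chosen
    adjacency; the component table is complete and gap-free.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    label_grid, k = ndi.label(mask.grid, structure=_STRUCTURES[connectivity])
    rows = []
    if k:
        counts = np.bincount(label_grid.ravel(), minlength=k + 1)[1:]
        slices = ndi.find_objects(label_grid)
        for lab in range(1, k + 1):
            sl = slices[lab - 1]
            rows.append(
                {
                    "label": lab,
                    "voxel_count": int(counts[lab - 1]),
                    "volume_um3": float(counts[lab - 1]) * mask.voxel_volume,
                    "z0": sl[0].start, "z1": sl[0].stop,
                    "y0": sl[1].start, "y1": sl[1].stop,
                    "x0": sl[2].start, "x1": sl[2].stop,
                }
            )
    components = pd.DataFrame(
        rows,
        columns=["label", "voxel_count", "volume_um3",
                 "z0", "z1", "y0", "y1", "x0", "x1"],
    )
    return Labeling(label_grid=label_grid, components=components, spacing=mask.spacing)


def filter_small_components(lab: Labeling, min_volume: float) -> BinaryMask:
    """Drop components whose physical volume is strictly below ``min_volume`` μm³."""
    if min_volume < 0:
        raise ValueError("min_volume must be >= 0")
    keep = lab.components.loc[lab.components["volume_um3"] >= min_volume, "label"]
    return lab.mask_of(keep.tolist())


def evaluate_thresholds(
    vol: Volume,
    candidates: Sequence[float],
    polarity: str | None = None,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Objective proxies for choosing a denoising threshold.

    Returns one row per candidate with columns ``threshold,
    foreground_fraction, n_components, largest_volume_um3``.  The report
    does not auto-select a threshold: the choice between background
    suppression and structure preservation is left to the operator.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("candidates must be nonempty")
    if any(b <= a for a, b in zip(cands, cands[1:])):
        raise ValueError("candidates must be strictly increasing")
    rows = []
    nvox = vol.grid.size
    for t in cands:
        mask = threshold_volume(vol, t, polarity)
        lab = label_components(mask, connectivity)
        largest = float(lab.components["volume_um3"].max()) if lab.n_components else 0.0
        rows.append(
            {
                "threshold": t,
                "foreground_fraction": mask.n_foreground / nvox,
                "n_components": lab.n_components,
                "largest_volume_um3": largest,
            }
        )
    return pd.DataFrame(rows)


def select_neuron(
    lab: Labeling,
    soma_seed: Sequence[float],
    snap_radius: float = 5.0,
) -> BinaryMask:
    """Extract the component containing the foreground voxel nearest the seed.

    The seed is a physical ``(x, y, z)`` point; it snaps to the closest
    labelled voxel within ``snap_radius`` μm (manual clicks rarely land on
    the medial axis).  Ties break to the smallest ``(z, y, x)`` index.
    """
    shape = lab.label_grid.shape
    dz, dy, dx = lab.spacing
    seed_idx = physical_to_index(soma_seed, lab.spacing, shape)
    # bounding box of the snap ball, clipped to the grid
    rz = int(np.ceil(snap_radius / dz))
    ry = int(np.ceil(snap_radius / dy))
    rx = int(np.ceil(snap_radius / dx))
    z0, z1 = max(0, seed_idx[0] - rz), min(shape[0], seed_idx[0] + rz + 1)
    y0, y1 = max(0, seed_idx[1] - ry), min(shape[1], seed_idx[1] + ry + 1)
    x0, x1 = max(0, seed_idx[2] - rx), min(shape[2], seed_idx[2] + rx + 1)
    sub = lab.label_grid[z0:z1, y0:y1, x0:x1]
    cand = np.argwhere(sub > 0)
    if cand.size == 0:
        raise SeedError(
            f"no foreground voxel within {snap_radius} μm of seed {tuple(soma_seed)}"
        )
    centers = (cand + [z0, y0, x0]) * np.array([dz, dy, dx])
    target = np.array([soma_seed[2], soma_seed[1], soma_seed[0]], dtype=float)  # (z,y,x)
    d = np.linalg.norm(centers - target, axis=1)
    if d.min() > snap_radius:
        raise SeedError(
            f"nearest foreground voxel is {d.min():.2f} μm from seed, "
            f"beyond snap radius {snap_radius} μm"
        )
    best = cand[int(np.argmin(d))]  # argmin → first in C-order = lexicographic (z,y,x)
    label = int(sub[tuple(best)])
    return lab.mask_of([label])


def apply_edits(mask: BinaryMask, erasers: MarkerSet) -> BinaryMask:
    """Erase voxels whose centres fall inside any eraser sphere or box."""
    grid = mask.grid.copy()
    dz, dy, dx = mask.spacing
    shape = grid.shape
    for m in erasers.of_kind("eraser_sphere", "eraser_box"):
        x, y, z = m.position
        if m.kind == "eraser_sphere":
            r = float(m.param)  # type: ignore[arg-type]
            hz, hy, hx = r, r, r
        else:
            ex, ey, ez = m.param  # type: ignore[misc]
            hz, hy, hx = ez / 2.0, ey / 2.0, ex / 2.0
        z0 = max(0, int(np.floor((z - hz) / dz)))
        z1 = min(shape[0], int(np.ceil((z + hz) / dz)) + 1)
        y0 = max(0, int(np.floor((y - hy) / dy)))
        y1 = min(shape[1], int(np.ceil((y + hy) / dy)) + 1)
        x0 = max(0, int(np.floor((x - hx) / dx)))
        x1 = min(shape[2], int(np.ceil((x + hx) / dx)) + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1) * dz - z,
            np.arange(y0, y1) * dy - y,
            np.arange(x0, x1) * dx - x,
            indexing="ij",
        )
        if m.kind == "eraser_sphere":
            inside = zz * zz + yy * yy + xx * xx <= r * r
        else:
            inside = (np.abs(xx) <= hx) & (np.abs(yy) <= hy) & (np.abs(zz) <= hz)
        grid[z0:z1, y0:y1, x0:x1][inside] = False
    return BinaryMask(grid, mask.spacing)
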