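"""Synthetic Golgi-like phantoms with ground truth.

Real Golgi-contrast volumes are not redistributable, so every pipeline
stage is exercised against phantoms that emulate the relevant failure
modes: bright tubular neurites on a dimmer noisy background, staining gaps
along branches (mid-branch interruptions and fully undetected branch
ends), vessel-like tubes and glia-like blobs at neurite intensity, and
punctate artefacts below the volume-filter floor.

All randomness flows through a single generator seeded once per phantom;
draws happen in a fixed documented order (tree topology → geometry → noise
→ gaps → distractors), so a given spec reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .morphometry import branch_segments
from .segmentation import BinaryMask
from .volio import Marker, MarkerSet, SWCTree, Volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "GenerationError",
    "generate_tree",
    "voxelize_tree",
    "corrupt_volume",
    "make_phantom",
]


class GenerationError(RuntimeError):
    """A phantom tree could not be fitted into the volume."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic neuron volume.

    Defaults emulate the fMOST regime: 8-bit contrast with anisotropic
    (2.5, 1, 1) μm voxels, neurite mean 240 over background mean 120 with
    noise sd 10 (so a threshold of 220 separates the classes), and a gap
    model averaging 1.5 gaps per 100 μm of 5–15 μm each — an expected 15%
    of arc length erased.  ``microct()`` switches to 0.65 μm isotropic
    voxels with a dimmer regime separated by threshold 40.
    """

    shape: tuple[int, int, int] = (40, 144, 144)          # (nz, ny, nx)
    spacing: tuple[float, float, float] = (2.5, 1.0, 1.0)  # μm
    bit_depth: int = 8
    n_bifurcations: int = 5
    segment_length: tuple[float, float] = (25.0, 45.0)     # μm
    branch_angle: tuple[float, float] = (20.0, 60.0)       # degrees
    soma_radius: float = 7.0                               # μm (≈14 μm somata, typical
                                                           # of cortical pyramidal cells;
                                                           # a real soma alone exceeds the
                                                           # 1000 μm³ artefact floor)
    root_radius: float = 2.0                               # μm neurite radius at soma
    taper: float = 0.005                                   # μm radius per μm arc
    min_radius: float = 1.2                                # μm (≳ half the coarsest
                                                           # spacing, so distal tubes
                                                           # stay connected when
                                                           # thresholded under noise)
    neurite_mean: float = 240.0
    background_mean: float = 120.0
    noise_sd: float = 10.0
    gaps_per_100um: float = 1.5
    gap_length: tuple[float, float] = (5.0, 15.0)          # μm
    marker_threshold: float = 220.0                        # operator marking is done
                                                           # on the regime's working
                                                           # threshold view
    n_vessels: int = 2
    n_glia: int = 3
    n_puncta: int = 30
    rng_seed: int = 0
    margin: float = 6.0                                    # μm kept clear of faces

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError("shape dimensions must be >= 1")
        if self.n_bifurcations < 0 or self.n_vessels < 0 or self.n_glia < 0 or self.n_puncta < 0:
            raise ValueError("counts must be >= 0")
        if self.neurite_mean <= self.background_mean:
            raise ValueError("neurite mean must exceed background mean (bright foreground)")
        if self.gap_length[1] >= self.segment_length[0]:
            raise ValueError("gap lengths must be shorter than the shortest segment")

    @staticmethod
    def microct(**overrides) -> "PhantomSpec":
        base = dict(
            shape=(120, 120, 120),
            spacing=(0.65, 0.65, 0.65),
            n_bifurcations=3,
            segment_length=(14.0, 24.0),
            branch_angle=(20.0, 60.0),
            root_radius=1.6,
            neurite_mean=60.0,
            background_mean=20.0,
            noise_sd=5.0,
            gap_length=(4.0, 8.0),
            marker_threshold=40.0,
        )
        base.update(overrides)
        return PhantomSpec(**base)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) μm of the voxel grid."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.spacing
        return ((nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth emitted alongside a corrupted phantom volume.

    ``gaps`` rows: branch_id (index into :func:`branch_segments` order of
    the truth tree), arc_lo/arc_hi (μm along the branch from its proximal
    end), kind (``interior`` or ``tip``).  ``terminal_markers`` holds one
    soma_seed at the tree root plus one branch_terminal per interrupted
    terminus: the broken fragment end just distal of each mid-branch
    interruption, the ground-truth tip of each undetected branch end, and
    any tip left disconnected from the soma component.
    """

    tree: SWCTree
    gaps: pd.DataFrame
    distractor_mask: BinaryMask
    terminal_markers: MarkerSet

    @property
    def total_gap_length(self) -> float:
        if len(self.gaps) == 0:
            return 0.0
        return float((self.gaps["arc_hi"] - self.gaps["arc_lo"]).sum())


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * float(np.dot(axis, v)) * (1 - math.cos(angle))
    )


def generate_tree(spec: PhantomSpec, rng: np.random.Generator | None = None) -> SWCTree:
    """Random rooted binary tree with exactly ``n_bifurcations`` bifurcations.

    Segments are straight, with lengths and child-branch angles drawn from
    the spec ranges; radii taper with arc distance from the soma.  The tree
    lies entirely inside the volume (``margin`` μm from every face);
    generation retries a bounded number of times and then fails.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    # topology first: split a random leaf segment, n_bifurcations times
    n_seg = 1
    children_of: dict[int, list[int]] = {0: []}
    parents_of: dict[int, int] = {0: -1}
    leaves = [0]
    for _ in range(spec.n_bifurcations):
        pick = int(rng.integers(len(leaves)))
        seg = leaves.pop(pick)
        for _ in range(2):
            children_of[seg].append(n_seg)
            children_of[n_seg] = []
            parents_of[n_seg] = seg
            leaves.append(n_seg)
            n_seg += 1

    ex, ey, ez = spec.extent
    lo = np.array([spec.margin] * 3)
    hi = np.array([ex - spec.margin, ey - spec.margin, ez - spec.margin])
    if (hi <= lo).any():
        raise GenerationError("volume too small for the requested margin")
    center = np.array([ex, ey, ez]) / 2.0

    for _attempt in range(60):
        ok = True
        seg_dir: dict[int, np.ndarray] = {}
        seg_start: dict[int, np.ndarray] = {}
        seg_end: dict[int, np.ndarray] = {}
        seg_len: dict[int, float] = {}
        placed_pts: list[np.ndarray] = []  # sampled centreline points of placed segments
        order = _preorder(children_of)
        for seg in order:
            start = center if parents_of[seg] == -1 else seg_end[parents_of[seg]]
            placed = False
            for _try in range(60):
                length = float(rng.uniform(*spec.segment_length))
                if parents_of[seg] == -1:
                    d = _random_unit(rng)
                else:
                    pdir = seg_dir[parents_of[seg]]
                    angle = math.radians(float(rng.uniform(*spec.branch_angle)))
                    axis = np.cross(pdir, _random_unit(rng))
                    if np.linalg.norm(axis) < 1e-9:
                        continue
                    d = _rotate_about(pdir, axis, angle)
                if _try >= 20:
                    # late tries fold the segment back toward the interior
                    pull = center - start
                    pn = np.linalg.norm(pull)
                    if pn > 1e-9:
                        d = d + (0.1 * (_try - 19)) * pull / pn
                        d = d / np.linalg.norm(d)
                end = start + d * length
                if not ((end >= lo).all() and (end <= hi).all()):
                    continue
                # self-avoidance: keep non-adjacent centrelines > 4 μm apart
                # (z offsets discounted: tubes are axially elongated, so pure-z
                # separation must be ~6.7 μm) so rendered tubes never merge and
                # truth topology stays valid
                n_s = max(2, int(math.ceil(length / 2.0)))
                cand = start + np.linspace(0, 1, n_s + 1)[:, None] * (end - start)
                cand_arc = np.linspace(0, length, n_s + 1)
                far_cand = cand[cand_arc >= 5.0]
                if placed_pts and len(far_cand):
                    existing = np.vstack(placed_pts)
                    near_junction = np.linalg.norm(existing - start, axis=1) < 6.0
                    others = existing[~near_junction]
                    if len(others):
                        diff = far_cand[:, None, :] - others[None, :, :]
                        diff = diff * np.array([1.0, 1.0, 0.6])  # (x, y, z)
                        if np.linalg.norm(diff, axis=2).min() < 4.0:
                            continue
                placed = True
                break
            if not placed:
                ok = False
                break
            seg_dir[seg] = d
            seg_start[seg] = start
            seg_end[seg] = end
            seg_len[seg] = length
            n_s = max(2, int(math.ceil(length / 2.0)))
            placed_pts.append(start + np.linspace(0, 1, n_s + 1)[:, None] * (end - start))
        if ok:
            return _segments_to_swc(spec, order, parents_of, seg_start, seg_end, seg_len)
    raise GenerationError(
        f"could not fit a {spec.n_bifurcations}-bifurcation tree inside {spec.shape}"
    )


def _preorder(children_of) -> list[int]:
    order = []
    stack = [0]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(reversed(children_of[u]))
    return order


def _segments_to_swc(spec, order, parents_of, seg_start, seg_end, seg_len) -> SWCTree:
    rows = []
    node_step = 2.0  # μm sampling along straight segments
    root_pos = seg_start[order[0]]
    rows.append([1, 1, root_pos[0], root_pos[1], root_pos[2], spec.soma_radius, -1])
    next_id = 2
    last_node_of_seg: dict[int, int] = {}
    arc_at_seg_start: dict[int, float] = {}
    for seg in order:
        parent_seg = parents_of[seg]
        arc0 = 0.0 if parent_seg == -1 else arc_at_seg_start[parent_seg] + seg_len[parent_seg]
        arc_at_seg_start[seg] = arc0
        pid = 1 if parent_seg == -1 else last_node_of_seg[parent_seg]
        start, end, length = seg_start[seg], seg_end[seg], seg_len[seg]
        n = max(1, int(math.ceil(length / node_step)))
        for k in range(1, n + 1):
            t = k / n
            p = start + (end - start) * t
            arc = arc0 + length * t
            r = max(spec.min_radius, spec.root_radius - spec.taper * arc)
            rows.append([next_id, 3, p[0], p[1], p[2], r, pid])
            pid = next_id
            next_id += 1
        last_node_of_seg[seg] = pid
    df = pd.DataFrame(rows, columns=["id", "stype", "x", "y", "z", "radius", "parent"])
    return SWCTree(df)


# ---------------------------------------------------------------------------
# Voxel rendering
# ---------------------------------------------------------------------------

def _tube_mask(tree: SWCTree, spec: PhantomSpec, radius_pad: float = 0.0) -> np.ndarray:
    """Boolean tube rendering of the tree; centreline voxels always included."""
    grid = np.zeros(spec.shape, dtype=bool)
    pos = tree.positions()
    rad = {int(r.id): float(r.radius) for r in tree.nodes.itertuples()}
    parents = tree.parent_map()
    step = 0.4 * min(spec.spacing)
    z_half = 0.8 * spec.spacing[0]  # axial PSF-like elongation
    for nid, pid in parents.items():
        if pid == -1:
            _stamp_phys_ball(grid, pos[nid], rad[nid] + radius_pad, spec.spacing,
                             z_half=z_half + radius_pad)
            continue
        p, q = pos[pid], pos[nid]
        l = float(np.linalg.norm(q - p))
        n = max(1, int(math.ceil(l / step)))
        for k in range(n + 1):
            t = k / n
            c = p + (q - p) * t
            r = rad[pid] + (rad[nid] - rad[pid]) * t + radius_pad
            _stamp_phys_ball(grid, c, r, spec.spacing, z_half=z_half + radius_pad)
    return grid


def _stamp_phys_ball(grid, center_xyz, r, spacing, value=True, z_half=None) -> None:
    """Stamp a physical ball (optionally axially elongated to ``z_half``).

    The voxel containing the centre is always set, so densely sampled
    centrelines stay 26-connected regardless of radius.
    """
    dz, dy, dx = spacing
    x, y, z = center_xyz
    hz = r if z_half is None else max(r, z_half)
    shape = grid.shape
    z0 = max(0, int(math.floor((z - hz) / dz)))
    z1 = min(shape[0], int(math.ceil((z + hz) / dz)) + 1)
    y0 = max(0, int(math.floor((y - r) / dy)))
    y1 = min(shape[1], int(math.ceil((y + r) / dy)) + 1)
    x0 = max(0, int(math.floor((x - r) / dx)))
    x1 = min(shape[2], int(math.ceil((x + r) / dx)) + 1)
    cz = int(math.floor(z / dz + 0.5))
    cy = int(math.floor(y / dy + 0.5))
    cx = int(math.floor(x / dx + 0.5))
    if 0 <= cz < shape[0] and 0 <= cy < shape[1] and 0 <= cx < shape[2]:
        grid[cz, cy, cx] = value
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.meshgrid(
        (np.arange(z0, z1) * dz - z) / hz,
        (np.arange(y0, y1) * dy - y) / r,
        (np.arange(x0, x1) * dx - x) / r,
        indexing="ij",
    )
    inside = zz * zz + yy * yy + xx * xx <= 1.0
    if value:
        grid[z0:z1, y0:y1, x0:x1] |= inside
    else:
        grid[z0:z1, y0:y1, x0:x1] &= ~inside


def _centerline_voxels(tree: SWCTree, spec: PhantomSpec) -> np.ndarray:
    """Boolean grid of voxels containing densely sampled centreline points."""
    grid = np.zeros(spec.shape, dtype=bool)
    pos = tree.positions()
    parents = tree.parent_map()
    dz, dy, dx = spec.spacing
    step = 0.4 * min(spec.spacing)
    for nid, pid in parents.items():
        if pid == -1:
            continue
        p, q = pos[pid], pos[nid]
        l = float(np.linalg.norm(q - p))
        n = max(1, int(math.ceil(l / step)))
        for k in range(n + 1):
            x, y, z = p + (q - p) * (k / n)
            iz = int(math.floor(z / dz + 0.5))
            iy = int(math.floor(y / dy + 0.5))
            ix = int(math.floor(x / dx + 0.5))
            if 0 <= iz < spec.shape[0] and 0 <= iy < spec.shape[1] and 0 <= ix < spec.shape[2]:
                grid[iz, iy, ix] = True
    return grid


def voxelize_tree(
    tree: SWCTree, spec: PhantomSpec, rng: np.random.Generator | None = None
) -> Volume:
    """Render the tree as bright tubes over textured background noise.

    The tube core (centreline voxels) is clamped to stay at least
    ``neurite_mean - 1.5 * noise_sd``: staining is reliably dense on the
    neurite axis and fluctuates at the surface, so the gap model — not
    noise luck — is the only source of signal discontinuity.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    tube = _tube_mask(tree, spec)
    base = np.where(tube, spec.neurite_mean, spec.background_mean)
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        core = _centerline_voxels(tree, spec)
        base[core] = np.maximum(base[core], spec.neurite_mean - 1.5 * spec.noise_sd)
    lim = 2 ** spec.bit_depth - 1
    grid = np.clip(np.floor(base + 0.5), 0, lim)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return Volume(grid.astype(dtype), spec.spacing, spec.bit_depth)


# ---------------------------------------------------------------------------
# Corruption: gaps + distractors
# ---------------------------------------------------------------------------

def corrupt_volume(
    vol: Volume,
    tree: SWCTree,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, PhantomTruth]:
    """Erase staining gaps along branches and add distractor structures.

    Interior arc intervals produce mid-branch interruptions; intervals
    abutting a branch end produce undetected branch ends.  Distractors —
    vessel-like random-walk tubes and glia-like ellipsoids at neurite
    intensity, plus 1–3 voxel bright puncta — are placed disjoint from the
    (dilated) neurite tube, with bounded retries.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    grid = vol.grid.astype(np.float64).copy()
    lim = 2 ** spec.bit_depth - 1
    pos = tree.positions()
    rad = {int(r.id): float(r.radius) for r in tree.nodes.itertuples()}
    branches = branch_segments(tree)
    blen = []
    for path in branches:
        l = sum(float(np.linalg.norm(pos[a] - pos[b])) for a, b in zip(path, path[1:]))
        blen.append(l)
    total = sum(blen)

    # --- gaps -------------------------------------------------------------
    gap_rows = []
    intervals: dict[int, list[tuple[float, float]]] = {i: [] for i in range(len(branches))}
    n_gaps = int(math.floor(total * spec.gaps_per_100um / 100.0 + 0.5)) if total > 0 else 0
    weights = np.array(blen) / total if total > 0 else None
    placed = 0
    attempts = 0
    while placed < n_gaps and attempts < 50 * max(1, n_gaps):
        attempts += 1
        b = int(rng.choice(len(branches), p=weights))
        glen = float(rng.uniform(*spec.gap_length))
        l = blen[b]
        is_tip_branch = _is_tip_branch(tree, branches[b])
        # keep the soma visible: no erasure across the soma ball
        min_start = spec.soma_radius + 4.0 if branches[b][0] == tree.root_id else 3.0
        tip_gap = is_tip_branch and (rng.random() < 0.35)
        if tip_gap:
            if l < glen + min_start:
                continue
            lo_hi = (l - glen, l)
        else:
            if l < glen + min_start + 3.0:
                continue
            start = float(rng.uniform(min_start, l - glen - 3.0))
            lo_hi = (start, start + glen)
        if any(lo_hi[0] < h + 2.0 and lo_hi[1] > lo - 2.0 for lo, h in intervals[b]):
            continue
        intervals[b].append(lo_hi)
        gap_rows.append(
            {"branch_id": b, "arc_lo": lo_hi[0], "arc_hi": lo_hi[1],
             "kind": "tip" if tip_gap else "interior"}
        )
        placed += 1

    for row in gap_rows:
        eff_lo, eff_hi = _erase_interval(
            grid, tree, branches[int(row["branch_id"])],
            row["arc_lo"], row["arc_hi"], row["kind"], spec, rng, pos, rad,
        )
        row["arc_lo"], row["arc_hi"] = eff_lo, eff_hi

    # --- distractors -------------------------------------------------------
    # distractors keep 4 μm clear of the neurite so repair corridors along
    # erased arcs cannot brush against them
    forbidden = _tube_mask(tree, spec, radius_pad=4.0)
    distractor = np.zeros(spec.shape, dtype=bool)
    ex, ey, ez = spec.extent
    lo_b = np.array([spec.margin] * 3)
    hi_b = np.array([ex - spec.margin, ey - spec.margin, ez - spec.margin])

    for _ in range(spec.n_vessels):
        for _try in range(10):
            m = _vessel_mask(spec, rng, lo_b, hi_b)
            if m is not None and not (m & forbidden).any():
                distractor |= m
                break
    for _ in range(spec.n_glia):
        for _try in range(10):
            m = _glia_mask(spec, rng, lo_b, hi_b)
            if not (m & forbidden).any():
                distractor |= m
                break
    # vessel/glia pixels at neurite-like intensity (they must survive thresholding)
    if distractor.any():
        vals = spec.neurite_mean + rng.normal(0.0, spec.noise_sd, size=int(distractor.sum()))
        grid[distractor] = vals

    punct = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.n_puncta):
        for _try in range(10):
            iz = int(rng.integers(spec.shape[0]))
            iy = int(rng.integers(spec.shape[1]))
            ix = int(rng.integers(spec.shape[2]))
            size = int(rng.integers(1, 4))
            voxels = [(iz, iy, ix)]
            for _k in range(size - 1):
                off = rng.integers(-1, 2, size=3)
                v = (iz + int(off[0]), iy + int(off[1]), ix + int(off[2]))
                if all(0 <= v[i] < spec.shape[i] for i in range(3)):
                    voxels.append(v)
            if any(forbidden[v] or distractor[v] for v in voxels):
                continue
            for v in voxels:
                punct[v] = True
            break
    if punct.any():
        grid[punct] = np.clip(
            spec.neurite_mean + 10 + rng.normal(0.0, spec.noise_sd, size=int(punct.sum())),
            0, lim,
        )
    distractor |= punct

    grid = np.clip(np.floor(grid + 0.5), 0, lim)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    out = Volume(grid.astype(dtype), spec.spacing, spec.bit_depth)

    gaps = pd.DataFrame(gap_rows, columns=["branch_id", "arc_lo", "arc_hi", "kind"])
    markers = _truth_markers(tree, branches, gaps, out.grid, spec)
    truth = PhantomTruth(
        tree=tree,
        gaps=gaps,
        distractor_mask=BinaryMask(distractor, spec.spacing),
        terminal_markers=markers,
    )
    return out, truth


def _is_tip_branch(tree: SWCTree, path: list[int]) -> bool:
    children = tree.children_map()
    return len(children[path[-1]]) == 0


def _branch_point_at_arc(pos, path, arc: float) -> np.ndarray:
    s = 0.0
    for a, b in zip(path, path[1:]):
        l = float(np.linalg.norm(pos[b] - pos[a]))
        if s + l >= arc or (a, b) == (path[-2], path[-1]):
            t = 0.0 if l == 0 else min(1.0, max(0.0, (arc - s) / l))
            return pos[a] + (pos[b] - pos[a]) * t
        s += l
    return pos[path[-1]]


def _erase_interval(grid, tree, path, arc_lo, arc_hi, kind, spec, rng, pos, rad):
    """Erase neurite signal over an arc interval; returns the effective arc.

    Stamp centres are pulled inside the nominal interval by the cut ball's
    shadow along the branch direction so the erased arc matches the booked
    gap length; a tip gap erases through the branch end.  Returns the
    ``(lo, hi)`` arc actually erased.
    """
    lim = 2 ** spec.bit_depth - 1
    step = 0.4 * min(spec.spacing)
    r_cut = max(rad[path[-1]], rad[path[0]]) + 0.8  # wider than the tube
    z_cut = 0.8 * spec.spacing[0] + 0.8
    u = pos[path[-1]] - pos[path[0]]
    un = np.linalg.norm(u)
    u = u / un if un > 0 else np.array([1.0, 0.0, 0.0])
    # axial shadow of the (possibly z-elongated) cut ball along the branch
    r_dir = math.sqrt(r_cut**2 * (u[0] ** 2 + u[1] ** 2) + max(r_cut, z_cut) ** 2 * u[2] ** 2)
    lo_c = arc_lo + r_dir
    hi_c = arc_hi if kind == "tip" else arc_hi - r_dir
    if hi_c < lo_c:  # interval shorter than one cut ball: single centred cut
        lo_c = hi_c = 0.5 * (arc_lo + arc_hi)
    erase = np.zeros(spec.shape, dtype=bool)
    n = max(1, int(math.ceil((hi_c - lo_c) / step)))
    for k in range(n + 1):
        arc = lo_c + (hi_c - lo_c) * k / n
        c = _branch_point_at_arc(pos, path, arc)
        _stamp_phys_ball(erase, c, r_cut, spec.spacing, z_half=z_cut)
    nvox = int(erase.sum())
    if nvox:
        grid[erase] = np.clip(
            spec.background_mean + rng.normal(0.0, spec.noise_sd, size=nvox), 0, lim
        )
    branch_len = sum(
        float(np.linalg.norm(pos[a] - pos[b])) for a, b in zip(path, path[1:])
    )
    eff_lo = max(0.0, lo_c - r_dir)
    eff_hi = branch_len if kind == "tip" else min(branch_len, hi_c + r_dir)
    return eff_lo, eff_hi


def _vessel_mask(spec, rng, lo_b, hi_b):
    grid = np.zeros(spec.shape, dtype=bool)
    p = rng.uniform(lo_b, hi_b)
    d = _random_unit(rng)
    length = float(rng.uniform(80.0, 140.0))
    radius = 2.5
    step = 2.0
    travelled = 0.0
    pts = [p.copy()]
    while travelled < length:
        d = d + rng.normal(0.0, 0.25, size=3)
        d = d / np.linalg.norm(d)
        p = p + d * step
        if (p < lo_b).any() or (p > hi_b).any():
            break
        pts.append(p.copy())
        travelled += step
    if travelled < 30.0:  # too short to look like a vessel
        return None
    for q in pts:
        _stamp_phys_ball(grid, q, radius, spec.spacing)
    return grid


def _glia_mask(spec, rng, lo_b, hi_b):
    grid = np.zeros(spec.shape, dtype=bool)
    c = rng.uniform(lo_b, hi_b)  # (x, y, z)
    ax = rng.uniform(3.0, 6.0, size=3)  # semi-axes μm
    dz, dy, dx = spec.spacing
    x, y, z = c
    shape = spec.shape
    z0 = max(0, int(math.floor((z - ax[2]) / dz)))
    z1 = min(shape[0], int(math.ceil((z + ax[2]) / dz)) + 1)
    y0 = max(0, int(math.floor((y - ax[1]) / dy)))
    y1 = min(shape[1], int(math.ceil((y + ax[1]) / dy)) + 1)
    x0 = max(0, int(math.floor((x - ax[0]) / dx)))
    x1 = min(shape[2], int(math.ceil((x + ax[0]) / dx)) + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1) * dz - z,
        np.arange(y0, y1) * dy - y,
        np.arange(x0, x1) * dx - x,
        indexing="ij",
    )
    inside = (xx / ax[0]) ** 2 + (yy / ax[1]) ** 2 + (zz / ax[2]) ** 2 <= 1.0
    grid[z0:z1, y0:y1, x0:x1] = inside
    return grid


def _truth_markers(
    tree: SWCTree, branches, gaps: pd.DataFrame, grid: np.ndarray, spec: PhantomSpec
) -> MarkerSet:
    """Emulate the operator's marking of interrupted branch termini.

    A mid-branch interruption gets a marker at the detached fragment's
    broken end (just distal of the erased arc); an undetected branch end
    gets a marker at the ground-truth tip.  As a safety net, any truth tip
    with no soma-connected foreground (at the regime's working threshold)
    within 2 μm is also marked.  Markers are ordered soma-outward so
    proximal fragments reconnect before the traces that build on them.
    """
    from scipy import ndimage as ndi

    root_pos = tree.soma_position()
    pos = tree.positions()
    children = tree.children_map()
    terminal_positions: list[np.ndarray] = []

    def add(p: np.ndarray) -> None:
        for q in terminal_positions:
            if np.linalg.norm(p - q) < 2.0:
                return
        terminal_positions.append(np.asarray(p, dtype=float))

    for row in gaps.itertuples():
        path = branches[int(row.branch_id)]
        if row.kind == "tip":
            add(pos[path[-1]])
        else:
            add(_branch_point_at_arc(pos, path, float(row.arc_hi) + 1.0))

    # safety net: tips still cut off from the soma component (multiple gaps,
    # residual noise) are marked as undetected branch ends
    fg = grid >= spec.marker_threshold
    labels, _ = ndi.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    dz, dy, dx = spec.spacing
    root_idx = (
        int(math.floor(root_pos[2] / dz + 0.5)),
        int(math.floor(root_pos[1] / dy + 0.5)),
        int(math.floor(root_pos[0] / dx + 0.5)),
    )
    soma_lab = labels[root_idx]
    for tid in sorted(i for i in children if not children[i]):
        x, y, z = pos[tid]
        iz = int(math.floor(z / dz + 0.5))
        iy = int(math.floor(y / dy + 0.5))
        ix = int(math.floor(x / dx + 0.5))
        rz, ry, rx = (int(np.ceil(2.0 / s)) for s in spec.spacing)
        sub = labels[
            max(0, iz - rz): iz + rz + 1,
            max(0, iy - ry): iy + ry + 1,
            max(0, ix - rx): ix + rx + 1,
        ]
        if soma_lab == 0 or not (sub == soma_lab).any():
            add(pos[tid])

    soma = np.asarray(root_pos, dtype=float)
    terminal_positions.sort(key=lambda p: float(np.linalg.norm(p - soma)))
    markers = [Marker(kind="soma_seed", position=tuple(root_pos))]
    markers += [
        Marker(kind="branch_terminal", position=tuple(p)) for p in terminal_positions
    ]
    return MarkerSet(tuple(markers))


def _descendant_tips(children, node) -> list[int]:
    tips = []
    stack = [node]
    while stack:
        u = stack.pop()
        if not children[u]:
            tips.append(u)
        else:
            stack.extend(children[u])
    return tips


def make_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Generate → voxelize → corrupt, fully deterministic per spec seed."""
    rng = np.random.default_rng(spec.rng_seed)
    tree = generate_tree(spec, rng)
    vol = voxelize_tree(tree, spec, rng)
    return corrupt_volume(vol, tree, spec, rng)
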