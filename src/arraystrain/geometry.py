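"""Parametric Utah-array and tissue geometry.

A bed-of-needles array is a grid of tapered silicon shanks on a common base
substrate, implanted tip-down into cortex.  This module builds the implicit
solid model (base slab + tapered shanks + ellipsoidal tip caps + surrounding
tissue block), and derives the electrode layout structures used everywhere
downstream: tip positions, concentric ring labels with a separate corner
group, Moore-neighborhood maps, and connectivity-mask presets.

Coordinate convention: the base underside lies in the plane z = 0 with the
origin at the array-base center; shanks point along -z; the driven
micromotion displacement lies in the XY plane ("Y direction" = in-plane
lateral shear).  All lengths are in micrometres; stresses in pascal
(a consistent Pa-um-pN unit system, chosen for solver conditioning).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ArraySpec",
    "TissueSpec",
    "SolidModel",
    "GeometryError",
    "build_geometry",
    "ring_labels",
    "corner_mask",
    "neighbor_map",
    "connectivity_preset",
    "ElectrodeLayout",
    "build_layout",
]


class GeometryError(ValueError):
    """Raised when array/tissue specifications are geometrically invalid."""


@dataclass(frozen=True)
class ArraySpec:
    """Dimensions of a planar multi-shank array.

    Defaults follow the standard 10x10 grid: 400 um pitch, 4x4x0.2 mm base,
    shanks tapering from a 150 um square at the base to a 10 um diameter
    circle at 1.49 mm, capped by a revolved quarter-ellipse tip (major
    radius 10 um along the shank axis, minor radius 5 um), for a total
    shank length of 1.5 mm.
    """

    rows: int = 10
    cols: int = 10
    pitch: float = 400.0
    base_lx: float = 4000.0
    base_ly: float = 4000.0
    base_lz: float = 200.0
    shank_base_side: float = 150.0
    shank_taper_length: float = 1490.0
    tip_major_radius: float = 10.0
    tip_minor_radius: float = 5.0
    # superellipse exponent at the shank base (square-to-circle loft);
    # 2.0 at the taper end by construction
    base_superellipse_exponent: float = 12.0

    @property
    def total_shank_length(self) -> float:
        return self.shank_taper_length + self.tip_major_radius

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise GeometryError("grid must have at least one shank")
        if self.pitch <= 0 or self.shank_base_side <= 0:
            raise GeometryError("pitch and shank_base_side must be positive")
        if min(self.rows, self.cols) > 1 and self.pitch < self.shank_base_side:
            raise GeometryError(
                f"shanks overlap: pitch {self.pitch} um < shank base side "
                f"{self.shank_base_side} um"
            )
        span_x = (self.cols - 1) * self.pitch + self.shank_base_side
        span_y = (self.rows - 1) * self.pitch + self.shank_base_side
        if span_x > self.base_lx or span_y > self.base_ly:
            raise GeometryError(
                f"grid span ({span_x} x {span_y} um) exceeds base "
                f"({self.base_lx} x {self.base_ly} um)"
            )


# the 10x6 and 8x8 grids used alongside the 10x10
ARRAY_10X10 = ArraySpec()
ARRAY_10X6 = ArraySpec(rows=10, cols=6, base_lx=2400.0, base_ly=4000.0)
ARRAY_8X8 = ArraySpec(rows=8, cols=8, base_lx=3200.0, base_ly=3200.0)


@dataclass(frozen=True)
class TissueSpec:
    """Extent of the cortical tissue block around the array.

    The tissue is a rectangular prism extending ``margin_below_tips`` beyond
    the electrode tips and ``margin_lateral`` outward from the base on all
    sides.
    """

    margin_below_tips: float = 1000.0
    margin_lateral: float = 2000.0

    def validate(self) -> None:
        if self.margin_below_tips <= 0 or self.margin_lateral <= 0:
            raise GeometryError("tissue margins must be strictly positive")


@dataclass
class SolidModel:
    """Implicit solid model of array + tissue with a shared interface.

    The array solid is the union of the base slab (z in [0, base_lz]) and
    the shank/tip solids (z in [-L, 0]); tissue fills the rest of the block
    x,y within the lateral extents, z in [-depth, 0].  ``inside_array``
    evaluates the implicit array solid; ``array_surface_distance`` is an
    approximate signed distance (negative inside) used for mesh snapping.
    """

    array: ArraySpec
    tissue: TissueSpec
    tips: np.ndarray  # (n, 3) tip coordinates
    shank_xy: np.ndarray  # (n, 2) shank axis positions

    @property
    def tissue_extent_x(self) -> float:
        return self.array.base_lx + 2.0 * self.tissue.margin_lateral

    @property
    def tissue_extent_y(self) -> float:
        return self.array.base_ly + 2.0 * self.tissue.margin_lateral

    @property
    def tissue_depth(self) -> float:
        """Depth of tissue below the base underside (z = 0)."""
        return self.array.total_shank_length + self.tissue.margin_below_tips

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners of the full meshing domain (tissue + base)."""
        hx, hy = self.tissue_extent_x / 2.0, self.tissue_extent_y / 2.0
        lo = np.array([-hx, -hy, -self.tissue_depth])
        hi = np.array([hx, hy, self.array.base_lz])
        return lo, hi

    def shank_half_width(self, z: np.ndarray) -> np.ndarray:
        """Half-width of the shank cross-section at depth z (z <= 0)."""
        a = self.array
        z = np.asarray(z, dtype=float)
        t = np.clip(-z / a.shank_taper_length, 0.0, 1.0)
        w_taper = (1.0 - t) * (a.shank_base_side / 2.0) + t * a.tip_minor_radius
        # ellipsoidal tip cap below the taper end
        zeta = np.clip(-z - a.shank_taper_length, 0.0, a.tip_major_radius)
        cap = a.tip_minor_radius * np.sqrt(
            np.maximum(0.0, 1.0 - (zeta / a.tip_major_radius) ** 2)
        )
        return np.where(-z > a.shank_taper_length, cap, w_taper)

    def _superellipse_exponent(self, z: np.ndarray) -> np.ndarray:
        a = self.array
        t = np.clip(-np.asarray(z, dtype=float) / a.shank_taper_length, 0.0, 1.0)
        return 2.0 + (a.base_superellipse_exponent - 2.0) * (1.0 - t)

    def _shank_boundary_radius(
        self, dx: np.ndarray, dy: np.ndarray, z: np.ndarray
    ) -> np.ndarray:
        """Boundary radius of the cross-section along the ray (dx, dy)."""
        w = self.shank_half_width(z)
        p = self._superellipse_exponent(z)
        below_taper = -np.asarray(z, float) > self.array.shank_taper_length
        r = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(r > 0, np.abs(dx) / np.maximum(r, 1e-300), 1.0)
            s = np.where(r > 0, np.abs(dy) / np.maximum(r, 1e-300), 0.0)
            denom = (c**p + s**p) ** (1.0 / p)
        rb = w / np.maximum(denom, 1e-300)
        return np.where(below_taper, w, rb)  # tip cap is circular

    def shank_lateral_distance(self, pts: np.ndarray) -> np.ndarray:
        """Approx. signed lateral distance to the nearest shank surface.

        Negative inside a shank.  Points above z = 0 or below the tips get
        +inf.  Used for size-field evaluation and vertex snapping.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        z = pts[:, 2]
        best = np.full(len(pts), np.inf)
        in_band = (z <= 0.0) & (z >= -self.array.total_shank_length)
        if not np.any(in_band):
            return best
        for sx, sy in self.shank_xy:
            dx = pts[:, 0] - sx
            dy = pts[:, 1] - sy
            rb = self._shank_boundary_radius(dx, dy, z)
            d = np.hypot(dx, dy) - rb
            d = np.where(in_band, d, np.inf)
            best = np.minimum(best, d)
        return best

    def inside_array(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask: points strictly inside the array solid."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        a = self.array
        in_base = (
            (z >= 0.0)
            & (z <= a.base_lz)
            & (np.abs(x) <= a.base_lx / 2.0)
            & (np.abs(y) <= a.base_ly / 2.0)
        )
        in_shank = self.shank_lateral_distance(pts) < 0.0
        return in_base | in_shank

    def distance_to_tips(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = np.linalg.norm(pts[:, None, :] - self.tips[None, :, :], axis=2)
        return d.min(axis=1)


def _grid_positions(spec: ArraySpec) -> tuple[np.ndarray, np.ndarray]:
    """Shank axis XY positions; rows run along +y, cols along +x, centered."""
    cols = np.arange(spec.cols) - (spec.cols - 1) / 2.0
    rows = np.arange(spec.rows) - (spec.rows - 1) / 2.0
    xy = np.array(
        [[c * spec.pitch, r * spec.pitch] for r in rows for c in cols]
    )
    rc = np.array(
        [[ri, ci] for ri in range(spec.rows) for ci in range(spec.cols)],
        dtype=int,
    )
    return xy, rc


def build_geometry(array: ArraySpec, tissue: TissueSpec) -> SolidModel:
    """Build the array + tissue solid model.

    Raises :class:`GeometryError` when shanks would overlap or the grid does
    not fit on the base.
    """
    array.validate()
    tissue.validate()
    xy, _ = _grid_positions(array)
    tips = np.column_stack([xy, np.full(len(xy), -array.total_shank_length)])
    return SolidModel(array=array, tissue=tissue, tips=tips, shank_xy=xy)


# ---------------------------------------------------------------------------
# electrode layout: rings, corners, neighbors, connectivity masks
# ---------------------------------------------------------------------------

def ring_labels(rows: int, cols: int) -> np.ndarray:
    """Concentric ring label per electrode, flattened row-major.

    Label 1 is the innermost ring and the outermost ring carries the largest
    label (= number of rings).  Corner electrodes keep the outermost label
    here; use :func:`corner_mask` to split them into their own group.
    """
    if rows < 1 or cols < 1:
        raise GeometryError("rows and cols must be >= 1")
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    depth = np.minimum.reduce(
        [np.broadcast_to(r, (rows, cols)),
         np.broadcast_to(rows - 1 - r, (rows, cols)),
         np.broadcast_to(c, (rows, cols)),
         np.broadcast_to(cols - 1 - c, (rows, cols))]
    )
    n_rings = depth.max() + 1
    return (n_rings - depth).ravel()


def corner_mask(rows: int, cols: int) -> np.ndarray:
    """Boolean mask for the four corner electrodes (row-major flattened)."""
    m = np.zeros((rows, cols), dtype=bool)
    m[0, 0] = m[0, -1] = m[-1, 0] = m[-1, -1] = True
    return m.ravel()


def neighbor_map(
    rows: int, cols: int, connected_mask: np.ndarray | None = None
) -> list[list[int]]:
    """Moore (8-connected) neighbor lists, restricted to connected electrodes.

    Electrodes are indexed row-major.  A fully connected grid yields 3
    neighbors at corners, 5 on edges, 8 in the interior.
    """
    if rows < 1 or cols < 1:
        raise GeometryError("rows and cols must be >= 1")
    if connected_mask is None:
        connected_mask = np.ones(rows * cols, dtype=bool)
    connected_mask = np.asarray(connected_mask, dtype=bool)
    out: list[list[int]] = []
    for r in range(rows):
        for c in range(cols):
            nbrs = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        j = rr * cols + cc
                        if connected_mask[j]:
                            nbrs.append(j)
            out.append(nbrs)
    return out


def connectivity_preset(name: str, rows: int, cols: int) -> np.ndarray:
    """Connectivity masks replicating the recording hardware limitations.

    - ``"all"``: every electrode connected.
    - ``"corners_unconnected"``: the 4 corner electrodes unconnected
      (the P3-style motor-array wiring).
    - ``"corner_triples_unconnected"``: three electrodes in each corner
      unconnected -- interpreted as the corner plus its two grid-adjacent
      electrodes, an L-shaped triple (the P2-style wiring; configurable
      interpretation, 12 unconnected in total).
    - ``"checkerboard"``: connected electrodes form a checkerboard keeping
      the (row+col)-even half (the 10x6 somatosensory wiring; 30 of 60).
    """
    mask = np.ones((rows, cols), dtype=bool)
    if name == "all":
        pass
    elif name == "corners_unconnected":
        mask[0, 0] = mask[0, -1] = mask[-1, 0] = mask[-1, -1] = False
    elif name == "corner_triples_unconnected":
        for r0, c0 in [(0, 0), (0, cols - 1), (rows - 1, 0), (rows - 1, cols - 1)]:
            mask[r0, c0] = False
            mask[r0, c0 + (1 if c0 == 0 else -1)] = False
            mask[r0 + (1 if r0 == 0 else -1), c0] = False
    elif name == "checkerboard":
        r = np.arange(rows)[:, None]
        c = np.arange(cols)[None, :]
        mask = (r + c) % 2 == 0
    else:
        raise ValueError(f"unknown connectivity preset: {name!r}")
    return mask.ravel()


@dataclass
class ElectrodeLayout:
    """Per-electrode layout table for one array."""

    rows: int
    cols: int
    table: pd.DataFrame  # electrode_id,row,col,tip_x,tip_y,tip_z,ring_label,is_corner,connected
    neighbors: list[list[int]]

    @property
    def n_electrodes(self) -> int:
        return len(self.table)

    def group3(self) -> pd.Series:
        """Three-way grouping: corner / edge (outermost ring minus corners)
        / interior (everything else)."""
        ring = self.table["ring_label"].to_numpy()
        corner = self.table["is_corner"].to_numpy()
        outer = ring == ring.max()
        g = np.where(corner, "corner", np.where(outer, "edge", "interior"))
        return pd.Series(g, index=self.table.index, name="group3")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_layout(
    model: SolidModel, connectivity: str | np.ndarray = "all"
) -> ElectrodeLayout:
    """Derive the electrode layout table from a solid model."""
    a = model.array
    _, rc = _grid_positions(a)
    ring = ring_labels(a.rows, a.cols)
    corner = corner_mask(a.rows, a.cols)
    if isinstance(connectivity, str):
        connected = connectivity_preset(connectivity, a.rows, a.cols)
    else:
        connected = np.asarray(connectivity, dtype=bool).ravel()
        if connected.size != a.n_electrodes:
            raise GeometryError("connectivity mask size mismatch")
    center = np.array([0.0, 0.0])
    dist_center = np.linalg.norm(model.tips[:, :2] - center, axis=1)
    table = pd.DataFrame(
        {
            "electrode_id": np.arange(a.n_electrodes),
            "row": rc[:, 0],
            "col": rc[:, 1],
            "tip_x": model.tips[:, 0],
            "tip_y": model.tips[:, 1],
            "tip_z": model.tips[:, 2],
            "ring_label": ring,
            "is_corner": corner,
            "connected": connected,
            "dist_center": dist_center,
        }
    )
    nbrs = neighbor_map(a.rows, a.cols, connected)
    return ElectrodeLayout(rows=a.rows, cols=a.cols, table=table, neighbors=nbrs)
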