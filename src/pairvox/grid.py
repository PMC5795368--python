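"""Anchor-region geometry for pairwise supervoxel segmentation.

A frame of ``W x H`` pixels is tiled into ``nx x ny`` rectangular *anchor
regions* of nominal size ``vx x vy`` (the desired superpixel size).  Each
anchor region is the home cell of one supervoxel, so the supervoxel count
is ``K = nx * ny`` with ``nx = floor(W / vx)`` and ``ny = floor(H / vy)``.
Every voxel carries the label ``hi`` of the anchor region that contains
it.  A voxel may only be generated by the supervoxels whose anchor cells
lie within ``eta_x`` columns and ``eta_y`` rows of its own cell — its
*candidate set* ``Ki``.  Dually, the *overlap region* ``Ik`` of supervoxel
``k`` is the set of voxels that list ``k`` as a candidate; it is the block
of anchor cells centred on cell ``k``, clipped at the frame border.

Conventions (fixed throughout the package):

* coordinates are 0-based with ``x`` the column and ``y`` the row;
* the flat voxel index is row-major, ``i = y * W + x``;
* anchor cells are numbered row-major, ``k = cy * nx + cx``;
* when ``vx`` does not divide ``W`` the rightmost anchor column absorbs
  the leftover pixel columns (likewise the bottom row for ``H mod vy``),
  so every voxel has an anchor label and ``K`` stays ``nx * ny``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "AnchorMap",
    "InvalidGeometryError",
    "InvalidParameterError",
    "build_grid",
    "anchor_label",
    "candidate_set",
    "overlap_region",
]


class InvalidGeometryError(ValueError):
    """Frame / superpixel geometry is inconsistent (e.g. vx > W)."""


class InvalidParameterError(ValueError):
    """A tuning parameter is outside its admissible range."""


@dataclass(frozen=True)
class GridSpec:
    """Frame geometry plus the anchor-grid constants derived from it.

    Attributes
    ----------
    W, H : int
        Frame width and height in pixels.
    vx, vy : int
        Desired superpixel width and height in pixels.
    nx, ny : int
        Number of anchor cells along width and height.
    K : int
        Total supervoxel count, ``nx * ny``.
    eta_x, eta_y : int
        Candidate-window half-extent in cells along width and height.
    """

    W: int
    H: int
    vx: int
    vy: int
    nx: int
    ny: int
    K: int
    eta_x: int
    eta_y: int

    # -- cell helpers -------------------------------------------------
    def cell_x(self, x: int | np.ndarray) -> int | np.ndarray:
        """Anchor-cell column of pixel column ``x`` (last cell absorbs remainder)."""
        return np.minimum(np.asarray(x) // self.vx, self.nx - 1)

    def cell_y(self, y: int | np.ndarray) -> int | np.ndarray:
        return np.minimum(np.asarray(y) // self.vy, self.ny - 1)

    def cell_x_bounds(self, cx: int) -> tuple[int, int]:
        """Half-open pixel-column range ``[x0, x1)`` of anchor column ``cx``."""
        x0 = cx * self.vx
        x1 = (cx + 1) * self.vx if cx < self.nx - 1 else self.W
        return x0, x1

    def cell_y_bounds(self, cy: int) -> tuple[int, int]:
        y0 = cy * self.vy
        y1 = (cy + 1) * self.vy if cy < self.ny - 1 else self.H
        return y0, y1


def build_grid(
    W: int, H: int, vx: int, vy: int, eta_x: int = 2, eta_y: int = 2
) -> GridSpec:
    """Validate the geometry and derive the anchor-grid constants.

    Raises
    ------
    InvalidGeometryError
        If any dimension is non-positive or a superpixel would not fit
        in the frame.
    InvalidParameterError
        If both candidate-window half-extents are zero (each voxel would
        have a single candidate and no competition between supervoxels),
        or either is negative.
    """
    if W <= 0 or H <= 0 or vx <= 0 or vy <= 0:
        raise InvalidGeometryError(
            f"dimensions must be positive, got W={W}, H={H}, vx={vx}, vy={vy}"
        )
    if vx > W or vy > H:
        raise InvalidGeometryError(
            f"superpixel size ({vx}x{vy}) exceeds frame size ({W}x{H})"
        )
    if eta_x < 0 or eta_y < 0:
        raise InvalidParameterError(f"eta_x, eta_y must be >= 0, got {eta_x}, {eta_y}")
    if eta_x == 0 and eta_y == 0:
        raise InvalidParameterError("at least one of eta_x, eta_y must be >= 1")
    nx = W // vx
    ny = H // vy
    return GridSpec(
        W=W, H=H, vx=vx, vy=vy, nx=nx, ny=ny, K=nx * ny, eta_x=eta_x, eta_y=eta_y
    )


def anchor_label(x: int, y: int, grid: GridSpec) -> int:
    """Supervoxel index of the anchor region containing pixel ``(x, y)``."""
    if not (0 <= x < grid.W and 0 <= y < grid.H):
        raise IndexError(f"pixel ({x}, {y}) outside {grid.W}x{grid.H} frame")
    return int(grid.cell_y(y)) * grid.nx + int(grid.cell_x(x))


def candidate_set(hi: int, grid: GridSpec) -> np.ndarray:
    """Candidate supervoxels of any voxel whose anchor label is ``hi``.

    The window of anchor cells within ``eta_x`` columns and ``eta_y``
    rows of cell ``hi``, clipped at the grid border, in ascending index
    order.  ``hi`` itself is always a member.
    """
    if not (0 <= hi < grid.K):
        raise IndexError(f"anchor label {hi} outside [0, {grid.K})")
    hix, hiy = hi % grid.nx, hi // grid.nx
    kx = np.arange(max(hix - grid.eta_x, 0), min(hix + grid.eta_x, grid.nx - 1) + 1)
    ky = np.arange(max(hiy - grid.eta_y, 0), min(hiy + grid.eta_y, grid.ny - 1) + 1)
    return (ky[:, None] * grid.nx + kx[None, :]).ravel()


def overlap_region(k: int, grid: GridSpec) -> np.ndarray:
    """Flat voxel indices of supervoxel ``k``'s overlap region ``Ik``.

    ``Ik = {i : k in Ki}``: the pixels of the anchor cells within the
    candidate window of cell ``k``, i.e. an axis-aligned rectangle of up
    to ``(2*eta_x+1)*vx`` by ``(2*eta_y+1)*vy`` pixels clipped at the
    frame border.  Returned sorted (row-major order).
    """
    if not (0 <= k < grid.K):
        raise IndexError(f"supervoxel index {k} outside [0, {grid.K})")
    kx, ky = k % grid.nx, k // grid.nx
    x0, _ = grid.cell_x_bounds(max(kx - grid.eta_x, 0))
    _, x1 = grid.cell_x_bounds(min(kx + grid.eta_x, grid.nx - 1))
    y0, _ = grid.cell_y_bounds(max(ky - grid.eta_y, 0))
    _, y1 = grid.cell_y_bounds(min(ky + grid.eta_y, grid.ny - 1))
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    return (ys[:, None] * grid.W + xs[None, :]).ravel()


class AnchorMap:
    """Materialized anchor labels, candidate sets and overlap regions.

    Candidate sets depend only on the anchor cell, so they are stored
    once per cell as a dense ``(K, n_slots)`` table aligned on the window
    offsets (``-1`` marks an offset clipped at the border).  The slot
    order is ascending in the candidate index, which makes smallest-index
    tie-breaking a plain ``argmax`` downstream.

    Attributes
    ----------
    grid : GridSpec
    labels : (H, W) int32 ndarray
        Per-voxel anchor label ``hi``.
    offsets : (n_slots, 2) int ndarray
        Window offsets ``(dy, dx)``, row-major over the window.
    cell_candidates : (K, n_slots) int32 ndarray
        Candidate supervoxel index per cell and slot, ``-1`` if clipped.
    voxel_candidates : (N, n_slots) int32 ndarray
        ``cell_candidates`` broadcast to voxels (``N = W * H``).
    n_candidates : (K,) int ndarray
        ``|Ki|`` per anchor cell.
    """

    def __init__(self, grid: GridSpec):
        self.grid = grid
        nx, ny = grid.nx, grid.ny

        ys, xs = np.mgrid[0 : grid.H, 0 : grid.W]
        self.labels = (grid.cell_y(ys) * nx + grid.cell_x(xs)).astype(np.int32)

        dy, dx = np.mgrid[-grid.eta_y : grid.eta_y + 1, -grid.eta_x : grid.eta_x + 1]
        self.offsets = np.stack([dy.ravel(), dx.ravel()], axis=1)

        cx = np.arange(grid.K) % nx
        cy = np.arange(grid.K) // nx
        tx = cx[:, None] + self.offsets[None, :, 1]
        ty = cy[:, None] + self.offsets[None, :, 0]
        valid = (tx >= 0) & (tx < nx) & (ty >= 0) & (ty < ny)
        self.cell_candidates = np.where(valid, ty * nx + tx, -1).astype(np.int32)
        self.n_candidates = valid.sum(axis=1)

        self.voxel_candidates = self.cell_candidates[self.labels.ravel()]

        # flat voxel indices of each anchor cell, reused by the M-step
        self._cell_voxels: list[np.ndarray] = []
        for k in range(grid.K):
            x0, x1 = grid.cell_x_bounds(cx[k])
            y0, y1 = grid.cell_y_bounds(cy[k])
            idx = (np.arange(y0, y1)[:, None] * grid.W + np.arange(x0, x1)).ravel()
            self._cell_voxels.append(idx)

    @property
    def n_slots(self) -> int:
        return self.offsets.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.grid.W * self.grid.H

    def mixture_weight(self) -> np.ndarray:
        """Per-voxel constant mixture weight ``P_ki = 1 / |Ki|``, shape (N,)."""
        return 1.0 / self.n_candidates[self.labels.ravel()]

    def candidate_sets(self, hi: int) -> np.ndarray:
        """``Ki`` for anchor label ``hi``, ascending order."""
        row = self.cell_candidates[hi]
        return row[row >= 0]

    def cell_voxels(self, k: int) -> np.ndarray:
        """Flat voxel indices of anchor cell ``k``."""
        return self._cell_voxels[k]

    def overlap_region(self, k: int) -> np.ndarray:
        """``Ik`` as sorted flat voxel indices."""
        return overlap_region(k, self.grid)
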