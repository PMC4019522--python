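"""Voxel grids, masks and the synthetic anatomical atlas.

The default grid is a 20 x 24 x 14 volume of 3 x 3 x 4 mm voxels centered
on the world origin -- a scaled-down analogue of a whole-brain EPI grid
that keeps simulations and tests fast.  A full-size 53 x 63 x 35 grid is
available through :func:`make_grid`.  The synthetic "brain" is an
ellipsoidal mask, partitioned into 116 labeled regions to mirror an
AAL-style anatomical parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SHAPE = (20, 24, 14)
FULL_SHAPE = (53, 63, 35)
VOXEL_SIZE_MM = (3.0, 3.0, 4.0)
N_REGIONS = 116


@dataclass(frozen=True)
class Grid:
    """A fixed 3D sampling grid with a voxel-to-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3])

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (X, Y, Z, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def make_grid(shape: tuple[int, int, int] = DEFAULT_SHAPE) -> Grid:
    """Build a grid of the given shape, 3x3x4 mm voxels, centered at 0 mm."""
    vs = np.array(VOXEL_SIZE_MM)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = -(np.array(shape) - 1) * vs / 2.0
    return Grid(shape=tuple(shape), affine=affine)


def brain_mask(grid: Grid, fill: float = 0.85) -> np.ndarray:
    """Ellipsoidal binary mask occupying ``fill`` of each half-extent."""
    centers = grid.voxel_centers_mm()
    semi = (np.array(grid.shape) - 1) * grid.voxel_size_mm / 2.0 * fill
    semi = np.maximum(semi, 1e-6)
    r2 = ((centers / semi) ** 2).sum(axis=-1)
    return r2 <= 1.0


def partition_atlas(mask: np.ndarray, n_regions: int = N_REGIONS) -> np.ndarray:
    """Split the mask into ``n_regions`` labeled parcels (labels 1..n).

    Voxels are ordered lexicographically by (x, y, z) index and chunked
    into near-equal contiguous runs; the result is deterministic for a
    given mask.  Background is labeled 0.
    """
    coords = np.argwhere(mask)  # argwhere is already lexicographic
    n_vox = len(coords)
    if n_vox == 0:
        raise ValueError("mask is empty")
    labels = np.zeros(mask.shape, dtype=np.int32)
    bounds = np.linspace(0, n_vox, n_regions + 1).astype(int)
    for region in range(n_regions):
        sel = coords[bounds[region] : bounds[region + 1]]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = region + 1
    return labels
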