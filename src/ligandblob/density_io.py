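"""Density-map input/output and resampling onto the canonical 0.2 Å grid.

X-ray difference maps (Fo-Fc) and cryoEM difference maps arrive as MRC/CCP4
files.  This module reads them into :class:`DensityMap` objects with a
normalized (x, y, z) axis order, resamples them onto axis-aligned voxel grids
with the canonical 0.2 Å spacing used throughout the pipeline, and provides a
lossless compressed-container dialect (``.npz``) for per-ligand blob grids
plus their provenance metadata.

Conventions
-----------
* ``DensityMap`` values are samples at grid *nodes*; node ``(i, j, k)`` sits at
  ``origin + step_matrix @ (i, j, k)`` where the step matrix is derived from
  the unit cell, so non-orthorhombic crystallographic cells are handled by
  interpolating in fractional coordinates.
* ``VoxelGrid`` uses the half-open voxel convention: voxel ``i`` spans
  ``[origin + i*s, origin + (i+1)*s)`` and its *center* is at
  ``origin + (i + 0.5)*s``.  Canonical blob grids have ``spacing == 0.2`` Å.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import FormatError, ValidationError

CANONICAL_SPACING = 0.2  # Å

__all__ = [
    "CANONICAL_SPACING",
    "DensityMap",
    "VoxelGrid",
    "read_density_map",
    "write_density_map",
    "resample_to_grid",
    "write_blob_grid",
    "read_blob_grid",
]


@dataclass
class DensityMap:
    """A 3D scalar field with physical geometry.

    Parameters
    ----------
    values : ndarray
        Scalar samples indexed ``[ix, iy, iz]`` (axis order normalized to
        x, y, z ascending).  Units are electrons/Å^3 for X-ray difference
        maps or volts for cryoEM potential maps.
    spacing : ndarray, shape (3,)
        Per-axis grid step lengths in Å (norms of the step vectors).
    origin : ndarray, shape (3,)
        Cartesian position (Å) of grid node ``(0, 0, 0)``.
    cell : ndarray, shape (3, 3)
        Orthogonalization matrix of the full unit cell (columns are the cell
        vectors, Å).
    full_sampling : ndarray, shape (3,)
        Number of grid intervals spanning the full unit cell along each
        crystal axis (MX, MY, MZ in MRC terms).
    source_kind : str
        ``"xray_diff"`` or ``"cryoem_diff"``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    cell: np.ndarray
    full_sampling: np.ndarray = None
    source_kind: str = "xray_diff"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError("map values must be a 3D array of shape >= (1,1,1)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("map contains non-finite values")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValidationError("map spacing must be positive on all axes")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.cell = np.asarray(self.cell, dtype=np.float64).reshape(3, 3)
        if self.full_sampling is None:
            self.full_sampling = np.asarray(self.values.shape)
        self.full_sampling = np.asarray(self.full_sampling, dtype=np.int64).reshape(3)

    @property
    def step_matrix(self) -> np.ndarray:
        """Columns are the Cartesian step vectors between adjacent nodes."""
        return self.cell / self.full_sampling[np.newaxis, :]

    def node_positions_bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned Cartesian bounding box of all grid nodes."""
        shape = np.asarray(self.values.shape) - 1
        corners = np.array(
            [[i, j, k] for i in (0, shape[0]) for j in (0, shape[1]) for k in (0, shape[2])],
            dtype=np.float64,
        )
        pts = (self.step_matrix @ corners.T).T + self.origin
        return pts.min(axis=0), pts.max(axis=0)


@dataclass
class VoxelGrid:
    """An axis-aligned voxel grid, canonically at 0.2 Å spacing.

    ``origin`` is the Cartesian corner of voxel ``(0, 0, 0)``; voxel centers
    sit at ``origin + (index + 0.5) * spacing``.
    """

    values: np.ndarray
    spacing: float = CANONICAL_SPACING
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError("grid values must be a 3D array of shape >= (1,1,1)")
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValidationError("grid spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian centers (Å) of the given ``(n, 3)`` integer voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return self.origin + (idx + 0.5) * self.spacing

    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.values))


def read_density_map(path, source_kind: str = "xray_diff") -> DensityMap:
    """Read an MRC/CCP4 2014 map, normalizing axis order to (x, y, z).

    The origin is taken from the ORIGIN header record plus the start-index
    offsets (NXSTART/NYSTART/NZSTART x step vectors), covering both the
    cryoEM and the crystallographic conventions.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC/CCP4 map {path}: {exc}") from exc
    # reorder data axes (MAPC/MAPR/MAPS) to x, y, z without unit-cell expansion
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True, dtype=np.float64)
    cell = m.grid.unit_cell
    if min(cell.a, cell.b, cell.c) <= 0:
        raise ValidationError(f"non-positive cell dimensions in {path}")
    orth = np.array(cell.orth.mat.tolist(), dtype=np.float64)
    full = np.array([m.header_i32(i) for i in (8, 9, 10)], dtype=np.int64)
    if np.any(full <= 0):
        full = np.asarray(values.shape, dtype=np.int64)
    step = orth / full[np.newaxis, :]
    starts = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=np.float64)
    origin_rec = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=np.float64)
    origin = origin_rec + step @ starts
    spacing = np.linalg.norm(step, axis=0)
    dm = DensityMap(
        values=values,
        spacing=spacing,
        origin=origin,
        cell=orth,
        full_sampling=full,
        source_kind=source_kind,
    )
    return dm


def write_density_map(dmap: DensityMap, path) -> None:
    """Write a DensityMap to an MRC/CCP4 file (x, y, z axis order)."""
    grid = gemmi.FloatGrid(*dmap.values.shape)
    np.asarray(grid)[:] = dmap.values.astype(np.float32)
    a, b, c = np.linalg.norm(dmap.cell, axis=0)
    cell = gemmi.UnitCell(a, b, c, *_cell_angles(dmap.cell))
    grid.unit_cell = cell
    grid.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, n in zip((8, 9, 10), dmap.full_sampling):
        m.set_header_i32(w, int(n))
    for w, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


def _cell_angles(cell: np.ndarray) -> tuple[float, float, float]:
    va, vb, vc = cell[:, 0], cell[:, 1], cell[:, 2]

    def ang(u, v):
        cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))

    return ang(vb, vc), ang(va, vc), ang(va, vb)


def resample_to_grid(dmap: DensityMap, spacing: float = CANONICAL_SPACING) -> VoxelGrid:
    """Trilinearly resample a density map onto an axis-aligned grid.

    The output grid covers the Cartesian bounding box of the map's nodes;
    samples falling outside the map get the value 0.  Interpolation is done
    in fractional (index) coordinates so non-orthorhombic cells are correct.
    For a map already at the target spacing with an orthogonal cell, values
    at coincident nodes are reproduced exactly (trilinear interpolation is
    exact on degree-<=1 fields).
    """
    if spacing <= 0:
        raise ValidationError("target spacing must be positive")
    step = dmap.step_matrix
    det = np.linalg.det(step)
    if abs(det) < 1e-300:
        raise ValidationError("cell matrix is not invertible")
    inv_step = np.linalg.inv(step)
    lo, hi = dmap.node_positions_bbox()
    n_nodes = np.floor((hi - lo) / spacing + 1e-9).astype(int) + 1
    axes = [lo[d] + spacing * np.arange(n_nodes[d]) for d in range(3)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    cart = np.stack([xs.ravel(), ys.ravel(), zs.ravel()])
    idx_coords = inv_step @ (cart - dmap.origin[:, None])
    sampled = map_coordinates(
        dmap.values, idx_coords, order=1, mode="constant", cval=0.0, prefilter=False
    ).reshape(tuple(n_nodes))
    # node (0,0,0) of the output sits at `lo`; as a VoxelGrid, nodes are voxel
    # centers, so the corner origin is half a voxel below
    return VoxelGrid(values=sampled, spacing=spacing, origin=lo - 0.5 * spacing)


REQUIRED_KEYS = ("values", "spacing", "origin")


def write_blob_grid(grid: VoxelGrid, metadata: dict, path) -> None:
    """Write a blob grid plus flat metadata to a compressed ``.npz`` container."""
    meta = dict(metadata or {})
    np.savez_compressed(
        path,
        values=grid.values,
        spacing=np.float64(grid.spacing),
        origin=grid.origin,
        metadata=np.bytes_(json.dumps(meta, sort_keys=True).encode()),
    )


def read_blob_grid(path) -> tuple[VoxelGrid, dict]:
    """Read a blob grid container written by :func:`write_blob_grid`."""
    try:
        with np.load(path, allow_pickle=False) as npz:
            entries = dict(npz)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read blob container {path}: {exc}") from exc
    for key in REQUIRED_KEYS:
        if key not in entries:
            raise ValidationError(f"blob container missing required entry '{key}'")
    metadata = {}
    if "metadata" in entries:
        metadata = json.loads(bytes(entries["metadata"]).decode())
    grid = VoxelGrid(
        values=entries["values"],
        spacing=float(entries["spacing"]),
        origin=entries["origin"],
    )
    return grid, metadata
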