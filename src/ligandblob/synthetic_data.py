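"""Synthetic densities, maps, shape datasets and calibration tables.

Everything the test suite consumes is generated here, seeded and
bit-reproducible:

* *Pseudo-ligand densities*: sums of isotropic Gaussian atoms on the
  canonical 0.2 Å grid.  The atomic width is tied to the nominal resolution
  via ``sigma_atom = 0.425 * resolution``, which gives a Gaussian whose FWHM
  approximates the resolution; each atom integrates to its weight.
* *Zero-inflated cryoEM-like maps*: a normal background with a configurable
  fraction of voxels zeroed exactly (emulating solvent masking and box
  padding, the source of the near-zero histogram spike in real maps) plus
  embedded pseudo-ligand blobs with recorded ground-truth masks.
* *Labeled shape datasets*: small multi-class point-cloud datasets built
  from distinct atom-arrangement templates (line, ring, tetrahedron,
  T-shape, helix) under random rigid rotations — a stand-in for the real
  219-group ligand corpus in training smoke tests.
* *Calibration tables*: monotone synthetic per-resolution targets for the
  voxel-value normalization step.

What these generators do NOT emulate: experiment-specific sharpening,
position-dependent resolution, map-model misfit, or chemically realistic
ligand geometry.  Tests passing on them demonstrate pipeline correctness,
not real-data performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density_io import CANONICAL_SPACING, DensityMap, VoxelGrid
from .errors import ValidationError
from .map_normalization import CalibrationTable
from .point_sampling import PointCloud

__all__ = [
    "PseudoLigandSpec",
    "SyntheticMapSpec",
    "render_pseudo_ligand",
    "make_zero_inflated_map",
    "make_shape_dataset",
    "make_calibration_table",
    "SHAPE_TEMPLATES",
]

#: Fraction of the peak value defining a blob's ground-truth mask.
MASK_LEVEL = 0.5


@dataclass
class PseudoLigandSpec:
    """Gaussian-atom model of a ligand density fragment."""

    atoms: list  # [(weight, (x, y, z) Å), ...]
    resolution: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError("a pseudo-ligand needs at least one atom")
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")

    @property
    def sigma_atom(self) -> float:
        return 0.425 * self.resolution


@dataclass
class SyntheticMapSpec:
    """Zero-inflated background plus embedded pseudo-ligands."""

    box: tuple = (64, 64, 64)
    mask_fraction: float = 0.6
    background: tuple = (0.0, 1.0)
    blob_specs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ValidationError("mask_fraction must lie in [0, 1)")


def render_pseudo_ligand(spec: PseudoLigandSpec, spacing: float = CANONICAL_SPACING) -> VoxelGrid:
    """Sample the Gaussian-atom density on a padded canonical grid.

    The grid pads 3 sigma beyond the atom bounding box (99.7% of each
    marginal, so the integral is accurate to better than 2%); each atom contributes
    ``weight * N(position, sigma_atom^2 I)`` so its integral equals its
    weight.  Seeded Gaussian noise is added if requested; negative values are
    clipped to zero.
    """
    sigma = spec.sigma_atom
    pos = np.array([p for _, p in spec.atoms], dtype=np.float64)
    weights = np.array([w for w, _ in spec.atoms], dtype=np.float64)
    lo = pos.min(axis=0) - 3 * sigma
    hi = pos.max(axis=0) + 3 * sigma
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[d] + spacing * (np.arange(n[d]) + 0.5) for d in range(3)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    values = np.zeros(tuple(n))
    norm_const = (2 * np.pi * sigma**2) ** -1.5
    for w, p in zip(weights, pos):
        d2 = (xs - p[0]) ** 2 + (ys - p[1]) ** 2 + (zs - p[2]) ** 2
        values += w * norm_const * np.exp(-d2 / (2 * sigma**2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    return VoxelGrid(values=values, spacing=spacing, origin=lo)


def make_zero_inflated_map(spec: SyntheticMapSpec) -> tuple[DensityMap, list[np.ndarray]]:
    """Construct a cryoEM-like map and per-blob ground-truth voxel masks.

    Background voxels are normal draws; a seeded random ``mask_fraction`` of
    them is set exactly to zero (the zero-inflation spike).  Each blob spec
    is rendered noiselessly and added at its recorded location; its
    ground-truth mask marks voxels where the blob's own density exceeds
    ``MASK_LEVEL`` (50%) of its peak.  Blob masks must not overlap.
    """
    rng = np.random.default_rng(spec.seed)
    box = tuple(int(b) for b in spec.box)
    mean, sd = spec.background
    values = rng.normal(mean, sd, size=box)
    zero_mask = rng.random(size=box) < spec.mask_fraction
    values[zero_mask] = 0.0

    spacing = CANONICAL_SPACING
    truth_masks = []
    occupied = np.zeros(box, dtype=bool)
    for bspec in spec.blob_specs:
        blob = render_pseudo_ligand(
            PseudoLigandSpec(atoms=bspec.atoms, resolution=bspec.resolution, noise_sd=0.0)
        )
        # voxel offset of the blob grid inside the map
        offset = np.round(blob.origin / spacing).astype(int)
        shape = blob.values.shape
        sl = tuple(slice(offset[d], offset[d] + shape[d]) for d in range(3))
        if any(offset[d] < 0 or offset[d] + shape[d] > box[d] for d in range(3)):
            raise ValidationError("blob does not fit inside the map box")
        mask = np.zeros(box, dtype=bool)
        mask[sl] = blob.values >= MASK_LEVEL * blob.values.max()
        if np.any(mask & occupied):
            raise ValidationError("overlapping blob ground-truth masks")
        occupied |= mask
        values[sl] += blob.values
        truth_masks.append(mask)

    dmap = DensityMap(
        values=values,
        spacing=(spacing,) * 3,
        origin=np.zeros(3),
        cell=np.diag(np.asarray(box) * spacing),
        full_sampling=box,
        source_kind="cryoem_diff",
    )
    return dmap, truth_masks


SHAPE_TEMPLATES = ("line", "ring", "tetrahedron", "tee", "helix")


def _template_atoms(name: str) -> np.ndarray:
    if name == "line":
        return np.array([[1.5 * i, 0.0, 0.0] for i in range(8)])
    if name == "ring":
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        return np.column_stack([3.0 * np.cos(ang), 3.0 * np.sin(ang), np.zeros(8)])
    if name == "tetrahedron":
        return np.array(
            [[0, 0, 0], [1.6, 1.6, 1.6], [1.6, -1.6, -1.6], [-1.6, 1.6, -1.6], [-1.6, -1.6, 1.6]],
            dtype=np.float64,
        )
    if name == "tee":
        bar = [[1.5 * i, 0.0, 0.0] for i in range(-3, 4)]
        stem = [[0.0, -1.5 * i, 0.0] for i in range(1, 6)]
        return np.array(bar + stem, dtype=np.float64)
    if name == "helix":
        t = np.linspace(0, 3 * np.pi, 12)
        return np.column_stack([2.0 * np.cos(t), 2.0 * np.sin(t), 0.8 * t])
    raise ValidationError(f"unknown shape template {name!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_shape_dataset(
    n_classes: int = 5,
    n_per_class: int = 100,
    max_p: int = 2000,
    seed: int = 0,
    points_per_atom: int = 6,
    jitter: float = 0.15,
) -> list[tuple[PointCloud, int]]:
    """Balanced labeled point clouds from rigid-rotated shape templates.

    Each example scatters ``points_per_atom`` points around every template
    atom (Gaussian jitter), assigns each point a density decaying with its
    offset, applies a random rotation and translation, and caps the cloud at
    ``max_p`` points.  Same seed, same dataset.
    """
    if not 2 <= n_classes <= len(SHAPE_TEMPLATES):
        raise ValidationError(f"n_classes must lie in [2, {len(SHAPE_TEMPLATES)}]")
    rng = np.random.default_rng(seed)
    dataset = []
    for label, name in enumerate(SHAPE_TEMPLATES[:n_classes]):
        atoms = _template_atoms(name)
        for _ in range(n_per_class):
            offsets = rng.normal(0.0, jitter, size=(atoms.shape[0], points_per_atom, 3))
            pts = (atoms[:, None, :] + offsets).reshape(-1, 3)
            d2 = np.sum(offsets**2, axis=2).ravel()
            dens = np.exp(-d2 / (2 * jitter**2)) + 0.05 * rng.random(pts.shape[0])
            rot = _random_rotation(rng)
            shift = rng.normal(0.0, 5.0, size=3)
            pts = pts @ rot.T + shift
            if pts.shape[0] > max_p:
                keep = rng.choice(pts.shape[0], size=max_p, replace=False)
                pts, dens = pts[keep], dens[keep]
            dataset.append((PointCloud(points=np.column_stack([pts, dens])), label))
    return dataset


def make_calibration_table(
    resolutions=np.arange(1.0, 4.1, 0.1), seed: int = 0
) -> CalibrationTable:
    """Synthetic, monotone calibration targets.

    Higher-resolution (smaller Å) X-ray blobs have higher minimum nonzero
    density, so targets decay smoothly with the resolution bin; a small
    seeded perturbation keeps the table from being exactly analytic.
    """
    res = np.asarray(sorted(resolutions), dtype=np.float64)
    rng = np.random.default_rng(seed)
    base = 2.0 / res
    targets = base * (1.0 + 0.05 * rng.random(res.size))
    # enforce strict monotone decrease with increasing resolution bin
    targets = np.minimum.accumulate(targets)
    targets += np.linspace(res.size * 1e-6, 0.0, res.size)
    return CalibrationTable(resolution_bins=res, target_min_value=targets)
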