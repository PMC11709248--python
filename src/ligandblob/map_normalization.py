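"""Density cutoffs and cryoEM map normalization.

X-ray Fo-Fc difference maps are standardized enough that a single fixed
cutoff works for all deposits: the 2.8 sigma isosurface, where sigma is the
population standard deviation of all map voxels.  CryoEM potential maps are
not standardized: masking during refinement zero-inflates the voxel value
histogram (a spike near zero whose size depends on the arbitrary box/mask
ratio), and ad hoc sharpening changes the value scale per deposit.  The
normalization implemented here therefore proceeds in three steps:

1. *Reduce zero inflation* - drop all voxel values within +-0.5 standard
   deviations of the median of the whole map, removing the masking spike.
2. *Quantile thresholding* - take the empirical q-quantile of the surviving
   values as the density cutoff, with q = Phi(2.8) ~ 0.99744 so that on a
   Gaussian map the cutoff coincides with the X-ray 2.8 sigma convention.
3. *Voxel value normalization* - after zeroing sub-threshold voxels,
   multiplicatively rescale so the lowest nonzero value matches the average
   lowest nonzero value observed for X-ray ligands at the same resolution
   (the calibration table).

All statistics are scale-equivariant, so the selected voxel set and final
calibrated values are invariant to a global rescaling of the input map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .density_io import DensityMap, VoxelGrid
from .errors import DegenerateBlobError, DegenerateMapError, ValidationError

#: Standard-normal CDF at 2.8; the quantile matching the X-ray 2.8 sigma cutoff.
DEFAULT_QUANTILE = float(norm.cdf(2.8))

__all__ = [
    "DEFAULT_QUANTILE",
    "ThresholdResult",
    "CalibrationTable",
    "sigma_threshold",
    "trim_zero_inflation",
    "quantile_threshold",
    "apply_density_cutoff",
    "rescale_to_calibration",
    "normalize_cryoem_map",
]


@dataclass
class ThresholdResult:
    """Provenance of a density cutoff.

    ``stats`` records (median, standard deviation, quantile) of the sample
    the threshold was derived from; for the sigma method the quantile slot
    holds the sigma multiplier's normal-CDF equivalent.
    """

    threshold: float
    method: str  # "sigma" | "quantile"
    trimmed_fraction: float = 0.0
    stats: tuple = (float("nan"), float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")
        if not 0.0 <= self.trimmed_fraction <= 1.0:
            raise ValidationError("trimmed_fraction must lie in [0, 1]")


@dataclass
class CalibrationTable:
    """Per-resolution targets for the lowest nonzero blob value.

    ``resolution_bins`` are strictly increasing bin centers (Å);
    ``target_min_value`` holds, per bin, the average lowest nonzero voxel
    value of X-ray ligand blobs at that resolution.  Lookup is nearest-bin
    with clamping at the edges.
    """

    resolution_bins: np.ndarray
    target_min_value: np.ndarray

    def __post_init__(self) -> None:
        self.resolution_bins = np.asarray(self.resolution_bins, dtype=np.float64).ravel()
        self.target_min_value = np.asarray(self.target_min_value, dtype=np.float64).ravel()
        if self.resolution_bins.size == 0:
            raise ValidationError("calibration table must have at least one bin")
        if self.resolution_bins.size != self.target_min_value.size:
            raise ValidationError("bins and targets must have equal length")
        if np.any(np.diff(self.resolution_bins) <= 0):
            raise ValidationError("resolution bins must be strictly increasing")
        if np.any(self.target_min_value <= 0):
            raise ValidationError("calibration targets must be positive")

    def target_for(self, resolution: float) -> float:
        i = int(np.argmin(np.abs(self.resolution_bins - resolution)))
        return float(self.target_min_value[i])

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.resolution_bins, self.target_min_value]),
            delimiter="\t",
            header="resolution_bin\ttarget_min_value",
            comments="",
        )

    @classmethod
    def from_tsv(cls, path) -> "CalibrationTable":
        arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(resolution_bins=arr[:, 0], target_min_value=arr[:, 1])


def sigma_threshold(dmap: DensityMap | VoxelGrid | np.ndarray, k: float = 2.8) -> ThresholdResult:
    """X-ray cutoff: ``k`` times the population SD of all voxel values."""
    values = _values_of(dmap)
    if values.size < 2:
        raise ValidationError("sigma threshold requires at least 2 voxels")
    sd = float(np.std(values))
    if sd == 0.0:
        raise DegenerateMapError("constant map: sigma threshold undefined")
    return ThresholdResult(
        threshold=k * sd,
        method="sigma",
        trimmed_fraction=0.0,
        stats=(float(np.median(values)), sd, float(norm.cdf(k))),
    )


def trim_zero_inflation(values: np.ndarray) -> np.ndarray:
    """Drop values within +-0.5 SD of the median (both tails are kept).

    Median and SD are computed on the *full* input sample, including zeros,
    since the zero-inflation spike is exactly what anchors the median.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValidationError("trimming requires a sample of size >= 2")
    med = float(np.median(v))
    sd = float(np.std(v))
    kept = v[np.abs(v - med) > 0.5 * sd]
    if kept.size == 0:
        raise DegenerateMapError("trimming removed every value (constant map?)")
    return kept


def quantile_threshold(values: np.ndarray, q: float = DEFAULT_QUANTILE) -> ThresholdResult:
    """Empirical q-quantile cutoff with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValidationError("quantile threshold requires a non-empty sample")
    if not 0.0 < q < 1.0:
        raise ValidationError("quantile must lie strictly inside (0, 1)")
    thr = float(np.quantile(v, q, method="linear"))
    return ThresholdResult(
        threshold=thr,
        method="quantile",
        trimmed_fraction=0.0,
        stats=(float(np.median(v)), float(np.std(v)), q),
    )


def apply_density_cutoff(grid: VoxelGrid | DensityMap, threshold: float) -> VoxelGrid:
    """Zero voxel values below ``threshold``; geometry is unchanged."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    values = _values_of(grid, ravel=False)
    out = np.where(values < threshold, 0.0, values)
    if isinstance(grid, VoxelGrid):
        return VoxelGrid(values=out, spacing=grid.spacing, origin=grid.origin)
    # a DensityMap loses its cell bookkeeping once thresholded to a blob region
    return VoxelGrid(values=out, spacing=float(grid.spacing[0]), origin=grid.origin)


def rescale_to_calibration(
    grid: VoxelGrid, resolution: float, table: CalibrationTable
) -> VoxelGrid:
    """Multiplicatively rescale so min nonzero value hits the calibrated target."""
    nz = grid.values[grid.values > 0]
    if nz.size == 0:
        raise DegenerateBlobError("all-zero grid cannot be calibrated")
    factor = table.target_for(resolution) / float(nz.min())
    return VoxelGrid(values=grid.values * factor, spacing=grid.spacing, origin=grid.origin)


def normalize_cryoem_map(
    dmap: DensityMap,
    resolution: float,
    table: CalibrationTable,
    q: float = DEFAULT_QUANTILE,
) -> tuple[VoxelGrid, ThresholdResult]:
    """Full three-step cryoEM normalization.

    Returns the thresholded, calibrated grid together with the threshold
    provenance (median/SD of the full map, quantile used, trimmed fraction).
    """
    all_values = _values_of(dmap)
    kept = trim_zero_inflation(all_values)
    qt = quantile_threshold(kept, q=q)
    result = ThresholdResult(
        threshold=qt.threshold,
        method="quantile",
        trimmed_fraction=1.0 - kept.size / all_values.size,
        stats=(float(np.median(all_values)), float(np.std(all_values)), q),
    )
    cut = apply_density_cutoff(dmap, result.threshold)
    calibrated = rescale_to_calibration(cut, resolution, table)
    return calibrated, result


def _values_of(obj, ravel: bool = True) -> np.ndarray:
    values = obj.values if hasattr(obj, "values") else np.asarray(obj, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    return values.ravel() if ravel else values
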