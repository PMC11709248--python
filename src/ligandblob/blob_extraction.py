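"""Connected-blob extraction and ligand quality filtering.

A *blob* is a maximal connected set of positive-density voxels in a
thresholded grid, presumed to correspond to one ligand.  Connectivity may be
6 (faces), 18 (faces+edges) or 26 (faces+edges+corners); the pipeline default
is 26, the most permissive choice, which avoids splitting ligands whose
density is bridged by thin diagonal connections at 0.2 Å sampling.

Quality filtering reproduces the deposition-hygiene criteria used to build
the training corpus:

* X-ray ligands are rejected when ANY of the following fires:
  resolution > 4.0 Å, RSCC < 0.6, RSZO < 1.0, RSZD >= 6.0,
  R factor > 0.3, or occupancy < 0.3.
* CryoEM ligands are kept only with Q-score >= 0.6 AND volume > 2.14 Å^3.

Boundary semantics follow these inequalities exactly (note RSZD's inclusive
bound and the strict volume bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .density_io import CANONICAL_SPACING, VoxelGrid
from .errors import ValidationError

__all__ = [
    "Blob",
    "LigandQualityRecord",
    "connected_components",
    "blob_volume",
    "filter_xray_ligands",
    "filter_cryoem_ligands",
    "assign_blob_to_ligand",
    "XRAY_CRITERIA",
]


@dataclass
class Blob:
    """A connected positive-density fragment with provenance metadata."""

    grid: VoxelGrid
    deposit_id: str = ""
    chain: str = ""
    residue_number: int = 0
    ligand_code: str = ""
    centroid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.grid.nonzero_count() < 1:
            raise ValidationError("a blob must contain at least one nonzero voxel")
        if self.centroid is None:
            idx = np.argwhere(self.grid.values > 0)
            self.centroid = self.grid.voxel_centers(idx).mean(axis=0)
        self.centroid = np.asarray(self.centroid, dtype=np.float64).reshape(3)


@dataclass
class LigandQualityRecord:
    """External validation metrics for one ligand instance.

    These metrics (RSCC, RSZO, RSZD, R factor, occupancy for X-ray; Q-score
    and blob volume for cryoEM) are consumed as inputs, not computed here.
    """

    resolution: float = None
    rscc: float = None
    rszo: float = None
    rszd: float = None
    r_factor: float = None
    occupancy: float = None
    q_score: float = None
    volume: float = None
    source_kind: str = "xray_diff"
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.occupancy is not None and not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError("occupancy must lie in [0, 1]")
        if self.volume is not None and self.volume < 0:
            raise ValidationError("volume must be non-negative")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(
    grid: VoxelGrid, connectivity: int = 26, min_voxels: int = 1, **blob_meta
) -> list[Blob]:
    """Label connected components of the nonzero voxels.

    Returns blobs ordered by descending voxel count (ties by label order);
    components smaller than ``min_voxels`` are dropped.  An all-zero grid
    yields an empty list.
    """
    if connectivity not in _STRUCTURES:
        raise ValidationError("connectivity must be one of 6, 18, 26")
    if np.any(grid.values < 0):
        raise ValidationError("grid must be thresholded (all values >= 0)")
    labels, n = ndimage.label(grid.values > 0, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]  # skip background
    order = np.argsort(-counts, kind="stable") + 1
    blobs = []
    for lab in order:
        if counts[lab - 1] < min_voxels:
            continue
        comp_values = np.where(labels == lab, grid.values, 0.0)
        blobs.append(
            Blob(
                grid=VoxelGrid(values=comp_values, spacing=grid.spacing, origin=grid.origin),
                **blob_meta,
            )
        )
    return blobs


def blob_volume(blob: Blob | VoxelGrid) -> float:
    """Blob volume in Å^3: nonzero voxel count x spacing^3."""
    grid = blob.grid if isinstance(blob, Blob) else blob
    return grid.nonzero_count() * grid.spacing**3


#: X-ray rejection criteria in the order they are checked and reported.
XRAY_CRITERIA = (
    ("resolution", lambda r: r.resolution > 4.0),
    ("rscc", lambda r: r.rscc < 0.6),
    ("rszo", lambda r: r.rszo < 1.0),
    ("rszd", lambda r: r.rszd >= 6.0),
    ("r_factor", lambda r: r.r_factor > 0.3),
    ("occupancy", lambda r: r.occupancy < 0.3),
)


def filter_xray_ligands(
    records: list[LigandQualityRecord],
) -> tuple[list[LigandQualityRecord], list[tuple[LigandQualityRecord, str]]]:
    """Apply the X-ray quality criteria.

    A record is rejected iff ANY criterion fires; the reported reason is the
    first firing criterion in the documented order.
    """
    kept, rejected = [], []
    for rec in records:
        for name in ("resolution", "rscc", "rszo", "rszd", "r_factor", "occupancy"):
            if getattr(rec, name) is None:
                raise ValidationError(f"X-ray record missing required field '{name}'")
        for name, fires in XRAY_CRITERIA:
            if fires(rec):
                rejected.append((rec, name))
                break
        else:
            kept.append(rec)
    return kept, rejected


def filter_cryoem_ligands(
    records: list[LigandQualityRecord],
    q_min: float = 0.6,
    volume_min: float = 2.14,
) -> tuple[list[LigandQualityRecord], list[tuple[LigandQualityRecord, str]]]:
    """Keep cryoEM ligands with Q-score >= 0.6 (inclusive) and volume > 2.14 Å^3 (strict)."""
    kept, rejected = [], []
    for rec in records:
        if rec.q_score is None:
            raise ValidationError("cryoEM record missing required field 'q_score'")
        if rec.volume is None:
            raise ValidationError("cryoEM record missing required field 'volume'")
        if rec.q_score < q_min:
            rejected.append((rec, "q_score"))
        elif not rec.volume > volume_min:
            rejected.append((rec, "volume"))
        else:
            kept.append(rec)
    return kept, rejected


def assign_blob_to_ligand(
    blob: Blob, ligand_atoms: list[tuple[str, np.ndarray]], max_dist: float = 2.0
) -> bool:
    """True iff any non-hydrogen atom lies within ``max_dist`` Å of a nonzero voxel center."""
    if not ligand_atoms:
        raise ValidationError("ligand must have at least one atom")
    heavy = [np.asarray(pos, dtype=np.float64) for el, pos in ligand_atoms if el.upper() != "H"]
    if not heavy:
        return False
    idx = np.argwhere(blob.grid.values > 0)
    centers = blob.grid.voxel_centers(idx)
    tree = cKDTree(centers)
    d, _ = tree.query(np.vstack(heavy), k=1)
    return bool(np.min(d) <= max_dist)


def xray_grid_spacing_check(grid: VoxelGrid) -> None:
    """Volume semantics assume the canonical 0.2 Å spacing."""
    if not np.isclose(grid.spacing, CANONICAL_SPACING):
        raise ValidationError("blob volume is defined on the canonical 0.2 Å grid")
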