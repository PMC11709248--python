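"""Grouping of ligand chemistries into density-indistinguishable classes.

Several distinct Chemical Component Dictionary (CCD) entries are identical as
far as a density map is concerned (same heavy-atom skeleton, e.g. D- vs
L-enantiomers resolved only by chirality, or protonation variants).  The
classifier label space is therefore built from *ligand groups*: equivalence
classes of ligands sharing the number of heavy atoms, number of rings, graph
connectivity, chirality, and the multiset of atomic numbers.  Groups with at
least ``min_instances`` blob instances (default 100) become classes of their
own; everything else is pooled into a single catch-all class ``"rare"``.

Hydrogens are excluded everywhere: they do not contribute observable density
at typical resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdMolDescriptors

from .errors import ChemistryParseError

RDLogger.DisableLog("rdApp.*")

RARE_LABEL = "rare"

__all__ = ["RARE_LABEL", "LigandChemistry", "LigandGroup", "ligand_descriptor_key", "cluster_into_groups"]


@dataclass(frozen=True)
class LigandChemistry:
    """Density-relevant descriptors of one ligand chemistry."""

    ccd_code: str
    smiles: str
    heavy_atom_count: int
    ring_count: int
    connectivity_key: str
    chirality_key: str
    atomic_numbers: tuple  # sorted multiset of heavy-atom atomic numbers

    @property
    def key(self) -> tuple:
        """The grouping key; ligands with equal keys are merged into one group."""
        return (
            self.heavy_atom_count,
            self.ring_count,
            self.connectivity_key,
            self.chirality_key,
            self.atomic_numbers,
        )


@dataclass
class LigandGroup:
    """One class of the label space: chemically indistinguishable ligand codes."""

    group_id: int
    member_codes: frozenset
    label: str
    instance_count: int


def ligand_descriptor_key(smiles: str, ccd_code: str = "") -> LigandChemistry:
    """Compute the grouping descriptor from a SMILES string.

    ``connectivity_key`` is the canonical SMILES of the hydrogen-suppressed
    skeleton with stereochemistry stripped (so graph-isomorphic skeletons
    compare equal regardless of input spelling); ``chirality_key`` collects
    the assigned stereo descriptors separately.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryParseError(f"unparseable SMILES for {ccd_code or '<ligand>'}: {smiles!r}")
    heavy = Chem.RemoveHs(mol)
    atomic_numbers = tuple(sorted(a.GetAtomicNum() for a in heavy.GetAtoms()))
    ring_count = rdMolDescriptors.CalcNumRings(heavy)
    flat = Chem.Mol(heavy)
    Chem.RemoveStereochemistry(flat)
    connectivity_key = Chem.MolToSmiles(flat, canonical=True, isomericSmiles=False)
    centers = Chem.FindMolChiralCenters(heavy, includeUnassigned=False, useLegacyImplementation=False)
    chirality_key = ";".join(f"{i}:{tag}" for i, tag in sorted(centers))
    return LigandChemistry(
        ccd_code=ccd_code,
        smiles=smiles,
        heavy_atom_count=heavy.GetNumAtoms(),
        ring_count=ring_count,
        connectivity_key=connectivity_key,
        chirality_key=chirality_key,
        atomic_numbers=atomic_numbers,
    )


def cluster_into_groups(
    chemistries: list[LigandChemistry],
    blob_counts: dict,
    min_instances: int = 100,
) -> list[LigandGroup]:
    """Merge equal-key ligands and pool small groups into the ``rare`` class.

    A group's instance count is the sum of its members' blob counts; groups
    below ``min_instances`` are merged into ``rare``.  Group ids are assigned
    by sorted key, so membership and ids are independent of input order.
    The ``rare`` group always exists (possibly empty) and has the largest id.
    """
    by_key: dict = {}
    for chem in chemistries:
        by_key.setdefault(chem.key, []).append(chem)

    kept, rare_codes, rare_count = [], set(), 0
    for key in sorted(by_key, key=repr):
        members = by_key[key]
        codes = frozenset(c.ccd_code for c in members)
        count = sum(int(blob_counts.get(c, 0)) for c in codes)
        if count >= min_instances:
            # representative label: member code with the most blobs, ties alphabetical
            label = min(codes, key=lambda c: (-int(blob_counts.get(c, 0)), c))
            kept.append((codes, label, count))
        else:
            rare_codes |= codes
            rare_count += count

    groups = [
        LigandGroup(group_id=i, member_codes=codes, label=label, instance_count=count)
        for i, (codes, label, count) in enumerate(kept)
    ]
    groups.append(
        LigandGroup(
            group_id=len(groups),
            member_codes=frozenset(rare_codes),
            label=RARE_LABEL,
            instance_count=rare_count,
        )
    )
    return groups
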