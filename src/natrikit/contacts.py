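"""Receptor–ligand contact residues and same-pocket pose classification.

Given complex coordinates (e.g. poses exported from an external docking
run), a receptor residue is a contact when any of its heavy atoms lies
within a distance cutoff (default 5.0 Å) of any ligand heavy atom. A pose
is labelled ``same_pocket`` when the Jaccard overlap between its contact
residue numbers and a reference pocket's residue numbers reaches a
threshold (default 0.3); otherwise ``different_pocket``. Both knobs are
configurable — the binary same/distinct call has no canonical criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import StructureModel
from .pocket import PocketDefinition

__all__ = [
    "ContactSet",
    "PoseClassification",
    "contact_residues",
    "classify_pose",
    "batch_classify",
    "batch_tsv",
]


@dataclass(frozen=True)
class ContactSet:
    receptor_chain: str
    residues: frozenset  # of (residue_number, residue_name)
    cutoff_A: float

    @property
    def residue_numbers(self) -> frozenset:
        return frozenset(num for num, _ in self.residues)


@dataclass(frozen=True)
class PoseClassification:
    pose_id: str
    contact_set: ContactSet
    reference_positions: frozenset
    jaccard: float
    threshold: float

    @property
    def label(self) -> str:
        return "same_pocket" if self.jaccard >= self.threshold else "different_pocket"


def _heavy_coords(residues) -> tuple[np.ndarray, list]:
    coords, owner = [], []
    for res in residues:
        for atom in res.atoms:
            if atom.element.upper() in ("H", "D"):
                continue
            coords.append((atom.x, atom.y, atom.z))
            owner.append((res.number, res.name))
    return np.asarray(coords, dtype=float), owner


def contact_residues(structure: StructureModel, receptor_chain: str,
                     ligand_chain: str, cutoff_A: float = 5.0) -> ContactSet:
    """Receptor residues with >= 1 heavy atom within ``cutoff_A`` of >= 1
    ligand heavy atom (minimum inter-atomic Euclidean distance)."""
    for chain in (receptor_chain, ligand_chain):
        if chain not in structure.chains:
            raise ValidationError(f"chain {chain!r} absent from structure")
    if cutoff_A <= 0:
        raise ValidationError("cutoff must be positive")
    rec_xyz, rec_owner = _heavy_coords(structure.chains[receptor_chain])
    lig_xyz, _ = _heavy_coords(structure.chains[ligand_chain])
    if lig_xyz.size == 0:
        raise ValidationError(f"ligand chain {ligand_chain!r} has no heavy atoms")
    if rec_xyz.size == 0:
        raise ValidationError(f"receptor chain {receptor_chain!r} has no heavy atoms")
    diff = rec_xyz[:, None, :] - lig_xyz[None, :, :]
    dmin = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
    residues = frozenset(rec_owner[i] for i in np.nonzero(dmin <= cutoff_A)[0])
    return ContactSet(receptor_chain=receptor_chain, residues=residues,
                      cutoff_A=cutoff_A)


def classify_pose(contacts: ContactSet, pocket: PocketDefinition,
                  threshold: float = 0.3, pose_id: str = "pose") -> PoseClassification:
    """Jaccard overlap of contact residue numbers with the pocket's residue
    numbers (pocket positions must be expressed in the receptor chain's
    numbering)."""
    reference = frozenset(pocket.positions)
    contact_nums = contacts.residue_numbers
    union = reference | contact_nums
    if not union:
        raise ValidationError("empty union of contacts and pocket: Jaccard undefined")
    jaccard = len(reference & contact_nums) / len(union)
    return PoseClassification(pose_id=pose_id, contact_set=contacts,
                              reference_positions=reference,
                              jaccard=jaccard, threshold=threshold)


def batch_classify(poses: list[tuple[str, StructureModel]], pocket: PocketDefinition,
                   receptor_chain: str = "A", ligand_chain: str = "B",
                   cutoff_A: float = 5.0, threshold: float = 0.3) -> dict:
    """Classify each (pose_id, structure); returns rows plus per-label
    summary counts."""
    rows = []
    for pose_id, structure in poses:
        contacts = contact_residues(structure, receptor_chain, ligand_chain, cutoff_A)
        rows.append(classify_pose(contacts, pocket, threshold, pose_id=pose_id))
    summary = {
        "same_pocket": sum(1 for r in rows if r.label == "same_pocket"),
        "different_pocket": sum(1 for r in rows if r.label == "different_pocket"),
    }
    return {"rows": rows, "summary": summary}


def batch_tsv(rows: list[PoseClassification]) -> str:
    lines = ["pose_id\tn_contacts\tjaccard\tlabel"]
    for r in rows:
        lines.append(f"{r.pose_id}\t{len(r.contact_set.residues)}\t"
                     f"{r.jaccard:.6f}\t{r.label}")
    return "\n".join(lines) + "\n"
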