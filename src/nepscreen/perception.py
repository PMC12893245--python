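"""Perceive typed 3-D pharmacophore feature points on small molecules.

Feature typing is purely topological (SMARTS substructure patterns),
so feature *counts* are conformer-independent; only the positions
depend on the conformer.  The pattern set is deliberately minimal and
standard:

* HBD — N or O bearing at least one hydrogen (explicit or implicit);
* HBA — N or O with an available lone pair, excluding amide and
  aniline nitrogens, pyrrole-type NH and nitro-group oxygens;
* AR  — every 5- or 6-membered aromatic ring, represented by one
  feature at the arithmetic centroid of its ring atoms.

This suits the catechol/galloyl-rich chemistry the screen targets,
where activity tracks the number and placement of phenolic OH groups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .pharmacophore import FeatureKind

__all__ = [
    "MoleculeRecord",
    "LigandFeaturePoint",
    "perceive_features",
    "ring_centroid",
    "read_sdf",
    "read_smiles",
    "write_feature_table",
]

# Topological definitions; see module docstring.  Nitro oxygens are
# excluded by vetoing O bound to a nitrogen that carries another oxygen.
_HBD_SMARTS = Chem.MolFromSmarts("[$([#7;!H0;+0,+1]),$([#8;!H0;+0])]")
_HBA_O_SMARTS = Chem.MolFromSmarts("[#8;+0,-1;!$([#8]~[#7]~[#8])]")
_HBA_N_SMARTS = Chem.MolFromSmarts(
    "[#7;+0;!$([#7]~[#8]);!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3]c);!$([nH])]"
)


@dataclass(frozen=True)
class LigandFeaturePoint:
    """A typed feature point in a conformer's coordinate frame."""

    kind: FeatureKind
    position: np.ndarray  # (3,) Å
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if len(self.atom_indices) == 0:
            raise ValueError("atom_indices must be non-empty")


@dataclass
class MoleculeRecord:
    """A screening-library entry.

    Either wraps an RDKit molecule with one or more conformers, or
    (for pseudo-ligands used in screening benchmarks) carries
    pre-typed feature points directly in ``feature_conformers``.
    """

    id: str
    mol: Chem.Mol | None = None
    feature_conformers: list[list[LigandFeaturePoint]] | None = None

    @property
    def n_conformers(self) -> int:
        if self.feature_conformers is not None:
            return len(self.feature_conformers)
        if self.mol is not None:
            return self.mol.GetNumConformers()
        return 0

    def features(self, conformer_index: int = 0) -> list[LigandFeaturePoint]:
        """Feature points for one conformer (perceived or pre-typed)."""
        if self.feature_conformers is not None:
            return self.feature_conformers[conformer_index]
        if self.mol is None:
            raise ValueError(f"molecule {self.id!r} has neither atoms nor features")
        return perceive_features(self.mol, conformer_index)


def ring_centroid(coords: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Arithmetic centroid of ring-atom coordinates (requires >= 3)."""
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 3:
        raise ValueError("ring_centroid needs at least 3 points of dimension 3")
    return arr.mean(axis=0)


def perceive_features(mol: Chem.Mol, conformer_index: int = 0) -> list[LigandFeaturePoint]:
    """Type HBA/HBD/AR feature points on one conformer of a molecule.

    Deterministic and order-stable: output is sorted by (kind, atom
    indices).  Raises if the molecule has no 3-D coordinates.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError(
            "molecule has no conformer coordinates; generate conformers upstream "
            "(e.g. RDKit ETKDG) before feature mapping"
        )
    conf = mol.GetConformer(conformer_index)
    pos = conf.GetPositions()

    feats: list[LigandFeaturePoint] = []
    for kind, patt in ((FeatureKind.HBD, _HBD_SMARTS), (FeatureKind.HBA, _HBA_O_SMARTS)):
        for (idx,) in mol.GetSubstructMatches(patt):
            feats.append(LigandFeaturePoint(kind, pos[idx], (idx,)))
    for (idx,) in mol.GetSubstructMatches(_HBA_N_SMARTS):
        feats.append(LigandFeaturePoint(FeatureKind.HBA, pos[idx], (idx,)))

    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if len(ring) in (5, 6) and all(
            mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring
        ):
            feats.append(
                LigandFeaturePoint(
                    FeatureKind.AR, ring_centroid(pos[list(ring)]), tuple(sorted(ring))
                )
            )

    feats.sort(key=lambda f: (f.kind.value, f.atom_indices))
    return feats


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """Read a multi-record SDF into molecule records.

    Consecutive records sharing a title are treated as conformers of
    one multi-conformer molecule.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    records: list[MoleculeRecord] = []
    for mol in supplier:
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not name:
            name = f"mol{len(records)}"
        if records and records[-1].id == name:
            conf = Chem.Conformer(mol.GetConformer(0))
            records[-1].mol.AddConformer(conf, assignId=True)
        else:
            records.append(MoleculeRecord(id=name, mol=mol))
    return records


def read_smiles(path: str | Path) -> list[MoleculeRecord]:
    """Read a SMILES list (``smiles [id]`` per line); no coordinates.

    Feature typing works on these records, but pharmacophore mapping
    requires conformers to be generated first.
    """
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        mol = Chem.MolFromSmiles(parts[0])
        if mol is None:
            raise ValueError(f"line {i + 1}: cannot parse SMILES {parts[0]!r}")
        name = parts[1] if len(parts) > 1 else f"mol{i}"
        records.append(MoleculeRecord(id=name, mol=mol))
    return records


def write_feature_table(
    records: Iterable[MoleculeRecord], path: str | Path, conformer_index: int = 0
) -> None:
    """Write a per-molecule feature table CSV (id, kind, x, y, z, atoms)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "kind", "x", "y", "z", "atoms"])
        for rec in records:
            for f in rec.features(conformer_index):
                writer.writerow(
                    [
                        rec.id,
                        f.kind.value,
                        f"{f.position[0]:.4f}",
                        f"{f.position[1]:.4f}",
                        f"{f.position[2]:.4f}",
                        "+".join(map(str, f.atom_indices)),
                    ]
                )
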