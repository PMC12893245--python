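"""Geometric interaction profiling of protein–ligand(–metal) complexes
and stability metrics (RMSD, RMSF, Rg) over coordinate ensembles.

Interactions are detected by conventional geometric criteria (all
cutoffs configurable via :class:`InteractionConfig`):

* hydrogen bond — donor/acceptor heavy atoms (N/O) within 3.5 Å;
  when explicit hydrogens are present the D–H···A angle must be
  >= 120° (angle-aware mode), otherwise distance-only;
* hydrophobic — apolar carbon/sulfur pairs within 4.5 Å, where
  "apolar" means the atom has no covalently bonded N or O;
* cation–π — cationic group center (Arg CZ, Lys NZ, or a formally
  positive ligand atom) within 6.0 Å of an aromatic ring centroid;
* anion–π — carboxylate/phosphate group center within 5.0 Å of a
  ring centroid;
* metal coordination — metal ion (Zn²⁺ and friends) within 2.8 Å of a
  ligand O/N/S.

Stability metrics follow the standard definitions: RMSD against a
reference (optionally after unweighted proper-rotation superposition),
per-atom RMSF about the mean structure after superposing every frame
onto it, and the (optionally mass-weighted) radius of gyration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ComplexStructure",
    "InteractionRecord",
    "InteractionConfig",
    "FrameEnsemble",
    "detect_interactions",
    "summarize_interactions",
    "rmsd",
    "rmsf",
    "radius_of_gyration",
    "superpose",
]

_METALS = {"ZN", "MG", "CA", "MN", "FE", "CU", "NI", "CO", "NA", "K"}
_AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_ANION_GROUP_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_CATION_ATOMS = {"ARG": "CZ", "LYS": "NZ"}

# masses for the elements this module meets; fall back to 12.0
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "ZN": 65.38, "MG": 24.305, "CA": 40.078,
           "FE": 55.845, "NA": 22.990, "K": 39.098}


@dataclass(frozen=True)
class InteractionConfig:
    """Geometric cutoffs (Å / degrees) for interaction detection."""

    hbond_dist: float = 3.5
    hbond_angle: float = 120.0  # D-H...A, only with explicit hydrogens
    hydrophobic_dist: float = 4.5
    cation_pi_dist: float = 6.0
    anion_pi_dist: float = 5.0
    metal_dist: float = 2.8
    covalent_dist: float = 1.8  # bond detection for apolarity / H parents


@dataclass(frozen=True)
class InteractionRecord:
    """One typed protein(or metal)–ligand contact."""

    type: str  # hbond | hydrophobic | cation_pi | anion_pi | metal_coordination
    residue: str  # e.g. "ASN542.A"
    protein_atoms: tuple[str, ...]
    ligand_atoms: tuple[str, ...]
    distance: float  # Å
    angle: float | None = None  # degrees, hbond only


class ComplexStructure:
    """Atoms of one protein–ligand(–metal) complex, with selections.

    The ligand is selected by residue name(s); metal ions by element.
    Protein/ligand selections are disjoint by construction.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        resnames: Sequence[str],
        resnums: Sequence[int],
        chains: Sequence[str],
        coords: np.ndarray,
        het: Sequence[bool],
        ligand_resnames: Sequence[str] = ("LIG",),
    ) -> None:
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resnums = np.asarray(resnums, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.coords = np.asarray(coords, dtype=float)
        self.het = np.asarray(het, dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        lig_set = set(ligand_resnames)
        self.ligand_mask = np.array([r in lig_set for r in self.resnames])
        self.metal_mask = np.array(
            [(e in _METALS) and h for e, h in zip(self.elements, self.het)]
        )
        self.protein_mask = ~self.ligand_mask & ~self.metal_mask

    @classmethod
    def from_pdb(cls, path: str | Path, ligand_resnames: Sequence[str] = ("LIG",),
                 model_index: int = 0) -> "ComplexStructure":
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        model = st[model_index]
        names, elements, resnames, resnums, chains, coords, het = \
            [], [], [], [], [], [], []
        inferred = 0
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue  # first altloc only
                    el = atom.element.name.upper()
                    if el in ("", "X"):
                        el = "".join(c for c in atom.name if c.isalpha())[:1]
                        inferred += 1
                    names.append(atom.name)
                    elements.append(el)
                    resnames.append(res.name)
                    resnums.append(res.seqid.num)
                    chains.append(chain.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    het.append(res.het_flag == "H")
        if inferred:
            warnings.warn(
                f"{inferred} atoms lacked element records; inferred from names",
                RuntimeWarning, stacklevel=2,
            )
        return cls(names, elements, resnames, resnums, chains,
                   np.array(coords), het, ligand_resnames)

    def residue_label(self, i: int) -> str:
        return f"{self.resnames[i]}{self.resnums[i]}.{self.chains[i]}"

    def _bonded(self, i: int, cutoff: float) -> np.ndarray:
        d = np.linalg.norm(self.coords - self.coords[i], axis=1)
        mask = (d > 1e-6) & (d <= cutoff)
        return np.flatnonzero(mask)


def _apolar_mask(cs: ComplexStructure, cfg: InteractionConfig) -> np.ndarray:
    """C/S atoms with no covalently bonded N or O."""
    is_cs = np.isin(cs.elements, ["C", "S"])
    out = np.zeros(len(cs.elements), dtype=bool)
    polar = np.isin(cs.elements, ["N", "O"])
    polar_xyz = cs.coords[polar]
    for i in np.flatnonzero(is_cs):
        if polar_xyz.size:
            d = np.linalg.norm(polar_xyz - cs.coords[i], axis=1)
            if np.any(d <= cfg.covalent_dist):
                continue
        out[i] = True
    return out


def _ligand_rings(cs: ComplexStructure, cfg: InteractionConfig) -> list[np.ndarray]:
    """5/6-membered rings in the ligand via a distance-based bond graph."""
    import networkx as nx  # lazy; only needed for π detection

    idx = np.flatnonzero(cs.ligand_mask & np.isin(cs.elements, ["C", "N"]))
    if len(idx) < 5:
        return []
    g = nx.Graph()
    g.add_nodes_from(idx)
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1:]:
            if np.linalg.norm(cs.coords[i] - cs.coords[j]) <= cfg.covalent_dist:
                g.add_edge(i, j)
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) in (5, 6):
            rings.append(np.array(sorted(cycle)))
    return rings


def _ligand_anion_centers(cs, cfg):
    """Carboxylate/phosphate group centers in the ligand."""
    centers = []
    lig = np.flatnonzero(cs.ligand_mask)
    for i in lig:
        if cs.elements[i] not in ("C", "P"):
            continue
        bonded = [j for j in cs._bonded(i, cfg.covalent_dist)
                  if cs.ligand_mask[j] and cs.elements[j] == "O"]
        terminal_o = [j for j in bonded
                      if len([k for k in cs._bonded(j, cfg.covalent_dist)
                              if cs.elements[k] != "H"]) == 1]
        if len(terminal_o) >= 2:
            centers.append((tuple(terminal_o),
                            cs.coords[terminal_o].mean(axis=0)))
    # formally charged atoms are not recorded in plain PDB; name-based
    # heuristics are avoided
    return centers


def _protein_group_centers(cs, table):
    """Centroids of named sidechain atom groups per residue."""
    out = []
    key = list(zip(cs.chains, cs.resnums, cs.resnames))
    seen = {}
    for i, k in enumerate(key):
        seen.setdefault(k, []).append(i)
    for (chain, num, rname), idxs in seen.items():
        if rname not in table:
            continue
        want = table[rname]
        got = [i for i in idxs if cs.names[i] in want and cs.protein_mask[i]]
        if len(got) == len(want):
            out.append((got, cs.coords[got].mean(axis=0)))
    return out


def _hydrogens_on(cs, i, cfg):
    return [j for j in cs._bonded(i, 1.3) if cs.elements[j] == "H"]


def detect_interactions(
    cs: ComplexStructure, config: InteractionConfig | None = None
) -> list[InteractionRecord]:
    """Detect typed protein(metal)–ligand contacts; one record per atom
    pair (or group pair for π/anion interactions)."""
    cfg = config or InteractionConfig()
    if not np.any(cs.ligand_mask):
        raise ValueError("ligand selection is empty")
    records: list[InteractionRecord] = []

    lig_idx = np.flatnonzero(cs.ligand_mask)
    prot_idx = np.flatnonzero(cs.protein_mask)
    has_h = bool(np.any(cs.elements == "H"))

    # --- hydrogen bonds -------------------------------------------------
    lig_no = [i for i in lig_idx if cs.elements[i] in ("N", "O")]
    prot_no = [i for i in prot_idx if cs.elements[i] in ("N", "O")]
    for i in lig_no:
        for j in prot_no:
            d = float(np.linalg.norm(cs.coords[i] - cs.coords[j]))
            if d > cfg.hbond_dist:
                continue
            angle = None
            if has_h:
                ok, angle = _hbond_angle_ok(cs, i, j, cfg)
                if not ok:
                    continue
            records.append(InteractionRecord(
                "hbond", cs.residue_label(j), (str(cs.names[j]),),
                (str(cs.names[i]),), d, angle))

    # --- hydrophobic ----------------------------------------------------
    apolar = _apolar_mask(cs, cfg)
    for i in lig_idx[apolar[lig_idx]]:
        for j in prot_idx[apolar[prot_idx]]:
            d = float(np.linalg.norm(cs.coords[i] - cs.coords[j]))
            if d <= cfg.hydrophobic_dist:
                records.append(InteractionRecord(
                    "hydrophobic", cs.residue_label(j), (str(cs.names[j]),),
                    (str(cs.names[i]),), d))

    # --- pi systems -----------------------------------------------------
    lig_rings = _ligand_rings(cs, cfg)
    prot_rings = _protein_group_centers(cs, _AROMATIC_RING_ATOMS)
    prot_cations = [
        ([i], cs.coords[i]) for i in prot_idx
        if _CATION_ATOMS.get(str(cs.resnames[i])) == str(cs.names[i])
    ]
    prot_anions = _protein_group_centers(cs, _ANION_GROUP_ATOMS)
    lig_anions = _ligand_anion_centers(cs, cfg)

    for atoms, center in prot_cations:  # protein cation vs ligand ring
        for ring in lig_rings:
            centroid = cs.coords[ring].mean(axis=0)
            d = float(np.linalg.norm(center - centroid))
            if d <= cfg.cation_pi_dist:
                records.append(InteractionRecord(
                    "cation_pi", cs.residue_label(atoms[0]),
                    tuple(str(cs.names[a]) for a in atoms),
                    tuple(str(cs.names[a]) for a in ring), d))
    for atoms, center in prot_anions:  # protein anion vs ligand ring
        for ring in lig_rings:
            centroid = cs.coords[ring].mean(axis=0)
            d = float(np.linalg.norm(center - centroid))
            if d <= cfg.anion_pi_dist:
                records.append(InteractionRecord(
                    "anion_pi", cs.residue_label(atoms[0]),
                    tuple(str(cs.names[a]) for a in atoms),
                    tuple(str(cs.names[a]) for a in ring), d))
    for ring_atoms, center in prot_rings:  # ligand anion vs protein ring
        for o_atoms, acenter in lig_anions:
            d = float(np.linalg.norm(center - acenter))
            if d <= cfg.anion_pi_dist:
                records.append(InteractionRecord(
                    "anion_pi", cs.residue_label(ring_atoms[0]),
                    tuple(str(cs.names[a]) for a in ring_atoms),
                    tuple(str(cs.names[a]) for a in o_atoms), d))

    # --- metal coordination ---------------------------------------------
    for m in np.flatnonzero(cs.metal_mask):
        for i in lig_idx:
            if cs.elements[i] not in ("O", "N", "S"):
                continue
            d = float(np.linalg.norm(cs.coords[m] - cs.coords[i]))
            if d <= cfg.metal_dist:
                records.append(InteractionRecord(
                    "metal_coordination", cs.residue_label(m),
                    (str(cs.names[m]),), (str(cs.names[i]),), d))
    return records


def _hbond_angle_ok(cs, i, j, cfg):
    """Angle-aware H-bond test: some H on either heavy atom must make a
    D-H...A angle >= the cutoff; returns (ok, best_angle)."""
    best = None
    for donor, acceptor in ((i, j), (j, i)):
        for h in _hydrogens_on(cs, donor, cfg):
            v1 = cs.coords[donor] - cs.coords[h]
            v2 = cs.coords[acceptor] - cs.coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if best is None or ang > best:
                best = ang
    if best is None:  # no H on either partner: fall back to distance-only
        return True, None
    return best >= cfg.hbond_angle, best


def summarize_interactions(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Residue-level summary: one row per (type, residue), min distance."""
    rows = [
        {"type": r.type, "residue": r.residue, "distance": r.distance}
        for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=["type", "residue", "n_contacts",
                                     "min_distance"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["type", "residue"])
             .agg(n_contacts=("distance", "size"),
                  min_distance=("distance", "min"))
             .reset_index())
    return out.sort_values(["type", "residue"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ensemble metrics
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Unweighted proper-rotation (Kabsch) superposition of ``mobile``
    onto ``reference``; returns the transformed coordinates."""
    X = np.asarray(mobile, float)
    Y = np.asarray(reference, float)
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (X - xc) @ R.T + yc


def rmsd(frame: np.ndarray, reference: np.ndarray,
         selection: np.ndarray | None = None, superpose_first: bool = True
         ) -> float:
    """RMSD between a frame and a reference over a selection."""
    X = np.asarray(frame, float)
    Y = np.asarray(reference, float)
    if selection is not None:
        X, Y = X[selection], Y[selection]
    if X.shape != Y.shape:
        raise ValueError("selection sizes differ between frame and reference")
    if superpose_first:
        X = superpose(X, Y)
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))


class FrameEnsemble:
    """An ordered stack of conformations of the same atom set."""

    def __init__(self, coords: np.ndarray, names=None, elements=None,
                 resnames=None, resnums=None, frame_interval_ps: float = 500.0
                 ) -> None:
        self.coords = np.asarray(coords, float)  # (F, N, 3)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        self.names = names
        self.elements = elements
        self.resnames = resnames
        self.resnums = resnums
        self.frame_interval_ps = frame_interval_ps

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_pdb(cls, path: str | Path, frame_interval_ps: float = 500.0
                 ) -> "FrameEnsemble":
        """Read a multi-model (MODEL/ENDMDL) PDB as an ensemble."""
        st = gemmi.read_structure(str(path))
        frames, names, elements, resnames, resnums = [], None, None, None, None
        for model in st:
            xyz, nm, el, rn, rq = [], [], [], [], []
            for chain in model:
                for res in chain:
                    for atom in res:
                        if atom.altloc not in ("", "\x00", "A"):
                            continue
                        xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        nm.append(atom.name)
                        el.append(atom.element.name.upper())
                        rn.append(res.name)
                        rq.append(res.seqid.num)
            frames.append(xyz)
            if names is None:
                names, elements, resnames, resnums = nm, el, rn, rq
        coords = np.asarray(frames, float)
        if coords.ndim != 3:
            raise ValueError("models have differing atom counts")
        return cls(coords, names, elements, resnames, resnums,
                   frame_interval_ps)

    def rmsd_series(self, selection=None, reference_frame: int = 0,
                    superpose_first: bool = True) -> np.ndarray:
        """Per-frame RMSD against a reference frame (default: the first,
        i.e. referenced against the initial structure)."""
        ref = self.coords[reference_frame]
        return np.array([
            rmsd(f, ref, selection, superpose_first) for f in self.coords
        ])

    def rg_series(self, selection=None, mass_weighted: bool = False
                  ) -> np.ndarray:
        masses = None
        if mass_weighted:
            if self.elements is None:
                raise ValueError("mass weighting needs element metadata")
            masses = np.array([_MASSES.get(e, 12.0) for e in self.elements])
            if selection is not None:
                masses = masses[selection]
        out = []
        for f in self.coords:
            sel = f if selection is None else f[selection]
            out.append(radius_of_gyration(sel, masses))
        return np.array(out)


def rmsf(ensemble: FrameEnsemble | np.ndarray,
         selection: np.ndarray | None = None) -> np.ndarray:
    """Per-atom RMS fluctuation about the mean structure.

    Every frame is superposed onto the ensemble mean, the mean is
    recomputed once from the superposed frames, and the fluctuation is
    measured about that refined mean.
    """
    coords = ensemble.coords if isinstance(ensemble, FrameEnsemble) else \
        np.asarray(ensemble, float)
    if selection is not None:
        coords = coords[:, selection]
    if coords.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mean = coords.mean(axis=0)
    aligned = np.array([superpose(f, mean) for f in coords])
    mean = aligned.mean(axis=0)  # one refinement pass
    dev2 = np.sum((aligned - mean) ** 2, axis=2)  # (F, N)
    return np.sqrt(dev2.mean(axis=0))


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None
                       ) -> float:
    """Rg = sqrt( Σ m_i ||r_i − r_cm||² / Σ m_i ); unweighted if no masses."""
    X = np.asarray(coords, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one atom")
    m = np.ones(X.shape[0]) if masses is None else np.asarray(masses, float)
    cm = (m[:, None] * X).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((X - cm) ** 2, axis=1)).sum() / m.sum()))
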