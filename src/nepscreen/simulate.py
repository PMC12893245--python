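"""Seeded generators for every input the analysis pipeline consumes.

Each generator takes an explicit integer seed (or ``numpy`` Generator),
returns the in-memory objects the corresponding analysis module reads,
and a :class:`GroundTruthManifest` recording the generating parameters
so recovery tests can compare fitted values against the truth.  The
same seed always reproduces the same output, byte for byte when
written to disk.

What the generators emulate (and what they do not) is documented in
the package's methods note; briefly:

* ``make_feature_library`` — a virtual-screening library as labelled
  pharmacophore feature-point sets: planted perfect hits, jittered
  near-hits, feature-deficient misses and random filler;
* ``make_molecule_library`` — a small companion library of genuine
  polyphenol-like molecules with embedded 3-D conformers, for
  end-to-end perception tests;
* ``make_assay_dataset`` — linear fluorescence progress curves (reads
  every 20 min over 60 min) whose slopes encode 4PL dose–response
  inhibition with multiplicative noise;
* ``make_sensorgram_set`` — closed-form 1:1 association/dissociation
  sensorgrams with additive Gaussian noise;
* ``make_toy_complex`` — a minimal protein–ligand(–Zn) complex with
  interactions planted at geometries satisfying (or, when flagged as
  violations, exceeding by a stated margin) each detection rule;
* ``make_ensemble`` — a multi-frame coordinate ensemble with known
  per-atom fluctuation magnitude and optional subdomain drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pharmacophore import FeatureKind, PharmacophoreModel
from .perception import LigandFeaturePoint, MoleculeRecord
from .lspr import Sensorgram, model_response
from .structure import ComplexStructure, FrameEnsemble, InteractionConfig

__all__ = [
    "GroundTruthManifest",
    "make_feature_library",
    "make_molecule_library",
    "make_assay_dataset",
    "make_sensorgram_set",
    "make_toy_complex",
    "make_ensemble",
    "write_library_json",
    "read_library_json",
]


@dataclass
class GroundTruthManifest:
    """Generating parameters of one synthetic dataset."""

    generator: str
    seed: int
    parameters: dict
    files: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# screening library
# ---------------------------------------------------------------------------

def make_feature_library(
    n: int,
    model: PharmacophoreModel,
    n_perfect: int = 1,
    n_near: int = 5,
    n_miss: int = 10,
    jitter_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> tuple[list[MoleculeRecord], GroundTruthManifest]:
    """Pseudo-ligand library as labelled feature-point sets.

    perfect — feature points exactly at the model centers under a
    random rigid motion; near — centers plus isotropic Gaussian jitter
    of ``jitter_sd`` per coordinate; miss — all features of one
    randomly chosen kind removed (unscoreable at max_omitted=0);
    filler — random feature points in a 10 Å box.
    """
    if n_perfect + n_near + n_miss > n:
        raise ValueError("n_perfect + n_near + n_miss must not exceed n")
    min_tol = min(f.tolerance for f in model.features)
    if jitter_sd >= min_tol:
        import warnings

        warnings.warn(
            "jitter_sd >= smallest tolerance: near-hits may fail to map",
            RuntimeWarning, stacklevel=2,
        )
    rng = _rng(seed)
    centers = model.centers
    kinds = [f.kind for f in model.features]
    roles = (["perfect"] * n_perfect + ["near"] * n_near + ["miss"] * n_miss
             + ["filler"] * (n - n_perfect - n_near - n_miss))

    records, manifest_entries = [], []
    for i, role in enumerate(roles):
        cid = f"CPD{i:04d}"
        R = _random_rotation(rng)
        t = rng.uniform(-10, 10, size=3)
        if role in ("perfect", "near"):
            pts = centers @ R.T + t
            if role == "near":
                pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
            feats = [LigandFeaturePoint(k, p, (j,))
                     for j, (k, p) in enumerate(zip(kinds, pts))]
        elif role == "miss":
            drop = FeatureKind(rng.choice([k.value for k in set(kinds)]))
            kept = [(k, c) for k, c in zip(kinds, centers) if k != drop]
            pts = np.array([c for _, c in kept]) @ R.T + t
            feats = [LigandFeaturePoint(k, p, (j,))
                     for j, ((k, _), p) in enumerate(zip(kept, pts))]
        else:  # filler: random counts and random geometry
            counts = {
                FeatureKind.HBA: int(rng.integers(2, 6)),
                FeatureKind.HBD: int(rng.integers(1, 4)),
                FeatureKind.AR: int(rng.integers(0, 3)),
            }
            feats = []
            j = 0
            for k, cnt in counts.items():
                for _ in range(cnt):
                    feats.append(LigandFeaturePoint(
                        k, rng.uniform(-5, 5, size=3), (j,)))
                    j += 1
        records.append(MoleculeRecord(id=cid, feature_conformers=[feats]))
        manifest_entries.append({"compound_id": cid, "role": role})

    manifest = GroundTruthManifest(
        generator="make_feature_library",
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        parameters={
            "n": n, "n_perfect": n_perfect, "n_near": n_near,
            "n_miss": n_miss, "jitter_sd": jitter_sd, "model": model.name,
            "sum_of_weights": model.sum_of_weights,
            "compounds": manifest_entries,
        },
    )
    return records, manifest


_LIBRARY_SMILES = [
    # polyphenol-adjacent chemistry: glycerol-like and galloyl-like scaffolds
    ("glycerol", "OCC(O)CO"),
    ("phenol", "Oc1ccccc1"),
    ("catechol", "Oc1ccccc1O"),
    ("pyrogallol", "Oc1cccc(O)c1O"),
    ("gallic_acid", "OC(=O)c1cc(O)c(O)c(O)c1"),
    ("methyl_gallate", "COC(=O)c1cc(O)c(O)c(O)c1"),
    ("benzamide", "NC(=O)c1ccccc1"),
    ("tyramine", "NCCc1ccc(O)cc1"),
]


def make_molecule_library(
    seed: int = 0, n_conformers: int = 3
) -> tuple[list[MoleculeRecord], GroundTruthManifest]:
    """Small genuine-molecule library with embedded ETKDG conformers."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    records = []
    for name, smi in _LIBRARY_SMILES:
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
        records.append(MoleculeRecord(id=name, mol=mol))
    manifest = GroundTruthManifest(
        generator="make_molecule_library", seed=int(seed),
        parameters={"n_conformers": n_conformers,
                    "smiles": dict(_LIBRARY_SMILES)},
    )
    return records, manifest


def write_library_json(records: Sequence[MoleculeRecord], path: str | Path
                       ) -> None:
    """Persist a feature-point pseudo-ligand library as JSON."""
    data = []
    for rec in records:
        if rec.feature_conformers is None:
            raise ValueError(f"{rec.id}: only feature-point records are "
                             "JSON-serialisable; use SDF for real molecules")
        data.append({
            "id": rec.id,
            "conformers": [
                [{"kind": f.kind.value,
                  "position": [float(x) for x in f.position],
                  "atoms": list(f.atom_indices)} for f in conf]
                for conf in rec.feature_conformers
            ],
        })
    Path(path).write_text(json.dumps(data, indent=1))


def read_library_json(path: str | Path) -> list[MoleculeRecord]:
    data = json.loads(Path(path).read_text())
    out = []
    for entry in data:
        confs = [
            [LigandFeaturePoint(FeatureKind(f["kind"]),
                                np.asarray(f["position"], float),
                                tuple(f["atoms"])) for f in conf]
            for conf in entry["conformers"]
        ]
        out.append(MoleculeRecord(id=entry["id"], feature_conformers=confs))
    return out


# ---------------------------------------------------------------------------
# enzymatic assay
# ---------------------------------------------------------------------------

def make_assay_dataset(
    compounds: Sequence[tuple[str, float, float]],
    concentrations: Sequence[float],
    replicates: int = 3,
    cv: float = 0.05,
    seed: int | np.random.Generator = 0,
    times: Sequence[float] = (0.0, 20.0, 40.0, 60.0),
    control_slope: float = 10.0,
    baseline_rfu: float = 100.0,
    control_label: str = "DMSO",
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Fluorescence progress curves encoding 4PL dose–response truth.

    ``compounds`` is a list of (id, true IC50 µM, hill).  Each
    replicate set gets its own control wells; test-well slopes are the
    control slope scaled by ``1 - inhibition(c)/100`` under the 4PL
    (bottom 0, top 100), and each RFU reading carries multiplicative
    Gaussian noise of coefficient of variation ``cv``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _rng(seed)
    t = np.asarray(times, float)
    rows = []
    well = 0
    for rep in range(replicates):
        rfu = baseline_rfu + control_slope * t
        noisy = rfu * (1.0 + rng.normal(0.0, cv, size=t.shape))
        for ti, yi in zip(t, noisy):
            rows.append({"well_id": f"W{well:04d}", "compound_id": control_label,
                         "concentration_uM": 0.0, "time_min": ti, "rfu": yi})
        well += 1
    for cid, ic50, hill in compounds:
        for conc in concentrations:
            inhibition = 100.0 / (1.0 + (ic50 / conc) ** hill)
            slope = control_slope * (1.0 - inhibition / 100.0)
            for rep in range(replicates):
                rfu = baseline_rfu + slope * t
                noisy = rfu * (1.0 + rng.normal(0.0, cv, size=t.shape))
                for ti, yi in zip(t, noisy):
                    rows.append({"well_id": f"W{well:04d}", "compound_id": cid,
                                 "concentration_uM": float(conc),
                                 "time_min": ti, "rfu": yi})
                well += 1
    df = pd.DataFrame(rows)
    manifest = GroundTruthManifest(
        generator="make_assay_dataset",
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        parameters={
            "compounds": [{"compound_id": c, "ic50_uM": i, "hill": h}
                          for c, i, h in compounds],
            "concentrations_uM": [float(c) for c in concentrations],
            "replicates": replicates, "cv": cv,
            "times_min": list(map(float, times)),
            "control_slope": control_slope, "baseline_rfu": baseline_rfu,
            "control_label": control_label,
        },
    )
    return df, manifest


# ---------------------------------------------------------------------------
# sensorgrams
# ---------------------------------------------------------------------------

def make_sensorgram_set(
    kon: float,
    koff: float,
    rmax: float,
    concentrations: Sequence[float],
    sigma: float = 2.0,
    seed: int | np.random.Generator = 0,
    analyte_id: str = "analyte",
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    dt: float = 2.0,
) -> tuple[list[Sensorgram], GroundTruthManifest]:
    """Closed-form 1:1 sensorgrams with additive Gaussian noise (RU)."""
    rng = _rng(seed)
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    grams = []
    for conc in concentrations:
        clean = model_response(kon, koff, rmax, conc, t, t_assoc)
        noisy = clean + rng.normal(0.0, sigma, size=t.shape)
        grams.append(Sensorgram(analyte_id, float(conc), t, noisy, t_assoc))
    manifest = GroundTruthManifest(
        generator="make_sensorgram_set",
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        parameters={
            "kon_per_uM_s": kon, "koff_per_s": koff, "kd_uM": koff / kon,
            "rmax_RU": rmax, "sigma_RU": sigma,
            "concentrations_uM": [float(c) for c in concentrations],
            "t_assoc_s": t_assoc, "t_dissoc_s": t_dissoc, "dt_s": dt,
        },
    )
    return grams, manifest


def sensorgrams_to_dataframe(grams: Sequence[Sensorgram]) -> pd.DataFrame:
    rows = []
    for g in grams:
        for t, r in zip(g.times, g.response):
            rows.append({
                "analyte_id": g.analyte_id,
                "concentration_uM": g.concentration,
                "time_s": t, "response_RU": r,
                "phase": "association" if t <= g.injection_end
                else "dissociation",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteraction:
    """One contact the toy complex must satisfy (or deliberately violate
    by ``margin`` beyond the cutoff when ``violate`` is set)."""

    type: str  # hbond | hydrophobic | cation_pi | anion_pi | metal_coordination
    violate: bool = False


# direction slots: pi-type interactions use the ring normal (±z); the
# rest fan out in the ring plane, far enough apart to avoid cross-talk
_PLANE_ANGLES = [0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0]
_MARGIN = 0.3  # Å beyond the cutoff for planted violations


def make_toy_complex(
    plan: Sequence[PlantedInteraction],
    seed: int | np.random.Generator = 0,
    hydrogens: bool = False,
    config: InteractionConfig | None = None,
) -> tuple[ComplexStructure, GroundTruthManifest]:
    """Minimal complex with each planted contact at a safe margin
    inside (or outside, for violations) its cutoff.

    The ligand is a benzene-like six-carbon ring at the origin plus one
    partner atom per planted site; protein fragments are placed along
    well-separated directions.  The whole complex is finally subjected
    to a seeded random rigid motion, so detectors must be rigid-motion
    invariant to reproduce the manifest.
    """
    cfg = config or InteractionConfig()
    rng = _rng(seed)
    pi_types = ("cation_pi", "anion_pi")
    n_pi = sum(1 for p in plan if p.type in pi_types)
    n_plane = len(plan) - n_pi
    if n_pi > 2 or n_plane > len(_PLANE_ANGLES):
        raise ValueError("too many planted interactions for the layout")

    names, elements, resnames, resnums, chains, coords, het = \
        [], [], [], [], [], [], []

    def add(name, el, rname, rnum, chain, xyz, is_het):
        names.append(name); elements.append(el); resnames.append(rname)
        resnums.append(rnum); chains.append(chain)
        coords.append(np.asarray(xyz, float)); het.append(is_het)

    # ligand ring: hexagon of C, radius 1.39 Å, in the xy plane
    for k in range(6):
        ang = np.deg2rad(60.0 * k)
        add(f"C{k + 1}", "C", "LIG", 1, "L",
            [1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0], True)

    expected = []
    plane_slots = iter(_PLANE_ANGLES)
    pi_slots = iter([np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])])
    resnum = 100
    lig_atom_n = 0

    for p in plan:
        resnum += 1
        if p.type in pi_types:
            u = next(pi_slots)
        else:
            ang = np.deg2rad(next(plane_slots))
            u = np.array([np.cos(ang), np.sin(ang), 0.0])

        if p.type == "hbond":
            d = cfg.hbond_dist + _MARGIN if p.violate else \
                float(rng.uniform(2.7, 3.1))
            lig_atom_n += 1
            o_pos = 4.0 * u
            add(f"O{lig_atom_n}", "O", "LIG", 1, "L", o_pos, True)
            n_pos = o_pos + d * u
            add("N", "N", "GLY", resnum, "A", n_pos, False)
            add("CA", "C", "GLY", resnum, "A", n_pos + 1.45 * u, False)
            angle = None
            if hydrogens:
                # H on the protein N, ~20° off the N->O axis: D-H...A ≈ 160°
                axis = -u
                perp = np.array([-u[1], u[0], 0.0])
                if np.linalg.norm(perp) < 1e-9:
                    perp = np.array([1.0, 0.0, 0.0])
                hdir = np.cos(np.deg2rad(20)) * axis + \
                    np.sin(np.deg2rad(20)) * perp
                h_pos = n_pos + 1.0 * hdir
                add("H", "H", "GLY", resnum, "A", h_pos, False)
                v1, v2 = n_pos - h_pos, o_pos - h_pos
                angle = float(np.degrees(np.arccos(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))))
            expected.append({"type": "hbond", "residue": f"GLY{resnum}.A",
                             "distance": d, "angle": angle,
                             "detected": not p.violate})
        elif p.type == "hydrophobic":
            d = cfg.hydrophobic_dist + _MARGIN if p.violate else \
                float(rng.uniform(3.6, 4.2))
            lig_atom_n += 1
            c_pos = 4.0 * u
            add(f"C{6 + lig_atom_n}", "C", "LIG", 1, "L", c_pos, True)
            cb = c_pos + d * u
            add("CB", "C", "ALA", resnum, "A", cb, False)
            add("CA", "C", "ALA", resnum, "A", cb + 1.52 * u, False)
            add("N", "N", "ALA", resnum, "A", cb + 1.52 * u + 1.45 * u, False)
            expected.append({"type": "hydrophobic", "residue": f"ALA{resnum}.A",
                             "distance": d, "detected": not p.violate})
        elif p.type == "metal_coordination":
            d = cfg.metal_dist + _MARGIN if p.violate else \
                float(rng.uniform(2.0, 2.3))
            lig_atom_n += 1
            o_pos = 4.0 * u
            add(f"O{lig_atom_n}", "O", "LIG", 1, "L", o_pos, True)
            add("ZN", "ZN", "ZN", resnum, "A", o_pos + d * u, True)
            expected.append({"type": "metal_coordination",
                             "residue": f"ZN{resnum}.A", "distance": d,
                             "detected": not p.violate})
        elif p.type == "cation_pi":
            d = cfg.cation_pi_dist + _MARGIN if p.violate else \
                float(rng.uniform(4.0, 5.2))
            cz = d * u  # distance measured from the ring centroid (origin)
            add("CZ", "C", "ARG", resnum, "A", cz, False)
            add("NH1", "N", "ARG", resnum, "A", cz + 1.33 * u
                + np.array([0.6, 0.0, 0.0]), False)
            add("NH2", "N", "ARG", resnum, "A", cz + 1.33 * u
                - np.array([0.6, 0.0, 0.0]), False)
            add("NE", "N", "ARG", resnum, "A", cz + np.array([0.0, 1.33, 0.0]),
                False)
            expected.append({"type": "cation_pi", "residue": f"ARG{resnum}.A",
                             "distance": d, "detected": not p.violate})
        elif p.type == "anion_pi":
            d = cfg.anion_pi_dist + _MARGIN if p.violate else \
                float(rng.uniform(3.6, 4.4))
            mid = d * u
            sep = np.array([1.1, 0.0, 0.0])
            add("OD1", "O", "ASP", resnum, "A", mid + sep, False)
            add("OD2", "O", "ASP", resnum, "A", mid - sep, False)
            add("CG", "C", "ASP", resnum, "A", mid + 0.7 * u, False)
            expected.append({"type": "anion_pi", "residue": f"ASP{resnum}.A",
                             "distance": d, "detected": not p.violate})
        else:
            raise ValueError(f"unknown interaction type {p.type!r}")

    # seeded global rigid motion: detection must be invariant to it
    R = _random_rotation(rng)
    t = rng.uniform(-20, 20, size=3)
    xyz = np.asarray(coords) @ R.T + t

    cs = ComplexStructure(names, elements, resnames, resnums, chains, xyz,
                          het, ligand_resnames=("LIG",))
    manifest = GroundTruthManifest(
        generator="make_toy_complex",
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        parameters={"plan": [asdict(p) for p in plan],
                    "hydrogens": hydrogens, "expected": expected},
    )
    return cs, manifest


def write_complex_pdb(cs: ComplexStructure, path: str | Path) -> None:
    """Write a complex as a minimal (single-model) PDB file."""
    lines = []
    for i in range(len(cs.names)):
        rec = "HETATM" if cs.het[i] else "ATOM  "
        x, y, z = cs.coords[i]
        lines.append(
            f"{rec}{i + 1:5d} {cs.names[i]:<4s} {cs.resnames[i]:<3s} "
            f"{cs.chains[i]}{cs.resnums[i]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{cs.elements[i]:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def make_ensemble(
    n_frames: int,
    n_atoms: int = 60,
    per_atom_sd: float | np.ndarray = 1.0,
    drift: tuple[slice, np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
    frame_interval_ps: float = 500.0,
) -> tuple[FrameEnsemble, GroundTruthManifest]:
    """Gaussian-fluctuation ensemble about a helix-like base structure.

    ``per_atom_sd`` is the target RMS 3-D displacement magnitude per
    atom (per-coordinate sigma = sd/sqrt(3)), so a long ensemble's
    RMSF converges to it.  ``drift`` optionally moves an atom slice by
    a constant vector per frame, emulating a mobile subdomain.
    """
    rng = _rng(seed)
    sd = np.broadcast_to(np.asarray(per_atom_sd, float), (n_atoms,))
    # base: gentle helix, 1.5 Å rise, 5 atoms per turn
    k = np.arange(n_atoms)
    base = np.stack([
        5.0 * np.cos(2 * np.pi * k / 5.0),
        5.0 * np.sin(2 * np.pi * k / 5.0),
        1.5 * k,
    ], axis=1)
    sigma_coord = sd[:, None] / np.sqrt(3.0)
    frames = base[None, :, :] + rng.normal(
        0.0, 1.0, size=(n_frames, n_atoms, 3)) * sigma_coord[None, :, :]
    if drift is not None:
        sl, vel = drift
        vel = np.asarray(vel, float)
        for f in range(n_frames):
            frames[f, sl] += f * vel
    ens = FrameEnsemble(
        frames,
        names=["CA"] * n_atoms,
        elements=["C"] * n_atoms,
        resnames=["ALA"] * n_atoms,
        resnums=list(range(1, n_atoms + 1)),
        frame_interval_ps=frame_interval_ps,
    )
    manifest = GroundTruthManifest(
        generator="make_ensemble",
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        parameters={
            "n_frames": n_frames, "n_atoms": n_atoms,
            "per_atom_sd": [float(s) for s in sd],
            "drift": None if drift is None else {
                "start": drift[0].start, "stop": drift[0].stop,
                "velocity": [float(v) for v in np.asarray(drift[1], float)],
            },
            "frame_interval_ps": frame_interval_ps,
        },
    )
    return ens, manifest


def write_ensemble_pdb(ens: FrameEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model (MODEL/ENDMDL) PDB."""
    lines = []
    for f in range(ens.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i in range(ens.coords.shape[1]):
            x, y, z = ens.coords[f, i]
            name = ens.names[i] if ens.names else "CA"
            rn = ens.resnames[i] if ens.resnames else "ALA"
            rq = ens.resnums[i] if ens.resnums else i + 1
            el = ens.elements[i] if ens.elements else "C"
            lines.append(
                f"ATOM  {i + 1:5d} {name:<4s} {rn:<3s} A{rq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{el:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
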