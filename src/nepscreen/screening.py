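"""Ligand–pharmacophore mapping: pose search, fit maximisation, ranking.

Given a pharmacophore model and a ligand conformer's typed feature
points, the screen must find (a) a *correspondence* — an injective,
kind-respecting assignment of model features to ligand feature points —
and (b) the rigid motion of the conformer that maximises the fit value
under that correspondence.

Because the fit value penalises each mapped feature by
``W * (D/T)**2``, maximising F for a fixed correspondence is the same
as minimising the weighted sum of square displacements with alignment
weights ``w = W / T**2``.  That least-squares problem has the
closed-form weighted Kabsch (SVD) solution, so for each correspondence
the optimal pose is exact; the search over correspondences is
exhaustive up to a cap, beyond which a greedy beam search takes over
and the result is flagged approximate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pharmacophore import FeatureKind, PharmacophoreModel, fit_value, MappedFeature
from .perception import LigandFeaturePoint, MoleculeRecord

__all__ = [
    "RigidTransform",
    "Correspondence",
    "FitResult",
    "ScreenHit",
    "UnderdeterminedError",
    "align_weighted",
    "best_fit",
    "screen",
]

ENUMERATION_CAP = 100_000  # correspondences per conformer before beam fallback
BEAM_WIDTH = 50


class UnderdeterminedError(ValueError):
    """Fewer than 3 point pairs: rigid alignment has no unique solution."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation det = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    well_determined: bool = True

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthogonal (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class Correspondence:
    """Injective, kind-respecting pairing (feature_id, ligand index)."""

    pairs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        fids = [p[0] for p in self.pairs]
        lidx = [p[1] for p in self.pairs]
        if len(set(fids)) != len(fids) or len(set(lidx)) != len(lidx):
            raise ValueError("correspondence must be injective both ways")


@dataclass
class FitResult:
    """Best pose of one compound against a model."""

    compound_id: str
    conformer_index: int
    correspondence: Correspondence
    transform: RigidTransform
    displacements: dict[str, float]  # feature_id -> D (Å)
    fit: float
    mapped_count: int
    approximate: bool = False  # True when found by beam search, not enumeration

    def omitted(self, model: PharmacophoreModel) -> list[str]:
        mapped = {fid for fid, _ in self.correspondence.pairs}
        return [f.id for f in model.features if f.id not in mapped]


@dataclass(frozen=True)
class ScreenHit:
    rank: int
    compound_id: str
    result: FitResult


def align_weighted(
    model_points: Sequence[tuple[np.ndarray, float]],
    ligand_points: Sequence[np.ndarray] | np.ndarray,
) -> RigidTransform:
    """Weighted rigid superposition of ligand points onto model centers.

    Returns the proper rotation + translation minimising
    ``sum_c w_c * ||T(x_c) - center_c||**2`` (weighted Kabsch via SVD).
    Degenerate geometry (collinear or coincident points) yields a
    best-effort solution flagged ``well_determined=False``.
    """
    centers = np.asarray([c for c, _ in model_points], dtype=float)
    weights = np.asarray([w for _, w in model_points], dtype=float)
    X = np.asarray(ligand_points, dtype=float)
    if len(centers) != len(X):
        raise ValueError("model and ligand point lists must have equal length")
    if len(centers) < 3:
        raise UnderdeterminedError("need at least 3 point pairs for a unique rotation")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    wsum = weights.sum()
    xc = (weights[:, None] * X).sum(axis=0) / wsum
    yc = (weights[:, None] * centers).sum(axis=0) / wsum
    H = (X - xc).T @ (weights[:, None] * (centers - yc))
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T

    # rank < 2 => rotation about the degenerate axis is unconstrained
    well = S[1] > 1e-8 * max(S[0], 1.0)
    if not well:
        warnings.warn(
            "degenerate (collinear/coincident) geometry: alignment is best-effort",
            RuntimeWarning,
            stacklevel=2,
        )
    t = yc - R @ xc
    return RigidTransform(R, t, well_determined=bool(well))


# ---------------------------------------------------------------------------
# correspondence search
# ---------------------------------------------------------------------------

def _group_by_kind(points: Sequence[LigandFeaturePoint]) -> dict[FeatureKind, list[int]]:
    groups: dict[FeatureKind, list[int]] = {}
    for i, p in enumerate(points):
        groups.setdefault(p.kind, []).append(i)
    return groups


def _count_assignments(model_feats, groups) -> int:
    """Number of injective kind-respecting assignments for one feature subset."""
    total = 1
    by_kind: dict[FeatureKind, int] = {}
    for f in model_feats:
        by_kind[f.kind] = by_kind.get(f.kind, 0) + 1
    for kind, need in by_kind.items():
        have = len(groups.get(kind, []))
        if have < need:
            return 0
        # falling factorial have! / (have-need)!
        cnt = 1
        for j in range(need):
            cnt *= have - j
        total *= cnt
    return total


def _enumerate_assignments(model_feats, groups):
    """Yield tuples of ligand indices matching model_feats order, injectively."""
    by_kind: dict[FeatureKind, list[int]] = {}
    for i, f in enumerate(model_feats):
        by_kind.setdefault(f.kind, []).append(i)
    kind_perms = []
    for kind, positions in by_kind.items():
        pool = groups.get(kind, [])
        kind_perms.append((positions, list(itertools.permutations(pool, len(positions)))))
        if not kind_perms[-1][1]:
            return
    for combo in itertools.product(*(perms for _, perms in kind_perms)):
        assign = [0] * len(model_feats)
        for (positions, _), perm in zip(kind_perms, combo):
            for pos, lig in zip(positions, perm):
                assign[pos] = lig
        yield tuple(assign)


def _score_correspondence(model_feats, lig_positions, assign):
    """Align one correspondence and score it; None if pose is rejected."""
    pts = [(f.center, f.weight / f.tolerance**2) for f in model_feats]
    X = np.array([lig_positions[i] for i in assign])
    transform = align_weighted(pts, X)
    moved = transform.apply(X)
    disp = np.linalg.norm(moved - np.array([f.center for f in model_feats]), axis=1)
    if np.any(disp > np.array([f.tolerance for f in model_feats])):
        return None  # some mapped feature left its tolerance sphere
    score = float(
        sum(
            f.weight * (1.0 - (d / f.tolerance) ** 2)
            for f, d in zip(model_feats, disp)
        )
    )
    return transform, disp, score


def _beam_search(model, points, groups, min_pairs):
    """Greedy beam search over feature-assignment order (weight-descending).

    Used only above the enumeration cap; the best full assignment found
    is returned (may be suboptimal, callers flag it approximate).
    """
    order = sorted(range(len(model.features)), key=lambda i: -model.features[i].weight)
    positions = [p.position for p in points]
    # partial state: (assigned dict feature_pos -> ligand idx, used set)
    beams: list[dict[int, int]] = [{}]
    for fi in order:
        kind = model.features[fi].kind
        candidates = groups.get(kind, [])
        new_beams: list[tuple[float, dict[int, int]]] = []
        for partial in beams:
            used = set(partial.values())
            options = [c for c in candidates if c not in used]
            allow_omit = (len(model.features) - len(partial) - 1) >= (
                min_pairs - len(partial)
            )
            if allow_omit:
                new_beams.append((_partial_cost(model, positions, partial), dict(partial)))
            for c in options:
                nxt = dict(partial)
                nxt[fi] = c
                new_beams.append((_partial_cost(model, positions, nxt), nxt))
        new_beams.sort(key=lambda x: x[0])
        beams = [b for _, b in new_beams[:BEAM_WIDTH]]
    full = [b for b in beams if len(b) >= min_pairs]
    return full


def _partial_cost(model, positions, partial) -> float:
    if len(partial) < 3:
        return 0.0
    feats = [model.features[i] for i in partial]
    pts = [(f.center, f.weight / f.tolerance**2) for f in feats]
    X = np.array([positions[partial[i]] for i in partial])
    try:
        tr = align_weighted(pts, X)
    except UnderdeterminedError:
        return 0.0
    moved = tr.apply(X)
    centers = np.array([f.center for f in feats])
    w = np.array([f.weight / f.tolerance**2 for f in feats])
    return float((w * np.sum((moved - centers) ** 2, axis=1)).sum())


def best_fit(
    model: PharmacophoreModel,
    mol: MoleculeRecord,
    mode: str = "flexible",
    enumeration_cap: int = ENUMERATION_CAP,
) -> FitResult | None:
    """Best pose of a molecule against a model, or None if no valid pose.

    ``mode='rigid'`` considers only the first conformer;
    ``mode='flexible'`` takes the maximum over all supplied conformers.
    Poses where any mapped feature lies outside its tolerance sphere
    are rejected after optimal alignment.
    """
    if mode not in ("rigid", "flexible"):
        raise ValueError("mode must be 'rigid' or 'flexible'")
    if mol.n_conformers == 0:
        raise ValueError(f"molecule {mol.id!r} has no conformers")
    conformers = [0] if mode == "rigid" else range(mol.n_conformers)

    n = len(model.features)
    min_pairs = n - model.max_omitted
    best: FitResult | None = None

    for ci in conformers:
        points = mol.features(ci)
        groups = _group_by_kind(points)
        positions = [p.position for p in points]

        # enumerate omission patterns from fewest omitted to most
        subsets = []
        total_assignments = 0
        for n_omit in range(model.max_omitted + 1):
            for omit in itertools.combinations(range(n), n_omit):
                feats = [f for i, f in enumerate(model.features) if i not in omit]
                if len(feats) < max(min_pairs, 3):
                    continue
                cnt = _count_assignments(feats, groups)
                total_assignments += cnt
                subsets.append(feats)

        if total_assignments > enumeration_cap:
            candidates = _beam_search(model, points, groups, max(min_pairs, 3))
            approximate = True
            scored = []
            for partial in candidates:
                feats = [model.features[i] for i in sorted(partial)]
                assign = tuple(partial[i] for i in sorted(partial))
                res = _score_correspondence(feats, positions, assign)
                if res is not None:
                    scored.append((feats, assign, res))
        else:
            approximate = False
            scored = []
            for feats in subsets:
                for assign in _enumerate_assignments(feats, groups):
                    res = _score_correspondence(feats, positions, assign)
                    if res is not None:
                        scored.append((feats, assign, res))

        for feats, assign, (transform, disp, score) in scored:
            if best is None or score > best.fit or (
                score == best.fit and ci < best.conformer_index
            ):
                corr = Correspondence(
                    tuple((f.id, a) for f, a in zip(feats, assign))
                )
                best = FitResult(
                    compound_id=mol.id,
                    conformer_index=ci,
                    correspondence=corr,
                    transform=transform,
                    displacements={f.id: float(d) for f, d in zip(feats, disp)},
                    fit=score,
                    mapped_count=len(feats),
                    approximate=approximate,
                )
    return best


def screen(
    model: PharmacophoreModel,
    library: Iterable[MoleculeRecord],
    top_n: int = 10,
    mode: str = "flexible",
) -> tuple[list[ScreenHit], pd.DataFrame]:
    """Score a library and rank it by fit value (descending).

    Molecules with no valid pose are excluded from the ranking.  Ties
    are broken by compound id ascending.  Returns the top-``top_n``
    hits plus the full score table.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    results: list[FitResult] = []
    n_seen = 0
    for mol in library:
        n_seen += 1
        res = best_fit(model, mol, mode=mode)
        if res is not None:
            results.append(res)
    if n_seen == 0:
        warnings.warn("empty library: nothing to screen", RuntimeWarning, stacklevel=2)

    results.sort(key=lambda r: (-r.fit, r.compound_id))
    hits = [
        ScreenHit(rank=i + 1, compound_id=r.compound_id, result=r)
        for i, r in enumerate(results)
    ]
    table = pd.DataFrame(
        {
            "rank": [h.rank for h in hits],
            "compound_id": [h.compound_id for h in hits],
            "fit": [h.result.fit for h in hits],
            "mapped_count": [h.result.mapped_count for h in hits],
            "conformer_index": [h.result.conformer_index for h in hits],
            "omitted_features": [
                len(model.features) - h.result.mapped_count for h in hits
            ],
            "approximate": [h.result.approximate for h in hits],
        }
    )
    return hits[:top_n], table
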