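"""Weighted superposition, pose search and library ranking.

The brute-force oracle used throughout this file is intentionally
independent of the package's search: it enumerates every correspondence
with itertools and solves each alignment with
``scipy.spatial.transform.Rotation.align_vectors``.
"""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nepscreen.pharmacophore import (
    FeatureKind,
    PharmacophoreFeature,
    PharmacophoreModel,
)
from nepscreen.perception import LigandFeaturePoint, MoleculeRecord
from nepscreen.screening import (
    UnderdeterminedError,
    align_weighted,
    best_fit,
    screen,
)
from nepscreen.simulate import make_feature_library, _random_rotation


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def oracle_best_fit(model, points):
    """Exhaustive correspondence enumeration scored with scipy alignment."""
    best = None
    n = len(model.features)
    for n_omit in range(model.max_omitted + 1):
        for omit in itertools.combinations(range(n), n_omit):
            feats = [f for i, f in enumerate(model.features) if i not in omit]
            if len(feats) < 3:
                continue
            pools = []
            for f in feats:
                pools.append([i for i, p in enumerate(points) if p.kind == f.kind])
            for assign in itertools.product(*pools):
                if len(set(assign)) != len(assign):
                    continue
                centers = np.array([f.center for f in feats])
                w = np.array([f.weight / f.tolerance**2 for f in feats])
                X = np.array([points[i].position for i in assign])
                cc = (w[:, None] * centers).sum(0) / w.sum()
                xc = (w[:, None] * X).sum(0) / w.sum()
                rot, _ = Rotation.align_vectors(centers - cc, X - xc, weights=w)
                moved = rot.apply(X - xc) + cc
                disp = np.linalg.norm(moved - centers, axis=1)
                tol = np.array([f.tolerance for f in feats])
                if np.any(disp > tol):
                    continue
                score = float(np.sum(
                    [f.weight * (1 - (d / f.tolerance) ** 2)
                     for f, d in zip(feats, disp)]))
                if best is None or score > best:
                    best = score
    return best


def feature_record(cid, kinds, positions):
    feats = [LigandFeaturePoint(k, p, (i,))
             for i, (k, p) in enumerate(zip(kinds, positions))]
    return MoleculeRecord(id=cid, feature_conformers=[feats])


def random_instance(rng, n_model=None, n_extra=None, max_omitted=0):
    """Random toy model plus a random ligand point cloud."""
    kinds = [FeatureKind.HBA, FeatureKind.HBD, FeatureKind.AR]
    n_model = n_model or int(rng.integers(3, 7))
    feats = []
    for i in range(n_model):
        feats.append(PharmacophoreFeature(
            f"f{i}", kinds[int(rng.integers(0, 3))],
            rng.uniform(-4, 4, 3), float(rng.uniform(0.8, 2.0)),
            float(rng.uniform(0.5, 2.0))))
    model = PharmacophoreModel("rnd", feats,
                               max_omitted=min(max_omitted, n_model - 3))
    n_extra = n_extra if n_extra is not None else int(rng.integers(0, 3))
    # ligand: jittered copy of the model geometry plus distractor points
    lig_kinds = [f.kind for f in feats] + \
        [kinds[int(rng.integers(0, 3))] for _ in range(n_extra)]
    lig_pos = np.vstack([
        np.array([f.center for f in feats]) + rng.normal(0, 0.6, (n_model, 3)),
        rng.uniform(-5, 5, (n_extra, 3)),
    ])
    R, t = _random_rotation(rng), rng.uniform(-8, 8, 3)
    return model, feature_record("x", lig_kinds, lig_pos @ R.T + t)


# ---------------------------------------------------------------------------
# align_weighted
# ---------------------------------------------------------------------------

def test_already_aligned_points_give_identity():
    pts = np.array([[0, 0, 0], [2, 0, 0], [0, 3, 0], [1, 1, 2]], float)
    model_pts = [(p, 1.0) for p in pts]
    tr = align_weighted(model_pts, pts)
    assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(tr.translation, 0.0, atol=1e-9)


def test_known_transform_recovered(rng):
    pts = rng.uniform(-5, 5, (6, 3))
    R, t = _random_rotation(rng), rng.uniform(-10, 10, 3)
    moved = pts @ R.T + t
    weights = rng.uniform(0.5, 3.0, 6)
    tr = align_weighted(list(zip(moved, weights)), pts)
    assert np.allclose(tr.rotation, R, atol=1e-6)
    assert np.allclose(tr.translation, t, atol=1e-6)
    assert np.allclose(tr.apply(pts), moved, atol=1e-6)


def test_mirror_image_keeps_proper_rotation(rng):
    pts = rng.uniform(-5, 5, (5, 3))
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    tr = align_weighted([(p, 1.0) for p in mirrored], pts)
    assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
    assert np.linalg.norm(tr.apply(pts) - mirrored) > 1e-6  # residual > 0


def test_underdetermined_and_degenerate_cases():
    with pytest.raises(UnderdeterminedError):
        align_weighted([(np.zeros(3), 1.0), (np.ones(3), 1.0)],
                       np.array([[0, 0, 0], [1, 1, 1]], float))
    collinear = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
    with pytest.warns(RuntimeWarning, match="degenerate"):
        tr = align_weighted([(p, 1.0) for p in collinear], collinear)
    assert not tr.well_determined


def test_weighted_objective_is_minimized(rng):
    """The returned pose beats random perturbed poses on the weighted SSD."""
    centers = rng.uniform(-5, 5, (5, 3))
    w = rng.uniform(0.2, 2.0, 5)
    X = rng.uniform(-5, 5, (5, 3))
    tr = align_weighted(list(zip(centers, w)), X)

    def cost(R, t):
        return float((w * np.sum((X @ R.T + t - centers) ** 2, axis=1)).sum())

    base = cost(tr.rotation, tr.translation)
    for _ in range(50):
        dR = Rotation.from_rotvec(rng.normal(0, 0.05, 3)).as_matrix()
        assert base <= cost(dR @ tr.rotation,
                            tr.translation + rng.normal(0, 0.05, 3)) + 1e-9


# ---------------------------------------------------------------------------
# best_fit
# ---------------------------------------------------------------------------

def test_planted_perfect_molecule_scores_sum_of_weights(example_model, rng):
    R, t = _random_rotation(rng), rng.uniform(-10, 10, 3)
    kinds = [f.kind for f in example_model.features]
    pts = example_model.centers @ R.T + t
    res = best_fit(example_model, feature_record("perfect", kinds, pts))
    assert res is not None
    assert res.fit == pytest.approx(example_model.sum_of_weights, abs=1e-9)
    assert res.mapped_count == 6
    assert max(res.displacements.values()) < 1e-6


def test_fit_invariant_under_rigid_motion(example_model, rng):
    kinds = [f.kind for f in example_model.features]
    pts = example_model.centers + rng.normal(0, 0.4, (6, 3))
    f0 = best_fit(example_model, feature_record("a", kinds, pts)).fit
    R, t = _random_rotation(rng), rng.uniform(-20, 20, 3)
    f1 = best_fit(example_model, feature_record("b", kinds, pts @ R.T + t)).fit
    assert f1 == pytest.approx(f0, abs=1e-8)


def test_best_fit_matches_bruteforce_on_toy_instance(toy_model, rng):
    """2 HBA + 1 AR model vs 3 HBA + 2 AR ligand: all correspondences."""
    kinds = [FeatureKind.HBA] * 3 + [FeatureKind.AR] * 2
    pts = np.vstack([toy_model.centers + rng.normal(0, 0.5, (3, 3)),
                     rng.uniform(-4, 4, (2, 3))])
    rec = feature_record("toy", kinds, pts)
    res = best_fit(toy_model, rec)
    expected = oracle_best_fit(toy_model, rec.feature_conformers[0])
    if expected is None:
        assert res is None
    else:
        assert res.fit == pytest.approx(expected, abs=1e-8)


def test_oracle_equivalence_on_seeded_instances():
    """best_fit equals exhaustive enumeration on random toy problems."""
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        model, rec = random_instance(rng, max_omitted=int(rng.integers(0, 2)))
        res = best_fit(model, rec)
        expected = oracle_best_fit(model, rec.feature_conformers[0])
        if expected is None:
            assert res is None
        else:
            assert res.fit == pytest.approx(expected, abs=1e-8)
            hits += 1
    assert hits > 10  # the comparison must actually exercise valid poses


def test_fit_recomputes_from_displacements(example_model, rng):
    from nepscreen.pharmacophore import MappedFeature, fit_value

    kinds = [f.kind for f in example_model.features]
    pts = example_model.centers + rng.normal(0, 0.5, (6, 3))
    res = best_fit(example_model, feature_record("c", kinds, pts))
    recomputed = fit_value(example_model, [
        MappedFeature(fid, d) for fid, d in res.displacements.items()])
    assert res.fit == pytest.approx(recomputed, abs=1e-10)
    for fid, d in res.displacements.items():
        assert d <= example_model[fid].tolerance


def test_tolerance_inflation_never_decreases_fit(example_model, rng):
    kinds = [f.kind for f in example_model.features]
    for _ in range(10):
        pts = example_model.centers + rng.normal(0, 0.7, (6, 3))
        rec = feature_record("m", kinds, pts)
        base = best_fit(example_model, rec)
        inflated = PharmacophoreModel(
            "inflated",
            [PharmacophoreFeature(f.id, f.kind, f.center, f.tolerance * 1.5,
                                  f.weight) for f in example_model.features],
        )
        up = best_fit(inflated, rec)
        if base is not None:
            assert up is not None and up.fit >= base.fit - 1e-9


def test_flexible_mode_takes_best_conformer(example_model, rng):
    kinds = [f.kind for f in example_model.features]
    good = example_model.centers
    bad = example_model.centers + rng.normal(0, 1.0, (6, 3))
    feats = lambda pts: [LigandFeaturePoint(k, p, (i,))
                         for i, (k, p) in enumerate(zip(kinds, pts))]
    rec = MoleculeRecord("2conf", feature_conformers=[feats(bad), feats(good)])
    rigid = best_fit(example_model, rec, mode="rigid")
    flex = best_fit(example_model, rec, mode="flexible")
    assert flex.conformer_index == 1
    assert flex.fit == pytest.approx(example_model.sum_of_weights, abs=1e-9)
    assert rigid is None or rigid.fit < flex.fit


def test_beam_fallback_is_flagged_approximate(example_model, rng):
    kinds = [f.kind for f in example_model.features]
    pts = example_model.centers + rng.normal(0, 0.2, (6, 3))
    rec = feature_record("crowded", kinds, pts)
    exact = best_fit(example_model, rec)
    approx = best_fit(example_model, rec, enumeration_cap=0)
    assert not exact.approximate
    assert approx is not None and approx.approximate
    assert approx.fit <= exact.fit + 1e-9


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def test_planted_screen_ranking(example_model):
    lib, manifest = make_feature_library(
        50, example_model, n_perfect=1, n_near=5, n_miss=5, seed=11)
    roles = {e["compound_id"]: e["role"]
             for e in manifest.parameters["compounds"]}
    hits, table = screen(example_model, lib, top_n=10)
    assert hits[0].result.fit == pytest.approx(example_model.sum_of_weights,
                                               abs=1e-9)
    assert roles[hits[0].compound_id] == "perfect"
    # misses have a whole feature kind absent: never scoreable at max_omitted=0
    scored = set(table["compound_id"])
    assert all(cid not in scored
               for cid, role in roles.items() if role == "miss")
    assert list(table["rank"]) == list(range(1, len(table) + 1))
    assert (table["fit"].diff().dropna() <= 1e-12).all()


def test_tie_broken_by_compound_id(example_model):
    kinds = [f.kind for f in example_model.features]
    pts = example_model.centers
    a = feature_record("zz", kinds, pts)
    b = feature_record("aa", kinds, pts)
    hits, _ = screen(example_model, [a, b], top_n=2)
    assert [h.compound_id for h in hits] == ["aa", "zz"]
    assert [h.rank for h in hits] == [1, 2]


def test_screen_ranking_matches_oracle(example_model):
    lib, _ = make_feature_library(40, example_model, n_perfect=1, n_near=4,
                                  n_miss=4, seed=23)
    _, table = screen(example_model, lib)
    oracle_scores = {}
    for rec in lib:
        s = oracle_best_fit(example_model, rec.feature_conformers[0])
        if s is not None:
            oracle_scores[rec.id] = s
    expected = sorted(oracle_scores, key=lambda c: (-oracle_scores[c], c))
    assert list(table["compound_id"]) == expected
    for cid, fit in zip(table["compound_id"], table["fit"]):
        assert fit == pytest.approx(oracle_scores[cid], abs=1e-8)


def test_empty_library_warns():
    from nepscreen.pharmacophore import PharmacophoreModel
    model = PharmacophoreModel("m", [PharmacophoreFeature(
        "a", FeatureKind.HBA, np.zeros(3), 1.0)])
    with pytest.warns(RuntimeWarning, match="empty"):
        hits, table = screen(model, [], top_n=3)
    assert hits == [] and table.empty


def test_screen_is_deterministic(example_model):
    lib, _ = make_feature_library(30, example_model, seed=5)
    _, t1 = screen(example_model, lib)
    lib2, _ = make_feature_library(30, example_model, seed=5)
    _, t2 = screen(example_model, lib2)
    assert t1.equals(t2)
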