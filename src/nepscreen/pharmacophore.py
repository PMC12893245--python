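"""Pharmacophore data model and fit-value scoring.

A pharmacophore model is a set of typed, weighted feature spheres
("location constraints"): each feature has a 3-D center, a tolerance
radius ``T`` (Å) and a weight ``W``.  A ligand conformer is scored by
how closely its own feature points sit to the corresponding constraint
centers.  With displacement ``D`` of a mapped ligand feature from its
constraint center, the per-feature square error is ``(D/T)**2`` and the
fit value is

    F = sum over mapped features of  W * (1 - (D/T)**2)

so a perfect mapping (every ``D = 0``) scores exactly the sum of the
feature weights, and a feature sitting on its tolerance sphere
contributes nothing.  Features displaced beyond their tolerance are not
considered mapped and never contribute negative terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FeatureKind",
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "MappedFeature",
    "feature_error",
    "fit_value",
    "load_model",
    "save_model",
    "load_example_model",
]


class FeatureKind(str, Enum):
    """Chemical feature categories used by the model.

    Exactly three kinds exist: hydrogen-bond acceptor (HBA),
    hydrogen-bond donor (HBD) and aromatic ring (AR).
    """

    HBA = "HBA"
    HBD = "HBD"
    AR = "AR"


@dataclass(frozen=True)
class PharmacophoreFeature:
    """One location constraint: a typed, weighted tolerance sphere."""

    id: str
    kind: FeatureKind
    center: np.ndarray  # shape (3,), Å
    tolerance: float  # sphere radius T, Å
    weight: float = 1.0  # importance W, unitless

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        if center.shape != (3,):
            raise ValueError(f"feature {self.id!r}: center must be a 3-vector")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "kind", FeatureKind(self.kind))
        if not self.tolerance > 0:
            raise ValueError(f"feature {self.id!r}: tolerance must be > 0")
        if not self.weight > 0:
            raise ValueError(f"feature {self.id!r}: weight must be > 0")

    def __eq__(self, other) -> bool:  # ndarray needs explicit comparison
        if not isinstance(other, PharmacophoreFeature):
            return NotImplemented
        return (
            self.id == other.id
            and self.kind == other.kind
            and np.array_equal(self.center, other.center)
            and self.tolerance == other.tolerance
            and self.weight == other.weight
        )


@dataclass
class PharmacophoreModel:
    """An ordered collection of features plus an omitted-feature allowance.

    ``max_omitted`` is the number of features a ligand may leave
    unmatched while still producing a valid pose (default 0: every
    feature must be matched).
    """

    name: str
    features: list[PharmacophoreFeature] = field(default_factory=list)
    max_omitted: int = 0

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise ValueError("model needs at least one feature")
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique within a model")
        if not 0 <= self.max_omitted < len(self.features):
            raise ValueError("max_omitted must satisfy 0 <= max_omitted < n_features")

    def __getitem__(self, feature_id: str) -> PharmacophoreFeature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)

    @property
    def sum_of_weights(self) -> float:
        return float(sum(f.weight for f in self.features))

    def kind_counts(self) -> dict[FeatureKind, int]:
        counts: dict[FeatureKind, int] = {}
        for f in self.features:
            counts[f.kind] = counts.get(f.kind, 0) + 1
        return counts

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features])


@dataclass(frozen=True)
class MappedFeature:
    """A model feature paired with its observed displacement D (Å)."""

    feature_id: str
    displacement: float

    def __post_init__(self) -> None:
        if self.displacement < 0:
            raise ValueError("displacement must be >= 0")


def feature_error(displacement: float, tolerance: float) -> float:
    """Square error of one location constraint: ``(D/T)**2``.

    Monotone increasing in the displacement, decreasing in the
    tolerance, and invariant to scaling both together.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    return (displacement / tolerance) ** 2


def fit_value(model: PharmacophoreModel, mapped: Sequence[MappedFeature]) -> float:
    """Fit value F = Σ W·(1 − (D/T)²) over mapped features.

    Features displaced beyond their tolerance sphere (D > T) are
    treated as unmapped and contribute nothing; hence
    ``0 <= F <= model.sum_of_weights`` always, with equality to the
    upper bound iff every feature is mapped with zero displacement.
    """
    seen: set[str] = set()
    total = 0.0
    for m in mapped:
        if m.feature_id in seen:
            raise ValueError(f"feature {m.feature_id!r} mapped more than once")
        seen.add(m.feature_id)
        feat = model[m.feature_id]  # KeyError on unknown id
        if m.displacement > feat.tolerance:
            continue  # outside the constraint sphere: not mapped
        total += feat.weight * (1.0 - feature_error(m.displacement, feat.tolerance))
    return total


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

_VALID_KINDS = {k.value for k in FeatureKind}


def _model_to_dict(model: PharmacophoreModel) -> dict:
    return {
        "name": model.name,
        "max_omitted": model.max_omitted,
        "features": [
            {
                "id": f.id,
                "kind": f.kind.value,
                "center": [float(x) for x in f.center],
                "tolerance": f.tolerance,
                "weight": f.weight,
            }
            for f in model.features
        ],
    }


def _model_from_dict(data: Mapping) -> PharmacophoreModel:
    if "features" not in data:
        raise ValueError("pharmacophore file: missing 'features'")
    features = []
    for i, fd in enumerate(data["features"]):
        label = fd.get("id", f"<feature #{i}>")
        for key in ("id", "kind", "center"):
            if key not in fd:
                raise ValueError(f"feature {label}: missing field {key!r}")
        if fd["kind"] not in _VALID_KINDS:
            raise ValueError(
                f"feature {label}: unknown kind {fd['kind']!r} "
                f"(valid: {sorted(_VALID_KINDS)})"
            )
        tol = fd.get("tolerance", 1.6)
        if not (isinstance(tol, (int, float)) and tol > 0):
            raise ValueError(f"feature {label}: tolerance must be > 0, got {tol!r}")
        features.append(
            PharmacophoreFeature(
                id=str(fd["id"]),
                kind=FeatureKind(fd["kind"]),
                center=np.asarray(fd["center"], dtype=float),
                tolerance=float(tol),
                weight=float(fd.get("weight", 1.0)),  # weight defaults to 1
            )
        )
    return PharmacophoreModel(
        name=str(data.get("name", "unnamed")),
        features=features,
        max_omitted=int(data.get("max_omitted", 0)),
    )


def save_model(model: PharmacophoreModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=2))


def load_model(path: str | Path) -> PharmacophoreModel:
    return _model_from_dict(json.loads(Path(path).read_text()))


def load_example_model() -> PharmacophoreModel:
    """Load the packaged 6-feature example model (3 HBA, 2 HBD, 1 AR).

    The feature composition follows the published NEP model; its
    geometry is a plausible, documented approximation (the source
    figures encode inter-feature distances graphically only), so the
    file carries ``"canonical_geometry": false`` and must not be taken
    as a faithful reproduction of the original model.
    """
    text = resources.files("nepscreen.data").joinpath("phar_a3d2r1.json").read_text()
    return _model_from_dict(json.loads(text))
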