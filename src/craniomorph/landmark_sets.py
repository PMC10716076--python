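"""Landmark-set specifications for cranial geometric morphometrics.

A landmark set is an ordered list of named 3D anatomical points. Midline
landmarks lie on the cranial symmetry plane; bilateral landmarks come in
left/right pairs linked by ``partner_index``. Five default sets are
provided, mirroring a common cranial design:

* ``craniofacial`` — 37 landmarks over the whole external cranium;
* ``facial`` — 22 landmarks, a strict subset of the craniofacial set;
* ``neurocranial`` — 9 landmarks on the cranial vault;
* ``temporalis`` — 6 landmarks around the temporalis muscle region;
* ``biteforce`` — 12 landmarks + 14 semilandmarks delimiting the
  temporalis and masseter muscles, plus the TMJ and the M2 bite point
  as reference points (28 points in total).

Exact anatomical membership of real datasets varies between studies, so
sets are plain data and fully configurable; the defaults reproduce the
cardinalities and named roles above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

Laterality = Literal["midline", "left", "right"]

__all__ = [
    "LandmarkDefinition",
    "LandmarkSetSpec",
    "default_set",
    "DEFAULT_SET_IDS",
]

DEFAULT_SET_IDS = ("craniofacial", "facial", "neurocranial", "temporalis", "biteforce")


@dataclass(frozen=True)
class LandmarkDefinition:
    """One landmark: name, 1-based ordinal, side, and bilateral partner.

    ``partner_index`` is the ordinal of the mirror-image landmark for
    bilateral points. It may be None for sided landmarks in subset
    configurations that do not contain the partner (such sets cannot be
    used for mirror imputation, only for shape analysis).
    """

    name: str
    index: int
    laterality: Laterality = "midline"
    partner_index: Optional[int] = None
    role: Literal["shape", "semilandmark"] = "shape"

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"landmark index must be >= 1, got {self.index}")
        if self.laterality == "midline" and self.partner_index is not None:
            raise ValueError(f"midline landmark {self.name!r} cannot have a partner")


@dataclass(frozen=True)
class LandmarkSetSpec:
    """Ordered, validated landmark set."""

    set_id: str
    definitions: tuple[LandmarkDefinition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "definitions", tuple(self.definitions))
        idx = [d.index for d in self.definitions]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(f"{self.set_id}: indices must be 1..n contiguous, got {idx}")
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.set_id}: duplicate landmark names")
        by_index = {d.index: d for d in self.definitions}
        for d in self.definitions:
            if d.partner_index is None:
                continue
            p = by_index.get(d.partner_index)
            if p is None:
                raise ValueError(f"{self.set_id}: {d.name} partner {d.partner_index} missing")
            if p.partner_index != d.index:
                raise ValueError(f"{self.set_id}: partnering not symmetric for {d.name}")
            if {d.laterality, p.laterality} != {"left", "right"}:
                raise ValueError(f"{self.set_id}: pair {d.name}/{p.name} must be left/right")

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def n_landmarks(self) -> int:
        return len(self.definitions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.definitions)

    @property
    def midline_indices(self) -> tuple[int, ...]:
        """0-based positions of midline landmarks."""
        return tuple(d.index - 1 for d in self.definitions if d.laterality == "midline")

    @property
    def bilateral_pairs(self) -> tuple[tuple[int, int], ...]:
        """0-based (left, right) position pairs, each pair listed once."""
        pairs = []
        for d in self.definitions:
            if d.laterality == "left" and d.partner_index is not None:
                pairs.append((d.index - 1, d.partner_index - 1))
        return tuple(pairs)

    @property
    def shape_indices(self) -> tuple[int, ...]:
        """0-based positions of true (non-semilandmark) landmarks."""
        return tuple(d.index - 1 for d in self.definitions if d.role == "shape")

    def index_of(self, name: str) -> int:
        """0-based position of a landmark by name."""
        for d in self.definitions:
            if d.name == name:
                return d.index - 1
        raise KeyError(name)

    def subset(self, names: Iterable[str], set_id: str) -> "LandmarkSetSpec":
        """Build a new spec from a subset of this one, re-indexed 1..m.

        Partner links are kept when both sides survive, dropped otherwise.
        """
        names = list(names)
        old = {d.name: d for d in self.definitions}
        missing = [n for n in names if n not in old]
        if missing:
            raise KeyError(f"not in {self.set_id}: {missing}")
        new_index = {n: i + 1 for i, n in enumerate(names)}
        old_by_index = {d.index: d for d in self.definitions}
        defs = []
        for n in names:
            d = old[n]
            partner = None
            if d.partner_index is not None:
                pname = old_by_index[d.partner_index].name
                partner = new_index.get(pname)
            defs.append(
                LandmarkDefinition(n, new_index[n], d.laterality, partner, d.role)
            )
        return LandmarkSetSpec(set_id, tuple(defs))

    def positions_in(self, parent: "LandmarkSetSpec") -> tuple[int, ...]:
        """0-based positions of this set's landmarks inside ``parent``."""
        return tuple(parent.index_of(n) for n in self.names)


def _build(set_id: str, midline: list[str], pairs: list[str],
           extra: list[tuple[str, Laterality, str]] = ()) -> LandmarkSetSpec:
    """Assemble a spec: midline names, paired names (expanded to _l/_r),
    then extra (name, laterality, role) entries."""
    defs: list[LandmarkDefinition] = []
    i = 1
    for n in midline:
        defs.append(LandmarkDefinition(n, i, "midline"))
        i += 1
    for n in pairs:
        defs.append(LandmarkDefinition(f"{n}_l", i, "left", i + 1))
        defs.append(LandmarkDefinition(f"{n}_r", i + 1, "right", i))
        i += 2
    for n, lat, role in extra:
        defs.append(LandmarkDefinition(n, i, lat, None, role))
        i += 1
    return LandmarkSetSpec(set_id, tuple(defs))


_CRANIOFACIAL_MIDLINE = [
    "nasion", "glabella", "bregma", "lambda", "inion",
    "opisthion", "basion", "prosthion", "subspinale",
]
_FACIAL_PAIRS = [
    "zygomaxillare", "zygoorbitale", "frontomalare_temporale", "ectomolare",
    "dacryon", "alare", "jugale", "ectoconchion", "zygion",
]
_NEURO_PAIRS = ["porion", "asterion", "pterion_posterior", "frontotemporale", "stephanion"]


def _craniofacial() -> LandmarkSetSpec:
    return _build("craniofacial", _CRANIOFACIAL_MIDLINE, _FACIAL_PAIRS + _NEURO_PAIRS)


def _facial() -> LandmarkSetSpec:
    cf = _craniofacial()
    names = ["nasion", "glabella", "prosthion", "subspinale"]
    for p in _FACIAL_PAIRS:
        names += [f"{p}_l", f"{p}_r"]
    return cf.subset(names, "facial")


def _neurocranial() -> LandmarkSetSpec:
    return _build(
        "neurocranial",
        ["glabella", "bregma", "lambda", "inion", "opisthion"],
        ["asterion", "porion"],
    )


def _temporalis() -> LandmarkSetSpec:
    # One-sided regional set; used for shape only, never for mirror imputation.
    extra = [
        ("zygomaxillare_l", "left", "shape"),
        ("stephanion_l", "left", "shape"),
        ("ethmion_l", "left", "shape"),
        ("frontotemporale_l", "left", "shape"),
        ("mw1_l", "left", "shape"),
        ("mw2_l", "left", "shape"),
    ]
    return _build("temporalis", [], [], extra)


def _biteforce() -> LandmarkSetSpec:
    """26 muscle-delimiting points (12 landmarks + 14 semilandmarks) plus
    TMJ and the M2 bite point as reference points."""
    extra: list[tuple[str, Laterality, str]] = []
    for k in range(1, 13):
        extra.append((f"muscle_lm{k:02d}", "left", "shape"))
    for k in range(13, 27):
        extra.append((f"muscle_sl{k:02d}", "left", "semilandmark"))
    extra.append(("tmj", "left", "shape"))
    extra.append(("m2_bite_point", "left", "shape"))
    return _build("biteforce", [], [], extra)


_BUILDERS = {
    "craniofacial": _craniofacial,
    "facial": _facial,
    "neurocranial": _neurocranial,
    "temporalis": _temporalis,
    "biteforce": _biteforce,
}


def default_set(set_id: str) -> LandmarkSetSpec:
    """Return the bundled default spec for one of the five set ids."""
    try:
        return _BUILDERS[set_id]()
    except KeyError:
        raise KeyError(f"unknown landmark set {set_id!r}; choose from {DEFAULT_SET_IDS}")
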