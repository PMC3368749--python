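"""Domain model for MACiE-style enzyme reaction entries.

A reaction entry couples a four-level EC code with the chemistry of the
catalysed transformation at two resolutions: the *overall* set of bond
changes from substrates to products, and the ordered *mechanism* — one set
of bond changes per elementary step.  Bond changes are written in the
``X.Y_a.b`` token grammar: a covalent bond between elements X and Y whose
order goes from ``a`` to ``b`` (order 0 meaning the bond is absent, so
``C.N_0.1`` is formation of a carbon-nitrogen single bond and ``C.O_1.0``
cleavage of a carbon-oxygen single bond).

The module also carries the species-level facts the human-designed
descriptors need (molecular weights from Hill formulas, and identity flags
for water/hydroxide, redox cofactors, O2 and the ATP/ADP/AMP system), plus
reversal semantics and JSON file I/O for entry lists.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "ATOMIC_MASSES",
    "BondChangeToken",
    "BondChangeVector",
    "Species",
    "ReactionEntry",
    "ScalingParams",
    "SchemaError",
    "parse_bond_change_token",
    "parse_formula",
    "molecular_weight",
    "reverse_entry",
    "read_entries",
    "write_entries",
]

# IUPAC standard atomic weights (2021, abridged) for elements plausibly
# appearing in enzyme-catalysed bond changes and cofactor formulas.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Na": 22.990,
    "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974, "S": 32.06,
    "Cl": 35.45, "K": 39.098, "Ca": 40.078, "V": 50.942, "Cr": 51.996,
    "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546,
    "Zn": 65.38, "As": 74.922, "Se": 78.971, "Br": 79.904, "Mo": 95.95,
    "Cd": 112.41, "I": 126.904, "W": 183.84,
}

_VALID_ORDERS = (0, 1, 2, 3)

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)\.([A-Z][a-z]?)_(\d)\.(\d)")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_EC_RE = re.compile(r"(\d+)\.(\d+|-)\.(\d+|-)\.(\d+|-)")


class SchemaError(ValueError):
    """Raised when an entry file violates the entry schema.

    Carries the offending entry id and field name where known.
    """

    def __init__(self, message: str, entry_id: Optional[str] = None,
                 field_name: Optional[str] = None):
        prefix = ""
        if entry_id is not None:
            prefix += f"entry {entry_id!r}: "
        if field_name is not None:
            prefix += f"field {field_name!r}: "
        super().__init__(prefix + message)
        self.entry_id = entry_id
        self.field_name = field_name


@dataclass(frozen=True, order=True)
class BondChangeToken:
    """One bond change ``X.Y_a.b``, stored in canonical element order.

    The element pair is unordered chemically, so tokens are canonicalized
    with ``element_a <= element_b`` alphabetically; the order transition is
    unchanged by that swap.
    """

    element_a: str
    element_b: str
    order_before: int
    order_after: int

    def __post_init__(self) -> None:
        if self.element_a > self.element_b:
            a, b = self.element_b, self.element_a
            object.__setattr__(self, "element_a", a)
            object.__setattr__(self, "element_b", b)
        for el in (self.element_a, self.element_b):
            if el not in ATOMIC_MASSES:
                raise ValueError(f"unknown element symbol {el!r} in bond-change token")
        if self.order_before not in _VALID_ORDERS or self.order_after not in _VALID_ORDERS:
            raise ValueError(
                f"bond orders must be in {set(_VALID_ORDERS)}: "
                f"got {self.order_before}.{self.order_after}"
            )
        if self.order_before == self.order_after:
            raise ValueError(
                f"token {self} has no change in bond order "
                f"({self.order_before} -> {self.order_after})"
            )

    def __str__(self) -> str:
        return f"{self.element_a}.{self.element_b}_{self.order_before}.{self.order_after}"

    @property
    def delta(self) -> int:
        """Change in bond order (order_after - order_before)."""
        return self.order_after - self.order_before

    def involves(self, element: str) -> bool:
        return element in (self.element_a, self.element_b)

    def inverse(self) -> "BondChangeToken":
        """The token describing the reverse change (a.b -> b.a)."""
        return BondChangeToken(self.element_a, self.element_b,
                               self.order_after, self.order_before)


def parse_bond_change_token(token: str) -> BondChangeToken:
    """Parse an ``X.Y_a.b`` token string into canonical form.

    Raises ``ValueError`` naming the token on malformed text, unknown
    elements, orders outside {0,1,2,3} or a no-op order transition.
    """
    m = _TOKEN_RE.fullmatch(token.strip())
    if m is None:
        raise ValueError(f"malformed bond-change token {token!r} "
                         "(expected <El>.<El>_<digit>.<digit>)")
    el_a, el_b, before, after = m.group(1), m.group(2), int(m.group(3)), int(m.group(4))
    try:
        return BondChangeToken(el_a, el_b, before, after)
    except ValueError as exc:
        raise ValueError(f"invalid bond-change token {token!r}: {exc}") from exc


@dataclass
class BondChangeVector:
    """Sparse multiset of bond-change tokens (the common descriptor currency).

    Invariants: all keys canonical tokens, all counts positive (zero-count
    keys are dropped on construction).
    """

    counts: Dict[BondChangeToken, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[BondChangeToken, int] = {}
        for tok, c in self.counts.items():
            if not isinstance(tok, BondChangeToken):
                tok = parse_bond_change_token(str(tok))
            c = int(c)
            if c < 0:
                raise ValueError(f"negative count for token {tok}")
            if c:
                clean[tok] = clean.get(tok, 0) + c
        self.counts = clean

    @classmethod
    def from_strings(cls, mapping: Mapping[str, int]) -> "BondChangeVector":
        return cls({parse_bond_change_token(t): int(c) for t, c in mapping.items()})

    @classmethod
    def from_tokens(cls, tokens: Iterable[BondChangeToken]) -> "BondChangeVector":
        counts: Dict[BondChangeToken, int] = {}
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        return cls(counts)

    def to_strings(self) -> Dict[str, int]:
        return {str(t): c for t, c in sorted(self.counts.items())}

    def get(self, token: BondChangeToken) -> int:
        return self.counts.get(token, 0)

    def items(self) -> Iterator[Tuple[BondChangeToken, int]]:
        return iter(self.counts.items())

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "BondChangeVector") -> "BondChangeVector":
        merged = dict(self.counts)
        for t, c in other.counts.items():
            merged[t] = merged.get(t, 0) + c
        return BondChangeVector(merged)

    def inverse(self) -> "BondChangeVector":
        """Every token replaced by its reverse change."""
        return BondChangeVector({t.inverse(): c for t, c in self.counts.items()})

    def net_bond_states(self) -> Dict[Tuple[str, str, int], int]:
        """Signed tally of bond states created/destroyed by these changes.

        Each token X.Y_a.b removes one (X,Y) bond of order ``a`` and creates
        one of order ``b`` (order 0 = no bond).  Two change sets have the
        same net chemical effect iff these tallies agree — this is what the
        step-composition invariant of a mechanism checks against.
        """
        net: Dict[Tuple[str, str, int], int] = {}
        for t, c in self.counts.items():
            for order, sign in ((t.order_before, -1), (t.order_after, +1)):
                key = (t.element_a, t.element_b, order)
                net[key] = net.get(key, 0) + sign * c
        return {k: v for k, v in net.items() if v}


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-style molecular formula into an element-count map."""
    if not formula or not formula.strip():
        raise ValueError("empty molecular formula")
    formula = formula.strip()
    pos = 0
    counts: Dict[str, int] = {}
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_MASSES:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
        if pos == len(formula):
            break
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def molecular_weight(formula: str) -> float:
    """Molecular weight in Daltons from a Hill-style formula string."""
    return sum(ATOMIC_MASSES[el] * n for el, n in parse_formula(formula).items())


# Fixed name registry driving species identity flags.  The descriptors that
# consume these flags refer to the species by identity (water as substrate,
# NAD(P)(H) involvement, ATP hydrolysis), not by structure.
_WATER_NAMES = frozenset({"water", "OH-", "hydroxide"})
_REDOX_COFACTOR_NAMES = frozenset({"NAD+", "NADH", "NADP+", "NADPH", "FAD", "FADH2"})
_O2_NAMES = frozenset({"O2", "dioxygen"})
_ATP_NAMES = frozenset({"ATP"})
_ADP_AMP_NAMES = frozenset({"ADP", "AMP"})

_ROLES = ("substrate", "product")


@dataclass
class Species:
    """A reactant or product: a name + molecular formula record.

    ``weight`` is computed from the formula when not supplied.  Identity
    flags come from a fixed name registry, because the features that use
    them key on the species' identity rather than its structure.
    """

    name: str
    formula: str
    role: str
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"species role must be one of {_ROLES}, got {self.role!r}")
        if self.weight is None:
            self.weight = molecular_weight(self.formula)
        if self.weight <= 0:
            raise ValueError(f"species {self.name!r} has non-positive weight")

    @property
    def is_water_or_hydroxide(self) -> bool:
        return self.name in _WATER_NAMES

    @property
    def is_redox_cofactor(self) -> bool:
        return self.name in _REDOX_COFACTOR_NAMES

    @property
    def is_o2(self) -> bool:
        return self.name in _O2_NAMES

    @property
    def is_atp(self) -> bool:
        return self.name in _ATP_NAMES

    @property
    def is_adp_or_amp(self) -> bool:
        return self.name in _ADP_AMP_NAMES


def _parse_ec(ec: str) -> Tuple[int, str]:
    m = _EC_RE.fullmatch(ec.strip())
    if m is None:
        raise ValueError(f"invalid EC code {ec!r} (expected four dot-separated fields)")
    ec_class = int(m.group(1))
    if not 1 <= ec_class <= 6:
        raise ValueError(f"EC class {ec_class} outside the six-class universe (EC {ec!r})")
    return ec_class, ec.strip()


@dataclass
class ReactionEntry:
    """One MACiE-like record: EC label, species, overall and stepwise changes.

    The stored direction is taken as the canonical direction; no direction
    inference is performed.  ``validate()`` checks the structural invariants
    including that the signed composition of the mechanism steps equals the
    overall transformation.
    """

    entry_id: str
    ec: str
    species: List[Species]
    overall_changes: BondChangeVector
    mechanism: List[BondChangeVector]

    @property
    def ec_class(self) -> int:
        return _parse_ec(self.ec)[0]

    @property
    def substrates(self) -> List[Species]:
        return [s for s in self.species if s.role == "substrate"]

    @property
    def products(self) -> List[Species]:
        return [s for s in self.species if s.role == "product"]

    def validate(self) -> "ReactionEntry":
        _parse_ec(self.ec)
        if not self.mechanism:
            raise SchemaError("mechanism must have at least one step",
                              entry_id=self.entry_id, field_name="mechanism")
        composed: Dict[Tuple[str, str, int], int] = {}
        for step in self.mechanism:
            for k, v in step.net_bond_states().items():
                composed[k] = composed.get(k, 0) + v
        composed = {k: v for k, v in composed.items() if v}
        if composed != self.overall_changes.net_bond_states():
            raise SchemaError(
                "signed composition of mechanism steps does not equal the "
                "overall bond changes", entry_id=self.entry_id, field_name="mechanism")
        return self


def reverse_entry(entry: ReactionEntry) -> ReactionEntry:
    """The same reaction run in the opposite direction.

    Substrates and products swap roles, every overall token ``X.Y_a.b``
    becomes ``X.Y_b.a``, and the mechanism steps are reversed in order with
    each step's changes inverted.  An involution: reversing twice restores
    the entry.
    """
    swapped = [
        Species(name=s.name, formula=s.formula,
                role="product" if s.role == "substrate" else "substrate",
                weight=s.weight)
        for s in entry.species
    ]
    return ReactionEntry(
        entry_id=entry.entry_id,
        ec=entry.ec,
        species=swapped,
        overall_changes=entry.overall_changes.inverse(),
        mechanism=[step.inverse() for step in reversed(entry.mechanism)],
    )


# ---------------------------------------------------------------------------
# JSON entry I/O

def _entry_to_obj(entry: ReactionEntry) -> dict:
    return {
        "entry_id": entry.entry_id,
        "ec": entry.ec,
        "species": [{"name": s.name, "formula": s.formula, "role": s.role}
                    for s in entry.species],
        "overall_changes": entry.overall_changes.to_strings(),
        "mechanism": [step.to_strings() for step in entry.mechanism],
    }


def _entry_from_obj(obj: dict) -> ReactionEntry:
    entry_id = obj.get("entry_id")
    if not entry_id:
        raise SchemaError("missing required field", field_name="entry_id")
    for f in ("ec", "species", "overall_changes", "mechanism"):
        if f not in obj:
            raise SchemaError("missing required field", entry_id=entry_id, field_name=f)
    try:
        species = [Species(name=s["name"], formula=s["formula"], role=s["role"])
                   for s in obj["species"]]
    except (KeyError, ValueError) as exc:
        raise SchemaError(str(exc), entry_id=entry_id, field_name="species") from exc
    try:
        overall = BondChangeVector.from_strings(obj["overall_changes"])
        mechanism = [BondChangeVector.from_strings(step) for step in obj["mechanism"]]
    except ValueError as exc:
        raise SchemaError(str(exc), entry_id=entry_id, field_name="bond changes") from exc
    try:
        entry = ReactionEntry(entry_id=entry_id, ec=obj["ec"], species=species,
                              overall_changes=overall, mechanism=mechanism)
        return entry.validate()
    except ValueError as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError(str(exc), entry_id=entry_id, field_name="ec") from exc


def read_entries(path) -> List[ReactionEntry]:
    """Read a JSON array (or JSON-lines) file of reaction entries.

    Every entry is validated; schema violations raise ``SchemaError`` naming
    the entry id and field.
    """
    text = Path(path).read_text(encoding="utf-8").strip()
    if not text:
        return []
    if text.startswith("["):
        objs = json.loads(text)
    else:
        objs = [json.loads(line) for line in text.splitlines() if line.strip()]
    return [_entry_from_obj(o) for o in objs]


def write_entries(entries: Sequence[ReactionEntry], path) -> None:
    """Write entries as a UTF-8 JSON array with canonical token strings."""
    objs = [_entry_to_obj(e) for e in entries]
    Path(path).write_text(json.dumps(objs, indent=1), encoding="utf-8")


@dataclass
class ScalingParams:
    """Per-feature mean and standard deviation fitted on a training matrix."""

    feature_names: List[str]
    mean: "object"  # numpy array; typed loosely to keep this module numpy-free
    std: "object"

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.mean) or len(self.feature_names) != len(self.std):
            raise ValueError("scaling parameter lengths do not match feature list")
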