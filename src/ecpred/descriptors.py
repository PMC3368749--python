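"""Descriptor sets built from reaction entries.

Three of the five descriptor sets used in the benchmark are plain feature
matrices built here:

* *overall bond change* — counts of each ``X.Y_a.b`` token in the overall
  transformation (substrates to products);
* *composite bond change* — the same token counts summed over every
  mechanism step, so a transient bond (formed in one step, broken in a
  later one) registers as both a formation and a cleavage token;
* *human designed* — a registry of engineered features of the overall
  reaction, several deliberately correlated with particular EC classes.

The remaining two sets (similarity-to-reference-entry columns) live in
:mod:`ecpred.similarity`.  Z-scaling to zero mean / unit standard deviation,
with test matrices transformed by training-set parameters, is also here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .reaction_model import (
    BondChangeVector,
    ReactionEntry,
    ScalingParams,
    parse_formula,
)

__all__ = [
    "DescriptorMatrix",
    "FeatureRegistry",
    "default_feature_registry",
    "overall_bond_change_vector",
    "composite_bond_change_vector",
    "human_designed_vector",
    "build_descriptor_matrix",
    "zscale_fit",
    "zscale_apply",
]


@dataclass
class DescriptorMatrix:
    """An entries x features numeric table with optional scaling metadata.

    For similarity descriptor sets the "features" are reference entry ids,
    which is what makes the cross-validation column-deletion rule possible.
    """

    df: pd.DataFrame
    scaling: Optional[ScalingParams] = None

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.df.index.duplicated().any():
            raise ValueError("entry ids must be unique")

    @property
    def entry_ids(self) -> List[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> List[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def rows(self, entry_ids: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(self.df.loc[list(entry_ids)], scaling=self.scaling)

    def to_csv(self, path) -> None:
        self.df.to_csv(Path(path), index_label="entry_id")

    @classmethod
    def from_csv(cls, path) -> "DescriptorMatrix":
        return cls(pd.read_csv(Path(path), index_col="entry_id"))


def overall_bond_change_vector(entry: ReactionEntry) -> BondChangeVector:
    """Bond changes of the overall transformation (already stored canonically)."""
    return entry.overall_changes


def composite_bond_change_vector(entry: ReactionEntry) -> BondChangeVector:
    """Token counts summed over every mechanism step.

    A bond formed in one step and broken in a subsequent one contributes
    both its formation and its cleavage token, although it is absent from
    the overall transformation.
    """
    if not entry.mechanism:
        raise ValueError(f"entry {entry.entry_id!r} has an empty mechanism")
    total = BondChangeVector()
    for step in entry.mechanism:
        total = total + step
    return total


# ---------------------------------------------------------------------------
# Human-designed feature registry

FeatureFn = Callable[[ReactionEntry], float]


class FeatureRegistry:
    """Ordered collection of named features, each a function of an entry.

    The default registry approximates the engineered descriptor set of the
    original MACiE benchmark: the full published list lives only in that
    study's supplementary material, so beyond the four documented features
    (``f:X-H``, ``dv:C``, ``water.OH-.su``, ``Mod_Diff``) the registry
    carries analogues built to the same design intent — recognising redox
    species (class 1), water as substrate (class 3), isomeric substrate and
    product (class 5) and ATP hydrolysis (class 6).  It is configurable so a
    curated list can be swapped in.
    """

    def __init__(self) -> None:
        self._features: Dict[str, FeatureFn] = {}

    def add(self, name: str, fn: FeatureFn) -> "FeatureRegistry":
        if name in self._features:
            raise ValueError(f"duplicate feature name {name!r}")
        self._features[name] = fn
        return self

    @property
    def names(self) -> List[str]:
        return list(self._features)

    def __len__(self) -> int:
        return len(self._features)

    def __getitem__(self, name: str) -> FeatureFn:
        return self._features[name]

    def evaluate(self, entry: ReactionEntry) -> List[float]:
        return [float(fn(entry)) for fn in self._features.values()]


def _sum_where(vec: BondChangeVector, pred) -> int:
    return sum(c for t, c in vec.items() if pred(t))


def _formed_to(element: str) -> FeatureFn:
    return lambda e: _sum_where(e.overall_changes,
                                lambda t: t.involves(element) and t.delta > 0)


def _cleaved_to(element: str) -> FeatureFn:
    return lambda e: _sum_where(e.overall_changes,
                                lambda t: t.involves(element) and t.delta < 0)


def _dv(element: str) -> FeatureFn:
    # Total change in the sum of bond orders to `element`; an X.X token
    # counts twice because both atoms of the pair are that element.
    def fn(e: ReactionEntry) -> float:
        total = 0
        for t, c in e.overall_changes.items():
            mult = (t.element_a == element) + (t.element_b == element)
            total += mult * c * t.delta
        return float(total)
    return fn


def _pair_total(el1: str, el2: str, formed: bool) -> FeatureFn:
    a, b = sorted((el1, el2))
    def fn(e: ReactionEntry) -> float:
        return float(_sum_where(
            e.overall_changes,
            lambda t: t.element_a == a and t.element_b == b
            and (t.delta > 0 if formed else t.delta < 0)))
    return fn


def _mod_diff(e: ReactionEntry) -> float:
    """|weight of heaviest substrate - weight of heaviest product|.

    Engineered to be 0.000 for isomerisations (one substrate turning into
    one isomeric product).
    """
    if not e.substrates or not e.products:
        raise ValueError(
            f"Mod_Diff undefined for entry {e.entry_id!r}: needs at least "
            "one substrate and one product")
    return abs(max(s.weight for s in e.substrates)
               - max(p.weight for p in e.products))


def _isomer_flag(e: ReactionEntry) -> float:
    subs, prods = e.substrates, e.products
    if len(subs) == 1 and len(prods) == 1:
        return float(parse_formula(subs[0].formula) == parse_formula(prods[0].formula))
    return 0.0


def _atp_hydrolysis_flag(e: ReactionEntry) -> float:
    return float(any(s.is_atp for s in e.substrates)
                 and any(p.is_adp_or_amp for p in e.products))


def default_feature_registry() -> FeatureRegistry:
    """The 28 default human-designed features (see class docstring)."""
    reg = FeatureRegistry()
    reg.add("f:X-H", _formed_to("H"))
    reg.add("c:X-H", _cleaved_to("H"))
    for el in ("C", "N", "O", "P", "S"):
        reg.add(f"dv:{el}", _dv(el))
    for el1, el2 in (("C", "C"), ("C", "N"), ("C", "O"), ("C", "S"), ("O", "P")):
        reg.add(f"f:{el1}-{el2}", _pair_total(el1, el2, formed=True))
        reg.add(f"c:{el1}-{el2}", _pair_total(el1, el2, formed=False))
    reg.add("water.OH-.su",
            lambda e: float(any(s.is_water_or_hydroxide for s in e.substrates)))
    reg.add("redox.cofactor.su",
            lambda e: float(any(s.is_redox_cofactor for s in e.species)))
    reg.add("O2.su", lambda e: float(any(s.is_o2 for s in e.substrates)))
    reg.add("ATP.hydrolysis", _atp_hydrolysis_flag)
    reg.add("isomer", _isomer_flag)
    reg.add("Mod_Diff", _mod_diff)
    reg.add("n.substrates", lambda e: float(len(e.substrates)))
    reg.add("n.products", lambda e: float(len(e.products)))
    reg.add("n.species", lambda e: float(len(e.species)))
    reg.add("net.bond.order",
            lambda e: float(sum(c * t.delta for t, c in e.overall_changes.items())))
    reg.add("n.bond.changes", lambda e: float(e.overall_changes.total()))
    return reg


def human_designed_vector(entry: ReactionEntry,
                          registry: Optional[FeatureRegistry] = None) -> List[float]:
    """Evaluate the human-designed feature registry on one entry."""
    if registry is None:
        registry = default_feature_registry()
    return registry.evaluate(entry)


# ---------------------------------------------------------------------------
# Matrix construction and scaling

_KINDS = ("overall", "composite", "human")


def build_descriptor_matrix(entries: Sequence[ReactionEntry], kind: str,
                            registry: Optional[FeatureRegistry] = None,
                            feature_names: Optional[Sequence[str]] = None,
                            ) -> DescriptorMatrix:
    """Assemble the entries x features table for one descriptor set.

    For the token-count kinds the feature set defaults to the sorted union
    of tokens across the entries; passing ``feature_names`` (e.g. the
    training set's features when building a test matrix) fixes the columns,
    with absent tokens filled with 0 and unseen tokens dropped.
    """
    if not entries:
        raise ValueError("need at least one entry")
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    ids = [e.entry_id for e in entries]
    if kind == "human":
        if registry is None:
            registry = default_feature_registry()
        names = list(feature_names) if feature_names is not None else registry.names
        data = [[float(registry[n](e)) for n in names] for e in entries]
        return DescriptorMatrix(pd.DataFrame(data, index=ids, columns=names, dtype=float))

    extract = overall_bond_change_vector if kind == "overall" else composite_bond_change_vector
    vectors = [extract(e) for e in entries]
    if feature_names is None:
        names = sorted({str(t) for v in vectors for t, _ in v.items()})
    else:
        names = list(feature_names)
    col = {n: i for i, n in enumerate(names)}
    data = np.zeros((len(entries), len(names)))
    for i, v in enumerate(vectors):
        for t, c in v.items():
            j = col.get(str(t))
            if j is not None:
                data[i, j] = c
    return DescriptorMatrix(pd.DataFrame(data, index=ids, columns=names, dtype=float))


def zscale_fit(matrix: DescriptorMatrix) -> ScalingParams:
    """Fit per-feature mean and population standard deviation."""
    x = matrix.values
    return ScalingParams(feature_names=matrix.feature_names,
                         mean=x.mean(axis=0), std=x.std(axis=0, ddof=0))


def zscale_apply(matrix: DescriptorMatrix, params: ScalingParams) -> DescriptorMatrix:
    """Transform a matrix with previously fitted scaling parameters.

    Constant training columns (sd 0) map to 0 and are kept, so matrix
    shapes stay stable across folds.
    """
    if matrix.feature_names != list(params.feature_names):
        raise ValueError("feature mismatch between matrix and scaling parameters")
    std = np.asarray(params.std, dtype=float)
    mean = np.asarray(params.mean, dtype=float)
    safe = np.where(std == 0.0, 1.0, std)
    scaled = (matrix.values - mean) / safe
    scaled[:, std == 0.0] = 0.0
    return DescriptorMatrix(
        pd.DataFrame(scaled, index=matrix.entry_ids, columns=matrix.feature_names),
        scaling=params)
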