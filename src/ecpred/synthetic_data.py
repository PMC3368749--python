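"""Synthetic MACiE-like dataset generator.

Emulates the statistical structure of a curated mechanism database so that
every pipeline stage can be exercised without downloads: six EC classes at
realistic proportions, class-dependent chemical signatures in the overall
bond changes, species rosters that trigger the engineered features (water
for hydrolases, NAD(P) cofactors for oxidoreductases, isomeric
substrate/product pairs for isomerases, ATP->ADP/AMP for ligases), and
stepwise mechanisms whose signed composition always reproduces the overall
transformation, with transient bonds inserted as formation/cleavage pairs.

The key knob is ``mechanism_heterogeneity`` (h): with probability 1 - h an
entry's mechanism follows its class-linked template (fixed step count and
transient bonds), otherwise a template drawn from a shared pool.  At h = 1
same-class entries share no mechanistic conventions — modelling the
finding that similar reactions tend to proceed by dissimilar mechanisms —
so purely mechanistic descriptors lose most of their class signal, while
the overall descriptors are untouched.  Isomerase (class 5) mechanisms are
drawn from the shared pool regardless of h by default, reflecting that the
class is united only by substrate and product being isomers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .reaction_model import (
    BondChangeToken,
    BondChangeVector,
    ReactionEntry,
    Species,
)

__all__ = [
    "GeneratorConfig",
    "ClassTemplate",
    "default_class_priors",
    "generate_entry",
    "expand_mechanism",
    "generate_dataset",
]

# Class counts observed in MACiE 3.0 (320 entries); the ligase count is the
# remainder 320 - (84 + 63 + 73 + 49 + 30) = 21, not directly reported.
_CLASS_COUNTS = (84, 63, 73, 49, 30, 21)


def default_class_priors() -> np.ndarray:
    """Six class proportions matching the MACiE 3.0 class balance."""
    counts = np.asarray(_CLASS_COUNTS, dtype=float)
    return counts / counts.sum()


def _tok(s: str) -> BondChangeToken:
    from .reaction_model import parse_bond_change_token
    return parse_bond_change_token(s)


@dataclass
class ClassTemplate:
    """Per-class generation recipe.

    ``signature`` tokens are each included in the overall change set with
    probability ``signature_strength``; ``mandatory`` tokens always appear
    (chemistry that defines the class, e.g. the P-O formation + cleavage
    pair of ATP-coupled ligation).  The mechanism template fixes the step
    count and transient bonds used when the entry follows its class's
    mechanistic convention.
    """

    class_id: int
    signature: List[BondChangeToken]
    mandatory: List[BondChangeToken] = field(default_factory=list)
    mech_steps: int = 3
    mech_transients: List[Tuple[str, str]] = field(default_factory=list)
    shared_mechanism_only: bool = False


def _default_templates() -> Dict[int, ClassTemplate]:
    return {
        # Oxidoreductases: C-H cleavage, O-H formation, C-C order changes.
        1: ClassTemplate(1, [_tok("C.H_1.0"), _tok("O.H_0.1"), _tok("C.C_1.2")],
                         mech_steps=4, mech_transients=[("O", "H"), ("C", "O")]),
        # Transferases: diverse chemistry, no consistent signature tokens.
        2: ClassTemplate(2, [], mech_steps=2, mech_transients=[("C", "S")]),
        # Hydrolases: amide-hydrolysis pattern; water is always a substrate.
        3: ClassTemplate(3, [_tok("C.N_1.0"), _tok("C.O_0.1"), _tok("N.H_0.1")],
                         mech_steps=3, mech_transients=[("C", "O")]),
        # Lyases: C-C single bond cleavage with C-H formation.
        4: ClassTemplate(4, [_tok("C.C_1.0"), _tok("C.H_0.1")],
                         mech_steps=2, mech_transients=[("N", "H")]),
        # Isomerases: O-H making/breaking; mechanism never class-linked.
        5: ClassTemplate(5, [_tok("O.H_1.0"), _tok("O.H_0.1"), _tok("C.H_0.1")],
                         mech_steps=3, shared_mechanism_only=True),
        # Ligases: P-O formation and cleavage (ATP hydrolysis) plus joining.
        6: ClassTemplate(6, [_tok("C.N_0.1")],
                         mandatory=[_tok("O.P_0.1"), _tok("O.P_1.0")],
                         mech_steps=3, mech_transients=[("O", "P"), ("N", "H")]),
    }


# Random extra bond changes are drawn from this fixed alphabet: element
# pairs from biochemistry's core set with single-step order transitions.
_NOISE_ELEMENTS = ("C", "H", "N", "O", "P", "S")
_NOISE_TRANSITIONS = ((0, 1), (1, 0), (1, 2), (2, 1))
NOISE_ALPHABET: List[BondChangeToken] = [
    BondChangeToken(a, b, o1, o2)
    for i, a in enumerate(_NOISE_ELEMENTS)
    for b in _NOISE_ELEMENTS[i:]
    for o1, o2 in _NOISE_TRANSITIONS
]

# Transient bonds in shared-pool mechanisms come from bond types that also
# occur in class signatures, so heterogeneous mechanisms blur the very
# token counts the composite descriptors rely on.
SHARED_TRANSIENT_BONDS: List[Tuple[str, str]] = [
    ("C", "O"), ("O", "H"), ("C", "H"), ("N", "H"),
    ("C", "N"), ("C", "C"), ("O", "P"), ("C", "S"),
]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults model a MACiE-like corpus: 320 entries at the observed class
    balance, strong but imperfect class signatures (each signature token
    present with probability 0.9), on average one random extra bond change
    per entry, mechanisms of 2-5 steps carrying 1-3 transient bonds, and
    high mechanism heterogeneity (h = 0.8) since conserved within-class
    mechanisms are the exception, not the rule.
    """

    n_entries: int = 320
    class_priors: Sequence[float] = field(default_factory=lambda: default_class_priors())
    signature_strength: float = 0.9
    noise_tokens: float = 1.0
    mechanism_heterogeneity: float = 0.8
    steps_range: Tuple[int, int] = (2, 5)
    transient_pairs_range: Tuple[int, int] = (1, 3)
    seed: int = 0
    near_isomer_exception: bool = False

    def __post_init__(self) -> None:
        priors = np.asarray(self.class_priors, dtype=float)
        if priors.shape != (6,) or not np.isclose(priors.sum(), 1.0):
            raise ValueError("class priors must be six proportions summing to 1")
        if not 0.0 <= self.signature_strength <= 1.0:
            raise ValueError("signature_strength must be in [0, 1]")
        if not 0.0 <= self.mechanism_heterogeneity <= 1.0:
            raise ValueError("mechanism_heterogeneity must be in [0, 1]")
        lo, hi = self.steps_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid steps_range")
        lo, hi = self.transient_pairs_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid transient_pairs_range")
        if self.noise_tokens < 0:
            raise ValueError("noise_tokens must be non-negative")


def expand_mechanism(overall: BondChangeVector, n_steps: int,
                     n_transient: int = 0,
                     rng: Optional[np.random.Generator] = None,
                     transient_bonds: Optional[Sequence[Tuple[str, str]]] = None,
                     ) -> List[BondChangeVector]:
    """Distribute an overall transformation over mechanism steps.

    Each overall token occurrence is assigned to a random step; each
    transient bond adds a formation token to an earlier step and the
    matching cleavage to a strictly later one, so the signed composition of
    the steps always equals the overall change set exactly.

    ``transient_bonds`` fixes the transient element pairs (class-linked
    templates); otherwise ``n_transient`` pairs are drawn from the shared
    pool.
    """
    if n_steps < 1:
        raise ValueError("a mechanism needs at least one step")
    rng = rng if rng is not None else np.random.default_rng()
    if transient_bonds is None:
        pool = SHARED_TRANSIENT_BONDS
        transient_bonds = [pool[rng.integers(len(pool))] for _ in range(n_transient)]
    if transient_bonds and n_steps < 2:
        raise ValueError("transient bonds need at least two steps")

    steps: List[Dict[BondChangeToken, int]] = [dict() for _ in range(n_steps)]

    def put(step: int, token: BondChangeToken) -> None:
        steps[step][token] = steps[step].get(token, 0) + 1

    for token, count in overall.items():
        for _ in range(count):
            put(int(rng.integers(n_steps)), token)
    for el_a, el_b in transient_bonds:
        i, j = sorted(rng.choice(n_steps, size=2, replace=False))
        put(int(i), BondChangeToken(el_a, el_b, 0, 1))
        put(int(j), BondChangeToken(el_a, el_b, 1, 0))
    return [BondChangeVector(s) for s in steps]


_COFACTOR_PAIRS = {
    "NAD": (("NAD+", "C21H27N7O14P2"), ("NADH", "C21H29N7O14P2")),
    "NADP": (("NADP+", "C21H28N7O17P3"), ("NADPH", "C21H30N7O17P3")),
}
_ATP = ("ATP", "C10H16N5O13P3")
_ADP = ("ADP", "C10H15N5O10P2")
_AMP = ("AMP", "C10H14N5O7P")
# Rates of NAD(H) and NADP(H) involvement among oxidoreductases (10 and 14
# of 84 entries).
_P_NAD = 10.0 / 84.0
_P_NADP = 14.0 / 84.0


def _random_formula(rng: np.random.Generator) -> str:
    c = int(rng.integers(2, 13))
    h = int(rng.integers(max(2, c), 2 * c + 3))
    o = int(rng.integers(0, 7))
    n = int(rng.integers(0, 4))
    parts = [f"C{c}", f"H{h}"]
    if n:
        parts.append(f"N{n}")
    if o:
        parts.append(f"O{o}")
    return "".join(parts)


def _generic_species(rng: np.random.Generator, role: str, i: int) -> Species:
    return Species(name=f"{role}_{i}", formula=_random_formula(rng), role=role)


def _species_for_class(class_id: int, rng: np.random.Generator,
                       near_isomer: bool = False) -> List[Species]:
    if class_id == 5:
        formula = _random_formula(rng)
        prod_formula = formula + "H" if near_isomer else formula
        return [Species("substrate_1", formula, "substrate"),
                Species("product_1", prod_formula, "product")]
    if class_id == 3:
        target = _generic_species(rng, "substrate", 1)
        frag = _random_formula(rng)
        return [target, Species("water", "H2O", "substrate"),
                _generic_species(rng, "product", 1),
                Species("product_2", frag, "product")]
    if class_id == 6:
        out = [_generic_species(rng, "substrate", 1),
               _generic_species(rng, "substrate", 2),
               Species(*_ATP, role="substrate"),
               _generic_species(rng, "product", 1)]
        nucleotide = _ADP if rng.random() < 0.5 else _AMP
        out.append(Species(*nucleotide, role="product"))
        return out
    out = [_generic_species(rng, "substrate", 1),
           _generic_species(rng, "product", 1)]
    if class_id == 1:
        u = rng.random()
        if u < _P_NAD:
            pair = _COFACTOR_PAIRS["NAD"]
        elif u < _P_NAD + _P_NADP:
            pair = _COFACTOR_PAIRS["NADP"]
        else:
            pair = None
        if pair is not None:
            (ox_name, ox_formula), (red_name, red_formula) = pair
            out.append(Species(ox_name, ox_formula, "substrate"))
            out.append(Species(red_name, red_formula, "product"))
    elif class_id in (2, 4):
        if rng.random() < 0.5:
            out.append(_generic_species(rng, "substrate", 2))
        if rng.random() < 0.5:
            out.append(_generic_species(rng, "product", 2))
    return out


def generate_entry(class_id: int, config: GeneratorConfig,
                   rng: np.random.Generator,
                   entry_id: Optional[str] = None,
                   templates: Optional[Dict[int, ClassTemplate]] = None,
                   near_isomer: bool = False) -> ReactionEntry:
    """Generate one validated entry of the given class."""
    if not 1 <= class_id <= 6:
        raise ValueError(f"EC class must be 1..6, got {class_id}")
    templates = templates or _default_templates()
    tpl = templates[class_id]

    tokens: Dict[BondChangeToken, int] = {}
    for t in tpl.mandatory:
        tokens[t] = tokens.get(t, 0) + 1
    for t in tpl.signature:
        if rng.random() < config.signature_strength:
            tokens[t] = tokens.get(t, 0) + 1
    for _ in range(int(rng.poisson(config.noise_tokens))):
        t = NOISE_ALPHABET[int(rng.integers(len(NOISE_ALPHABET)))]
        tokens[t] = tokens.get(t, 0) + 1
    if not tokens:
        # Guarantee a non-degenerate reaction even at low signature strength.
        fallback = tpl.signature or [NOISE_ALPHABET[int(rng.integers(len(NOISE_ALPHABET)))]]
        t = fallback[int(rng.integers(len(fallback)))]
        tokens[t] = 1
    overall = BondChangeVector(tokens)

    use_class_template = (not tpl.shared_mechanism_only
                          and rng.random() >= config.mechanism_heterogeneity)
    if use_class_template:
        mechanism = expand_mechanism(overall, tpl.mech_steps, rng=rng,
                                     transient_bonds=tpl.mech_transients)
    else:
        lo, hi = config.steps_range
        n_steps = int(rng.integers(lo, hi + 1))
        lo_t, hi_t = config.transient_pairs_range
        n_transient = int(rng.integers(lo_t, hi_t + 1)) if n_steps >= 2 else 0
        mechanism = expand_mechanism(overall, n_steps, n_transient, rng=rng)

    species = _species_for_class(class_id, rng, near_isomer=near_isomer)
    ec = f"{class_id}.{rng.integers(1, 10)}.{rng.integers(1, 10)}.{rng.integers(1, 100)}"
    entry = ReactionEntry(entry_id=entry_id or f"S{rng.integers(0, 10**6):06d}",
                          ec=ec, species=species, overall_changes=overall,
                          mechanism=mechanism)
    return entry.validate()


def generate_dataset(config: GeneratorConfig,
                     templates: Optional[Dict[int, ClassTemplate]] = None,
                     ) -> List[ReactionEntry]:
    """Generate a full dataset: classes sampled from the configured priors.

    Reproducible from ``config.seed``.  With ``near_isomer_exception`` one
    isomerase entry (when any exist) has a product one protonation state
    away from isomerism, for negative testing of the isomer features.
    """
    rng = np.random.default_rng(config.seed)
    priors = np.asarray(config.class_priors, dtype=float)
    classes = rng.choice(np.arange(1, 7), size=config.n_entries, p=priors)
    entries: List[ReactionEntry] = []
    exception_used = not config.near_isomer_exception
    for i, class_id in enumerate(classes):
        near_isomer = False
        if class_id == 5 and not exception_used:
            near_isomer = True
            exception_used = True
        entries.append(generate_entry(int(class_id), config, rng,
                                      entry_id=f"S{i + 1:04d}",
                                      templates=templates,
                                      near_isomer=near_isomer))
    return entries
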