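"""Compound/reaction algebra with carbon and electron conservation.

Anaerobic fermentation stoichiometry is constrained by two conservation
laws: carbon and electrons.  The electron bookkeeping uses the *degree of
reduction* gamma of a compound — the electron-mol released per mol on full
oxidation to CO2, H2O and NH3 — computed from the elemental formula as

    gamma = 4*C + 1*H - 2*O - 3*N

(the -3 for nitrogen corresponds to ammonia as the nitrogen source, the
convention under which a Cmol of yeast biomass CH1.8O0.5N0.2 has
gamma = 4.2).  Redox cofactors are tracked as tags outside the element
balances: one NADH carries 2 electron-mol, ATP carries none.

The module also provides the redox-neutral combination of half reactions:
given pathway lumps that produce and consume NADH, it finds the unique
non-negative weighting whose net reaction has a zero NADH coefficient and
normalizes it to smallest-integer coefficients.  This is the operation that
turns the glycolytic and PRK-RuBisCO half reactions for sorbitol into the
overall fermentation equation 6 sorbitol -> 13 ethanol + 10 CO2 + 7 ATP.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd, lcm
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import (
    AmbiguousCombinationError,
    InfeasibleCombinationError,
    InvalidFormulaError,
    InvalidScalingError,
    UnknownCompoundError,
)

Number = Union[int, float, Fraction]

#: Electron-mol carried per mol of each cofactor tag.
GAMMA_NADH = 2.0
GAMMA_ATP = 0.0

#: Coefficients below this magnitude are treated as structural zeros.
_ZERO_TOL = 1e-12


# ---------------------------------------------------------------------------
# formulas and compounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementalFormula:
    """Per-mole element counts; real-valued so per-Cmol biomass formulas fit."""

    C: float = 0.0
    H: float = 0.0
    O: float = 0.0
    N: float = 0.0

    def __post_init__(self) -> None:
        if any(x < 0 for x in (self.C, self.H, self.O, self.N)):
            raise InvalidFormulaError(f"negative element count in {self}")
        if all(abs(x) < _ZERO_TOL for x in (self.C, self.H, self.O, self.N)):
            raise InvalidFormulaError("formula must contain at least one atom")


def degree_of_reduction(formula: ElementalFormula) -> float:
    """Electron-mol available per mol on oxidation to CO2, H2O and NH3.

    gamma = 4C + H - 2O - 3N.  Examples: glucose 24, sorbitol 26,
    ethanol 12, CO2 0, yeast biomass (per Cmol) 4.2.
    """
    if not isinstance(formula, ElementalFormula):
        raise InvalidFormulaError(f"not an elemental formula: {formula!r}")
    return 4.0 * formula.C + 1.0 * formula.H - 2.0 * formula.O - 3.0 * formula.N


@dataclass(frozen=True)
class Compound:
    """A named species.

    Cofactors (ATP, NADH) carry ``formula=None`` and are exempt from the
    element balances; their electron content is given explicitly.
    """

    name: str
    formula: Optional[ElementalFormula]
    molar_mass: Optional[float] = None  # g/mol; None only for cofactors
    cofactor_gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise InvalidFormulaError(f"{self.name}: molar mass must be positive")
        if self.formula is None and self.cofactor_gamma is None:
            raise InvalidFormulaError(f"{self.name}: cofactor needs an explicit gamma")

    @property
    def is_cofactor(self) -> bool:
        return self.formula is None

    @property
    def gamma(self) -> float:
        """Degree of reduction (electron-mol per mol)."""
        if self.is_cofactor:
            return float(self.cofactor_gamma)  # type: ignore[arg-type]
        return degree_of_reduction(self.formula)  # type: ignore[arg-type]

    @classmethod
    def cofactor(cls, name: str, gamma: float) -> "Compound":
        return cls(name=name, formula=None, molar_mass=None, cofactor_gamma=gamma)


class CompoundRegistry:
    """Name -> :class:`Compound` lookup used by balance checks and rates."""

    def __init__(self, compounds: Iterable[Compound] = ()):
        self._compounds: Dict[str, Compound] = {}
        for c in compounds:
            self.register(c)

    def register(self, compound: Compound) -> None:
        self._compounds[compound.name] = compound

    def __getitem__(self, name: str) -> Compound:
        try:
            return self._compounds[name]
        except KeyError:
            raise UnknownCompoundError(f"unknown compound: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._compounds

    def __iter__(self):
        return iter(self._compounds.values())

    @property
    def names(self) -> List[str]:
        return list(self._compounds)

    def gamma(self, name: str) -> float:
        return self[name].gamma

    def molar_mass(self, name: str) -> float:
        m = self[name].molar_mass
        if m is None:
            raise UnknownCompoundError(f"{name!r} has no molar mass (cofactor)")
        return m


def default_registry() -> CompoundRegistry:
    """Registry of the species appearing in anaerobic yeast fermentations.

    Biomass is registered per Cmol (CH1.8O0.5N0.2, 26.4 g/Cmol, gamma 4.2).
    """
    F = ElementalFormula
    return CompoundRegistry([
        Compound("glucose", F(C=6, H=12, O=6), molar_mass=180.156),
        Compound("fructose", F(C=6, H=12, O=6), molar_mass=180.156),
        Compound("sorbitol", F(C=6, H=14, O=6), molar_mass=182.172),
        Compound("ethanol", F(C=2, H=6, O=1), molar_mass=46.068),
        Compound("glycerol", F(C=3, H=8, O=3), molar_mass=92.094),
        Compound("acetate", F(C=2, H=4, O=2), molar_mass=60.052),
        Compound("CO2", F(C=1, O=2), molar_mass=44.009),
        Compound("biomass", F(C=1, H=1.8, O=0.5, N=0.2), molar_mass=26.4),
        Compound.cofactor("ATP", GAMMA_ATP),
        Compound.cofactor("NADH", GAMMA_NADH),
    ])


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometric map over compound names (mol basis).

    Negative coefficients are consumed, positive produced.  Pure drains
    (e.g. a maintenance ATP sink) are permitted.  Zero coefficients are
    dropped on construction; :meth:`coefficient` returns 0 for absent
    species.
    """

    id: str
    stoich: Mapping[str, Number]
    reversible: bool = False

    def __post_init__(self) -> None:
        cleaned = {
            name: coef
            for name, coef in self.stoich.items()
            if abs(float(coef)) > _ZERO_TOL
        }
        if not cleaned:
            raise InvalidScalingError(f"reaction {self.id!r} has no nonzero coefficients")
        object.__setattr__(self, "stoich", cleaned)

    def coefficient(self, name: str) -> Number:
        return self.stoich.get(name, 0)

    @property
    def reactants(self) -> List[str]:
        return [n for n, c in self.stoich.items() if float(c) < 0]

    @property
    def products(self) -> List[str]:
        return [n for n, c in self.stoich.items() if float(c) > 0]

    def scaled(self, factor: Number, new_id: Optional[str] = None) -> "Reaction":
        return Reaction(
            id=new_id or self.id,
            stoich={n: c * factor for n, c in self.stoich.items()},
            reversible=self.reversible,
        )

    def __str__(self) -> str:
        def fmt(c: Number) -> str:
            c = Fraction(c).limit_denominator(10**6) if not isinstance(c, Fraction) else c
            return str(c) if c.denominator != 1 else str(c.numerator)

        lhs = " + ".join(f"{fmt(-c)} {n}" for n, c in self.stoich.items() if float(c) < 0)
        rhs = " + ".join(f"{fmt(c)} {n}" for n, c in self.stoich.items() if float(c) > 0)
        arrow = "<->" if self.reversible else "->"
        return f"{self.id}: {lhs or '∅'} {arrow} {rhs or '∅'}"


def linear_combination(
    reactions: Sequence[Reaction],
    weights: Sequence[Number],
    new_id: str = "combined",
) -> Reaction:
    """Weighted sum of reactions; exact when coefficients are Fractions."""
    net: Dict[str, Number] = {}
    for r, w in zip(reactions, weights):
        for name, coef in r.stoich.items():
            net[name] = net.get(name, 0) + w * coef
    return Reaction(id=new_id, stoich=net)


# ---------------------------------------------------------------------------
# balance validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BalanceReport:
    """Signed carbon and electron imbalances of a reaction.

    Imbalances are reported on coefficients normalized by the largest
    absolute coefficient, so the 1e-9 tolerance is scale-free.  NADH counts
    2 electron-mol, ATP 0; cofactors are exempt from the carbon balance.
    """

    reaction_id: str
    carbon_imbalance: float
    electron_imbalance: float
    balanced: bool
    tolerance: float = 1e-9

    def to_dict(self) -> Dict[str, object]:
        return {
            "reaction_id": self.reaction_id,
            "carbon_imbalance": self.carbon_imbalance,
            "electron_imbalance": self.electron_imbalance,
            "balanced": self.balanced,
            "tolerance": self.tolerance,
        }


def validate_reaction(
    reaction: Reaction,
    registry: Optional[CompoundRegistry] = None,
    tolerance: float = 1e-9,
) -> BalanceReport:
    """Check carbon and electron conservation of ``reaction``."""
    registry = registry or default_registry()
    carbon = 0.0
    electrons = 0.0
    scale = 0.0
    for name, coef in reaction.stoich.items():
        compound = registry[name]
        c = float(coef)
        scale = max(scale, abs(c))
        electrons += c * compound.gamma
        if not compound.is_cofactor:
            carbon += c * compound.formula.C  # type: ignore[union-attr]
    scale = scale or 1.0
    carbon /= scale
    electrons /= scale
    balanced = abs(carbon) < tolerance and abs(electrons) < tolerance
    return BalanceReport(
        reaction_id=reaction.id,
        carbon_imbalance=carbon,
        electron_imbalance=electrons,
        balanced=balanced,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# redox-neutral combination
# ---------------------------------------------------------------------------

def _as_fraction(x: Number, max_denominator: int = 1000) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(x).limit_denominator(max_denominator)


def _smallest_integers(
    stoich: Dict[str, Fraction],
    max_denominator: int,
    substrate: Optional[str],
) -> Dict[str, Fraction]:
    """Rescale to the smallest integer coefficients when rational; else
    normalize per mole of the designated (or first consumed) substrate."""
    denominators = [c.denominator for c in stoich.values()]
    common = 1
    for d in denominators:
        common = lcm(common, d)
    if common <= max_denominator:
        ints = {n: c * common for n, c in stoich.items()}
        g = 0
        for c in ints.values():
            g = gcd(g, abs(c.numerator))
        g = g or 1
        return {n: c / g for n, c in ints.items()}
    # fall back: per mole of substrate
    if substrate is None:
        consumed = [n for n, c in stoich.items() if c < 0]
        if not consumed:
            return stoich
        substrate = consumed[0]
    ref = stoich.get(substrate)
    if ref is None or ref >= 0:
        raise InvalidScalingError(f"cannot normalize per {substrate!r}: not consumed")
    return {n: c / abs(ref) for n, c in stoich.items()}


def _nullspace_basis(n: List[Fraction]) -> List[List[Fraction]]:
    """Basis of the nullspace of the 1 x k row vector ``n``."""
    k = len(n)
    pivot = next((j for j, x in enumerate(n) if x != 0), None)
    if pivot is None:
        return [[Fraction(int(i == j)) for j in range(k)] for i in range(k)]
    basis = []
    for i in range(k):
        if i == pivot:
            continue
        v = [Fraction(0)] * k
        v[i] = Fraction(1)
        v[pivot] = -n[i] / n[pivot]
        basis.append(v)
    return basis


def combine_redox_neutral(
    reactions: Sequence[Reaction],
    balanced_species: str = "NADH",
    substrate: Optional[str] = None,
    max_denominator: int = 1000,
    new_id: Optional[str] = None,
) -> Reaction:
    """Combine half reactions with non-negative weights zeroing a cofactor.

    Finds weights ``w_i >= 0`` (not all zero) with
    ``sum_i w_i * n_i(balanced_species) = 0`` and returns the net reaction
    ``sum_i w_i * r_i`` normalized to smallest integer coefficients.  A
    single already-neutral reaction is returned unchanged (weight 1).

    Raises
    ------
    InfeasibleCombinationError
        If every nonzero coefficient of the balanced species has the same
        sign, so no cancelling combination exists.
    AmbiguousCombinationError
        If the weight nullspace has more than one dimension; the free
        directions are attached to the exception.
    """
    if not reactions:
        raise InfeasibleCombinationError("no reactions to combine")

    fracs = [
        {name: _as_fraction(c, max_denominator) for name, c in r.stoich.items()}
        for r in reactions
    ]
    n = [d.get(balanced_species, Fraction(0)) for d in fracs]

    if len(reactions) == 1:
        if n[0] == 0:
            return reactions[0]
        raise InfeasibleCombinationError(
            f"single reaction has nonzero {balanced_species} coefficient {n[0]}"
        )

    has_pos = any(x > 0 for x in n)
    has_neg = any(x < 0 for x in n)
    if not (has_pos and has_neg):
        raise InfeasibleCombinationError(
            f"{balanced_species} coefficients {list(map(float, n))} all share one "
            "sign; no non-negative weighting can cancel them"
        )
    if len(reactions) > 2:
        raise AmbiguousCombinationError(
            f"{len(reactions)} reactions leave "
            f"{len(reactions) - 1} free directions in the weight nullspace",
            free_directions=_nullspace_basis(n),
        )

    # two reactions, opposite signs: unique direction (|n2|, |n1|)
    weights = [abs(n[1]), abs(n[0])]
    net: Dict[str, Fraction] = {}
    for d, w in zip(fracs, weights):
        for name, coef in d.items():
            net[name] = net.get(name, Fraction(0)) + w * coef
    assert net.get(balanced_species, Fraction(0)) == 0
    net = {name: c for name, c in net.items() if c != 0}
    net = _smallest_integers(net, max_denominator, substrate)
    rid = new_id or "+".join(r.id for r in reactions)
    return Reaction(id=rid, stoich=net)


def per_substrate(reaction: Reaction, substrate: str) -> Reaction:
    """Rescale so the substrate coefficient is exactly -1."""
    coef = reaction.coefficient(substrate)
    if float(coef) >= 0:
        raise InvalidScalingError(
            f"{substrate!r} is not consumed by reaction {reaction.id!r}"
        )
    if isinstance(coef, Fraction):
        factor: Number = 1 / abs(coef)
    else:
        factor = 1.0 / abs(float(coef))
    return reaction.scaled(factor, new_id=f"{reaction.id}_per_{substrate}")
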