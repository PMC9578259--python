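"""Core metabolic network model for anaerobic yeast fermentation.

The network is deliberately small: lumped fermentative catabolism, one
redox sink for surplus NADH, a parameterized biomass equation and a
growth-independent maintenance ATP drain.  Three operating modes are
supported:

``wt_glucose``
    Reference strain on glucose.  Surplus NADH from biosynthesis is
    re-oxidized by the native glycerol branch (1 NADH + 1 ATP + 1/2
    glucose -> 1 glycerol).
``bypass_glucose``
    PRK-RuBisCO strain on glucose.  Surplus NADH drives extra ethanol via
    the engineered bypass of glyceraldehyde-3-phosphate dehydrogenase.
``bypass_sorbitol``
    PRK-RuBisCO strain on sorbitol.  Sorbitol enters through a facilitator
    and an NAD+-dependent sorbitol dehydrogenase (one extra NADH per mole),
    so the bypass must also absorb the assimilation NADH.  Fermenting the
    sorbitol entirely requires running glycolysis and the bypass side by
    side in a 3.5 : 2.5 ratio, with an overall stoichiometry of
    6 sorbitol -> 13 ethanol + 10 CO2 + 7 ATP.

For a given specific growth rate ``mu`` the model fixes the biomass flux
at ``mu`` and the maintenance drain at ``m_ATP``, then solves the square
linear system that closes the NADH, ATP and intermediate balances.  The
solution yields biomass-specific rates (mmol per g dry biomass per h) and
the ethanol and biomass yields on substrate.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    ConfigurationError,
    DomainError,
    InfeasibleBiomassError,
    InfeasibleModelError,
    ModelStructureError,
)
from .stoich import (
    CompoundRegistry,
    Reaction,
    default_registry,
    linear_combination,
    validate_reaction,
)

F = Fraction

# ---------------------------------------------------------------------------
# printed half reactions (per the 3.5 / 2.5 sorbitol lumping)
# ---------------------------------------------------------------------------

#: Native glycolysis lump: 3.5 sorbitol -> 7 ethanol + 7 CO2 + 3.5 NADH + 7 ATP
GLYCOLYSIS_HALF = Reaction(
    "glycolysis_half",
    {"sorbitol": F(-7, 2), "ethanol": 7, "CO2": 7, "NADH": F(7, 2), "ATP": 7},
)

#: PRK-RuBisCO lump: 2.5 sorbitol + 3.5 NADH -> 6 ethanol + 3 CO2 (no net ATP)
BYPASS_HALF = Reaction(
    "bypass_half",
    {"sorbitol": F(-5, 2), "NADH": F(-7, 2), "ethanol": 6, "CO2": 3},
)

#: Canonical glucose fermentation (already redox-neutral)
GLUCOSE_FERMENTATION = Reaction(
    "glucose_fermentation",
    {"glucose": -1, "ethanol": 2, "CO2": 2, "ATP": 2},
)

# ---------------------------------------------------------------------------
# per-mole network reactions
# ---------------------------------------------------------------------------

#: Sorbitol facilitator + sorbitol dehydrogenase (energy-independent uptake,
#: NAD+-dependent oxidation to fructose): sorbitol -> fructose + NADH.
SORBITOL_ASSIMILATION = Reaction(
    "sorbitol_assimilation",
    {"sorbitol": -1, "fructose": 1, "NADH": 1},
)

#: Fructose fermentation via fructokinase + lower glycolysis; the two
#: glycolytic NADH are consumed again by alcohol dehydrogenase, and the net
#: ATP is +2 (one kinase + one phosphofructokinase investment, four payoffs).
FRUCTOSE_FERMENTATION = Reaction(
    "fructose_fermentation",
    {"fructose": -1, "ethanol": 2, "CO2": 2, "ATP": 2},
)

#: Glycerol branch (NADH sink of the reference strain).  Half a glucose is
#: diverted at dihydroxyacetone phosphate; the triose costs 1 ATP.
GLYCEROL_SINK = Reaction(
    "glycerol_sink",
    {"glucose": F(-1, 2), "NADH": -1, "ATP": -1, "glycerol": 1},
)

#: PRK-RuBisCO bypass on sorbitol, the printed 2.5-sorbitol half reaction
#: scaled per mole: 1 sorbitol + 1.4 NADH -> 2.4 ethanol + 1.2 CO2.  The
#: PRK ATP investment is internal to the lump; net ATP is zero.
BYPASS_SINK_SORBITOL = Reaction(
    "prk_rubisco_bypass",
    {"sorbitol": -1, "NADH": F(-7, 5), "ethanol": F(12, 5), "CO2": F(6, 5)},
)

#: Glucose-entry variant of the bypass: identical to the sorbitol lump minus
#: the sorbitol-dehydrogenase NADH (glucose enters at the hexose level, same
#: 1 ATP phosphorylation cost), re-balanced on carbon and electrons:
#: 1 glucose + 0.4 NADH -> 31/15 ethanol + 28/15 CO2.
BYPASS_SINK_GLUCOSE = Reaction(
    "prk_rubisco_bypass_glucose",
    {"glucose": -1, "NADH": F(-2, 5), "ethanol": F(31, 15), "CO2": F(28, 15)},
)

#: Growth-independent ATP drain; its flux is fixed at m_ATP.
MAINTENANCE = Reaction("maintenance_atp", {"ATP": -1})


class NetworkMode(str, enum.Enum):
    """Substrate / redox-sink combination; exactly one sink per solve."""

    WT_GLUCOSE = "wt_glucose"
    BYPASS_GLUCOSE = "bypass_glucose"
    BYPASS_SORBITOL = "bypass_sorbitol"

    @property
    def substrate(self) -> str:
        return "sorbitol" if self is NetworkMode.BYPASS_SORBITOL else "glucose"

    @property
    def redox_sink(self) -> str:
        return "glycerol" if self is NetworkMode.WT_GLUCOSE else "bypass"


def _coerce_mode(mode) -> NetworkMode:
    try:
        return NetworkMode(mode)
    except ValueError:
        raise ConfigurationError(
            f"unknown network mode {mode!r}; expected one of "
            f"{[m.value for m in NetworkMode]}"
        ) from None


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomassParameters:
    """Growth-associated demands of biomass synthesis.

    n_ATP : mmol ATP per g biomass (growth-associated ATP demand)
    n_NADH : mmol surplus NADH released per g biomass formed
    m_ATP : mmol ATP per g biomass per h (maintenance)
    cmol_mass : g dry biomass per Cmol (CH1.8O0.5N0.2 -> 26.4)
    gamma_x : electron-mol per Cmol biomass (4.2 under the NH3 convention)

    Defaults put the anaerobic biomass yield on ATP near 16 g/mol and the
    surplus-NADH yield at the order of the wild-type glycerol-per-biomass
    ratio; both are meant to be re-anchored to observed chemostat data via
    :func:`calibrate_biomass_params`.
    """

    n_ATP: float = 62.5
    n_NADH: float = 10.0
    m_ATP: float = 1.0
    cmol_mass: float = 26.4
    gamma_x: float = 4.2

    def __post_init__(self) -> None:
        for name in ("n_ATP", "n_NADH", "m_ATP", "cmol_mass", "gamma_x"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"BiomassParameters.{name} must be >= 0")
        if self.cmol_mass <= 0:
            raise ConfigurationError("cmol_mass must be positive")


def biomass_reaction(
    params: BiomassParameters,
    substrate: str,
    registry: Optional[CompoundRegistry] = None,
) -> Reaction:
    """Biomass equation producing 1 g dry biomass from ``substrate``.

    The substrate coefficient sigma (mol/g) and the CO2 coefficient follow
    from carbon and electron conservation:

        C_s * sigma = 1/cmol_mass + v_CO2          (carbon)
        gamma_s * sigma = gamma_x/cmol_mass + 2 * n_NADH/1000   (electrons)

    so the emitted reaction is balanced by construction.  ATP demand and
    surplus NADH appear as cofactor coefficients (mol per g biomass).
    """
    registry = registry or default_registry()
    compound = registry[substrate]
    if compound.is_cofactor:
        raise InfeasibleBiomassError(f"{substrate!r} is a cofactor, not a substrate")
    gamma_s = compound.gamma
    carbons = compound.formula.C  # type: ignore[union-attr]
    if gamma_s <= 0 or carbons <= 0:
        raise InfeasibleBiomassError(
            f"substrate {substrate!r} has non-positive degree of reduction "
            f"({gamma_s}) or carbon content ({carbons})"
        )
    sigma = (params.gamma_x / params.cmol_mass + 2.0 * params.n_NADH / 1000.0) / gamma_s
    v_co2 = carbons * sigma - 1.0 / params.cmol_mass
    if sigma <= 0 or v_co2 < -1e-12:
        raise InfeasibleBiomassError(
            f"biomass on {substrate}: sigma={sigma:.6g}, v_CO2={v_co2:.6g}; "
            "parameters force a negative coefficient"
        )
    stoich = {
        substrate: -sigma,
        "biomass": 1.0 / params.cmol_mass,  # Cmol per g
        "ATP": -params.n_ATP / 1000.0,
        "NADH": params.n_NADH / 1000.0,
    }
    if v_co2 > 1e-12:
        stoich["CO2"] = v_co2
    return Reaction(id=f"biomass_on_{substrate}", stoich=stoich)


# ---------------------------------------------------------------------------
# network assembly and solve
# ---------------------------------------------------------------------------

def _catabolic_reactions(mode: NetworkMode) -> List[Reaction]:
    if mode is NetworkMode.WT_GLUCOSE:
        return [GLUCOSE_FERMENTATION, GLYCEROL_SINK]
    if mode is NetworkMode.BYPASS_GLUCOSE:
        return [GLUCOSE_FERMENTATION, BYPASS_SINK_GLUCOSE]
    return [SORBITOL_ASSIMILATION, FRUCTOSE_FERMENTATION, BYPASS_SINK_SORBITOL]


def _balanced_species(mode: NetworkMode) -> List[str]:
    species = []
    if mode is NetworkMode.BYPASS_SORBITOL:
        species.append("fructose")  # internal intermediate
    species += ["NADH", "ATP"]
    return species


def build_network(
    mode,
    params: Optional[BiomassParameters] = None,
    registry: Optional[CompoundRegistry] = None,
) -> List[Reaction]:
    """All reactions of a mode: catabolism, redox sink, biomass, maintenance."""
    mode = _coerce_mode(mode)
    params = params or BiomassParameters()
    reactions = list(_catabolic_reactions(mode))
    reactions.append(biomass_reaction(params, mode.substrate, registry))
    reactions.append(MAINTENANCE)
    return reactions


@dataclass(frozen=True)
class ModelPrediction:
    """Solved fluxes, rates and yields at one growth rate.

    Rates are biomass-specific (mmol per g dry biomass per h); the biomass
    flux itself is mu (g per g per h).  Yields: mol ethanol per mol
    substrate and g biomass per mol substrate.
    """

    mode: NetworkMode
    mu: float
    fluxes: Dict[str, float]
    q_substrate: float
    q_ethanol: float
    q_glycerol: float
    q_co2: float
    y_ethanol: float
    y_biomass: float

    def to_dict(self) -> Dict[str, object]:
        return {
            "mode": self.mode.value,
            "mu_per_h": self.mu,
            "q_substrate_mmol_g_h": self.q_substrate,
            "q_ethanol_mmol_g_h": self.q_ethanol,
            "q_glycerol_mmol_g_h": self.q_glycerol,
            "q_co2_mmol_g_h": self.q_co2,
            "y_ethanol_mol_mol": self.y_ethanol,
            "y_biomass_g_mol": self.y_biomass,
            "fluxes": dict(self.fluxes),
        }


def predict(
    mu: float,
    mode,
    params: Optional[BiomassParameters] = None,
    registry: Optional[CompoundRegistry] = None,
) -> ModelPrediction:
    """Solve the network at specific growth rate ``mu`` (1/h).

    Fixes biomass flux = mu and maintenance = m_ATP, closes the NADH/ATP
    (and intermediate) balances with the mode's single redox sink, and
    derives yields.  Raises :class:`InfeasibleModelError` when a flux would
    have to run backwards.
    """
    mode = _coerce_mode(mode)
    if mu < 0:
        raise DomainError("mu must be >= 0")
    params = params or BiomassParameters()
    registry = registry or default_registry()

    catabolic = _catabolic_reactions(mode)
    bio = biomass_reaction(params, mode.substrate, registry)
    species = _balanced_species(mode)

    k = len(catabolic)
    A = np.zeros((len(species), k))
    b = np.zeros(len(species))
    for i, s in enumerate(species):
        for j, r in enumerate(catabolic):
            A[i, j] = float(r.coefficient(s))
        # fixed contributions: biomass (mol/g * 1000 * mu -> mmol/g/h), maintenance
        b[i] = -(float(bio.coefficient(s)) * 1000.0 * mu
                 + float(MAINTENANCE.coefficient(s)) * params.m_ATP)
    try:
        v = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ModelStructureError(f"singular network for mode {mode.value}") from exc

    if np.any(v < -1e-9):
        worst = {r.id: float(x) for r, x in zip(catabolic, v) if x < -1e-9}
        raise InfeasibleModelError(
            f"negative flux at mu={mu} in mode {mode.value}: {worst}"
        )
    v = np.clip(v, 0.0, None)

    # net biomass-specific exchange rates (mmol/g/h), biomass excluded
    exchanged: Dict[str, float] = {}
    for j, r in enumerate(catabolic):
        for name, coef in r.stoich.items():
            exchanged[name] = exchanged.get(name, 0.0) + float(coef) * v[j]
    for name, coef in bio.stoich.items():
        if name != "biomass":
            exchanged[name] = exchanged.get(name, 0.0) + float(coef) * 1000.0 * mu
    exchanged["ATP"] = exchanged.get("ATP", 0.0) - params.m_ATP

    q_sub = -exchanged.get(mode.substrate, 0.0)
    q_eth = exchanged.get("ethanol", 0.0)
    q_gly = exchanged.get("glycerol", 0.0)
    q_co2 = exchanged.get("CO2", 0.0)
    y_eth = q_eth / q_sub if q_sub > 0 else float("nan")
    y_x = mu / q_sub * 1000.0 if q_sub > 0 else float("nan")

    fluxes = {r.id: float(x) for r, x in zip(catabolic, v)}
    fluxes[bio.id] = mu
    fluxes[MAINTENANCE.id] = params.m_ATP
    return ModelPrediction(
        mode=mode,
        mu=mu,
        fluxes=fluxes,
        q_substrate=q_sub,
        q_ethanol=q_eth,
        q_glycerol=q_gly,
        q_co2=q_co2,
        y_ethanol=y_eth,
        y_biomass=y_x,
    )


# ---------------------------------------------------------------------------
# exact catabolic yields
# ---------------------------------------------------------------------------

def _solve_exact(A: List[List[Fraction]], b: List[Fraction]) -> List[Fraction]:
    """Gaussian elimination over Fractions for small square systems."""
    n = len(A)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(n):
        pivot = next((r for r in range(col, n) if M[r][col] != 0), None)
        if pivot is None:
            raise ModelStructureError("singular catabolic system")
        M[col], M[pivot] = M[pivot], M[col]
        pv = M[col][col]
        M[col] = [x / pv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [x - f * y for x, y in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def _catabolic_net(mode: NetworkMode) -> Reaction:
    """Exact net catabolic reaction per mole of substrate (growth excluded).

    Solves the catabolic subnetwork with intermediates and NADH balanced and
    substrate consumption normalized to 1 mol, using rational arithmetic.
    """
    mode = _coerce_mode(mode)
    reactions = _catabolic_reactions(mode)
    substrate = mode.substrate
    balanced = [s for s in _balanced_species(mode) if s != "ATP"]

    k = len(reactions)
    rows: List[List[Fraction]] = []
    rhs: List[Fraction] = []
    for s in balanced:
        rows.append([Fraction(r.coefficient(s)) for r in reactions])
        rhs.append(Fraction(0))
    rows.append([-Fraction(r.coefficient(substrate)) for r in reactions])
    rhs.append(Fraction(1))
    if len(rows) != k:
        raise ModelStructureError(
            f"catabolic subnetwork of {mode.value} is not square "
            f"({len(rows)} constraints, {k} fluxes)"
        )
    weights = _solve_exact(rows, rhs)
    if any(w < 0 for w in weights):
        raise InfeasibleModelError(
            f"catabolic solve of {mode.value} needs a negative flux"
        )
    frac_reactions = [
        Reaction(r.id, {n: Fraction(c) for n, c in r.stoich.items()})
        for r in reactions
    ]
    return linear_combination(
        frac_reactions, weights, new_id=f"{mode.value}_catabolism"
    )


def theoretical_max_yield(mode) -> Fraction:
    """Mol ethanol per mol substrate of the growth-free catabolic pathway."""
    net = _catabolic_net(_coerce_mode(mode))
    return Fraction(net.coefficient("ethanol"))


def atp_yield(mode) -> Fraction:
    """Mol ATP per mol substrate of the growth-free catabolic pathway."""
    net = _catabolic_net(_coerce_mode(mode))
    return Fraction(net.coefficient("ATP"))


def maintenance_threshold_rate(params: BiomassParameters, mode) -> float:
    """Minimum substrate uptake (mmol/g/h) that covers maintenance ATP.

    threshold * atp_yield == m_ATP exactly; for the combined sorbitol
    pathway with m_ATP = 1 this is 6/7 ≈ 0.86 mmol per g biomass per h.
    """
    y = atp_yield(mode)
    if y <= 0:
        raise DomainError(
            f"mode {_coerce_mode(mode).value} has ATP yield {y}; the maintenance "
            "threshold is undefined (no net ATP is formed)"
        )
    return params.m_ATP / float(y)


# ---------------------------------------------------------------------------
# yield curves and calibration
# ---------------------------------------------------------------------------

def yield_curve(
    mu_grid: Sequence[float],
    mode,
    params: Optional[BiomassParameters] = None,
    registry: Optional[CompoundRegistry] = None,
) -> pd.DataFrame:
    """Predictions across a growth-rate grid; infeasible rows are flagged."""
    mode = _coerce_mode(mode)
    mu_arr = np.asarray(list(mu_grid), dtype=float)
    if mu_arr.size == 0 or np.any(np.diff(mu_arr) < 0) or np.any(mu_arr < 0):
        raise DomainError("mu grid must be non-empty, ascending and non-negative")
    rows = []
    for mu in mu_arr:
        try:
            p = predict(float(mu), mode, params, registry)
            rows.append({
                "mu_per_h": mu,
                "q_substrate_mmol_g_h": p.q_substrate,
                "q_ethanol_mmol_g_h": p.q_ethanol,
                "q_glycerol_mmol_g_h": p.q_glycerol,
                "q_co2_mmol_g_h": p.q_co2,
                "y_ethanol_mol_mol": p.y_ethanol,
                "y_biomass_g_mol": p.y_biomass,
                "feasible": True,
                "error": "",
            })
        except (InfeasibleModelError, InfeasibleBiomassError) as exc:
            rows.append({
                "mu_per_h": mu,
                "q_substrate_mmol_g_h": np.nan,
                "q_ethanol_mmol_g_h": np.nan,
                "q_glycerol_mmol_g_h": np.nan,
                "q_co2_mmol_g_h": np.nan,
                "y_ethanol_mol_mol": np.nan,
                "y_biomass_g_mol": np.nan,
                "feasible": False,
                "error": str(exc),
            })
    return pd.DataFrame(rows)


def calibrate_biomass_params(
    glycerol_per_biomass: float,
    biomass_yield: float,
    dilution_rate: float,
    m_ATP: float = 1.0,
    cmol_mass: float = 26.4,
    gamma_x: float = 4.2,
    registry: Optional[CompoundRegistry] = None,
) -> BiomassParameters:
    """Anchor biomass parameters to wild-type chemostat observations.

    The surplus-NADH yield is read directly from the observed
    glycerol-per-biomass ratio (in the reference strain every surplus NADH
    makes one glycerol), and the ATP demand is solved so that the
    wt_glucose prediction reproduces the observed biomass yield (g/mol) at
    the observation's dilution rate.
    """
    if glycerol_per_biomass <= 0:
        raise CalibrationError("glycerol per biomass must be positive")
    if biomass_yield <= 0 or dilution_rate <= 0:
        raise CalibrationError("biomass yield and dilution rate must be positive")

    n_NADH = float(glycerol_per_biomass)
    registry = registry or default_registry()
    gamma_glc = registry.gamma("glucose")
    sigma = (gamma_x / cmol_mass + 2.0 * n_NADH / 1000.0) / gamma_glc
    D = float(dilution_rate)
    q_target = D / biomass_yield * 1000.0  # mmol glucose per g per h
    # invert the wt_glucose solve:
    #   q = (D*n_ATP + m + D*n_NADH)/2 + 0.5*D*n_NADH + D*sigma*1000
    n_ATP = (
        2.0 * (q_target - 0.5 * D * n_NADH - D * sigma * 1000.0)
        - m_ATP - D * n_NADH
    ) / D
    if n_ATP <= 0:
        raise CalibrationError(
            f"observations imply non-positive ATP demand (n_ATP={n_ATP:.4g}); "
            "biomass yield too high for the assumed maintenance"
        )
    return BiomassParameters(
        n_ATP=n_ATP, n_NADH=n_NADH, m_ATP=m_ATP,
        cmol_mass=cmol_mass, gamma_x=gamma_x,
    )


def validate_network(
    mode,
    params: Optional[BiomassParameters] = None,
    registry: Optional[CompoundRegistry] = None,
):
    """Balance reports for every reaction of a mode's network."""
    registry = registry or default_registry()
    return [validate_reaction(r, registry) for r in build_network(mode, params, registry)]
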