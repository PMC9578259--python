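"""Seeded generators for batch and chemostat culture series.

The generators produce data with exactly the stoichiometric structure the
quantification routines assume, so every estimator can be exercised
against a known ground truth:

* Batch: biomass grows exponentially at mu until the primary substrate is
  exhausted; substrate, ethanol, glycerol and co-substrate trajectories are
  linear in the biomass formed, with coefficients taken either from a
  network-model prediction or specified directly (e.g. from a published
  table row).
* Chemostat: the biomass stays at its steady-state value and each residual
  concentration obeys dc/dt = D*(c_in - c) - q*Cx, a linear ODE solved
  analytically piece by piece between events.  An event that sets an
  uptake rate to zero produces exactly the first-order wash-in curve.

Measurement noise is multiplicative lognormal per observation (default
sigma 0.02), applied last; the same seed reproduces a series bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import DomainError, SimulationIntegrityError
from .model import ModelPrediction
from .quant import CultureSeries, SteadyState
from .stoich import CompoundRegistry, default_registry

import pandas as pd


# ---------------------------------------------------------------------------
# ground-truth stoichiometry for batch simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProductStoichiometry:
    """Fixed product stoichiometry of an exponential batch culture.

    y_biomass_g_per_mol : g biomass per mol primary substrate
    y_ethanol_mol_per_mol : mol ethanol per mol primary substrate
        (apparent yield; includes ethanol from any co-substrate)
    glycerol_per_biomass_mmol_per_g, sorbitol_per_biomass_mmol_per_g :
        production/consumption coupled to biomass formation
    """

    y_biomass_g_per_mol: float
    y_ethanol_mol_per_mol: float
    glycerol_per_biomass_mmol_per_g: float = 0.0
    sorbitol_per_biomass_mmol_per_g: float = 0.0

    def __post_init__(self) -> None:
        if self.y_biomass_g_per_mol <= 0:
            raise DomainError("biomass yield must be positive")
        if self.y_ethanol_mol_per_mol < 0:
            raise DomainError("ethanol yield must be >= 0")

    @classmethod
    def from_prediction(cls, prediction: ModelPrediction) -> "ProductStoichiometry":
        """Coefficients implied by a network-model solve (single substrate)."""
        if prediction.mu <= 0:
            raise DomainError("batch stoichiometry needs mu > 0")
        gly_per_x = prediction.q_glycerol / prediction.mu
        return cls(
            y_biomass_g_per_mol=prediction.y_biomass,
            y_ethanol_mol_per_mol=prediction.y_ethanol,
            glycerol_per_biomass_mmol_per_g=gly_per_x,
            sorbitol_per_biomass_mmol_per_g=0.0,
        )


# ---------------------------------------------------------------------------
# batch
# ---------------------------------------------------------------------------

@dataclass
class BatchSimulationSpec:
    """Anaerobic glucose(+sorbitol) batch culture specification.

    Defaults mirror the mixed-substrate study conditions: 20 g/L glucose
    plus 30 g/L sorbitol, a small inoculum, and 2% multiplicative
    measurement noise.
    """

    stoich: ProductStoichiometry
    mu: float = 0.30                 # 1/h
    biomass_0_gL: float = 0.15
    glucose_0_gL: float = 20.0
    sorbitol_0_gL: float = 30.0
    times_h: Optional[Sequence[float]] = None
    noise_sigma: Union[float, Mapping[str, float]] = 0.02
    detection_floor_gL: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise DomainError("mu must be positive")
        if self.biomass_0_gL <= 0:
            raise DomainError("inoculum must be positive")
        if self.times_h is not None:
            t = np.asarray(self.times_h, dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise DomainError("sampling times must be strictly increasing")
        sigmas = (
            self.noise_sigma.values()
            if isinstance(self.noise_sigma, Mapping)
            else [self.noise_sigma]
        )
        if any(s < 0 for s in sigmas):
            raise DomainError("noise sigma must be >= 0")


def _sigma_for(spec_sigma, column: str) -> float:
    if isinstance(spec_sigma, Mapping):
        return float(spec_sigma.get(column, 0.0))
    return float(spec_sigma)


def _apply_noise(
    df: pd.DataFrame, sigma, rng: np.random.Generator, floor: float
) -> pd.DataFrame:
    noisy = df.copy()
    for col in df.columns:
        if col == "time_h":
            continue
        s = _sigma_for(sigma, col)
        if s > 0:
            noisy[col] = df[col].to_numpy() * rng.lognormal(0.0, s, size=len(df))
    if floor > 0:
        value_cols = [c for c in noisy.columns if c != "time_h"]
        vals = noisy[value_cols].to_numpy()
        noisy[value_cols] = np.where(vals < floor, 0.0, vals)
    return noisy


def simulate_batch(
    spec: BatchSimulationSpec,
    registry: Optional[CompoundRegistry] = None,
) -> CultureSeries:
    """Exponential mixed-substrate batch with fixed product stoichiometry.

    Growth stops when glucose is exhausted; all trajectories plateau from
    that point.  Noise-free output round-trips exactly through
    :func:`redoxferm.quant.batch_stoichiometry` and
    :func:`redoxferm.quant.fit_growth_rate`.
    """
    registry = registry or default_registry()
    st = spec.stoich
    M_glc = registry.molar_mass("glucose")
    M_eth = registry.molar_mass("ethanol")
    M_gly = registry.molar_mass("glycerol")
    M_sorb = registry.molar_mass("sorbitol")

    # biomass gain at glucose exhaustion, g/L
    dX_max = spec.glucose_0_gL / M_glc * st.y_biomass_g_per_mol
    t_exhaust = np.log1p(dX_max / spec.biomass_0_gL) / spec.mu

    if spec.times_h is None:
        times = np.linspace(0.0, 1.15 * t_exhaust, 12)
    else:
        times = np.asarray(spec.times_h, dtype=float)

    t_eff = np.minimum(times, t_exhaust)
    X = spec.biomass_0_gL * np.exp(spec.mu * t_eff)
    dX = X - spec.biomass_0_gL

    glc_consumed_mol = dX / st.y_biomass_g_per_mol
    glucose = np.clip(spec.glucose_0_gL - glc_consumed_mol * M_glc, 0.0, None)
    ethanol = st.y_ethanol_mol_per_mol * glc_consumed_mol * M_eth
    glycerol = st.glycerol_per_biomass_mmol_per_g * dX / 1000.0 * M_gly
    sorb_consumed = st.sorbitol_per_biomass_mmol_per_g * dX / 1000.0 * M_sorb
    sorbitol = np.clip(spec.sorbitol_0_gL - sorb_consumed, 0.0, None)

    df = pd.DataFrame({
        "time_h": times,
        "biomass_gL": X,
        "glucose_gL": glucose,
        "sorbitol_gL": sorbitol,
        "ethanol_gL": ethanol,
        "glycerol_gL": glycerol,
    })
    rng = np.random.default_rng(spec.seed)
    noisy = _apply_noise(df, spec.noise_sigma, rng, spec.detection_floor_gL)
    metadata = {
        "generator": "simulate_batch",
        "seed": spec.seed,
        "mu_true": spec.mu,
        "t_exhaust_h": float(t_exhaust),
        "stoich_true": asdict(st),
    }
    return CultureSeries(data=noisy, metadata=metadata)


# ---------------------------------------------------------------------------
# chemostat
# ---------------------------------------------------------------------------

@dataclass
class ChemostatSimulationSpec:
    """Anaerobic glucose-sorbitol chemostat specification.

    ``q_mmol_g_h`` holds signed biomass-specific rates, consumption
    positive (products carry negative values).  ``events`` is a list of
    ``(time_h, {compound: new_q})`` pairs, e.g. switching sorbitol uptake
    off when CO2 sparging stops.  Defaults mirror the study's chemostats:
    feed 10 g/L glucose + 10 g/L sorbitol at D = 0.025 1/h.
    """

    q_mmol_g_h: Dict[str, float]
    biomass_gL: float
    D: float = 0.025
    feed_gL: Dict[str, float] = field(
        default_factory=lambda: {"glucose": 10.0, "sorbitol": 10.0}
    )
    times_h: Sequence[float] = field(
        default_factory=lambda: tuple(np.linspace(0.0, 600.0, 61))
    )
    events: List[Tuple[float, Dict[str, float]]] = field(default_factory=list)
    initial_gL: Optional[Dict[str, float]] = None  # default: pre-event steady state
    noise_sigma: Union[float, Mapping[str, float]] = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise DomainError("dilution rate must be positive")
        if self.biomass_gL <= 0:
            raise DomainError("biomass must be positive")
        t = np.asarray(self.times_h, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise DomainError("sampling times must be strictly increasing")
        self.events = sorted(self.events, key=lambda e: e[0])


def _asymptote(c_in: float, q: float, Cx: float, M: float, D: float) -> float:
    """Steady-state residual of dc/dt = D(c_in - c) - q*Cx*M/1000."""
    return c_in - q * Cx * M / (1000.0 * D)


def simulate_chemostat(
    spec: ChemostatSimulationSpec,
    registry: Optional[CompoundRegistry] = None,
) -> Tuple[CultureSeries, SteadyState]:
    """Piecewise-analytic chemostat time course plus its final steady state.

    Between events every concentration relaxes exponentially (rate D)
    toward the segment's asymptote; concentrations are continuous across
    events.  With an uptake rate switched to zero the trajectory is exactly
    the first-order wash-in curve.
    """
    registry = registry or default_registry()
    compounds = sorted(set(spec.feed_gL) | set(spec.q_mmol_g_h))
    times = np.asarray(spec.times_h, dtype=float)
    Cx, D = spec.biomass_gL, spec.D

    q_now = dict(spec.q_mmol_g_h)
    segments: List[Tuple[float, Dict[str, float]]] = [(times[0], dict(q_now))]
    for ev_time, changes in spec.events:
        if ev_time <= times[0]:
            q_now.update(changes)
            segments[0] = (times[0], dict(q_now))
            continue
        q_now.update(changes)
        segments.append((float(ev_time), dict(q_now)))

    # initial concentrations: supplied, or the first segment's steady state
    c_now: Dict[str, float] = {}
    for name in compounds:
        M = registry.molar_mass(name)
        c_in = spec.feed_gL.get(name, 0.0)
        if spec.initial_gL is not None and name in spec.initial_gL:
            c0 = float(spec.initial_gL[name])
        else:
            c0 = _asymptote(c_in, segments[0][1].get(name, 0.0), Cx, M, D)
        if c0 < -1e-9:
            raise SimulationIntegrityError(
                f"initial steady state of {name} is negative ({c0:.4g} g/L); "
                "uptake exceeds supply"
            )
        c_now[name] = max(c0, 0.0)

    traj = {name: np.empty_like(times) for name in compounds}
    seg_bounds = [s[0] for s in segments] + [np.inf]
    for k, (t_start, q_seg) in enumerate(segments):
        t_end = seg_bounds[k + 1]
        mask = (times >= t_start) & (times < t_end)
        c_seg_end: Dict[str, float] = {}
        for name in compounds:
            M = registry.molar_mass(name)
            c_in = spec.feed_gL.get(name, 0.0)
            c_star = _asymptote(c_in, q_seg.get(name, 0.0), Cx, M, D)
            if c_star < -1e-9:
                raise SimulationIntegrityError(
                    f"asymptote of {name} is negative ({c_star:.4g} g/L) "
                    f"in segment starting at t={t_start}"
                )
            c = c_star + (c_now[name] - c_star) * np.exp(-D * (times[mask] - t_start))
            traj[name][mask] = c
            horizon = (t_end - t_start) if np.isfinite(t_end) else 0.0
            c_seg_end[name] = c_star + (c_now[name] - c_star) * np.exp(-D * horizon)
        c_now = c_seg_end

    df = pd.DataFrame({"time_h": times, "biomass_gL": np.full_like(times, Cx)})
    for name in compounds:
        if np.any(traj[name] < -1e-9):
            raise SimulationIntegrityError(f"negative concentration of {name}")
        df[f"{name}_gL"] = np.clip(traj[name], 0.0, None)

    rng = np.random.default_rng(spec.seed)
    noisy = _apply_noise(df, spec.noise_sigma, rng, floor=0.0)
    metadata = {
        "generator": "simulate_chemostat",
        "seed": spec.seed,
        "D_per_h": D,
        "q_true": dict(spec.q_mmol_g_h),
        "events": [(t, dict(ch)) for t, ch in spec.events],
    }
    series = CultureSeries(data=noisy, metadata=metadata)

    # final steady state (asymptote of the last segment), with its own noise
    q_final = segments[-1][1]
    c_out: Dict[str, float] = {}
    for name in compounds:
        M = registry.molar_mass(name)
        c_star = _asymptote(spec.feed_gL.get(name, 0.0), q_final.get(name, 0.0), Cx, M, D)
        s = _sigma_for(spec.noise_sigma, f"{name}_gL")
        if s > 0:
            c_star *= rng.lognormal(0.0, s)
        c_out[name] = max(c_star, 0.0)
    Cx_obs = Cx
    s_x = _sigma_for(spec.noise_sigma, "biomass_gL")
    if s_x > 0:
        Cx_obs *= rng.lognormal(0.0, s_x)
    steady = SteadyState(
        D=D, c_in=dict(spec.feed_gL), c_out=c_out, Cx=Cx_obs, replicate="simulated"
    )
    return series, steady


# ---------------------------------------------------------------------------
# study-condition factories
# ---------------------------------------------------------------------------

def engineered_chemostat_spec(
    seed: int = 0,
    noise_sigma: Union[float, Mapping[str, float]] = 0.0,
    events: Optional[List[Tuple[float, Dict[str, float]]]] = None,
    times_h: Optional[Sequence[float]] = None,
) -> ChemostatSimulationSpec:
    """Chemostat spec emulating the engineered sorbitol-co-fermenting strain.

    Feed 10 g/L glucose + 10 g/L sorbitol at D = 0.025 1/h; sorbitol uptake
    0.675 mmol/g/h (27 mmol per g biomass formed) with near-complete glucose
    consumption, leaving roughly 4 g/L of sorbitol unused.  Ethanol
    production closes the electron balance exactly, so the noise-free
    output has a degree-of-reduction recovery of 100%.
    """
    Cx = 1.18
    D = 0.025
    registry = default_registry()
    q_glc = D * (10.0 - 0.03) * 1000.0 / (registry.molar_mass("glucose") * Cx)
    q_sorb = 0.675
    glc_mol = (10.0 - 0.03) / registry.molar_mass("glucose")       # mol/L throughput
    sorb_mol = q_sorb * Cx / (1000.0 * D)
    gly_mol = 1.0 * Cx / 1000.0  # 1 mmol glycerol per g biomass
    bio = registry["biomass"]
    e_in = registry.gamma("glucose") * glc_mol + registry.gamma("sorbitol") * sorb_mol
    e_out_other = (
        registry.gamma("glycerol") * gly_mol + bio.gamma * Cx / bio.molar_mass
    )
    eth_mol = (e_in - e_out_other) / registry.gamma("ethanol")
    q_eth = D * eth_mol * 1000.0 / Cx
    q_gly = D * gly_mol * 1000.0 / Cx
    spec = ChemostatSimulationSpec(
        q_mmol_g_h={
            "glucose": q_glc,
            "sorbitol": q_sorb,
            "ethanol": -q_eth,
            "glycerol": -q_gly,
        },
        biomass_gL=Cx,
        D=D,
        feed_gL={"glucose": 10.0, "sorbitol": 10.0},
        noise_sigma=noise_sigma,
        seed=seed,
    )
    if events is not None:
        spec.events = sorted(events, key=lambda e: e[0])
    if times_h is not None:
        spec.times_h = tuple(times_h)
    return spec
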