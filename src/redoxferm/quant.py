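"""Quantitative physiology from batch and chemostat measurements.

Batch cultures: the specific growth rate is the slope of ln(biomass)
against time over an exponential-phase window of at least seven samples;
yields and per-biomass stoichiometries are slopes of product (or biomass)
against substrate consumed over the same window, so measurement offsets
cancel.

Chemostats: at steady state the specific growth rate equals the dilution
rate D = F_out/V_L, and biomass-specific rates follow from the feed/outflow
concentration difference,

    q_i = D * (c_in,i - c_out,i) / (M_i * Cx) * 1000   [mmol g^-1 h^-1]

(sign-flipped for products).  When consumption of a non-consumed feed
component ceases, its residual concentration washes back toward the feed
concentration along first-order kinetics

    c(t) = c_in - (c_in - c_t0) * exp(-D * (t - t0)),

which is the fingerprint used here to classify a culture as still
consuming, fully washed-in (consumption lost), or in between.

Because CO2-enriched inlet gas precludes accurate carbon recoveries, the
closure check is an electron balance: the degree-of-reduction recovery, the
percentage of substrate electrons recovered in products plus biomass.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.integrate import cumulative_trapezoid

from .errors import (
    DegenerateRegressionError,
    DomainError,
    InsufficientDataError,
    ParseError,
)
from .stoich import CompoundRegistry, default_registry

#: default resolution of a concentration difference (g/L) below which a
#: consumption is reported as a censored bound rather than a value
BATCH_DETECTION_LIMIT_GL = 0.3
CHEMOSTAT_DETECTION_LIMIT_GL = 0.5


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CultureSeries:
    """Time-resolved culture measurements.

    ``data`` columns: ``time_h``, ``biomass_gL`` and one ``<compound>_gL``
    column per measured metabolite.  Time must be strictly increasing and
    values non-negative.
    """

    data: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time_h", "biomass_gL"):
            if col not in df.columns:
                raise ParseError(f"culture series is missing column {col!r}")
        extra = [c for c in df.columns if c not in ("time_h", "biomass_gL")]
        bad = [c for c in extra if not c.endswith("_gL")]
        if bad:
            raise ParseError(f"unexpected columns (must end in _gL): {bad}")
        if df[df.columns].isna().any().any():
            col = df.columns[df.isna().any()][0]
            row = int(df.index[df[col].isna()][0])
            raise ParseError(f"missing value at row {row}, column {col!r}")
        t = df["time_h"].to_numpy(float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ParseError("time_h must be strictly increasing")
        values = df[[c for c in df.columns if c != "time_h"]].to_numpy(float)
        if values.size and values.min() < -1e-9:
            raise ParseError("concentrations and biomass must be non-negative")

    @property
    def time(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    @property
    def biomass(self) -> np.ndarray:
        return self.data["biomass_gL"].to_numpy(float)

    @property
    def compounds(self) -> List[str]:
        return [
            c[: -len("_gL")]
            for c in self.data.columns
            if c.endswith("_gL") and c != "biomass_gL"
        ]

    def concentration(self, compound: str) -> np.ndarray:
        col = f"{compound}_gL"
        if col not in self.data.columns:
            raise ParseError(f"series has no column {col!r}")
        return self.data[col].to_numpy(float)


@dataclass(frozen=True)
class SteadyState:
    """One steady-state chemostat observation (a single replicate)."""

    D: float                    # dilution rate, 1/h (= F_out / V_L)
    c_in: Mapping[str, float]   # feed concentrations, g/L
    c_out: Mapping[str, float]  # residual concentrations, g/L
    Cx: float                   # biomass dry weight, g/L
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise DomainError("dilution rate must be positive")
        if any(v < 0 for v in self.c_out.values()):
            raise DomainError("residual concentrations must be non-negative")


@dataclass(frozen=True)
class WashinParams:
    """Parameters of the first-order wash-in curve after a cessation event."""

    c_in: float   # feed concentration, g/L
    c_t0: float   # concentration at the event time, g/L
    D: float      # dilution rate, 1/h
    t0: float = 0.0  # event time, h

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise DomainError("dilution rate must be positive")


@dataclass(frozen=True)
class Measurement:
    """A value that may be a censored upper bound (below detection)."""

    value: float
    censored: bool = False

    def __float__(self) -> float:
        return float(self.value)

    def __str__(self) -> str:
        return f"< {self.value:.3g}" if self.censored else f"{self.value:.6g}"


# ---------------------------------------------------------------------------
# growth-rate estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthFit:
    """Log-linear growth-rate fit with its 95% confidence interval."""

    mu: float
    stderr: float
    ci_low: float
    ci_high: float
    r_squared: float
    n_points: int
    window: Tuple[float, float]

    def to_dict(self) -> Dict[str, float]:
        return {
            "mu_per_h": self.mu,
            "stderr": self.stderr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "window_start_h": self.window[0],
            "window_end_h": self.window[1],
        }


def _window_mask(time: np.ndarray, window: Optional[Tuple[float, float]]) -> np.ndarray:
    if window is None:
        return np.ones_like(time, dtype=bool)
    lo, hi = window
    return (time >= lo) & (time <= hi)


def _fast_r2(t: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Slope and R^2 of a simple regression (used for window search)."""
    t = t - t.mean()
    y0 = y - y.mean()
    stt = float(t @ t)
    if stt == 0:
        return 0.0, 0.0
    slope = float(t @ y0) / stt
    ss_tot = float(y0 @ y0)
    if ss_tot == 0:
        return slope, 0.0
    ss_res = ss_tot - slope**2 * stt
    return slope, 1.0 - ss_res / ss_tot


def select_exponential_window(
    series: CultureSeries, min_points: int = 7
) -> Tuple[float, float]:
    """Contiguous window (>= min_points, positive slope) maximizing the R^2
    of ln(biomass) versus time."""
    t = series.time
    x = series.biomass
    if np.any(x <= 0):
        keep = x > 0
        t, x = t[keep], x[keep]
    n = t.size
    if n < min_points:
        raise InsufficientDataError(
            f"{n} positive-biomass points; at least {min_points} required"
        )
    lnx = np.log(x)
    best = None
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            slope, r2 = _fast_r2(t[i:j], lnx[i:j])
            if slope <= 0:
                continue
            if best is None or r2 > best[0]:
                best = (r2, t[i], t[j - 1])
    if best is None:
        raise InsufficientDataError("no growing window found")
    return best[1], best[2]


def fit_growth_rate(
    series: CultureSeries,
    window: Optional[Tuple[float, float]] = None,
    min_points: int = 7,
    alpha: float = 0.05,
) -> GrowthFit:
    """Specific growth rate as the slope of ln(biomass) versus time.

    With ``window=None`` the exponential phase is auto-selected as the
    highest-R^2 sliding window of at least ``min_points`` samples.
    """
    if window is None:
        window = select_exponential_window(series, min_points)
    mask = _window_mask(series.time, window)
    t = series.time[mask]
    x = series.biomass[mask]
    if t.size < min_points:
        raise InsufficientDataError(
            f"{t.size} points in window; at least {min_points} required"
        )
    if np.any(x <= 0):
        raise DomainError("biomass must be positive for a log-linear fit")
    res = sm.OLS(np.log(x), sm.add_constant(t)).fit()
    ci = res.conf_int(alpha)
    return GrowthFit(
        mu=float(res.params[1]),
        stderr=float(res.bse[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        r_squared=float(res.rsquared),
        n_points=int(t.size),
        window=(float(t[0]), float(t[-1])),
    )


# ---------------------------------------------------------------------------
# batch stoichiometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatchYields:
    """Slope-based yields over an exponential-phase window."""

    y_biomass_g_per_mol: float              # g biomass per mol glucose
    y_ethanol_mol_per_mol: float            # mol ethanol per mol glucose
    y_ethanol_substrates_mol_per_mol: float  # mol ethanol per mol (glc + sorb)
    glycerol_per_biomass_mmol_per_g: float
    sorbitol_per_biomass: Measurement       # mmol per g biomass, may be censored
    window: Tuple[float, float]
    n_points: int

    def to_dict(self) -> Dict[str, object]:
        return {
            "y_biomass_g_per_mol": self.y_biomass_g_per_mol,
            "y_ethanol_mol_per_mol": self.y_ethanol_mol_per_mol,
            "y_ethanol_substrates_mol_per_mol": self.y_ethanol_substrates_mol_per_mol,
            "glycerol_per_biomass_mmol_per_g": self.glycerol_per_biomass_mmol_per_g,
            "sorbitol_per_biomass_mmol_per_g": self.sorbitol_per_biomass.value,
            "sorbitol_censored": self.sorbitol_per_biomass.censored,
            "window_start_h": self.window[0],
            "window_end_h": self.window[1],
            "n_points": self.n_points,
        }


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(x, y, 1)[0])


def batch_stoichiometry(
    series: CultureSeries,
    window: Optional[Tuple[float, float]] = None,
    substrate: str = "glucose",
    co_substrate: str = "sorbitol",
    detection_limit_gL: float = BATCH_DETECTION_LIMIT_GL,
    registry: Optional[CompoundRegistry] = None,
) -> BatchYields:
    """Yields and per-biomass stoichiometries from a batch series.

    Each quantity is the least-squares slope of a product (or biomass)
    against molar substrate consumption over the window, which makes the
    estimates insensitive to initial-concentration offsets.  Co-substrate
    consumption below ``detection_limit_gL`` is reported as a censored
    bound, not as a value.
    """
    registry = registry or default_registry()
    if window is None:
        window = select_exponential_window(series)
    mask = _window_mask(series.time, window)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"{n} points in window; need at least 3")

    M_sub = registry.molar_mass(substrate)
    c_sub = series.concentration(substrate)[mask]
    consumed = (c_sub[0] - c_sub) / M_sub  # mol/L
    if consumed.max() <= 1e-12 or np.allclose(c_sub, c_sub[0]):
        raise DegenerateRegressionError(
            f"no {substrate} consumption in window; slopes are undefined"
        )

    biomass = series.biomass[mask]
    d_biomass = biomass - biomass[0]
    y_x = _slope(consumed, biomass)

    M_eth = registry.molar_mass("ethanol")
    eth_mol = series.concentration("ethanol")[mask] / M_eth
    y_eth = _slope(consumed, eth_mol)

    # combined substrates (molar)
    co_available = co_substrate in series.compounds
    if co_available:
        M_co = registry.molar_mass(co_substrate)
        c_co = series.concentration(co_substrate)[mask]
        co_consumed = (c_co[0] - c_co) / M_co
    else:
        co_consumed = np.zeros_like(consumed)
    y_eth_substrates = _slope(consumed + co_consumed, eth_mol)

    M_gly = registry.molar_mass("glycerol")
    gly_mmol = series.concentration("glycerol")[mask] / M_gly * 1000.0
    if np.ptp(d_biomass) <= 1e-12:
        raise DegenerateRegressionError("no biomass formation in window")
    gly_per_x = _slope(biomass, gly_mmol)

    dX = float(d_biomass[-1])
    if co_available and float(c_co[0] - c_co[-1]) >= detection_limit_gL:
        co_mmol = (c_co[0] - c_co) / M_co * 1000.0
        sorb_per_x = Measurement(_slope(biomass, co_mmol), censored=False)
    else:
        bound = detection_limit_gL / registry.molar_mass(co_substrate) * 1000.0 / max(dX, 1e-12)
        sorb_per_x = Measurement(bound, censored=True)

    t = series.time[mask]
    return BatchYields(
        y_biomass_g_per_mol=y_x,
        y_ethanol_mol_per_mol=y_eth,
        y_ethanol_substrates_mol_per_mol=y_eth_substrates,
        glycerol_per_biomass_mmol_per_g=gly_per_x,
        sorbitol_per_biomass=sorb_per_x,
        window=(float(t[0]), float(t[-1])),
        n_points=n,
    )


# ---------------------------------------------------------------------------
# chemostat rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemostatQuant:
    """Biomass-specific rates and yields of one steady state.

    ``q`` holds consumption rates for substrates and production rates for
    products, both positive, in mmol per g biomass per h.  ``per_biomass``
    is q/D for substrates (mmol consumed per g biomass formed), the exact
    identity the printed chemostat tables obey.
    """

    D: float
    q: Dict[str, Union[float, Measurement]]
    per_biomass: Dict[str, Union[float, Measurement]]
    y_biomass_substrates_g_per_mol: float
    y_ethanol_glucose_mol_per_mol: Optional[float]
    y_ethanol_substrates_mol_per_mol: float
    glycerol_per_biomass_mmol_per_g: float
    replicate: str = ""

    def to_dict(self) -> Dict[str, object]:
        def enc(v):
            if isinstance(v, Measurement):
                return {"value": v.value, "censored": v.censored}
            return v

        return {
            "replicate": self.replicate,
            "D_per_h": self.D,
            "q_mmol_g_h": {k: enc(v) for k, v in self.q.items()},
            "per_biomass_mmol_g": {k: enc(v) for k, v in self.per_biomass.items()},
            "y_biomass_substrates_g_per_mol": self.y_biomass_substrates_g_per_mol,
            "y_ethanol_glucose_mol_per_mol": self.y_ethanol_glucose_mol_per_mol,
            "y_ethanol_substrates_mol_per_mol": self.y_ethanol_substrates_mol_per_mol,
            "glycerol_per_biomass_mmol_per_g": self.glycerol_per_biomass_mmol_per_g,
        }


def chemostat_rates(
    ss: SteadyState,
    substrates: Sequence[str] = ("glucose", "sorbitol"),
    detection_limit_gL: float = CHEMOSTAT_DETECTION_LIMIT_GL,
    registry: Optional[CompoundRegistry] = None,
) -> ChemostatQuant:
    """Specific rates, yields and per-biomass consumptions at steady state."""
    if ss.Cx <= 0:
        raise DomainError("biomass concentration must be positive")
    registry = registry or default_registry()

    q: Dict[str, Union[float, Measurement]] = {}
    per_biomass: Dict[str, Union[float, Measurement]] = {}
    substrate_mol = 0.0
    names = set(ss.c_in) | set(ss.c_out)
    for name in sorted(names):
        M = registry.molar_mass(name)
        delta = ss.c_in.get(name, 0.0) - ss.c_out.get(name, 0.0)
        rate = ss.D * delta / (M * ss.Cx) * 1000.0
        if name in substrates:
            if delta < detection_limit_gL:
                bound_rate = ss.D * detection_limit_gL / (M * ss.Cx) * 1000.0
                q[name] = Measurement(bound_rate, censored=True)
                per_biomass[name] = Measurement(bound_rate / ss.D, censored=True)
            else:
                q[name] = rate
                per_biomass[name] = rate / ss.D
                substrate_mol += delta / M
        else:
            q[name] = -rate  # production positive

    if substrate_mol <= 0:
        raise DegenerateRegressionError("no measurable substrate consumption")

    y_x = ss.Cx / substrate_mol  # g biomass per mol substrates

    M_eth = registry.molar_mass("ethanol")
    eth_mol = (ss.c_out.get("ethanol", 0.0) - ss.c_in.get("ethanol", 0.0)) / M_eth
    glc_mol = (
        (ss.c_in.get("glucose", 0.0) - ss.c_out.get("glucose", 0.0))
        / registry.molar_mass("glucose")
        if "glucose" in names
        else 0.0
    )
    y_eth_glc = eth_mol / glc_mol if glc_mol > 0 else None
    y_eth_sub = eth_mol / substrate_mol

    M_gly = registry.molar_mass("glycerol")
    gly_mol = (ss.c_out.get("glycerol", 0.0) - ss.c_in.get("glycerol", 0.0)) / M_gly
    gly_per_x = gly_mol * 1000.0 / ss.Cx

    return ChemostatQuant(
        D=ss.D,
        q=q,
        per_biomass=per_biomass,
        y_biomass_substrates_g_per_mol=y_x,
        y_ethanol_glucose_mol_per_mol=y_eth_glc,
        y_ethanol_substrates_mol_per_mol=y_eth_sub,
        glycerol_per_biomass_mmol_per_g=gly_per_x,
        replicate=ss.replicate,
    )


def pooled_steady_state(states: Sequence[SteadyState]) -> SteadyState:
    """Average replicate steady states into one pooled observation."""
    if not states:
        raise InsufficientDataError("no steady states to pool")
    names_in = sorted({n for s in states for n in s.c_in})
    names_out = sorted({n for s in states for n in s.c_out})
    return SteadyState(
        D=float(np.mean([s.D for s in states])),
        c_in={n: float(np.mean([s.c_in.get(n, 0.0) for s in states])) for n in names_in},
        c_out={n: float(np.mean([s.c_out.get(n, 0.0) for s in states])) for n in names_out},
        Cx=float(np.mean([s.Cx for s in states])),
        replicate="pooled",
    )


# ---------------------------------------------------------------------------
# wash-in kinetics
# ---------------------------------------------------------------------------

def washin_concentration(params: WashinParams, t) -> Union[float, np.ndarray]:
    """Residual concentration expected when consumption has fully stopped.

    c(t) = c_in - (c_in - c_t0) * exp(-D * (t - t0)),  valid for t >= t0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < params.t0 - 1e-12):
        raise DomainError(f"t must be >= event time t0={params.t0}")
    c = params.c_in - (params.c_in - params.c_t0) * np.exp(-params.D * (t_arr - params.t0))
    return float(c) if np.isscalar(t) else c


@dataclass(frozen=True)
class WashinClassification:
    """Outcome of comparing residuals to the wash-in curve."""

    label: str  # "washed-in" | "consuming" | "partial"
    mean_abs_relative_deviation: float
    mean_relative_deviation: float
    n_points: int
    tolerance: float

    def to_dict(self) -> Dict[str, object]:
        return {
            "classification": self.label,
            "mean_abs_relative_deviation": self.mean_abs_relative_deviation,
            "mean_relative_deviation": self.mean_relative_deviation,
            "n_points": self.n_points,
            "tolerance": self.tolerance,
        }


def detect_consumption_loss(
    series: CultureSeries,
    params: WashinParams,
    compound: str = "sorbitol",
    tol: float = 0.05,
    min_points: int = 3,
) -> WashinClassification:
    """Classify post-event residuals against the pure wash-in prediction.

    Observations tracking the wash-in curve within ``tol`` (mean relative
    deviation) mean consumption has ceased; a plateau persistently below
    the curve by more than ``tol`` means the culture is still consuming;
    anything else is classified as partial.
    """
    mask = series.time >= params.t0
    t = series.time[mask]
    obs = series.concentration(compound)[mask]
    if t.size < min_points:
        raise InsufficientDataError(
            f"{t.size} post-event points; at least {min_points} required"
        )
    pred = washin_concentration(params, t)
    pred = np.where(np.abs(pred) < 1e-12, 1e-12, pred)
    rel = (obs - pred) / pred
    mean_abs = float(np.mean(np.abs(rel)))
    mean_signed = float(np.mean(rel))
    if mean_abs < tol:
        label = "washed-in"
    elif mean_signed < -tol:
        label = "consuming"
    else:
        label = "partial"
    return WashinClassification(
        label=label,
        mean_abs_relative_deviation=mean_abs,
        mean_relative_deviation=mean_signed,
        n_points=int(t.size),
        tolerance=tol,
    )


# ---------------------------------------------------------------------------
# electron balance
# ---------------------------------------------------------------------------

def reduction_recovery(
    consumed_mol: Mapping[str, float],
    produced_mol: Mapping[str, float],
    biomass_g: float = 0.0,
    registry: Optional[CompoundRegistry] = None,
) -> float:
    """Degree-of-reduction recovery in percent.

    100 * (electrons in products + electrons in biomass) / (electrons in
    consumed substrates).  CO2 contributes nothing by construction
    (gamma = 0); biomass electrons use the per-Cmol biomass entry of the
    registry.  A closed electron balance gives exactly 100%.
    """
    registry = registry or default_registry()
    e_in = sum(registry.gamma(n) * mol for n, mol in consumed_mol.items())
    if e_in <= 0:
        raise DomainError("substrate electron input must be positive")
    e_out = sum(registry.gamma(n) * mol for n, mol in produced_mol.items())
    if biomass_g:
        bio = registry["biomass"]
        e_out += bio.gamma * biomass_g / bio.molar_mass  # type: ignore[operator]
    return 100.0 * e_out / e_in


def reduction_recovery_chemostat(
    ss: SteadyState,
    substrates: Sequence[str] = ("glucose", "sorbitol"),
    products: Sequence[str] = ("ethanol", "glycerol", "acetate"),
    registry: Optional[CompoundRegistry] = None,
) -> float:
    """Electron recovery of a steady state, per litre of throughput."""
    registry = registry or default_registry()
    consumed = {}
    for name in substrates:
        delta = ss.c_in.get(name, 0.0) - ss.c_out.get(name, 0.0)
        if delta > 0:
            consumed[name] = delta / registry.molar_mass(name)
    produced = {}
    for name in products:
        delta = ss.c_out.get(name, 0.0) - ss.c_in.get(name, 0.0)
        if delta > 0:
            produced[name] = delta / registry.molar_mass(name)
    return reduction_recovery(consumed, produced, biomass_g=ss.Cx, registry=registry)


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def correct_ethanol_evaporation(
    series: CultureSeries,
    k_evap: float,
    compound: str = "ethanol",
) -> CultureSeries:
    """Add back first-order stripping losses from the off-gas.

    corrected(t) = measured(t) + k_evap * integral of measured dt
    (trapezoidal).  ``k_evap`` is the first-order evaporation constant in
    1/h; 0 returns the series unchanged.
    """
    if k_evap < 0:
        raise DomainError("evaporation constant must be >= 0")
    col = f"{compound}_gL"
    measured = series.concentration(compound)
    losses = k_evap * cumulative_trapezoid(measured, series.time, initial=0.0)
    df = series.data.copy()
    df[col] = measured + losses
    return CultureSeries(data=df, metadata=dict(series.metadata))
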