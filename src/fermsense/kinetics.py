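"""Off-gas rates, windowed growth-rate estimation and logistic growth fits.

OUR and CER are computed from inlet/outlet gas fractions and air flow using
the ideal-gas mass density rho·M/(R·T); the outlet flow is closed by the
inert (nitrogen) balance, and both rates are divided by the broth volume to
give volumetric rates in g L⁻¹ h⁻¹.  RQ is reported on a molar basis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .media import FeedPolicy, exponential_feed_rate, initial_feed_rate  # noqa: F401

__all__ = [
    "GasConditions",
    "LogisticParams",
    "LogisticFitError",
    "outlet_flow",
    "compute_our",
    "compute_cer",
    "compute_rq",
    "estimate_growth_rate",
    "logistic_curve",
    "fit_logistic",
    "exponential_feed_rate",
    "initial_feed_rate",
]


@dataclass(frozen=True)
class GasConditions:
    """Head-space/off-gas analyser conditions.

    ``pressure_pa`` is the absolute pressure, so pressure·M/(R·T) is the
    pure-gas mass density.  ``c_o2_in``/``c_co2_in`` are the inlet
    (calibration-gas) fractions in percent.
    """

    pressure_pa: float = 101325.0
    temp_k: float = 310.15          # 37 °C cultivation
    r_gas: float = 8.314            # J/(mol K)
    m_o2: float = 32.0              # g/mol
    m_co2: float = 44.01            # g/mol
    f_air_in: float = 12.0          # L/h air sparging
    c_o2_in: float = 20.95          # % O2 in inlet air
    c_co2_in: float = 0.04          # % CO2 in inlet air

    def __post_init__(self) -> None:
        if self.temp_k <= 0 or self.pressure_pa <= 0 or self.f_air_in <= 0:
            raise ValueError("temperature, pressure and air flow must be positive")
        for name in ("c_o2_in", "c_co2_in"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100]")

    def gas_density(self, molar_mass: float) -> float:
        """Pure-gas mass density in g/L at the stated pressure and temperature."""
        return self.pressure_pa * molar_mass / (self.r_gas * self.temp_k) / 1000.0

    @property
    def molar_flow_in(self) -> float:
        """Total inlet molar flow in mol/h."""
        return self.pressure_pa * (self.f_air_in / 1000.0) / (self.r_gas * self.temp_k)


def _series_cols(series, names):
    frame = getattr(series, "frame", series)
    out = []
    for n in names:
        if n not in frame:
            raise KeyError(f"channel {n!r} missing from series")
        out.append(np.asarray(frame[n], dtype=float))
    return out


def outlet_flow(gas: GasConditions, o2_out_pct, co2_out_pct):
    """Outlet gas flow (L/h) from the inert-gas (N2) balance."""
    o2 = np.asarray(o2_out_pct, dtype=float)
    co2 = np.asarray(co2_out_pct, dtype=float)
    if np.any(o2 + co2 >= 100.0):
        raise ValueError("outlet O2 + CO2 fractions must sum below 100%")
    inert_in = 100.0 - gas.c_o2_in - gas.c_co2_in
    return gas.f_air_in * inert_in / (100.0 - o2 - co2)


def compute_our(series, gas: GasConditions) -> np.ndarray:
    """Volumetric oxygen uptake rate, g O2 L⁻¹ h⁻¹."""
    o2, co2, vol = _series_cols(series, ["o2_out_pct", "co2_out_pct", "volume_l"])
    f_out = outlet_flow(gas, o2, co2)
    dens = gas.gas_density(gas.m_o2)
    return dens * (gas.f_air_in * gas.c_o2_in / 100.0 - f_out * o2 / 100.0) / vol


def compute_cer(series, gas: GasConditions) -> np.ndarray:
    """Volumetric carbon-dioxide evolution rate, g CO2 L⁻¹ h⁻¹."""
    o2, co2, vol = _series_cols(series, ["o2_out_pct", "co2_out_pct", "volume_l"])
    f_out = outlet_flow(gas, o2, co2)
    dens = gas.gas_density(gas.m_co2)
    return dens * (f_out * co2 / 100.0 - gas.f_air_in * gas.c_co2_in / 100.0) / vol


def compute_rq(
    our, cer, gas: GasConditions | None = None, our_threshold: float = 1e-4
) -> np.ndarray:
    """Molar respiratory quotient CER/OUR; NaN where OUR is below threshold.

    ``our``/``cer`` are the mass-based volumetric rates; the ratio is
    rescaled by the molar masses so RQ is mol CO2 per mol O2.
    """
    gas = gas or GasConditions()
    our = np.asarray(our, dtype=float)
    cer = np.asarray(cer, dtype=float)
    if our.shape != cer.shape:
        raise ValueError("OUR and CER series must be aligned")
    rq = np.full(our.shape, np.nan)
    ok = our > our_threshold
    rq[ok] = (cer[ok] / gas.m_co2) / (our[ok] / gas.m_o2)
    return rq


def estimate_growth_rate(
    biomass,
    volume,
    window_minutes: float = 20.0,
    sample_interval_minutes: float = 5.0,
    center: bool = True,
) -> np.ndarray:
    """Windowed specific growth rate mu_est = ln(X_t·V_t / X_{t−w}·V_{t−w}) / Δt.

    With ``center=True`` (default) each estimate is placed at the midpoint of
    its window, which removes the first-order lag bias of a trailing window;
    half a window at each end of the series carries no estimate (NaN).  With
    ``center=False`` the estimate is placed at the trailing edge and the
    first full window carries no estimate.  Samples where X·V is
    non-positive at either window end are NaN.
    """
    x = np.asarray(biomass, dtype=float)
    v = np.asarray(volume, dtype=float)
    if x.shape != v.shape or x.ndim != 1:
        raise ValueError("biomass and volume must be aligned 1-d series")
    k = int(round(window_minutes / sample_interval_minutes))
    if k < 1:
        raise ValueError("window must span at least one sampling interval")
    m = x * v
    n = m.size
    mu = np.full(n, np.nan)
    dt_h = sample_interval_minutes / 60.0
    if center:
        half = max(1, round(k / 2))
        span_h = 2 * half * dt_h
        lo, hi = m[: n - 2 * half], m[2 * half :]
        ok = (lo > 0) & (hi > 0)
        vals = np.full(n - 2 * half, np.nan)
        vals[ok] = np.log(hi[ok] / lo[ok]) / span_h
        mu[half : n - half] = vals
    else:
        span_h = k * dt_h
        lo, hi = m[: n - k], m[k:]
        ok = (lo > 0) & (hi > 0)
        vals = np.full(n - k, np.nan)
        vals[ok] = np.log(hi[ok] / lo[ok]) / span_h
        mu[k:] = vals
    return mu


@dataclass(frozen=True)
class LogisticParams:
    """Sigmoidal growth parameters: plateau Xm (g/L), delay lambda_x (h) and
    maximum volumetric growth rate Vx (g/L/h)."""

    xm: float
    lambda_x: float
    vx: float

    def __post_init__(self) -> None:
        if self.xm <= 0 or self.vx <= 0:
            raise ValueError("xm and vx must be positive")


def logistic_curve(t, params: LogisticParams) -> np.ndarray:
    """x(t) = Xm / (1 + exp(2 + (4·Vx/Xm)·(lambda_x − t)))."""
    t = np.asarray(t, dtype=float)
    z = 2.0 + (4.0 * params.vx / params.xm) * (params.lambda_x - t)
    # clip keeps exp finite for extreme starts during fitting
    return params.xm / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))


class LogisticFitError(RuntimeError):
    """Raised when no start converges; carries the best parameters found."""

    def __init__(self, message: str, best: LogisticParams, sse: float) -> None:
        super().__init__(message)
        self.best = best
        self.sse = sse


def fit_logistic(
    times, cdw, n_starts: int = 8, seed: int = 0
) -> tuple[LogisticParams, float]:
    """Least-squares logistic fit to offline cell-dry-weight samples.

    Multi-start local optimization: a data-driven start (Xm from the largest
    sample, Vx from the steepest finite-difference slope, lambda_x from the
    time the curve passes Xm/(1+e²)) plus seeded ±50% jitters of it.
    Returns the converged parameters and the sum of squared errors.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(cdw, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 samples spanning lag and plateau")
    if np.any(y < 0):
        raise ValueError("cell dry weight must be non-negative")

    ymax = float(y.max())
    if ymax <= 0:
        raise ValueError("all-zero samples cannot constrain a growth curve")
    slopes = np.diff(y) / np.maximum(np.diff(t), 1e-9)
    vx0 = max(float(slopes.max()), ymax / (t.max() - t.min() + 1e-9))
    thresh = ymax / (1.0 + math.e**2)
    above = np.nonzero(y >= thresh)[0]
    lam0 = float(t[above[0]]) if above.size else float(t[t.size // 2])

    rng = np.random.default_rng(seed)
    starts = [(1.05 * ymax, lam0, vx0)]
    for _ in range(n_starts - 1):
        f = rng.uniform(0.5, 1.5, size=3)
        starts.append((1.05 * ymax * f[0], max(lam0 * f[1], 0.01), vx0 * f[2]))

    def resid(p):
        xm, lam, vx = p
        return logistic_curve(t, LogisticParams(xm, lam, vx)) - y

    lower = [0.2 * ymax, 0.0, 1e-6]
    upper = [10.0 * max(ymax, 1e-6), float(t.max()) + 1.0, np.inf]
    best, best_sse, converged = None, np.inf, False
    for p0 in starts:
        p0 = np.clip(p0, lower, upper)
        try:
            res = least_squares(
                resid, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:  # pragma: no cover - defensive
            continue
        sse = float(np.sum(res.fun**2))
        if sse < best_sse:
            best, best_sse = res.x, sse
            converged = converged or res.success
    if best is None:
        raise LogisticFitError(
            "logistic fit failed from every start",
            LogisticParams(ymax, lam0, vx0),
            np.inf,
        )
    params = LogisticParams(*map(float, best))
    if not converged:
        raise LogisticFitError("no start converged", params, best_sse)
    return params, best_sse
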