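"""Assay analytics: inactivation kinetics, DSF melt curves, Michaelis-Menten
fits, activity units, substrate conversion, and reusability summaries.

Models
------
* Thermal inactivation is treated as first-order: A(t) = 100 exp(-k t),
  with half-life t_1/2 = ln 2 / k. A model-free linear interpolation of the
  first 50 % crossing is available as a fallback.
* DSF melt curves are fitted with the Boltzmann sigmoid
  F(T) = F_min + (F_max - F_min) / (1 + exp((Tm - T)/s)) on the ascending
  limb (the curve is truncated at the global fluorescence maximum to drop
  post-peak aggregation decay); a derivative method (T at max dF/dT) is the
  cross-check.
* Steady-state kinetics use v = Vmax S / (Km + S). kcat is derived only
  when an explicit molar mass is supplied; catalytic efficiency is kcat/Km.
* One enzyme unit (U) releases 1 umol of reducing sugar per minute;
  specific activity is U per mg enzyme.
* Substrate conversion counts each chitobiose (M = 424.40 g/mol) as one
  reducing end: conversion % = product mass / substrate mass x 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

CHITOBIOSE_MOLAR_MASS = 424.40  # g/mol, (GlcNAc)2


class AssayDataError(ValueError):
    """Raised when assay input data violates its contract."""


class FitWarning(UserWarning):
    """Non-fatal fit diagnostics (non-decaying data, poor saturation...)."""


# ---------------------------------------------------------------------------
# Datasets


@dataclass
class ActivityTimeCourse:
    """Residual activity (% of t=0) vs heat-challenge time at a fixed
    temperature."""

    temperature: float                 # degrees C
    times: np.ndarray                  # min
    residual: np.ndarray               # % of initial

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.times.shape != self.residual.shape:
            raise AssayDataError("times and residual activities differ in length")
        if np.any(self.times < 0):
            raise AssayDataError("times must be non-negative")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise AssayDataError("times must be strictly increasing")
        if self.times[0] == 0 and abs(self.residual[0] - 100.0) > 5.0:
            warnings.warn("residual activity at t=0 deviates from 100%",
                          FitWarning, stacklevel=2)


@dataclass
class MeltCurve:
    temperatures: np.ndarray           # degrees C
    fluorescence: np.ndarray           # arbitrary units

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise AssayDataError("temperature and fluorescence lengths differ")
        if not np.all(np.diff(self.temperatures) > 0):
            raise AssayDataError("temperatures must be strictly increasing")


@dataclass
class KineticsDataset:
    substrate: np.ndarray              # substrate concentration (e.g. mg/mL)
    rates: np.ndarray                  # umol min^-1 mg^-1
    substrate_units: str = "mg/mL"

    def __post_init__(self) -> None:
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.substrate.shape != self.rates.shape:
            raise AssayDataError("substrate and rate arrays differ in length")
        if np.any(self.substrate <= 0):
            raise AssayDataError("substrate concentrations must be positive")
        if np.any(self.rates < 0):
            raise AssayDataError("rates must be non-negative")


@dataclass
class CycleYields:
    """Product measured per reuse cycle.

    ``mode='accumulation'`` means each value is the running total present in
    the (reused) reaction system; ``mode='per_cycle'`` means each value is
    that cycle's own release.
    """

    values: np.ndarray                 # mM product (or conversion %)
    mode: Literal["accumulation", "per_cycle"] = "accumulation"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise AssayDataError("at least one cycle is required")


# ---------------------------------------------------------------------------
# Results


@dataclass
class HalfLifeFit:
    k: float                           # min^-1
    t_half: float                      # min
    method: str
    residual_ss: float | None = None
    k_stderr: float | None = None


@dataclass
class TmFit:
    tm: float                          # degrees C
    method: str
    slope: float | None = None         # Boltzmann slope parameter, degrees C
    residual_ss: float | None = None


@dataclass
class KineticsFit:
    vmax: float                        # umol min^-1 mg^-1
    km: float                          # substrate units
    substrate_units: str
    kcat: float | None = None          # s^-1
    efficiency: float | None = None    # kcat / Km
    specific_activity: float | None = None  # U/mg (= vmax under the unit definition)
    residual_ss: float | None = None
    vmax_stderr: float | None = None
    km_stderr: float | None = None


@dataclass
class ReusabilitySummary:
    cumulative: float                  # final running total (accumulation) or sum
    fold_vs_first: float
    n_cycles: int
    final_cycle_conversion_pct: float | None = None


# ---------------------------------------------------------------------------
# Fits


def fit_half_life(
    tc: ActivityTimeCourse, method: Literal["exp_fit", "interpolate"] = "exp_fit"
) -> HalfLifeFit:
    """Half-life from a residual-activity time course.

    ``exp_fit`` (default): least-squares fit of A(t) = 100 exp(-k t);
    t_1/2 = ln 2 / k. ``interpolate``: linear interpolation of the first
    crossing of 50 %.
    """
    t, a = tc.times, tc.residual
    if method == "exp_fit":
        if len(t) < 3:
            raise AssayDataError("exponential fit needs at least 3 points")
        # log-linear seed, then nonlinear refinement on the original scale
        positive = a > 0
        k0 = 0.01
        if positive.sum() >= 2:
            slope = np.polyfit(t[positive], np.log(a[positive]), 1)[0]
            k0 = max(-slope, 1e-6)
        popt, pcov = curve_fit(lambda tt, k: 100.0 * np.exp(-k * tt), t, a,
                               p0=[k0], maxfev=10000)
        k = float(popt[0])
        if k <= 0:
            warnings.warn(f"fitted rate constant k={k:.4g} min^-1 is not a decay",
                          FitWarning, stacklevel=2)
            return HalfLifeFit(k=k, t_half=np.inf, method=method)
        resid = a - 100.0 * np.exp(-k * t)
        stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None
        return HalfLifeFit(k=k, t_half=float(np.log(2) / k), method=method,
                           residual_ss=float(np.sum(resid ** 2)), k_stderr=stderr)
    if method == "interpolate":
        below = np.nonzero(a <= 50.0)[0]
        if len(below) == 0 or below[0] == 0:
            raise AssayDataError("activity never crosses 50% (or starts below it); "
                                 "cannot interpolate a half-life")
        j = below[0]
        t_half = t[j - 1] + (50.0 - a[j - 1]) * (t[j] - t[j - 1]) / (a[j] - a[j - 1])
        k = float(np.log(2) / t_half)
        return HalfLifeFit(k=k, t_half=float(t_half), method=method)
    raise ValueError(f"unknown method {method!r}")


def _boltzmann(T, fmin, fmax, tm, slope):
    return fmin + (fmax - fmin) / (1.0 + np.exp((tm - T) / slope))


def fit_tm(mc: MeltCurve, method: Literal["boltzmann", "derivative"] = "boltzmann") -> TmFit:
    """Melting temperature from a DSF fluorescence-vs-temperature curve.

    The ascending limb up to the global fluorescence maximum is used;
    beyond the peak, dye-protein aggregation artefacts dominate.
    """
    T, F = mc.temperatures, mc.fluorescence
    if len(T) < 8:
        raise AssayDataError("at least 8 points spanning the transition are required")
    peak = int(np.argmax(F))
    if peak < 3:
        raise AssayDataError("no ascending transition before the fluorescence maximum")
    Tt, Ft = T[: peak + 1], F[: peak + 1]
    if np.ptp(Ft) <= 0:
        raise AssayDataError("flat melt curve: no transition to fit")

    if method == "derivative":
        dF = np.gradient(F, T)
        # restrict to the ascending limb
        j = int(np.argmax(dF[: peak + 1]))
        return TmFit(tm=float(T[j]), method=method)
    if method == "boltzmann":
        fmin0, fmax0 = float(Ft.min()), float(Ft.max())
        half = fmin0 + 0.5 * (fmax0 - fmin0)
        tm0 = float(Tt[np.argmin(np.abs(Ft - half))])
        try:
            popt, _ = curve_fit(_boltzmann, Tt, Ft,
                                p0=[fmin0, fmax0, tm0, 2.0], maxfev=20000)
        except RuntimeError as exc:
            raise AssayDataError(f"Boltzmann fit failed to converge: {exc}") from exc
        fmin, fmax, tm, slope = map(float, popt)
        resid = Ft - _boltzmann(Tt, *popt)
        return TmFit(tm=tm, method=method, slope=slope,
                     residual_ss=float(np.sum(resid ** 2)))
    raise ValueError(f"unknown method {method!r}")


def delta_tm(tm_variant: float, tm_wt: float) -> float:
    """Melting-temperature shift of a variant relative to the wild type."""
    return tm_variant - tm_wt


def fit_michaelis_menten(
    kd: KineticsDataset, molar_mass: float | None = None
) -> KineticsFit:
    """Nonlinear least-squares Michaelis-Menten fit, v = Vmax S / (Km + S).

    ``molar_mass`` (g/mol) converts Vmax (umol min^-1 mg^-1) to kcat (s^-1):
    kcat = Vmax x M / 60000. Catalytic efficiency kcat/Km is reported in
    (1/substrate units) s^-1.
    """
    S, v = kd.substrate, kd.rates
    if len(np.unique(S)) < 4:
        raise AssayDataError("at least 4 distinct substrate concentrations required")
    vmax0 = float(v.max()) * 1.5 if v.max() > 0 else 1.0
    km0 = float(np.median(S))
    popt, pcov = curve_fit(lambda s, vmax, km: vmax * s / (km + s), S, v,
                           p0=[vmax0, km0], maxfev=20000)
    vmax, km = map(float, popt)
    if vmax <= 0 or km <= 0:
        raise AssayDataError(f"non-physical fit (Vmax={vmax:.3g}, Km={km:.3g})")
    if km > S.max():
        warnings.warn(
            f"Km ({km:.3g}) exceeds the highest substrate concentration; the "
            "data do not saturate and the confidence bounds are wide",
            FitWarning, stacklevel=2)
    resid = v - vmax * S / (km + S)
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [None, None]
    kcat = efficiency = None
    if molar_mass is not None:
        kcat = vmax * molar_mass / 60000.0
        efficiency = kcat / km
    return KineticsFit(
        vmax=vmax, km=km, substrate_units=kd.substrate_units,
        kcat=kcat, efficiency=efficiency, specific_activity=None,
        residual_ss=float(np.sum(resid ** 2)),
        vmax_stderr=None if stderr[0] is None else float(stderr[0]),
        km_stderr=None if stderr[1] is None else float(stderr[1]),
    )


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat / Km in (1/substrate-concentration-units) per second."""
    if km <= 0:
        raise AssayDataError("Km must be positive")
    return kcat / km


def optimal_temperature(profile: list[tuple[float, float]]) -> float:
    """Temperature of maximum specific activity; ties resolve to the lower
    temperature with a warning."""
    if len(profile) < 3:
        raise AssayDataError("at least 3 temperatures are required")
    temps = np.array([p[0] for p in profile], dtype=float)
    acts = np.array([p[1] for p in profile], dtype=float)
    best = acts.max()
    winners = np.sort(temps[acts == best])
    if len(winners) > 1:
        warnings.warn(
            f"activity ties at {winners.tolist()}; reporting the lowest temperature",
            FitWarning, stacklevel=2)
    return float(winners[0])


def activity_units(
    reducing_sugar_umol: float, minutes: float, enzyme_mg: float
) -> tuple[float, float]:
    """(U, U/mg): one unit releases 1 umol reducing sugar per minute."""
    if minutes <= 0 or enzyme_mg <= 0:
        raise AssayDataError("duration and enzyme mass must be positive")
    units = reducing_sugar_umol / minutes
    return units, units / enzyme_mg


def reducing_sugar_to_conversion(
    product_umol: float,
    substrate_mass_mg: float,
    basis: Literal["chitobiose"] = "chitobiose",
) -> float:
    """Substrate conversion (%) from the amount of product released.

    Each chitobiose carries one reducing end, so product mass =
    product_umol x M(chitobiose) x 1e-3 mg. Values above 100 % are reported
    with a warning rather than clipped.
    """
    if substrate_mass_mg <= 0:
        raise AssayDataError("substrate mass must be positive")
    if basis != "chitobiose":
        raise ValueError(f"unsupported conversion basis {basis!r}")
    product_mass_mg = product_umol * CHITOBIOSE_MOLAR_MASS * 1e-3
    pct = product_mass_mg / substrate_mass_mg * 100.0
    if pct > 100.0:
        warnings.warn(f"computed conversion {pct:.1f}% exceeds 100%",
                      FitWarning, stacklevel=2)
    return pct


def reusability_summary(
    cy: CycleYields,
    substrate_mass_mg_per_cycle: float | None = None,
    reaction_volume_ml: float | None = None,
) -> ReusabilitySummary:
    """Summarize a multi-cycle reuse experiment.

    cumulative = final value under accumulation semantics, or the sum under
    per-cycle semantics; fold = cumulative / first-cycle value. When the
    per-cycle substrate load and reaction volume are given, the final
    cycle's conversion (%) is also computed (product of the last cycle
    alone, chitobiose basis).
    """
    vals = cy.values
    if cy.mode == "accumulation":
        cumulative = float(vals[-1])
        per_cycle = np.diff(np.concatenate([[0.0], vals]))
    else:
        cumulative = float(vals.sum())
        per_cycle = vals
    first = float(per_cycle[0]) if cy.mode == "per_cycle" else float(vals[0])
    if first == 0:
        raise AssayDataError("first-cycle yield is zero; fold change undefined")
    final_conv = None
    if substrate_mass_mg_per_cycle is not None and reaction_volume_ml is not None:
        final_umol = float(per_cycle[-1]) * reaction_volume_ml  # mM * mL = umol
        final_conv = reducing_sugar_to_conversion(final_umol, substrate_mass_mg_per_cycle)
    return ReusabilitySummary(
        cumulative=cumulative,
        fold_vs_first=cumulative / first,
        n_cycles=len(vals),
        final_cycle_conversion_pct=final_conv,
    )
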