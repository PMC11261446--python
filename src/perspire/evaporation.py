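"""Evaporation-rate and mass-transfer analysis for ventilated-capsule data.

The capsule is flushed with dry air at a set flow rate Q̇ (L·min⁻¹); a
humidity probe at the outlet reads the water-vapor concentration C_out
(g·m⁻³). Because the physiology-standard units cancel their conversion
factors, the evaporation rate in mg·min⁻¹ is simply

    ṁe = Q̇ · (C_out − C_in)

and the flux is ṁe″ = ṁe / A_total (mg·min⁻¹·cm⁻²) over the exposed
skin area. When only a fraction ω of the skin is wet, an isothermal-film
model gives

    ṁe″ = ω · h_m · (C_sat(T_sur) − C∞)

so the slope of flux against ω measures h_m·C_sat(T_sur) and separates
the dropwise and filmwise sweating modes: the dropwise slope is roughly
three times the filmwise one under matched conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .physics import AmbientState, PhysicalConstants, saturation_vapor_concentration

__all__ = [
    "cascade_lag_filter",
    "EvapSeries",
    "MassTransferFit",
    "DecayFit",
    "evaporation_series",
    "flux_from_film_model",
    "fit_mode_slopes",
    "fit_first_order_decay",
    "quasi_steady_residual",
    "lewis_equivalent_wind_speed",
    "flat_plate_equivalent_velocity",
    "AirProperties",
]

#: (m·s⁻¹ × g·m⁻³ = g·m⁻²·s⁻¹) → mg·min⁻¹·cm⁻²: ×1000 mg/g ×60 s/min ÷1e4 cm²/m².
FLUX_SI_TO_PHYS = 1000.0 * 60.0 / 1e4  # = 6.0


@dataclass
class EvapSeries:
    """Time series of capsule flow, concentrations and evaporation rate.

    ``rate`` is Q̇·(C_out − C_in) in mg·min⁻¹ and ``flux`` is
    rate/total_area in mg·min⁻¹·cm⁻². Negative rates (condensation) are
    preserved, not clipped.
    """

    time_min: np.ndarray
    flow_lpm: np.ndarray
    cout_gm3: np.ndarray
    cin_gm3: np.ndarray
    rate_mg_min: np.ndarray
    flux_mg_min_cm2: np.ndarray
    total_area_cm2: float
    has_negative_rate: bool = False


@dataclass
class MassTransferFit:
    """Per-mode linear fit of evaporative flux against wet fraction."""

    mode: str
    slope: float  # d(flux)/dω, mg·min⁻¹·cm⁻²
    intercept: float
    h_m: float  # m·s⁻¹
    surface_temperature: float  # °C
    r_value: float
    n_points: int
    window: tuple


@dataclass
class DecayFit:
    """First-order exponential fit C(t) = C_ss + A·exp(−t/τ)."""

    steady_value: float
    amplitude: float
    time_constant: float  # same unit as the time axis
    residual_norm: float
    identifiable: bool = True


def evaporation_series(
    time_min,
    flow_lpm,
    cout_gm3,
    cin_gm3=0.0,
    total_area_cm2: float = 1.93,
) -> EvapSeries:
    """Compute evaporation rate and flux from capsule probe records.

    Parameters use the physiology convention: flow in L·min⁻¹,
    concentrations in g·m⁻³; the product is directly mg·min⁻¹.
    ``cin_gm3`` may be a scalar (dry inlet: 0) or a series.
    """
    time_min = np.asarray(time_min, dtype=float)
    flow = np.asarray(flow_lpm, dtype=float)
    cout = np.asarray(cout_gm3, dtype=float)
    cin = np.broadcast_to(np.asarray(cin_gm3, dtype=float), cout.shape).copy()
    if np.any(flow <= 0):
        raise ValueError("flow rate must be strictly positive")
    if np.any(cin < 0) or np.any(cout < 0):
        raise ValueError("concentrations must be nonnegative")
    if total_area_cm2 <= 0:
        raise ValueError("total_area_cm2 must be strictly positive")
    rate = flow * (cout - cin)
    return EvapSeries(
        time_min=time_min,
        flow_lpm=flow,
        cout_gm3=cout,
        cin_gm3=cin,
        rate_mg_min=rate,
        flux_mg_min_cm2=rate / total_area_cm2,
        total_area_cm2=total_area_cm2,
        has_negative_rate=bool(np.any(rate < 0)),
    )


def flux_from_film_model(omega, h_m: float, surface_temperature: float, c_inf: float = 0.0):
    """Isothermal-film evaporative flux ω·h_m·(C_sat(T_sur) − C∞).

    Parameters
    ----------
    omega : float or array
        Wet area fraction in [0, 1].
    h_m : float
        Mass transfer coefficient, m·s⁻¹.
    surface_temperature : float
        Film surface temperature, °C.
    c_inf : float
        Far-field vapor concentration, g·m⁻³.

    Returns
    -------
    Flux in mg·min⁻¹·cm⁻², linear in ω.
    """
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0) or np.any(om > 1):
        raise ValueError("omega must lie in [0, 1]")
    if h_m < 0:
        raise ValueError("h_m must be nonnegative")
    dc = saturation_vapor_concentration(surface_temperature) - c_inf
    flux = om * h_m * dc * FLUX_SI_TO_PHYS
    return float(flux) if np.isscalar(omega) else flux


def h_m_from_slope(slope: float, surface_temperature: float, c_inf: float = 0.0) -> float:
    """Invert dṁe″/dω = h_m·(C_sat(T_sur) − C∞) for h_m (m·s⁻¹)."""
    dc = saturation_vapor_concentration(surface_temperature) - c_inf
    return slope / (dc * FLUX_SI_TO_PHYS)


def fit_mode_slopes(
    flux_mg_min_cm2,
    omega,
    mode_windows: dict,
    surface_temperature: float = 34.0,
    c_inf: float = 0.0,
):
    """Fit flux-vs-ω slopes per sweating-mode window and their ratio.

    Parameters
    ----------
    flux_mg_min_cm2, omega : arrays
        Paired evaporative-flux and wet-fraction samples.
    mode_windows : dict
        Mode label → boolean mask or index array selecting its samples
        (mode windows are user-specified; the modes were separated by
        inspection in the original analysis).
    surface_temperature : float
        T_sur used to convert each slope to h_m (default 34 °C, the
        average observed film surface temperature).

    Returns
    -------
    (fits, ratio) where ``fits`` maps mode → :class:`MassTransferFit`
    and ``ratio`` is h_m(dropwise)/h_m(filmwise) when both labels are
    present, else None.
    """
    flux = np.asarray(flux_mg_min_cm2, dtype=float)
    om = np.asarray(omega, dtype=float)
    fits: dict[str, MassTransferFit] = {}
    for mode, sel in mode_windows.items():
        sel = np.asarray(sel)
        f, w = flux[sel], om[sel]
        if f.size < 3:
            raise ValueError(f"mode window '{mode}' has fewer than 3 points")
        if np.ptp(w) == 0:
            raise ValueError(f"mode window '{mode}' has constant wet fraction")
        res = stats.linregress(w, f)
        fits[mode] = MassTransferFit(
            mode=mode,
            slope=float(res.slope),
            intercept=float(res.intercept),
            h_m=h_m_from_slope(float(res.slope), surface_temperature, c_inf),
            surface_temperature=surface_temperature,
            r_value=float(res.rvalue),
            n_points=int(f.size),
            window=(int(np.flatnonzero(sel)[0]), int(np.flatnonzero(sel)[-1]))
            if sel.dtype == bool
            else (int(np.min(sel)), int(np.max(sel))),
        )
    ratio = None
    if "dropwise" in fits and "filmwise" in fits:
        ratio = fits["dropwise"].h_m / fits["filmwise"].h_m
    return fits, ratio


def cascade_lag_filter(time_s, values, tau1_s: float, tau2_s: float = 0.0):
    """Apply one or two cascaded first-order lags to a sampled signal.

    This reproduces the capsule-mixing + probe response acting on any
    quantity. Because the response is linear, filtering both sides of a
    proportional relation (e.g. flux = h_m·C_sat·ω) with the same
    kernel preserves the proportionality — the standard way to compare
    a lag-measured flux with a fast optically-measured wet fraction
    without deconvolution.
    """
    t = np.asarray(time_s, dtype=float)
    x = np.asarray(values, dtype=float)
    out = x.copy()
    for tau in (tau1_s, tau2_s):
        if tau <= 0:
            continue
        y = out.copy()
        for i in range(1, t.size):
            a = 1.0 - math.exp(-(t[i] - t[i - 1]) / tau)
            y[i] = y[i - 1] + (out[i] - y[i - 1]) * a
        out = y
    return out


def fit_first_order_decay(time, concentration) -> DecayFit:
    """Fit C(t) = C_ss + A·exp(−t/τ) by nonlinear least squares.

    Initialization comes from a log-linear fit of (C − tail mean); τ is
    reported in the units of ``time``. A series with no resolvable
    amplitude (flat within noise) is returned with
    ``identifiable=False`` rather than a spurious τ.
    """
    t = np.asarray(time, dtype=float)
    c = np.asarray(concentration, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 samples for a decay fit")
    t0 = t - t[0]
    span = t0[-1]
    tail = float(np.mean(c[-max(3, c.size // 5):]))
    amp0 = float(c[0] - tail)
    if abs(amp0) < 1e-12 * max(1.0, abs(tail)) or np.ptp(c) == 0:
        return DecayFit(tail, 0.0, math.nan, 0.0, identifiable=False)

    # log-linear initial guess on the portion still far from the tail
    dev = (c - tail) / amp0
    usable = dev > 0.05
    if np.count_nonzero(usable) >= 2:
        p = np.polyfit(t0[usable], np.log(dev[usable]), 1)
        tau0 = -1.0 / p[0] if p[0] < 0 else span / 3.0
    else:
        tau0 = span / 3.0
    tau0 = float(np.clip(tau0, span * 1e-3, span * 10))

    def model(tt, c_ss, a, tau):
        return c_ss + a * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t0, c, p0=[tail, amp0, tau0], maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"decay fit failed to converge (init c_ss={tail:.3g}, "
            f"A={amp0:.3g}, tau={tau0:.3g}): {exc}"
        ) from exc
    resid = c - model(t0, *popt)
    tau = float(abs(popt[2]))
    if tau <= 0 or not np.isfinite(tau):
        return DecayFit(float(popt[0]), float(popt[1]), math.nan, float(
            np.linalg.norm(resid)), identifiable=False)
    return DecayFit(
        steady_value=float(popt[0]),
        amplitude=float(popt[1]),
        time_constant=tau,
        residual_norm=float(np.linalg.norm(resid)),
    )


def quasi_steady_residual(elapsed, time_constant: float):
    """Fraction of the initial deviation remaining after ``elapsed``.

    exp(−t/τ); e.g. 4 min after a flow step with τ = 1.5 min, 6.9% of
    the initial concentration offset remains.
    """
    if time_constant <= 0:
        raise ValueError("time_constant must be strictly positive")
    r = np.exp(-np.asarray(elapsed, dtype=float) / time_constant)
    return float(r) if np.isscalar(elapsed) else r


def lewis_equivalent_wind_speed(
    flux_mg_min_cm2: float,
    omega: float,
    surface_temperature: float,
    ambient: AmbientState,
    constants: PhysicalConstants | None = None,
) -> float:
    """Wind speed over the head producing a given evaporative flux.

    Combines the Lewis-analogy mass transfer coefficient
    h_m = lewis_ratio·h_t with the head correlation h_t = a·V^0.5 in the
    film model and solves for V:

        V = [ flux_SI / (ω · lewis_ratio · a · ΔC) ]²

    with ΔC = C_sat(T_sur) − C∞ in g·m⁻³ and flux in SI (g·m⁻²·s⁻¹).
    """
    if constants is None:
        constants = PhysicalConstants()
    if flux_mg_min_cm2 < 0:
        raise ValueError("flux must be nonnegative")
    if not 0 < omega <= 1:
        raise ValueError("omega must lie in (0, 1]")
    dc = saturation_vapor_concentration(surface_temperature) - ambient.vapor_concentration
    if dc <= 0:
        raise ValueError("ambient air is saturated relative to the surface")
    flux_si = flux_mg_min_cm2 / FLUX_SI_TO_PHYS
    root = flux_si / (omega * constants.lewis_ratio * constants.head_ht_coefficient * dc)
    return root**2


@dataclass
class AirProperties:
    """Dry-air transport properties near a ~30 °C film temperature."""

    thermal_conductivity: float = 0.026  # W·m⁻¹·K⁻¹
    kinematic_viscosity: float = 1.6e-5  # m²·s⁻¹
    prandtl: float = 0.71


def flat_plate_equivalent_velocity(
    h_t: float, plate_length: float, air: AirProperties | None = None
) -> float:
    """Free-stream velocity matching h_t for laminar flow over a plate.

    Inverts the average-Nusselt correlation Nu = 0.664·Re^0.5·Pr^(1/3):

        V = (h_t·L / (0.664·Pr^(1/3)·k))² · ν / L

    Over the short exposed skin segment the boundary layers are thin, so
    a head-scale h_t of ~18 W·m⁻²·K⁻¹ corresponds to only ~0.3 m·s⁻¹
    when referred to a 1.5 cm plate.
    """
    if air is None:
        air = AirProperties()
    if h_t <= 0 or plate_length <= 0:
        raise ValueError("h_t and plate_length must be strictly positive")
    denom = 0.664 * air.prandtl ** (1.0 / 3.0) * air.thermal_conductivity
    return (h_t * plate_length / denom) ** 2 * air.kinematic_viscosity / plate_length
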