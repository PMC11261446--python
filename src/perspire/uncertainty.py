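"""Measurement-uncertainty propagation for capsule evaporation rates.

The evaporation rate is the product of the flow-controller reading and
the humidity-probe concentration reading (with dry inlet air), so its
systematic uncertainty follows from standard error propagation of that
product. The random component uses a two-sided Student-t interval over
replicate runs; for the three replicates typical of bench validation
the 95% multiplier is 4.30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "UncertaintyBudget",
    "systematic_uncertainty",
    "random_uncertainty",
    "total_uncertainty",
    "build_budget",
]

#: Humidity probe accuracy, g·m⁻³ (manufacturer spec).
DEFAULT_U_COUT = 0.18

#: Flow controller: max(0.1% of full scale, 0.6% of reading), L·min⁻¹.
DEFAULT_FLOW_FULL_SCALE = 1.0


def flow_uncertainty(flow_lpm: float, full_scale: float = DEFAULT_FLOW_FULL_SCALE) -> float:
    """Controller spec: larger of 0.1% full scale and 0.6% of reading."""
    return max(0.001 * full_scale, 0.006 * flow_lpm)


@dataclass
class UncertaintyBudget:
    """Systematic/random/total uncertainty of one evaporation rate.

    All uncertainties in mg·min⁻¹; inputs are echoed for the report.
    """

    u_systematic: float
    u_random: float
    u_total: float
    flow_lpm: float
    cout_gm3: float
    u_flow: float
    u_cout: float
    sigma: float
    n_replicates: int
    confidence: float


def systematic_uncertainty(
    flow_lpm: float, cout_gm3: float, u_flow: float, u_cout: float
) -> float:
    """Propagated instrument uncertainty of ṁe = Q̇·Cout, mg·min⁻¹.

    U_sys = sqrt(Q̇²·U_Cout² + Cout²·U_Q̇²) in the L·min⁻¹ × g·m⁻³ →
    mg·min⁻¹ unit convention.
    """
    if min(flow_lpm, cout_gm3, u_flow, u_cout) < 0:
        raise ValueError("all inputs must be nonnegative")
    return math.hypot(flow_lpm * u_cout, cout_gm3 * u_flow)


def random_uncertainty(sigma: float, n_replicates: int, confidence: float = 0.95) -> float:
    """Two-sided Student-t half-width over replicate measurements.

    Returns t_{(1+confidence)/2, n−1} · σ; with n = 3 at 95% the
    multiplier is 4.303 (df = 2).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    t_crit = stats.t.ppf(0.5 + confidence / 2.0, df=n_replicates - 1)
    return float(t_crit * sigma)


def total_uncertainty(u_systematic: float, u_random: float) -> float:
    """Root-sum-square combination of the two components."""
    if u_systematic < 0 or u_random < 0:
        raise ValueError("uncertainties must be nonnegative")
    return math.hypot(u_systematic, u_random)


def build_budget(
    flow_lpm: float,
    cout_gm3: float,
    sigma: float,
    n_replicates: int = 3,
    confidence: float = 0.95,
    u_flow: float | None = None,
    u_cout: float = DEFAULT_U_COUT,
    flow_full_scale: float = DEFAULT_FLOW_FULL_SCALE,
) -> UncertaintyBudget:
    """Assemble a full uncertainty budget for one operating point."""
    if u_flow is None:
        u_flow = flow_uncertainty(flow_lpm, flow_full_scale)
    u_sys = systematic_uncertainty(flow_lpm, cout_gm3, u_flow, u_cout)
    u_rand = random_uncertainty(sigma, n_replicates, confidence)
    return UncertaintyBudget(
        u_systematic=u_sys,
        u_random=u_rand,
        u_total=total_uncertainty(u_sys, u_rand),
        flow_lpm=flow_lpm,
        cout_gm3=cout_gm3,
        u_flow=u_flow,
        u_cout=u_cout,
        sigma=sigma,
        n_replicates=n_replicates,
        confidence=confidence,
    )
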