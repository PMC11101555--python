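"""Orifice-consistent scaling of the applied pressure difference.

Driving the shell mesh with the raw mean aortic pressure (MAP) ignores
that paravalvular leakage is physically closer to flow through an
orifice than to flow through a full annular die.  The boundary pressure
is therefore rescaled in five steps:

1. pick the slice that throttles the flow — the one with the smallest
   maximum gap h_max (ties broken toward the smallest z);
2. compute its cross-sectional area A₂ and the Bernoulli orifice flow
   rate it would pass under the MAP,

       Q_B = C_d √(2Δp/ρ) · A₂ · (1 − (A₂/A₁)²)^(−1/2),

   with A₁ the aortic cross-section and C_d a discharge coefficient;
3. invert the annular-die (annular Poiseuille) flow expression

       Q_c = ∫₀^{2π} (Δp R_o⁴ / 16 μ L) · Φ(B) dθ,
       Φ(B) = 1 − B⁴ − (1 − B²)² / ln(1/B),   B = R_i/R_o,

   evaluated by the periodic trapezoid rule over the slice's angular
   stations, to find the pressure difference that would drive Q_B
   through an annular die shaped like the selected slice;
4. correct for the volume mismatch between that idealised die
   (V_c = A₂·L) and the actual leakage volume V = Σ A_slice Δl via
   f_V = V_c / V;
5. apply Δp_app = f_V · Δp_inverted at the inlet.

All steps are linear in Q_B, so scaling the MAP by s scales Q_B — and
hence Δp_app — by √s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import SliceStack, leakage_volume
from . import units

__all__ = [
    "HemodynamicContext",
    "ScalingReport",
    "select_scaling_slice",
    "bernoulli_orifice_flow",
    "annular_die_flow",
    "invert_annular_die",
    "scale_pressure",
]

#: default aorta diameter used to derive A1 when not supplied (m)
DEFAULT_AORTA_DIAMETER = 25e-3
#: sharp-edged-orifice discharge coefficient
DEFAULT_CD = 0.61


def _default_a1() -> float:
    return float(np.pi * (DEFAULT_AORTA_DIAMETER / 2) ** 2)


@dataclass(frozen=True)
class HemodynamicContext:
    """Hemodynamic boundary-condition parameters (SI).

    map_pressure : diastolic transvalvular pressure difference (MAP), Pa.
        Default 100 mmHg.
    p0 : reference (outlet) pressure, Pa.
    aorta_area : aortic cross-sectional area A₁ (m²).  Defaults to a
        25 mm-diameter circle; should be patient-specific in real use.
    discharge_coefficient : orifice C_d, default 0.61 (sharp-edged).
    heart_rate : beats per minute.
    diastolic_fraction : fraction of the cycle spent in diastole.
    """

    map_pressure: float = 100.0 * units.MMHG_TO_PA
    p0: float = 0.0
    aorta_area: float = field(default_factory=_default_a1)
    discharge_coefficient: float = DEFAULT_CD
    heart_rate: float = 70.0
    diastolic_fraction: float = 0.65

    def __post_init__(self) -> None:
        if self.map_pressure <= 0:
            raise ValueError("map_pressure must be positive")
        if not (0 < self.discharge_coefficient <= 1):
            raise ValueError("discharge_coefficient must be in (0, 1]")
        if not (0 < self.diastolic_fraction < 1):
            raise ValueError("diastolic_fraction must be in (0, 1)")
        if self.aorta_area <= 0:
            raise ValueError("aorta_area must be positive")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")


@dataclass(frozen=True)
class ScalingReport:
    """Full trace of the pressure-scaling pipeline (SI units)."""

    selected_slice_index: int
    h_max: tuple          # per-slice maximum gap (m)
    A2: float             # selected-slice area (m²)
    Q_B: float            # Bernoulli orifice flow rate (m³/s)
    dp_inverted: float    # annular-die pressure for Q_B (Pa)
    V_c: float            # idealised die volume A2*L (m³)
    V: float              # actual leakage volume (m³)
    f_V: float            # V_c / V
    dp_applied: float     # f_V * dp_inverted (Pa)
    L: float              # axial extent used (m)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["h_max"] = list(self.h_max)
        return d


def select_scaling_slice(stack: SliceStack) -> int:
    """Index of the slice with the smallest maximum gap among open slices.

    Fully occluded (zero-area) slices are skipped; ties go to the
    smallest z.  Raises if every slice is occluded (Q = 0 path).
    """
    areas = stack.areas()
    open_slices = areas > 0
    if not open_slices.any():
        raise ValueError("all slices are fully occluded; the leak path is closed (Q = 0)")
    h_max = stack.h_max.copy()
    h_max[~open_slices] = np.inf
    return int(np.argmin(h_max))


def bernoulli_orifice_flow(dp: float, ctx: HemodynamicContext, A2: float, rho: float = 1060.0) -> float:
    """Ideal-orifice flow rate with area-ratio correction (m³/s)."""
    if dp < 0:
        raise ValueError("pressure difference must be non-negative")
    if not (0 < A2 < ctx.aorta_area):
        raise ValueError(
            f"orifice area A2={A2:.3e} m² must be positive and smaller than "
            f"the aortic area A1={ctx.aorta_area:.3e} m²"
        )
    ratio = A2 / ctx.aorta_area
    return (
        ctx.discharge_coefficient
        * np.sqrt(2.0 * dp / rho)
        * A2
        / np.sqrt(1.0 - ratio**2)
    )


def _annular_bracket(B: np.ndarray) -> np.ndarray:
    """Φ(B) = 1 − B⁴ − (1−B²)²/ln(1/B) for 0 < B < 1; 1 at B=0; 0 for B ≥ 1."""
    B = np.asarray(B, dtype=float)
    out = np.zeros_like(B)
    out[B <= 0] = 1.0
    inner = (B > 0) & (B < 1)
    b = B[inner]
    out[inner] = 1.0 - b**4 - (1.0 - b**2) ** 2 / np.log(1.0 / b)
    return out


def annular_die_flow(
    dp: float,
    mu: float,
    L: float,
    inner_radius: np.ndarray,
    outer_radius: np.ndarray,
    theta: np.ndarray | None = None,
) -> float:
    """Pressure-driven flow through an annular die with θ-varying radii.

    Q_c = ∮ (Δp R_o⁴ / 16 μ L) Φ(R_i/R_o) dθ, integrated with the
    periodic composite trapezoid rule over the angular stations
    (uniform stations assumed when ``theta`` is omitted).  Contact
    stations (R_i ≥ R_o) contribute nothing; a fully blocked profile
    gives Q_c = 0.
    """
    R_i = np.asarray(inner_radius, dtype=float)
    R_o = np.asarray(outer_radius, dtype=float)
    if np.any(R_o <= 0):
        raise ValueError("outer radius must be positive")
    if mu <= 0 or L <= 0:
        raise ValueError("viscosity and length must be positive")
    B = R_i / R_o
    integrand = R_o**4 * _annular_bracket(B) / (16.0 * mu * L)
    if theta is None:
        weights = np.full(R_i.size, 2.0 * np.pi / R_i.size)
    else:
        theta = np.asarray(theta, dtype=float)
        dtheta = np.diff(theta, append=theta[0] + 2.0 * np.pi)
        weights = 0.5 * (dtheta + np.roll(dtheta, 1))
    return float(dp * (integrand @ weights))


def invert_annular_die(
    Q_target: float,
    mu: float,
    L: float,
    inner_radius: np.ndarray,
    outer_radius: np.ndarray,
    theta: np.ndarray | None = None,
) -> float:
    """Pressure difference driving ``Q_target`` through the annular die.

    The die flow is linear in Δp, so the inversion is exact:
    Δp = Q_target / K with K the flow at unit pressure difference.
    """
    K = annular_die_flow(1.0, mu, L, inner_radius, outer_radius, theta)
    if K == 0:
        raise ValueError("slice is fully blocked (zero conductance); cannot invert")
    return Q_target / K


def scale_pressure(
    stack: SliceStack,
    ctx: HemodynamicContext,
    mu: float = 0.0035,
    rho: float = 1060.0,
    L: float | None = None,
) -> ScalingReport:
    """Run the five-step scaling pipeline and return the full trace."""
    if L is None:
        L = stack.axial_length
    if L <= 0:
        raise ValueError("axial extent L must be positive")
    try:
        k = select_scaling_slice(stack)
    except ValueError as exc:
        raise ValueError(f"slice selection: {exc}") from exc
    areas = stack.areas()
    A2 = float(areas[k])
    try:
        Q_B = bernoulli_orifice_flow(ctx.map_pressure, ctx, A2, rho=rho)
    except ValueError as exc:
        raise ValueError(f"orifice flow: {exc}") from exc
    try:
        dp_inv = invert_annular_die(
            Q_B, mu, L, stack.inner_radius[k], stack.outer_radius[k], stack.theta
        )
    except ValueError as exc:
        raise ValueError(f"die inversion: {exc}") from exc
    V_c = A2 * L
    V = leakage_volume(stack)
    if V <= 0:
        raise ValueError("volume correction: leakage volume is zero")
    f_V = V_c / V
    return ScalingReport(
        selected_slice_index=k,
        h_max=tuple(stack.h_max),
        A2=A2,
        Q_B=float(Q_B),
        dp_inverted=float(dp_inv),
        V_c=float(V_c),
        V=float(V),
        f_V=float(f_V),
        dp_applied=float(f_V * dp_inv),
        L=float(L),
    )
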