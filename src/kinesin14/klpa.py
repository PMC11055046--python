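"""Closed-form dynamics of the nonprocessive KlpA family.

Three motility contexts share one stepping machinery and differ only in
the elastic energies the neck stalk stores per step:

* **Microtubule gliding** (neck or tail surface-anchored): forward and
  backward elastic energies are equal, the odds reduce to the geometric
  ``r1 = alpha^2`` and the gliding velocity is
  ``v1 = (alpha^2-1)/(alpha^2+1) * k * d``.
* **Single microtubule** (head and tail on the same filament): the
  ATP-state neck offset Delta makes the forward step cost
  ``kappa*(d+Delta)^2/2`` against ``kappa*(d-Delta)^2/2`` backward,
  giving ``r2 = alpha^2 * exp(-2*lam*beta*d*kappa*Delta)``.  Stiff necks
  (large kappa*Delta) invert the bias: the motor switches from minus- to
  plus-end-directed at a crossover stiffness
  ``kappa* = ln(alpha)*kBT/(lam*d*Delta)``.
* **Parallel microtubule overlap** (head and tail on different,
  same-polarity microtubules): the offset is not fixed but uniformly
  distributed over [Delta1, Delta2]; the velocity is the uniform average
  of the single-filament expression over that window, which stays
  minus-end-directed for every kappa when alpha > 1.

Positive velocity = minus-end-directed motor movement (= plus-end
microtubule movement in a gliding assay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate, optimize

from .core import NeckElasticity, PotentialGeometry, ThermoContext, velocity_from_ratio

__all__ = [
    "OverlapConfig",
    "stepping_ratio_gliding",
    "gliding_velocity",
    "atpase_rate_from_gliding",
    "klpa_single_mt_ratio",
    "klpa_single_mt_velocity",
    "crossover_kappa",
    "overlap_velocity",
]


@dataclass(frozen=True)
class OverlapConfig:
    """Uniform neck-offset window inside a parallel-overlap region.

    Delta is drawn uniformly from [Delta_low, Delta_high] (defaults
    -4 nm to +4 nm, half a lattice period either way).
    """

    Delta_low: float = -4.0
    Delta_high: float = 4.0
    rel_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.Delta_low < self.Delta_high:
            raise ValueError(
                f"need Delta_low < Delta_high, got {self.Delta_low}, {self.Delta_high}"
            )
        if not 0 < self.rel_tol < 1:
            raise ValueError("rel_tol must be in (0, 1)")


def stepping_ratio_gliding(geometry: PotentialGeometry) -> float:
    """Forward/backward odds in a gliding assay: r1 = alpha^2.

    Anchoring removes any net elastic bias between the two wells, so only
    the potential asymmetry survives.
    """
    return geometry.alpha**2


def gliding_velocity(k: float, geometry: PotentialGeometry) -> float:
    """Gliding velocity v1 = (alpha^2-1)/(alpha^2+1) * k * d, nm/s."""
    return velocity_from_ratio(k, geometry.d, stepping_ratio_gliding(geometry))


def atpase_rate_from_gliding(v1: float, geometry: PotentialGeometry) -> float:
    """ATPase rate k reproducing an observed gliding velocity.

    Inverts the gliding relation: k = v1*(alpha^2+1)/((alpha^2-1)*d).
    Requires alpha > 1 (a symmetric or backward-biased potential cannot
    glide with positive velocity) and v1 > 0.
    """
    a2 = geometry.alpha**2
    if geometry.alpha <= 1:
        raise ValueError(
            f"no positive-velocity solution for alpha <= 1 (alpha={geometry.alpha})"
        )
    if not v1 > 0:
        raise ValueError(f"gliding velocity must be positive, got {v1}")
    return v1 * (a2 + 1.0) / ((a2 - 1.0) * geometry.d)


def klpa_single_mt_ratio(
    geometry: PotentialGeometry,
    elasticity: NeckElasticity,
    thermo: ThermoContext,
) -> float:
    """Single-filament stepping odds r2 = alpha^2 * exp(-2*lam*beta*d*kappa*Delta).

    Equivalent to the generic biased ratio with forward/backward elastic
    energies kappa*(d±Delta)^2/2; only the product kappa*Delta survives
    in the exponent, so the two can be treated as one parameter.
    """
    x = -2.0 * thermo.lam * thermo.beta * geometry.d * elasticity.kappa * elasticity.Delta
    return geometry.alpha**2 * math.exp(x)


def klpa_single_mt_velocity(
    k: float,
    geometry: PotentialGeometry,
    elasticity: NeckElasticity,
    thermo: ThermoContext,
) -> float:
    """Single-filament velocity v2 = k*d*(r2-1)/(r2+1), nm/s.

    Reduces to the gliding velocity at kappa = 0 and decreases strictly
    with kappa for alpha > 1, Delta > 0, crossing zero at the
    directionality crossover.
    """
    return velocity_from_ratio(
        k, geometry.d, klpa_single_mt_ratio(geometry, elasticity, thermo)
    )


def crossover_kappa(
    geometry: PotentialGeometry,
    elasticity: NeckElasticity,
    thermo: ThermoContext,
) -> float:
    """Neck stiffness kappa* at which single-filament motion is unbiased.

    Closed form kappa* = ln(alpha)*kBT/(lam*d*Delta), the unique zero of
    the single-filament velocity for alpha > 1, Delta > 0.
    """
    if geometry.alpha <= 1:
        raise ValueError(
            f"no crossover for alpha <= 1 (alpha={geometry.alpha}): "
            "velocity never changes sign"
        )
    if elasticity.Delta <= 0:
        raise ValueError(f"crossover requires Delta > 0, got {elasticity.Delta}")
    return math.log(geometry.alpha) * thermo.kBT / (
        thermo.lam * geometry.d * elasticity.Delta
    )


def crossover_kappa_rootfind(
    geometry: PotentialGeometry,
    elasticity: NeckElasticity,
    thermo: ThermoContext,
    k: float = 1.0,
    bracket: tuple[float, float] = (1e-9, 10.0),
    xtol: float = 1e-9,
) -> float:
    """Crossover stiffness found by bisection on the velocity itself.

    Independent numerical route used to validate :func:`crossover_kappa`;
    v2 is strictly decreasing in kappa, so the bracket is guaranteed once
    the endpoints straddle zero.
    """

    def v_of_kappa(kap: float) -> float:
        ela = NeckElasticity(
            kappa=kap,
            Delta=elasticity.Delta,
            DeltaD=elasticity.DeltaD,
            dE_neck_T=elasticity.dE_neck_T,
        )
        return klpa_single_mt_velocity(k, geometry, ela, thermo)

    lo, hi = bracket
    if v_of_kappa(lo) * v_of_kappa(hi) > 0:
        raise ValueError(f"velocity does not change sign on kappa bracket {bracket}")
    return optimize.brentq(v_of_kappa, lo, hi, xtol=xtol)


def overlap_velocity(
    k: float,
    geometry: PotentialGeometry,
    elasticity: NeckElasticity,
    thermo: ThermoContext,
    overlap: OverlapConfig | None = None,
) -> float:
    """Velocity inside a parallel microtubule overlap, nm/s.

    Averages the single-filament velocity over a uniform neck offset
    x in [Delta1, Delta2]:

        v3 = k*d/(Delta2-Delta1) * Int f(x) dx,
        f(x) = (alpha^2 e^{-2 lam beta d kappa x} - 1)
             / (alpha^2 e^{-2 lam beta d kappa x} + 1).

    For alpha > 1 and a window symmetric about zero the average is
    positive for every kappa >= 0: the motor stays minus-end-directed in
    the overlap even when it is plus-end-directed on a single filament.
    Adaptive quadrature at the configured relative tolerance.
    """
    if overlap is None:
        overlap = OverlapConfig()
    log_a2 = 2.0 * math.log(geometry.alpha)
    c = 2.0 * thermo.lam * thermo.beta * geometry.d * elasticity.kappa

    # (A e^{-cx} - 1)/(A e^{-cx} + 1) = tanh((ln A - c x)/2), overflow-safe
    def integrand(x: float) -> float:
        return math.tanh(0.5 * (log_a2 - c * x))

    val, err = integrate.quad(
        integrand,
        overlap.Delta_low,
        overlap.Delta_high,
        epsrel=overlap.rel_tol,
        epsabs=0.0,
        limit=200,
    )
    width = overlap.Delta_high - overlap.Delta_low
    if not math.isfinite(val) or (abs(val) > 1e-12 and err > 1e-4 * abs(val)):
        raise RuntimeError(
            f"overlap quadrature did not converge: value={val}, abs err={err}"
        )
    return k * geometry.d * val / width
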