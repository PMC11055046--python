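"""Closed-form dynamics of the processive GiKIN14a family.

For a processive kinesin-14 the tailless construct already steps with
the geometric odds alpha^2.  Binding the tail to the adjacent filament
adds neck elasticity, which here *helps* forward stepping: the forward
move costs kappa*(d/2 - Delta)^2/2 (the neck rotation contributes about
half a lattice period) while the backward move costs
kappa*(d + Delta)^2/2, so the odds

    r2 = alpha^2 * exp(lam*beta*kappa*(d+Delta)^2 / 2)
                 / exp(lam*beta*kappa*(d/2-Delta)^2 / 2)

grow with kappa and the coupling efficiency E = (r2-1)/(r2+1) — the net
number of forward steps per ATP — saturates at one.

The tail also modulates the ATPase rate through the occupancy of the
ATP-state neck orientation (closed nucleotide pocket).  With the neck
spring stretched by Delta in the ATP-state orientation and by DeltaD in
the ADP-state orientation, and an intrinsic orientation energy
dEneck(T), the rate normalized by the tailless reference is

    k_bar = [A/(A+B)] / [C/(C+1)],
    A = exp(-beta*kappa*Delta^2/2 - beta*dEneck(T)),
    B = exp(-beta*kappa*DeltaD^2/2),  C = exp(-beta*dEneck(T)),

which is exactly 1 at kappa = 0 and rises toward (C+1)/C when
Delta < DeltaD.  The velocity combines both effects: v2 = E*k_bar*k0*d.
"""

from __future__ import annotations

import math

from .core import NeckElasticity, PotentialGeometry, ThermoContext

__all__ = [
    "gikin_tailless_ratio",
    "gikin_ratio",
    "gikin_efficiency",
    "gikin_normalized_atpase",
    "gikin_velocity",
]


def gikin_tailless_ratio(geometry: PotentialGeometry) -> float:
    """Stepping odds of the tailless motor: r2 = alpha^2."""
    return geometry.alpha**2


def gikin_ratio(
    geometry: PotentialGeometry,
    elasticity: NeckElasticity,
    thermo: ThermoContext,
) -> float:
    """Tail-bound stepping odds; reduces to alpha^2 at kappa = 0."""
    d, Delta = geometry.d, elasticity.Delta
    dE_fwd = 0.5 * elasticity.kappa * (0.5 * d - Delta) ** 2
    dE_bwd = 0.5 * elasticity.kappa * (d + Delta) ** 2
    x = thermo.lam * thermo.beta * (dE_bwd - dE_fwd)
    return geometry.alpha**2 * math.exp(x)


def gikin_efficiency(
    geometry: PotentialGeometry,
    elasticity: NeckElasticity,
    thermo: ThermoContext,
) -> float:
    """Chemo-mechanical coupling efficiency E = (r2-1)/(r2+1).

    Net forward steps per ATP hydrolysed: (alpha^2-1)/(alpha^2+1) for the
    tailless motor, increasing with kappa and levelling off at one.
    """
    r2 = gikin_ratio(geometry, elasticity, thermo)
    return (r2 - 1.0) / (r2 + 1.0)


def gikin_normalized_atpase(
    elasticity: NeckElasticity, thermo: ThermoContext
) -> float:
    """ATPase rate of a tail-bound construct over the tailless reference.

    Ratio of closed-nucleotide-pocket occupancies with and without the
    neck spring; exactly 1 at kappa = 0, monotone increasing in kappa
    when Delta < DeltaD, bounded above by (C+1)/C with
    C = exp(-dEneck(T)/kBT).  ``dE_neck_T`` is stored in kBT units.
    """
    beta = thermo.beta
    kap = elasticity.kappa
    dE = elasticity.dE_neck_T  # kBT units: beta * (dE * kBT) = dE
    A = math.exp(-0.5 * beta * kap * elasticity.Delta**2 - dE)
    B = math.exp(-0.5 * beta * kap * elasticity.DeltaD**2)
    C = math.exp(-dE)
    return (A / (A + B)) / (C / (C + 1.0))


def gikin_velocity(
    k0: float,
    geometry: PotentialGeometry,
    elasticity: NeckElasticity,
    thermo: ThermoContext,
) -> float:
    """Single-filament velocity v2 = E * k_bar * k0 * d, nm/s.

    ``k0`` is the ATPase rate of the tailless reference construct;
    positive velocity is minus-end-directed.
    """
    if not (k0 > 0 and math.isfinite(k0)):
        raise ValueError(f"k0 must be positive, got {k0}")
    E = gikin_efficiency(geometry, elasticity, thermo)
    kbar = gikin_normalized_atpase(elasticity, thermo)
    return E * kbar * k0 * geometry.d
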