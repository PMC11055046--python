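"""Shared domain types and Arrhenius-weighted stepping primitives.

Units are fixed package-wide: lengths in nm, forces in pN, energies in
pN·nm, rates in s^-1, stiffnesses in pN/nm.  One kBT = 4.114 pN·nm
(room temperature); this value also reproduces the printed directionality
crossover of the KlpA family (see :mod:`kinesin14.klpa`).

The model pictures a kinesin-14 head interacting with the microtubule
lattice through a periodic, asymmetric potential of period ``d`` (8 nm,
the tubulin repeat).  Per ATP hydrolysed the detached head falls into
either the forward (minus-end) or the backward well; the odds of the two
outcomes are a capture-time ratio carrying a baseline asymmetry ``r0``
(= alpha^2) times Boltzmann factors of the elastic energies stored in the
neck stalk, each attenuated by an energy-splitting factor ``lambda``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

__all__ = [
    "KBT_ROOM",
    "ThermoContext",
    "PotentialGeometry",
    "NeckElasticity",
    "MotorSpec",
    "boltzmann_weight",
    "biased_step_ratio",
    "velocity_from_ratio",
]

#: Thermal energy at room temperature (298.15 K), pN·nm.
KBT_ROOM = 4.114


@dataclass(frozen=True)
class ThermoContext:
    """Thermal energy and energy-splitting factor shared by all weights.

    Parameters
    ----------
    kBT : float
        Thermal energy in pN·nm. Default 4.114 (room temperature).
    lam : float
        Energy-splitting factor lambda in (0, 1]: the fraction of an
        elastic energy change entering the Arrhenius weighting of a
        capture time. Default 0.5.
    """

    kBT: float = KBT_ROOM
    lam: float = 0.5

    def __post_init__(self) -> None:
        if not (self.kBT > 0 and math.isfinite(self.kBT)):
            raise ValueError(f"kBT must be positive and finite, got {self.kBT}")
        if not (0 < self.lam <= 1):
            raise ValueError(f"lam must satisfy 0 < lam <= 1, got {self.lam}")

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kBT (1/(pN·nm))."""
        return 1.0 / self.kBT


@dataclass(frozen=True)
class PotentialGeometry:
    """Geometry of the periodic head–microtubule interaction potential.

    ``alpha = d2/d1`` is the asymmetry of the potential: the ratio of the
    backward to the forward capture distance. ``alpha = 1`` is a symmetric
    potential (unbiased stepping); ``alpha > 1`` biases stepping toward
    the minus end.  Only ``alpha`` and the lattice period ``d`` enter the
    closed-form dynamics; ``d1``/``d2`` individually and the affinity
    labels are descriptive (they document the potential's well depths and
    are never used numerically).
    """

    d: float = 8.0
    alpha: float = 4.0
    d1: Optional[float] = None
    d2: Optional[float] = None
    diffusion_D: Optional[float] = None  # nm^2/s, simulator bookkeeping only
    affinities: dict = field(default_factory=dict)  # E_w1, E_w2, ... pN·nm

    def __post_init__(self) -> None:
        if not (self.d > 0 and math.isfinite(self.d)):
            raise ValueError(f"period d must be positive, got {self.d}")
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.d1 is not None and self.d1 <= 0:
            raise ValueError("d1 must be positive when given")
        if self.d2 is not None and self.d2 <= 0:
            raise ValueError("d2 must be positive when given")
        if self.d1 is not None and self.d2 is not None:
            if abs(self.d2 / self.d1 - self.alpha) > 1e-9 * self.alpha:
                raise ValueError(
                    "inconsistent geometry: d2/d1 = "
                    f"{self.d2 / self.d1} but alpha = {self.alpha}"
                )


@dataclass(frozen=True)
class NeckElasticity:
    """Effective elasticity and orientation offsets of the neck stalk.

    The flexible central region of the coiled-coil neck stalk, together
    with the bendable rigid segments, acts as a linear spring of
    stiffness ``kappa`` (pN/nm). ``Delta`` is the axial offset (nm)
    between the neck-segment endpoints in the ATP-state orientation;
    ``DeltaD`` the analogous ADP-state offset (processive motors only).
    ``dE_neck_T`` is the energy cost, in kBT units, for the neck to adopt
    the ATP-state orientation when ATP is bound.
    """

    kappa: float = 0.0
    Delta: float = 0.0
    DeltaD: float = 0.0
    dE_neck_T: float = 0.0  # kBT units

    def __post_init__(self) -> None:
        if not (self.kappa >= 0 and math.isfinite(self.kappa)):
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        for name in ("Delta", "DeltaD", "dE_neck_T"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


MotorClass = Literal["nonprocessive", "processive"]


@dataclass(frozen=True)
class MotorSpec:
    """A named motor construct binding geometry, elasticity and ATPase rate.

    ``motor_class`` selects the equation family: ``nonprocessive`` motors
    (KlpA family) use the tail-on-same-filament elastic energies, while
    ``processive`` motors (GiKIN14a family) use the half-period forward
    rotation energies and the orientation-modulated ATPase rate.
    ``atpase_rate`` is k for the KlpA family and the tailless reference
    rate k0 for the GiKIN14a family.
    """

    name: str
    motor_class: MotorClass
    geometry: PotentialGeometry
    elasticity: NeckElasticity
    atpase_rate: float

    def __post_init__(self) -> None:
        if self.motor_class not in ("nonprocessive", "processive"):
            raise ValueError(f"unknown motor_class {self.motor_class!r}")
        if not (self.atpase_rate > 0 and math.isfinite(self.atpase_rate)):
            raise ValueError(f"atpase_rate must be positive, got {self.atpase_rate}")


def boltzmann_weight(energy: float, thermo: ThermoContext, use_lambda: bool = True) -> float:
    """Arrhenius/Boltzmann factor exp(lam*beta*E), or exp(beta*E).

    Parameters
    ----------
    energy : float
        Energy in pN·nm; positive energies slow a capture (weight > 1).
    thermo : ThermoContext
    use_lambda : bool
        Apply the energy-splitting factor lambda (capture-time weights);
        ``False`` gives the plain Boltzmann factor (occupancies).
    """
    if not math.isfinite(energy):
        raise ValueError(f"energy must be finite, got {energy}")
    scale = thermo.lam * thermo.beta if use_lambda else thermo.beta
    return math.exp(scale * energy)


def biased_step_ratio(
    r0: float, dE_fwd: float, dE_bwd: float, thermo: ThermoContext
) -> float:
    """Forward/backward stepping odds under elastic biasing.

    The detached head is captured forward in a time proportional to
    exp(lam*beta*dE_fwd) and backward in a time proportional to
    exp(lam*beta*dE_bwd); the forward/backward odds are therefore

        r = r0 * exp(lam*beta*dE_bwd) / exp(lam*beta*dE_fwd)

    with ``r0`` the zero-stiffness (purely geometric) odds.  The ratio is
    invariant under adding a constant to both energies.
    """
    if not (r0 > 0 and math.isfinite(r0)):
        raise ValueError(f"r0 must be positive, got {r0}")
    # single exp of the difference avoids overflow when both energies are large
    if not (math.isfinite(dE_fwd) and math.isfinite(dE_bwd)):
        raise ValueError("step energies must be finite")
    return r0 * math.exp(thermo.lam * thermo.beta * (dE_bwd - dE_fwd))


def velocity_from_ratio(k: float, d: float, r: float) -> float:
    """Mean velocity of tightly coupled stepping, nm/s.

    One ATP hydrolysis yields one step of size ``d``, forward with
    probability r/(1+r): v = k*d*(r-1)/(r+1).  Bounded in (-k*d, k*d);
    the sign follows sign(r-1) (positive = minus-end-directed motor
    movement, equivalently plus-end microtubule movement in gliding).
    """
    if not k > 0:
        raise ValueError(f"rate k must be positive, got {k}")
    if not d > 0:
        raise ValueError(f"step size d must be positive, got {d}")
    if not (r > 0 and math.isfinite(r)):
        raise ValueError(f"stepping ratio r must be positive and finite, got {r}")
    return k * d * (r - 1.0) / (r + 1.0)
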