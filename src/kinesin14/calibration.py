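"""Parameter determination from the published experimental values.

The model has few free parameters and they are anchored one at a time:

1. the ATPase rate k follows from the mean gliding-assay velocity via
   the gliding relation, for a chosen asymmetry alpha;
2. the neck-stalk stiffness (as the product kappa*Delta, pN) follows
   from an observed single-filament velocity by inverting the
   single-filament velocity relation in closed form;
3. kappa itself is kappa*Delta / Delta once Delta is fixed;
4. the error bars of the normalized ATPase rate use first-order
   propagation of the measured rates.

The experimental anchor values (gliding velocities 309 +/- 35 and
287 +/- 10 nm/s; tailless GiKIN14a ATPase 10.0 +/- 0.7 1/s; fitted
kappa*Delta 0.78 and 2.92 pN) ship as a frozen CSV table with the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .core import PotentialGeometry, ThermoContext
from .klpa import gliding_velocity

__all__ = [
    "ExperimentalFixture",
    "CalibrationResult",
    "load_fixtures",
    "average_gliding_velocity",
    "fit_kappa_delta",
    "kappa_from_kappa_delta",
    "normalized_rate_error",
]


@dataclass(frozen=True)
class ExperimentalFixture:
    """One published measurement: construct, quantity, value ± uncertainty."""

    construct: str
    quantity: str
    value: float
    uncertainty: float
    units: str
    source: str

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass(frozen=True)
class CalibrationResult:
    """A fitted parameter with its residual and solver diagnostics."""

    parameter: str
    value: float
    units: str
    residual: float
    diagnostics: dict = field(default_factory=dict)


def load_fixtures() -> list[ExperimentalFixture]:
    """Load the packaged table of published experimental values."""
    with resources.files("kinesin14.data").joinpath("experimental_values.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        ExperimentalFixture(
            construct=row.construct,
            quantity=row.quantity,
            value=float(row.value),
            uncertainty=float(row.uncertainty),
            units=row.units,
            source=row.source,
        )
        for row in df.itertuples()
    ]


def average_gliding_velocity(fixtures: list[ExperimentalFixture]) -> float:
    """Arithmetic mean of the gliding-velocity fixtures, nm/s."""
    vals = [f.value for f in fixtures if f.quantity == "gliding_velocity"]
    if not vals:
        raise ValueError("no gliding_velocity fixtures provided")
    return sum(vals) / len(vals)


def fit_kappa_delta(
    v_obs: float,
    k: float,
    geometry: PotentialGeometry,
    thermo: ThermoContext,
    tol: float = 1e-6,
) -> CalibrationResult:
    """Fit kappa*Delta (pN) to an observed single-filament velocity.

    Inverts v2(kappa*Delta) in closed form:

        kappa*Delta = kBT/(2*lam*d) * ln(alpha^2 * (k*d - v)/(k*d + v)).

    The observed velocity must lie in (-k*d, v1], where v1 is the gliding
    (kappa = 0) velocity; outside that band no non-negative stiffness
    reproduces it (v_obs = v1 gives kappa*Delta = 0 exactly).  The fit is
    verified by substitution.
    """
    if geometry.alpha <= 1:
        raise ValueError("fit requires alpha > 1")
    kd = k * geometry.d
    v1 = gliding_velocity(k, geometry)
    if not (-kd < v_obs <= v1):
        raise ValueError(
            f"observed velocity {v_obs} nm/s outside the attainable range "
            f"({-kd:.3g}, {v1:.3g}) nm/s"
        )
    a2 = geometry.alpha**2
    kappa_delta = (
        thermo.kBT
        / (2.0 * thermo.lam * geometry.d)
        * math.log(a2 * (kd - v_obs) / (kd + v_obs))
    )
    # substitute back through the forward ratio/velocity expressions
    # (direct arithmetic: kappa_delta may round to -0 at the gliding limit)
    r = a2 * math.exp(-2.0 * thermo.lam * thermo.beta * geometry.d * kappa_delta)
    v_check = kd * (r - 1.0) / (r + 1.0)
    residual = v_obs - v_check
    if abs(residual) > tol:
        raise RuntimeError(
            f"closed-form inversion failed verification: residual {residual} nm/s"
        )
    return CalibrationResult(
        parameter="kappa_delta",
        value=kappa_delta,
        units="pN",
        residual=residual,
        diagnostics={"v_obs_nm_per_s": v_obs, "k_per_s": k, "method": "closed_form"},
    )


def kappa_from_kappa_delta(kappa_delta: float, Delta: float) -> float:
    """Neck stiffness kappa = (kappa*Delta)/Delta, pN/nm."""
    if Delta <= 0:
        raise ValueError(f"Delta must be positive, got {Delta}")
    return kappa_delta / Delta


def normalized_rate_error(
    k: float, dk: float, k0: float, dk0: float, reference: bool = False
) -> float:
    """First-order error of the normalized ATPase rate k/k0.

    Delta(k_bar) = dk/k0 + (k/k0^2)*dk0 for a tail-bound construct; for
    the tailless reference itself (``reference=True``) the error is
    simply dk0/k0.
    """
    if k0 <= 0:
        raise ValueError(f"k0 must be positive, got {k0}")
    if dk < 0 or dk0 < 0:
        raise ValueError("uncertainties must be >= 0")
    if reference:
        return dk0 / k0
    return dk / k0 + (k / k0**2) * dk0
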