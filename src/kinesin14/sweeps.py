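"""Parameter sweeps and the self-checking reproduction report.

A sweep evaluates one closed-form quantity over a 1-D parameter grid and
writes a tidy CSV (one row per grid point).  Families cover the standard
views of the model: the ATPase-rate/asymmetry trade-off at fixed gliding
velocity, single-filament and overlap velocities versus neck stiffness
for the KlpA family, and efficiency / normalized ATPase / velocity
versus stiffness for the GiKIN14a family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .core import NeckElasticity, PotentialGeometry, ThermoContext
from . import calibration, gikin, klpa
from .config import GIKIN_K0, KLPA_ATPASE

__all__ = ["SweepSpec", "run_sweep", "run_reproduction_report"]


def _thermo(p: dict) -> ThermoContext:
    return ThermoContext(kBT=p["kBT"], lam=p["lam"])


def _geom(p: dict) -> PotentialGeometry:
    return PotentialGeometry(d=p["d"], alpha=p["alpha"])


def _ela(p: dict) -> NeckElasticity:
    return NeckElasticity(
        kappa=p["kappa"], Delta=p["Delta"], DeltaD=p["DeltaD"],
        dE_neck_T=p["dE_neck_T"],
    )


def _f_atpase_vs_alpha(p: dict) -> float:
    return klpa.atpase_rate_from_gliding(p["v1"], _geom(p))


def _f_klpa_single_mt(p: dict) -> float:
    return klpa.klpa_single_mt_velocity(p["k"], _geom(p), _ela(p), _thermo(p))


def _f_klpa_overlap(p: dict) -> float:
    cfg = klpa.OverlapConfig(Delta_low=p["Delta_low"], Delta_high=p["Delta_high"])
    return klpa.overlap_velocity(p["k"], _geom(p), _ela(p), _thermo(p), cfg)


def _f_gikin_efficiency(p: dict) -> float:
    return gikin.gikin_efficiency(_geom(p), _ela(p), _thermo(p))


def _f_gikin_atpase(p: dict) -> float:
    return gikin.gikin_normalized_atpase(_ela(p), _thermo(p))


def _f_gikin_velocity(p: dict) -> float:
    return gikin.gikin_velocity(p["k0"], _geom(p), _ela(p), _thermo(p))


_KLPA_DEFAULTS = dict(
    kBT=4.114, lam=0.5, d=8.0, alpha=4.0, k=KLPA_ATPASE, v1=298.0,
    kappa=0.0, Delta=2.0, DeltaD=0.0, dE_neck_T=0.0,
    Delta_low=-4.0, Delta_high=4.0, kappa_delta=0.0,
)
_GIKIN_DEFAULTS = dict(
    kBT=4.114, lam=0.5, d=8.0, alpha=4.0, k0=GIKIN_K0,
    kappa=0.0, Delta=0.5, DeltaD=3.5, dE_neck_T=0.8,
)

#: family -> (evaluator, defaults, quantity column name)
FAMILIES: dict[str, tuple[Callable[[dict], float], dict, str]] = {
    "klpa_atpase_vs_alpha": (_f_atpase_vs_alpha, _KLPA_DEFAULTS, "atpase_rate_per_s"),
    "klpa_single_mt": (_f_klpa_single_mt, _KLPA_DEFAULTS, "velocity_nm_per_s"),
    "klpa_overlap": (_f_klpa_overlap, _KLPA_DEFAULTS, "velocity_nm_per_s"),
    "gikin_efficiency": (_f_gikin_efficiency, _GIKIN_DEFAULTS, "efficiency"),
    "gikin_atpase": (_f_gikin_atpase, _GIKIN_DEFAULTS, "normalized_atpase"),
    "gikin_velocity": (_f_gikin_velocity, _GIKIN_DEFAULTS, "velocity_nm_per_s"),
}


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional parameter sweep of a closed-form quantity.

    ``parameter`` is swept over ``num`` evenly spaced points in
    [start, stop]; ``overrides`` pin any other family parameter.  The
    special parameter ``kappa_delta`` (pN) sweeps the product
    kappa*Delta by setting kappa = kappa_delta/Delta at Delta = 1 nm.
    """

    family: str
    parameter: str
    start: float
    stop: float
    num: int = 101
    overrides: dict = field(default_factory=dict)
    construct: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; valid: {sorted(FAMILIES)}"
            )
        _, defaults, _ = FAMILIES[self.family]
        for name in [self.parameter, *self.overrides]:
            if name not in defaults:
                raise ValueError(
                    f"unknown parameter {name!r} for family {self.family!r}; "
                    f"valid: {sorted(defaults)}"
                )
        if self.num < 1 or not self.start <= self.stop:
            raise ValueError("need start <= stop and num >= 1")


def run_sweep(spec: SweepSpec, out: str | Path | None = None) -> pd.DataFrame:
    """Evaluate a sweep; optionally write the tidy CSV artifact."""
    fn, defaults, quantity = FAMILIES[spec.family]
    grid = np.linspace(spec.start, spec.stop, spec.num)
    rows = []
    for x in grid:
        p = {**defaults, **spec.overrides, spec.parameter: float(x)}
        if spec.parameter == "kappa_delta" or "kappa_delta" in spec.overrides:
            p["Delta"] = 1.0
            p["kappa"] = p["kappa_delta"]
        rows.append(
            {
                "parameter": spec.parameter,
                "value": float(x),
                "quantity": quantity,
                "result": fn(p),
                "model": spec.family,
                "construct": spec.construct,
            }
        )
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out, index=False, lineterminator="\n")
    return df


def run_reproduction_report(overrides: dict | None = None) -> dict:
    """Recompute the model's headline numbers and compare to the published ones.

    Every check is a closed-form (or root-finding/quadrature) evaluation
    at the published parameter set; failures are recorded, not raised.
    ``overrides`` may replace any of kBT, lam, d, alpha for sensitivity
    checks.
    """
    p = dict(kBT=4.114, lam=0.5, d=8.0, alpha=4.0)
    p.update(overrides or {})
    thermo = ThermoContext(kBT=p["kBT"], lam=p["lam"])
    geom = PotentialGeometry(d=p["d"], alpha=p["alpha"])

    checks: list[dict] = []

    def add(name, computed, printed, tol):
        checks.append(
            {
                "check": name,
                "computed": computed,
                "printed": printed,
                "tolerance": tol,
                "pass": bool(abs(computed - printed) <= tol),
            }
        )

    fixtures = calibration.load_fixtures()
    v1 = calibration.average_gliding_velocity(fixtures)
    add("mean_gliding_velocity_nm_per_s", v1, 298.0, 1e-9)
    k = klpa.atpase_rate_from_gliding(v1, geom)
    add("gliding_velocity_roundtrip_nm_per_s", klpa.gliding_velocity(k, geom), v1, 1e-9)

    ela_cross = NeckElasticity(kappa=0.0, Delta=2.0)
    kstar = klpa.crossover_kappa_rootfind(geom, ela_cross, thermo, k=k)
    add("directionality_crossover_pN_per_nm", kstar, 0.71, 0.01)

    for kd, kap_printed in ((0.78, 0.39), (2.92, 1.46)):
        add(
            f"kappa_from_kappa_delta_{kd}",
            calibration.kappa_from_kappa_delta(kd, 2.0),
            kap_printed,
            1e-12,
        )

    for kap, printed, tol in ((0.0, 0.88, 0.01), (0.39, 0.97, 0.01), (1.46, 1.0, 0.01)):
        ela = NeckElasticity(kappa=kap, Delta=0.5, DeltaD=3.5, dE_neck_T=0.8)
        add(f"gikin_efficiency_kappa_{kap}", gikin.gikin_efficiency(geom, ela, thermo),
            printed, tol)

    ela0 = NeckElasticity(kappa=0.0, Delta=0.5, DeltaD=3.5, dE_neck_T=0.8)
    add("gikin_normalized_atpase_kappa_0",
        gikin.gikin_normalized_atpase(ela0, thermo), 1.0, 1e-12)

    ela39 = NeckElasticity(kappa=0.39, Delta=0.5, DeltaD=3.5, dE_neck_T=0.8)
    v_pred = gikin.gikin_velocity(GIKIN_K0, geom, ela39, thermo)
    add("gikin_3xGS_velocity_nm_per_s", v_pred, 140.0, 0.05 * 140.0)

    return {
        "parameters": p,
        "checks": checks,
        "n_pass": sum(c["pass"] for c in checks),
        "n_total": len(checks),
        "all_pass": all(c["pass"] for c in checks),
    }
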