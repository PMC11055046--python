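"""Config loading (YAML/JSON) and named motor presets.

Config keys carry explicit unit suffixes (``kappa_pN_per_nm``,
``Delta_nm``, ``kBT_pN_nm`` ...); unknown keys are rejected so that a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core import (
    KBT_ROOM,
    MotorSpec,
    NeckElasticity,
    PotentialGeometry,
    ThermoContext,
)

__all__ = ["load_config", "build_motor", "preset", "PRESETS"]

_THERMO_KEYS = {"kBT_pN_nm": "kBT", "lambda": "lam"}
_GEOM_KEYS = {"d_nm": "d", "alpha": "alpha", "d1_nm": "d1", "d2_nm": "d2",
              "diffusion_D_nm2_per_s": "diffusion_D"}
_ELA_KEYS = {"kappa_pN_per_nm": "kappa", "Delta_nm": "Delta",
             "DeltaD_nm": "DeltaD", "dE_neck_T_kBT": "dE_neck_T"}
_MOTOR_KEYS = {"name": "name", "motor_class": "motor_class",
               "atpase_rate_per_s": "atpase_rate"}


def _map_section(section: dict, mapping: dict, where: str) -> dict:
    unknown = set(section) - set(mapping)
    if unknown:
        raise ValueError(
            f"unknown keys in {where!r}: {sorted(unknown)}; "
            f"valid keys: {sorted(mapping)}"
        )
    return {mapping[k]: v for k, v in section.items()}


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON parameter file into validated domain objects.

    Recognized top-level sections: ``thermo``, ``geometry``,
    ``elasticity``, ``motor``.  Returns a dict with a ``ThermoContext``
    under "thermo" and, when the motor section is present, a
    ``MotorSpec`` under "motor".
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {"thermo", "geometry", "elasticity", "motor"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    out: dict = {}
    thermo = ThermoContext(**_map_section(raw.get("thermo", {}), _THERMO_KEYS, "thermo"))
    out["thermo"] = thermo
    geometry = PotentialGeometry(
        **_map_section(raw.get("geometry", {}), _GEOM_KEYS, "geometry")
    )
    out["geometry"] = geometry
    elasticity = NeckElasticity(
        **_map_section(raw.get("elasticity", {}), _ELA_KEYS, "elasticity")
    )
    out["elasticity"] = elasticity
    if "motor" in raw:
        fields = _map_section(raw["motor"], _MOTOR_KEYS, "motor")
        out["motor"] = MotorSpec(geometry=geometry, elasticity=elasticity, **fields)
    return out


def build_motor(
    name: str,
    motor_class: str,
    atpase_rate: float,
    alpha: float = 4.0,
    d: float = 8.0,
    kappa: float = 0.0,
    Delta: float = 0.0,
    DeltaD: float = 0.0,
    dE_neck_T: float = 0.0,
) -> MotorSpec:
    """Convenience constructor from scalar parameters."""
    return MotorSpec(
        name=name,
        motor_class=motor_class,
        geometry=PotentialGeometry(d=d, alpha=alpha),
        elasticity=NeckElasticity(
            kappa=kappa, Delta=Delta, DeltaD=DeltaD, dE_neck_T=dE_neck_T
        ),
        atpase_rate=atpase_rate,
    )


#: ATPase rate reproducing the 298 nm/s mean gliding velocity at alpha = 4.
KLPA_ATPASE = 298.0 * 17.0 / (15.0 * 8.0)  # 42.216... 1/s
#: ATPase rate of the tailless GiKIN14a reference construct, 1/s.
GIKIN_K0 = 12.8

PRESETS: dict[str, MotorSpec] = {
    # KlpA family: nonprocessive, alpha=4, Delta=2 nm; kappa from the
    # single-filament velocity fits (kappa*Delta = 2.92 / 0.78 pN).
    "KlpA": build_motor("KlpA", "nonprocessive", KLPA_ATPASE,
                        kappa=1.46, Delta=2.0),
    "KlpA-3xGS": build_motor("KlpA-3xGS", "nonprocessive", KLPA_ATPASE,
                             kappa=0.39, Delta=2.0),
    "KlpA-dtail": build_motor("KlpA-dtail", "nonprocessive", KLPA_ATPASE),
    # GiKIN14a family: processive, alpha=4, Delta=0.5 nm, DeltaD=3.5 nm,
    # dEneck(T)=0.8 kBT, tailless reference rate k0=12.8 1/s.
    "GiKIN14a": build_motor("GiKIN14a", "processive", GIKIN_K0,
                            kappa=1.46, Delta=0.5, DeltaD=3.5, dE_neck_T=0.8),
    "GiKIN14a-3xGS": build_motor("GiKIN14a-3xGS", "processive", GIKIN_K0,
                                 kappa=0.39, Delta=0.5, DeltaD=3.5,
                                 dE_neck_T=0.8),
    "GiKIN14a-dtail": build_motor("GiKIN14a-dtail", "processive", GIKIN_K0,
                                  kappa=0.0, Delta=0.5, DeltaD=3.5,
                                  dE_neck_T=0.8),
}


def preset(name: str) -> MotorSpec:
    """Return a named motor preset (KlpA, KlpA-3xGS, GiKIN14a, ...)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
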