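"""Kinetic Monte Carlo stepping trajectories and estimators.

The simulator realizes the model's per-ATP statistics directly: ATP
hydrolysis events form a Poisson process at the motor's ATPase rate
(exponential dwells — the minimal assumption consistent with a mean
rate), and each event moves the motor one lattice period ``d`` forward
with probability r/(1+r), where r is the stepping-odds ratio of the
construct's equation family.  One event consumes exactly one ATP.

Modes
-----
``gliding``
    Nonprocessive motors anchored in a gliding assay; odds alpha^2.
``single_mt``
    Head and tail on the same filament; odds from the construct's
    single-filament closed form (KlpA or GiKIN14a family).  For a
    processive motor the event rate is the modulated k_bar * k0.
``overlap``
    Nonprocessive motors in a parallel overlap; each event draws a fresh
    neck offset Delta ~ Uniform(Delta_low, Delta_high) and uses the
    single-filament odds at that offset, so the empirical mean velocity
    converges to the uniform-average closed form.

Estimators recover the mean velocity, the stepping-odds ratio (with a
Wilson confidence interval mapped to the ratio scale) and, by inverting
the closed forms, the neck stiffness kappa — closing the loop from
parameters to trajectories and back.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .core import MotorSpec, ThermoContext
from .gikin import gikin_normalized_atpase, gikin_ratio
from .klpa import OverlapConfig, klpa_single_mt_ratio, stepping_ratio_gliding
from .core import NeckElasticity

__all__ = [
    "SteppingTrajectory",
    "VelocityEstimate",
    "RatioEstimate",
    "KappaEstimate",
    "simulate_trajectory",
    "estimate_velocity",
    "estimate_step_ratio",
    "recover_kappa",
    "write_trajectory",
    "read_trajectory",
]

Mode = str  # "single_mt" | "gliding" | "overlap"


@dataclass(frozen=True)
class SteppingTrajectory:
    """Event record of a simulated stepping trajectory.

    ``times`` are strictly increasing event times (s); ``signs`` are +1
    (forward, minus-end) or -1 per event; ``positions`` the cumulative
    motor position (nm, multiples of the lattice period).  Exactly one
    ATP is consumed per event.
    """

    times: np.ndarray
    signs: np.ndarray
    positions: np.ndarray
    atp_consumed: int
    seed: int
    spec: MotorSpec
    mode: Mode
    duration: float

    def __post_init__(self) -> None:
        if self.atp_consumed != len(self.times):
            raise ValueError("atp_consumed must equal the number of events")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")


@dataclass(frozen=True)
class VelocityEstimate:
    mean: float  # nm/s
    se: float  # nm/s
    n_events: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class RatioEstimate:
    """Empirical stepping-odds ratio with a Wilson-type CI.

    ``one_sided`` flags the degenerate case of no backward steps, where
    only a lower confidence bound on r is meaningful (ci_high = inf).
    """

    ratio: float
    ci_low: float
    ci_high: float
    n_forward: int
    n_backward: int
    one_sided: bool = False


@dataclass(frozen=True)
class KappaEstimate:
    value: float  # pN/nm
    ci_low: float
    ci_high: float
    clipped: bool = False


def _step_ratio_for(spec: MotorSpec, thermo: ThermoContext, mode: Mode) -> float:
    if mode == "gliding":
        if spec.motor_class != "nonprocessive":
            raise ValueError("gliding mode is defined for nonprocessive motors")
        return stepping_ratio_gliding(spec.geometry)
    if mode == "single_mt":
        if spec.motor_class == "nonprocessive":
            return klpa_single_mt_ratio(spec.geometry, spec.elasticity, thermo)
        return gikin_ratio(spec.geometry, spec.elasticity, thermo)
    raise ValueError(f"unknown mode {mode!r}")


def _event_rate(spec: MotorSpec, thermo: ThermoContext, mode: Mode) -> float:
    if spec.motor_class == "processive" and mode == "single_mt":
        return spec.atpase_rate * gikin_normalized_atpase(spec.elasticity, thermo)
    return spec.atpase_rate


def simulate_trajectory(
    spec: MotorSpec,
    mode: Mode,
    duration: float,
    seed: int,
    thermo: ThermoContext | None = None,
    overlap: OverlapConfig | None = None,
) -> SteppingTrajectory:
    """Simulate a stepping trajectory of the given construct.

    Parameters
    ----------
    spec : MotorSpec
    mode : {"single_mt", "gliding", "overlap"}
        Overlap mode requires a nonprocessive motor; each event draws an
        independent neck offset from the overlap window.
    duration : float
        Trajectory length in seconds; events after ``duration`` are
        discarded.
    seed : int
        Mandatory seed of the trajectory's own generator; identical
        (spec, mode, duration, seed) reproduce the trajectory exactly.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    thermo = thermo or ThermoContext()
    rng = np.random.default_rng(seed)

    if mode == "overlap":
        if spec.motor_class != "nonprocessive":
            raise ValueError("overlap mode is defined for nonprocessive motors")
        overlap = overlap or OverlapConfig()
    rate = _event_rate(spec, thermo, mode)

    # draw dwell times in batches until the duration is covered
    times_parts: list[np.ndarray] = []
    t_end = 0.0
    batch = max(64, int(rate * duration * 1.1) + 16)
    while t_end < duration:
        dwells = rng.exponential(1.0 / rate, size=batch)
        part = t_end + np.cumsum(dwells)
        times_parts.append(part)
        t_end = part[-1]
    times = np.concatenate(times_parts)
    times = times[times <= duration]
    n = len(times)

    if mode == "overlap":
        deltas = rng.uniform(overlap.Delta_low, overlap.Delta_high, size=n)
        x = (
            -2.0
            * thermo.lam
            * thermo.beta
            * spec.geometry.d
            * spec.elasticity.kappa
            * deltas
        )
        r = spec.geometry.alpha**2 * np.exp(x)
        p_fwd = r / (1.0 + r)
    else:
        r0 = _step_ratio_for(spec, thermo, mode)
        p_fwd = r0 / (1.0 + r0)
    signs = np.where(rng.random(n) < p_fwd, 1, -1).astype(np.int8)
    positions = np.cumsum(signs * spec.geometry.d)

    return SteppingTrajectory(
        times=times,
        signs=signs,
        positions=positions,
        atp_consumed=n,
        seed=seed,
        spec=spec,
        mode=mode,
        duration=duration,
    )


def estimate_velocity(traj: SteppingTrajectory) -> VelocityEstimate:
    """Mean velocity = net displacement / elapsed time, with closed-form SE.

    Steps are i.i.d. by construction, so the standard error combines the
    binomial variance of the step signs with the Poisson variance of the
    event count: SE^2 = (d^2 n / T^2) Var(s) + v^2 / n.
    """
    n = traj.atp_consumed
    if n < 2:
        raise ValueError("need at least 2 events to estimate a velocity")
    T = traj.duration
    d = traj.spec.geometry.d
    v = float(traj.positions[-1]) / T
    var_s = float(np.var(traj.signs, ddof=1))
    se = math.sqrt((d * d * n / (T * T)) * var_s + (v * v) / n)
    return VelocityEstimate(mean=v, se=se, n_events=n)


def estimate_step_ratio(traj: SteppingTrajectory, conf: float = 0.95) -> RatioEstimate:
    """Empirical odds ratio N+/N- with a Wilson CI on the ratio scale.

    The Wilson interval for the forward fraction p is transformed through
    the monotone map r = p/(1-p).  With no backward steps only the lower
    bound is informative and the estimate is flagged one-sided.
    """
    n_fwd = int(np.sum(traj.signs == 1))
    n_bwd = int(np.sum(traj.signs == -1))
    n = n_fwd + n_bwd
    if n == 0:
        raise ValueError("empty trajectory")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = n_fwd / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    p_lo, p_hi = max(center - half, 0.0), min(center + half, 1.0)
    r_lo = p_lo / (1.0 - p_lo) if p_lo < 1 else math.inf
    r_hi = p_hi / (1.0 - p_hi) if p_hi < 1 else math.inf
    if n_bwd == 0:
        warnings.warn("no backward steps observed; returning one-sided bound")
        return RatioEstimate(math.inf, r_lo, math.inf, n_fwd, n_bwd, one_sided=True)
    return RatioEstimate(n_fwd / n_bwd, r_lo, r_hi, n_fwd, n_bwd)


def recover_kappa(
    traj: SteppingTrajectory,
    thermo: ThermoContext | None = None,
    conf: float = 0.95,
) -> KappaEstimate:
    """Invert the single-filament stepping odds for the neck stiffness.

    Nonprocessive family: kappa = -ln(r/alpha^2) * kBT / (2*lam*d*Delta).
    Processive family:    kappa =  ln(r/alpha^2) * kBT / (lam*G), with
    G = ((d+Delta)^2 - (d/2-Delta)^2)/2.  The CI is the image of the
    ratio CI under the (monotone) inverse map.  A ratio implying a
    negative stiffness is clipped to zero and flagged.
    """
    if traj.mode != "single_mt":
        raise ValueError("kappa recovery requires a single_mt trajectory")
    thermo = thermo or ThermoContext()
    est = estimate_step_ratio(traj, conf=conf)
    if est.one_sided:
        raise ValueError("cannot invert a one-sided ratio estimate")
    geom, ela = traj.spec.geometry, traj.spec.elasticity
    a2 = geom.alpha**2

    if traj.spec.motor_class == "nonprocessive":
        if ela.Delta == 0:
            raise ValueError("Delta = 0: stepping odds carry no kappa information")
        scale = -thermo.kBT / (2.0 * thermo.lam * geom.d * ela.Delta)
    else:
        G = 0.5 * ((geom.d + ela.Delta) ** 2 - (0.5 * geom.d - ela.Delta) ** 2)
        scale = thermo.kBT / (thermo.lam * G)

    def inv(r: float) -> float:
        return scale * math.log(r / a2)

    k_hat = inv(est.ratio)
    k_a, k_b = sorted((inv(est.ci_low), inv(est.ci_high)))
    clipped = False
    if k_hat < 0:
        warnings.warn(
            f"recovered kappa {k_hat:.4g} pN/nm is negative; clipping to 0"
        )
        k_hat, clipped = 0.0, True
    return KappaEstimate(
        value=k_hat, ci_low=max(k_a, 0.0) if clipped else k_a, ci_high=k_b,
        clipped=clipped,
    )


def write_trajectory(traj: SteppingTrajectory, path: str | Path) -> None:
    """Write a trajectory as TSV plus a JSON sidecar with its provenance."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s\tstep\tposition_nm\tatp_cumulative\n")
        for i in range(traj.atp_consumed):
            fh.write(
                f"{traj.times[i]:.9f}\t{int(traj.signs[i])}\t"
                f"{traj.positions[i]:.6f}\t{i + 1}\n"
            )
    sidecar = {
        "seed": traj.seed,
        "mode": traj.mode,
        "duration_s": traj.duration,
        "motor": {
            "name": traj.spec.name,
            "motor_class": traj.spec.motor_class,
            "alpha": traj.spec.geometry.alpha,
            "d_nm": traj.spec.geometry.d,
            "kappa_pN_per_nm": traj.spec.elasticity.kappa,
            "Delta_nm": traj.spec.elasticity.Delta,
            "DeltaD_nm": traj.spec.elasticity.DeltaD,
            "dE_neck_T_kBT": traj.spec.elasticity.dE_neck_T,
            "atpase_rate_per_s": traj.spec.atpase_rate,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def read_trajectory(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back the (times, signs, positions) columns of a trajectory TSV."""
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    arr = np.atleast_2d(arr)
    return arr[:, 0], arr[:, 1].astype(np.int8), arr[:, 2]
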