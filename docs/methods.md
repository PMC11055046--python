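# Methods

## The model

Kinesin-14 motors (KlpA from *Aspergillus nidulans*, GiKIN14a from
*Giardia intestinalis*) are homodimers with C-terminal heads, a
coiled-coil neck stalk with an intrinsically flexible central region,
and an N-terminal tail that can bind microtubules on its own. The
package implements a chemo-mechanical coupling model in which the
direction and speed of these motors follow from two ingredients:

1. **An asymmetric periodic head–microtubule potential.** Per ATP
   hydrolysed the head briefly loses grip on its tubulin, diffuses, and
   is recaptured one lattice period `d = 8 nm` away, forward
   (minus-end) or backward. In the unloaded limit the odds of the two
   outcomes are set purely by the ratio of capture distances,
   `r0 = (d2/d1)^2 = alpha^2`, with `alpha` the asymmetry of the
   potential (`alpha = 1` is symmetric and unbiased). This squared-
   distance form comes from the diffusive time-to-distance scaling
   `t ~ x^2/D` of the capture times; it is the model's normative choice
   and is deliberately *not* the splitting probability of free
   first-passage diffusion between absorbing boundaries (which would
   give odds proportional to `alpha`, not `alpha^2`). The simulator and
   all tests therefore treat `alpha^2` as the ground truth rather than
   deriving odds from a Brownian simulation.
2. **A linear neck-stalk spring.** When head and tail are bound at the
   same time, each capture stretches or relaxes the neck stalk
   (effective stiffness `kappa`, pN/nm). Elastic energy changes enter
   the capture times as Arrhenius factors `exp(lam*beta*dE)` with an
   energy-splitting factor `lam = 0.5` and `beta = 1/kBT`.

Stepping odds `r` convert to velocity through tight coupling — one ATP,
one step of size `d`, forward with probability `r/(1+r)`:

    v = k d (r - 1)/(r + 1),

where `k` is the ATPase rate. Positive velocity is minus-end-directed
motor movement (equivalently plus-end microtubule movement in a gliding
assay).

### Nonprocessive family (KlpA)

* **Gliding** (motor anchored by neck or tail): forward and backward
  elastic costs are equal (`kappa d^2/2` each) and cancel, so
  `r1 = alpha^2` and `v1 = (alpha^2-1)/(alpha^2+1) k d`. Gliding
  velocity is independent of the neck stalk — tailless and full-length
  constructs glide identically.
* **Single microtubule** (head and tail on the same filament): the
  ATP-state neck offset `Delta` biases the costs to
  `kappa (d ± Delta)^2 / 2`, giving
  `r2 = alpha^2 exp(-2 lam beta d kappa Delta)`. Only the product
  `kappa*Delta` (pN) matters, and the entry points accept it as a
  single parameter. The velocity crosses zero at
  `kappa* = ln(alpha) kBT / (lam d Delta)`; below `kappa*` the motor is
  minus-end-directed, above it plus-end-directed. With `alpha = 4`,
  `Delta = 2 nm` this is 0.713 pN/nm — the directionality switch that
  inserting a flexible 3×GS linker (which lowers `kappa`) flips.
* **Parallel overlap** (head and tail on different, same-polarity
  microtubules): the offset is not fixed; the velocity is the uniform
  average of the single-filament expression over
  `Delta in [-4, +4] nm`. Because the integrand is a shifted tanh, the
  symmetric average stays positive for every `kappa` when `alpha > 1`:
  the same motor that walks plus-end on a single filament walks
  minus-end inside an overlap.

### Processive family (GiKIN14a)

The tailless construct steps with odds `alpha^2` and coupling
efficiency `E = (alpha^2-1)/(alpha^2+1)` (net forward steps per ATP,
0.88 at `alpha = 4`). With the tail bound, the neck spring *helps*
forward stepping — the forward capture costs
`kappa (d/2 - Delta)^2 / 2` (the neck rotation contributes about half a
period) against `kappa (d + Delta)^2 / 2` backward — so the odds grow
with `kappa` and `E` saturates at 1. The tail also modulates the ATPase
rate through the occupancy of the ATP-state neck orientation (closed
nucleotide pocket):

    k_bar = [A/(A+B)] / [C/(C+1)],
    A = exp(-beta kappa Delta^2/2 - dEneck(T)/kBT),
    B = exp(-beta kappa DeltaD^2/2),   C = exp(-dEneck(T)/kBT),

exactly 1 at `kappa = 0` and rising toward `(C+1)/C` when
`Delta < DeltaD`. Velocity factorizes as `v2 = E k_bar k0 d` with `k0`
the tailless reference ATPase rate.

## Parameters

| symbol | meaning | unit | default | origin |
|---|---|---|---|---|
| `d` | lattice period | nm | 8 | tubulin repeat |
| `alpha` | potential asymmetry d2/d1 | — | 4 | fixed where the rate–asymmetry trade-off flattens |
| `lam` | energy-splitting factor | — | 0.5 | standard choice for this model family |
| `kBT` | thermal energy | pN·nm | 4.114 | room temperature (298.15 K) |
| `kappa` | neck-stalk stiffness | pN/nm | construct-specific | fitted: 1.46 full length, 0.39 with 3×GS linker |
| `Delta` | ATP-state neck offset | nm | 2 (KlpA), 0.5 (GiKIN14a) | adjustable; Delta=2 converts the fitted kappa*Delta products |
| `DeltaD` | ADP-state neck offset | nm | 3.5 | from the ~4 nm neck rotation minus Delta |
| `dEneck(T)` | ATP-orientation energy | kBT | 0.8 | adjustable, fits the measured ATPase ratios |
| `k` | KlpA ATPase rate | 1/s | 42.217 | calibrated from the 298 nm/s mean gliding velocity at alpha=4 |
| `k0` | tailless GiKIN14a ATPase rate | 1/s | 12.8 | given reference value (close to the measured 10.0 ± 0.7 1/s) |

`dEneck(T)` is stored in kBT units because that is how it is naturally
stated; the ADP-state analogue `dEneck(D)` plays no numeric role in the
closed forms and is not carried. `d1`/`d2` individually are optional
and only checked for consistency with `alpha`; the model never relates
`d1 + d2` to `d`, and neither does the package. The published anchor
values (gliding velocities 309 ± 35 and 287 ± 10 nm/s, tailless ATPase
10.0 ± 0.7 1/s, fitted `kappa*Delta` 0.78 and 2.92 pN) ship as a frozen
CSV fixture; updating them means editing the table, not code.

## Calibration

`atpase_rate_from_gliding` inverts the gliding relation at a chosen
`alpha`; `fit_kappa_delta` inverts the single-filament velocity in
closed form,

    kappa*Delta = kBT/(2 lam d) ln(alpha^2 (kd - v)/(kd + v)),

verified by substitution to < 1e-6 nm/s (a bisection route exists in
the test suite as an independent check). The observed velocity must lie
in `(-kd, v1]`; the boundary `v = v1` maps to `kappa*Delta = 0`. The
experimental single-filament velocities behind the published 0.78 and
2.92 pN fits were reported only graphically, so the calibration tests
exercise round-trip identities and the printed products rather than
underlying velocity numbers. Error bars of the normalized ATPase rate
use first-order propagation, `dk/k0 + (k/k0^2) dk0` (and `dk0/k0` for
the reference construct itself).

## Stochastic simulator

The kinetic Monte Carlo generator realizes exactly the statistics the
closed forms average: exponential dwell times at the construct's total
ATPase rate (memoryless dwells are the minimal assumption consistent
with a mean rate — the model specifies no dwell-time shape), then an
independent Bernoulli step of ±d with forward probability `r/(1+r)`.
For the processive family the event rate is `k_bar * k0`; the
futile/orientation sub-states behind `k_bar` are not simulated
explicitly, since they are already folded into the rate. In overlap
mode each event draws a fresh offset `Delta ~ Uniform(-4, 4) nm`;
per-event resampling (rather than per-encounter) makes the empirical
mean converge exactly to the uniform-average closed form. One named
`numpy` generator per trajectory; the seed is a mandatory API argument.

Estimators: velocity is net displacement over elapsed time with a
closed-form standard error combining binomial step variance and Poisson
count variance, `SE^2 = (d^2 n / T^2) Var(s) + v^2/n` (steps are i.i.d.
by construction, so no block bootstrap is needed); the stepping ratio
is `N+/N-` with a Wilson interval on the forward fraction mapped
through `r = p/(1-p)`; `kappa` recovery inverts the single-filament
closed form of the construct's family, propagating the ratio CI through
the monotone inverse. A ratio implying negative stiffness is clipped to
zero and flagged.

What the generator does *not* emulate: detachment and rebinding (run
length / processivity), spatially continuous Langevin motion on the
potential, mechanical coupling between motors beyond the uniform-offset
average, and experimental noise (localization error, frame averaging).
Passing simulation tests therefore demonstrate internal consistency of
the stepping statistics with the closed forms — not that real
trajectories, which include all of the above, would be fit equally
well.

## Numerical choices

* Overlap quadrature: adaptive (`scipy.integrate.quad`) at relative
  tolerance 1e-8, window default [-4, 4] nm; the integrand is evaluated
  as `tanh((ln alpha^2 - c x)/2)`, algebraically identical to the ratio
  form but immune to overflow at large `kappa`. Tests compare against a
  1e5-point trapezoid rule to 1e-6 relative.
* Crossover root-finding: Brent's method on `kappa` in [1e-9, 10] pN/nm
  (velocity is strictly monotone, so the bracket is guaranteed),
  `xtol = 1e-9`, cross-checked against the closed form.
* Exponentiation of energy differences happens on the difference, never
  on the two terms separately, to avoid overflow.
* Validation suites assert CI containment at several `kappa` values
  jointly and therefore use 99% intervals (a 95% level would give about
  a one-in-three familywise miss rate across the suite by design);
  recovery bias is separately bounded at 0.02 pN/nm.
* Simulated-trajectory problem sizes in the test suite are ~1e5 events
  (2400 s at the KlpA rate, 5500–8000 s for GiKIN14a constructs),
  enough for ~1% relative standard errors on velocities and ~0.004
  pN/nm standard errors on recovered stiffness.

## Output formats

Sweeps are tidy CSV — one row per grid point with columns `parameter,
value, quantity, result, model, construct` — rather than a per-quantity
column layout, because the sweep families return different physical
quantities (velocities in nm/s, an ATPase rate in 1/s, dimensionless
efficiency and normalized rate); the `quantity` column names the unit
so files from different families concatenate cleanly. Trajectories are
TSV (`time_s, step, position_nm, atp_cumulative`) with a JSON sidecar
carrying the generating motor spec, mode and seed, so a trajectory file
is self-describing and re-analyzable without the session that produced
it. Calibration and report outputs are JSON.

## Known limitations

* Processivity, run length and detachment kinetics are out of scope;
  the potential's affinity labels (E_w1, E_w2, ...) are carried as
  documentation only and never enter a number.
* The uniform offset distribution in overlap mode is an acknowledged
  approximation; alternative distributions are not implemented.
* The `alpha^2` capture-odds rule is a modelling postulate (see above);
  the package reproduces its consequences and does not attempt to
  justify it from first-passage theory.
* Force–velocity behaviour is not modelled (the closed forms carry no
  external load).
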