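"""KlpA-family closed forms: gliding, single filament, parallel overlap."""

import math

import numpy as np
import pytest

from kinesin14 import (
    NeckElasticity,
    OverlapConfig,
    PotentialGeometry,
    ThermoContext,
    atpase_rate_from_gliding,
    biased_step_ratio,
    crossover_kappa,
    gliding_velocity,
    klpa_single_mt_ratio,
    klpa_single_mt_velocity,
    overlap_velocity,
    stepping_ratio_gliding,
)
from kinesin14.klpa import crossover_kappa_rootfind

K_FIT = 42.21666666666667  # 1/s, reproduces 298 nm/s gliding at alpha=4


class TestGliding:
    @pytest.mark.parametrize("alpha,expected", [(1.0, 1.0), (2.0, 4.0), (4.0, 16.0)])
    def test_ratio_is_alpha_squared(self, alpha, expected):
        assert stepping_ratio_gliding(PotentialGeometry(alpha=alpha)) == expected

    def test_symmetric_potential_does_not_glide(self):
        assert gliding_velocity(10.0, PotentialGeometry(alpha=1.0)) == 0.0

    def test_velocity_approaches_kd_for_large_alpha(self):
        v = gliding_velocity(10.0, PotentialGeometry(alpha=1e6))
        assert v == pytest.approx(80.0, rel=1e-9)

    def test_calibrated_velocity(self, geom4):
        assert gliding_velocity(K_FIT, geom4) == pytest.approx(298.0, rel=1e-12)


class TestAtpaseFromGliding:
    @pytest.mark.parametrize(
        "v1,alpha,expected",
        [
            (298.0, 4.0, 42.21666666666667),
            (298.0, 2.0, 62.083333333333336),
        ],
    )
    def test_closed_form_inversion(self, v1, alpha, expected):
        geom = PotentialGeometry(alpha=alpha)
        k = atpase_rate_from_gliding(v1, geom)
        assert k == pytest.approx(expected, rel=1e-12)
        # substitute back
        assert gliding_velocity(k, geom) == pytest.approx(v1, rel=1e-12)

    def test_large_alpha_limit_is_v_over_d(self):
        k = atpase_rate_from_gliding(80.0, PotentialGeometry(alpha=1e8))
        assert k == pytest.approx(10.0, rel=1e-6)

    def test_rejects_alpha_at_most_one(self):
        with pytest.raises(ValueError):
            atpase_rate_from_gliding(100.0, PotentialGeometry(alpha=1.0))


class TestSingleMT:
    def test_zero_stiffness_recovers_gliding_ratio(self, geom4, thermo):
        ela = NeckElasticity(kappa=0.0, Delta=2.0)
        assert klpa_single_mt_ratio(geom4, ela, thermo) == pytest.approx(16.0)

    def test_unbiased_at_crossover(self, geom4, thermo):
        ela = NeckElasticity(kappa=0.7129018752059038, Delta=2.0)
        assert klpa_single_mt_ratio(geom4, ela, thermo) == pytest.approx(1.0, rel=1e-9)
        assert klpa_single_mt_velocity(K_FIT, geom4, ela, thermo) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_stiff_neck_reverses_direction(self, geom4, thermo):
        # kappa*Delta = 2.92 pN, the full-length-construct fit
        ela = NeckElasticity(kappa=2.92, Delta=1.0)
        r = klpa_single_mt_ratio(geom4, ela, thermo)
        assert r == pytest.approx(0.054716860947183546, rel=1e-10)
        v = klpa_single_mt_velocity(K_FIT, geom4, ela, thermo)
        assert v == pytest.approx(-302.6913073233705, rel=1e-10)

    @pytest.mark.parametrize("kappa", [0.0, 0.2, 0.39, 0.71, 1.46, 3.0])
    @pytest.mark.parametrize("alpha", [1.5, 4.0, 8.0])
    def test_closed_form_matches_generic_construction(self, alpha, kappa, thermo):
        """The explicit ratio equals the generic Arrhenius-weighted odds
        with forward/backward elastic energies kappa*(d +/- Delta)^2/2."""
        geom = PotentialGeometry(alpha=alpha)
        Delta = 2.0
        ela = NeckElasticity(kappa=kappa, Delta=Delta)
        dE_fwd = 0.5 * kappa * (geom.d + Delta) ** 2
        dE_bwd = 0.5 * kappa * (geom.d - Delta) ** 2
        generic = biased_step_ratio(alpha**2, dE_fwd, dE_bwd, thermo)
        assert klpa_single_mt_ratio(geom, ela, thermo) == pytest.approx(
            generic, rel=1e-10
        )

    def test_velocity_strictly_decreasing_in_kappa(self, geom4, thermo):
        kappas = np.linspace(0.0, 3.0, 61)
        vs = [
            klpa_single_mt_velocity(
                K_FIT, geom4, NeckElasticity(kappa=k, Delta=2.0), thermo
            )
            for k in kappas
        ]
        assert all(a > b for a, b in zip(vs, vs[1:]))
        assert sum(v > 0 for v in vs) > 0 and sum(v < 0 for v in vs) > 0


class TestCrossover:
    def test_printed_value(self, geom4, thermo):
        ela = NeckElasticity(kappa=0.0, Delta=2.0)
        assert crossover_kappa(geom4, ela, thermo) == pytest.approx(0.713, abs=5e-4)

    def test_closed_form_agrees_with_rootfinding(self, geom4, thermo):
        for Delta in (0.5, 2.0):
            ela = NeckElasticity(kappa=0.0, Delta=Delta)
            closed = crossover_kappa(geom4, ela, thermo)
            root = crossover_kappa_rootfind(geom4, ela, thermo, k=K_FIT)
            assert root == pytest.approx(closed, abs=1e-8)

    def test_small_delta_gives_large_crossover(self, geom4, thermo):
        ela = NeckElasticity(kappa=0.0, Delta=0.5)
        assert crossover_kappa(geom4, ela, thermo) == pytest.approx(
            2.851607500823615, rel=1e-12
        )

    def test_vanishes_as_alpha_approaches_one(self, thermo):
        ela = NeckElasticity(kappa=0.0, Delta=2.0)
        k = crossover_kappa(PotentialGeometry(alpha=1.0 + 1e-9), ela, thermo)
        assert k == pytest.approx(0.0, abs=1e-8)

    def test_rejects_symmetric_potential(self, thermo):
        with pytest.raises(ValueError):
            crossover_kappa(
                PotentialGeometry(alpha=1.0), NeckElasticity(Delta=2.0), thermo
            )


class TestOverlap:
    def test_zero_stiffness_equals_gliding(self, geom4, thermo):
        ela = NeckElasticity(kappa=0.0, Delta=2.0)
        v3 = overlap_velocity(K_FIT, geom4, ela, thermo)
        assert v3 == pytest.approx(gliding_velocity(K_FIT, geom4), rel=1e-10)

    def test_faster_than_single_filament_at_moderate_stiffness(self, geom4, thermo):
        ela = NeckElasticity(kappa=0.39, Delta=2.0)
        v3 = overlap_velocity(K_FIT, geom4, ela, thermo)
        v2 = klpa_single_mt_velocity(K_FIT, geom4, ela, thermo)
        assert v3 > v2 > 0

    def test_stiff_limit_vanishes_from_above(self, geom4, thermo):
        ela = NeckElasticity(kappa=50.0, Delta=2.0)
        v3 = overlap_velocity(K_FIT, geom4, ela, thermo)
        assert 0 < v3 < 5.0

    @pytest.mark.parametrize("kappa", [0.0, 0.39, 1.46, 10.0, 100.0])
    def test_quadrature_matches_trapezoid_oracle(self, geom4, thermo, kappa):
        ela = NeckElasticity(kappa=kappa, Delta=2.0)
        v3 = overlap_velocity(K_FIT, geom4, ela, thermo)
        # independent dense-trapezoid evaluation of the same average
        x = np.linspace(-4.0, 4.0, 100_001)
        c = 2.0 * thermo.lam * thermo.beta * geom4.d * kappa
        f = np.tanh(0.5 * (2 * np.log(geom4.alpha) - c * x))
        oracle = K_FIT * geom4.d * np.trapezoid(f, x) / 8.0
        assert v3 == pytest.approx(oracle, rel=1e-6)

    def test_minus_end_directed_for_all_stiffness(self, geom4, thermo):
        for kappa in np.linspace(0.0, 100.0, 26):
            ela = NeckElasticity(kappa=float(kappa), Delta=2.0)
            assert overlap_velocity(K_FIT, geom4, ela, thermo) > 0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            OverlapConfig(Delta_low=4.0, Delta_high=-4.0)
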