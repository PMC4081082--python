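"""Kinetic repression model: rate construction, steady states, gains."""

import math

import numpy as np
import pytest

from triplexkit.kinetics import (
    RHO0_NM,
    KineticConfig,
    build_model,
    repression_gain,
    repression_surface,
    steady_state,
)
from triplexkit.rna_structure import R_KCAL, TriplexEnergetics

STRONG = TriplexEnergetics(dG_triplex=-30.0, dG_duplex1=-10.0, dG_duplex2=-10.0)
WEAK = TriplexEnergetics(dG_triplex=-12.263, dG_duplex1=-7.481, dG_duplex2=-7.481)


def random_energetics(rng):
    d1 = float(rng.uniform(-14.0, -5.0))
    d2 = float(rng.uniform(-14.0, -5.0))
    dg_t = min(float(rng.uniform(-40.0, -8.0)), min(d1, d2) - 0.5)
    return TriplexEnergetics(dG_triplex=dg_t, dG_duplex1=d1, dG_duplex2=d2)


class TestBuildModel:
    def test_zero_duplex_energy_gives_standard_state_dissociation(self):
        cfg = KineticConfig()
        m = build_model(
            TriplexEnergetics(dG_triplex=-1.0, dG_duplex1=0.0, dG_duplex2=-5.0),
            config=cfg,
        )
        assert m.d1 == pytest.approx(cfg.k_on * RHO0_NM, rel=1e-12)

    def test_additive_energies_reproduce_first_duplex_kd(self):
        # dG_triplex = dG_d1 + dG_d2: the stepwise Kd of miRNA1 joining C2
        # equals miRNA1's own duplex Kd
        m = build_model(
            TriplexEnergetics(dG_triplex=-18.0, dG_duplex1=-8.0, dG_duplex2=-10.0)
        )
        assert m.d12 == pytest.approx(m.d1, rel=1e-12)

    def test_energy_decade_scales_dissociation_tenfold(self):
        delta = math.log(10.0) * R_KCAL * 310.15  # ~1.42 kcal/mol
        m1 = build_model(
            TriplexEnergetics(dG_triplex=-20.0, dG_duplex1=-9.0, dG_duplex2=-9.0)
        )
        m2 = build_model(
            TriplexEnergetics(
                dG_triplex=-20.0 - delta, dG_duplex1=-9.0, dG_duplex2=-9.0
            )
        )
        assert m1.d12 / m2.d12 == pytest.approx(10.0, rel=1e-9)


class TestSteadyState:
    def test_mirna_free_model_is_normalized_to_one(self):
        m = build_model(STRONG)
        assert steady_state(m, 0.0, 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_no_binding_means_no_repression(self):
        m = build_model(STRONG)
        m = m.__class__(**{**m.__dict__, "a1": 0.0, "a2": 0.0, "a12": 0.0, "a21": 0.0})
        for tf in (0.1, 1.0, 10.0, 100.0):
            assert steady_state(m, tf, tf) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_model_is_symmetric_in_tf(self):
        m = build_model(STRONG)
        assert steady_state(m, 3.0, 30.0) == pytest.approx(
            steady_state(m, 30.0, 3.0), rel=1e-9
        )

    def test_two_solvers_agree(self):
        rng = np.random.default_rng(8)
        for _ in range(8):
            m = build_model(random_energetics(rng))
            tf1 = float(rng.uniform(0.1, 100.0))
            tf2 = float(rng.uniform(0.1, 100.0))
            a = steady_state(m, tf1, tf2, method="newton")
            b = steady_state(m, tf1, tf2, method="ode")
            assert a == pytest.approx(b, rel=1e-6)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            m = build_model(random_energetics(rng))
            ss = steady_state(m, float(rng.uniform(0.1, 100)), float(rng.uniform(0.1, 100)))
            assert -1e-9 <= ss <= 1.0 + 1e-9


class TestRepressionGain:
    def test_no_binding_model_has_zero_gains(self):
        m = build_model(STRONG)
        m = m.__class__(**{**m.__dict__, "a1": 0.0, "a2": 0.0, "a12": 0.0, "a21": 0.0})
        assert repression_gain(m) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_single_binding_mirna_gives_one_sided_gain(self):
        m = build_model(STRONG)
        m = m.__class__(**{**m.__dict__, "a2": 0.0, "a12": 0.0, "a21": 0.0})
        rg1, rg2, rg3 = repression_gain(m)
        assert rg2 == pytest.approx(0.0, abs=1e-9)
        assert rg1 > 0.0

    def test_strong_triplex_with_weak_duplexes_is_synergistic(self):
        rg1, rg2, rg3 = repression_gain(build_model(STRONG))
        assert rg3 > max(rg1, rg2)

    def test_unstable_triplex_is_not_synergistic(self):
        rg1, rg2, rg3 = repression_gain(build_model(WEAK))
        assert rg3 <= max(rg1, rg2) + 0.01

    def test_literal_sign_convention_negates(self):
        pos = repression_gain(build_model(STRONG), sign_convention="positive")
        lit = repression_gain(build_model(STRONG), sign_convention="literal")
        assert lit == pytest.approx(tuple(-g for g in pos), rel=1e-12)


class TestRepressionSurface:
    def test_no_binding_surface_is_identically_one(self):
        m = build_model(STRONG)
        m = m.__class__(**{**m.__dict__, "a1": 0.0, "a2": 0.0, "a12": 0.0, "a21": 0.0})
        res = repression_surface(m, tf_points=5)
        assert np.allclose(res.ss_grid, 1.0, atol=1e-9)
        assert res.synergy_class == "additive"

    def test_surface_monotone_and_corner_minimal(self):
        res = repression_surface(build_model(STRONG), tf_points=7)
        grid = res.ss_grid
        assert np.all(np.diff(grid, axis=0) <= 1e-9)
        assert np.all(np.diff(grid, axis=1) <= 1e-9)
        assert grid[-1, -1] <= grid.min() + 1e-9
        assert np.all(grid >= -1e-9) and np.all(grid <= 1.0 + 1e-9)
        assert res.synergy_class == "synergistic"

    def test_grid_bounds_validated(self):
        with pytest.raises(ValueError):
            repression_surface(build_model(STRONG), tf_points=3, tf_bounds=(0.01, 10))
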