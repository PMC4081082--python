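"""Mass-action equilibrium of the strand system and the TEC filter."""

import math

import numpy as np
import pytest

from triplexkit.equilibrium import (
    DEFAULT_COMPLEXES,
    EquilibriumState,
    dg_for_kd,
    equilibrium_concentrations,
    equilibrium_from_energetics,
    triplex_filter,
)

DIMER_ONLY = {"A": {"A": 1}, "B": {"B": 1}, "AB": {"A": 1, "B": 1}}


def dimer_closed_form(A0, B0, kd):
    return ((A0 + B0 + kd) - math.sqrt((A0 + B0 + kd) ** 2 - 4 * A0 * B0)) / 2


class TestEquilibriumConcentrations:
    def test_binding_disabled_leaves_monomers_at_totals(self):
        inf = float("inf")
        st = equilibrium_concentrations(
            {"MA": inf, "MB": inf, "AB": inf, "MAB": inf}
        )
        for s in ("M", "A", "B"):
            assert st.concentrations[s] == pytest.approx(100.0, rel=1e-9)
        for c in ("MA", "MB", "AB", "MAB"):
            assert st.concentrations[c] == 0.0

    def test_dimer_matches_closed_form_quadratic(self):
        st = equilibrium_concentrations(
            {"AB": dg_for_kd(100.0)},
            strand_totals={"A": 100.0, "B": 100.0},
            complexes=DIMER_ONLY,
        )
        assert st.concentrations["AB"] == pytest.approx(38.19660112501051, rel=1e-9)

    @pytest.mark.parametrize("kd_nM", [1.0, 10.0, 100.0, 1e3, 1e4])
    def test_closed_form_agreement_across_kd_range(self, kd_nM):
        st = equilibrium_concentrations(
            {"AB": dg_for_kd(kd_nM)},
            strand_totals={"A": 100.0, "B": 100.0},
            complexes=DIMER_ONLY,
        )
        expected = dimer_closed_form(100.0, 100.0, kd_nM)
        assert st.concentrations["AB"] == pytest.approx(expected, rel=1e-6)

    def test_symmetric_system_gives_equal_duplexes(self):
        st = equilibrium_concentrations(
            {"MA": -12.0, "MB": -12.0, "AB": -3.0, "MAB": -20.0}
        )
        assert st.concentrations["MA"] == pytest.approx(
            st.concentrations["MB"], rel=1e-9
        )

    def test_mass_conservation_on_random_systems(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            dgs = {k: float(rng.uniform(-60, 0)) for k in ("MA", "MB", "AB", "MAB")}
            totals = {s: float(rng.uniform(5, 500)) for s in ("M", "A", "B")}
            st = equilibrium_concentrations(dgs, strand_totals=totals)
            for strand, total in totals.items():
                bound = sum(
                    comp.get(strand, 0) * st.concentrations[name]
                    for name, comp in st.complexes.items()
                )
                assert bound == pytest.approx(total, rel=1e-6)

    def test_stabler_triplex_never_loses_concentration(self):
        prev = -1.0
        for dg_t in np.linspace(-5.0, -45.0, 20):
            st = equilibrium_concentrations(
                {"MA": -12.0, "MB": -11.0, "AB": -4.0, "MAB": float(dg_t)}
            )
            assert st.concentrations["MAB"] >= prev - 1e-9
            prev = st.concentrations["MAB"]

    def test_invariant_to_adding_disabled_complex(self):
        dgs = {"MA": -12.0, "MB": -11.0, "AB": -3.0, "MAB": -20.0}
        st1 = equilibrium_concentrations(dgs)
        extended = {k: dict(v) for k, v in DEFAULT_COMPLEXES.items()}
        extended["MMAB"] = {"M": 2, "A": 1, "B": 1}
        st2 = equilibrium_concentrations(
            {**dgs, "MMAB": float("inf")}, complexes=extended
        )
        for name in st1.concentrations:
            assert st2.concentrations[name] == pytest.approx(
                st1.concentrations[name], abs=1e-8
            )


class TestTriplexFilter:
    def make_state(self, mab):
        return EquilibriumState(
            strand_totals={"M": 100.0, "A": 100.0, "B": 100.0},
            dG={},
            concentrations={"MAB": mab},
            temperature=310.15,
        )

    def test_threshold_is_strict(self):
        assert triplex_filter(self.make_state(50.0)) is False
        assert triplex_filter(self.make_state(50.1)) is True

    def test_disabled_binding_fails(self):
        inf = float("inf")
        st = equilibrium_concentrations({"MA": inf, "MB": inf, "AB": inf, "MAB": inf})
        assert triplex_filter(st) is False


def test_strong_energetics_pass_the_tec_filter():
    st = equilibrium_from_energetics(-45.0, -18.0, -20.0, dG_mirna_dimer=-4.0)
    assert st.concentrations["MAB"] > 50.0
    assert triplex_filter(st)
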