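"""Transporter kinetic schemes: structure, steady state, stepping, Q10."""

import numpy as np
import pytest

from calfluct.kinetics import (
    RT_MV,
    KineticScheme,
    RateContext,
    SchemeStepper,
    TimeStepViolation,
    Transition,
    TransporterPopulation,
    apply_q10,
    build_eaat_scheme,
    build_ncx_scheme,
    cycle_flux,
    gillespie_occupancy,
    steady_state,
    step_population,
)


def two_state_scheme(k12=2.0, k21=1.0) -> KineticScheme:
    return KineticScheme(
        "toy2",
        ["a", "b"],
        [
            Transition("fwd", "a", "b", k12),
            Transition("rev", "b", "a", k21),
        ],
        ["a", "b", "a"],
    )


def ring_scheme(n=5, k=3.0) -> KineticScheme:
    states = [f"s{i}" for i in range(n)]
    trans = []
    for i in range(n):
        j = (i + 1) % n
        trans.append(Transition(f"f{i}", states[i], states[j], k))
        trans.append(Transition(f"b{i}", states[j], states[i], k))
    return KineticScheme("ring", states, trans, states + [states[0]])


class TestStructure:
    def test_step_counts(self):
        assert build_eaat_scheme().n_steps == 13
        assert build_ncx_scheme().n_steps == 6

    def test_strong_connectivity_and_positive_rates(self):
        for scheme in (build_eaat_scheme(), build_ncx_scheme()):
            ctx = RateContext(temperature_factor=3.0)
            assert np.all(scheme.transition_rates(ctx) >= 0)
            assert scheme._strongly_connected()

    def test_detailed_balance_products(self):
        # shipped rate sets are thermodynamically neutral rings
        assert build_eaat_scheme().detailed_balance_ratio() == pytest.approx(1.0, rel=1e-9)
        assert build_ncx_scheme().detailed_balance_ratio() == pytest.approx(1.0, rel=1e-9)

    def test_eaat_forward_stoichiometry(self):
        # one completed forward cycle: 3 Na+, 1 H+, 1 Glu in; 1 K+ out
        assert build_eaat_scheme().cycle_stoichiometry() == {
            "na": 3,
            "h": 1,
            "glu": 1,
            "k": -1,
        }

    def test_ncx_forward_stoichiometry(self):
        # forward: 3 Na+ in per 1 Ca2+ out
        assert build_ncx_scheme().cycle_stoichiometry() == {"na": 3, "ca": -1}

    def test_reverse_is_exact_negation(self):
        for scheme in (build_eaat_scheme(), build_ncx_scheme()):
            fwd = scheme.cycle_stoichiometry("forward")
            rev = scheme.cycle_stoichiometry("reverse")
            assert rev == {sp: -n for sp, n in fwd.items()}

    def test_rate_overrides(self):
        s = build_ncx_scheme(rates={"ca_release_in": 99.0})
        assert s.edge("in_ca", "in_apo").rate == 99.0
        with pytest.raises(ValueError, match="unknown transitions"):
            build_ncx_scheme(rates={"nope": 1.0})


class TestSteadyState:
    def test_two_state_closed_form(self):
        p = steady_state(two_state_scheme(2.0, 1.0), RateContext())
        assert p == pytest.approx([1 / 3, 2 / 3])

    def test_symmetric_ring_uniform(self):
        for n in (3, 6):
            p = steady_state(ring_scheme(n), RateContext())
            assert p == pytest.approx(np.full(n, 1 / n))

    def test_degenerate_generator_rejected(self):
        s = two_state_scheme(0.0, 0.0)
        with pytest.raises(ValueError, match="all rates are zero"):
            steady_state(s, RateContext())

    def test_missing_rate_reported(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "name: bad\nstates: [a, b]\nforward_cycle: [a, b, a]\n"
            "transitions:\n"
            "  - {name: fwd, from: a, to: b}\n"
            "  - {name: rev, from: b, to: a, rate: 1.0}\n"
        )
        from calfluct.kinetics import load_scheme

        with pytest.raises(ValueError, match="fwd"):
            load_scheme(bad)

    @pytest.mark.parametrize("scheme_name", ["eaat", "ncx"])
    def test_matches_gillespie_oracle(self, scheme_name, rng):
        scheme = build_eaat_scheme() if scheme_name == "eaat" else build_ncx_scheme()
        ctx = RateContext(glu_e=0.01, temperature_factor=3.0)
        p = steady_state(scheme, ctx)
        occ = np.zeros(scheme.n_states)
        n_rep = 40
        for _ in range(n_rep):
            occ += gillespie_occupancy(scheme, ctx, t_total_ms=50.0, rng=rng)
        occ /= n_rep
        # time-averaged occupancy from an exact sampler
        assert np.abs(occ - p).max() < 0.05


class TestNcxReversal:
    def test_flux_sign_flips_at_nernst_potential(self):
        """The exchanger's analytic net flux must vanish exactly at the
        thermodynamic reversal potential 3 E_Na - 2 E_Ca."""
        scheme = build_ncx_scheme()

        def flux_at(v_mv, na_i=15.0, ca_i=1e-4):
            ctx = RateContext(
                na_i=na_i, ca_i=ca_i, membrane_potential_mv=v_mv,
                temperature_factor=3.0,
            )
            return cycle_flux(scheme, ctx)

        e_na = RT_MV * np.log(140.0 / 15.0)
        e_ca = RT_MV / 2.0 * np.log(2.0 / 1e-4)
        v_rev = 3 * e_na - 2 * e_ca
        # bisect the analytic flux zero
        lo, hi = v_rev - 40, v_rev + 40
        assert flux_at(lo) * flux_at(hi) < 0
        for _ in range(60):
            mid = (lo + hi) / 2
            if flux_at(lo) * flux_at(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert (lo + hi) / 2 == pytest.approx(v_rev, abs=0.1)

    def test_direction_switch_with_na_i(self):
        """At -70 mV the exchanger runs forward (Ca2+ efflux) at low
        [Na+]i and reverse (Ca2+ entry) at high [Na+]i."""
        scheme = build_ncx_scheme()
        fluxes = [
            cycle_flux(scheme, RateContext(na_i=na, temperature_factor=3.0))
            for na in (10.0, 15.0, 20.0)
        ]
        assert fluxes[0] > 0  # forward at 10 mM
        assert fluxes[2] < 0  # reverse at 20 mM
        assert fluxes == sorted(fluxes, reverse=True)  # monotone


class TestStepping:
    def test_all_rates_zero_no_events(self, rng):
        s = two_state_scheme(0.0, 0.0)
        pop = TransporterPopulation(s, np.zeros(100, int), np.zeros((100, 3)))
        events = step_population(pop, RateContext(), n_steps=10, rng=rng)
        assert all(len(m) == 0 for m, _ in events)
        assert np.all(pop.states == 0)

    def test_bernoulli_frequency(self, rng):
        # single transition k = 10/ms at dt = 1 us -> p = 0.01 per step
        s = KineticScheme(
            "one",
            ["a", "b"],
            [Transition("f", "a", "b", 10.0), Transition("r", "b", "a", 0.0)],
            ["a", "b", "a"],
        )
        n = 10**6
        stepper = SchemeStepper(s, RateContext(), dt_ms=1e-3)
        states = np.zeros(n, dtype=np.int64)
        mols, _ = stepper.step(states, rng)
        p_hat = len(mols) / n
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(p_hat - 0.01) < 3 * se

    def test_temperature_factor_triples_frequency(self, rng):
        s = KineticScheme(
            "one",
            ["a", "b"],
            [Transition("f", "a", "b", 10.0), Transition("r", "b", "a", 0.0)],
            ["a", "b", "a"],
        )
        n = 10**6
        stepper = SchemeStepper(s, RateContext(temperature_factor=3.0), dt_ms=1e-3)
        states = np.zeros(n, dtype=np.int64)
        mols, _ = stepper.step(states, rng)
        p_hat = len(mols) / n
        se = np.sqrt(0.03 * 0.97 / n)
        assert abs(p_hat - 0.03) < 3 * se

    def test_time_step_violation_names_transition(self):
        s = KineticScheme(
            "hot",
            ["a", "b"],
            [Transition("toofast", "a", "b", 2000.0), Transition("r", "b", "a", 1.0)],
            ["a", "b", "a"],
        )
        with pytest.raises(TimeStepViolation, match="toofast"):
            SchemeStepper(s, RateContext(), dt_ms=1e-3)

    def test_grouped_equals_per_molecule_in_distribution(self, rng):
        """The multinomial-grouped sampler and the per-molecule sampler
        draw from the same law: state histograms after many steps agree
        within Monte-Carlo error."""
        scheme = build_ncx_scheme()
        ctx = RateContext(temperature_factor=3.0)
        n, n_steps = 2000, 4000
        stepper = SchemeStepper(scheme, ctx, dt_ms=1e-3)
        s1 = np.zeros(n, dtype=np.int64)
        s2 = np.zeros(n, dtype=np.int64)
        r1, r2 = np.random.default_rng(1), np.random.default_rng(2)
        for _ in range(n_steps):
            stepper.step(s1, r1)
            stepper.step_grouped(s2, r2)
        h1 = np.bincount(s1, minlength=scheme.n_states) / n
        h2 = np.bincount(s2, minlength=scheme.n_states) / n
        se = np.sqrt(np.maximum(h1 * (1 - h1), 1e-6) / n)
        assert np.all(np.abs(h1 - h2) < 4 * se + 2e-3)

    @pytest.mark.parametrize("na_i", [10.0, 15.0, 20.0])
    @pytest.mark.parametrize("scheme_name", ["eaat", "ncx"])
    def test_long_run_occupancy_matches_steady_state(self, scheme_name, na_i):
        """Stochastic/analytic agreement across the Na+ titration grid."""
        scheme = build_eaat_scheme() if scheme_name == "eaat" else build_ncx_scheme()
        ctx = RateContext(na_i=na_i, glu_e=0.003, temperature_factor=3.0)
        p = steady_state(scheme, ctx)
        n = 3000
        rng = np.random.default_rng(hash((scheme_name, na_i)) % 2**31)
        stepper = SchemeStepper(scheme, ctx, dt_ms=1e-3)
        states = rng.choice(scheme.n_states, size=n, p=p)
        counts = np.bincount(states, minlength=scheme.n_states)
        for _ in range(20000):
            stepper.step_grouped(states, rng, counts)
        occ = counts / n
        se = np.sqrt(np.maximum(p * (1 - p), 1e-7) / n)
        assert np.all(np.abs(occ - p) <= 4 * se + 2e-3)


class TestQ10:
    def test_identity_at_reference(self):
        assert apply_q10(5.0, q10=3, t_ref_c=27, t_sim_c=27) == 5.0

    def test_one_decade(self):
        assert apply_q10(5.0, q10=3, t_ref_c=27, t_sim_c=37) == pytest.approx(15.0)

    def test_fractional_decade(self):
        assert apply_q10(1.0, q10=3, t_ref_c=22, t_sim_c=37) == pytest.approx(
            3**1.5, rel=1e-12
        )

    def test_mapping_input(self):
        out = apply_q10({"a": 1.0, "b": 2.0}, q10=3)
        assert out == pytest.approx({"a": 3.0, "b": 6.0})

    def test_invalid_q10(self):
        with pytest.raises(ValueError):
            apply_q10(1.0, q10=0)


class TestLigandBookkeeping:
    def test_holding_states_derivation(self):
        from calfluct.sim import _holding_states

        eaat = build_eaat_scheme()
        held = _holding_states(eaat)["glu"]
        names = {eaat.states[i] for i in held}
        assert names == {
            "out_na_h_glu",
            "out_na2_h_glu",
            "out_na3_h_glu",
            "in_na3_h_glu",
            "in_na2_h_glu",
        }
        ncx = build_ncx_scheme()
        held = _holding_states(ncx)["ca"]
        assert {ncx.states[i] for i in held} == {"in_ca", "out_ca"}
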