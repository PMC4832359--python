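"""Model-layer tests: relaxation rates, bolus shape, ODE right-hand sides,
conservation laws and the first-order limit."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import hpkinetics as hp
from hpkinetics import model as m

RNG = np.random.default_rng(7)


class TestEffectiveRelaxationRate:
    def test_zero_flip_is_pure_t1_decay(self):
        assert hp.effective_relaxation_rate(50.0, 0.0, 2.0) == pytest.approx(0.02, abs=1e-15)

    def test_study_conditions_value(self):
        # frozen high-precision (symbolic) evaluation of 1/76.7 - ln(cos 10 deg)/2
        r = hp.effective_relaxation_rate(76.7, 10.0, 2.0)
        assert r == pytest.approx(0.020692225380972021, abs=1e-12)

    def test_exceeds_pure_t1_rate(self):
        for t1, th, tr in [(50, 10, 2), (100, 45, 1), (5, 89, 10)]:
            assert hp.effective_relaxation_rate(t1, th, tr) > 1.0 / t1

    def test_rejects_90_degree_flip(self):
        with pytest.raises(ValueError):
            hp.effective_relaxation_rate(50.0, 90.0, 2.0)


class TestInputRate:
    def test_causal(self):
        p = hp.InputParams(k_in=1.0, t_arrival=10.0, delta=2.0, beta=0.2)
        t = np.array([0.0, 5.0, 9.999])
        assert np.all(hp.input_rate(t, p) == 0.0)

    def test_exponential_limit_at_arrival(self):
        p = hp.InputParams(k_in=3.0, t_arrival=10.0, delta=0.0, beta=0.2)
        assert hp.input_rate(10.0, p) == pytest.approx(3.0)

    def test_peak_location_and_value_against_grid_search(self):
        # dense grid-search oracle: max of t^2 exp(-0.2 t) at t = 10, value 100 e^-2
        p = hp.InputParams(k_in=1.0, t_arrival=10.0, delta=2.0, beta=0.2)
        t = np.linspace(10.0, 70.0, 600001)
        u = hp.input_rate(t, p)
        i = int(np.argmax(u))
        assert t[i] == pytest.approx(20.0, abs=1e-3)
        assert u[i] == pytest.approx(100.0 * np.exp(-2.0), rel=1e-7)

    def test_single_interior_maximum(self):
        p = hp.InputParams(k_in=1.0, t_arrival=0.0, delta=1.5, beta=0.1)
        u = hp.input_rate(np.linspace(0, 120, 2000), p)
        d = np.diff(u)
        # rises then falls: sign changes exactly once
        assert np.sum(np.diff(np.sign(d[np.abs(d) > 0])) != 0) == 1


def _zero_relax_schedule():
    # tiny flip and huge T1 make every effective relaxation rate negligible
    sched = hp.AcquisitionSchedule(flip_angle=1e-9)
    relax = hp.RelaxationParams(T1_pyruvate=1e12, T1_lactate=1e12,
                                T1_alanine=1e12, T1_bicarbonate=1e12)
    return sched, relax


class TestSecondOrderRHS:
    def test_all_zero_rates_and_input_gives_zero_derivative(self):
        sched, relax = _zero_relax_schedule()
        k = hp.SecondOrderParams(k_PL=0, k_PA=0, k_PB=0)
        inp = hp.InputParams(k_in=0.0)
        y = np.ones(15)
        y[14] = 0.0  # no accumulated relaxed input
        d = hp.second_order_rhs(5.0, y, k, relax, sched, inp)
        assert np.allclose(d, 0.0, atol=1e-11)

    def test_hand_evaluated_example(self):
        # P*=1 with unit NADHc/Glu/NADm pools; flux bookkeeping checked term by term
        sched, relax = _zero_relax_schedule()
        k = hp.SecondOrderParams(k_PL=0.1, k_PA=0.01, k_PB=0.05,
                                 NADc0=0, NADHc0=1, Glu0=1, aKG0=0, NADm0=1, NADHm0=0)
        inp = hp.InputParams(k_in=0.0)
        y = np.zeros(15)
        y[0] = 1.0          # Pstar
        y[9] = 1.0          # NADHc
        y[10] = 1.0         # Glu
        y[12] = 1.0         # NADm
        d = dict(zip(m.STATE_NAMES, hp.second_order_rhs(0.0, y, k, relax, sched, inp)))
        assert d["Pstar"] == pytest.approx(-0.16)
        assert d["Lstar"] == pytest.approx(0.1)
        assert d["Astar"] == pytest.approx(0.01)
        assert d["Bstar"] == pytest.approx(0.05)
        assert d["NADHc"] == pytest.approx(-0.1)
        assert d["NADc"] == pytest.approx(0.1)
        assert d["Glu"] == pytest.approx(-0.01)
        assert d["aKG"] == pytest.approx(0.01)
        assert d["NADm"] == pytest.approx(-0.05)
        assert d["NADHm"] == pytest.approx(0.05)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 10), min_size=15, max_size=15),
           st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_cofactor_pair_sums_have_zero_derivative(self, state, kpl, kpa, kpb):
        sched = hp.AcquisitionSchedule()
        relax = hp.RelaxationParams()
        k = hp.SecondOrderParams(k_PL=kpl, k_PA=kpa, k_PB=kpb)
        d = hp.second_order_rhs(30.0, np.array(state), k, relax, sched, hp.InputParams())
        assert d[8] + d[9] == 0.0    # NADc + NADHc
        assert d[10] + d[11] == 0.0  # Glu + aKG
        assert d[12] + d[13] == 0.0  # NADm + NADHm

    def test_compiled_core_matches_reference(self):
        # the numba-compiled solver core must agree with the Python definition
        p = np.array([0.1, 0.02, 0.05, 0.02, 0.025, 0.02, 0.021,
                      0.5, 10.0, 2.0, 0.1, 1.0, 1.0])
        for _ in range(20):
            y = RNG.uniform(-0.1, 5.0, 15)
            t = RNG.uniform(0, 200)
            np.testing.assert_allclose(m._second_core_fast(t, y, p),
                                       m._second_core(t, y, p), rtol=0, atol=0)

    def test_pdh_cofactor_switch_changes_coupling(self):
        sched, relax = _zero_relax_schedule()
        k = hp.SecondOrderParams(k_PL=0, k_PA=0, k_PB=0.1, NADm0=2.0, NADHm0=0.5)
        y = np.zeros(15)
        y[0] = 1.0
        y[12], y[13] = 2.0, 0.5
        inp = hp.InputParams(k_in=0.0)
        d_nadm = hp.second_order_rhs(0.0, y, k, relax, sched, inp, pdh_cofactor="nadm")
        d_nadhm = hp.second_order_rhs(0.0, y, k, relax, sched, inp, pdh_cofactor="nadhm")
        assert d_nadm[3] == pytest.approx(0.2)   # k_PB * NADm * Pstar
        assert d_nadhm[3] == pytest.approx(0.05)


class TestFirstOrderRHS:
    def test_zero_state_zero_input_is_fixed_point(self):
        sched = hp.AcquisitionSchedule()
        k = hp.FirstOrderParams()
        d = hp.first_order_rhs(5.0, np.zeros(15), k, hp.RelaxationParams(),
                               sched, hp.InputParams(k_in=0.0))
        assert np.allclose(d, 0.0)

    def test_one_way_bicarbonate_production(self):
        sched, relax = _zero_relax_schedule()
        k = hp.FirstOrderParams(k_PL=0.1, k_LP=0, k_PA=0.01, k_AP=0, k_PB=0.05)
        y = np.zeros(15)
        y[0] = 2.0
        d = hp.first_order_rhs(0.0, y, k, relax, sched, hp.InputParams(k_in=0.0))
        assert d[3] == pytest.approx(0.05 * 2.0)

    def test_matches_second_order_at_matched_pseudo_rates_with_frozen_cofactors(self):
        # with enormous pools at fixed product the second-order derivative of the
        # metabolite block equals the first-order one
        sched = hp.AcquisitionSchedule()
        relax = hp.RelaxationParams()
        inp = hp.InputParams()
        S = 1e6
        k2 = hp.SecondOrderParams(k_PL=0.082 / S, k_PA=0.005 / S, k_PB=0.075 / S,
                                  NADc0=2 * S, NADHc0=S, Glu0=S, aKG0=2 * S,
                                  NADm0=S, NADHm0=S)
        k1 = hp.FirstOrderParams(k_PL=0.082, k_LP=0.164, k_PA=0.005,
                                 k_AP=0.010, k_PB=0.075)
        y = np.zeros(15)
        y[:8] = RNG.uniform(0, 1, 8)
        y[8:14] = [2 * S, S, S, 2 * S, S, S]
        d2 = hp.second_order_rhs(30.0, y, k2, relax, sched, inp)
        d1 = hp.first_order_rhs(30.0, y, k1, relax, sched, inp)
        np.testing.assert_allclose(d2[:8], d1[:8], rtol=1e-9)


class TestConservationAndPositivity:
    def test_metabolite_mass_conserved_without_input(self):
        # nonzero metabolite pools, no bolus: total pyr+lac+ala+bic mass constant
        sched = hp.AcquisitionSchedule()
        relax = hp.RelaxationParams()
        k = hp.SecondOrderParams()
        inp = hp.InputParams(k_in=0.0)
        y0 = np.zeros(15)
        y0[:8] = [1.0, 0.2, 0.1, 0.05, 0.5, 0.3, 0.2, 0.1]
        y0[8:14] = k.initial_pools
        rhs = m.make_rhs("second_order", k, relax, sched, inp)
        sol = solve_ivp(rhs, (0, 180), y0, rtol=1e-10, atol=1e-12, method="LSODA",
                        t_eval=np.linspace(0, 180, 50))
        total = sol.y[:8].sum(axis=0)
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-8

    def test_cofactor_pair_sums_constant_along_flow(self, glucose_second_order_data):
        traj = glucose_second_order_data["trajectory"]
        for a, b in [("NADc", "NADHc"), ("Glu", "aKG"), ("NADm", "NADHm")]:
            s = traj[a] + traj[b]
            assert np.max(np.abs(s - s.iloc[0])) / s.iloc[0] < 1e-8

    def test_positivity_from_nonnegative_initial_conditions(self, glucose_second_order_data):
        traj = glucose_second_order_data["trajectory"]
        scale = float(traj.abs().to_numpy().max())
        assert traj.to_numpy().min() >= -1e-9 * scale


class TestFirstOrderLimit:
    def test_second_order_converges_to_first_order_as_pools_grow(self):
        sched = hp.AcquisitionSchedule(n_points=45)
        relax = hp.RelaxationParams()
        inp = hp.InputParams(k_in=0.001)
        k1 = hp.FirstOrderParams(k_PL=0.082, k_LP=0.164, k_PA=0.005,
                                 k_AP=0.010, k_PB=0.075)
        ts1, _ = hp.simulate("first_order", k1, relax, sched, inp,
                             solver_opts={"rtol": 1e-10, "atol": 1e-13})
        devs = []
        for S in (1e2, 1e4, 1e6):
            k2 = hp.SecondOrderParams(k_PL=0.082 / S, k_PA=0.005 / S, k_PB=0.075 / S,
                                      NADc0=2 * S, NADHc0=S, Glu0=S, aKG0=2 * S,
                                      NADm0=S, NADHm0=S)
            ts2, _ = hp.simulate("second_order", k2, relax, sched, inp,
                                 solver_opts={"rtol": 1e-10, "atol": 1e-13})
            devs.append(np.max(np.abs(ts2.signals - ts1.signals)) / ts1.signals.max())
        assert devs[-1] < 1e-3
        assert devs[0] > devs[1] > devs[2]


class TestPseudoRates:
    def test_constant_cofactors_give_constant_rates(self):
        import pandas as pd
        traj = pd.DataFrame(
            {n: np.ones(5) for n in m.STATE_NAMES},
            index=pd.Index(np.arange(5.0), name="time_s"))
        k = hp.SecondOrderParams(k_PL=0.1, k_PA=0.2, k_PB=0.3)
        pr = hp.pseudo_rates(traj, k)
        for col in pr:
            assert pr[col].nunique() == 1

    def test_products_match_independent_recomputation(self, glucose_second_order_data):
        traj = glucose_second_order_data["trajectory"]
        k = glucose_second_order_data["params"]
        pr = hp.pseudo_rates(traj, k)
        np.testing.assert_allclose(pr["k_PL"], k.k_PL * np.clip(traj["NADHc"], 0, None))
        np.testing.assert_allclose(pr["k_LP"], k.k_PL * np.clip(traj["NADc"], 0, None))
        np.testing.assert_allclose(pr["k_AP"], k.k_PA * np.clip(traj["aKG"], 0, None))
        np.testing.assert_allclose(pr["k_PB"], k.k_PB * np.clip(traj["NADm"], 0, None))

    def test_pdh_pseudo_rate_monotone_non_increasing(self, glucose_second_order_data):
        pr = hp.pseudo_rates(glucose_second_order_data["trajectory"],
                             glucose_second_order_data["params"])
        assert np.all(np.diff(pr["k_PB"]) <= 1e-12)


class TestDomainTypes:
    @pytest.mark.parametrize("kwargs", [
        {"repetition_time": 0.0}, {"flip_angle": 0.0}, {"flip_angle": 90.0},
        {"n_points": 1},
    ])
    def test_schedule_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            hp.AcquisitionSchedule(**kwargs)

    def test_schedule_times_uniform(self):
        s = hp.AcquisitionSchedule(repetition_time=2.0, n_points=90)
        assert s.times.size == 90
        assert np.allclose(np.diff(s.times), 2.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            hp.FirstOrderParams(k_PL=-0.1)
        with pytest.raises(ValueError):
            hp.SecondOrderParams(NADm0=-1)
        with pytest.raises(ValueError):
            hp.RelaxationParams(T1_lactate=0)
        with pytest.raises(ValueError):
            hp.InputParams(beta=0)
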