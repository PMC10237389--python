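"""Core ODE model: right-hand side, integration, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nfkbid as nk
from nfkbid.model import IntegrationError, STATE_NAMES

REST = np.array([1.0, 0, 0, 0, 0, 0])


class TestRHS:
    @pytest.mark.parametrize("params", [nk.FITTED, nk.PRE_FITTED],
                             ids=["fitted", "pre-fitted"])
    def test_resting_state_is_equilibrium_without_tnf(self, params):
        assert np.allclose(nk.rhs(REST, params, 0), 0.0, atol=1e-15)

    def test_tnf_switch_drains_ikkn_into_ikka(self):
        # from rest, TNF only moves IKKn -> IKKa at rate k1
        d = nk.rhs(REST, nk.FITTED, 1)
        assert d[0] == pytest.approx(-0.00195, rel=1e-12)
        assert d[1] == pytest.approx(+0.00195, rel=1e-12)
        assert np.allclose(d[2:], 0.0)

    def test_without_ikka_nuclear_nfkb_cannot_rise(self, rng):
        for _ in range(50):
            y = rng.uniform(0, 1, 6)
            y[1] = 0.0  # no active kinase
            assert nk.rhs(y, nk.FITTED, 0)[2] <= 0.0

    def test_michaelis_split_conserves_a3_flux(self, rng):
        # the release fraction δ/(B+δ) in the NFkBn equation and the
        # consumption fraction B/(B+δ) in the IkBa equation sum to one, so
        # with translation, decay and import switched off the total
        # a3-driven flux is exactly a3·IKKa·(1−NFkBn)
        p = nk.FITTED.with_updates(c4a=0.0, c5a=0.0, a2=0.0, i1a=0.0)
        for _ in range(50):
            y = rng.uniform(0, 1, 6)
            d = nk.rhs(y, p, 1)
            total = p.a3 * y[1] * (1 - y[2])
            assert d[2] - d[4] == pytest.approx(total, rel=1e-12, abs=1e-15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nk.rhs([-0.1, 0, 0, 0, 0, 0], nk.FITTED, 0)
        with pytest.raises(ValueError, match="tnf"):
            nk.rhs(REST, nk.FITTED, 2)

    def test_jacobian_matches_finite_differences(self, rng):
        y = rng.uniform(0.05, 0.9, 6)
        J = nk.jacobian(y, nk.FITTED, 1)
        h = 1e-7
        for k in range(6):
            yp, ym = y.copy(), y.copy()
            yp[k] += h
            ym[k] -= h
            col = (nk.rhs(yp, nk.FITTED, 1) - nk.rhs(ym, nk.FITTED, 1)) / (2 * h)
            assert np.allclose(J[:, k], col, rtol=1e-5, atol=1e-10)


class TestSteadyStates:
    def test_resting_steady_state_value(self):
        for p in (nk.FITTED, nk.PRE_FITTED):
            assert np.array_equal(nk.resting_steady_state(p), REST)

    def test_long_unstimulated_run_returns_to_rest(self):
        y0 = [0.5, 0.1, 0.2, 0.1, 0.1, 0.1]
        traj = nk.simulate(nk.FITTED, [(0.0, 6000.0, 0)], y0=y0,
                           grid_step_min=50.0)
        assert np.allclose(traj.iloc[-1][list(STATE_NAMES)], REST, atol=1e-5)

    def test_stimulated_fixed_point_nominal_is_stable_positive(self):
        fp = nk.stimulated_fixed_point(nk.FITTED)
        assert fp.converged and fp.residual_norm < 1e-12
        assert fp.stable and np.all(fp.state > 0)

    def test_limit_cycle_variant_has_unstable_fixed_point(self):
        p = nk.FITTED.with_updates(a2=0.02, c5a=1e-5, i1a=1e-4)
        fp = nk.stimulated_fixed_point(p)
        assert fp.converged and not fp.stable
        assert fp.eigenvalue_max_real_part > 0

    def test_strong_feedback_variant_parks_nfkb_near_zero(self):
        fp = nk.stimulated_fixed_point(nk.FITTED.with_updates(k2=3.57,
                                                              i1a=0.01))
        assert fp.converged and fp.stable
        assert fp.state[2] < 0.05  # NFkBn close to its resting value


class TestSimulate:
    def test_unstimulated_trajectory_is_constant(self):
        traj = nk.simulate(nk.FITTED, [(0.0, 720.0, 0)], grid_step_min=60.0)
        assert np.allclose(traj[list(STATE_NAMES)].to_numpy(), REST,
                           atol=1e-10)

    def test_on_off_direction_of_response(self, on_off):
        traj = nk.simulate(nk.FITTED, on_off.stimulus)
        t = traj["time_min"].to_numpy()
        during = (t > 0) & (t <= 120)
        # all measured observables rise during stimulation, IKKn falls
        for obs in ("IKKa", "NFkBn", "A20", "IkBat"):
            assert traj.loc[during, obs].max() > 1e-3
        assert traj.loc[during, "IKKn"].is_monotonic_decreasing
        # washout brings NFkBn and IKKa back down
        end = traj.iloc[-1]
        assert end["IKKa"] < 1e-3
        assert end["NFkBn"] < 0.01

    def test_derived_columns(self, on_off):
        traj = nk.simulate(nk.FITTED, on_off.stimulus, grid_step_min=10.0)
        assert np.allclose(traj["IkBa_total"],
                           traj["IkBa"] + 1 - traj["NFkBn"])
        assert np.allclose(traj["NFkB_complexed"], 1 - traj["NFkBn"])

    def test_tolerance_halving_does_not_move_trajectory(self, on_off):
        times = np.array([5.0, 30, 60, 120, 180, 300, 720])
        a = nk.simulate(nk.FITTED, on_off.stimulus, t_eval_min=times)
        b = nk.simulate(nk.FITTED, on_off.stimulus, t_eval_min=times,
                        rtol=5e-9, atol=5e-11)
        diff = np.abs(a[list(STATE_NAMES)].to_numpy()
                      - b[list(STATE_NAMES)].to_numpy())
        assert diff.max() < 1e-6

    def test_a20ko_equals_k2_zero_for_other_variables(self, on_off):
        times = np.linspace(0, 720, 25)
        ko = nk.simulate(nk.FITTED, on_off.stimulus, genotype="A20KO",
                         t_eval_min=times)
        k2zero = nk.simulate(nk.FITTED.with_updates(k2=0.0),
                             on_off.stimulus, t_eval_min=times)
        others = [n for n in STATE_NAMES if n != "A20"]
        assert np.allclose(ko[others].to_numpy(), k2zero[others].to_numpy(),
                           atol=1e-8)
        assert np.allclose(ko["A20"], 0.0)

    def test_out_of_span_request_rejected(self, on_off):
        with pytest.raises(ValueError, match="span"):
            nk.simulate(nk.FITTED, on_off.stimulus, t_eval_min=[800.0])

    @settings(max_examples=12, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounds_preserved_under_parameter_perturbation(self, seed):
        # up to 3-fold random perturbation of every rate constant
        r = np.random.default_rng(seed)
        factors = np.exp(r.uniform(-np.log(3), np.log(3), 13))
        params = nk.ParameterSet.from_array(nk.FITTED.to_array() * factors)
        traj = nk.simulate(params, [(0.0, 120.0, 1), (120.0, 480.0, 0)],
                           grid_step_min=5.0)
        y = traj[list(STATE_NAMES)].to_numpy()
        assert y.min() >= 0.0
        assert traj["NFkBn"].max() <= 1.0 + 1e-9
        assert traj["IKKn"].max() <= 1.0 + 1e-9
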