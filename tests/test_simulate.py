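"""Batch integration, serial transfer, and the Euler cross-check oracle."""

import numpy as np
import pytest

from phfeedback.model import Environment, SpeciesParams, SystemState, NULL_SPECIES
from phfeedback.simulate import (
    TransferProtocol,
    integrate,
    euler_endpoint,
    apply_dilution,
    run_serial_transfer,
    read_trajectory_csv,
    write_trajectory_csv,
    EVENT_PRE,
    EVENT_POST,
)

ENV = Environment(b=5.0, p0=5.0)


def test_sterile_start_stays_constant(archetypes):
    species, env = archetypes
    tr = integrate(SystemState(0.0, 0.0, 3.0), species["lp"], species["ca"], env, 50.0)
    assert np.all(tr.n_a == 0) and np.all(tr.n_b == 0)
    assert np.allclose(tr.p, 3.0, atol=1e-9)


def test_self_killer_rises_then_collapses(archetypes):
    """A species preferring moderate proton levels that keeps acidifying
    first booms, then drives the environment past its niche and dies; the
    proton concentration rises monotonically past its optimum."""
    species, env = archetypes
    sm = species["sm"]
    tr = integrate(SystemState(0.1, 0.0, 1.0), sm, NULL_SPECIES, env, 200.0)
    peak = tr.n_a.max()
    assert peak > 10 * tr.n_a[0]
    assert tr.n_a[-1] < 1e-3 * sm.K
    assert np.all(np.diff(tr.p) >= -1e-9)
    assert tr.p[-1] > sm.p_pref


def test_adaptive_endpoint_matches_euler(archetypes):
    species, env = archetypes
    lp, ca = species["lp"], species["ca"]
    state0 = SystemState(0.7, 1.3, 6.0)
    tr = integrate(state0, lp, ca, env, 20.0)
    euler = euler_endpoint(state0, lp, ca, env, 20.0, dt=1e-4)
    got = np.array([tr.n_a[-1], tr.n_b[-1], tr.p[-1]])
    ref = np.array(euler)
    assert np.all(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-6) < 1e-3)


def test_invalid_horizon_rejected(archetypes):
    species, env = archetypes
    with pytest.raises(ValueError):
        integrate(SystemState(1, 0, 5), species["lp"], NULL_SPECIES, env, -1.0)


class TestDilution:
    def test_proton_reset_formula(self):
        state = apply_dilution(SystemState(1e6, 0.0, 4.0), 10.0, ENV, p0=1.0)
        assert state.p == pytest.approx(1.3)
        assert state.n_a == pytest.approx(1e5)

    def test_identity_at_unit_factor(self):
        s = SystemState(2.0, 3.0, 6.0, t=1.5)
        assert apply_dilution(s, 1.0, ENV) == s

    def test_densities_divided_exactly(self):
        s = apply_dilution(SystemState(1e6, 4e4, 5.0), 100.0, ENV)
        assert s.n_a == 1e4 and s.n_b == 4e2

    def test_sub_unit_factor_rejected(self):
        with pytest.raises(ValueError):
            apply_dilution(SystemState(1, 1, 5), 0.5, ENV)


class TestSerialTransfer:
    def test_sterile_cycles_stay_sterile(self, archetypes):
        species, env = archetypes
        proto = TransferProtocol(cycle_length=5, dilution_factor=10, n_cycles=4)
        tr = run_serial_transfer(
            SystemState(0, 0, env.p0), species["lp"], species["ca"], env, proto
        )
        assert np.all(tr.n_a == 0) and np.all(tr.n_b == 0)
        assert np.allclose(tr.p, env.p0, atol=1e-9)

    def test_single_cycle_without_dilution_equals_batch(self, archetypes):
        species, env = archetypes
        lp = species["lp"]
        proto = TransferProtocol(cycle_length=5, dilution_factor=1, n_cycles=1)
        s0 = SystemState(1.0, 0.0, 6.0)
        tr1 = run_serial_transfer(s0, lp, NULL_SPECIES, env, proto)
        tr2 = integrate(s0, lp, NULL_SPECIES, env, 5.0)
        assert tr1.n_a[-1] == pytest.approx(tr2.n_a[-1], rel=1e-9)
        assert tr1.p[-1] == pytest.approx(tr2.p[-1], rel=1e-9)

    def test_post_transfer_density_is_exact_division(self, archetypes):
        species, env = archetypes
        proto = TransferProtocol(cycle_length=5, dilution_factor=10, n_cycles=5)
        tr = run_serial_transfer(
            SystemState(1.0, 0.0, 5.0), species["lp"], NULL_SPECIES, env, proto
        )
        pre = np.flatnonzero(tr.event == EVENT_PRE)
        post = np.flatnonzero(tr.event == EVENT_POST)
        for i_pre, i_post in zip(pre[:-1], post):
            assert tr.n_a[i_post] == pytest.approx(tr.n_a[i_pre] / 10.0, rel=1e-12)

    def test_high_dilution_outdilutes(self, archetypes):
        species, env = archetypes
        lp = species["lp"]
        proto = TransferProtocol(cycle_length=5, dilution_factor=1000, n_cycles=8)
        tr = run_serial_transfer(SystemState(1.0, 0.0, 8.0), lp, NULL_SPECIES, env, proto)
        assert tr.n_a[-1] < 1e-3 * lp.K

    def test_time_strictly_increasing(self, archetypes):
        species, env = archetypes
        proto = TransferProtocol(cycle_length=5, dilution_factor=10, n_cycles=3)
        tr = run_serial_transfer(
            SystemState(1.0, 0.0, 5.0), species["lp"], NULL_SPECIES, env, proto
        )
        assert np.all(np.diff(tr.t) > 0)


def test_bounds_hold_for_random_initial_conditions(archetypes):
    """p stays on its scale and densities never exceed max(n0, K)."""
    species, env = archetypes
    rng = np.random.default_rng(7)
    pairs = [(species["lp"], species["ca"]), (species["sm"], species["pv"])]
    for _ in range(20):
        sp_a, sp_b = pairs[rng.integers(len(pairs))]
        n_a0 = rng.uniform(0, sp_a.K)
        n_b0 = rng.uniform(0, sp_b.K)
        tr = integrate(
            SystemState(n_a0, n_b0, rng.uniform(0, 10)), sp_a, sp_b, env, 60.0
        )
        tol = 1e-6
        assert np.all((tr.p >= -tol) & (tr.p <= 10 + tol))
        assert np.all(tr.n_a <= max(n_a0, sp_a.K) + tol)
        assert np.all(tr.n_b <= max(n_b0, sp_b.K) + tol)


def test_trajectory_csv_round_trip(tmp_path, archetypes):
    species, env = archetypes
    proto = TransferProtocol(cycle_length=5, dilution_factor=10, n_cycles=2)
    tr = run_serial_transfer(
        SystemState(1.0, 0.5, 5.0), species["lp"], species["ca"], env, proto
    )
    path = tmp_path / "traj.csv"
    write_trajectory_csv(tr, path, meta={"seed": 1})
    back = read_trajectory_csv(path)
    np.testing.assert_allclose(back.t, tr.t)
    np.testing.assert_allclose(back.n_a, tr.n_a)
    np.testing.assert_allclose(back.p, tr.p)
    assert list(back.event) == list(tr.event)
    assert open(path).readline().startswith("# seed")
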