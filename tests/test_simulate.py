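"""Numeric integration: closed forms, conserved quantities, solver sanity."""

import numpy as np
import pytest

from offl import (DomainError, IntegrationError, build_example,
                  check_conservation, integrate)


def test_growth_matches_exponential_closed_form(growth):
    traj = integrate(growth, {"κ": 0.3}, t_end=5.0, n_points=51)
    expected = 2.0 * np.exp(0.3 * traj.times)
    assert traj["N"] == pytest.approx(expected, rel=1e-6)


def test_trajectory_row_zero_is_initial_condition(si):
    traj = integrate(si, t_end=1.0, n_points=5)
    assert traj.values[0].tolist() == [990.0, 10.0]
    assert np.all(np.diff(traj.times) > 0)


def test_si_conserves_total_population(si):
    # 1 S + 1 I -> 2 I: every encounter conserves the number of people
    traj = integrate(si, t_end=50.0, n_points=201)
    totals = traj["S"] + traj["I"]
    assert totals == pytest.approx(np.full_like(totals, 1000.0), rel=1e-6)


def test_lotka_volterra_first_integral_is_constant(lotka_volterra):
    # V = aβR - δ log R + aαF - k log F has dV/dt = 0 along any orbit
    p = lotka_volterra.parameter_values()
    traj = integrate(lotka_volterra, t_end=30.0, n_points=301)
    r, f = traj["R"], traj["F"]
    v = (p["a"] * p["β"] * r - p["δ"] * np.log(r)
         + p["a"] * p["α"] * f - p["k"] * np.log(f))
    assert v == pytest.approx(np.full_like(v, v[0]), rel=1e-5)


def test_check_conservation_sir_total_parcels(sir):
    # all seven interactions redeposit every parcel they draw (infection is
    # 1 + 1 -> 2), so S+I+R+K+Δ stays fixed
    traj = integrate(sir, t_end=50.0, n_points=101)
    drift = check_conservation(traj, np.ones(5))
    total = float(np.sum(traj.values[0]))
    assert drift < 1e-6 * total


def test_check_conservation_zero_weights_and_growth(growth):
    traj = integrate(growth, t_end=2.0, n_points=21)
    assert check_conservation(traj, [0.0]) == 0.0
    drift = check_conservation(traj, [1.0])
    assert drift == pytest.approx(traj["N"][-1] - traj["N"][0], rel=1e-9)
    assert drift > 0  # growth is non-conservative


def test_check_conservation_rejects_length_mismatch(growth):
    traj = integrate(growth, t_end=1.0, n_points=5)
    with pytest.raises(DomainError):
        check_conservation(traj, [1.0, 1.0])


def test_parameter_overrides_win_over_table_defaults(growth):
    traj = integrate(growth, {"κ": 0.0}, t_end=5.0, n_points=11)
    assert traj["N"] == pytest.approx(np.full(11, 2.0))


def test_tightening_tolerance_changes_little(lotka_volterra):
    # convergence sanity: halving rtol moves the endpoint by less than rtol
    end = []
    for rtol in (1e-8, 5e-9):
        traj = integrate(lotka_volterra, t_end=20.0, n_points=21,
                         options={"rtol": rtol, "atol": rtol * 1e-2})
        end.append(traj.values[-1, :2])
    assert end[0] == pytest.approx(end[1], rel=1e-8 * 100)


def test_domain_errors_on_bad_grid(growth):
    with pytest.raises(DomainError):
        integrate(growth, t_end=-1.0)
    with pytest.raises(DomainError):
        integrate(growth, t_end=1.0, n_points=1)


def test_negative_excursion_warns():
    from offl import OfflModel
    m = OfflModel()
    m.add_species("N", 1.0)
    m.add_parameter("κ", 1.0)
    # constant drain: N crosses zero and keeps falling, per the literal ODE
    m.add_species("W", 1.0)
    m.add_interaction("drain", "κ/N", sources=["N"], targets=[("W", 1)])
    with pytest.warns(RuntimeWarning, match="negative"):
        integrate(m, t_end=3.0, n_points=31)


def test_solver_failure_is_reported():
    from offl import OfflModel
    m = OfflModel()
    m.add_species("N", 1.0)
    m.add_parameter("κ", 1.0)
    m.add_interaction("blowup", "κ*N", sources=["N"], targets=[("N", 3)])
    # finite-time blow-up of dN/dt = 2κN^2: the step size underflows
    import warnings
    with pytest.raises(IntegrationError), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # overflow en route
        integrate(m, t_end=10.0, n_points=11, options={"method": "RK45"})
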