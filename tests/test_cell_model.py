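"""Unit tests for the endocardial cell model and its integrator."""

import dataclasses

import numpy as np
import pytest

from apdiff.cell_model import (
    CellState,
    ModelParameters,
    StimulusProtocol,
    compute_currents,
    derivatives,
    resting_state,
    run_paced,
    run_unstimulated,
)
from apdiff.ap_features import measure_apd


def test_current_set_sums_to_total(params):
    cur = compute_currents(resting_state(), params)
    members = [cur.I_Na, cur.I_K1, cur.I_to, cur.I_Kr, cur.I_Ks, cur.I_CaL,
               cur.I_NaCa, cur.I_NaK, cur.I_pCa, cur.I_pK, cur.I_bCa,
               cur.I_bNa]
    assert cur.I_ion == pytest.approx(sum(members), abs=1e-12)


def test_zero_gate_zeroes_current(params):
    st = dataclasses.replace(resting_state(), m=0.0)
    assert compute_currents(st, params).I_Na == 0.0
    st = dataclasses.replace(resting_state(), xs=0.0)
    assert compute_currents(st, params).I_Ks == 0.0


def test_current_vanishes_at_nernst_potential(params):
    # set V to E_K: every purely H-H K+ current has zero driving force
    st = resting_state()
    e_k = params.R * params.T / params.F * np.log(params.Ko / st.K_i)
    st = dataclasses.replace(st, V=float(e_k))
    cur = compute_currents(st, params)
    assert cur.I_to == pytest.approx(0.0, abs=1e-12)
    assert cur.I_Kr == pytest.approx(0.0, abs=1e-12)
    assert cur.I_K1 == pytest.approx(0.0, abs=1e-12)


def test_resting_steady_state_residual(params):
    # oracle: long unpaced integration; residual total current ~ 0
    rest = run_unstimulated(params, duration=200_000.0)
    assert abs(compute_currents(rest, params).I_ion) < 0.01


def test_unstimulated_model_is_stable(params):
    rest = run_unstimulated(params, duration=200_000.0)
    after = run_unstimulated(params, duration=10_000.0, initial_state=rest)
    dvdt = derivatives(after, params)[0]
    assert abs(dvdt) < 1e-3


def test_membrane_equation_sign_and_consistency(params):
    st = resting_state()
    cur = compute_currents(st, params)
    dy = derivatives(st, params, i_stim=0.0)
    # currents are per-capacitance (A/F): dV/dt = -(I_ion + I_stim)
    assert dy[0] == pytest.approx(-cur.I_ion, rel=1e-12)
    # opposite sign to (I_ion + I_stim)
    dy_stim = derivatives(st, params, i_stim=-80.0)
    assert np.sign(dy_stim[0]) == -np.sign(cur.I_ion - 80.0)


def test_gate_at_steady_value_has_zero_derivative(params):
    # hold V fixed; a gate moved to its V-dependent target stops moving
    st = resting_state()
    dy = derivatives(st, params)
    y = st.as_vector()
    # Newton-free check: move each gate by the sign of its derivative and
    # verify the derivative shrinks toward zero at the implied target
    for idx in range(1, 14):
        if abs(dy[idx]) < 1e-12:
            continue
        # dx/dt = (x_inf - x)/tau  =>  x_inf = x + dx/dt * tau; setting the
        # gate there must zero its derivative
        y2 = y.copy()
        # estimate tau by finite perturbation of the gate value
        eps = 1e-6
        y_eps = y.copy()
        y_eps[idx] += eps
        dy_eps = derivatives(CellState.from_vector(y_eps), params)
        slope = (dy_eps[idx] - dy[idx]) / eps          # = -1/tau
        x_inf = y[idx] - dy[idx] / slope
        y2[idx] = min(max(x_inf, 0.0), 1.0)
        dy2 = derivatives(CellState.from_vector(y2), params)
        assert abs(dy2[idx]) < 1e-6 * max(1.0, abs(dy[idx]))


def test_invalid_state_raises(params):
    st = dataclasses.replace(resting_state(), V=float("nan"))
    with pytest.raises(ValueError):
        compute_currents(st, params)
    st = dataclasses.replace(resting_state(), m=1.5)
    with pytest.raises(ValueError):
        derivatives(st, params)
    st = dataclasses.replace(resting_state(), Ca_i=-1e-5)
    with pytest.raises(ValueError):
        compute_currents(st, params)


def test_zero_amplitude_gives_no_upstroke(params):
    prot = StimulusProtocol(amplitude=0.0, n_beats=2)
    trace = run_paced(params, prot)
    assert np.all(np.abs(trace.vm - trace.vm[0]) < 1.0)


def test_trajectory_respects_state_bounds(params, standard_trace_fixture):
    trace = standard_trace_fixture
    final = trace.final_state
    final.validate()   # gates in [0,1], concentrations positive
    assert np.all(trace.vm > -120) and np.all(trace.vm < 60)


def test_scale_one_reproduces_standard_bit_identically(params,
                                                       fixture_protocol):
    base = run_paced(params, fixture_protocol)
    scaled = run_paced(params.scaled(3, 1.0), fixture_protocol)
    assert np.array_equal(base.vm, scaled.vm)


def test_reduced_gcal_shortens_apd(params, fixture_protocol):
    # oracle: the simulation itself at the two settings
    base = run_paced(params, fixture_protocol)
    half = run_paced(params.scaled(5, 0.5), fixture_protocol)
    assert measure_apd(half) < measure_apd(base)


def test_solver_convergence_under_step_refinement(params):
    prot = StimulusProtocol(n_beats=10)
    apd_coarse = measure_apd(run_paced(params, prot, dt=0.02))
    apd_fine = measure_apd(run_paced(params, prot, dt=0.002))
    assert abs(apd_coarse - apd_fine) < 0.5


def test_rush_larsen_matches_adaptive_solver_one_beat(params):
    prot = StimulusProtocol(n_beats=1)
    rl = run_paced(params, prot, method="rush_larsen")
    ad = run_paced(params, prot, method="lsoda", rtol=1e-8, atol=1e-8)
    assert np.max(np.abs(rl.vm - ad.vm)) < 1.0


def test_sample_interval_must_divide_cycle(params):
    with pytest.raises(ValueError):
        run_paced(params, StimulusProtocol(n_beats=1), sample_interval=3.0)


def test_protocol_invariants():
    with pytest.raises(ValueError):
        StimulusProtocol(duration=0.0)
    with pytest.raises(ValueError):
        StimulusProtocol(cycle_length=0.5, duration=1.0)
    with pytest.raises(ValueError):
        StimulusProtocol(n_beats=0)


def test_parameter_invariants():
    with pytest.raises(ValueError):
        ModelParameters(GKs=0.0)
    with pytest.raises(ValueError):
        ModelParameters().scaled(0, -1.0)
    with pytest.raises(IndexError):
        ModelParameters().scaled(10, 0.5)
    np.testing.assert_allclose(
        ModelParameters().conductances(),
        [0.392, 0.153, 5.405, 14.838, 0.00029, 0.0000398, 0.000592,
         0.073, 0.1238, 0.0146])


def test_load_config_yaml_and_json(tmp_path):
    from apdiff.cell_model import load_config

    yml = tmp_path / "cfg.yaml"
    yml.write_text(
        "conductances:\n  GKs: 0.5\n  GNa: 10.0\n"
        "protocol:\n  amplitude: -52.0\n  n_beats: 3\n")
    params, protocol = load_config(yml)
    assert params.GKs == 0.5 and params.GNa == 10.0
    assert params.GKr == 0.153           # untouched defaults
    assert protocol.amplitude == -52.0 and protocol.n_beats == 3

    js = tmp_path / "cfg.json"
    js.write_text('{"conductances": {"GpK": 0.02}}')
    params2, protocol2 = load_config(js)
    assert params2.GpK == 0.02
    assert protocol2.n_beats == 10

    bad = tmp_path / "bad.json"
    bad.write_text('{"conductances": {"GFoo": 1.0}}')
    with pytest.raises(ValueError):
        load_config(bad)
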