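"""Discretization, delay lines, scenario engine, metrics."""

import dataclasses
import math

import numpy as np
import pytest

from oxyloop.config import load_config, save_config
from oxyloop.gas_exchange import gas_exchange_tf
from oxyloop.plant import RationalTransferFunction, cylinder_tf
from oxyloop.simulate import (
    DelayLine,
    PerformanceMetrics,
    Scenario,
    SimulationResult,
    compute_metrics,
    discretize,
    run_scenario,
    scenario_library,
)


def _step_response(blk, n):
    return np.array([blk.step(1.0) for _ in range(n)])


def test_discretize_reaches_dc_gain():
    blk = discretize(RationalTransferFunction((1.0,), (1.0, 1.0)), 1e-3)
    y = _step_response(blk, 10_000)
    assert y[-1] == pytest.approx(1.0, abs=1e-3)


def test_discretize_first_order_closed_form():
    # output sample k is y(k*dt), so y at t=tau sits at index tau/dt
    tau = 0.3
    blk = discretize(cylinder_tf(tau), 1e-3)
    y = _step_response(blk, int(tau / 1e-3) + 1)
    assert y[-1] == pytest.approx(1 - math.exp(-1), abs=1e-6)


def test_discretize_gas_block_settles_at_constant_ratio():
    blk = discretize(gas_exchange_tf(), 1e-3)
    y = _step_response(blk, 80_000)
    assert y[-1] == pytest.approx(62.0 / 67.0, abs=1e-3)


def test_discretize_rejects_bad_dt():
    with pytest.raises(ValueError):
        discretize(cylinder_tf(0.5), 0.0)


def test_delay_line_identity_and_shift():
    dt = 1e-3
    assert DelayLine(0.0, dt).push(7.0) == 7.0
    d = DelayLine(0.30, dt)
    out = [d.push(1.0 if k == 0 else 0.0) for k in range(400)]
    assert out.index(1.0) == 300


def test_delay_composition_is_additive():
    dt = 1e-3
    d1, d2 = DelayLine(0.12, dt), DelayLine(0.23, dt)
    d12 = DelayLine(0.35, dt)
    sig = np.sin(np.arange(600) * 0.01)
    a = [d2.push(d1.push(x)) for x in sig]
    b = [d12.push(x) for x in sig]
    assert a == pytest.approx(b)


def test_delay_rounds_to_nearest_sample():
    d = DelayLine(0.0014, 1e-3)
    assert d.steps == 1
    assert d.realized == pytest.approx(0.001)


def test_open_loop_settles_below_commanded_level(library):
    """Without control the unity-DC plant settles at setpoint x DC gain — the
    commanded saturation is never reached."""
    res = run_scenario(library["open_loop_step"])
    assert res.y[-1] == pytest.approx(95.0 * 62.0 / 67.0, abs=0.1)
    assert res.y.max() < 95.0


def test_metrics_perfect_tracking_is_all_zero():
    t = np.arange(0, 10, 1e-2)
    r = np.full_like(t, 95.0)
    zeros = np.zeros_like(t)
    res = SimulationResult(t=t, r=r, r_mod=r, u=r, y=r.copy(), ym=r, e=zeros,
                           theta=zeros, m=zeros)
    m = compute_metrics(res)
    assert m.overshoot_pct == 0.0
    assert m.settling_time_s == 0.0
    assert m.iae == 0.0
    assert m.steady_state_error == 0.0


def test_metrics_first_order_closed_forms():
    """y = r(1 - exp(-t/tau)): settling = tau*ln(1/band), rise = tau*ln 9."""
    tau, band = 2.0, 0.02
    t = np.arange(0, 30, 1e-3)
    r = np.full_like(t, 90.0)
    y = r * (1 - np.exp(-t / tau))
    zeros = np.zeros_like(t)
    res = SimulationResult(t=t, r=r, r_mod=r, u=r, y=y, ym=r, e=zeros,
                           theta=zeros, m=zeros)
    m = compute_metrics(res, band=band)
    assert m.overshoot_pct == 0.0
    assert m.settling_time_s == pytest.approx(tau * math.log(1 / band), abs=5e-3)
    assert m.rise_time_s == pytest.approx(tau * math.log(9), abs=5e-3)


def test_metrics_flags_unsettled_horizon():
    t = np.arange(0, 5, 1e-2)
    r = np.full_like(t, 90.0)
    y = np.full_like(t, 50.0)
    zeros = np.zeros_like(t)
    res = SimulationResult(t=t, r=r, r_mod=r, u=r, y=y, ym=r, e=zeros,
                           theta=zeros, m=zeros)
    assert math.isnan(compute_metrics(res).settling_time_s)


def test_library_contents(library):
    assert "tau_sweep_050" in library
    assert library["tau_sweep_050"].cylinder_tau == 0.5
    assert {f"gas_variant_model{i}" for i in (1, 2, 3)} <= set(library)
    drops = library["load_event"].setpoint
    assert drops == ((0.0, 95.0), (40.0, 80.0), (60.0, 95.0))


def test_library_yaml_round_trip(tmp_path, library):
    for name, sc in library.items():
        p = tmp_path / f"{name}.yaml"
        save_config(sc, p)
        assert load_config(p).to_dict() == sc.to_dict()


def test_engine_is_deterministic():
    sc = Scenario(name="short", duration=3.0)
    a = run_scenario(sc)
    b = run_scenario(sc)
    assert np.array_equal(a.y, b.y) and np.array_equal(a.theta, b.theta)


def test_noise_is_seed_reproducible():
    sc = Scenario(name="noisy", duration=3.0, noise_std=0.5, noise_seed=7)
    a, b = run_scenario(sc), run_scenario(sc)
    assert np.array_equal(a.y, b.y)
    c = run_scenario(dataclasses.replace(sc, noise_seed=8))
    assert not np.array_equal(a.y, c.y)


def test_noise_requires_seed():
    with pytest.raises(ValueError):
        Scenario(name="bad", duration=3.0, noise_std=0.5)


def test_scenario_validation():
    with pytest.raises(ValueError):
        Scenario(name="bad", duration=3.0, cylinder_tau=-1.0)
    with pytest.raises(ValueError):
        Scenario(name="bad", duration=3.0, setpoint=((1.0, 95.0),))
    with pytest.raises(ValueError):
        Scenario(name="bad", duration=3.0, setpoint=((0.0, 120.0),))
    with pytest.raises(ValueError):
        Scenario(name="bad", duration=3.0, gas_model="model9")
    with pytest.raises(ValueError):
        Scenario(name="bad", duration=3.0, controller={"type": "sfpimrac", "zeta": 1})


def test_step_size_convergence():
    """Halving dt changes the final-5-s mean by <0.1% (fixed-step adequacy)."""
    sc = Scenario(name="conv", duration=30.0)
    means = []
    for dt in (1e-3, 5e-4):
        res = run_scenario(dataclasses.replace(sc, dt=dt))
        means.append(np.mean(res.y[res.t >= 25.0]))
    assert abs(means[1] - means[0]) / means[0] < 1e-3


def test_cascaded_unity_blocks_settle_at_composite_dc_gain():
    """Constant supply drive u through the full chain settles at u*62/67,
    matching the frequency-domain DC prediction."""
    sc = Scenario(name="dc", duration=40.0, controller={"type": "none"},
                  setpoint=((0.0, 50.0),))
    res = run_scenario(sc)
    assert res.y[-1] == pytest.approx(50.0 * 62.0 / 67.0, abs=0.05)


def test_result_csv_round_trip(tmp_path):
    res = run_scenario(Scenario(name="short", duration=2.0))
    p = tmp_path / "run.csv"
    res.to_csv(p)
    header = p.read_text().splitlines()[0]
    assert header == "t,r,r_mod,u,y,ym,e,theta,m"
    back = SimulationResult.from_csv(p)
    assert back.y == pytest.approx(res.y)
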