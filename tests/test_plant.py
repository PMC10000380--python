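"""Transfer-function blocks: coefficients, stability, margins."""

import math

import numpy as np
import pytest

from oxyloop.gas_exchange import gas_exchange_tf, patient_model
from oxyloop.plant import (
    CANONICAL_SEGMENTS,
    RationalTransferFunction,
    airway_cascade,
    cylinder_tf,
    healthy_alveoli_tf,
    infected_alveoli_tf,
    segment_tf,
    segments_from_table,
    stability_margins,
)
from oxyloop.simulate import discretize


def test_cylinder_tf_coefficients():
    tf = cylinder_tf(0.5)
    assert tf.num == (1.0,)
    assert tf.den == (0.5, 1.0)
    assert tf.dc_gain == 1.0


@pytest.mark.parametrize("tau", [0.0, -1.0])
def test_cylinder_rejects_nonpositive_tau(tau):
    with pytest.raises(ValueError):
        cylinder_tf(tau)


def test_cylinder_step_response_closed_form():
    tau = 0.5
    blk = discretize(cylinder_tf(tau), 1e-3)
    trace = [blk.step(1.0) for _ in range(10_000)]
    assert trace[-1] == pytest.approx(1.0, abs=1e-3)
    # output sample k is y(k*dt): the value at t=tau sits at index tau/dt
    assert trace[int(tau / 1e-3)] == pytest.approx(1 - math.exp(-1), abs=1e-6)


@pytest.mark.parametrize(
    "label, lc, rc",
    [
        ("nasal", 2.7e-3, 2.165),
        ("trachea", 3.7e-4, 5.4e-3),
        ("bronchi", 1.44e-5, 4.02e-4),
        ("alveoli", 6.72e-8, 5.71e-4),
    ],
)
def test_segment_coefficients_match_canonical_equations(label, lc, rc):
    tf = segment_tf(CANONICAL_SEGMENTS[label])
    assert tf.den == (lc, rc, 1.0)
    assert tf.dc_gain == 1.0


def test_infected_alveoli_coefficients_and_stiffening_ratio():
    tf = infected_alveoli_tf()
    assert tf.den == (1.0e-10, 1.15e-6, 1.0)
    assert tf.dc_gain == 1.0
    ratio = healthy_alveoli_tf().den[0] / tf.den[0]
    assert ratio == pytest.approx(672.0, rel=1e-9)


def test_cascade_structure():
    inf = airway_cascade("infected")
    assert inf.order == 8
    assert inf.dc_gain == pytest.approx(1.0, rel=1e-12)
    # healthy and infected cascades differ only in the alveolar factor
    conducting = (
        segment_tf(CANONICAL_SEGMENTS["nasal"])
        * segment_tf(CANONICAL_SEGMENTS["trachea"])
        * segment_tf(CANONICAL_SEGMENTS["bronchi"])
    )
    assert inf.den == (conducting * infected_alveoli_tf()).den
    assert airway_cascade("healthy").den == (conducting * healthy_alveoli_tf()).den


def test_cascade_rejects_unknown_condition():
    with pytest.raises(ValueError):
        airway_cascade("mild")


def test_open_loop_gain_cannot_reach_raised_setpoint():
    """A unity-DC plant driven open loop settles at the drive level, so a
    commanded level above the open-loop steady state is unreachable."""
    tp = patient_model(airway_cascade("infected"))
    assert tp.dc_gain * 95.0 < 95.0


@pytest.mark.parametrize("tf", [
    segment_tf(CANONICAL_SEGMENTS["nasal"]),
    infected_alveoli_tf(),
    airway_cascade("healthy"),
    airway_cascade("infected"),
    patient_model(airway_cascade("infected")),
])
def test_blocks_are_bibo_stable(tf):
    assert tf.is_stable()


def test_table_reconstruction_matches_equation_coefficients():
    """The RC/LC products tabulated for the four sections reproduce the
    canonical equation coefficients within 0.5% (the nasal s-coefficient is
    printed 0.4% apart between the two sources)."""
    table = segments_from_table()
    for label, spec in CANONICAL_SEGMENTS.items():
        assert table[label].RC == pytest.approx(spec.RC, rel=5e-3)
        assert table[label].LC == pytest.approx(spec.LC, rel=5e-3)


def test_first_order_lag_has_infinite_margins():
    mg = stability_margins(RationalTransferFunction((1.0,), (1.0, 1.0)))
    assert mg.gain_margin_db == math.inf and mg.no_phase_crossover
    assert mg.phase_margin_deg > 0


def test_integrator_with_quarter_period_delay_is_marginal():
    """1/s with dead time pi/2 crosses unity gain at 1 rad/s where the phase
    is exactly -180 deg: zero phase margin."""
    mg = stability_margins(
        RationalTransferFunction((1.0,), (1.0, 0.0), dead_time=math.pi / 2)
    )
    assert mg.w_gain_crossover == pytest.approx(1.0, rel=1e-9)
    assert mg.phase_margin_deg == pytest.approx(0.0, abs=1e-6)


def test_patient_model_margins_positive():
    mg = stability_margins(patient_model(airway_cascade("infected")))
    assert mg.gain_margin_db > 0
    assert mg.phase_margin_deg > 0


def test_margins_reject_improper_tf():
    with pytest.raises(ValueError):
        RationalTransferFunction((1.0, 0.0), (1.0,))


def test_multiplication_convolves_and_adds_dead_time():
    a = RationalTransferFunction((1.0,), (1.0, 1.0), dead_time=0.2)
    b = RationalTransferFunction((2.0,), (1.0, 2.0), dead_time=0.3)
    c = a * b
    assert c.den == (1.0, 3.0, 2.0)
    assert c.num == (2.0,)
    assert c.dead_time == pytest.approx(0.5)


def test_json_round_trip(tmp_path):
    tf = patient_model(airway_cascade("infected"), intermediate_delay=0.75)
    p = tmp_path / "model.json"
    tf.to_json(p)
    back = RationalTransferFunction.from_json(p)
    assert back == tf


def test_frequency_response_delay_is_pure_phase():
    tf = RationalTransferFunction((1.0,), (1.0, 1.0))
    tfd = tf.with_dead_time(0.7)
    w = np.logspace(-2, 2, 50)
    assert np.allclose(np.abs(tf.freq_response(w)), np.abs(tfd.freq_response(w)))
    assert np.allclose(
        np.angle(tfd.freq_response(w) / tf.freq_response(w)),
        np.angle(np.exp(-1j * w * 0.7)),
    )
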