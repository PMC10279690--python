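"""Dual-report likelihood: symmetry, monotonicity, nesting, and structure."""

import math

import numpy as np
import pytest

from hgfbehav.hgf import HgfParams, filter_inputs, schedule_inputs
from hgfbehav.respmodel import (
    MODEL_NAMES,
    ResponseModelConfig,
    ResponseParams,
    log_likelihood,
    perception_probability,
    prediction_probability,
)
from hgfbehav.task import TrialResponses, generate_run, simulate_agent


def _ambiguous_trial():
    run = generate_run(3)
    return next(t for t in run.trials if t.rotation == "none")


def _unambiguous_trial(direction="CW"):
    run = generate_run(3)
    return next(t for t in run.trials if t.rotation == direction)


def test_model_space_enumerates_eight_variants():
    assert len(MODEL_NAMES) == 8
    seen = set()
    for name in MODEL_NAMES:
        cfg = ResponseModelConfig.from_name(name)
        assert cfg.name == name
        seen.add((cfg.use_associative, cfg.use_priming, cfg.use_sensory_memory))
    assert len(seen) == 8
    with pytest.raises(ValueError):
        ResponseModelConfig.from_name("X")


def test_null_model_is_indifferent_on_ambiguous_trials():
    cfg = ResponseModelConfig.from_name("0")
    pp = perception_probability(_ambiguous_trial(), mu_a=0.9, config=cfg,
                                params=ResponseParams())
    assert pp.p_cw == pytest.approx(0.5)
    assert pp.P_theta1 == pytest.approx(0.5)


def test_stimulus_evidence_dominates_unambiguous_trials():
    cfg = ResponseModelConfig.from_name("0")
    pp_cw = perception_probability(_unambiguous_trial("CW"), 0.5, cfg,
                                   ResponseParams())
    pp_ccw = perception_probability(_unambiguous_trial("CCW"), 0.5, cfg,
                                    ResponseParams())
    assert pp_cw.p_cw == pytest.approx(1 - 1e-4, abs=1e-6)
    assert pp_ccw.p_cw == pytest.approx(1e-4, abs=1e-6)


def test_associative_bias_is_monotone_in_pi_a():
    tr = _ambiguous_trial()
    cfg = ResponseModelConfig.from_name("A")
    grid = np.linspace(0.0, 4.0, 15)
    up = [perception_probability(tr, 0.8, cfg, ResponseParams(pi_a=k)).p_cw
          for k in grid]
    down = [perception_probability(tr, 0.2, cfg, ResponseParams(pi_a=k)).p_cw
            for k in grid]
    assert np.all(np.diff(up) > 0)
    assert np.all(np.diff(down) < 0)
    assert up[0] == pytest.approx(0.5)


def test_priming_and_sensory_memory_history_terms():
    tr = _ambiguous_trial()
    p = ResponseParams(priming_weight=1.2, sensory_memory_weight=0.8)
    cfg_p = ResponseModelConfig.from_name("P")
    # empty history contributes no bias
    assert perception_probability(tr, 0.5, cfg_p, p).p_cw == pytest.approx(0.5)
    assert perception_probability(tr, 0.5, cfg_p, p,
                                  prev_percept="CW").p_cw > 0.5
    assert perception_probability(tr, 0.5, cfg_p, p,
                                  prev_percept="CCW").p_cw < 0.5
    cfg_s = ResponseModelConfig.from_name("S")
    assert perception_probability(tr, 0.5, cfg_s, p,
                                  prev_ambiguous_percept="CW").p_cw > 0.5
    # sensory memory acts on ambiguous trials only
    tru = _unambiguous_trial("CW")
    a = perception_probability(tru, 0.5, cfg_s, p, prev_ambiguous_percept="CW")
    b = perception_probability(tru, 0.5, cfg_s, p, prev_ambiguous_percept="CCW")
    assert a.p_cw == pytest.approx(b.p_cw)


def test_percept_probability_normalized_for_random_parameters(rng):
    trials = [_ambiguous_trial(), _unambiguous_trial("CW"),
              _unambiguous_trial("CCW")]
    for _ in range(500):
        cfg = ResponseModelConfig.from_name(
            MODEL_NAMES[rng.integers(len(MODEL_NAMES))])
        p = ResponseParams(
            pi_a=float(np.exp(rng.normal(0, 1))),
            priming_weight=float(rng.normal(0, 1)),
            sensory_memory_weight=float(rng.normal(0, 1)),
            decision_noise=float(np.exp(rng.normal(-2, 1))),
        )
        tr = trials[rng.integers(3)]
        pp = perception_probability(
            tr, float(rng.uniform(0.01, 0.99)), cfg, p,
            prev_percept=["CW", "CCW", None][rng.integers(3)],
            prev_ambiguous_percept=["CW", "CCW", None][rng.integers(3)])
        assert 0.0 < pp.p_cw < 1.0
        for y, rep in ((1.0, "CW"), (0.0, "CCW")):
            dq = pp.delta_q(rep)
            assert -1.0 <= dq <= 1.0
            assert dq == pytest.approx(pp.P_theta1 - y)


def test_prediction_probability_properties():
    p = ResponseParams(decision_noise=0.5)
    assert prediction_probability(0.5, p) == pytest.approx(0.5)
    # noise-dominated limit
    assert prediction_probability(0.9, ResponseParams(decision_noise=1e6)) == \
        pytest.approx(0.5, abs=1e-4)
    assert prediction_probability(0.9, p) > prediction_probability(0.6, p)
    grid = np.linspace(0.05, 0.95, 19)
    vals = [prediction_probability(m, p) for m in grid]
    assert np.all(np.diff(vals) > 0)


def test_nesting_all_variants_collapse_at_zero_weights():
    run = generate_run(11)
    traj = filter_inputs(schedule_inputs(run), HgfParams())
    resp = simulate_agent(run, HgfParams(), ResponseParams(pi_a=1.0),
                          ResponseModelConfig.from_name("A"), seed=2)
    p0 = ResponseParams(pi_a=0.0, priming_weight=0.0,
                        sensory_memory_weight=0.0, decision_noise=0.2)
    lls = [log_likelihood(resp, run, traj,
                          ResponseModelConfig.from_name(m), p0)
           for m in MODEL_NAMES]
    assert np.allclose(lls, lls[0], atol=1e-12)


def test_all_missing_reports_give_zero_likelihood():
    run = generate_run(1)
    traj = filter_inputs(schedule_inputs(run), HgfParams())
    resp = TrialResponses(prediction=["missing"] * 72,
                          perception=["missing"] * 72)
    ll = log_likelihood(resp, run, traj, ResponseModelConfig.from_name("0"),
                        ResponseParams())
    assert ll == 0.0


def test_constructed_run_likelihood_structure():
    """Null-model agent reporting every unambiguous rotation correctly and
    CW on ambiguous trials, predictions missing: the perception likelihood
    decomposes into 63 near-certain unambiguous terms plus 9 fair-coin
    ambiguous terms."""
    run = generate_run(21)
    traj = filter_inputs(schedule_inputs(run), HgfParams())
    perception = [tr.rotation if tr.rotation != "none" else "CW"
                  for tr in run.trials]
    resp = TrialResponses(prediction=["missing"] * 72, perception=perception)
    ll = log_likelihood(resp, run, traj, ResponseModelConfig.from_name("0"),
                        ResponseParams())
    expected = 63 * math.log(1.0 - 1e-4) + 9 * math.log(0.5)
    assert ll == pytest.approx(expected, abs=1e-9)


def test_generating_model_attains_higher_likelihood_than_null():
    """Data simulated with associative learning is better explained by the
    associative variant than by the null model, on average over runs."""
    cfg_a = ResponseModelConfig.from_name("A")
    cfg_0 = ResponseModelConfig.from_name("0")
    gen = ResponseParams(pi_a=1.4, decision_noise=0.1)
    hgf = HgfParams(omega2=-0.72, omega3=-6.23)
    diffs = []
    for seed in range(50):
        run = generate_run(seed + 300)
        traj = filter_inputs(schedule_inputs(run), hgf)
        resp = simulate_agent(run, hgf, gen, cfg_a, seed=seed)
        diffs.append(
            log_likelihood(resp, run, traj, cfg_a, gen)
            - log_likelihood(resp, run, traj, cfg_0, gen))
    assert np.mean(diffs) > 0


def test_misaligned_responses_rejected():
    run = generate_run(1)
    traj = filter_inputs(schedule_inputs(run), HgfParams())
    resp = TrialResponses(prediction=["CW"] * 10, perception=["CW"] * 10)
    with pytest.raises(ValueError):
        log_likelihood(resp, run, traj, ResponseModelConfig.from_name("0"),
                       ResponseParams())
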