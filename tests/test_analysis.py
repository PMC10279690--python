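"""Behavioral scoring, statistics, FDR, modulator export, recovery report."""

import math

import numpy as np
import pandas as pd
import pytest

from hgfbehav import analysis
from hgfbehav.analysis import (
    MODULATOR_COLUMNS,
    correlate_with_fdr,
    export_modulators,
    one_sample_test,
    rescale_confidence,
    score_behavior,
    two_sample_test,
)
from hgfbehav.hgf import HgfParams, filter_inputs, schedule_inputs
from hgfbehav.respmodel import ResponseModelConfig, ResponseParams
from hgfbehav.task import TrialResponses, generate_run, generate_session

from .oracles.bh_fdr import bh_adjust


def _oracle_agent_responses(schedule):
    """Deterministic contingency-following agent (predicts and perceives the
    contingency-implied rotation; reports the true rotation when shown)."""
    preds, percs = [], []
    for tr in schedule.trials:
        implied = tr.contingency_implied_rotation()
        preds.append(implied)
        percs.append(implied if tr.rotation == "none" else tr.rotation)
    return TrialResponses(prediction=preds, perception=percs)


def test_oracle_agent_saturates_bias_score():
    sched = generate_session(9)
    resp = _oracle_agent_responses(sched)
    s = score_behavior(resp, sched)
    assert s.prop_ambiguous_congruent == 1.0
    assert s.prop_correct_perception_unambiguous == 1.0
    # unambiguous predictions match the presented rotation only on expected
    # trials: 54/63 of unambiguous + all 45 ambiguous scored vs contingency
    assert s.prop_correct_prediction == pytest.approx((270 + 45) / 360)
    s2 = score_behavior(resp, sched, convention="contingency")
    assert s2.prop_correct_prediction == 1.0


def test_uniform_responder_scores_at_chance():
    rng = np.random.default_rng(17)
    ok = 0.0
    total = 0
    congr = 0.0
    n_amb = 0
    for seed in range(30):
        sched = generate_session(seed)
        resp = TrialResponses(
            prediction=[("CW" if rng.random() < 0.5 else "CCW")
                        for _ in range(360)],
            perception=[("CW" if rng.random() < 0.5 else "CCW")
                        for _ in range(360)],
        )
        s = score_behavior(resp, sched)
        ok += s.prop_correct_prediction * 360
        total += 360
        congr += s.prop_ambiguous_congruent * s.n_ambiguous
        n_amb += s.n_ambiguous
    for frac, n in ((ok / total, total), (congr / n_amb, n_amb)):
        assert abs(frac - 0.5) < 3 * 0.5 / math.sqrt(n)


def test_no_ambiguous_trials_yields_missing_congruency():
    run = generate_run(2)
    keep = [i for i, tr in enumerate(run.trials) if tr.rotation != "none"]
    from hgfbehav.task import TaskSchedule
    sub = TaskSchedule(trials=[run.trials[i] for i in keep], run_id=1)
    resp = TrialResponses(prediction=["CW"] * len(keep),
                          perception=["CW"] * len(keep))
    assert score_behavior(resp, sub).prop_ambiguous_congruent is None


def test_confidence_rescaling_endpoints_and_interpolation():
    assert rescale_confidence(1) == 100.0
    assert rescale_confidence(4) == 0.0
    assert rescale_confidence(2) == pytest.approx(66.67, abs=0.01)
    assert rescale_confidence(3) == pytest.approx(33.33, abs=0.01)
    with pytest.raises(ValueError):
        rescale_confidence(0)
    with pytest.raises(ValueError):
        rescale_confidence(5)


def test_one_sample_t_and_effect_size():
    x = [0.5] * 10
    r = one_sample_test(x, 0.5)
    assert r["t"] == 0.0 and r["p"] == 1.0
    # sample constructed to the reported group summary: mean .76, SD .09, n 26
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 26)
    x = (x - x.mean()) / x.std(ddof=1) * 0.09 + 0.76
    r = one_sample_test(x, 0.5)
    assert r["t"] == pytest.approx(0.26 * math.sqrt(26) / 0.09, abs=1e-6)
    assert r["t"] == pytest.approx(14.7, abs=0.05)
    assert r["d"] == pytest.approx(0.26 / 0.09, abs=1e-6)


def test_two_sample_t_null_case():
    g = list(np.arange(10) / 10)
    r = two_sample_test(g, g)
    assert r["t"] == pytest.approx(0.0, abs=1e-12)
    assert r["p"] == pytest.approx(1.0)
    assert r["d"] == pytest.approx(0.0, abs=1e-12)


def test_correlation_identities_and_bh_oracle(rng):
    x = rng.normal(0, 1, 20)
    out = correlate_with_fdr({"self": (x, x)})
    assert out.loc[0, "r"] == pytest.approx(1.0)
    assert out.loc[0, "p_fdr"] == out.loc[0, "p"]  # BH identity at m = 1

    # random families: adjusted p-values match the literal step-up oracle
    for _ in range(20):
        m = int(rng.integers(2, 12))
        pairs = {}
        for i in range(m):
            x = rng.normal(0, 1, 15)
            y = 0.3 * x + rng.normal(0, 1, 15)
            pairs[f"t{i}"] = (x, y)
        out = correlate_with_fdr(pairs)
        oracle = bh_adjust(list(out["p"]))
        assert np.allclose(out["p_fdr"], oracle, atol=1e-12)


def test_constant_input_reports_missing_correlation(rng):
    x = np.ones(10)
    y = rng.normal(0, 1, 10)
    out = correlate_with_fdr({"const": (x, y), "ok": (y, y)})
    assert math.isnan(out.loc[0, "r"])
    assert out.loc[1, "p_fdr"] == out.loc[1, "p"]


def test_modulator_table_columns_and_values():
    run = generate_run(14)
    hgf = HgfParams()
    traj = filter_inputs(schedule_inputs(run), hgf)
    resp = _oracle_agent_responses(run)
    cfg = ResponseModelConfig.from_name("A")
    params = ResponseParams(pi_a=1.0, decision_noise=0.1)
    table = export_modulators(traj, resp, run, cfg, params)
    assert len(table) == 72
    assert [c for c in table.columns if c in MODULATOR_COLUMNS] == \
        list(MODULATOR_COLUMNS)
    for c in ("pihat3", "pihat2", "abs_muhat3", "abs_muhat2",
              "abs_eps3", "abs_eps2", "abs_delta_q"):
        assert (table[c].dropna() >= 0).all()
    # |delta_q| = |P(theta1) - y| exactly
    y = np.array([1.0 if p == "CW" else 0.0 for p in resp.perception])
    assert np.allclose(table["abs_delta_q"], np.abs(table["P_theta1"] - y))


def test_modulator_delta_q_example_and_missing_percept():
    run = generate_run(14)
    traj = filter_inputs(schedule_inputs(run), HgfParams())
    resp = _oracle_agent_responses(run)
    i_amb = next(i for i, t in enumerate(run.trials) if t.rotation == "none")
    resp.perception[i_amb] = "missing"
    table = export_modulators(traj, resp, run,
                              ResponseModelConfig.from_name("0"),
                              ResponseParams())
    assert math.isnan(table.loc[i_amb, "abs_delta_q"])
    # null config, ambiguous trial: P(theta1) = 0.9 analog -> here 0.5,
    # so a CW report gives |delta_q| = 0.5
    other_amb = [i for i, t in enumerate(run.trials)
                 if t.rotation == "none" and i != i_amb]
    assert table.loc[other_amb[0], "abs_delta_q"] == pytest.approx(0.5)


def test_all_missing_inputs_produce_zero_prediction_errors():
    run = generate_run(14)
    traj = filter_inputs([np.nan] * 72, HgfParams())
    resp = _oracle_agent_responses(run)
    table = export_modulators(traj, resp, run,
                              ResponseModelConfig.from_name("0"),
                              ResponseParams())
    assert (table["abs_eps2"] == 0).all()
    assert (table["abs_eps3"] == 0).all()


def test_confidence_anova_detects_ambiguity_effect(rng):
    rows = []
    for s in range(1, 21):
        grp = "NT" if s <= 10 else "ASD"
        rows.append({"subject": s, "group": grp, "ambiguity": "ambiguous",
                     "certainty": rng.normal(60, 10)})
        rows.append({"subject": s, "group": grp, "ambiguity": "unambiguous",
                     "certainty": rng.normal(90, 10)})
    table = analysis.confidence_anova(pd.DataFrame(rows))
    p_amb = table.loc[table["Source"] == "ambiguity", "p_unc"].iloc[0]
    assert p_amb < 0.001


def test_zero_replicate_recovery_is_empty():
    rep = analysis.run_recovery(["A"], [1.0], n_subjects=0, seed=1)
    assert len(rep.parameters) == 0
    assert len(rep.confusion) == 0
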