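"""Behavioral scoring, group statistics, modulator export, and recovery.

Scoring conventions
-------------------
Prediction correctness is scored against the presented rotation on
unambiguous trials and against the contingency-implied rotation on
ambiguous trials (which present no rotation); ``convention='contingency'``
scores every trial against the contingency-implied rotation instead.
The ambiguous-trial congruency (prior-bias score) is the fraction of
ambiguous-trial percepts matching the rotation the current contingency
implies for the trial's tone.

Confidence ratings on the 1 (very sure) .. 4 (very unsure) scale are
rescaled to a 0..100% certainty scale: certainty = (4 - rating) * 100 / 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .respmodel import (
    MODEL_NAMES,
    ResponseModelConfig,
    ResponseParams,
    trial_probabilities,
)

__all__ = [
    "BehaviorSummary",
    "score_behavior",
    "rescale_confidence",
    "one_sample_test",
    "two_sample_test",
    "confidence_anova",
    "correlate_with_fdr",
    "export_modulators",
    "MODULATOR_COLUMNS",
    "run_recovery",
    "RecoveryReport",
]

MODULATOR_COLUMNS = (
    # tone-locked (pre-update, hatted, quantities of the trial)
    "pihat3", "abs_muhat3", "pihat2", "abs_muhat2", "mu_a",
    # rotation-locked (computed from the trial's outcome)
    "abs_eps3", "abs_eps2", "abs_delta_q", "P_theta1",
)


@dataclass
class BehaviorSummary:
    prop_correct_prediction: float
    prop_ambiguous_congruent: Optional[float]
    prop_correct_perception_unambiguous: Optional[float]
    n_trials: int
    n_ambiguous: int
    mean_certainty_ambiguous: Optional[float] = None
    mean_certainty_unambiguous: Optional[float] = None


def score_behavior(responses, schedule, convention: str = "mixed") -> BehaviorSummary:
    """Score one subject's session (or run)."""
    if convention not in ("mixed", "contingency"):
        raise ValueError("convention must be 'mixed' or 'contingency'")
    n = len(schedule.trials)
    if len(responses.prediction) != n:
        raise ValueError("responses not aligned with schedule")

    pred_ok, pred_n = 0, 0
    cong_ok, cong_n = 0, 0
    perc_ok, perc_n = 0, 0
    cert_amb: List[float] = []
    cert_unamb: List[float] = []
    for t, tr in enumerate(schedule.trials):
        implied = tr.contingency_implied_rotation()
        target = implied if (convention == "contingency"
                             or tr.rotation == "none") else tr.rotation
        pred = responses.prediction[t]
        if pred in ("CW", "CCW"):
            pred_n += 1
            pred_ok += pred == target
        perc = responses.perception[t]
        if tr.rotation == "none":
            if perc in ("CW", "CCW"):
                cong_n += 1
                cong_ok += perc == implied
        else:
            if perc in ("CW", "CCW"):
                perc_n += 1
                perc_ok += perc == tr.rotation
        if responses.confidence is not None:
            c = responses.confidence[t]
            if c is not None:
                cert = rescale_confidence(c)
                (cert_amb if tr.rotation == "none" else cert_unamb).append(cert)

    return BehaviorSummary(
        prop_correct_prediction=pred_ok / pred_n if pred_n else math.nan,
        prop_ambiguous_congruent=cong_ok / cong_n if cong_n else None,
        prop_correct_perception_unambiguous=perc_ok / perc_n if perc_n else None,
        n_trials=n,
        n_ambiguous=sum(tr.rotation == "none" for tr in schedule.trials),
        mean_certainty_ambiguous=float(np.mean(cert_amb)) if cert_amb else None,
        mean_certainty_unambiguous=float(np.mean(cert_unamb)) if cert_unamb else None,
    )


def rescale_confidence(rating):
    """Map a 1..4 confidence rating to 100..0% certainty."""
    r = np.asarray(rating, dtype=float)
    if np.any((r < 1) | (r > 4)):
        raise ValueError("confidence ratings must be in 1..4")
    out = (4.0 - r) * 100.0 / 3.0
    return float(out) if np.isscalar(rating) or out.ndim == 0 else out


def _cohen_d_one(x: np.ndarray, mu: float) -> float:
    sd = np.std(x, ddof=1)
    return math.nan if sd == 0 else float((np.mean(x) - mu) / sd)


def _cohen_d_two(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    pooled = math.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                       / (nx + ny - 2))
    return math.nan if pooled == 0 else float((np.mean(x) - np.mean(y)) / pooled)


def one_sample_test(x, mu: float = 0.5) -> Dict[str, float]:
    """Two-tailed one-sample t test against mu, with Cohen's d."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 observations")
    if np.std(x, ddof=1) == 0:
        # degenerate variance: t undefined unless mean == mu
        return {"t": 0.0 if np.mean(x) == mu else math.nan,
                "p": 1.0 if np.mean(x) == mu else math.nan,
                "df": len(x) - 1, "d": math.nan, "mean": float(np.mean(x))}
    t, p = sps.ttest_1samp(x, mu)
    return {"t": float(t), "p": float(p), "df": len(x) - 1,
            "d": _cohen_d_one(x, mu), "mean": float(np.mean(x))}


def two_sample_test(x, y) -> Dict[str, float]:
    """Two-tailed two-sample (pooled-variance) t test with Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        same = np.mean(x) == np.mean(y)
        return {"t": 0.0 if same else math.nan, "p": 1.0 if same else math.nan,
                "df": len(x) + len(y) - 2, "d": 0.0 if same else math.nan}
    t, p = sps.ttest_ind(x, y)
    return {"t": float(t), "p": float(p), "df": len(x) + len(y) - 2,
            "d": _cohen_d_two(x, y)}


def confidence_anova(certainty: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures ambiguity x group design on certainty scores.

    ``certainty`` columns: subject, group, ambiguity, certainty
    (two rows per subject: ambiguous / unambiguous).
    """
    import pingouin as pg
    return pg.mixed_anova(data=certainty, dv="certainty", within="ambiguity",
                          between="group", subject="subject")


def correlate_with_fdr(pairs: Mapping[str, tuple], alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlations with Benjamini-Hochberg control over the family.

    ``pairs`` maps test name -> (x, y).  Constant inputs yield an undefined
    correlation reported as NaN and excluded from the BH family.
    """
    names, rs, ps = [], [], []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3:
            raise ValueError(f"{name}: need >= 3 complete pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = math.nan, math.nan
        else:
            r, p = sps.pearsonr(x, y)
        names.append(name)
        rs.append(float(r))
        ps.append(float(p) if np.isfinite(r) else math.nan)
    ps_arr = np.asarray(ps)
    adj = np.full(len(ps_arr), math.nan)
    valid = np.isfinite(ps_arr)
    if valid.any():
        adj[valid] = multipletests(ps_arr[valid], alpha=alpha,
                                   method="fdr_bh")[1]
    return pd.DataFrame({"test": names, "r": rs, "p": ps, "p_fdr": adj,
                         "n": [len(pairs[n][0]) for n in names]})


def export_modulators(
    traj,
    responses,
    schedule,
    config: ResponseModelConfig,
    params: ResponseParams,
) -> pd.DataFrame:
    """Nine trial-wise parametric modulators for event-related GLM use.

    Tone-locked: pihat3, |muhat3|, pihat2, |muhat2|, mu_a (all pre-update
    quantities of the trial).  Rotation-locked: |eps3|, |eps2|, |delta_q|,
    P(theta1), computed from the trial's outcome.  delta_q is missing
    (NaN) where the percept report is missing.
    """
    n = len(schedule.trials)
    if len(traj) != n or len(responses.perception) != n:
        raise ValueError("trajectories/responses not aligned with schedule")
    probs = trial_probabilities(schedule, traj, config, params,
                                responses.perception)
    rows = []
    for t, tr in enumerate(schedule.trials):
        _, pp, mu_a = probs[t]
        perc = responses.perception[t]
        if perc in ("CW", "CCW"):
            dq = pp.delta_q(perc)
        else:
            dq = math.nan
        rows.append({
            "trial": tr.index,
            "tone": tr.tone,
            "trial_type": tr.trial_type,
            "pihat3": traj.pihat3[t],
            "abs_muhat3": abs(traj.muhat3[t]),
            "pihat2": traj.pihat2[t],
            "abs_muhat2": abs(traj.muhat2[t]),
            "mu_a": mu_a,
            "abs_eps3": abs(traj.eps3[t]),
            "abs_eps2": abs(traj.eps2[t]),
            "abs_delta_q": abs(dq),
            "P_theta1": pp.P_theta1,
        })
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    parameters: pd.DataFrame     # per replicate: true vs recovered values
    parameter_stats: pd.DataFrame  # per parameter: correlation, bias, rmse
    confusion: pd.DataFrame      # generating model x BMS winner counts
    bms_results: Dict[str, object]


def run_recovery(
    generating_models: Sequence[str],
    pi_a_grid: Sequence[float],
    n_subjects: int,
    seed: int,
    n_runs: int = 5,
    fit_models: Sequence[str] = MODEL_NAMES,
    inversion_opts=None,
    n_bms_samples: int = 100_000,
) -> RecoveryReport:
    """Parameter- and model-recovery study on synthetic cohorts.

    For each generating model, ``n_subjects`` agents are simulated (pi_a
    cycling over ``pi_a_grid`` for associative variants), all ``fit_models``
    are inverted per run, group BMS identifies the winning model, and
    generating vs recovered parameters are tabulated.  ``n_subjects = 0``
    returns an empty report.
    """
    from .inversion import InversionOptions, evidence_matrix, fit_subject
    from .bms import rfx_bms
    from .task import CohortSpec, simulate_cohort

    opts = inversion_opts or InversionOptions()
    ss = np.random.SeedSequence(seed)
    par_rows: List[dict] = []
    conf_rows: List[dict] = []
    bms_results: Dict[str, object] = {}

    for gi, gmodel in enumerate(generating_models):
        if n_subjects == 0:
            continue
        gseed = int(ss.generate_state(gi + 1)[-1]) & 0x7FFFFFFF
        cohort = []
        for si in range(n_subjects):
            pi_a = float(pi_a_grid[si % len(pi_a_grid)]) if pi_a_grid else 1.37
            spec = CohortSpec(model=gmodel, pi_a_mean=pi_a, pi_a_sd=0.0,
                              omega2_sd=0.0, omega3_sd=0.0)
            cohort.extend(simulate_cohort(1, seed=gseed + 7919 * si, spec=spec,
                                          n_runs=n_runs))
        all_fits = []
        for si, sub in enumerate(cohort):
            fits = fit_subject(sub["responses"], sub["schedule"],
                               models=fit_models, opts=opts, subject=si + 1)
            all_fits.append(fits)
            fr_g = [f for f in fits.get(gmodel, []) if f is not None]
            rec = {}
            for p in ("pi_a", "omega2", "omega3"):
                vals = [f.map_estimates[p] for f in fr_g if p in f.map_estimates]
                if vals:
                    rec[p] = float(np.mean(vals))
            par_rows.append({
                "generating_model": gmodel, "subject": si + 1,
                "true_pi_a": sub["resp_params"].pi_a,
                "recovered_pi_a": rec.get("pi_a", math.nan),
                "true_omega2": sub["hgf_params"].omega2,
                "recovered_omega2": rec.get("omega2", math.nan),
                "true_omega3": sub["hgf_params"].omega3,
                "recovered_omega3": rec.get("omega3", math.nan),
            })
        lme = evidence_matrix(all_fits, models=fit_models)
        bms = rfx_bms(lme, model_names=list(fit_models),
                      n_samples=n_bms_samples, seed=gseed)
        bms_results[gmodel] = bms
        winner = bms.model_names[int(np.argmax(
            bms.protected_exceedance_probability))]
        conf_rows.append({"generating_model": gmodel, "bms_winner": winner,
                          "pxp_winner": float(np.max(
                              bms.protected_exceedance_probability))})

    par = pd.DataFrame(par_rows)
    stats_rows = []
    if len(par):
        for p in ("pi_a", "omega2", "omega3"):
            t = par[f"true_{p}"].to_numpy()
            r = par[f"recovered_{p}"].to_numpy()
            ok = np.isfinite(t) & np.isfinite(r)
            if ok.sum() >= 3 and np.ptp(t[ok]) > 0 and np.ptp(r[ok]) > 0:
                corr = float(sps.pearsonr(t[ok], r[ok])[0])
            else:
                corr = math.nan
            stats_rows.append({
                "parameter": p,
                "correlation": corr,
                "bias": float(np.mean(r[ok] - t[ok])) if ok.any() else math.nan,
                "rmse": float(np.sqrt(np.mean((r[ok] - t[ok]) ** 2)))
                if ok.any() else math.nan,
            })
    confusion = pd.DataFrame(conf_rows)
    return RecoveryReport(
        parameters=par,
        parameter_stats=pd.DataFrame(stats_rows),
        confusion=confusion,
        bms_results=bms_results,
    )
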