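"""Response models: mapping beliefs to dual-report probabilities.

Each trial yields two reports: a *prediction* of the upcoming rotation
(driven by the contingency belief mu_a through a noisy decision rule) and a
*perception* report of the rotation itself.  The perception report is
modeled as arising from a posterior percept probability P(theta1) that
combines, additively in log-odds:

* stimulus evidence -- decisive for unambiguous trials (up to a small fixed
  report-error floor), null for ambiguous trials;
* associative learning (A): the contingency prediction mu_a, weighted by the
  precision pi_a;
* priming (P): the previous trial's percept, weighted by priming_weight;
* sensory memory (S): the previous *ambiguous* trial's percept, acting only
  on ambiguous trials, weighted by sensory_memory_weight.

The eight model variants {0, A, P, S, AP, AS, PS, APS} toggle these three
influences.  With all weights at zero every variant reduces to model 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hgf import Trajectories, clamp_probability, conditional_prediction

__all__ = [
    "MODEL_NAMES",
    "ResponseModelConfig",
    "ResponseParams",
    "PerceptProbability",
    "perception_probability",
    "prediction_probability",
    "log_likelihood",
    "trial_probabilities",
]

MODEL_NAMES = ("0", "A", "P", "S", "AP", "AS", "PS", "APS")

#: report-error probability on unambiguous trials (stimulus evidence floor)
REPORT_ERROR_FLOOR = 1e-4
_STIM_LOGODDS = float(np.log((1.0 - REPORT_ERROR_FLOOR) / REPORT_ERROR_FLOOR))


@dataclass(frozen=True)
class ResponseModelConfig:
    """Which perceptual influences are active."""

    use_associative: bool = False
    use_priming: bool = False
    use_sensory_memory: bool = False

    @classmethod
    def from_name(cls, name: str) -> "ResponseModelConfig":
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
        return cls(
            use_associative="A" in name,
            use_priming="P" in name,
            use_sensory_memory="S" in name,
        )

    @property
    def name(self) -> str:
        n = ("A" if self.use_associative else "") + \
            ("P" if self.use_priming else "") + \
            ("S" if self.use_sensory_memory else "")
        return n or "0"


@dataclass(frozen=True)
class ResponseParams:
    """Response-model parameters.

    pi_a            : precision (strength) of associative learning, >= 0
    priming_weight  : log-odds weight of the preceding percept
    sensory_memory_weight : log-odds weight of the preceding ambiguous percept
    decision_noise  : temperature of the prediction report; the report
                      probability is sigma(logit(mu_a)/decision_noise), so
                      noise -> 0 gives deterministic reports and
                      noise -> inf gives indifference.
    """

    pi_a: float = 0.0
    priming_weight: float = 0.0
    sensory_memory_weight: float = 0.0
    decision_noise: float = 0.1

    def validate(self) -> None:
        vals = [self.pi_a, self.priming_weight,
                self.sensory_memory_weight, self.decision_noise]
        if not np.isfinite(vals).all():
            raise ValueError("response parameters must be finite")
        if self.pi_a < 0:
            raise ValueError(f"pi_a must be non-negative, got {self.pi_a}")
        if self.decision_noise <= 0:
            raise ValueError("decision_noise must be positive")


@dataclass(frozen=True)
class PerceptProbability:
    p_cw: float        # probability of reporting CW
    P_theta1: float    # posterior probability of perceiving CW
    # delta_q = P_theta1 - y_perception is computed once the report is known

    def delta_q(self, percept: str) -> float:
        if percept not in ("CW", "CCW"):
            raise ValueError(f"percept must be CW or CCW, got {percept!r}")
        return self.P_theta1 - (1.0 if percept == "CW" else 0.0)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _percept_sign(percept: Optional[str]) -> float:
    """+1 for CW, -1 for CCW, 0 for missing/none."""
    if percept == "CW":
        return 1.0
    if percept == "CCW":
        return -1.0
    return 0.0


def perception_probability(
    trial,
    mu_a: float,
    config: ResponseModelConfig,
    params: ResponseParams,
    prev_percept: Optional[str] = None,
    prev_ambiguous_percept: Optional[str] = None,
) -> PerceptProbability:
    """Posterior percept probability P(theta1) and the CW report probability.

    ``prev_percept`` is the percept reported on the immediately preceding
    trial of the run (None on the first trial or after a missing report);
    ``prev_ambiguous_percept`` is the percept of the most recent earlier
    ambiguous trial.  Absent history contributes no bias.
    """
    params.validate()
    ambiguous = trial.rotation == "none"

    x = 0.0
    if not ambiguous:
        x += _STIM_LOGODDS if trial.rotation == "CW" else -_STIM_LOGODDS
    if config.use_associative:
        x += params.pi_a * _logit(clamp_probability(mu_a))
    if config.use_priming:
        x += params.priming_weight * _percept_sign(prev_percept)
    if config.use_sensory_memory and ambiguous:
        x += params.sensory_memory_weight * _percept_sign(prev_ambiguous_percept)

    p = clamp_probability(1.0 / (1.0 + np.exp(-x)) if x >= 0
                          else np.exp(x) / (1.0 + np.exp(x)))
    return PerceptProbability(p_cw=p, P_theta1=p)


def prediction_probability(mu_a: float, params: ResponseParams) -> float:
    """Probability of predicting CW given the contingency prediction mu_a."""
    params.validate()
    x = _logit(clamp_probability(mu_a)) / params.decision_noise
    p = 1.0 / (1.0 + np.exp(-x)) if x >= 0 else np.exp(x) / (1.0 + np.exp(x))
    return clamp_probability(p)


def trial_probabilities(
    schedule,
    traj: Trajectories,
    config: ResponseModelConfig,
    params: ResponseParams,
    percepts: Sequence[Optional[str]],
):
    """Per-trial (p_predict_cw, PerceptProbability) under a percept history.

    ``percepts`` supplies the percept reported on each trial (observed data
    during likelihood evaluation, sampled reports during simulation); entry t
    is only consulted for trials after t.
    """
    trials = schedule.trials
    if len(percepts) != len(trials):
        raise ValueError("percept history length must match schedule length")
    out = []
    prev_percept: Optional[str] = None
    prev_ambig: Optional[str] = None
    for t, tr in enumerate(trials):
        mu_a = conditional_prediction(traj.muhat2[t], tr.tone)
        p_pred = prediction_probability(mu_a, params)
        pp = perception_probability(
            tr, mu_a, config, params,
            prev_percept=prev_percept,
            prev_ambiguous_percept=prev_ambig,
        )
        out.append((p_pred, pp, mu_a))
        rep = percepts[t]
        prev_percept = rep if rep in ("CW", "CCW") else None
        if tr.rotation == "none" and rep in ("CW", "CCW"):
            prev_ambig = rep
    return out


def log_likelihood(
    responses,
    schedule,
    traj: Trajectories,
    config: ResponseModelConfig,
    params: ResponseParams,
) -> float:
    """Joint log-likelihood of the prediction and perception reports.

    Missing reports contribute zero.  The percept history driving priming
    and sensory memory is the observed perception sequence.
    """
    n = len(schedule.trials)
    if len(responses.prediction) != n or len(responses.perception) != n:
        raise ValueError(
            f"responses ({len(responses.prediction)}) not aligned with "
            f"schedule ({n})"
        )
    if len(traj) != n:
        raise ValueError("trajectories not aligned with schedule")

    probs = trial_probabilities(schedule, traj, config, params,
                                responses.perception)
    ll = 0.0
    for t in range(n):
        p_pred, pp, _ = probs[t]
        pred = responses.prediction[t]
        if pred == "CW":
            ll += np.log(p_pred)
        elif pred == "CCW":
            ll += np.log1p(-p_pred)
        perc = responses.perception[t]
        if perc == "CW":
            ll += np.log(pp.p_cw)
        elif perc == "CCW":
            ll += np.log1p(-pp.p_cw)
    return float(ll)
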