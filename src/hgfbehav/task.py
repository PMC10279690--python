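"""Task schedules and synthetic agents.

The task: on each trial a low (352 Hz) or high (576 Hz) tone precedes the
rotation of a pair of dots.  A hidden contingency links tone to rotation
(reference state c1: high -> CW, low -> CCW; c2 reversed) and holds with 75%
probability; it reverses every 16, 24 or 32 trials.  Each run of 72 trials
is built from 8-trial blocks containing exactly 6 expected, 1 unexpected and
1 ambiguous trial (ambiguous: the dots jump without rotating).  A session
comprises 5 runs (360 trials).

Synthetic agents sample their prediction and perception reports from the
same likelihood the inversion machinery evaluates, so that parameter- and
model-recovery studies close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .hgf import (
    HgfParams,
    ModelInstabilityError,
    conditional_prediction,
    filter_inputs,
    schedule_inputs,
)
from .respmodel import (
    ResponseModelConfig,
    ResponseParams,
    perception_probability,
    prediction_probability,
)

__all__ = [
    "TrialSpec",
    "TaskSchedule",
    "TrialResponses",
    "generate_run",
    "generate_session",
    "simulate_agent",
    "simulate_cohort",
    "CohortSpec",
]

TONES = ("low", "high")
BLOCK = 8
BLOCK_COMPOSITION = ("expected",) * 6 + ("unexpected",) + ("ambiguous",)
TONE_FREQ_HZ = {"low": 352, "high": 576}
MAIN_CONTINGENCY = 0.75  # implied by the 6/1/1 composition of unambiguous trials


@dataclass(frozen=True)
class TrialSpec:
    index: int                # 1-based within the run
    tone: str                 # "low" | "high"
    contingency: str          # hidden state "c1" | "c2"
    trial_type: str           # "expected" | "unexpected" | "ambiguous"
    rotation: str             # "CW" | "CCW" | "none"
    block_index: int          # 0-based 8-trial block id

    def contingency_implied_rotation(self) -> str:
        """Rotation the current contingency implies for this trial's tone."""
        cw_under_c1 = self.tone == "high"
        cw = cw_under_c1 if self.contingency == "c1" else not cw_under_c1
        return "CW" if cw else "CCW"


@dataclass
class TaskSchedule:
    trials: List[TrialSpec]
    run_id: int = 1
    session_id: int = 1
    seed: Optional[int] = None
    reversal_points: List[int] = field(default_factory=list)
    #: (run_id, start, stop) slices when the schedule concatenates runs
    run_slices: List[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def runs(self) -> List["TaskSchedule"]:
        """Split a session schedule into its per-run schedules."""
        if not self.run_slices:
            return [self]
        out = []
        for run_id, start, stop in self.run_slices:
            out.append(TaskSchedule(
                trials=self.trials[start:stop], run_id=run_id,
                session_id=self.session_id, seed=self.seed,
                reversal_points=[],
            ))
        return out


@dataclass
class TrialResponses:
    prediction: List[str]            # "CW" | "CCW" | "missing"
    perception: List[str]            # "CW" | "CCW" | "missing"
    confidence: Optional[List[Optional[int]]] = None  # 1..4, confidence sessions only

    def __len__(self) -> int:
        return len(self.prediction)

    def subset(self, start: int, stop: int) -> "TrialResponses":
        return TrialResponses(
            prediction=self.prediction[start:stop],
            perception=self.perception[start:stop],
            confidence=None if self.confidence is None
            else self.confidence[start:stop],
        )


def _validate_run_args(n_trials: int, reversal_lengths) -> tuple:
    lengths = tuple(sorted(set(int(x) for x in reversal_lengths)))
    if n_trials <= 0 or n_trials % BLOCK != 0:
        raise ValueError(f"n_trials must be a positive multiple of {BLOCK}, got {n_trials}")
    if not lengths:
        raise ValueError("reversal_lengths must be nonempty")
    for L in lengths:
        if L <= 0 or L % BLOCK != 0:
            raise ValueError(f"reversal lengths must be positive multiples of {BLOCK}, got {L}")
        if L > n_trials:
            raise ValueError(f"reversal length {L} exceeds n_trials {n_trials}")
    return lengths


def generate_run(
    seed: int,
    n_trials: int = 72,
    reversal_lengths: Sequence[int] = (16, 24, 32),
    run_id: int = 1,
    session_id: int = 1,
) -> TaskSchedule:
    """Generate one pseudo-randomized run.

    Deterministic given ``seed``.  The initial contingency is drawn
    uniformly; segment lengths between reversals are drawn uniformly from
    ``reversal_lengths`` subject to fitting inside the run, and trials after
    the last reversal keep the final contingency.  Trial types are shuffled
    within each 8-trial block (6 expected / 1 unexpected / 1 ambiguous);
    tones are drawn uniformly per trial.
    """
    lengths = _validate_run_args(n_trials, reversal_lengths)
    rng = np.random.default_rng(seed)

    contingency = "c1" if rng.integers(2) == 0 else "c2"
    # place reversals
    reversal_points: List[int] = []
    pos = 0
    while True:
        feasible = [L for L in lengths if pos + L < n_trials]
        if not feasible:
            break
        L = int(rng.choice(feasible))
        pos += L
        reversal_points.append(pos + 1)  # 1-based first trial of new regime

    trials: List[TrialSpec] = []
    flips = set(reversal_points)
    for b in range(n_trials // BLOCK):
        types = list(BLOCK_COMPOSITION)
        rng.shuffle(types)
        for j, ttype in enumerate(types):
            idx = b * BLOCK + j + 1
            if idx in flips:
                contingency = "c2" if contingency == "c1" else "c1"
            tone = TONES[rng.integers(2)]
            if ttype == "ambiguous":
                rotation = "none"
            else:
                cw_under_c1 = tone == "high"
                cw = cw_under_c1 if contingency == "c1" else not cw_under_c1
                if ttype == "unexpected":
                    cw = not cw
                rotation = "CW" if cw else "CCW"
            trials.append(TrialSpec(
                index=idx, tone=tone, contingency=contingency,
                trial_type=ttype, rotation=rotation, block_index=b,
            ))

    return TaskSchedule(
        trials=trials, run_id=run_id, session_id=session_id,
        seed=int(seed), reversal_points=reversal_points,
    )


def generate_session(
    seed: int,
    n_runs: int = 5,
    n_trials: int = 72,
    reversal_lengths: Sequence[int] = (16, 24, 32),
    session_id: int = 1,
) -> TaskSchedule:
    """Generate a session of ``n_runs`` runs with independent reversal placement."""
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_runs)]
    trials: List[TrialSpec] = []
    run_slices = []
    reversal_points: List[int] = []
    for r, rs in enumerate(run_seeds, start=1):
        run = generate_run(rs, n_trials=n_trials,
                           reversal_lengths=reversal_lengths,
                           run_id=r, session_id=session_id)
        start = len(trials)
        trials.extend(run.trials)
        run_slices.append((r, start, len(trials)))
        reversal_points.extend(start + p for p in run.reversal_points)
    return TaskSchedule(
        trials=trials, run_id=0, session_id=session_id, seed=int(seed),
        reversal_points=reversal_points, run_slices=run_slices,
    )


def simulate_agent(
    schedule: TaskSchedule,
    hgf_params: HgfParams,
    resp_params: ResponseParams,
    config: ResponseModelConfig,
    seed: int,
    lapse_rate: float = 0.0,
) -> TrialResponses:
    """Sample an agent's dual reports trial by trial.

    Reports are drawn from exactly the probabilities the inversion
    likelihood assigns (prediction from the noisy decision rule on mu_a,
    perception from P(theta1)), with the sampled percepts feeding the
    priming / sensory-memory history.  The contingency filter restarts at
    each run boundary, mirroring per-run inversion.  A positive
    ``lapse_rate`` replaces reports by "missing" independently per report.
    """
    if not 0.0 <= lapse_rate < 1.0:
        raise ValueError("lapse_rate must be in [0, 1)")
    hgf_params.validate()
    resp_params.validate()
    rng = np.random.default_rng(seed)

    predictions: List[str] = []
    percepts: List[str] = []
    for run in schedule.runs():
        traj = filter_inputs(schedule_inputs(run), hgf_params)
        prev_percept: Optional[str] = None
        prev_ambig: Optional[str] = None
        for t, tr in enumerate(run.trials):
            mu_a = conditional_prediction(traj.muhat2[t], tr.tone)
            p_pred = prediction_probability(mu_a, resp_params)
            pred = "CW" if rng.random() < p_pred else "CCW"
            pp = perception_probability(
                tr, mu_a, config, resp_params,
                prev_percept=prev_percept, prev_ambiguous_percept=prev_ambig,
            )
            perc = "CW" if rng.random() < pp.p_cw else "CCW"
            # lapses are applied to the *reports*, after history bookkeeping
            prev_percept = perc
            if tr.rotation == "none":
                prev_ambig = perc
            if lapse_rate > 0.0 and rng.random() < lapse_rate:
                pred = "missing"
            if lapse_rate > 0.0 and rng.random() < lapse_rate:
                perc = "missing"
            predictions.append(pred)
            percepts.append(perc)

    return TrialResponses(prediction=predictions, perception=percepts)


@dataclass(frozen=True)
class CohortSpec:
    """Between-subject parameter distribution for a simulated cohort.

    Defaults are the study conditions of the modeled experiment's
    neurotypical group: associative-learning model (A) agents with
    group-mean (SD) pi_a 1.37 (0.28), omega2 -0.72 (0.86), omega3
    -6.23 (0.09), and a sharp prediction decision rule.
    """

    model: str = "A"
    pi_a_mean: float = 1.37
    pi_a_sd: float = 0.28
    omega2_mean: float = -0.72
    omega2_sd: float = 0.86
    omega3_mean: float = -6.23
    omega3_sd: float = 0.09
    decision_noise: float = 0.1
    priming_weight_mean: float = 0.0
    priming_weight_sd: float = 0.0
    sensory_memory_weight_mean: float = 0.0
    sensory_memory_weight_sd: float = 0.0


def simulate_cohort(
    n_subjects: int,
    seed: int,
    spec: CohortSpec = CohortSpec(),
    n_runs: int = 5,
    n_trials: int = 72,
):
    """Simulate a cohort of agents, one session each.

    Returns a list of dicts with keys ``subject``, ``schedule``,
    ``responses``, ``hgf_params``, ``resp_params``, ``config``.
    Per-subject parameters are drawn from truncated normals (pi_a floored
    at 0.05, omega2/omega3 clipped to a broad range).  The generative model
    is only defined where the contingency filter is numerically stable, so
    parameter draws that destabilize the filter on the subject's schedule
    are rejected and redrawn (deterministic given the seed).
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    config = ResponseModelConfig.from_name(spec.model)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(2 * n_subjects)]

    cohort = []
    for i in range(n_subjects):
        schedule = generate_session(subject_seeds[2 * i], n_runs=n_runs,
                                    n_trials=n_trials, session_id=i + 1)
        for _attempt in range(100):
            pi_a = max(0.05, rng.normal(spec.pi_a_mean, spec.pi_a_sd)) \
                if config.use_associative else 0.0
            omega2 = float(np.clip(rng.normal(spec.omega2_mean, spec.omega2_sd),
                                   -8.0, 1.0))
            omega3 = float(np.clip(rng.normal(spec.omega3_mean, spec.omega3_sd),
                                   -10.0, -2.0))
            priming = rng.normal(spec.priming_weight_mean, spec.priming_weight_sd) \
                if config.use_priming else 0.0
            sm = rng.normal(spec.sensory_memory_weight_mean,
                            spec.sensory_memory_weight_sd) \
                if config.use_sensory_memory else 0.0
            hgf_params = HgfParams(omega2=omega2, omega3=omega3)
            resp_params = ResponseParams(
                pi_a=pi_a, priming_weight=priming, sensory_memory_weight=sm,
                decision_noise=spec.decision_noise,
            )
            try:
                responses = simulate_agent(schedule, hgf_params, resp_params,
                                           config, seed=subject_seeds[2 * i + 1])
                break
            except ModelInstabilityError:
                continue
        else:
            raise ModelInstabilityError(
                0, hgf_params,
                "cohort draw (no stable parameter set found in 100 attempts)")
        cohort.append({
            "subject": i + 1,
            "schedule": schedule,
            "responses": responses,
            "hgf_params": hgf_params,
            "resp_params": resp_params,
            "config": config,
        })
    return cohort
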