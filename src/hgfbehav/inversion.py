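"""MAP inversion of the coupled contingency/perceptual model.

Each run of each subject is fitted separately: the free parameters of a
model variant are estimated in an unbounded estimation space (log transform
for positive parameters) by maximizing log-likelihood + log-prior with
quasi-Newton BFGS, restarted from the prior mean and from prior draws.  The
log model evidence is the Laplace approximation

    ln p(y | m) ~= ln p(y | theta*) + ln p(theta*) + (d/2) ln 2*pi
                   - (1/2) ln det H,

with H the numerical Hessian of the negative log-joint at the MAP theta*.
Parameter proposals that destabilize the filter (non-positive precision)
are rejected with objective +inf.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .hgf import HgfParams, ModelInstabilityError, filter_inputs, schedule_inputs
from .respmodel import (
    MODEL_NAMES,
    ResponseModelConfig,
    ResponseParams,
)

__all__ = [
    "Prior",
    "PriorSpec",
    "FitResult",
    "InversionOptions",
    "UnfittableRunError",
    "default_priors",
    "invert",
    "fit_subject",
    "evidence_matrix",
]

_LN2PI = math.log(2.0 * math.pi)
EIG_FLOOR = 1e-8


class UnfittableRunError(ValueError):
    """Raised when a run contains no scorable responses."""


@dataclass(frozen=True)
class Prior:
    """Gaussian prior on one parameter in estimation space.

    transform maps estimation space -> native space:
    identity, log (native = exp(est)), logit (native = sigmoid(est)).
    A zero prior variance fixes the parameter at its (estimation-space) mean.
    """

    mean: float
    variance: float
    transform: str = "identity"

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("prior variance must be >= 0")
        if self.transform not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def fixed(self) -> bool:
        return self.variance == 0.0

    def to_native(self, est: float) -> float:
        if self.transform == "identity":
            return float(est)
        if self.transform == "log":
            return float(np.exp(est))
        return float(1.0 / (1.0 + np.exp(-est)))

    def to_estimation(self, native: float) -> float:
        if self.transform == "identity":
            return float(native)
        if self.transform == "log":
            return float(np.log(native))
        return float(np.log(native / (1.0 - native)))

    @property
    def native_mean(self) -> float:
        return self.to_native(self.mean)


#: PriorSpec maps parameter name -> Prior
PriorSpec = Dict[str, Prior]

# parameter bookkeeping: which parameters exist for a model variant
_HGF_PARAMS = ("omega2", "omega3")
_RESP_ALWAYS = ("decision_noise",)


def model_parameters(config: ResponseModelConfig) -> List[str]:
    names = list(_HGF_PARAMS) + list(_RESP_ALWAYS)
    if config.use_associative:
        names.append("pi_a")
    if config.use_priming:
        names.append("priming_weight")
    if config.use_sensory_memory:
        names.append("sensory_memory_weight")
    return names


def default_priors(config: ResponseModelConfig) -> PriorSpec:
    """Default priors in estimation space.

    omega2/omega3 are estimated natively; pi_a and decision_noise in log
    space; the priming / sensory-memory log-odds weights natively.  The
    level-3 prior is centred at -6 where the volatility random walk is
    slow, reflecting its weak identifiability from 72-trial runs.
    """
    priors: PriorSpec = {
        "omega2": Prior(-3.0, 4.0, "identity"),
        "omega3": Prior(-6.0, 4.0, "identity"),
        "decision_noise": Prior(math.log(0.1), 1.0, "log"),
    }
    if config.use_associative:
        priors["pi_a"] = Prior(0.0, 1.0, "log")
    if config.use_priming:
        priors["priming_weight"] = Prior(0.0, 1.0, "identity")
    if config.use_sensory_memory:
        priors["sensory_memory_weight"] = Prior(0.0, 1.0, "identity")
    return priors


@dataclass(frozen=True)
class InversionOptions:
    n_restarts: int = 8            # 1 at the prior mean + (n-1) prior draws
    seed: int = 0                  # seeds the restart draws
    gtol: float = 1e-5
    objective_tol: float = 1e-6    # restart-improvement tolerance
    max_iter: int = 200
    ambiguous_input: str = "missing"


@dataclass
class FitResult:
    model_name: str
    run_id: int
    map_estimates: Dict[str, float]          # native space
    map_estimation_space: Dict[str, float]
    posterior_covariance: np.ndarray         # estimation space, free params
    free_parameters: List[str]
    log_evidence: float
    log_joint: float
    log_likelihood_value: float
    converged: bool
    n_restarts_used: int
    subject: Optional[int] = None
    priors: Optional[Dict[str, Prior]] = None

    def laplace_interval(self, name: str, level: float = 0.95):
        """Central Laplace credible interval in native space."""
        from scipy.stats import norm
        i = self.free_parameters.index(name)
        sd = math.sqrt(self.posterior_covariance[i, i])
        z = norm.ppf(0.5 * (1.0 + level))
        prior = self.priors[name]
        c = self.map_estimation_space[name]
        return (prior.to_native(c - z * sd), prior.to_native(c + z * sd))

    def to_json(self) -> str:
        d = {
            "model_name": self.model_name,
            "run_id": self.run_id,
            "subject": self.subject,
            "map_estimates": self.map_estimates,
            "map_estimation_space": self.map_estimation_space,
            "posterior_covariance": np.asarray(self.posterior_covariance).tolist(),
            "free_parameters": self.free_parameters,
            "log_evidence": self.log_evidence,
            "log_joint": self.log_joint,
            "log_likelihood": self.log_likelihood_value,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "priors": {k: asdict(v) for k, v in (self.priors or {}).items()},
        }
        return json.dumps(d, indent=1)


def _build_params(native: Mapping[str, float]):
    hgf = HgfParams(
        omega2=native["omega2"],
        omega3=native["omega3"],
    )
    resp = ResponseParams(
        pi_a=native.get("pi_a", 0.0),
        priming_weight=native.get("priming_weight", 0.0),
        sensory_memory_weight=native.get("sensory_memory_weight", 0.0),
        decision_noise=native["decision_noise"],
    )
    return hgf, resp


class _Objective:
    """Negative log-joint over the free parameters of one run.

    The percept history driving priming / sensory memory is the observed
    perception sequence and does not depend on the parameters, so all
    per-trial report terms are precomputed as arrays; only the contingency
    filter runs sequentially per evaluation.  The vectorized likelihood is
    checked against :func:`hgfbehav.respmodel.log_likelihood` in the tests.
    """

    def __init__(self, responses, schedule, config, priors, opts):
        self.responses = responses
        self.schedule = schedule
        self.config = config
        self.priors = priors
        self.inputs = schedule_inputs(schedule, opts.ambiguous_input)
        self.names = model_parameters(config)
        missing = [n for n in self.names if n not in priors]
        if missing:
            raise ValueError(f"priors missing for parameters {missing}")
        self.free = [n for n in self.names if not priors[n].fixed]
        self.fixed_native = {
            n: priors[n].native_mean for n in self.names if priors[n].fixed
        }
        self._precompute_trial_arrays()

    def _precompute_trial_arrays(self):
        from .respmodel import _STIM_LOGODDS, _percept_sign
        trials = self.schedule.trials
        n = len(trials)
        tone_sign = np.array([1.0 if t.tone == "high" else -1.0 for t in trials])
        stim = np.zeros(n)
        prev_sign = np.zeros(n)
        prev_ambig_sign = np.zeros(n)
        pa, ps = None, None
        for t, tr in enumerate(trials):
            if tr.rotation != "none":
                stim[t] = _STIM_LOGODDS if tr.rotation == "CW" else -_STIM_LOGODDS
            prev_sign[t] = _percept_sign(ps)
            if tr.rotation == "none":
                prev_ambig_sign[t] = _percept_sign(pa)
            rep = self.responses.perception[t]
            ps = rep if rep in ("CW", "CCW") else None
            if tr.rotation == "none" and rep in ("CW", "CCW"):
                pa = rep
        self._tone_sign = tone_sign
        self._stim = stim
        self._prev_sign = prev_sign
        self._prev_ambig_sign = prev_ambig_sign
        self._pred_obs = np.array(
            [1.0 if r == "CW" else (-1.0 if r == "CCW" else 0.0)
             for r in self.responses.prediction])
        self._perc_obs = np.array(
            [1.0 if r == "CW" else (-1.0 if r == "CCW" else 0.0)
             for r in self.responses.perception])
        self._logit_bound = math.log((1.0 - 1e-8) / 1e-8)

    def _fast_loglik(self, native, traj) -> float:
        # log P(report) with the same (0,1) clamping as the reference path
        lb = math.log(1e-8)
        mu_a_logit = np.clip(self._tone_sign * traj.muhat2,
                             -self._logit_bound, self._logit_bound)
        x_pred = mu_a_logit / native["decision_noise"]
        x_perc = self._stim.copy()
        if self.config.use_associative:
            x_perc += native["pi_a"] * mu_a_logit
        if self.config.use_priming:
            x_perc += native["priming_weight"] * self._prev_sign
        if self.config.use_sensory_memory:
            x_perc += native["sensory_memory_weight"] * self._prev_ambig_sign
        ll = 0.0
        for x, obs in ((x_pred, self._pred_obs), (x_perc, self._perc_obs)):
            scored = obs != 0.0
            terms = -np.logaddexp(0.0, -obs[scored] * x[scored])
            ll += float(np.sum(np.maximum(terms, lb)))
        return ll

    def native(self, theta: np.ndarray) -> Dict[str, float]:
        out = dict(self.fixed_native)
        for n, v in zip(self.free, theta):
            out[n] = self.priors[n].to_native(v)
        return out

    def log_prior(self, theta: np.ndarray) -> float:
        lp = 0.0
        for n, v in zip(self.free, theta):
            p = self.priors[n]
            lp += -0.5 * ((v - p.mean) ** 2 / p.variance
                          + math.log(p.variance) + _LN2PI)
        return lp

    def log_joint(self, theta: np.ndarray) -> float:
        native = self.native(theta)
        hgf, _ = _build_params(native)
        try:
            traj = filter_inputs(self.inputs, hgf)
            ll = self._fast_loglik(native, traj)
        except (ModelInstabilityError, FloatingPointError, OverflowError):
            return -np.inf
        if not np.isfinite(ll):
            return -np.inf
        return ll + self.log_prior(theta)

    def __call__(self, theta: np.ndarray) -> float:
        lj = self.log_joint(theta)
        return 1e12 if not np.isfinite(lj) else -lj


def _numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = step
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = step
            fij = f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            H[i, j] = H[j, i] = fij / (4.0 * step**2)
    return H


def invert(
    responses,
    schedule,
    config: ResponseModelConfig,
    priors: Optional[PriorSpec] = None,
    opts: InversionOptions = InversionOptions(),
) -> FitResult:
    """Fit one model variant to one run by MAP + Laplace evidence."""
    if priors is None:
        priors = default_priors(config)
    n_scorable = sum(r in ("CW", "CCW") for r in responses.prediction) + \
        sum(r in ("CW", "CCW") for r in responses.perception)
    if n_scorable == 0:
        raise UnfittableRunError(
            f"run {schedule.run_id}: no non-missing responses to fit"
        )

    obj = _Objective(responses, schedule, config, priors, opts)
    d = len(obj.free)
    theta0 = np.array([priors[n].mean for n in obj.free])

    if d == 0:
        lj = obj.log_joint(theta0)
        ll = lj  # no free params: prior contributes nothing
        return FitResult(
            model_name=config.name, run_id=schedule.run_id,
            map_estimates=obj.native(theta0),
            map_estimation_space={},
            posterior_covariance=np.zeros((0, 0)), free_parameters=[],
            log_evidence=lj, log_joint=lj, log_likelihood_value=ll,
            converged=True, n_restarts_used=0, priors=dict(priors),
        )

    rng = np.random.default_rng(opts.seed)
    sds = np.array([math.sqrt(priors[n].variance) for n in obj.free])
    starts = [theta0]
    for _ in range(max(0, opts.n_restarts - 1)):
        starts.append(theta0 + sds * rng.standard_normal(d))

    best = None
    n_used = 0
    any_converged = False
    for x0 in starts:
        n_used += 1
        res = optimize.minimize(
            obj, x0, method="BFGS",
            options={"gtol": opts.gtol, "maxiter": opts.max_iter},
        )
        if best is None or res.fun < best.fun - opts.objective_tol:
            best = res
        any_converged = any_converged or bool(res.success)

    theta_map = best.x
    log_joint = -best.fun
    H = _numeric_hessian(obj, theta_map)
    H = 0.5 * (H + H.T)
    evals, evecs = np.linalg.eigh(H)
    evals = np.maximum(evals, EIG_FLOOR)
    cov = (evecs / evals) @ evecs.T
    log_det_H = float(np.sum(np.log(evals)))
    log_evidence = log_joint + 0.5 * d * _LN2PI - 0.5 * log_det_H

    native = obj.native(theta_map)
    est_space = {n: float(v) for n, v in zip(obj.free, theta_map)}
    ll = log_joint - obj.log_prior(theta_map)

    return FitResult(
        model_name=config.name, run_id=schedule.run_id,
        map_estimates=native, map_estimation_space=est_space,
        posterior_covariance=cov, free_parameters=list(obj.free),
        log_evidence=float(log_evidence), log_joint=float(log_joint),
        log_likelihood_value=float(ll),
        converged=bool(any_converged and np.isfinite(log_evidence)),
        n_restarts_used=n_used, priors=dict(priors),
    )


def fit_subject(
    responses,
    schedule,
    models: Sequence[str] = MODEL_NAMES,
    priors_by_model: Optional[Mapping[str, PriorSpec]] = None,
    opts: InversionOptions = InversionOptions(),
    subject: Optional[int] = None,
) -> Dict[str, List[FitResult]]:
    """Fit every (run, model) pair for one subject's session.

    Returns {model_name: [FitResult per run]}.  Unfittable runs are recorded
    as ``None`` gaps.  Per-subject per-model evidence is the sum of run
    evidences (runs are modeled as independent).
    """
    runs = schedule.runs()
    if not runs:
        raise ValueError("session has no runs")
    out: Dict[str, List[FitResult]] = {}
    for m in models:
        config = ResponseModelConfig.from_name(m)
        priors = (priors_by_model or {}).get(m) or default_priors(config)
        fits: List[FitResult] = []
        for run in runs:
            _, start, stop = next(
                (rid, s, e) for rid, s, e in
                (schedule.run_slices or [(run.run_id, 0, len(schedule))])
                if rid == run.run_id
            )
            rresp = responses.subset(start, stop)
            try:
                fr = invert(rresp, run, config, priors, opts)
                fr.subject = subject
            except UnfittableRunError:
                fr = None
            fits.append(fr)
        out[m] = fits
    return out


def subject_evidence(fits: Mapping[str, List[Optional[FitResult]]]) -> Dict[str, float]:
    """Per-model evidence summed over fitted runs."""
    return {
        m: float(sum(f.log_evidence for f in frs if f is not None))
        for m, frs in fits.items()
    }


def evidence_matrix(all_fits: Sequence[Mapping[str, List[Optional[FitResult]]]],
                    models: Sequence[str] = MODEL_NAMES) -> np.ndarray:
    """Subjects x models log-evidence array from per-subject fit tables."""
    rows = []
    for fits in all_fits:
        ev = subject_evidence(fits)
        rows.append([ev[m] for m in models])
    return np.asarray(rows, dtype=float)
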