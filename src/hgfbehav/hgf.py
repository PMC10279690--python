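"""Three-level Hierarchical Gaussian Filter for binary inputs.

The filter tracks a binary environmental contingency through three coupled
levels.  Level 1 is the binary input itself (here: whether the trial's
tone-rotation pairing is congruent with a fixed reference coding of the
contingency).  Level 2 is the log-odds tendency of that contingency,
performing a Gaussian random walk whose step variance exp(kappa*mu3 + omega2)
is controlled by level 3.  Level 3 is the log-volatility of the contingency,
itself a random walk with step variance exp(omega3).

Belief updates are the closed-form variational updates of the binary HGF:
each trial yields prediction (hatted) quantities computed before the input
and posterior quantities after it.  The precision-weighted prediction errors
eps2 and eps3 are the increments applied to mu2 and mu3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HgfParams",
    "Trajectories",
    "ModelInstabilityError",
    "filter_inputs",
    "conditional_prediction",
    "schedule_inputs",
]

#: probabilities are kept strictly inside (0, 1) by this margin
PROB_CLAMP = 1e-8
#: precisions below this are treated as numerically degenerate
PRECISION_FLOOR = 1e-8

_TRAJ_COLUMNS = (
    "muhat1", "muhat2", "muhat3", "pihat2", "pihat3",
    "delta1", "eps2", "eps3",
    "mu2", "mu3", "sigma2", "sigma3",
)


class ModelInstabilityError(ValueError):
    """The variational update produced a non-positive precision.

    Raised with the offending trial index and parameters so that inversion
    can reject the parameter proposal (objective -inf) instead of letting
    NaN/Inf propagate through the trajectories.
    """

    def __init__(self, trial: int, params: "HgfParams", quantity: str):
        self.trial = trial
        self.params = params
        self.quantity = quantity
        super().__init__(
            f"HGF unstable at trial {trial}: non-positive {quantity} "
            f"(omega2={params.omega2:.4g}, omega3={params.omega3:.4g}, "
            f"kappa={params.kappa:.4g})"
        )


@dataclass(frozen=True)
class HgfParams:
    """Perceptual (contingency-model) parameters.

    omega2, omega3 : tonic log-volatility of levels 2 and 3 (learning rates)
    kappa          : phasic coupling of level 3 onto level-2 step variance
    mu2_0, sigma2_0, mu3_0, sigma3_0 : initial state means / variances
    """

    omega2: float = -3.0
    omega3: float = -6.0
    kappa: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 0.1
    mu3_0: float = 0.0
    sigma3_0: float = 1.0

    def validate(self) -> None:
        if not np.isfinite([self.omega2, self.omega3, self.kappa,
                            self.mu2_0, self.sigma2_0,
                            self.mu3_0, self.sigma3_0]).all():
            raise ValueError("HGF parameters must be finite")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial state variances must be positive")


@dataclass
class Trajectories:
    """Trial-wise belief quantities, one entry per input.

    Hatted quantities (muhat*, pihat*) are predictions formed before the
    trial's input; mu*/sigma* are the posteriors after it.  delta1 is the
    first-level prediction error, eps2/eps3 the precision-weighted
    prediction errors (the belief-update steps at levels 2 and 3).
    """

    muhat1: np.ndarray
    muhat2: np.ndarray
    muhat3: np.ndarray
    pihat2: np.ndarray
    pihat3: np.ndarray
    delta1: np.ndarray
    eps2: np.ndarray
    eps3: np.ndarray
    mu2: np.ndarray
    mu3: np.ndarray
    sigma2: np.ndarray
    sigma3: np.ndarray
    params: HgfParams = field(default_factory=HgfParams)

    def __len__(self) -> int:
        return len(self.muhat1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in _TRAJ_COLUMNS})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sigmoid(x: float) -> float:
    # overflow-safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def clamp_probability(p: float) -> float:
    """Clamp a probability strictly inside (0, 1)."""
    return min(max(p, PROB_CLAMP), 1.0 - PROB_CLAMP)


def filter_inputs(inputs, params: HgfParams) -> Trajectories:
    """Run the forward filter over a sequence of binary inputs.

    Parameters
    ----------
    inputs : sequence of {0, 1, nan/None}
        One entry per trial; NaN or None marks a missing input (e.g. an
        ambiguous trial that carries no objective contingency information).
        On missing inputs the posterior equals the trial's prediction and
        prediction errors are zero.
    params : HgfParams

    Raises
    ------
    ModelInstabilityError
        If an update yields a non-positive precision at any level.
    """
    params.validate()
    u = np.asarray(
        [np.nan if v is None else float(v) for v in inputs], dtype=float
    )
    n = u.size
    if n == 0:
        raise ValueError("inputs must be nonempty")
    observed = ~np.isnan(u)
    if not np.isin(u[observed], (0.0, 1.0)).all():
        raise ValueError("inputs must be 0, 1 or missing")

    traj = {c: np.empty(n) for c in _TRAJ_COLUMNS}
    k2, w2o2, o3 = params.kappa, params.omega2, params.omega3

    mu2, sig2 = params.mu2_0, params.sigma2_0
    mu3, sig3 = params.mu3_0, params.sigma3_0

    for t in range(n):
        # ---- prediction step (before the input) ----
        muhat2 = mu2
        try:
            step2 = math.exp(k2 * mu3 + w2o2)
        except OverflowError:
            # runaway volatility state: treat as instability, not NaN
            raise ModelInstabilityError(t + 1, params, "level-2 step variance")
        sigmahat2 = sig2 + step2
        pihat2 = 1.0 / sigmahat2
        muhat3 = mu3
        sigmahat3 = sig3 + math.exp(o3)
        pihat3 = 1.0 / sigmahat3
        if pihat2 <= PRECISION_FLOOR or pihat3 <= PRECISION_FLOOR:
            raise ModelInstabilityError(t + 1, params, "prediction precision")
        muhat1 = clamp_probability(_sigmoid(muhat2))

        traj["muhat1"][t] = muhat1
        traj["muhat2"][t] = muhat2
        traj["muhat3"][t] = muhat3
        traj["pihat2"][t] = pihat2
        traj["pihat3"][t] = pihat3

        # ---- update step ----
        if not observed[t]:
            # no input: carry the prediction forward unchanged
            traj["delta1"][t] = 0.0
            traj["eps2"][t] = 0.0
            traj["eps3"][t] = 0.0
            mu2, sig2 = muhat2, sigmahat2
            mu3, sig3 = muhat3, sigmahat3
        else:
            delta1 = u[t] - muhat1
            pi2 = pihat2 + muhat1 * (1.0 - muhat1)
            eps2 = delta1 / pi2
            mu2 = muhat2 + eps2
            sig2 = 1.0 / pi2

            # volatility prediction error and level-3 update
            w2 = step2 * pihat2
            delta2 = (sig2 + eps2 * eps2) * pihat2 - 1.0
            pi3 = pihat3 + 0.5 * k2 * k2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
            if pi3 <= PRECISION_FLOOR:
                raise ModelInstabilityError(t + 1, params, "level-3 precision")
            eps3 = 0.5 * k2 * (w2 / pi3) * delta2
            mu3 = muhat3 + eps3
            sig3 = 1.0 / pi3

            traj["delta1"][t] = delta1
            traj["eps2"][t] = eps2
            traj["eps3"][t] = eps3

        traj["mu2"][t] = mu2
        traj["mu3"][t] = mu3
        traj["sigma2"][t] = sig2
        traj["sigma3"][t] = sig3

    return Trajectories(params=params, **traj)


def conditional_prediction(muhat2: float, tone: str) -> float:
    """Inferred conditional probability mu_a of a CW rotation given the tone.

    muhat2 is the log-odds belief that the contingency is in its reference
    state (high tone -> CW, low tone -> CCW).  A high tone therefore predicts
    CW with probability sigma(muhat2); a low tone with 1 - sigma(muhat2).
    """
    p = _sigmoid(muhat2)
    if tone == "high":
        return clamp_probability(p)
    if tone == "low":
        return clamp_probability(1.0 - p)
    raise ValueError(f"unknown tone {tone!r}")


def schedule_inputs(schedule, ambiguous_input: str = "missing") -> np.ndarray:
    """Binary contingency-model inputs for a schedule.

    u = 1 iff the trial's tone-rotation pair is congruent with the reference
    contingency coding (high -> CW, low -> CCW).  Ambiguous trials carry no
    objective rotation and contribute a missing input by default; with
    ``ambiguous_input='none'`` they are simply missing as well (alias), and
    downstream code may substitute the reported percept where configured.
    """
    u = np.empty(len(schedule.trials))
    for i, tr in enumerate(schedule.trials):
        if tr.rotation == "none":
            u[i] = np.nan
        else:
            cw_under_c1 = tr.tone == "high"
            is_cw = tr.rotation == "CW"
            u[i] = 1.0 if (is_cw == cw_under_c1) else 0.0
    return u
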