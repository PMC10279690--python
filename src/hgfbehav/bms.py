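"""Group-level random-effects Bayesian model selection and model averaging.

Random-effects BMS treats the generating model of each subject as a draw
from a population multinomial with Dirichlet-distributed frequencies r.
Variational inference on q(r) = Dir(alpha) and q(m_n) = Cat(u_n) yields
expected model frequencies; exceedance probabilities (the posterior
probability that a model is the most frequent) are computed by seeded
Monte-Carlo over the Dirichlet posterior.  The Bayes omnibus risk (BOR)
compares the free energy of this random-effects model against the null
model in which all frequencies are exactly equal, and protects the
exceedance probabilities:

    PXP_k = EP_k * (1 - BOR) + BOR / K.

Bayesian model averaging (BMA) summarizes each subject's parameters as the
mixture over models weighted by that subject's posterior model
probabilities, with a model's absent parameters contributing its prior mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["BmsResult", "rfx_bms", "bma"]


@dataclass
class BmsResult:
    model_names: List[str]
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    bayes_omnibus_risk: float
    protected_exceedance_probability: np.ndarray
    subject_posteriors: np.ndarray     # subjects x models
    n_samples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.model_names,
            "alpha": self.dirichlet_alpha,
            "expected_frequency": self.expected_frequency,
            "exceedance_probability": self.exceedance_probability,
            "protected_exceedance_probability":
                self.protected_exceedance_probability,
        })


def _ln_beta(alpha: np.ndarray) -> float:
    return float(np.sum(gammaln(alpha)) - gammaln(np.sum(alpha)))


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray, tol: float = 1e-6,
                  max_iter: int = 10000):
    """Variational updates for the random-effects model; returns (alpha, u, F)."""
    n, k = lme.shape
    alpha = alpha0.copy()
    u = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        elog_r = digamma(alpha) - digamma(alpha.sum())
        log_u = lme + elog_r
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    # variational free energy (evidence lower bound) of the RFX model
    elog_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ulogu = np.where(u > 0, u * np.log(u), 0.0)
    F = float(
        np.sum(u * lme)
        + np.sum(u * elog_r)
        - np.sum(ulogu)
        + np.sum((alpha0 - alpha) * elog_r)
        + _ln_beta(alpha) - _ln_beta(alpha0)
    )
    return alpha, u, F


def _exceedance_mc(alpha: np.ndarray, n_samples: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    k = alpha.size
    counts = np.zeros(k, dtype=np.int64)
    chunk = 100_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        g = rng.standard_gamma(alpha, size=(m, k))
        counts += np.bincount(np.argmax(g, axis=1), minlength=k)
        remaining -= m
    return counts / n_samples


def rfx_bms(
    evidence: np.ndarray,
    model_names: Optional[Sequence[str]] = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
    alpha0: Optional[np.ndarray] = None,
) -> BmsResult:
    """Random-effects BMS over a subjects x models log-evidence matrix."""
    lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2:
        raise ValueError("evidence must be a 2-D subjects x models array")
    n, k = lme.shape
    if k < 2:
        raise ValueError("BMS requires at least 2 models")
    if not np.isfinite(lme).all():
        raise ValueError("evidence matrix must be finite")
    if model_names is None:
        model_names = [f"m{i + 1}" for i in range(k)]
    if len(model_names) != k:
        raise ValueError("model_names length mismatch")
    if alpha0 is None:
        alpha0 = np.ones(k)

    alpha, u, F1 = _vb_dirichlet(lme, np.asarray(alpha0, dtype=float))
    ef = alpha / alpha.sum()
    ep = _exceedance_mc(alpha, n_samples, seed)

    # null model: all frequencies fixed at 1/K
    F0 = float(np.sum(logsumexp(lme, axis=1) - np.log(k)))
    bor = float(1.0 / (1.0 + np.exp(F1 - F0)))
    pxp = ep * (1.0 - bor) + bor / k

    return BmsResult(
        model_names=list(model_names),
        dirichlet_alpha=alpha,
        expected_frequency=ef,
        exceedance_probability=ep,
        bayes_omnibus_risk=bor,
        protected_exceedance_probability=pxp,
        subject_posteriors=u,
        n_samples=n_samples,
        seed=seed,
    )


def bma(
    all_fits: Sequence[Mapping[str, Sequence]],
    bms: BmsResult,
    weighting: str = "subject",
) -> pd.DataFrame:
    """Bayesian model averaging of MAP parameters.

    Parameters
    ----------
    all_fits : per-subject mapping model -> list of per-run FitResult
        (``None`` entries mark unfittable runs).  A subject's per-model
        parameter value is the mean MAP across fitted runs; a parameter
        absent from a model contributes that model's prior mean.
    bms : BmsResult whose subject order matches ``all_fits``.
    weighting : "subject" (each subject's own posterior model
        probabilities) or "group" (expected model frequencies for all).

    Returns a subjects x parameters DataFrame of averaged native-space values.
    """
    if weighting not in ("subject", "group"):
        raise ValueError("weighting must be 'subject' or 'group'")
    models = bms.model_names
    n = len(all_fits)
    if bms.subject_posteriors.shape[0] != n:
        raise ValueError("BMS result does not match number of subjects")

    # collect union of parameters and per-model prior means
    param_names: List[str] = []
    prior_means: Dict[str, Dict[str, float]] = {}
    for fits in all_fits:
        for m, frs in fits.items():
            for fr in frs:
                if fr is None:
                    continue
                for p in fr.map_estimates:
                    if p not in param_names:
                        param_names.append(p)
                prior_means.setdefault(m, {})
                for p, pr in (fr.priors or {}).items():
                    prior_means[m].setdefault(p, pr.native_mean)

    fallback_prior: Dict[str, float] = {}
    for pm in prior_means.values():
        for p, v in pm.items():
            fallback_prior.setdefault(p, v)

    rows = []
    for i, fits in enumerate(all_fits):
        w = (bms.subject_posteriors[i] if weighting == "subject"
             else bms.expected_frequency)
        # drop models with no fitted runs for this subject, renormalize
        have = np.array([
            m in fits and any(fr is not None for fr in fits[m]) for m in models
        ])
        wi = np.where(have, w, 0.0)
        if wi.sum() == 0:
            raise ValueError(f"subject {i}: no fitted models to average")
        wi = wi / wi.sum()
        row = {}
        for p in param_names:
            val = 0.0
            for j, m in enumerate(models):
                if wi[j] == 0.0:
                    continue
                frs = [fr for fr in fits[m] if fr is not None]
                vals = [fr.map_estimates[p] for fr in frs if p in fr.map_estimates]
                if vals:
                    mv = float(np.mean(vals))
                else:
                    # model lacks this parameter: contribute its prior mean
                    # (shared default prior where the model never defines it)
                    mv = prior_means.get(m, {}).get(p, fallback_prior.get(p, np.nan))
                val += wi[j] * mv
            row[p] = val
        rows.append(row)
    return pd.DataFrame(rows, columns=param_names)
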