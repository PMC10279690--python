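"""Literal step-by-step transcription of the binary three-level HGF updates.

Written directly from the published update equations as an independent
oracle for the package's filter: every trial is computed with explicit
scalar arithmetic in the variance (sigma) parametrization, one equation per
line, with no code shared with the implementation under test.

Equations, for trial k with posterior states (mu2, sigma2, mu3, sigma3)
from trial k-1:

prediction:
    muhat2    = mu2
    sigmahat2 = sigma2 + exp(kappa * mu3 + omega2)
    muhat3    = mu3
    sigmahat3 = sigma3 + exp(omega3)
    muhat1    = 1 / (1 + exp(-muhat2))          (clamped to (0,1))

update on observed input u:
    delta1 = u - muhat1
    pi2    = 1/sigmahat2 + muhat1 * (1 - muhat1)
    mu2'   = muhat2 + delta1 / pi2
    sigma2' = 1 / pi2
    w2     = exp(kappa * mu3 + omega2) / sigmahat2
    delta2 = (sigma2' + (mu2' - muhat2)**2) / sigmahat2 - 1
    pi3    = 1/sigmahat3 + (kappa**2 / 2) * w2 * (w2 + (2*w2 - 1) * delta2)
    mu3'   = muhat3 + (kappa / 2) * (w2 / pi3) * delta2
    sigma3' = 1 / pi3

update on missing input: posterior = prediction, prediction errors zero.
"""

import math


def oracle_filter(inputs, omega2, omega3, kappa=1.0,
                  mu2_0=0.0, sigma2_0=0.1, mu3_0=0.0, sigma3_0=1.0,
                  clamp=1e-8):
    """Return a list of per-trial dicts of all trajectory quantities.

    Raises ValueError on a non-positive level-3 precision.
    """
    mu2, sigma2 = mu2_0, sigma2_0
    mu3, sigma3 = mu3_0, sigma3_0
    rows = []
    for k, u in enumerate(inputs):
        muhat2 = mu2
        sigmahat2 = sigma2 + math.exp(kappa * mu3 + omega2)
        muhat3 = mu3
        sigmahat3 = sigma3 + math.exp(omega3)
        muhat1 = 1.0 / (1.0 + math.exp(-muhat2)) if muhat2 > -500 else 0.0
        muhat1 = min(max(muhat1, clamp), 1.0 - clamp)

        missing = u is None or (isinstance(u, float) and math.isnan(u))
        if missing:
            delta1 = 0.0
            eps2 = 0.0
            eps3 = 0.0
            mu2, sigma2 = muhat2, sigmahat2
            mu3, sigma3 = muhat3, sigmahat3
        else:
            delta1 = u - muhat1
            pi2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
            mu2_new = muhat2 + delta1 / pi2
            sigma2_new = 1.0 / pi2
            w2 = math.exp(kappa * mu3 + omega2) / sigmahat2
            delta2 = (sigma2_new + (mu2_new - muhat2) ** 2) / sigmahat2 - 1.0
            pi3 = 1.0 / sigmahat3 \
                + (kappa ** 2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
            if pi3 <= 0.0:
                raise ValueError(f"oracle: non-positive level-3 precision at trial {k + 1}")
            mu3_new = muhat3 + (kappa / 2.0) * (w2 / pi3) * delta2
            sigma3_new = 1.0 / pi3
            eps2 = delta1 / pi2
            eps3 = (kappa / 2.0) * (w2 / pi3) * delta2
            mu2, sigma2 = mu2_new, sigma2_new
            mu3, sigma3 = mu3_new, sigma3_new

        rows.append({
            "muhat1": muhat1, "muhat2": muhat2, "muhat3": muhat3,
            "pihat2": 1.0 / sigmahat2, "pihat3": 1.0 / sigmahat3,
            "delta1": delta1, "eps2": eps2, "eps3": eps3,
            "mu2": mu2, "mu3": mu3, "sigma2": sigma2, "sigma3": sigma3,
        })
    return rows
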