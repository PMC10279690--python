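"""Brute-force exceedance probabilities by posterior importance sampling.

The random-effects model posterior over population model frequencies r is

    p(r | L) ~ Dir(r; alpha0) * prod_n sum_k r_k exp(L_nk).

Sampling r from the Dirichlet prior and weighting by the marginal
likelihood term gives exact (up to Monte-Carlo error) exceedance
probabilities EP_k = P(r_k = max r | L), with no variational
approximation.  Practical only for small problems.
"""

import numpy as np


def exceedance_bruteforce(lme, n_samples=200_000, seed=0, alpha0=1.0):
    lme = np.asarray(lme, dtype=float)
    n, k = lme.shape
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(np.full(k, alpha0), size=n_samples)          # (S, K)
    b = np.exp(lme - lme.max(axis=1, keepdims=True))               # (N, K)
    # log importance weight: sum_n log( sum_k r_k * b_nk )
    logw = np.zeros(n_samples)
    for i in range(n):
        logw += np.log(r @ b[i])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    winners = np.argmax(r, axis=1)
    ep = np.array([w[winners == j].sum() for j in range(k)])
    return ep
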