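"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (explicit
risk-set enumeration, exact rational arithmetic, direct optimisation of the
written-out likelihood) and share no code with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import optimize


def oracle_partial_loglik(beta, time, event, X, ties="efron"):
    """Cox partial log-likelihood by explicit risk-set enumeration."""
    beta = np.atleast_1d(np.asarray(beta, float))
    eta = X @ beta
    ll = 0.0
    event_times = np.unique(time[event.astype(bool)])
    for t in event_times:
        dead = np.flatnonzero((time == t) & event.astype(bool))
        risk = np.flatnonzero(time >= t)
        ll += eta[dead].sum()
        m = dead.size
        sum_risk = np.exp(eta[risk]).sum()
        sum_dead = np.exp(eta[dead]).sum()
        for l in range(m):
            frac = l / m if ties == "efron" else 0.0
            ll -= np.log(sum_risk - frac * sum_dead)
    return float(ll)


def oracle_cox_mle(time, event, X, ties="efron"):
    """Maximize the explicit partial likelihood numerically (Nelder-Mead)."""
    p = X.shape[1]

    def neg(beta):
        return -oracle_partial_loglik(beta, time, event, X, ties)

    res = optimize.minimize(
        neg,
        np.zeros(p),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    return res.x, -res.fun


def exact_pairwise_auc(times, scores, horizon):
    """Mann-Whitney AUC of scores for (T <= t) vs (T > t), exact rationals."""
    cases = [s for T, s in zip(times, scores) if T <= horizon]
    ctrls = [s for T, s in zip(times, scores) if T > horizon]
    if not cases or not ctrls:
        raise ValueError("degenerate horizon")
    num = Fraction(0)
    for sc in cases:
        for st in ctrls:
            if sc > st:
                num += 1
            elif sc == st:
                num += Fraction(1, 2)
    return num / (len(cases) * len(ctrls))
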