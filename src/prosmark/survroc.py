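"""Time-dependent ROC AUC for censored survival outcomes.

Discrimination of a risk score at a fixed horizon ``t`` is measured with the
cumulative/dynamic AUC: cases are subjects who fail by ``t``, controls are
subjects still event-free beyond ``t``. Under right censoring, case/control
contributions are reweighted by the inverse probability of censoring (IPCW):
a case failing at ``T`` gets weight ``1/G(T-)`` and a control ``1/G(t)``,
where ``G`` is the Kaplan-Meier estimate of the censoring distribution.
With no censoring this reduces *exactly* to the Mann-Whitney AUC of the
scores for (T <= t) versus (T > t); tied scores count 1/2.

The signature-evaluation layer fits a Cox model on a fixed biomarker set,
scores subjects by the linear predictor, averages the AUC over multiply
imputed datasets, adjusts for overfitting by pooled out-of-fold
cross-validation scoring, and attaches percentile-bootstrap confidence
intervals and a bootstrap-inversion p-value against AUC = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import _fit_arrays, fit_cox

__all__ = [
    "AUCResult",
    "DegenerateHorizonError",
    "censoring_survival",
    "cd_auc",
    "risk_scores",
    "signature_auc",
    "bootstrap_inference",
]


class DegenerateHorizonError(ValueError):
    """No cases or no controls at the requested horizon."""


@dataclass
class AUCResult:
    horizon: float
    auc: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    adjusted: bool = False
    m_averaged: int = 1


def censoring_survival(time, event):
    """Kaplan-Meier estimator of the censoring survival function G.

    Censorings (event == 0) are the "events" here. Returns a callable
    ``G(t, left=False)``; ``left=True`` evaluates the left limit G(t-).
    """
    time = np.asarray(time, float)
    cens = 1.0 - np.asarray(event, float)
    order = np.argsort(time, kind="stable")
    t, c = time[order], cens[order]
    uniq, first, inv = np.unique(t, return_index=True, return_inverse=True)
    n = t.size
    at_risk = n - first
    d_cens = np.bincount(inv, weights=c)
    surv = np.cumprod(1.0 - d_cens / at_risk)

    def G(x, left=False):
        x = np.asarray(x, float)
        side = "left" if left else "right"
        idx = np.searchsorted(uniq, x, side=side) - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    return G


def cd_auc(time, event, scores, horizon) -> float:
    """IPCW cumulative/dynamic AUC at one horizon.

    Raises :class:`DegenerateHorizonError` when no case (event by the
    horizon) or no control (followed beyond it) exists, and ``ValueError``
    when the censoring survival G vanishes at a needed point.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    scores = np.asarray(scores, float)
    case = (time <= horizon) & event
    ctrl = time > horizon
    if not case.any():
        raise DegenerateHorizonError(f"no events by horizon {horizon}")
    if not ctrl.any():
        raise DegenerateHorizonError(f"no subjects followed beyond horizon {horizon}")
    G = censoring_survival(time, event)
    g_case = G(time[case], left=True)
    g_ctrl = G(horizon)
    if np.any(g_case <= 0) or g_ctrl <= 0:
        raise ValueError("censoring survival is zero at a required time point")
    w_case = 1.0 / g_case
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / g_ctrl)

    s_case, s_ctrl = scores[case], scores[ctrl]
    # weighted Mann-Whitney via sorted controls
    order = np.argsort(s_ctrl, kind="stable")
    sc, wc = s_ctrl[order], w_ctrl[order]
    cumw = np.concatenate([[0.0], np.cumsum(wc)])
    lo = np.searchsorted(sc, s_case, side="left")
    hi = np.searchsorted(sc, s_case, side="right")
    wins = cumw[lo]                      # control weight strictly below
    ties = cumw[hi] - cumw[lo]
    num = float(np.sum(w_case * (wins + 0.5 * ties)))
    return num / (w_case.sum() * wc.sum())


def risk_scores(df: pd.DataFrame, signature: list[str]) -> np.ndarray:
    """Linear predictor of a Cox fit on the signature biomarkers."""
    fit = fit_cox(df, signature)
    return df[list(signature)].to_numpy(float) @ fit.coef


def _stratified_folds(event, n_folds, rng):
    """Event-stratified fold assignment so every fold sees events."""
    n = event.size
    folds = np.empty(n, dtype=int)
    for val in (0, 1):
        idx = np.flatnonzero(event == val)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def _as_arrays(df, signature):
    return (
        df["time"].to_numpy(float),
        df["event"].to_numpy(float).astype(bool),
        df[list(signature)].to_numpy(float),
    )


def _cv_scores_arrays(time, event, X, names, n_folds, rng, max_refolds=20):
    ev = event.astype(int)
    for _ in range(max_refolds):
        folds = _stratified_folds(ev, n_folds, rng)
        if all(ev[folds != f].sum() >= 2 for f in range(n_folds)):
            break
    else:
        raise RuntimeError("could not build folds with events in every training set")
    scores = np.empty(time.size, dtype=float)
    for f in range(n_folds):
        tr = folds != f
        fit = _fit_arrays(time[tr], event[tr], X[tr], names)
        scores[~tr] = X[~tr] @ fit.coef
    return scores


def signature_auc(
    completed_datasets: list[pd.DataFrame],
    signature: list[str],
    horizons=(3.0, 5.0),
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[dict[float, AUCResult], dict[float, AUCResult]]:
    """Averaged unadjusted and cross-validation-adjusted AUC per horizon.

    Per imputed dataset the signature Cox model is fit on all subjects
    (unadjusted) or per event-stratified fold with pooled out-of-fold
    scores (adjusted), and the cumulative/dynamic AUC is computed at each
    horizon; the reported value is the mean over the m imputations.
    """
    m = len(completed_datasets)
    rng = np.random.default_rng(seed)
    unadj = {h: [] for h in horizons}
    adj = {h: [] for h in horizons}
    names = list(signature)
    for df in completed_datasets:
        t, e, X = _as_arrays(df, names)
        s_full = X @ _fit_arrays(t, e, X, names).coef
        s_cv = _cv_scores_arrays(t, e, X, names, cv_folds, rng)
        for h in horizons:
            unadj[h].append(cd_auc(t, e, s_full, h))
            adj[h].append(cd_auc(t, e, s_cv, h))
    mk = lambda h, vals, adjusted: AUCResult(
        horizon=h, auc=float(np.mean(vals)), adjusted=adjusted, m_averaged=m
    )
    return (
        {h: mk(h, unadj[h], False) for h in horizons},
        {h: mk(h, adj[h], True) for h in horizons},
    )


def bootstrap_inference(
    completed_datasets: list[pd.DataFrame],
    signature: list[str],
    horizon: float,
    B: int = 1000,
    seed: int = 0,
    adjusted: bool = False,
    cv_folds: int = 10,
) -> dict:
    """Percentile-bootstrap 95% CI and p-value for the averaged AUC.

    Subjects are resampled with replacement; the *same* bootstrap index set
    is applied across the m completed datasets so the imputation structure
    is respected. Replicates where the horizon degenerates (no cases or no
    controls) are dropped and counted. The two-sided p-value inverts the
    bootstrap distribution around 0.5 with a 1/(B+1) continuity guard.
    """
    rng = np.random.default_rng(seed)
    n = len(completed_datasets[0])
    names = list(signature)
    arrays = [_as_arrays(df, names) for df in completed_datasets]
    stats = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        vals = []
        try:
            for t0, e0, X0 in arrays:
                t, e, X = t0[idx], e0[idx], X0[idx]
                if adjusted:
                    s = _cv_scores_arrays(t, e, X, names, cv_folds, rng)
                else:
                    s = X @ _fit_arrays(t, e, X, names).coef
                vals.append(cd_auc(t, e, s, horizon))
        except (DegenerateHorizonError, ValueError, RuntimeError):
            dropped += 1
            continue
        stats.append(float(np.mean(vals)))
    if not stats:
        raise RuntimeError("all bootstrap replicates degenerate")
    stats = np.asarray(stats)
    b_eff = stats.size
    ci_low, ci_high = np.percentile(stats, [2.5, 97.5])
    p_low = np.mean(stats <= 0.5)
    p_high = np.mean(stats >= 0.5)
    p = max(2.0 * min(p_low, p_high), 1.0 / (b_eff + 1))
    out = {
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "p": float(min(p, 1.0)),
        "n_dropped": dropped,
        "B_effective": int(b_eff),
    }
    if dropped > 0.1 * B:
        out["warning"] = f"{dropped}/{B} bootstrap replicates dropped as degenerate"
    return out
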