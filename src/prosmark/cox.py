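"""Cox proportional-hazards fitting by Newton-Raphson partial-likelihood maximization.

The module provides the survival workhorse for the biomarker screens: maximum
partial-likelihood estimation with Efron or Breslow handling of tied event
times, Wald inference, and the per-standard-deviation hazard-ratio reporting
convention used throughout the package (a continuous biomarker's hazard ratio
is expressed per 1 SD of its observed distribution, so markers on different
staining scales are directly comparable).

Datasets are plain :class:`pandas.DataFrame` objects with reserved columns
``time`` (years, > 0) and ``event`` (0/1); every other column is a covariate.
Missing covariate values are the caller's problem: fits here are strictly
complete-case (the screens subset rows, the imputation module fills values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoxFit",
    "ConvergenceError",
    "fit_cox",
    "per_sd_report",
    "univariate_screen",
    "adjusted_screen",
]

# 97.5% standard-normal quantile, fixed for bit-reproducible intervals
Z_975 = 1.959964


class ConvergenceError(RuntimeError):
    """Raised when the partial likelihood cannot be maximized."""


@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit.

    Attributes
    ----------
    names : list of str
        Covariate names, in the order of ``coef``.
    coef : ndarray
        Log-hazard coefficients (per covariate unit).
    cov : ndarray
        Inverse observed information; coefficient covariance matrix.
    loglik : float
        Partial log-likelihood at the optimum.
    n, n_events : int
        Subjects and events used in the fit.
    converged : bool
    iterations : int
    message : str
        Diagnostic for non-convergence (e.g. monotone likelihood).
    """

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _design(df: pd.DataFrame, covariates: list[str]):
    required = {"time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset lacks required column(s): {sorted(missing)}")
    sub = df[["time", "event", *covariates]].dropna()
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=float)
    X = sub[list(covariates)].to_numpy(dtype=float)
    if np.any(time <= 0):
        raise ValueError("all survival times must be positive")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(bool), X


def _loglik_grad_hess(beta, time, event, X, ties):
    """Partial log-likelihood, score and observed information.

    Vectorised over risk sets via reversed cumulative sums on the
    time-sorted sample; tied event groups are handled per Efron's or
    Breslow's correction.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t, d, Xs = time[order], event[order], X[order]
    eta = Xs @ beta
    # guard against overflow during wild Newton proposals
    eta = np.clip(eta, -200.0, 200.0)
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]

    # risk-set sums: S0(t_i) = sum_{t_j >= t_i} w_j, likewise S1, S2
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    # group tied times; only Efron groups with >= 2 deaths need a loop
    _, first, inv = np.unique(t, return_index=True, return_inverse=True)
    dg = np.bincount(inv, weights=d.astype(float)).astype(int)

    loglik = float(eta[d].sum())
    grad = Xs[d].sum(axis=0)
    info = np.zeros((p, p))

    simple = (dg > 0) & ((dg == 1) if ties == "efron" else True)
    sel = np.flatnonzero(simple)
    if sel.size:
        m = dg[sel].astype(float)
        g0 = S0[first[sel]]
        psi = S1[first[sel]] / g0[:, None]
        loglik -= float(m @ np.log(g0))
        grad -= m @ psi
        info += np.einsum("g,gij->ij", m / g0, S2[first[sel]])
        info -= np.einsum("g,gi,gj->ij", m, psi, psi)

    if ties == "efron":
        for g in np.flatnonzero(dg >= 2):
            i = first[g]
            j = i + np.searchsorted(t[i:], t[i], side="right")
            dead = np.arange(i, j)[d[i:j]]
            m_g = dead.size
            # eta/X death sums already counted in the global terms above
            s0d = float(w[dead].sum())
            s1d = wx[dead].sum(axis=0)
            s2d = wxx[dead].sum(axis=0)
            for l in range(m_g):
                f = l / m_g
                phi0 = S0[i] - f * s0d
                phi1 = S1[i] - f * s1d
                phi2 = S2[i] - f * s2d
                loglik -= np.log(phi0)
                psi = phi1 / phi0
                grad -= psi
                info += phi2 / phi0 - np.outer(psi, psi)
    return loglik, grad, info


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
    max_iter: int = 100,
    tol_score: float = 1e-9,
    tol_loglik: float = 1e-10,
) -> CoxFit:
    """Maximize the Cox partial likelihood by damped Newton-Raphson.

    Parameters
    ----------
    df : DataFrame
        Survival dataset with ``time``/``event`` columns. Rows with any
        missing value among the requested covariates are dropped
        (complete-case analysis).
    covariates : list of str
        Covariate columns to enter the model.
    ties : {"efron", "breslow"}
        Correction for tied event times. The two coincide exactly when no
        event times are tied.

    Convergence is declared when the largest score component falls below
    ``tol_score`` or the relative log-likelihood change falls below
    ``tol_loglik``. A monotone (divergent) likelihood is flagged via
    ``converged=False`` with a diagnostic message rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    if not covariates:
        raise ValueError("at least one covariate required")
    time, event, X = _design(df, list(covariates))
    return _fit_arrays(time, event, X, list(covariates), ties, max_iter,
                       tol_score, tol_loglik)


def _fit_arrays(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    names: list[str],
    ties: str = "efron",
    max_iter: int = 100,
    tol_score: float = 1e-9,
    tol_loglik: float = 1e-10,
) -> CoxFit:
    """Array fast path of :func:`fit_cox` (no DataFrame handling)."""
    covariates = names
    n, p = X.shape
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("dataset contains no events")
    sds = X.std(axis=0)
    const = np.where(sds == 0)[0]
    if const.size:
        raise ValueError(
            f"constant covariate(s): {[covariates[k] for k in const]}"
        )

    beta = np.zeros(p)
    loglik, grad, info = _loglik_grad_hess(beta, time, event, X, ties)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving line search
        new_beta = beta + step
        new_ll, new_grad, new_info = _loglik_grad_hess(
            new_beta, time, event, X, ties
        )
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _loglik_grad_hess(
                new_beta, time, event, X, ties
            )
            halvings += 1
        rel_change = abs(new_ll - loglik) / max(1.0, abs(loglik))
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(grad)) < tol_score or rel_change < tol_loglik:
            converged = True
            break
        if np.max(np.abs(beta * sds)) > 50.0:
            message = (
                "monotone likelihood suspected: coefficient diverging "
                "(complete or quasi-complete separation of event times)"
            )
            break

    if converged and (
        np.max(np.abs(beta * sds)) > 50.0 or np.max(np.abs(X @ beta)) > 100.0
    ):
        # runaway linear predictor: the eta clip flattens the likelihood and
        # can zero the score at absurd beta, mimicking convergence
        converged = False
        message = (
            "monotone likelihood suspected: coefficient diverging "
            "(complete or quasi-complete separation of event times)"
        )

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return CoxFit(
        names=list(covariates),
        coef=beta,
        cov=cov,
        loglik=float(loglik),
        n=n,
        n_events=n_events,
        converged=converged,
        iterations=it,
        message=message,
    )


def per_sd_report(fit: CoxFit, df: pd.DataFrame, name: str) -> dict:
    """Hazard ratio per 1 SD of a continuous covariate, with Wald inference.

    The SD is computed on the complete-case subset actually used in the fit
    (rows complete on *all* fit covariates), so reports are self-consistent
    with the varying per-biomarker N of the screens. The Wald p-value is
    scale-invariant; the interval is ``exp((beta +/- z*se) * sd)``.
    """
    if name not in fit.names:
        raise KeyError(f"{name!r} not among fit covariates {fit.names}")
    j = fit.names.index(name)
    sub = df[["time", "event", *fit.names]].dropna()
    s = float(sub[name].std(ddof=1))
    if not np.isfinite(s) or s == 0:
        raise ValueError(f"covariate {name!r} has zero SD on analyzed subjects")
    beta, se = float(fit.coef[j]), float(fit.se[j])
    from scipy import stats

    z = beta / se
    return {
        "variable": name,
        "n": fit.n,
        "n_events": fit.n_events,
        "hr": float(np.exp(beta * s)),
        "ci_low": float(np.exp((beta - Z_975 * se) * s)),
        "ci_high": float(np.exp((beta + Z_975 * se) * s)),
        "p": float(2 * stats.norm.sf(abs(z))),
        "sd": s,
        "unit": "per 1 SD",
    }


def _screen_row(df, covariates, biomarker, analysis, ties, alpha):
    try:
        fit = fit_cox(df, covariates, ties=ties)
        rep = per_sd_report(fit, df, biomarker)
    except (ValueError, ConvergenceError) as exc:
        return {
            "variable": biomarker,
            "n": int(df[["time", "event", *covariates]].dropna().shape[0]),
            "n_events": np.nan,
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "significant": False,
            "analysis": analysis,
            "note": str(exc),
        }
    rep.pop("sd")
    rep.pop("unit")
    rep["significant"] = rep["p"] <= alpha
    rep["analysis"] = analysis
    rep["note"] = "" if fit.converged else fit.message
    return rep


def univariate_screen(
    df: pd.DataFrame,
    biomarkers: list[str],
    ties: str = "efron",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One single-covariate Cox fit per biomarker on its complete cases.

    Per-biomarker N varies with each marker's missingness. Biomarkers with
    fewer than 2 events among complete cases (or otherwise degenerate) yield
    a missing-flagged row carrying the failure reason in ``note``.
    """
    rows = []
    for b in biomarkers:
        sub = df[["time", "event", b]].dropna()
        if sub["event"].sum() < 2:
            rows.append(
                {
                    "variable": b,
                    "n": len(sub),
                    "n_events": int(sub["event"].sum()),
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "significant": False,
                    "analysis": "univariate",
                    "note": "fewer than 2 events among complete cases",
                }
            )
            continue
        rows.append(_screen_row(df, [b], b, "univariate", ties, alpha))
    return pd.DataFrame(rows)


DEFAULT_ADJUSTERS = ("preop_psa", "age", "primary_pattern", "non_localized")


def adjusted_screen(
    df: pd.DataFrame,
    biomarkers: list[str],
    adjusters: tuple[str, ...] = DEFAULT_ADJUSTERS,
    ties: str = "efron",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-biomarker Cox fits adjusted for clinicopathologic covariates.

    Each model contains one biomarker plus the adjusters (pre-operative PSA,
    age at prostatectomy, primary Gleason pattern group, and the composite
    non-localized tumor indicator by default); only the biomarker row is
    reported, per SD. Collinear adjusters raise with the offending pair.
    """
    adjusters = list(adjusters)
    sub = df[list(adjusters)].dropna()
    if len(sub) >= 2:
        corr = sub.corr().to_numpy()
        for i in range(len(adjusters)):
            for j in range(i + 1, len(adjusters)):
                if abs(corr[i, j]) > 0.9999:
                    raise ValueError(
                        f"collinear adjusters: {adjusters[i]!r} and {adjusters[j]!r}"
                    )
    rows = [
        _screen_row(df, [b, *adjusters], b, "multivariate", ties, alpha)
        for b in biomarkers
    ]
    return pd.DataFrame(rows)
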