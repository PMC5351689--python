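"""Survival stratification: Cox screening, ROC/Youden cut-offs, KM/log-rank.

The statistical chain mirrors standard prognostic-imaging practice:

1. a multivariable Cox proportional-hazards screen over the z-scored
   heterogeneity features (Breslow tie handling, Newton iteration);
2. per-feature ROC analysis against the event-vs-censored label, with
   the Youden index J = sensitivity + specificity - 1 choosing the
   cut-off and a Hanley-McNeil confidence interval on the AUC deciding
   significance (0.5 outside the 95% CI);
3. Kaplan-Meier curves of the cut-off-defined low/high-risk groups,
   compared by the two-group log-rank test, with per-group hazard
   ratios from the observed/expected (O/E) estimator.

Labelling events-within-follow-up against censored patients ignores
censoring time in the ROC step; this mirrors the conventional (if
imperfect) clinical usage and is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, StratificationError

DEFAULT_FEATURES = (
    "cov",
    "skewness",
    "entropy",
    "homogeneity",
    "correlation",
    "contrast",
    "short_zone_emphasis",
    "size_variation",
)

ROC_LABEL_NOTE = "labels are event-within-follow-up vs censored; censoring time ignored"


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow partial likelihood, Newton iteration)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    outcome: str
    covariates: list[str]
    table: pd.DataFrame  # index: covariate; columns: coef, hr, se, z, p
    n: int
    n_events: int
    log_likelihood: float
    standardized: bool = True


def _breslow_quantities(times, events, X, beta):
    """Log-likelihood, gradient and Hessian of the Breslow partial likelihood."""
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    Xs = X[order]
    eta = Xs @ beta
    w = np.exp(eta)
    # reverse cumulative sums: S0[k] = sum_{j>=k} w_j etc. over the
    # ascending-time ordering; the risk set at time t_i is {j : t_j >= t_i}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    outer = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    S2 = np.cumsum(outer[::-1], axis=0)[::-1]
    # ties: every subject at a tied time shares the risk set starting at
    # the first index with that time
    first = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(e)
    idx = first[ev]
    s0 = S0[idx]
    m = S1[idx] / s0[:, None]
    ll = float(np.sum(eta[ev] - np.log(s0)))
    grad = np.sum(Xs[ev] - m, axis=0)
    hess = -np.sum(S2[idx] / s0[:, None, None] - m[:, :, None] * m[:, None, :], axis=0)
    return ll, grad, hess


def fit_cox(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton maximization of the Breslow partial likelihood.

    Returns (beta, covariance, log-likelihood).  Raises
    :class:`ConvergenceError` on non-convergence or monotone likelihood
    (perfect separation), naming the offending covariate.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, hess = _breslow_quantities(times, events, X, beta)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            worst = names[int(np.argmax(np.abs(grad)))]
            raise ConvergenceError(
                f"singular information matrix; covariate {worst!r} may be degenerate"
            ) from exc
        # step-halving line search on the partial likelihood
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _breslow_quantities(times, events, X, cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 40.0:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone partial likelihood (perfect separation) on covariate {worst!r}"
            )
    else:
        worst = names[int(np.argmax(np.abs(grad)))]
        raise ConvergenceError(
            f"Cox fit did not converge in {max_iter} iterations; worst gradient on {worst!r}"
        )
    # monotone likelihood: every event term converges to probability one
    # (the partial likelihood approaches its upper bound of 0), so the
    # gradient vanishes at a diverging coefficient with exploding variance
    if ll > -1e-6 * max(int(events.sum()), 1):
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"monotone partial likelihood (perfect separation) on covariate {worst!r}"
        )
    cov = np.linalg.inv(-hess)
    return beta, cov, ll


def cox_multivariable(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str,
    standardize: bool = True,
) -> CoxResult:
    """Multivariable Cox regression of PFS or OS on the given covariates.

    Covariates are z-scored before fitting (hazard ratios are per SD)
    unless ``standardize`` is disabled.  Requires at least 2 events.
    """
    outcome = outcome.lower()
    if outcome not in ("pfs", "os"):
        raise StratificationError(f"outcome must be 'pfs' or 'os', got {outcome!r}")
    tcol, ecol = f"{outcome}_months", f"{outcome}_event"
    missing = [c for c in list(covariates) + [tcol, ecol] if c not in cohort.columns]
    if missing:
        raise StratificationError(f"cohort frame is missing columns: {missing}")
    times = cohort[tcol].to_numpy(dtype=float)
    events = cohort[ecol].to_numpy(dtype=bool)
    if events.sum() < 2:
        raise StratificationError(
            f"need at least 2 observed {outcome.upper()} events, got {int(events.sum())}"
        )
    X = cohort[list(covariates)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = [c for c in covariates if not np.all(np.isfinite(cohort[c]))]
        raise StratificationError(f"non-finite covariate values in {bad}")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            bad = [covariates[i] for i in np.flatnonzero(zero)]
            raise StratificationError(f"constant covariates cannot be standardized: {bad}")
        X = (X - X.mean(axis=0)) / sd
    beta, cov, ll = fit_cox(times, events, X, list(covariates))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"coef": beta, "hr": np.exp(beta), "se": se, "z": z, "p": pvals},
        index=list(covariates),
    )
    return CoxResult(
        outcome=outcome.upper(),
        covariates=list(covariates),
        table=table,
        n=len(cohort),
        n_events=int(events.sum()),
        log_likelihood=ll,
        standardized=standardize,
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    direction: str  # '>' or '<=' : the side classified as positive/adverse
    sensitivity_pct: float
    specificity_pct: float
    youden_j: float
    significant: bool
    p_value: float
    n_positive: int
    n_negative: int
    note: str = ROC_LABEL_NOTE


def event_labels(cohort: pd.DataFrame, outcome: str) -> np.ndarray:
    """Binary outcome labels: event observed within follow-up vs censored."""
    ecol = f"{outcome.lower()}_event"
    if ecol not in cohort.columns:
        raise StratificationError(f"cohort frame has no column {ecol!r}")
    return cohort[ecol].to_numpy(dtype=bool).astype(int)


def _auc_mann_whitney(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC for 'higher value -> positive' via midranks (tie-corrected)."""
    ranks = stats.rankdata(values)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    r_pos = ranks[labels == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_youden(values, labels) -> RocResult:
    """ROC analysis with Youden-index cut-off selection.

    The orientation is chosen so AUC >= 0.5 ('>' when high values are
    adverse, '<=' otherwise); candidate cut-offs sit at midpoints between
    consecutive distinct values; ties in J break toward higher
    specificity.  The AUC confidence interval uses the Hanley-McNeil
    standard error with normal quantiles, truncated to [0, 1], and the
    feature is flagged significant when 0.5 lies outside the CI.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise StratificationError("labels must be binary 0/1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise StratificationError(
            f"both classes required for ROC (got {n_pos} positives, {n_neg} negatives)"
        )
    auc_high = _auc_mann_whitney(values, labels)
    if auc_high >= 0.5:
        direction, auc = ">", auc_high
    else:
        direction, auc = "<=", 1.0 - auc_high

    uniq = np.unique(values)
    if len(uniq) < 2:
        raise StratificationError("feature is constant; no cut-off exists")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    pos = values[labels == 1]
    neg = values[labels == 0]
    best = None
    for c in cuts:
        if direction == ">":
            sens = float((pos > c).mean())
            spec = float((neg <= c).mean())
        else:
            sens = float((pos <= c).mean())
            spec = float((neg > c).mean())
        j = sens + spec - 1.0
        key = (j, spec, c if direction == ">" else -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, j)
    _, cutoff, sens, spec, j = best

    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    zq = stats.norm.ppf(0.975)
    ci_low = float(np.clip(auc - zq * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + zq * se, 0.0, 1.0))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return RocResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=float(cutoff),
        direction=direction,
        sensitivity_pct=100.0 * sens,
        specificity_pct=100.0 * spec,
        youden_j=j,
        significant=not (ci_low <= 0.5 <= ci_high),
        p_value=p,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def dichotomize(values, roc: RocResult) -> np.ndarray:
    """Split patients into 'low_risk'/'high_risk' by the ROC cut-off.

    The adverse side (per the ROC direction, boundary included for '<=')
    becomes high_risk.  Both groups must be non-empty.
    """
    values = np.asarray(values, dtype=float)
    if roc.direction == ">":
        high = values > roc.cutoff
    else:
        high = values <= roc.cutoff
    if high.all() or (~high).all():
        raise StratificationError(
            f"cut-off {roc.cutoff} puts every patient on one side; non-informative split"
        )
    return np.where(high, "high_risk", "low_risk")


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else np.nan


@dataclass
class KmResult:
    curves: dict[str, KmCurve]
    chi2: float
    p_value: float
    hazard_ratios: dict[str, tuple[float, float, float]]  # group -> (hr, lo, hi)
    observed: dict[str, float] = field(default_factory=dict)
    expected: dict[str, float] = field(default_factory=dict)


def km_curve(times, events) -> KmCurve:
    """Product-limit survival estimator with number-at-risk bookkeeping."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = len(times)
    if n == 0:
        raise StratificationError("empty group")
    event_times = np.unique(times[events])
    surv = []
    risk = []
    s = 1.0
    for t in event_times:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
        risk.append(at_risk)
    return KmCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(risk),
        n=n,
        n_events=int(events.sum()),
    )


def km_logrank(times, events, groups) -> KmResult:
    """Two-group Kaplan-Meier comparison with O/E hazard ratios.

    The log-rank statistic is (O1 - E1)^2 / V with the hypergeometric
    variance summed over distinct event times; per-group hazard ratios
    are (O_g/E_g) / (O_other/E_other) with log-scale confidence
    intervals exp(log HR +/- 1.96 sqrt(1/E1 + 1/E2)).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise StratificationError(f"exactly two groups required, got {labels}")
    g1 = groups == labels[0]
    g2 = ~g1
    if not g1.any() or not g2.any():
        raise StratificationError("both groups must be non-empty")

    event_times = np.unique(times[events])
    O1 = E1 = V = 0.0
    O2 = E2 = 0.0
    for t in event_times:
        at = times >= t
        n1 = int((at & g1).sum())
        n2 = int((at & g2).sum())
        ntot = n1 + n2
        d = int(((times == t) & events).sum())
        d1 = int(((times == t) & events & g1).sum())
        O1 += d1
        O2 += d - d1
        E1 += d * n1 / ntot
        E2 += d * n2 / ntot
        if ntot > 1:
            V += d * (n1 / ntot) * (n2 / ntot) * (ntot - d) / (ntot - 1)
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if V > 0 else 1.0

    def hr_pair(oa, ea, ob, eb):
        if ea == 0 or eb == 0:
            return (np.nan, np.nan, np.nan)
        if ob == 0 or oa == 0:
            hr = (oa / ea) / (ob / eb) if ob > 0 else np.inf
            return (float(hr), np.nan, np.nan)
        hr = (oa / ea) / (ob / eb)
        se = np.sqrt(1.0 / ea + 1.0 / eb)
        zq = stats.norm.ppf(0.975)
        return (float(hr), float(hr * np.exp(-zq * se)), float(hr * np.exp(zq * se)))

    result = KmResult(
        curves={
            labels[0]: km_curve(times[g1], events[g1]),
            labels[1]: km_curve(times[g2], events[g2]),
        },
        chi2=float(chi2),
        p_value=p,
        hazard_ratios={
            labels[0]: hr_pair(O1, E1, O2, E2),
            labels[1]: hr_pair(O2, E2, O1, E1),
        },
        observed={labels[0]: O1, labels[1]: O2},
        expected={labels[0]: E1, labels[1]: E2},
    )
    return result


def logrank_many(times: np.ndarray, events: np.ndarray, groups_bool: np.ndarray) -> tuple[float, float]:
    """Fast two-group log-rank (chi2, p) for simulation studies.

    ``groups_bool`` marks membership of group 1.  Vectorized over the
    distinct event times of the pooled sample.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = groups_bool[order]
    n = len(t)
    # at-risk counts just before each index's time
    total_at = n - np.searchsorted(t, t, side="left")
    g_cum = np.concatenate([[0], np.cumsum(g)])
    n1_at = g.sum() - g_cum[np.searchsorted(t, t, side="left")]
    ut, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(float), first)
    d1 = np.add.reduceat((e & g).astype(float), first)
    n1 = n1_at[first].astype(float)
    ntot = total_at[first].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        E1 = d * n1 / ntot
        V = np.where(
            ntot > 1, d * (n1 / ntot) * (1 - n1 / ntot) * (ntot - d) / (ntot - 1), 0.0
        )
    keep = d > 0
    O1 = d1[keep].sum()
    e1 = E1[keep].sum()
    v = V[keep].sum()
    chi2 = (O1 - e1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    return float(chi2), p
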