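"""Outcome association of repertoire statistics.

Patients are dichotomized at the cohort median of a repertoire statistic
(strictly below-median = low), survival is summarized by Kaplan-Meier
product-limit curves, group differences are tested both by the classical
log-rank statistic and by the likelihood-ratio test of a Cox proportional
hazards model on the group indicator, and hazard ratios with 95% confidence
intervals come from a Cox model maximized by Newton-Raphson with Breslow
handling of tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class CoxResult:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    wald_p: np.ndarray
    loglik: float
    loglik_null: float
    score_at_null: np.ndarray
    info_at_null: np.ndarray
    converged: bool
    unbounded: bool = False

    @property
    def lrt_p(self) -> float:
        """Likelihood-ratio test p-value against the null model."""
        chi2 = 2.0 * (self.loglik - self.loglik_null)
        return float(stats.chi2.sf(max(chi2, 0.0), df=len(self.names)))

    @property
    def score_statistic(self) -> float:
        """Score (Rao) statistic at beta = 0; equals the log-rank statistic
        for a single binary covariate without tied event times."""
        u, i = self.score_at_null, self.info_at_null
        return float(u @ np.linalg.solve(i, u))


def median_split(values: dict[str, float]) -> dict[str, str]:
    """Dichotomize patients at the cohort median.

    ``low`` = value strictly below the median; values at the median join
    the high group. All-equal values make the split degenerate and raise.
    """
    vals = {k: v for k, v in values.items() if v is not None and not np.isnan(v)}
    if len(vals) < 2:
        raise ValueError("median split needs at least 2 non-missing values")
    arr = np.array(list(vals.values()), dtype=float)
    med = float(np.median(arr))
    if np.allclose(arr, arr[0]):
        raise ValueError("all values equal; median split is degenerate")
    return {k: ("low" if v < med else "high") for k, v in vals.items()}


def _to_arrays(records):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([bool(r.event) for r in records])
    if (t < 0).any():
        raise ValueError("negative survival time")
    return t, e


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit survival curve."""
    if not records:
        raise ValueError("no records")
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array(
        [int((t >= u).sum()) for u in times], dtype=int
    )
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def group_test(records, groups: dict[str, str]):
    """Log-rank and Cox likelihood-ratio tests between two groups.

    Returns ``(logrank_chi2, logrank_p, cox_lrt_p)``.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    recs = [r for r in records if r.patient_id in groups]
    g = np.array([groups[r.patient_id] for r in recs])
    if (g == labels[0]).sum() == 0 or (g == labels[1]).sum() == 0:
        raise ValueError("a group has zero subjects")
    t, e = _to_arrays(recs)
    mask = g == labels[1]
    lr = logrank_test(t[mask], t[~mask], event_observed_A=e[mask],
                      event_observed_B=e[~mask])
    x = mask.astype(float)[:, None]
    cox = _cox_newton(t, e, x, ["group"])
    return float(lr.test_statistic), float(lr.p_value), cox.lrt_p


def cox_fit(records, covariate_names) -> CoxResult:
    """Cox proportional-hazards fit over the named covariates.

    Newton-Raphson on the Breslow partial likelihood; convergence when the
    largest score component falls below 1e-8 (at most 50 iterations).
    Monotone likelihood (complete separation) is reported via the
    ``unbounded`` flag rather than raised.
    """
    if not records:
        raise ValueError("no records")
    t, e = _to_arrays(records)
    if not e.any():
        raise ValueError("no events observed")
    x = np.array(
        [[float(r.covariates[c]) for c in covariate_names] for r in records]
    )
    return _cox_newton(t, e, x, list(covariate_names))


def _breslow_quantities(t, e, x, beta):
    """Log partial likelihood, score and information under Breslow ties."""
    order = np.argsort(-t, kind="stable")  # decreasing time: risk sets grow
    t_s, e_s, x_s = t[order], e[order], x[order]
    eta = x_s @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x_s, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x_s[:, :, None] * x_s[:, None, :]), axis=0)
    # group tied times; the risk set of a group is everyone up to its end
    p = x.shape[1]
    new = np.r_[True, t_s[1:] != t_s[:-1]]
    ends = np.r_[np.flatnonzero(new)[1:], len(t_s)] - 1
    gid = np.cumsum(new) - 1
    n_groups = len(ends)
    d = np.bincount(gid[e_s], minlength=n_groups).astype(float)
    has = d > 0
    S0, S1, S2 = s0[ends][has], s1[ends][has], s2[ends][has]
    dh = d[has]
    eta_ev = np.bincount(gid[e_s], weights=eta[e_s], minlength=n_groups)[has]
    x_ev = np.stack(
        [np.bincount(gid[e_s], weights=x_s[e_s, j], minlength=n_groups)[has]
         for j in range(p)], axis=1)
    loglik = float(eta_ev.sum() - (dh * np.log(S0)).sum())
    score = x_ev.sum(axis=0) - (dh[:, None] * S1 / S0[:, None]).sum(axis=0)
    info = (dh[:, None, None]
            * (S2 / S0[:, None, None]
               - S1[:, :, None] * S1[:, None, :] / S0[:, None, None] ** 2)
            ).sum(axis=0)
    return loglik, score, info


def _cox_newton(t, e, x, names, tol: float = 1e-8, max_iter: int = 50) -> CoxResult:
    p = x.shape[1]
    # center covariates for numerical stability (beta unchanged)
    xc = x - x.mean(axis=0)
    beta = np.zeros(p)
    ll0, u0, i0 = _breslow_quantities(t, e, xc, beta)
    loglik, score, info = ll0, u0, i0
    converged = False
    unbounded = False
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            unbounded = True
            break
        if np.max(np.abs(step)) < 1e-10:  # parameter change below noise
            converged = True
            break
        # step-halving to keep the likelihood increasing (tolerance scaled
        # to the loglik magnitude so float noise cannot reject a good step)
        ll_tol = 1e-9 * (abs(loglik) + 1.0)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, sc_new, in_new = _breslow_quantities(t, e, xc, cand)
            if ll_new >= loglik - ll_tol:
                beta, loglik, score, info = cand, ll_new, sc_new, in_new
                break
            factor /= 2.0
        else:
            break
        if np.max(np.abs(beta)) > 20:  # hazard ratio beyond e^20: separation
            unbounded = True
            break
    if not converged and np.max(np.abs(score)) < 1e-4:
        converged = True  # flat likelihood near optimum
    with np.errstate(over="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.inf)
            unbounded = True
        z = np.divide(beta, se, out=np.zeros(p), where=se > 0)
        return CoxResult(
            names=names,
            beta=beta,
            se=se,
            hr=np.exp(beta),
            ci_low=np.exp(beta - 1.959963984540054 * se),
            ci_high=np.exp(beta + 1.959963984540054 * se),
            wald_p=2.0 * stats.norm.sf(np.abs(z)),
            loglik=loglik,
            loglik_null=ll0,
            score_at_null=u0,
            info_at_null=i0,
            converged=converged,
            unbounded=unbounded,
        )
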