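"""Survival analytics: concordance, Kaplan-Meier, log-rank, Cox PH.

Conventions
-----------
* Comparable pair: ordered (i, j) with t_i < t_j and subject i's event
  observed (Harrell). Event-event time ties are excluded; score ties
  credit 0.5.
* Kaplan-Meier and the two-group log-rank test are delegated to
  ``lifelines``.
* Cox proportional hazards is fit in-module by Newton-Raphson on the
  partial likelihood with Breslow handling of tied event times (Efron
  available), so that the classical identity "log-rank statistic =
  squared Cox score test for a binary group covariate" holds exactly.
  Hazard ratios carry Wald 95% CIs on the log scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "concordance_index",
    "KMCurve",
    "kaplan_meier",
    "logrank_test",
    "CoxFit",
    "cox_fit",
    "ctx_benefit_analysis",
]


class SeparationError(RuntimeError):
    """Cox fit diverged: a covariate perfectly orders the events."""


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def comparable_pair_mask(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (i, j) of all comparable pairs: t_i < t_j, event_i = 1."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ii, jj = [], []
    for i in np.nonzero(event == 1)[0]:
        js = np.nonzero(time > time[i])[0]
        ii.extend([i] * len(js))
        jj.extend(js)
    return np.array(ii, dtype=int), np.array(jj, dtype=int)


def concordance_index(scores, time, event) -> float:
    """Harrell's C-index of risk scores against censored survival.

    The fraction of comparable pairs in which the member with the shorter
    observed survival has the strictly higher risk score; score ties
    credit 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    ii, jj = comparable_pair_mask(time, event)
    if ii.size == 0:
        raise ValueError("no comparable pairs; C-index undefined")
    d = scores[ii] - scores[jj]
    concordant = (d > 0).sum()
    tied = (d == 0).sum()
    return float((concordant + 0.5 * tied) / ii.size)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate with the risk-set bookkeeping."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return float(s)


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier estimate for one group (lifelines under the hood)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    # the survival curve only steps at times with observed events
    ev = kmf.event_table[kmf.event_table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in times])
    return KMCurve(
        event_times=times,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        survival=surv,
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(group_labels, time, event) -> dict:
    """Two-group log-rank test (hypergeometric variance, chi2 with 1 df)."""
    labels = np.asarray(group_labels)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {uniq.size}")
    a = labels == uniq[0]
    b = ~a
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("each group must be non-empty")
    res = _ll_logrank(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox PH fit: coefficients, Wald inference, likelihood diagnostics."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    ties: str
    score_chi2_null: float = np.nan  # score test at beta=0 (1-covariate fits)

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - 1.96 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + 1.96 * self.se)

    @property
    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def lr_p(self) -> float:
        lr = 2.0 * (self.loglik - self.loglik_null)
        return float(stats.chi2.sf(lr, df=len(self.coef)))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratio,
                "HR_ci_low": self.ci_lower,
                "HR_ci_high": self.ci_upper,
                "p": self.wald_p,
            },
            index=self.covariates,
        )


def cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray,
               ties: str = "breslow") -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, gradient and information (Breslow/Efron ties)."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # descending time
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    w = np.exp(eta)
    # running risk-set sums (descending time -> cumulative)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        # block [i..j] shares one time; risk set = everything up to j
        ev_idx = [k for k in range(i, j + 1) if es[k] == 1]
        d = len(ev_idx)
        if d > 0:
            s0, s1, s2 = S0[j], S1[j], S2[j]
            sum_eta = sum(eta[k] for k in ev_idx)
            sum_x = Xs[ev_idx].sum(axis=0)
            if ties == "breslow" or d == 1:
                ll += sum_eta - d * np.log(s0)
                grad += sum_x - d * (s1 / s0)
                info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            elif ties == "efron":
                wd = w[ev_idx].sum()
                s1d = (w[ev_idx, None] * Xs[ev_idx]).sum(axis=0)
                s2d = (w[ev_idx, None, None] * (Xs[ev_idx][:, :, None] * Xs[ev_idx][:, None, :])).sum(axis=0)
                ll += sum_eta
                grad += sum_x
                for l in range(d):
                    f = l / d
                    s0l = s0 - f * wd
                    s1l = s1 - f * s1d
                    s2l = s2 - f * s2d
                    ll -= np.log(s0l)
                    grad -= s1l / s0l
                    info += s2l / s0l - np.outer(s1l, s1l) / s0l**2
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j + 1
    return float(ll), grad, info


def cox_fit(covariates: pd.DataFrame, time, event, ties: str = "breslow",
            max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson Cox PH fit with Wald and likelihood-ratio inference.

    Raises :class:`SeparationError` when the coefficient diverges (a
    covariate that strictly orders the events drives |beta| to infinity)
    and ``ValueError`` for degenerate inputs (constant covariates, fewer
    events than covariates).
    """
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if event.sum() < p:
        raise ValueError(f"{int(event.sum())} events cannot support {p} covariates")
    if np.any(X.std(axis=0) == 0):
        const = [names[k] for k in range(p) if X[:, k].std() == 0]
        raise ValueError(f"constant covariate(s): {const}")

    beta = np.zeros(p)
    ll_null, grad0, info0 = cox_loglik(beta, X, time, event, ties=ties)
    score_chi2 = np.nan
    try:
        score_chi2 = float(grad0 @ np.linalg.solve(info0, grad0))
    except np.linalg.LinAlgError:
        pass

    ll_prev = ll_null
    for it in range(1, max_iter + 1):
        ll, grad, info = cox_loglik(beta, X, time, event, ties=ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix at iteration {it}: {exc}")
        # step-halving for robustness
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            ll_new, _, _ = cox_loglik(candidate, X, time, event, ties=ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.any(np.abs(beta) > 20):
            raise SeparationError(
                f"coefficient diverged (|beta| > 20 at iteration {it}); "
                "likely monotone likelihood / separation"
            )
        if np.max(np.abs(factor * step)) < tol or abs(ll_new - ll_prev) < tol:
            ll_prev = ll_new
            break
        ll_prev = ll_new
    else:
        raise SeparationError(f"Newton did not converge in {max_iter} iterations "
                              f"(last |step| {np.max(np.abs(step)):.2e})")

    ll_final, _, info_final = cox_loglik(beta, X, time, event, ties=ties)
    cov = np.linalg.inv(info_final)
    se = np.sqrt(np.diag(cov))
    return CoxFit(covariates=names, coef=beta, se=se, loglik=ll_final,
                  loglik_null=ll_null, iterations=it, ties=ties,
                  score_chi2_null=score_chi2)


# ---------------------------------------------------------------------------
# treatment-benefit stratification
# ---------------------------------------------------------------------------

def ctx_benefit_analysis(scores: pd.Series, clinical: pd.DataFrame) -> dict:
    """Adjuvant-chemotherapy benefit within median-split risk strata.

    Restricts to stage III samples with a recorded CTX flag, splits them
    at the median risk score, and within each stratum compares treated vs
    untreated relapse-free survival by Kaplan-Meier, log-rank, and a
    univariate Cox HR for CTX (HR < 1 = benefit). Strata where the test
    is impossible (one arm < 2 samples, or a constant flag) are skipped
    with a warning.
    """
    from netprog.ssvm import median_stratify

    df = clinical.loc[scores.index].copy()
    df = df[(df["stage"] == "III") & df["ctx"].notna()]
    if df.empty:
        raise ValueError("no stage III samples with CTX information")
    s = scores.loc[df.index]
    groups = median_stratify(s)
    out: dict[str, dict] = {}
    for label in ("high-risk", "low-risk"):
        idx = groups[groups == label].index
        sub = df.loc[idx]
        ctx = sub["ctx"].astype(int)
        arm_sizes = ctx.value_counts()
        if ctx.nunique() < 2 or arm_sizes.min() < 2:
            warnings.warn(f"{label} stratum skipped: insufficient samples per CTX arm")
            out[label] = {"skipped": True, "n": int(len(sub))}
            continue
        lr = logrank_test(ctx.to_numpy(), sub["time"], sub["event"])
        try:
            fit = cox_fit(pd.DataFrame({"ctx": ctx.to_numpy(dtype=float)},
                                       index=sub.index),
                          sub["time"], sub["event"])
            hr = float(fit.hazard_ratio[0])
            hr_ci = (float(fit.ci_lower[0]), float(fit.ci_upper[0]))
            cox_p = float(fit.wald_p[0])
        except (SeparationError, ValueError) as exc:
            # tiny strata can have monotone likelihoods; keep the log-rank
            # comparison and flag the unavailable hazard ratio
            warnings.warn(f"{label} stratum Cox HR unavailable: {exc}")
            hr, hr_ci, cox_p = float("nan"), (float("nan"), float("nan")), float("nan")
        km = {
            "ctx": kaplan_meier(sub.loc[ctx == 1, "time"], sub.loc[ctx == 1, "event"]),
            "no_ctx": kaplan_meier(sub.loc[ctx == 0, "time"], sub.loc[ctx == 0, "event"]),
        }
        out[label] = {
            "skipped": False,
            "n": int(len(sub)),
            "n_ctx": int((ctx == 1).sum()),
            "n_no_ctx": int((ctx == 0).sum()),
            "logrank_p": lr["p"],
            "hr_ctx": hr,
            "hr_ci": hr_ci,
            "cox_p": cox_p,
            "km": km,
        }
    return out
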