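"""Risk-group assignment, survival endpoints, Kaplan-Meier, log-rank, Cox.

Patients are assigned to one of three prognostic groups from stage,
MYCN status, age at diagnosis (12-month cutoff) and outcome:

* HR-DOD  — high-risk, died of disease: stage 2/3 with MYCN
  amplification; stage 4 under 12 months with MYCN amplification; or
  stage 4 over 12 months (any MYCN), each with death of disease.
* HR-SURV — the same high-risk criteria, alive with follow-up over
  1,000 days.
* LR-SURV — stage 1/2 MYCN single copy, or stage 3 single copy under
  12 months, alive with follow-up over 1,000 days.

Overall survival (OS) is time to disease-related death or last
follow-up; event-free survival (EFS) is time to relapse or death.
The log-rank test is the Mantel-Cox chi-square, optionally summing
observed-minus-expected and variance over strata; the Cox model is a
single-covariate proportional-hazards fit with Breslow tie handling,
whose score statistic at beta = 0 coincides with the log-rank
chi-square for a binary covariate without ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .assoc_stats import TestResult

AGE_CUTOFF_DAYS = 365  # 12 months
FOLLOWUP_MIN_DAYS = 1000

LR_SURV = "LR-SURV"
HR_DOD = "HR-DOD"
HR_SURV = "HR-SURV"
UNASSIGNED = "unassigned"


def _is_high_risk(stage: str, mycn: str, age_days: float) -> bool:
    amplified = mycn == "amplified"
    if stage in {"2", "3"} and amplified:
        return True
    if stage == "4" and age_days < AGE_CUTOFF_DAYS and amplified:
        return True
    if stage == "4" and age_days >= AGE_CUTOFF_DAYS:
        return True
    return False


def _is_low_risk(stage: str, mycn: str, age_days: float) -> bool:
    if mycn != "single_copy":
        return False
    if stage in {"1", "2"}:
        return True
    return stage == "3" and age_days < AGE_CUTOFF_DAYS


def assign_risk_group(record: pd.Series | dict) -> str:
    """Assign a clinical record to LR-SURV / HR-DOD / HR-SURV / unassigned."""
    r = dict(record)
    stage = str(r["stage"])
    mycn, age = r["mycn"], float(r["age_days"])
    outcome, fup = r["outcome"], float(r["followup_days"])
    if outcome not in {"alive", "dod"}:
        raise ValueError(f"invalid outcome {outcome!r}")
    if outcome == "dod":
        return HR_DOD if _is_high_risk(stage, mycn, age) else UNASSIGNED
    if fup > FOLLOWUP_MIN_DAYS:
        if _is_high_risk(stage, mycn, age):
            return HR_SURV
        if _is_low_risk(stage, mycn, age):
            return LR_SURV
    return UNASSIGNED


def assign_risk_groups(clinical: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [assign_risk_group(row) for _, row in clinical.iterrows()],
        index=clinical["sample"].to_numpy(),
        name="risk_group",
    )


def os_efs(clinical: pd.DataFrame) -> pd.DataFrame:
    """Overall and event-free survival records for each patient.

    OS events are disease-related deaths; EFS events occur at the
    earlier of relapse and death; otherwise the record is censored at
    last follow-up.
    """
    rows = []
    for r in clinical.itertuples():
        fup = float(r.followup_days)
        dead = r.outcome == "dod"
        relapse = None if pd.isna(r.relapse_days) else float(r.relapse_days)
        if relapse is not None and relapse > fup:
            raise ValueError(
                f"sample {r.sample}: relapse day {relapse} after follow-up end {fup}"
            )
        if relapse is not None:
            efs_time, efs_event = relapse, 1
        elif dead:
            efs_time, efs_event = fup, 1
        else:
            efs_time, efs_event = fup, 0
        rows.append(
            {
                "sample": r.sample,
                "os_time": fup,
                "os_event": int(dead),
                "efs_time": efs_time,
                "efs_event": efs_event,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


def administrative_censor(
    time: np.ndarray, event: np.ndarray, censor_at: float | None
) -> tuple[np.ndarray, np.ndarray]:
    if censor_at is None:
        return time, event
    time = np.asarray(time, dtype=float).copy()
    event = np.asarray(event, dtype=int).copy()
    late = time > censor_at
    time[late] = censor_at
    event[late] = 0
    return time, event


def km_curve(time, event, censor_at: float | None = 2000) -> KMCurve:
    """Product-limit survival estimate, administratively censored
    (default 2,000 days, matching how the study plots follow-up)."""
    time, event = administrative_censor(
        np.asarray(time, dtype=float), np.asarray(event, dtype=int), censor_at
    )
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table
    return KMCurve(
        times=table.index.to_numpy(dtype=float),
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        at_risk=table["at_risk"].to_numpy(),
        censor_times=np.sort(time[event == 0]),
    )


def _logrank_moments(
    time: np.ndarray, event: np.ndarray, gidx: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-minus-expected vector and covariance for one stratum."""
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = int(((time == t) & (event == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(
            gidx[(time == t) & (event == 1)], minlength=k
        ).astype(float)
        frac = n_g / n_t
        o_minus_e += d_g - d_t * frac
        if n_t > 1:
            scale = d_t * (n_t - d_t) / (n_t - 1)
            cov += scale * (np.diag(frac) - np.outer(frac, frac))
    return o_minus_e, cov


def logrank(
    time, event, group, strata=None
) -> TestResult:
    """Mantel-Cox log-rank test across two or more groups.

    With ``strata``, observed-minus-expected and variance are summed
    over strata before forming the chi-square (df = groups - 1).
    Strata containing a single group contribute nothing.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    k = len(labels)
    gidx = np.searchsorted(labels, group)
    if strata is None:
        strata = np.zeros(len(time), dtype=int)
    strata = np.asarray(strata)
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for s in np.unique(strata):
        m = strata == s
        ome, c = _logrank_moments(time[m], event[m], gidx[m], k)
        o_minus_e += ome
        cov += c
    v = o_minus_e[:-1]
    c = cov[:-1, :-1]
    stat = float(v @ np.linalg.pinv(c) @ v)
    from scipy.stats import chi2

    p = float(chi2.sf(stat, df=k - 1))
    return TestResult(stat, p, "logrank_mantel_cox", df=k - 1)


@dataclass(frozen=True)
class CoxResult:
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float          # Wald
    se: float
    score_statistic: float  # score chi-square at beta = 0
    n_iter: int


def _cox_derivatives(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[float, float]:
    """Score and information of the Breslow partial likelihood."""
    order = np.argsort(-time)  # descending: risk sets grow as we walk
    t_s, e_s, x_s = time[order], event[order], x[order]
    exp_bx = np.exp(beta * x_s)
    s0 = np.cumsum(exp_bx)
    s1 = np.cumsum(x_s * exp_bx)
    s2 = np.cumsum(x_s**2 * exp_bx)
    # risk set at event time t: all with time >= t -> cumulative index of
    # the last tied position
    u = 0.0
    info = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        d_idx = [m for m in range(i, j + 1) if e_s[m] == 1]
        if d_idx:
            mean1 = s1[j] / s0[j]
            mean2 = s2[j] / s0[j]
            for m in d_idx:
                u += x_s[m] - mean1
                info += mean2 - mean1**2
        i = j + 1
    return u, info


def cox_score_test(time, event, covariate) -> TestResult:
    """Cox partial-likelihood score test at beta = 0.

    Defined even when the maximum-likelihood fit diverges (monotone
    likelihood); for a binary covariate without ties it equals the
    Mantel-Cox log-rank chi-square.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("covariate is constant: no information")
    u0, i0 = _cox_derivatives(0.0, time, event, x)
    stat = u0**2 / i0
    from scipy.stats import chi2

    return TestResult(float(stat), float(chi2.sf(stat, df=1)), "cox_score", df=1)


def cox_fit(
    time, event, covariate, tol: float = 1e-8, max_iter: int = 50
) -> CoxResult:
    """Single-covariate Cox proportional-hazards fit (Breslow ties).

    Newton-Raphson to |delta beta| < ``tol``; Wald confidence interval
    and p-value.  Raises on a constant covariate, absence of events, or
    a monotone likelihood (perfect separation).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("covariate is constant: no information")
    if event.sum() == 0:
        raise ValueError("no events")
    u0, i0 = _cox_derivatives(0.0, time, event, x)
    score_stat = u0**2 / i0
    beta = 0.0
    for it in range(1, max_iter + 1):
        u, info = _cox_derivatives(beta, time, event, x)
        if info <= 0:
            raise ValueError("non-convergence: flat partial likelihood")
        step = u / info
        beta += step
        if abs(beta) > 50:
            raise ValueError(
                "non-convergence: monotone likelihood (perfect separation?)"
            )
        if abs(step) < tol:
            break
    else:
        raise ValueError("Newton iterations did not converge")
    _, info = _cox_derivatives(beta, time, event, x)
    se = 1.0 / math.sqrt(info)
    from scipy.stats import norm

    z = beta / se
    p = 2 * float(norm.sf(abs(z)))
    return CoxResult(
        beta=beta,
        hr=math.exp(beta),
        ci_low=math.exp(beta - 1.959963984540054 * se),
        ci_high=math.exp(beta + 1.959963984540054 * se),
        p=p,
        se=se,
        score_statistic=float(score_stat),
        n_iter=it,
    )


def dichotomize(values: pd.Series) -> pd.Series:
    """Split values into ``low`` (< median) and ``high`` (>= median)."""
    v = pd.Series(values, dtype=float)
    if v.nunique() < 2:
        raise ValueError("all values equal: cannot dichotomize")
    med = float(v.median())
    return pd.Series(np.where(v < med, "low", "high"), index=v.index)
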