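"""Association of methylation calls with risk factors and groups.

Fisher's exact test (2x2 through scipy; larger tables by complete
enumeration of margin-fixed tables under the multivariate hypergeometric
null), the chi-square test without continuity correction,
Benjamini-Hochberg adjustment, sensitivity/specificity against outcome
groups, and group means with t confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ENUMERATION_GUARD = 200


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p: float
    method: str
    df: int | None = None
    p_adjusted: float | None = None


def _log_table_prob(table: np.ndarray, row_sums, col_sums, log_n_fact) -> float:
    from scipy.special import gammaln

    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - log_n_fact
        - gammaln(table + 1).sum()
    )


def _enumerate_fisher(table: np.ndarray) -> float:
    """Two-sided Fisher p by complete enumeration of tables with the
    observed margins; sums probabilities no larger than the observed
    table's (point-probability rule)."""
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())
    from scipy.special import gammaln

    log_n_fact = gammaln(n + 1)
    p_obs = _log_table_prob(table, row_sums, col_sums, log_n_fact)
    r, c = table.shape
    total = 0.0
    extreme = 0.0

    cells = np.zeros((r, c), dtype=int)

    def fill(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray):
        nonlocal total, extreme
        if i == r - 1:
            # last row determined by column remainders
            if j == 0:
                if (col_left < 0).any():
                    return
                cells[r - 1, :] = col_left
                lp = _log_table_prob(cells, row_sums, col_sums, log_n_fact)
                p = np.exp(lp)
                total += p
                if lp <= p_obs + 1e-10:
                    extreme += p
            return
        if j == c - 1:
            v = row_left[i]
            if v < 0 or v > col_left[j]:
                return
            cells[i, j] = v
            col2 = col_left.copy()
            col2[j] -= v
            row2 = row_left.copy()
            row2[i] = 0
            fill(i + 1, 0, row2, col2)
            return
        hi = min(row_left[i], col_left[j])
        for v in range(hi + 1):
            cells[i, j] = v
            row2 = row_left.copy()
            row2[i] -= v
            col2 = col_left.copy()
            col2[j] -= v
            fill(i, j + 1, row2, col2)

    fill(0, 0, row_sums.copy(), col_sums.copy())
    return min(extreme / total, 1.0)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on an r x c contingency table.

    For 2x2 tables the standard hypergeometric test is used; for larger
    tables all margin-preserving tables are enumerated (total count
    guarded at 200) and the probabilities of tables no more likely than
    the observed one are summed.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.shape == (2, 2):
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return TestResult(None, float(p), "fisher_exact")
    if t.sum() > ENUMERATION_GUARD:
        raise ValueError(
            f"total count {t.sum()} exceeds enumeration guard "
            f"{ENUMERATION_GUARD}; use chi_square instead"
        )
    return TestResult(None, _enumerate_fisher(t), "fisher_exact_rxc")


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(p), "chi_square", df=int(df))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def sens_spec(
    calls: pd.Series, labels: pd.Series,
    positive_label: str = "HR-DOD", negative_label: str = "LR-SURV",
) -> tuple[float, float]:
    """Sensitivity and specificity of one assay's methylation calls for
    discriminating outcome groups.

    Sensitivity is the methylated fraction among ``positive_label``
    samples; specificity the unmethylated fraction among
    ``negative_label`` samples.
    """
    labels = labels.reindex(calls.index)
    pos = calls[labels == positive_label]
    neg = calls[labels == negative_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    sens = float((pos == "M").sum() / len(pos))
    spec = float((neg == "U").sum() / len(neg))
    return sens, spec


def group_mean_ci(
    values: pd.Series, groups: pd.Series, level: float = 0.95
) -> pd.DataFrame:
    """Per-group mean with a t confidence interval (NaN CI when n = 1)."""
    groups = groups.reindex(values.index)
    rows = []
    for g, sub in values.groupby(groups):
        n = len(sub)
        mean = float(sub.mean())
        if n >= 2:
            se = float(sub.std(ddof=1)) / np.sqrt(n)
            tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
            lo, hi = mean - tcrit * se, mean + tcrit * se
        else:
            lo = hi = np.nan
        rows.append({"group": g, "n": n, "mean": mean, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows).set_index("group")
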