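"""RT-qPCR relative quantification and reference-gene normalization.

Relative quantities follow the delta-Cq model RQ = E**(Cq_min - Cq)
with amplification efficiency E (2 = perfect doubling), scaled per
assay to its lowest-Cq sample.  Expression is normalized by the
geometric mean of a panel of reference genes, sample by sample, so any
per-sample global offset (input amount, reverse-transcription yield)
cancels.  Group comparisons use the Mann-Whitney and Kruskal-Wallis
tests, exact where sample sizes allow.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_stats import TestResult


def relative_quantity(cq: pd.DataFrame | pd.Series, efficiency: float = 2.0):
    """Relative quantities from Cq values, per assay (row).

    The sample with the lowest Cq of an assay gets RQ = 1.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if isinstance(cq, pd.Series):
        return efficiency ** (cq.min() - cq)
    cq_min = cq.min(axis=1)
    return efficiency ** cq_min.to_numpy()[:, None] * efficiency ** (-cq)


def normalize(rq: pd.DataFrame, refs: list[str]) -> pd.DataFrame:
    """Normalize relative quantities by the geometric mean of reference
    genes, per sample.  Samples missing any reference are dropped with
    a warning; reference rows are removed from the output."""
    missing_refs = [r for r in refs if r not in rq.index]
    if missing_refs:
        raise ValueError(f"reference genes absent from matrix: {missing_refs}")
    ref_block = rq.loc[refs]
    bad = ref_block.isna().any(axis=0) | (ref_block <= 0).any(axis=0)
    if bad.any():
        warnings.warn(
            f"dropping samples without complete positive reference values: "
            f"{list(rq.columns[bad])}",
            stacklevel=2,
        )
    keep = rq.columns[~bad]
    geomean = np.exp(np.log(ref_block[keep]).mean(axis=0))
    out = rq.loc[[g for g in rq.index if g not in refs], keep] / geomean
    return out


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test; exact when both samples are small
    (min(n, m) <= 8) and tie-free, normal approximation with tie
    correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), f"mann_whitney_{method}")


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test (chi-square approximation, df = k - 1)."""
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if all(np.all(np.asarray(g) == np.asarray(groups[0])[0]) for g in groups):
        # identical constant groups: H = 0 by convention
        return TestResult(0.0, 1.0, "kruskal_wallis", df=len(groups) - 1)
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal_wallis", df=len(groups) - 1)
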