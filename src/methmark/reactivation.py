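"""Re-expression screening after demethylating (DAC) treatment.

Genes silenced by promoter methylation are expected to be re-expressed
when cells are treated with a demethylating agent.  This module provides
fold-change computation, counting of detection-call reactivation events
(absent in untreated, present in treated), the rank-product statistic
with a permutation estimate of the proportion of false positives (pfp),
and the screening filter combining both.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def log2_fold_change(treated: float, untreated: float) -> float:
    """log2 ratio of treated over untreated linear-scale expression."""
    if treated <= 0 or untreated <= 0:
        raise ValueError("expression values must be positive on the linear scale")
    return float(np.log2(treated / untreated))


def reactivation_events(
    call_untreated: pd.Series, call_treated: pd.Series
) -> int:
    """Number of cell lines where a probe flips absent -> present.

    Both series are indexed by cell line with values ``present``/``absent``.
    """
    if call_untreated.isna().any() or call_treated.isna().any():
        raise ValueError("missing detection call")
    u = call_untreated.reindex(call_treated.index)
    if u.isna().any():
        raise ValueError("cell lines of the two call sets differ")
    return int(((u == "absent") & (call_treated == "present")).sum())


def _rank_columns(fc: np.ndarray) -> np.ndarray:
    """Per-column ascending ranks of -fold-change (rank 1 = most upregulated).

    Ties receive average ranks.
    """
    ranks = np.empty_like(fc, dtype=float)
    for j in range(fc.shape[1]):
        col = fc[:, j]
        if np.all(col == col[0]):
            warnings.warn(
                f"constant fold changes in column {j}; ranks averaged",
                stacklevel=3,
            )
        ranks[:, j] = rankdata(-col, method="average")
    return ranks


def _rank_product(ranks: np.ndarray) -> np.ndarray:
    # geometric mean of per-line ranks, computed in log space
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product(
    fc_matrix: pd.DataFrame, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Rank-product upregulation statistic with permutation pfp.

    Parameters
    ----------
    fc_matrix : DataFrame
        Probes x cell lines of log2 fold changes (treated vs untreated).
    n_perm : int
        Number of within-line rank permutations for the null; >= 100 for
        any FDR use.
    seed : int
        Seed for the permutation RNG.

    Returns
    -------
    DataFrame indexed by probe with columns ``RP`` (geometric mean of
    per-line upregulation ranks), ``E_value`` (expected number of null
    probes at least as extreme), ``pfp`` (E divided by the probe's rank,
    truncated at 1 for reporting), ``p_value`` (the per-probe permutation
    p, E divided by the number of probes — uniform under the null) and
    one ``rank_<line>`` column per line.
    """
    if fc_matrix.shape[0] < 2:
        raise ValueError("need at least 2 probes")
    fc = fc_matrix.to_numpy(dtype=float)
    n_probes, n_lines = fc.shape
    ranks = _rank_columns(fc)
    rp = _rank_product(ranks)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_probes)
    for _ in range(n_perm):
        perm = np.empty_like(ranks)
        for j in range(n_lines):
            perm[:, j] = ranks[rng.permutation(n_probes), j]
        rp_null = np.sort(_rank_product(perm))
        # count of null RPs <= each observed RP
        exceed += np.searchsorted(rp_null, rp, side="right")
    e_value = exceed / n_perm
    order_rank = rankdata(rp, method="max")  # 1 = smallest RP = best
    pfp = e_value / order_rank

    out = pd.DataFrame(
        {
            "RP": rp,
            "E_value": e_value,
            "pfp": np.minimum(pfp, 1.0),
            "p_value": np.minimum(e_value / n_probes, 1.0),
        },
        index=fc_matrix.index,
    )
    for j, line in enumerate(fc_matrix.columns):
        out[f"rank_{line}"] = ranks[:, j]
    return out


def filter_upregulated(
    rp: pd.DataFrame,
    fc_matrix: pd.DataFrame,
    fdr_max: float = 0.05,
    min_fold: float = 2.0,
    min_lines: int = 1,
) -> list[str]:
    """Probes with pfp below ``fdr_max`` and at least ``min_fold``
    upregulation (linear scale) in at least ``min_lines`` cell lines."""
    if not rp.index.equals(fc_matrix.index):
        rp = rp.reindex(fc_matrix.index)
        if rp["pfp"].isna().any():
            raise ValueError("rank-product results do not cover all probes")
    fold_ok = (fc_matrix >= np.log2(min_fold)).sum(axis=1) >= min_lines
    # fdr_max >= 1 disables the FDR filter (pfp is truncated at 1, so a
    # strict comparison would spuriously drop pfp == 1 probes)
    pfp_ok = rp["pfp"] < fdr_max if fdr_max < 1 else pd.Series(True, index=rp.index)
    keep = pfp_ok & fold_ok
    return list(fc_matrix.index[keep])
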