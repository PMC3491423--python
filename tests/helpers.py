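"""Shared test utilities: independent oracles and pipeline compositions."""

import itertools

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from methmark import integration, mbd_peaks, qpcr, reactivation
from methmark.core_io import PromoterAnnotation


def exhaustive_pfp(fc: pd.DataFrame) -> pd.Series:
    """Oracle: rank-product pfp by complete enumeration of per-line rank
    permutations (feasible up to ~4 probes x 3 lines)."""
    n, k = fc.shape
    ranks = np.column_stack([rankdata(-fc.iloc[:, j]) for j in range(k)])
    rp_obs = np.exp(np.log(ranks).mean(axis=1))
    base = np.arange(1, n + 1, dtype=float)
    counts = np.zeros(n)
    n_perm = 0
    for cols in itertools.product(
        *[itertools.permutations(base) for _ in range(k)]
    ):
        rp_null = np.exp(np.log(np.column_stack(cols)).mean(axis=1))
        counts += (rp_null[:, None] <= rp_obs[None, :] + 1e-12).sum(axis=0)
        n_perm += 1
    e_value = counts / n_perm
    order = rankdata(rp_obs, method="max")
    return pd.Series(np.minimum(e_value / order, 1.0), index=fc.index)


def integrated_ranking(bundle, n_perm: int = 200, seed: int = 0, k: int = 43):
    """Full discovery integration on a synthetic bundle.

    Builds the three evidence sources the scoring system combines:
    demethylation reactivation (rank product on fold changes),
    methylation-capture promoter peaks (ranked by supporting cell
    lines), and tumor differential expression between risk groups
    (Mann-Whitney p), then returns the integrated top-k table.
    """
    fc = bundle.dac.fc_matrix
    rp = reactivation.rank_product(fc, n_perm=n_perm, seed=seed)
    dac_rank = {g: int(r) for g, r in zip(rp.index, rp["RP"].rank(method="first"))}

    ann = [
        PromoterAnnotation(r.gene, r.chrom, int(r.tss), r.strand)
        for r in bundle.promoters.tss.itertuples()
    ]
    hits = mbd_peaks.map_peaks_to_promoters(bundle.mbd.peaks, ann)
    n_lines = hits.sum(axis=1)
    mbd_rank = {
        g: int(r) for g, r in zip(n_lines.index, (-n_lines).rank(method="first"))
    }

    groups = bundle.clinical.set_index("sample")["risk_group"]
    lr = groups.index[groups == "LR-SURV"]
    hr = groups.index[groups != "LR-SURV"]
    expr = bundle.tumor_expression
    pvals = pd.Series(
        {
            g: qpcr.mann_whitney(expr.loc[g, lr], expr.loc[g, hr]).p
            for g in expr.index
        }
    )
    expr_rank = {g: int(r) for g, r in zip(pvals.index, pvals.rank(method="first"))}

    return integration.combine_and_select(
        {"dac": dac_rank, "mbd": mbd_rank, "expr": expr_rank}, k=k
    )
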