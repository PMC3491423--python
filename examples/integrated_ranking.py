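"""Full discovery integration: three evidence sources into a top-43 list.

Generates a complete synthetic study (DAC re-expression, methylation
peaks, tumor expression) with 8 planted marker genes among 200, ranks
each evidence source, combines them with the tan-scaled rank scores and
reports how many planted genes reach the top 43.
"""

import pandas as pd

from methmark import integration, mbd_peaks, qpcr, reactivation, simulate
from methmark.core_io import PromoterAnnotation

bundle = simulate.gen_bundle(simulate.TruthConfig(seed=2), n_genes=200)
planted = sorted(bundle.config.marker_freqs)

# source 1: demethylation reactivation (rank product)
rp = reactivation.rank_product(bundle.dac.fc_matrix, n_perm=300, seed=0)
dac_rank = {g: int(r) for g, r in zip(rp.index, rp["RP"].rank(method="first"))}

# source 2: methylation-capture promoter peaks (supporting cell lines)
ann = [
    PromoterAnnotation(r.gene, r.chrom, int(r.tss), r.strand)
    for r in bundle.promoters.tss.itertuples()
]
hits = mbd_peaks.map_peaks_to_promoters(bundle.mbd.peaks, ann)
n_lines = hits.sum(axis=1)
mbd_rank = {g: int(r) for g, r in zip(n_lines.index, (-n_lines).rank(method="first"))}

# source 3: tumor differential expression between risk groups
groups = bundle.clinical.set_index("sample")["risk_group"]
lr = groups.index[groups == "LR-SURV"]
hr = groups.index[groups != "LR-SURV"]
expr = bundle.tumor_expression
pvals = pd.Series(
    {g: qpcr.mann_whitney(expr.loc[g, lr], expr.loc[g, hr]).p for g in expr.index}
)
expr_rank = {g: int(r) for g, r in zip(pvals.index, pvals.rank(method="first"))}

table = integration.combine_and_select(
    {"dac": dac_rank, "mbd": mbd_rank, "expr": expr_rank}, k=43
)
recovered = [g for g in planted if g in table.index]
print("top 10 integrated candidates:")
print(table[["combined_score", "final_rank"]].head(10).round(3))
print(f"\nplanted marker genes in the top 43: {len(recovered)}/{len(planted)}")
print(
    "\nEach source alone is noisy; summing the equal-weight tan-scaled rank "
    "scores concentrates the planted genes at the top without per-source "
    "significance cutoffs."
)
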