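"""Demethylation re-expression screen: fold changes, rank product, filter.

Builds a synthetic panel of 8 cell lines profiled before and after
demethylating treatment with 40 planted methylation-silenced genes
among 800 probes, then recovers them with the rank-product statistic
and the two-fold / FDR filter.
"""

from methmark import reactivation, simulate

planted = [f"silenced{i:02d}" for i in range(40)]
dac = simulate.gen_dac_experiment(800, planted, simulate.DacConfig(seed=0))
fc = dac.fc_matrix

rp = reactivation.rank_product(fc, n_perm=500, seed=0)
upregulated = reactivation.filter_upregulated(
    rp, fc, fdr_max=0.05, min_fold=2, min_lines=2
)

events = {
    probe: reactivation.reactivation_events(
        dac.call_untreated.loc[probe], dac.call_treated.loc[probe]
    )
    for probe in planted[:5]
}

recovered = len(set(upregulated) & set(planted))
false_hits = len(set(upregulated) - set(planted))
print(f"probes passing two-fold / FDR 5% in >=2 lines: {len(upregulated)}")
print(f"  planted genes recovered: {recovered}/{len(planted)}")
print(f"  background probes passing: {false_hits}")
print(f"reactivation events (absent->present) for 5 planted genes: {events}")
print(
    "\nA high recovery with few background hits means the screen separates "
    "methylation-silenced genes from expression noise at these settings."
)
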