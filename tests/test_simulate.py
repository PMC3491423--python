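"""Synthetic-study generators: determinism, planted structure, round trips."""

import numpy as np
import pandas as pd
import pytest

from methmark import mbd_peaks, msp_caller, simulate, survival
from methmark.core_io import PromoterAnnotation
from methmark.simulate import NoiseParams, TruthConfig


def test_empty_cohort():
    cfg = TruthConfig(n_lr_surv=0, n_hr_dod=0, n_hr_surv=0)
    assert len(simulate.gen_clinical_cohort(cfg)) == 0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TruthConfig(n_lr_surv=-1)
    with pytest.raises(ValueError):
        TruthConfig(marker_freqs={"m": {"LR-SURV": 1.2, "HR-SURV": 0, "HR-DOD": 0}})
    with pytest.raises(ValueError):
        NoiseParams(flip_rate=1.5)


def test_validation_cohort_sizes_and_reassignment():
    cfg = TruthConfig(seed=11)
    clin = simulate.gen_clinical_cohort(cfg)
    assert len(clin) == 89
    groups = survival.assign_risk_groups(clin)
    assert (groups.to_numpy() == clin["risk_group"].to_numpy()).all()


def test_seed_determinism_of_generators():
    cfg = TruthConfig(seed=7)
    b1 = simulate.gen_bundle(cfg, n_genes=40)
    b2 = simulate.gen_bundle(cfg, n_genes=40)
    assert b1.clinical.equals(b2.clinical)
    assert b1.truth_calls.equals(b2.truth_calls)
    assert b1.msp.readouts.equals(b2.msp.readouts)
    assert b1.dac.treated.equals(b2.dac.treated)
    assert b1.promoters.sequences == b2.promoters.sequences
    assert b1.mbd.counts.equals(b2.mbd.counts)
    assert b1.survival.equals(b2.survival)
    assert b1.tumor_expression.equals(b2.tumor_expression)
    assert b1.qpcr.equals(b2.qpcr)


def test_marker_frequencies_recovered():
    """Empirical per-group methylation frequencies stay within 3 binomial
    SDs of the configured probabilities."""
    cfg = TruthConfig(seed=3)
    clin = simulate.gen_clinical_cohort(cfg)
    truth = simulate.gen_truth_calls(cfg, clin)
    groups = clin.set_index("sample")["risk_group"]
    for marker, freqs in cfg.marker_freqs.items():
        for group, p in freqs.items():
            idx = groups.index[groups == group]
            n = len(idx)
            observed = (truth.loc[marker, idx] == "M").sum()
            sd = np.sqrt(max(n * p * (1 - p), 0.25))
            assert abs(observed - n * p) <= 3 * sd, (marker, group)


def test_noisy_readouts_flip_rate():
    """At flip rate 0.05 the call accuracy lands inside the binomial
    99% interval around 0.95."""
    rng_cfg = TruthConfig(seed=9)
    clin = simulate.gen_clinical_cohort(rng_cfg)
    markers = {f"a{i}": {"LR-SURV": 0.4, "HR-SURV": 0.4, "HR-DOD": 0.4}
               for i in range(48)}
    cfg = TruthConfig(seed=9, marker_freqs=markers,
                      mna_specific_markers=frozenset(),
                      prognostic_markers=())
    truth = simulate.gen_truth_calls(cfg, clin)
    rs = simulate.gen_msp_readouts(truth, NoiseParams(flip_rate=0.05), seed=2)
    calls = msp_caller.call_matrix(rs.readouts, rs.controls).drop(columns=["POS_CTRL"])
    agree = (calls.loc[truth.index, truth.columns] == truth).to_numpy()
    n = agree.size
    acc = agree.mean()
    half_width = 2.576 * np.sqrt(0.95 * 0.05 / n)
    assert abs(acc - 0.95) <= half_width + 1e-9


def test_dac_planted_genes_satisfy_contract():
    planted = ["gA", "gB", "gC"]
    dac = simulate.gen_dac_experiment(50, planted, simulate.DacConfig(seed=1))
    fc = dac.fc_matrix
    for g in planted:
        reactivated = (
            (fc.loc[g] >= 1.0)
            & (dac.call_untreated.loc[g] == "absent")
            & (dac.call_treated.loc[g] == "present")
        )
        assert reactivated.sum() >= 2
        assert (fc.loc[g] >= 1.0).sum() >= 2


def test_dac_empty_universe_rejected():
    with pytest.raises(ValueError):
        simulate.gen_dac_experiment(0, [])


def test_dac_null_permutation_p_uniform():
    """With no planted genes the rank-product permutation p-values carry
    no signal: a KS test against uniform does not reject."""
    from scipy.stats import kstest

    from methmark import reactivation

    dac = simulate.gen_dac_experiment(150, [], simulate.DacConfig(seed=5))
    rp = reactivation.rank_product(dac.fc_matrix, n_perm=200, seed=0)
    assert kstest(rp["p_value"], "uniform").pvalue > 0.01


def test_mbd_planted_peak_inside_window():
    genes = ["g1", "g2", "g3"]
    proms = simulate.gen_promoters(genes, seed=0)
    data = simulate.gen_mbd_peaks(
        proms, ["g1"], [], simulate.MbdConfig(seed=0, background_peaks=0)
    )
    ann = [PromoterAnnotation(r.gene, r.chrom, int(r.tss), r.strand)
           for r in proms.tss.itertuples()]
    hits = mbd_peaks.map_peaks_to_promoters(data.peaks, ann)
    assert hits.loc["g1"].sum() >= 2
    assert hits.loc["g2"].sum() == 0


def test_mbd_unannotated_gene_rejected():
    proms = simulate.gen_promoters(["g1"], seed=0)
    with pytest.raises(ValueError, match="TSS"):
        simulate.gen_mbd_peaks(proms, ["gX"], [])


def test_mbd_mna_specific_regions_detected():
    """MNA-specific regions at 8-fold elevation are flagged by the NB
    test at BH 0.1 in at least 80% of cases."""
    genes = [f"g{i}" for i in range(120)]
    mna_specific = genes[:20]
    proms = simulate.gen_promoters(genes, seed=1)
    data = simulate.gen_mbd_peaks(
        proms, genes[:30], mna_specific, simulate.MbdConfig(seed=1)
    )
    res = mbd_peaks.nb_two_group_test(data.counts, data.groups)
    assert (res.loc[mna_specific, "q"] <= 0.1).mean() >= 0.8


def test_survival_all_censored_km_flat():
    clin = simulate.gen_clinical_cohort(
        TruthConfig(n_lr_surv=10, n_hr_dod=0, n_hr_surv=0, seed=0)
    )
    truth = pd.DataFrame("U", index=["CNR1"], columns=clin["sample"])
    sv = simulate.gen_survival(clin, truth, ("CNR1",), 1.0,
                               baseline_hazard=1e-9, seed=0)
    km = survival.km_curve(sv["time"], sv["event"], censor_at=None)
    assert np.all(km.survival == 1.0)


def test_survival_dod_records_end_in_events(bundle):
    dod = bundle.clinical.loc[bundle.clinical["outcome"] == "dod", "sample"]
    assert (bundle.survival.loc[dod, "event"] == 1).all()


def test_survival_null_multiplier_logrank_uniform():
    """With hazard multiplier 1, methylation carries no signal: log-rank
    p-values spread over [0, 1] instead of piling near 0."""
    ps = []
    for seed in range(12):
        cfg = TruthConfig(seed=seed, hazard_multiplier=1.0)
        clin = simulate.gen_clinical_cohort(
            TruthConfig(n_lr_surv=0, n_hr_dod=0, n_hr_surv=60, seed=seed)
        )
        truth = simulate.gen_truth_calls(cfg, clin)
        sv = simulate.gen_survival(clin, truth, ("PRPH",), 1.0, seed=seed)
        meth = (truth.loc["PRPH", sv.index] == "M").map({True: "M", False: "U"})
        if meth.nunique() < 2 or sv["event"].sum() == 0:
            continue
        ps.append(survival.logrank(sv["time"], sv["event"], meth).p)
    ps = np.array(ps)
    assert (ps < 0.05).mean() <= 0.25
    assert ps.mean() > 0.2


def test_write_bundle_roundtrip(tmp_path, bundle):
    from methmark import core_io

    simulate.write_bundle(bundle, tmp_path)
    clin = core_io.read_clinical(tmp_path / "clinical.csv")
    assert len(clin) == len(bundle.clinical)
    peaks = core_io.read_bed(tmp_path / "peaks_line1.bed")
    assert len(peaks) == len(bundle.mbd.peaks["line1"])
    seqs = core_io.read_fasta(tmp_path / "promoters.fasta")
    assert seqs == bundle.promoters.sequences
    counts = core_io.read_matrix(tmp_path / "region_counts.tsv")
    assert counts.equals(bundle.mbd.counts)
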