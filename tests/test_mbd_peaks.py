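"""Peak-to-promoter mapping, GSEA running sum, NB differential counts."""

import numpy as np
import pandas as pd
import pytest

from methmark import mbd_peaks
from methmark.core_io import GenomicInterval, PromoterAnnotation


def _hit(tss, strand, peak_start, peak_end, shift=0):
    peaks = {"L1": [GenomicInterval("chr1", peak_start + shift, peak_end + shift)]}
    proms = [PromoterAnnotation("G", "chr1", tss + shift, strand)]
    return bool(mbd_peaks.map_peaks_to_promoters(peaks, proms).loc["G", "L1"])


@pytest.mark.parametrize(
    "tss,strand,start,end,expected",
    [
        (10_000, "+", 9_000, 9_200, True),
        (10_000, "+", 11_000, 11_200, False),  # half-open boundary
        (10_000, "-", 11_400, 11_600, True),   # minus-strand window [9000, 11500)
    ],
)
def test_peak_promoter_overlap(tss, strand, start, end, expected):
    assert _hit(tss, strand, start, end) is expected


@pytest.mark.parametrize("shift", [0, 1_000, 123_457])
def test_mapping_invariant_under_joint_shift(shift):
    assert _hit(10_000, "-", 11_400, 11_600, shift=shift) is True
    assert _hit(10_000, "+", 11_000, 11_200, shift=shift) is False


def test_gene_without_peaks_on_its_chromosome():
    peaks = {"L1": [GenomicInterval("chr2", 0, 100)]}
    proms = [PromoterAnnotation("G", "chr1", 10_000, "+")]
    assert not mbd_peaks.map_peaks_to_promoters(peaks, proms).loc["G", "L1"]


# --- GSEA running sum ---------------------------------------------------

def test_es_degenerate_full_hit_set():
    res = mbd_peaks.gsea_enrichment(["a", "b", "c"], {"a", "b", "c"}, n_perm=10)
    assert res.es == 1.0


def test_es_hand_running_sum():
    res = mbd_peaks.gsea_enrichment(["g1", "g2", "g3", "g4"], {"g2"}, n_perm=10)
    assert res.es == pytest.approx(2 / 3)


def test_es_reversed_ranking_flips_leading_edge():
    genes = [f"g{i}" for i in range(10)]
    hits = {"g0", "g1", "g2"}
    fwd = mbd_peaks.gsea_enrichment(genes, hits, n_perm=10)
    rev = mbd_peaks.gsea_enrichment(genes[::-1], hits, n_perm=10)
    assert fwd.es > 0 > rev.es


def test_es_empty_hit_set_rejected():
    with pytest.raises(ValueError):
        mbd_peaks.gsea_enrichment(["a", "b"], set(), n_perm=10)


def test_gsea_null_p_uniformish():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(60)]
    ps = []
    for _ in range(40):
        hits = set(rng.choice(genes, size=10, replace=False))
        ps.append(mbd_peaks.gsea_enrichment(genes, hits, n_perm=99, seed=1).p_value)
    assert 0.2 < np.mean(np.array(ps) < 0.5) < 0.8


# --- reactivation x methylation intersection ----------------------------

def _intersection_fixture(peak_lines, fc_lines):
    lines = ["L1", "L2", "L3", "L4"]
    fc = pd.DataFrame(0.0, index=["G"], columns=lines)
    fc.loc["G", fc_lines] = 2.0
    hits = pd.DataFrame(False, index=["G"], columns=lines)
    hits.loc["G", peak_lines] = True
    return fc, hits


def test_intersection_same_lines():
    fc, hits = _intersection_fixture(["L1", "L2", "L3"], ["L1", "L2", "L3"])
    counts = mbd_peaks.intersect_reactivated_methylated(fc, hits)
    assert counts.loc["G"] == 3


def test_intersection_disjoint_lines():
    fc, hits = _intersection_fixture(["L4"], ["L1", "L2", "L3"])
    counts = mbd_peaks.intersect_reactivated_methylated(fc, hits)
    assert "G" not in counts.index


# --- size factors and NB test -------------------------------------------

def test_size_factors_identical_columns():
    counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
    sf = mbd_peaks.size_factors(counts)
    assert np.allclose(sf, [1.0, 1.0])


def test_size_factors_scale_equivariance():
    rng = np.random.default_rng(0)
    base = rng.integers(5, 100, size=20)
    counts = pd.DataFrame({"a": base, "b": base * 2})
    sf = mbd_peaks.size_factors(counts)
    assert sf["b"] / sf["a"] == pytest.approx(2.0)


def test_size_factors_hand_median_of_ratios():
    counts = pd.DataFrame({"a": [2, 1], "b": [4, 2]})
    sf = mbd_peaks.size_factors(counts)
    assert sf["b"] / sf["a"] == pytest.approx(2.0)
    assert sf["a"] * sf["b"] == pytest.approx(1.0)
    assert sorted(sf) == pytest.approx([np.sqrt(0.5), np.sqrt(2)])


def test_size_factors_all_zero_rows_rejected():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError):
        mbd_peaks.size_factors(counts)


def _nb_counts(rng, mu, alpha, n_regions, n_lines):
    r = 1 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=(n_regions, n_lines))


def test_nb_test_null_p_values_not_anticonservative():
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        _nb_counts(rng, 50.0, 0.1, 300, 6),
        columns=[f"L{i}" for i in range(6)],
    )
    groups = {f"L{i}": ("A" if i < 3 else "B") for i in range(6)}
    res = mbd_peaks.nb_two_group_test(counts, groups)
    assert res["p"].median() >= 0.4


def test_nb_test_type_one_error_controlled():
    """False positive rate at alpha=0.05 stays below 1.5x nominal on a
    1,000-region null simulation."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        _nb_counts(rng, 60.0, 0.1, 1000, 6),
        columns=[f"L{i}" for i in range(6)],
    )
    groups = {f"L{i}": ("A" if i < 3 else "B") for i in range(6)}
    res = mbd_peaks.nb_two_group_test(counts, groups)
    assert (res["p"] < 0.05).mean() <= 0.075


def test_nb_test_detects_planted_fold_change():
    rng = np.random.default_rng(3)
    n_planted = 40
    mu = np.full((200, 6), 50.0)
    mu[:n_planted, :3] *= 8.0
    r = 1 / 0.1
    counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + mu)),
        columns=[f"L{i}" for i in range(6)],
    )
    groups = {f"L{i}": ("A" if i < 3 else "B") for i in range(6)}
    res = mbd_peaks.nb_two_group_test(counts, groups)
    detected = (res["q"].iloc[:n_planted] <= 0.1).mean()
    assert detected >= 0.8


def test_nb_test_single_region_near_equal_counts():
    counts = pd.DataFrame([[10, 11, 10, 12]], columns=list("abcd"))
    groups = {"a": "A", "b": "A", "c": "B", "d": "B"}
    res = mbd_peaks.nb_two_group_test(counts, groups, alpha=0.1)
    assert res["p"].iloc[0] > 0.5


def test_nb_test_requires_two_per_group():
    counts = pd.DataFrame([[10, 11, 12]], columns=list("abc"))
    with pytest.raises(ValueError):
        mbd_peaks.nb_two_group_test(counts, {"a": "A", "b": "B", "c": "B"})
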