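"""RPKM quantification, temporal profiles and the entropy specificity score."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineagescan.expression import (
    SampleInfo,
    compute_rpkm,
    late_stage_enrichment,
    mean_normalized_expression,
    peak_stage,
    peak_stage_proportions,
    pearson_chi2_2x2,
    pool_replicates,
    proportion_expressed,
    specificity_contrast,
    specificity_scores,
    temporal_specificity,
)
from lineagescan.phylostrat import ConservationCall


def _samples(totals, stages=None):
    stages = stages or [f"s{i}" for i in range(len(totals))]
    return [
        SampleInfo(sample_id=s, stage=s, hours_post_fertilization=float(i),
                   stage_class="EARLY", total_valid_reads=t)
        for i, (s, t) in enumerate(zip(stages, totals))
    ]


def test_rpkm_unit_cases():
    counts = pd.DataFrame({"s0": [10, 0, 25]}, index=["a", "b", "c"])
    rpkm = compute_rpkm(counts, {"a": 1000, "b": 500, "c": 2500},
                        _samples([1_000_000]))
    assert rpkm.loc["a", "s0"] == pytest.approx(10.0)
    assert rpkm.loc["b", "s0"] == 0.0
    counts5 = pd.DataFrame({"s0": [25]}, index=["c"])
    rpkm5 = compute_rpkm(counts5, {"c": 2500}, _samples([5_000_000]))
    assert rpkm5.loc["c", "s0"] == pytest.approx(2.0)


def test_rpkm_linearity_and_zero_iff_zero():
    counts = pd.DataFrame({"s0": [7], "s1": [14]}, index=["a"])
    rpkm = compute_rpkm(counts, {"a": 800}, _samples([2_000_000, 2_000_000]))
    assert rpkm.loc["a", "s1"] == pytest.approx(2 * rpkm.loc["a", "s0"])
    assert (rpkm.to_numpy() == 0).sum() == (counts.to_numpy() == 0).sum()


def test_rpkm_errors():
    counts = pd.DataFrame({"s0": [1]}, index=["a"])
    with pytest.raises(ValueError, match="a"):
        compute_rpkm(counts, {"a": 0}, _samples([100]))
    with pytest.raises(ValueError):
        SampleInfo("s0", "s0", 0.0, "EARLY", total_valid_reads=0)


def test_replicate_pooling_sums_counts_and_totals():
    counts = pd.DataFrame({"r1": [3, 0], "r2": [5, 1]}, index=["a", "b"])
    samples = [
        SampleInfo("r1", "stageX", 1.0, "EARLY", 100),
        SampleInfo("r2", "stageX", 1.0, "EARLY", 200),
    ]
    pooled, meta = pool_replicates(counts, samples)
    assert list(pooled.columns) == ["stageX"]
    assert pooled.loc["a", "stageX"] == 8
    assert meta[0].total_valid_reads == 300


def test_mean_normalized_expression():
    rpkm = pd.DataFrame({"s0": [2.0, 4.0], "s1": [0.0, 0.0]}, index=["a", "b"])
    m = mean_normalized_expression(rpkm, ["a", "b"])
    assert m["s0"] == pytest.approx(3.0)
    assert m["s1"] == 0.0


def test_proportion_expressed_bounds():
    counts = pd.DataFrame(
        {"s0": [5, 0, 1, 0, 2, 0]}, index=list("abcdef")
    )
    p = proportion_expressed(counts, list("abcdef"))
    assert p["s0"] == pytest.approx(0.5)
    assert ((p >= 0) & (p <= 1)).all()


def test_peak_stage_rules():
    row = pd.Series({"s0": 1.0, "s3": 0.5, "s12": 9.0})
    assert peak_stage(row) == "s12"
    tie = pd.Series({"s0": 0.0, "s3": 2.0, "s9": 2.0})
    assert peak_stage(tie) == "s3"          # earliest-tie rule
    assert peak_stage(tie, k=2) == "s9"
    assert peak_stage(pd.Series({"s0": 0.0, "s1": 0.0})) is None


def test_peak_stage_proportions_excludes_all_zero_genes():
    rpkm = pd.DataFrame(
        {"s0": [1.0, 0.0, 0.0], "s1": [0.0, 2.0, 0.0]}, index=["a", "b", "z"]
    )
    props, excluded = peak_stage_proportions(rpkm, ["a", "b", "z"])
    assert excluded == ["z"]
    assert props["s0"] == pytest.approx(0.5)
    assert props.sum() == pytest.approx(1.0)


def _calls(cat_by_gene):
    return {g: ConservationCall(gene_id=g, category=c)
            for g, c in cat_by_gene.items()}


def test_late_stage_enrichment_on_printed_counts():
    """37.9% vs 21.5% late-peaking, chi-square ~6.07, p ~0.014."""
    calls = {}
    peaks = {}
    i = 0
    for cat, late, n in (("ORPHAN", 25, 66), ("CTSG", 29, 135)):
        for j in range(n):
            g = f"g{i}"; i += 1
            calls[g] = cat
            peaks[g] = "late_stage" if j < late else "early_stage"
    res = late_stage_enrichment(
        peaks, _calls(calls), {"late_stage": "LATE", "early_stage": "EARLY"},
        "ORPHAN", "CTSG",
    )
    assert res["percent_1"] == pytest.approx(37.9, abs=0.05)
    assert res["percent_2"] == pytest.approx(21.5, abs=0.05)
    # closed-form Pearson oracle on the same table
    a, b, n1, n2 = 25, 29, 66, 135
    n = n1 + n2
    chi_oracle = (
        n * (a * (n2 - b) - b * (n1 - a)) ** 2
        / (n1 * n2 * (a + b) * (n1 - a + n2 - b))
    )
    assert res["chi2"] == pytest.approx(chi_oracle, rel=1e-12)
    assert res["chi2"] == pytest.approx(6.07, abs=0.01)
    assert res["p_value"] == pytest.approx(0.0138, abs=0.001)
    assert res["p_value"] < 0.05


def test_chi2_equal_fractions_is_null():
    chi2, p = pearson_chi2_2x2(10, 40, 5, 20)
    assert chi2 == 0.0 and p == pytest.approx(1.0)


def test_chi2_matches_scipy_uncorrected():
    from scipy.stats import chi2_contingency
    chi2, p = pearson_chi2_2x2(25, 66, 29, 135)
    ref, pref, _, _ = chi2_contingency(
        [[25, 41], [29, 106]], correction=False
    )
    assert chi2 == pytest.approx(ref, rel=1e-12)
    assert p == pytest.approx(pref, rel=1e-12)


def test_temporal_specificity_limits():
    assert temporal_specificity([1.0] * 15) == pytest.approx(0.0)
    assert temporal_specificity([0.0] * 14 + [5.0]) == pytest.approx(1.0)
    two = [0.0] * 13 + [3.0, 3.0]
    assert temporal_specificity(two) == pytest.approx(1 - 1 / math.log2(15))
    assert temporal_specificity([0.0] * 15) is None
    with pytest.raises(ValueError):
        temporal_specificity([1.0])


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                min_size=2, max_size=30))
def test_specificity_bounds_on_fuzz_rows(row):
    s = temporal_specificity(row)
    if s is not None:
        assert -1e-12 <= s <= 1.0 + 1e-12


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False),
             min_size=3, max_size=20).filter(lambda r: sum(r) > 0),
    st.floats(min_value=1e-6, max_value=1e6),
)
def test_specificity_scale_invariance(row, c):
    s1 = temporal_specificity(row)
    s2 = temporal_specificity([c * x for x in row])
    assert s2 == pytest.approx(s1, abs=1e-9)


def test_specificity_contrast_recovers_planted_pattern(default_cohort, cohort_calls):
    """Stage-restricted lineage-specific genes score higher than uniform
    conserved genes, with a decisive ANOVA."""
    from lineagescan.gtfio import GeneModel
    cohort = default_cohort
    exon_lengths = {g: m.exon_union_length() for g, m in cohort.models.items()}
    samples = [
        SampleInfo(r.sample_id, r.stage, r.hours_post_fertilization,
                   r.stage_class, r.total_valid_reads)
        for r in cohort.sample_meta.itertuples()
    ]
    rpkm = compute_rpkm(cohort.counts, exon_lengths, samples)
    scores = specificity_scores(rpkm)
    summary = specificity_contrast(scores, cohort_calls)
    assert summary.means["ORPHAN"] > summary.means["EC"]
    assert summary.means["CTSG"] > summary.means["EC"]
    assert summary.p_value < 1e-3


def test_specificity_contrast_constant_scores_undefined():
    scores = {"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5}
    calls = _calls({"a": "EC", "b": "EC", "c": "ORPHAN", "d": "ORPHAN"})
    with pytest.raises(ValueError):
        specificity_contrast(scores, calls)
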