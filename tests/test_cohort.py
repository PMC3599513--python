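"""Synthetic cohort generator: planted truth, determinism, recoverability."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from lineagescan.cohort import (
    STAGE_RESTRICTED,
    UNIFORM,
    CohortConfig,
    CohortSelfTestError,
    PlantedTruth,
    generate_alignments,
    generate_cohort,
    generate_counts,
    write_cohort,
)
from lineagescan.expression import SampleInfo, compute_rpkm
from lineagescan.transcript_map import DISCARD_AMBIGUOUS, FAIL, PASS, qc_filter


def test_planted_class_counts_match_config():
    cfg = CohortConfig(seed=1, n_ec=5, n_ctsg=3, n_orphan=2,
                       n_paralog_pairs=4)
    cohort = generate_cohort(cfg, self_test=False)
    classes = list(cohort.truth.gene_class.values())
    assert len(classes) == 10
    assert classes.count("EC") == 5
    assert classes.count("CTSG") == 3
    assert classes.count("ORPHAN") == 2
    # every focal gene appears exactly once in the truth
    assert sorted(cohort.truth.gene_class) == sorted(cohort.models)


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = CohortConfig(seed=3, n_ec=4, n_ctsg=2, n_orphan=2)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = write_cohort(generate_cohort(cfg, self_test=False), d1)
    p2 = write_cohort(generate_cohort(cfg, self_test=False), d2)
    assert sorted(p1) == sorted(p2)
    for name in p1:
        assert filecmp.cmp(p1[name], p2[name], shallow=False), f"{name} differs"


def test_different_seed_changes_sequences():
    a = generate_cohort(CohortConfig(seed=1, n_ec=2, n_ctsg=1, n_orphan=1),
                        self_test=False)
    b = generate_cohort(CohortConfig(seed=2, n_ec=2, n_ctsg=1, n_orphan=1),
                        self_test=False)
    assert a.focal_proteins != b.focal_proteins


def test_classification_recovers_planted_truth(default_cohort, cohort_calls):
    got = {g: c.category for g, c in cohort_calls.items()}
    assert got == default_cohort.truth.gene_class


def test_genome_only_species_exercised(default_cohort, cohort_calls):
    """At least one out-group species has no proteome, and at least one EC
    call rests on a translated-genome hit."""
    panel = default_cohort.panel
    proteomeless = [s for s in panel.by_clade("OUTGROUP") if not s.has_proteome]
    assert proteomeless
    genome_backed = [
        c for c in cohort_calls.values()
        if c.category == "EC"
        and any(m == "PROT_VS_GENOME" for _, _, m in c.evidence)
    ]
    assert genome_backed


def test_single_exon_orphan_present(default_cohort):
    orphans = [g for g, c in default_cohort.truth.gene_class.items()
               if c == "ORPHAN"]
    assert any(
        default_cohort.models[g].transcripts[0].exon_count == 1 for g in orphans
    )


def test_unrecoverable_homologs_abort_generation():
    with pytest.raises(CohortSelfTestError):
        generate_cohort(
            CohortConfig(seed=1, n_ec=3, n_ctsg=0, n_orphan=0,
                         mutation_rate_homolog=0.95)
        )


def _toy_truth(n_stages, restricted_stage=None, n_genes=1):
    truth = PlantedTruth()
    for i in range(n_genes):
        gid = f"g{i:04d}"
        truth.gene_class[gid] = "EC" if restricted_stage is None else "ORPHAN"
        truth.temporal_pattern[gid] = (
            (UNIFORM, None) if restricted_stage is None
            else (STAGE_RESTRICTED, restricted_stage)
        )
    return truth


def test_noiseless_restricted_gene_peaks_at_planted_stage():
    cfg = CohortConfig(seed=5, nb_dispersion=0.0)
    truth = _toy_truth(cfg.n_stages, restricted_stage=12)
    counts, _ = generate_counts(cfg, truth, equal_libraries=True)
    assert int(np.argmax(counts.iloc[0].to_numpy())) == 12


def test_noiseless_uniform_gene_is_flat_at_equal_libraries():
    cfg = CohortConfig(seed=5, nb_dispersion=0.0)
    truth = _toy_truth(cfg.n_stages, restricted_stage=None)
    counts, _ = generate_counts(cfg, truth, equal_libraries=True)
    assert counts.iloc[0].nunique() == 1


def test_library_sizes_span_a_four_fold_range():
    cfg = CohortConfig(seed=6)
    truth = _toy_truth(cfg.n_stages)
    _, meta = generate_counts(cfg, truth)
    totals = meta["total_valid_reads"].to_numpy(float)
    assert totals.max() / totals.min() > 1.5  # log-uniform over [1, 4]


def test_peak_recovery_rate_on_monte_carlo_restricted_genes():
    """>= 95% of stage-restricted genes peak (in RPKM) at the planted stage
    under the default dispersion."""
    cfg = CohortConfig(seed=9)
    rng = np.random.default_rng(9)
    truth = PlantedTruth()
    n = 220
    planted = rng.integers(0, cfg.n_stages, size=n)
    for i in range(n):
        truth.gene_class[f"g{i:04d}"] = "ORPHAN"
        truth.temporal_pattern[f"g{i:04d}"] = (STAGE_RESTRICTED, int(planted[i]))
    counts, meta = generate_counts(cfg, truth, rng=rng)
    samples = [
        SampleInfo(r.sample_id, r.stage, r.hours_post_fertilization,
                   r.stage_class, r.total_valid_reads)
        for r in meta.itertuples()
    ]
    rpkm = compute_rpkm(counts, {g: 1000 for g in counts.index}, samples)
    genes = sorted(truth.gene_class)
    hit = sum(
        int(np.argmax(rpkm.loc[g].to_numpy()) == truth.temporal_pattern[g][1])
        for g in genes
    )
    assert hit / n >= 0.95


def test_psl_fixture_straddles_every_threshold(default_cohort):
    """Each QC criterion has a planted exemplar on both sides, and the
    computed verdicts agree with the planted truth."""
    truth = default_cohort.truth
    verdicts = {v.transcript_id: v for v in qc_filter(default_cohort.alignments)}
    for crit in ("length", "identity", "coverage_mapping", "coverage_transcript"):
        statuses = {
            s for tx, (s, failed) in truth.qc_status.items()
            if crit in failed or (s == PASS and f"est_{crit.split('_')[-1]}" in tx)
        }
        planted_fail = [tx for tx, (s, f) in truth.qc_status.items() if crit in f]
        assert planted_fail, f"no planted failing exemplar for {crit}"
        for tx in planted_fail:
            assert verdicts[tx].status == FAIL
            assert crit in verdicts[tx].failed_criteria
    # planted passing exemplars
    for tx, (status, _) in truth.qc_status.items():
        if status == PASS and tx in verdicts:
            per_tx = [v for v in qc_filter(default_cohort.alignments)
                      if v.transcript_id == tx]
            assert any(v.status == PASS for v in per_tx), tx
    assert any(s == DISCARD_AMBIGUOUS for s, _ in truth.qc_status.values())


def test_counts_and_metadata_are_consistent(default_cohort):
    counts, meta = default_cohort.counts, default_cohort.sample_meta
    assert list(counts.columns) == list(meta["sample_id"])
    assert (counts.to_numpy() >= 0).all()
    # totals at least cover the listed genes' reads
    assert (meta["total_valid_reads"].to_numpy() >= counts.sum(axis=0).to_numpy()).all()


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_ec=-1)
    with pytest.raises(ValueError):
        CohortConfig(mutation_rate_homolog=1.0)
    with pytest.raises(ValueError):
        CohortConfig(n_stages=1)
    with pytest.raises(ValueError):
        CohortConfig(stage_boundary_index=0)
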