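"""EST mapping QC chain, multi-mapping resolution, gene assignment,
tissue table and enrichment."""

import itertools
import math
import random

import pytest

from lineagescan.gtfio import GeneModel, Transcript
from lineagescan.phylostrat import ConservationCall
from lineagescan.psl import TranscriptAlignment, read_psl, write_psl
from lineagescan.transcript_map import (
    DISCARD_AMBIGUOUS,
    FAIL,
    PASS,
    assign_to_genes,
    build_tissue_table,
    filter_chain,
    qc_filter,
    resolve_multimapping,
    tissue_enrichment,
)


def _aln(tx="t1", blocks=(200,), matches=200, mismatches=0, tx_len=250,
         chrom="chr1", strand="+", t_start=1000):
    starts, pos = [], t_start
    for b in blocks:
        starts.append(pos)
        pos += b
    return TranscriptAlignment(
        transcript_id=tx, transcript_length=tx_len, chromosome=chrom,
        strand=strand, t_start=t_start, t_end=pos, matches=matches,
        mismatches=mismatches, block_sizes=list(blocks), t_starts=starts,
        t_size=10**6, q_start=0, q_end=sum(blocks),
    )


def test_qc_ratios_worked_example():
    """120 aligned bases, 116 matches, 4 mismatches, 150 nt transcript:
    identity 96.7%, full mapping coverage, 80% transcript coverage -> PASS."""
    v = qc_filter([_aln(blocks=(120,), matches=116, mismatches=4, tx_len=150)])[0]
    assert v.status == PASS
    assert v.identity == pytest.approx(100 * 116 / 120)
    assert v.coverage_mapping == pytest.approx(100.0)
    assert v.coverage_transcript == pytest.approx(80.0)


@pytest.mark.parametrize(
    "kwargs, expect_status, expect_failed",
    [
        (dict(blocks=(100,), matches=100, tx_len=130), PASS, []),
        (dict(blocks=(99,), matches=99, tx_len=130), FAIL, ["length"]),
        (dict(blocks=(1000,), matches=960, mismatches=40, tx_len=1250), PASS, []),
        (dict(blocks=(1000,), matches=959, mismatches=41, tx_len=1250),
         FAIL, ["identity"]),
        (dict(blocks=(1000,), matches=970, tx_len=1250), PASS, []),
        (dict(blocks=(1000,), matches=969, tx_len=1250),
         FAIL, ["coverage_mapping"]),
        (dict(blocks=(750,), matches=750, tx_len=1000), PASS, []),
        (dict(blocks=(749,), matches=749, tx_len=1000),
         FAIL, ["coverage_transcript"]),
    ],
)
def test_each_threshold_inclusive_both_sides(kwargs, expect_status, expect_failed):
    v = qc_filter([_aln(**kwargs)])[0]
    assert v.status == expect_status
    assert v.failed_criteria == expect_failed


def test_all_violations_listed():
    v = qc_filter([_aln(blocks=(90,), matches=80, mismatches=10, tx_len=1000)])[0]
    assert set(v.failed_criteria) == {"length", "identity", "coverage_transcript"}


def test_filter_idempotence_and_order_independence():
    rng = random.Random(0)
    alns = [
        _aln(tx=f"t{i}", blocks=(150 + i,), matches=150 + i, tx_len=200 + i)
        for i in range(10)
    ] + [_aln(tx="bad", blocks=(90,), matches=90, tx_len=500)]
    verdicts = qc_filter(alns)
    passing = [a for a, v in zip(alns, verdicts) if v.status == PASS]
    again = qc_filter(passing)
    assert all(v.status == PASS for v in again)
    shuffled = alns[:]
    rng.shuffle(shuffled)
    v1 = {v.transcript_id: v.status for v in qc_filter(alns)}
    v2 = {v.transcript_id: v.status for v in qc_filter(shuffled)}
    assert v1 == v2


def test_multimapping_resolution_thresholds():
    single = [_aln(tx="t", matches=200)]
    kept, discarded = resolve_multimapping(single)
    assert "t" in kept and not discarded

    close = [
        _aln(tx="t", blocks=(1000,), matches=1000, tx_len=1250),
        _aln(tx="t", blocks=(1000,), matches=980, mismatches=20, tx_len=1250,
             t_start=50000),
    ]
    kept, discarded = resolve_multimapping(close)  # gap 4% < 5%
    assert discarded == ["t"] and not kept

    clear = [
        _aln(tx="t", blocks=(1000,), matches=1000, tx_len=1250),
        _aln(tx="t", blocks=(1000,), matches=970, mismatches=30, tx_len=1250,
             t_start=50000),
    ]
    kept, discarded = resolve_multimapping(clear)  # gap 6%
    assert kept["t"].score == 1000 and not discarded


def test_count_conservation_through_the_chain():
    alns = (
        [_aln(tx=f"p{i}", matches=200) for i in range(5)]
        + [_aln(tx="f", blocks=(90,), matches=90, tx_len=500)]
        + [
            _aln(tx="amb", blocks=(1000,), matches=1000, tx_len=1250),
            _aln(tx="amb", blocks=(1000,), matches=980, mismatches=20,
                 tx_len=1250, t_start=9000),
        ]
    )
    verdicts, kept, status = filter_chain(alns)
    n_pass = sum(1 for v in verdicts if v.status == PASS)
    n_fail = sum(1 for v in verdicts if v.status == FAIL)
    assert n_pass + n_fail == len(alns)
    n_discarded = sum(1 for s in status.values() if s == DISCARD_AMBIGUOUS)
    assert len(kept) + n_discarded == len(
        {a.transcript_id for a, v in zip(alns, verdicts) if v.status == PASS}
    )


def _gene(gid="G", chrom="chr1", strand="+", start=1000, end=2000):
    return GeneModel(
        gene_id=gid, chromosome=chrom, strand=strand, start=start, end=end,
        transcripts=[Transcript(transcript_id=f"{gid}.t1", exons=[(start, end)])],
    )


def test_assignment_requires_overlap_and_strand():
    models = {"G": _gene()}
    # 150 bp overlap, same strand -> assigned
    a = _aln(tx="t", blocks=(150,), matches=150, tx_len=160, t_start=999)
    assert assign_to_genes({"t": a}, models) == {"t": "G"}
    # opposite strand -> unassigned
    b = _aln(tx="t", blocks=(150,), matches=150, tx_len=160, t_start=999,
             strand="-")
    assert assign_to_genes({"t": b}, models) == {}
    # exactly 100 bp overlap -> unassigned (strict >)
    c = _aln(tx="t", blocks=(100,), matches=100, tx_len=120, t_start=999)
    assert assign_to_genes({"t": c}, models) == {}
    # 101 bp -> assigned
    d = _aln(tx="t", blocks=(101,), matches=101, tx_len=120, t_start=999)
    assert assign_to_genes({"t": d}, models) == {"t": "G"}


def test_assignment_tie_leaves_unassigned_and_max_overlap_wins():
    models = {
        "A": _gene("A", start=1000, end=2000),
        "B": _gene("B", start=1000, end=2000),
    }
    a = _aln(tx="t", blocks=(300,), matches=300, tx_len=320, t_start=999)
    assert assign_to_genes({"t": a}, models) == {}  # exact tie
    models2 = {
        "A": _gene("A", start=1000, end=2000),
        "B": _gene("B", start=1500, end=2000),
    }
    b = _aln(tx="t", blocks=(600,), matches=600, tx_len=620, t_start=999)
    assert assign_to_genes({"t": b}, models2) == {"t": "A"}


def test_tissue_table_counts_and_single_est_rule():
    assignments = {"e1": "G", "e2": "G", "e3": "G", "e4": "H"}
    tissues = {"e1": "brain", "e2": "brain", "e3": "brain", "e4": "gonad"}
    table = build_tissue_table(assignments, tissues)
    assert table["G"]["brain"] == 3
    assert table["H"]["gonad"] == 1          # one EST is enough
    assert "G" in table and "gonad" not in table["G"]
    with pytest.warns(UserWarning, match="no tissue label"):
        build_tissue_table({"e9": "G"}, {})


def _fisher_oracle(a, b, c, d):
    """Exact two-sided p by full enumeration over fixed margins."""
    from math import comb
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def pmf(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = pmf(a)
    lo, hi = max(0, col1 - row2), min(col1, row1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-12))


def _calls(categories):
    return {
        g: ConservationCall(gene_id=g, category=cat)
        for g, cat in categories.items()
    }


def _table_from_counts(a, b, c, d):
    """Build calls + tissue table realizing the 2x2 (rows ORPHAN, EC;
    cols gonad, elsewhere)."""
    calls, table = {}, {}
    i = 0
    for cat, in_t, out_t in (("ORPHAN", a, b), ("EC", c, d)):
        for _ in range(in_t):
            g = f"g{i}"; i += 1
            calls[g] = cat
            table[g] = {"gonad": 1}
        for _ in range(out_t):
            g = f"g{i}"; i += 1
            calls[g] = cat
            table[g] = {"brain": 1}
    return _calls(calls), table


def test_fisher_trivial_tables():
    calls, table = _table_from_counts(12, 12, 12, 12)
    counts, p = tissue_enrichment(table, calls, "gonad", "ORPHAN", "EC")
    assert counts == (12, 12, 12, 12)
    assert p == pytest.approx(1.0)
    calls, table = _table_from_counts(10, 0, 0, 10)
    _, p = tissue_enrichment(table, calls, "gonad", "ORPHAN", "EC")
    assert p < 1e-4


@pytest.mark.parametrize("seed", range(6))
def test_fisher_matches_enumeration_oracle(seed):
    rng = random.Random(seed)
    a, b = rng.randint(0, 12), rng.randint(0, 12)
    c, d = rng.randint(0, 12), rng.randint(0, 12)
    if a + b == 0 or c + d == 0 or a + c == 0:
        a, b, c, d = 3, 4, 5, 6
    calls, table = _table_from_counts(a, b, c, d)
    _, p = tissue_enrichment(table, calls, "gonad", "ORPHAN", "EC")
    assert p == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)


def test_enrichment_empty_margin_raises():
    calls, table = _table_from_counts(3, 3, 0, 0)
    with pytest.raises(ValueError):
        tissue_enrichment(table, calls, "gonad", "ORPHAN", "EC")


def test_psl_round_trip(tmp_path, default_cohort):
    p = tmp_path / "est.psl"
    write_psl(default_cohort.alignments, p)
    back = read_psl(p)
    assert len(back) == len(default_cohort.alignments)
    a0, b0 = default_cohort.alignments[0], back[0]
    assert (a0.transcript_id, a0.matches, a0.block_sizes) == (
        b0.transcript_id, b0.matches, b0.block_sizes
    )
    assert {v.transcript_id: v.status for v in qc_filter(back)} == {
        v.transcript_id: v.status for v in qc_filter(default_cohort.alignments)
    }
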