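"""Stage-resolved expression: RPKM, temporal profiles and specificity.

RPKM for gene g in sample s is

    count(g, s) / (exon_length(g) / 1e3) / (total_valid_reads(s) / 1e6)

with exon_length the merged union of all exons over the gene's
transcripts and total_valid_reads the per-sample number of uniquely
mapped reads (supplied as metadata, never recomputed from the listed
genes).  Replicate samples of the same named stage are pooled by
summing counts and totals before normalization.

The temporal specificity score of a gene over N stages is
1 - H(g)/log2(N), where H(g) is the Shannon entropy of the gene's RPKM
shares across stages: 0 for a perfectly uniform profile, 1 for
expression confined to a single stage.  All-zero genes have no defined
score and are excluded from group contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .phylostrat import ConservationCall
from .stats import GroupSummary, group_anova

EARLY = "EARLY"
LATE = "LATE"


@dataclass
class SampleInfo:
    sample_id: str
    stage: str
    hours_post_fertilization: Optional[float]
    stage_class: str  # EARLY | LATE (or a tissue label for tissue panels)
    total_valid_reads: int

    def __post_init__(self) -> None:
        if self.total_valid_reads <= 0:
            raise ValueError(f"{self.sample_id}: total valid reads must be positive")


def pool_replicates(
    counts: pd.DataFrame, samples: Sequence[SampleInfo]
) -> tuple[pd.DataFrame, list[SampleInfo]]:
    """Sum counts and totals of samples sharing a stage name."""
    by_stage: dict[str, list[SampleInfo]] = {}
    for s in samples:
        by_stage.setdefault(s.stage, []).append(s)
    pooled_cols = {}
    pooled_meta = []
    for stage, members in by_stage.items():
        pooled_cols[stage] = counts[[m.sample_id for m in members]].sum(axis=1)
        pooled_meta.append(
            SampleInfo(
                sample_id=stage,
                stage=stage,
                hours_post_fertilization=members[0].hours_post_fertilization,
                stage_class=members[0].stage_class,
                total_valid_reads=sum(m.total_valid_reads for m in members),
            )
        )
    order = [s.stage for s in sorted(pooled_meta, key=lambda m: (
        m.hours_post_fertilization if m.hours_post_fertilization is not None else 0.0,
        m.stage))]
    pooled_meta.sort(key=lambda m: order.index(m.stage))
    return pd.DataFrame(pooled_cols)[order], pooled_meta


def compute_rpkm(
    counts: pd.DataFrame,
    exon_lengths: Mapping[str, int],
    samples: Sequence[SampleInfo],
) -> pd.DataFrame:
    """Genes x samples RPKM matrix."""
    totals = {s.sample_id: s.total_valid_reads for s in samples}
    missing = [c for c in counts.columns if c not in totals]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    lens = []
    for g in counts.index:
        L = exon_lengths.get(g)
        if L is None or L <= 0:
            raise ValueError(f"gene {g}: zero or missing exon length")
        lens.append(L)
    len_kb = np.asarray(lens, dtype=float) / 1e3
    rpkm = counts.astype(float).copy()
    for c in rpkm.columns:
        rpkm[c] = rpkm[c] / len_kb / (totals[c] / 1e6)
    return rpkm


def mean_normalized_expression(
    rpkm: pd.DataFrame, gene_set: Sequence[str]
) -> pd.Series:
    """Per stage: sum of the set's RPKM divided by the set size."""
    genes = [g for g in gene_set if g in rpkm.index]
    if not genes:
        raise ValueError("empty gene set")
    return rpkm.loc[genes].sum(axis=0) / len(gene_set)


def proportion_expressed(
    counts: pd.DataFrame, gene_set: Sequence[str], min_count: int = 1
) -> pd.Series:
    """Fraction of the set with >= min_count reads, per stage."""
    genes = [g for g in gene_set if g in counts.index]
    if not gene_set:
        raise ValueError("empty gene set")
    return (counts.loc[genes] >= min_count).sum(axis=0) / len(gene_set)


def peak_stage(row: pd.Series, k: int = 1) -> Optional[str]:
    """Stage with the k-th highest RPKM; ties go to the earliest stage
    (column order).  None for an all-zero profile when k = 1."""
    vals = row.to_numpy(dtype=float)
    if k == 1 and not np.any(vals > 0):
        return None
    # stable sort on descending value keeps original (earliest-first) order
    order = np.argsort(-vals, kind="stable")
    if k > len(vals):
        raise ValueError(f"rank {k} exceeds number of stages {len(vals)}")
    return str(row.index[order[k - 1]])


def peak_stage_proportions(
    rpkm: pd.DataFrame, gene_set: Sequence[str], k: int = 1
) -> tuple[pd.Series, list[str]]:
    """Per-stage fraction of genes peaking there, and excluded genes."""
    genes = [g for g in gene_set if g in rpkm.index]
    peaks: dict[str, int] = {str(c): 0 for c in rpkm.columns}
    excluded: list[str] = []
    for g in genes:
        p = peak_stage(rpkm.loc[g], k)
        if p is None:
            excluded.append(g)
        else:
            peaks[p] += 1
    n = len(genes) - len(excluded)
    props = pd.Series(
        {c: (peaks[c] / n if n else 0.0) for c in peaks}, dtype=float
    )[list(map(str, rpkm.columns))]
    return props, excluded


def late_stage_enrichment(
    peaks_by_gene: Mapping[str, Optional[str]],
    calls: Mapping[str, ConservationCall],
    stage_class: Mapping[str, str],
    category_1: str,
    category_2: str,
) -> dict[str, float]:
    """Pearson chi-square (no continuity correction) on late-peaking
    fractions of two categories.

    Returns a, b, n1, n2, the two percentages, the statistic and the
    two-sided p; flags the result when any expected cell is below 1.
    """
    def _tally(cat: str) -> tuple[int, int]:
        genes = [
            g for g, c in calls.items()
            if c.category == cat and peaks_by_gene.get(g) is not None
        ]
        late = sum(1 for g in genes if stage_class.get(peaks_by_gene[g]) == LATE)
        return late, len(genes)
    a, n1 = _tally(category_1)
    b, n2 = _tally(category_2)
    if n1 == 0 or n2 == 0:
        raise ValueError("a category has no genes with a defined peak")
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    chi2, p = pearson_chi2_2x2(a, n1, b, n2)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    flagged = bool((expected < 1).any())
    if flagged:
        warnings.warn("chi-square expected cell < 1; result flagged")
    return {
        "late_1": a, "n_1": n1, "late_2": b, "n_2": n2,
        "percent_1": 100.0 * a / n1, "percent_2": 100.0 * b / n2,
        "chi2": chi2, "p_value": p, "low_expected_flag": flagged,
    }


def pearson_chi2_2x2(a: int, n1: int, b: int, n2: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) comparing the
    fractions a/n1 and b/n2.  Equal fractions give statistic 0, p = 1;
    a degenerate margin (both fractions 0 or both 1) likewise carries no
    signal and returns (0, 1)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("empty group")
    c, d = n1 - a, n2 - b
    n = n1 + n2
    col1, col2 = a + b, c + d
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (n1 * n2 * col1 * col2)
    return float(chi2), float(_scipy_stats.chi2.sf(chi2, df=1))


def temporal_specificity(row: Sequence[float]) -> Optional[float]:
    """1 - H/log2(N) over the row's RPKM shares; None when all zero."""
    vals = np.asarray(row, dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("temporal specificity needs at least 2 stages")
    if np.any(vals < 0):
        raise ValueError("negative expression values")
    total = vals.sum()
    if total == 0:
        return None
    p = vals / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return 1.0 - entropy / math.log2(n)


def specificity_scores(rpkm: pd.DataFrame) -> pd.Series:
    """Per-gene temporal specificity; NaN marks undefined (all-zero)."""
    return pd.Series(
        {
            g: (s if (s := temporal_specificity(rpkm.loc[g])) is not None else np.nan)
            for g in rpkm.index
        },
        dtype=float,
    )


def specificity_contrast(
    scores: Mapping[str, float] | pd.Series,
    calls: Mapping[str, ConservationCall],
) -> GroupSummary:
    """ANOVA of specificity scores across conservation categories;
    undefined scores are dropped."""
    groups: dict[str, list[float]] = {}
    items = scores.items() if hasattr(scores, "items") else scores
    for gid, s in items:
        if s is None or (isinstance(s, float) and math.isnan(s)):
            continue
        call = calls.get(gid)
        if call is None:
            continue
        groups.setdefault(call.category, []).append(float(s))
    return group_anova(groups)
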