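"""Per-gene structural features and per-stratum summaries.

For every gene: genomic span length, protein length (longest isoform),
exon count (transcript with the most exons), GC content over the span
(introns included by default; a CDS-only mode is available), transcript
support, and chromosome.  Category-level contrasts reuse the ANOVA +
post-hoc machinery in :mod:`lineagescan.stats`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .gtfio import GeneModel
from .phylostrat import CATEGORIES, ConservationCall
from .stats import GroupSummary, group_anova, spearman_vs_length

GC_SPAN = "span"
GC_CDS = "cds"


@dataclass
class FeatureRow:
    gene_id: str
    gene_size: int          # genomic span, nt
    protein_size: int       # longest isoform, aa
    exon_number: int        # transcript with most exons
    gc_content: float       # percent over unambiguous bases
    has_transcript_support: bool
    chromosome: str

    def __post_init__(self) -> None:
        if self.gene_size < 1 or self.exon_number < 1:
            raise ValueError(f"{self.gene_id}: degenerate feature values")
        if not 0.0 <= self.gc_content <= 100.0:
            raise ValueError(f"{self.gene_id}: GC content outside [0, 100]")


def gc_percent(seq: str) -> float:
    """GC over A/C/G/T only; ambiguous bases are excluded entirely."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    return 100.0 * gc / denom if denom else 0.0


def compute_features(
    models: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    proteins: Mapping[str, str],
    gene_isoforms: Mapping[str, Sequence[str]],
    support: Mapping[str, bool],
    gc_region: str = GC_SPAN,
) -> dict[str, FeatureRow]:
    """FeatureRow per gene.

    ``genome`` maps chromosome -> sequence; ``proteins`` maps isoform
    protein id -> sequence; ``support`` marks genes with transcript
    (EST / FL-cDNA) evidence.
    """
    if gc_region not in (GC_SPAN, GC_CDS):
        raise ValueError(f"unknown gc_region {gc_region!r}")
    rows: dict[str, FeatureRow] = {}
    for gid, g in models.items():
        if not g.transcripts:
            raise ValueError(f"gene {gid} has no transcripts")
        chrom_seq = genome.get(g.chromosome)
        if chrom_seq is None:
            raise KeyError(f"gene {gid}: chromosome {g.chromosome!r} not in genome")
        if len(chrom_seq) < g.end:
            raise ValueError(
                f"gene {gid}: chromosome {g.chromosome} shorter than gene span"
            )
        if gc_region == GC_SPAN:
            gc = gc_percent(chrom_seq[g.start - 1 : g.end])
        else:
            cds_seq = "".join(
                chrom_seq[s - 1 : e] for t in g.transcripts for s, e in t.cds
            )
            gc = gc_percent(cds_seq or chrom_seq[g.start - 1 : g.end])
        isoform_lengths = [
            len(proteins[pid].rstrip("*")) for pid in gene_isoforms.get(gid, []) if pid in proteins
        ]
        if not isoform_lengths:
            raise ValueError(f"gene {gid}: no protein sequence for any isoform")
        rows[gid] = FeatureRow(
            gene_id=gid,
            gene_size=g.span_length,
            protein_size=max(isoform_lengths),
            exon_number=max(t.exon_count for t in g.transcripts),
            gc_content=gc,
            has_transcript_support=bool(support.get(gid, False)),
            chromosome=g.chromosome,
        )
    return rows


def feature_anova(
    rows: Mapping[str, FeatureRow],
    calls: Mapping[str, ConservationCall],
    feature: str,
) -> GroupSummary:
    """One-way ANOVA of one feature across conservation categories."""
    groups: dict[str, list[float]] = {}
    for gid, row in rows.items():
        call = calls.get(gid)
        if call is None:
            continue
        groups.setdefault(call.category, []).append(float(getattr(row, feature)))
    return group_anova(groups)


def transcript_support_rate(
    rows: Mapping[str, FeatureRow],
    calls: Mapping[str, ConservationCall],
) -> dict[str, float]:
    """Percent of genes with transcript support, per category."""
    out: dict[str, float] = {}
    for cat in CATEGORIES:
        genes = [g for g, c in calls.items() if c.category == cat and g in rows]
        if not genes:
            out[cat] = float("nan")
            continue
        supported = sum(1 for g in genes if rows[g].has_transcript_support)
        out[cat] = 100.0 * supported / len(genes)
    return out


def chromosome_distribution(
    calls: Mapping[str, ConservationCall],
    models: Mapping[str, GeneModel],
    chromosomes: Optional[Sequence[str]] = None,
) -> dict[str, dict[str, dict[str, float]]]:
    """Per-category, per-chromosome counts and percentages.

    Chromosomes with zero genes of a category are listed explicitly;
    pass ``chromosomes`` to fix the universe (defaults to every
    chromosome seen in the models).
    """
    if chromosomes is None:
        chromosomes = sorted({g.chromosome for g in models.values()})
    out: dict[str, dict[str, dict[str, float]]] = {}
    for cat in CATEGORIES:
        genes = [g for g, c in calls.items() if c.category == cat]
        total = len(genes)
        per_chrom: dict[str, dict[str, float]] = {}
        for chrom in chromosomes:
            n = sum(1 for g in genes if g in models and models[g].chromosome == chrom)
            per_chrom[chrom] = {
                "count": n,
                "percent": 100.0 * n / total if total else 0.0,
            }
        out[cat] = per_chrom
    return out


def write_features(rows: Mapping[str, FeatureRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "gene_id", "gene_size", "protein_size", "exon_number",
                "gc_content", "has_transcript_support", "chromosome",
            ]
        )
        for gid in sorted(rows):
            r = rows[gid]
            w.writerow(
                [
                    r.gene_id, r.gene_size, r.protein_size, r.exon_number,
                    f"{r.gc_content:.4f}", int(r.has_transcript_support), r.chromosome,
                ]
            )


__all__ = [
    "FeatureRow",
    "compute_features",
    "feature_anova",
    "transcript_support_rate",
    "chromosome_distribution",
    "spearman_vs_length",
    "gc_percent",
    "write_features",
]
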