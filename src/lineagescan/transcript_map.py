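"""EST / FL-cDNA mapping quality control and gene assignment.

The filter chain keeps a transcript-to-genome alignment only when

* mapping length (sum of aligned blocks) >= 100 bp,
* identity = matches / (matches + mismatches) >= 96%,
* coverage within the mapping = (matches + mismatches) / mapping length
  >= 97%, and
* coverage within the whole transcript = mapping length / transcript
  length >= 75%.

When a transcript maps to several loci only the best-scoring mapping
survives, unless the runner-up is within 5% of the best score, in which
case the transcript is discarded as ambiguous.  A surviving mapping is
assigned to a gene only when it overlaps the gene span by more than
100 bp on the same strand; ties on maximal overlap leave the transcript
unassigned.  A gene counts as expressed in a tissue as soon as a single
assigned transcript from that tissue's library supports it.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from intervaltree import IntervalTree
from scipy import stats as _scipy_stats

from .gtfio import GeneModel
from .phylostrat import ConservationCall, EC
from .psl import TranscriptAlignment

PASS = "PASS"
FAIL = "FAIL"
DISCARD_AMBIGUOUS = "DISCARD_AMBIGUOUS"

#: QC thresholds (inclusive) and the ambiguity / overlap rules
MIN_MAPPING_LENGTH = 100       # bp
MIN_IDENTITY = 96.0            # percent
MIN_COVERAGE_MAPPING = 97.0    # percent
MIN_COVERAGE_TRANSCRIPT = 75.0  # percent
AMBIGUITY_GAP = 0.05           # discard when (best-second)/best < 5%
MIN_GENE_OVERLAP = 100         # strict >, bp


@dataclass
class QCVerdict:
    transcript_id: str
    status: str
    failed_criteria: list[str] = field(default_factory=list)
    # computed ratios, for reporting
    mapping_length: int = 0
    identity: float = 0.0
    coverage_mapping: float = 0.0
    coverage_transcript: float = 0.0


def qc_metrics(a: TranscriptAlignment) -> tuple[int, float, float, float]:
    ml = a.mapping_length
    aligned = a.matches + a.mismatches
    identity = 100.0 * a.matches / aligned if aligned else 0.0
    cov_map = 100.0 * aligned / ml if ml else 0.0
    cov_tx = 100.0 * ml / a.transcript_length
    return ml, identity, cov_map, cov_tx


def qc_filter(alignments: Sequence[TranscriptAlignment]) -> list[QCVerdict]:
    """Apply the four-threshold filter to each alignment independently."""
    verdicts: list[QCVerdict] = []
    for a in alignments:
        ml, identity, cov_map, cov_tx = qc_metrics(a)
        failed = []
        if ml < MIN_MAPPING_LENGTH:
            failed.append("length")
        if identity < MIN_IDENTITY:
            failed.append("identity")
        if cov_map < MIN_COVERAGE_MAPPING:
            failed.append("coverage_mapping")
        if cov_tx < MIN_COVERAGE_TRANSCRIPT:
            failed.append("coverage_transcript")
        verdicts.append(
            QCVerdict(
                transcript_id=a.transcript_id,
                status=FAIL if failed else PASS,
                failed_criteria=failed,
                mapping_length=ml,
                identity=identity,
                coverage_mapping=cov_map,
                coverage_transcript=cov_tx,
            )
        )
    return verdicts


def resolve_multimapping(
    alignments: Sequence[TranscriptAlignment],
    ambiguity_gap: float = AMBIGUITY_GAP,
) -> tuple[dict[str, TranscriptAlignment], list[str]]:
    """Keep one mapping per transcript or discard it as ambiguous.

    Input should already have passed :func:`qc_filter`.  Returns
    (surviving mapping per transcript, discarded transcript ids).
    """
    by_tx: dict[str, list[TranscriptAlignment]] = {}
    for a in alignments:
        by_tx.setdefault(a.transcript_id, []).append(a)
    kept: dict[str, TranscriptAlignment] = {}
    discarded: list[str] = []
    for tx in sorted(by_tx):
        group = sorted(by_tx[tx], key=lambda a: (-a.score, a.chromosome, a.t_start))
        if len(group) == 1:
            kept[tx] = group[0]
            continue
        best, second = group[0], group[1]
        if best.score <= 0 or (best.score - second.score) / best.score < ambiguity_gap:
            discarded.append(tx)
        else:
            kept[tx] = best
    return kept, discarded


def assign_to_genes(
    surviving: Mapping[str, TranscriptAlignment],
    models: Mapping[str, GeneModel],
    min_overlap: int = MIN_GENE_OVERLAP,
) -> dict[str, str]:
    """(transcript -> gene) for overlaps > ``min_overlap`` bp, same strand.

    Overlap is measured between the alignment's target span and the gene
    span on genome coordinates (PSL half-open spans converted to the
    1-based inclusive convention here, in one place).  Among candidate
    genes the single one with maximal overlap wins; an exact tie leaves
    the transcript unassigned.
    """
    trees: dict[str, IntervalTree] = {}
    for g in models.values():
        trees.setdefault(g.chromosome, IntervalTree()).addi(
            g.start, g.end + 1, g
        )  # tree uses half-open ends

    out: dict[str, str] = {}
    for tx in sorted(surviving):
        a = surviving[tx]
        # PSL 0-based half-open -> 1-based inclusive
        a_start, a_end = a.t_start + 1, a.t_end
        tree = trees.get(a.chromosome)
        if tree is None:
            continue
        candidates: list[tuple[int, str]] = []
        for iv in tree.overlap(a_start, a_end + 1):
            g: GeneModel = iv.data
            if g.strand != a.strand:
                continue
            overlap = min(a_end, g.end) - max(a_start, g.start) + 1
            if overlap > min_overlap:
                candidates.append((overlap, g.gene_id))
        if not candidates:
            continue
        candidates.sort(key=lambda t: (-t[0], t[1]))
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            continue  # tied best overlap -> unassigned
        out[tx] = candidates[0][1]
    return out


def build_tissue_table(
    assignments: Mapping[str, str],
    tissue_of: Mapping[str, str],
) -> dict[str, dict[str, int]]:
    """gene -> tissue -> supporting transcript count."""
    table: dict[str, dict[str, int]] = {}
    for tx in sorted(assignments):
        gene = assignments[tx]
        tissue = tissue_of.get(tx)
        if tissue is None:
            warnings.warn(f"transcript {tx} has no tissue label; skipped")
            continue
        table.setdefault(gene, {})
        table[gene][tissue] = table[gene].get(tissue, 0) + 1
    return table


def tissue_enrichment(
    table: Mapping[str, Mapping[str, int]],
    calls: Mapping[str, ConservationCall],
    tissue: str,
    category: str,
    background_category: str = EC,
) -> tuple[tuple[int, int, int, int], float]:
    """Two-sided Fisher's exact test for tissue-preferred expression.

    The 2x2 table crosses (category vs background) with (expressed in
    ``tissue`` vs expressed only elsewhere), over genes expressed in at
    least one tissue.  Returns ((a, b, c, d), p) with rows = category,
    background and columns = in-tissue, elsewhere.
    """
    def _counts(cat: str) -> tuple[int, int]:
        genes = [
            g for g, c in calls.items() if c.category == cat and g in table and table[g]
        ]
        in_tissue = sum(1 for g in genes if table[g].get(tissue, 0) >= 1)
        return in_tissue, len(genes) - in_tissue
    a, b = _counts(category)
    c, d = _counts(background_category)
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("a category has no expressed genes: empty margin")
    if (a + c) == 0 and (b + d) == 0:
        raise ValueError("empty table")
    _, p = _scipy_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return (a, b, c, d), float(p)


def filter_chain(
    alignments: Sequence[TranscriptAlignment],
    ambiguity_gap: float = AMBIGUITY_GAP,
) -> tuple[list[QCVerdict], dict[str, TranscriptAlignment], dict[str, str]]:
    """QC filter then multi-mapping resolution.

    Returns (per-alignment verdicts, surviving mapping per transcript,
    per-transcript status).  A transcript's status is PASS when one of
    its mappings survives, DISCARD_AMBIGUOUS when near-equal best
    mappings forced a discard, and FAIL when no mapping passed QC.
    """
    verdicts = qc_filter(alignments)
    passing = [a for a, v in zip(alignments, verdicts) if v.status == PASS]
    kept, discarded = resolve_multimapping(passing, ambiguity_gap)
    status: dict[str, str] = {}
    for a in alignments:
        status.setdefault(a.transcript_id, FAIL)
    for tx in discarded:
        status[tx] = DISCARD_AMBIGUOUS
    for tx in kept:
        status[tx] = PASS
    return verdicts, kept, status


def write_verdicts(verdicts: Sequence[QCVerdict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["transcript_id", "status", "failed_criteria",
             "mapping_length", "identity", "coverage_mapping", "coverage_transcript"]
        )
        for v in verdicts:
            w.writerow(
                [v.transcript_id, v.status, ",".join(v.failed_criteria) or ".",
                 v.mapping_length, f"{v.identity:.3f}",
                 f"{v.coverage_mapping:.3f}", f"{v.coverage_transcript:.3f}"]
            )
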