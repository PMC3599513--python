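"""Duplication-origin inference from paralog conservation.

A lineage-specific gene is taken to have originated by duplication
followed by rapid divergence when at least one of its paralogs is
evolutionarily conserved (category EC).  The module also contrasts a
category's percent identity to conserved vs non-conserved paralog
partners with a Welch two-sample t-test: under the
duplication-divergence model, similarity to the conserved parent should
be lower.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .phylostrat import ConservationCall, EC
from .stats import welch_t

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ParalogRecord:
    gene_id: str
    paralog_gene_id: str
    similarity: float  # percent identity

    def __post_init__(self) -> None:
        if self.gene_id == self.paralog_gene_id:
            raise ValueError(f"{self.gene_id}: self-paralog record")
        if not 0.0 <= self.similarity <= 100.0:
            raise ValueError(f"{self.gene_id}: similarity outside [0, 100]")


@dataclass
class OriginSummary:
    category: str
    n_total: int
    n_with_paralog: int
    n_with_conserved_paralog: int

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_with_conserved_paralog <= self.n_with_paralog <= self.n_total
        ):
            raise ValueError("inconsistent origin counts")

    @property
    def fraction_with_paralog(self) -> float:
        return self.n_with_paralog / self.n_total if self.n_total else 0.0

    @property
    def fraction_duplication_origin(self) -> float:
        return self.n_with_conserved_paralog / self.n_total if self.n_total else 0.0


def _dedupe(paralogs: Sequence[ParalogRecord]) -> list[ParalogRecord]:
    """Deduplicate on the unordered gene pair (first record wins)."""
    seen: set[frozenset[str]] = set()
    out: list[ParalogRecord] = []
    for r in paralogs:
        key = frozenset((r.gene_id, r.paralog_gene_id))
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def partner_category(
    record: ParalogRecord, calls: Mapping[str, ConservationCall]
) -> str:
    call = calls.get(record.paralog_gene_id)
    if call is None:
        logger.info(
            "paralog %s of %s not in call set; treated as non-conserved",
            record.paralog_gene_id, record.gene_id,
        )
        return UNKNOWN
    return call.category


def infer_origin(
    paralogs: Sequence[ParalogRecord],
    calls: Mapping[str, ConservationCall],
    category: str,
) -> OriginSummary:
    """Counts and fractions of duplication-derived genes in a category.

    Paralogs absent from the call set count as non-conserved.  Records
    are deduplicated on the unordered pair, so the summary is invariant
    to record order and repeated rows.
    """
    genes = sorted(g for g, c in calls.items() if c.category == category)
    recs = _dedupe([r for r in paralogs if r.gene_id in set(genes)])
    with_par = {r.gene_id for r in recs}
    with_cons = {
        r.gene_id for r in recs if partner_category(r, calls) == EC
    }
    return OriginSummary(
        category=category,
        n_total=len(genes),
        n_with_paralog=len(with_par),
        n_with_conserved_paralog=len(with_cons),
    )


def similarity_contrast(
    paralogs: Sequence[ParalogRecord],
    calls: Mapping[str, ConservationCall],
    category: str,
) -> dict[str, Optional[float]]:
    """Welch t-test of similarity to conserved vs non-conserved partners.

    Means are always reported; the test is skipped (t, p None) when a
    side has fewer than two values.
    """
    genes = {g for g, c in calls.items() if c.category == category}
    cons: list[float] = []
    noncons: list[float] = []
    for r in _dedupe([r for r in paralogs if r.gene_id in genes]):
        (cons if partner_category(r, calls) == EC else noncons).append(r.similarity)
    out: dict[str, Optional[float]] = {
        "mean_conserved": sum(cons) / len(cons) if cons else None,
        "mean_nonconserved": sum(noncons) / len(noncons) if noncons else None,
        "n_conserved": len(cons),
        "n_nonconserved": len(noncons),
        "t_statistic": None,
        "p_value": None,
    }
    if len(cons) >= 2 and len(noncons) >= 2:
        t, p = welch_t(cons, noncons)
        out["t_statistic"], out["p_value"] = t, p
    return out


def read_paralogs(path: str | Path) -> list[ParalogRecord]:
    out: list[ParalogRecord] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        for row in reader:
            if not row:
                continue
            out.append(
                ParalogRecord(
                    gene_id=row[0], paralog_gene_id=row[1], similarity=float(row[2])
                )
            )
    return out


def write_origin_summary(
    summaries: Sequence[OriginSummary],
    contrasts: Mapping[str, Mapping[str, Optional[float]]],
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["category", "n_total", "n_with_paralog", "n_with_conserved_paralog",
             "pct_with_paralog", "pct_duplication_origin",
             "mean_similarity_conserved_partner", "mean_similarity_other_partner",
             "welch_t", "p_value"]
        )
        for s in summaries:
            c = contrasts.get(s.category, {})
            w.writerow(
                [s.category, s.n_total, s.n_with_paralog, s.n_with_conserved_paralog,
                 f"{100 * s.fraction_with_paralog:.1f}",
                 f"{100 * s.fraction_duplication_origin:.1f}",
                 c.get("mean_conserved"), c.get("mean_nonconserved"),
                 c.get("t_statistic"), c.get("p_value")]
            )
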