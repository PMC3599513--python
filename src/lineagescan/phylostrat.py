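"""Homology-cascade classification of focal genes.

Each focal gene is placed in one of three conservation strata by where in
the species panel its closest detectable homologs lie:

* ``EC`` (evolutionarily conserved) — any isoform has a qualifying hit in
  an out-group species;
* ``CTSG`` (conserved clade-specific) — no out-group hit, but a
  qualifying hit in at least one non-focal in-group species;
* ``ORPHAN`` — no qualifying hit in any non-focal species.

A hit qualifies when its e-value is strictly below the cutoff (default
1e-5).  Hits are aggregated over all isoforms of a gene: one hitting
isoform is enough.  Out-group species with annotated proteomes are
searched in protein mode only; translated-genome searches are reserved
for species that lack a proteome (a flag forces genome mode everywhere).
An optional validation hit table — e.g. from a broader external database
re-check — may promote CTSG/ORPHAN calls back to EC.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .aligner import MODE_GENOME, MODE_PROT, SimilarityHit, builtin_search
from .panel import FOCAL, INGROUP, OUTGROUP, SpeciesPanel
from .seqio import read_fasta

EC = "EC"
CTSG = "CTSG"
ORPHAN = "ORPHAN"
CATEGORIES = (EC, CTSG, ORPHAN)

DEFAULT_CUTOFF = 1e-5


@dataclass
class ConservationCall:
    gene_id: str
    category: str
    #: (species_id, best e-value, mode) rows supporting the call
    evidence: list[tuple[str, float, str]] = field(default_factory=list)
    isoforms_considered: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_genes(
    hits: Sequence[SimilarityHit],
    panel: SpeciesPanel,
    gene_isoforms: Mapping[str, Sequence[str]],
    cutoff: float = DEFAULT_CUTOFF,
    validation_hits: Optional[Sequence[SimilarityHit]] = None,
) -> dict[str, ConservationCall]:
    """Assign every focal gene exactly one conservation category.

    ``gene_isoforms`` maps gene id -> protein (isoform) ids; every hit's
    query must be one of those proteins.  ``validation_hits`` are treated
    as out-group evidence: a qualifying validation hit promotes a
    CTSG/ORPHAN gene to EC, mirroring a re-check against a broad external
    protein database.  Classification is a pure function of the hit
    table — deterministic and independent of row order.
    """
    if cutoff <= 0:
        raise ValueError("e-value cutoff must be positive")
    if not gene_isoforms:
        raise ValueError("no genes to classify")

    protein_to_gene: dict[str, str] = {}
    for gid, isos in gene_isoforms.items():
        for iso in isos:
            protein_to_gene[iso] = gid

    focal_id = panel.focal.species_id
    # best qualifying evidence per (gene, species)
    best: dict[str, dict[str, tuple[float, str]]] = {g: {} for g in gene_isoforms}

    def _ingest(h: SimilarityHit, species_override: Optional[str] = None) -> None:
        gid = protein_to_gene.get(h.query_protein_id)
        if gid is None:
            raise KeyError(
                f"hit query {h.query_protein_id!r} does not map to any focal gene"
            )
        sp = species_override if species_override is not None else h.subject_species_id
        if sp != "__validation__" and sp not in panel:
            raise KeyError(f"hit references unknown species {sp!r}")
        if sp == focal_id:  # self-hits carry no phylostratigraphic signal
            return
        if not h.e_value < cutoff:
            return
        prev = best[gid].get(sp)
        if prev is None or h.e_value < prev[0]:
            best[gid][sp] = (h.e_value, h.mode)

    for h in hits:
        _ingest(h)
    for h in validation_hits or ():
        _ingest(h, species_override="__validation__")

    clade_of = {s.species_id: s.clade for s in panel}
    clade_of["__validation__"] = OUTGROUP

    calls: dict[str, ConservationCall] = {}
    for gid in sorted(gene_isoforms):
        ev = best[gid]
        out_ev = sorted(
            (sp, e, m) for sp, (e, m) in ev.items() if clade_of[sp] == OUTGROUP
        )
        in_ev = sorted(
            (sp, e, m) for sp, (e, m) in ev.items() if clade_of[sp] == INGROUP
        )
        if out_ev:
            cat, evidence = EC, out_ev
        elif in_ev:
            cat, evidence = CTSG, in_ev
        else:
            cat, evidence = ORPHAN, []
        calls[gid] = ConservationCall(
            gene_id=gid,
            category=cat,
            evidence=evidence,
            isoforms_considered=list(gene_isoforms[gid]),
        )
    return calls


def search_cascade(
    focal_proteins: Mapping[str, str],
    gene_isoforms: Mapping[str, Sequence[str]],
    panel: SpeciesPanel,
    cutoff: float = DEFAULT_CUTOFF,
    force_genome_search: bool = False,
    proteomes: Optional[Mapping[str, Mapping[str, str]]] = None,
    genomes: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[SimilarityHit]:
    """Run the two-stage search with the built-in aligner.

    Stage 1 searches all focal isoforms against out-group species; genes
    already conserved there are not carried into stage 2, which searches
    the remainder against the in-group.  Species with proteomes are
    searched in protein mode; proteome-less species in translated-genome
    mode.  ``proteomes``/``genomes`` may supply sequences in memory
    (species_id -> id -> sequence); otherwise the panel's FASTA paths
    are read.  Returns the combined hit table (the classifier re-derives
    categories from it, so the staging is purely a compute saving).
    """
    hits: list[SimilarityHit] = []
    proteomes = proteomes or {}
    genomes = genomes or {}

    def _read_genome(species) -> Mapping[str, str]:
        if species.species_id in genomes:
            return genomes[species.species_id]
        return read_fasta(species.genome_path)

    def _search_species(queries: Mapping[str, str], species) -> list[SimilarityHit]:
        found: list[SimilarityHit] = []
        if species.has_proteome:
            if species.species_id in proteomes:
                subjects = proteomes[species.species_id]
            else:
                subjects = read_fasta(species.proteome_path)
            found.extend(
                builtin_search(queries, subjects, species.species_id, MODE_PROT)
            )
            if force_genome_search and (
                species.genome_path or species.species_id in genomes
            ):
                found.extend(
                    builtin_search(
                        queries, _read_genome(species), species.species_id, MODE_GENOME
                    )
                )
        else:
            found.extend(
                builtin_search(
                    queries, _read_genome(species), species.species_id, MODE_GENOME
                )
            )
        return found

    # stage 1: out-group
    for sp in panel.by_clade(OUTGROUP):
        hits.extend(_search_species(focal_proteins, sp))

    conserved_genes = {
        gid
        for gid, isos in gene_isoforms.items()
        if any(
            h.e_value < cutoff and h.query_protein_id in set(isos) for h in hits
        )
    }
    remaining = {
        pid: seq
        for gid, isos in gene_isoforms.items()
        if gid not in conserved_genes
        for pid in isos
        for seq in (focal_proteins[pid],)
    }

    # stage 2: in-group, remaining genes only
    if remaining:
        for sp in panel.by_clade(INGROUP):
            hits.extend(_search_species(remaining, sp))
    return hits


def summarize_strata(
    calls: Mapping[str, ConservationCall] | Iterable[ConservationCall],
) -> dict[str, dict[str, float]]:
    """Counts and percentages per conservation category."""
    if isinstance(calls, Mapping):
        call_list = list(calls.values())
    else:
        call_list = list(calls)
    if not call_list:
        raise ValueError("no calls to summarize")
    total = len(call_list)
    out: dict[str, dict[str, float]] = {}
    for cat in CATEGORIES:
        n = sum(1 for c in call_list if c.category == cat)
        out[cat] = {"count": n, "percent": 100.0 * n / total}
    return out


def write_calls(calls: Mapping[str, ConservationCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "category", "best_evidence"])
        for gid in sorted(calls):
            c = calls[gid]
            if c.evidence:
                sp, e, m = min(c.evidence, key=lambda t: t[1])
                ev = f"{sp}:{e:.3g}:{m}"
            else:
                ev = "."
            w.writerow([gid, c.category, ev])


def read_calls(path: str | Path) -> dict[str, ConservationCall]:
    calls: dict[str, ConservationCall] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        for row in reader:
            gid, cat = row[0], row[1]
            evidence = []
            if len(row) > 2 and row[2] != ".":
                sp, e, m = row[2].rsplit(":", 2)
                evidence = [(sp, float(e), m)]
            calls[gid] = ConservationCall(gene_id=gid, category=cat, evidence=evidence)
    return calls
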