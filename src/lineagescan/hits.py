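"""12-column tabular hit files (the BLAST ``outfmt 6`` layout).

Columns: qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
sstart, send, evalue, bitscore.  External search tools can therefore be
dropped in place of the built-in aligner.  The subject species is encoded
as a ``species_id|subject_id`` prefix on sseqid, which keeps the file
strictly 12 columns.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .aligner import MODE_GENOME, MODE_PROT, SimilarityHit

COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [
                    h.query_protein_id,
                    f"{h.subject_species_id}|{h.subject_id}",
                    f"{h.percent_identity:.2f}",
                    h.length,
                    h.mismatch,
                    h.gapopen,
                    h.qstart,
                    h.qend,
                    h.sstart,
                    h.send,
                    f"{h.e_value:.3g}",
                    f"{h.bit_score:.1f}",
                ]
            )


def read_hits(path: str | Path, default_mode: str = MODE_PROT) -> list[SimilarityHit]:
    """Parse a 12-column hit file.

    Subjects whose id (after the species prefix) contains a six-frame
    segment tag (``|+0:`` etc.) are taken to be translated-genome hits.
    """
    out: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            sseqid = parts[1]
            if "|" in sseqid:
                species, subject = sseqid.split("|", 1)
            else:
                species, subject = "", sseqid
            mode = default_mode
            if "|" in subject and ":" in subject.rsplit("|", 1)[1]:
                mode = MODE_GENOME
            out.append(
                SimilarityHit(
                    query_protein_id=parts[0],
                    subject_id=subject,
                    subject_species_id=species,
                    percent_identity=float(parts[2]),
                    length=int(parts[3]),
                    mismatch=int(parts[4]),
                    gapopen=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                    mode=mode,
                )
            )
    return out
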