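"""Desk-scale protein similarity search.

A small Smith-Waterman search engine used when no external search tool's
tabular output is supplied.  Scoring is BLOSUM62 with affine gaps
(open 11, extend 1); raw scores are converted to bit scores and e-values
with the Karlin-Altschul formula using fixed, published gapped-BLOSUM62
constants.  Protein-vs-genome mode translates the subject in all six
reading frames and searches the resulting stop-free segments.

This is deliberately an exhaustive (non-heuristic) aligner: at the panel
sizes this package targets, exactness is worth more than speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

# Gapped BLOSUM62 (open 11 / extend 1) Karlin-Altschul parameters, as
# published with BLAST.  Fixed constants, not refit per database.
KA_LAMBDA = 0.267
KA_K = 0.041

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")
DNA_ALPHABET = set("ACGTN")

MODE_PROT = "PROT_VS_PROT"
MODE_GENOME = "PROT_VS_GENOME"

#: minimum length of a translated stop-free segment worth searching
_MIN_ORF_AA = 20


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


@dataclass(frozen=True)
class SimilarityHit:
    """One similarity-search result row.

    ``e_value`` is the Karlin-Altschul expect value for the search space
    of this query/subject pair; ``mode`` records whether the subject was a
    protein or a translated genome segment.
    """

    query_protein_id: str
    subject_id: str
    subject_species_id: str
    e_value: float
    bit_score: float
    percent_identity: float
    mode: str
    # extra tabular fields so hits round-trip through 12-column files
    length: int = 0
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 1
    qend: int = 0
    sstart: int = 1
    send: int = 0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value for {self.query_protein_id}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.mode not in (MODE_PROT, MODE_GENOME):
            raise ValueError(f"unknown search mode {self.mode!r}")


def _check_alphabet(seq_id: str, seq: str, alphabet: set[str]) -> None:
    for pos, ch in enumerate(seq):
        if ch.upper() not in alphabet:
            raise SequenceAlphabetError(
                f"sequence {seq_id!r}: illegal character {ch!r} at position {pos}"
            )


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def bit_score(raw_score: float) -> float:
    """Normalized (bit) score: (lambda*S - ln K) / ln 2."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def expect_value(raw_score: float, m: int, n: int) -> float:
    """Karlin-Altschul expect value E = m * n * 2**(-S')."""
    return m * n * 2.0 ** (-bit_score(raw_score))


def six_frame_segments(dna: str) -> list[tuple[str, str]]:
    """Translate ``dna`` in all six frames, split at stops.

    Returns (segment_id, peptide) pairs for every stop-free segment of at
    least ``_MIN_ORF_AA`` residues; segment ids encode frame and offset.
    """
    out: list[tuple[str, str]] = []
    seq = Seq(dna.upper())
    for strand, s in (("+", seq), ("-", seq.reverse_complement())):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            peptide = str(sub.translate())
            start = 0
            for chunk in peptide.split("*"):
                if len(chunk) >= _MIN_ORF_AA:
                    out.append((f"{strand}{frame}:{start}", chunk))
                start += len(chunk) + 1
    return out


def _align_pair(aligner: PairwiseAligner, query: str, subject: str):
    """Best local alignment of a pair, or None when no positive score."""
    try:
        alignments = aligner.align(query, subject)
        if len(alignments) == 0:
            return None
        return alignments[0]
    except (OverflowError, MemoryError):  # pathological inputs only
        return None


def builtin_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    subject_species_id: str,
    mode: str = MODE_PROT,
    e_ceiling: float = 10.0,
) -> list[SimilarityHit]:
    """All-vs-all local alignment search returning hits with e < ceiling.

    Parameters
    ----------
    queries
        protein_id -> amino-acid sequence.
    subjects
        For ``PROT_VS_PROT``: subject protein_id -> amino-acid sequence.
        For ``PROT_VS_GENOME``: sequence_id -> DNA; each subject is
        translated in six frames and every stop-free segment is searched.
    e_ceiling
        Hits with e-value >= this ceiling are dropped.
    """
    if not queries or not subjects:
        raise ValueError("builtin_search requires non-empty query and subject sets")
    if mode not in (MODE_PROT, MODE_GENOME):
        raise ValueError(f"unknown search mode {mode!r}")

    for qid, q in queries.items():
        _check_alphabet(qid, q, PROTEIN_ALPHABET)

    if mode == MODE_PROT:
        for sid, s in subjects.items():
            _check_alphabet(sid, s, PROTEIN_ALPHABET)
        search_units = [(sid, s.upper(), len(s)) for sid, s in subjects.items()]
    else:
        search_units = []
        for sid, dna in subjects.items():
            _check_alphabet(sid, dna, DNA_ALPHABET)
            # search space for genome mode: total translated residues
            segs = six_frame_segments(dna)
            n_total = sum(len(p) for _, p in segs)
            for seg_id, peptide in segs:
                search_units.append((f"{sid}|{seg_id}", peptide, n_total))

    aligner = _make_aligner()
    hits: list[SimilarityHit] = []
    for qid, qseq in queries.items():
        q = qseq.upper().rstrip("*")
        for sid, sseq, n_space in search_units:
            aln = _align_pair(aligner, q, sseq)
            if aln is None or aln.score <= 0:
                continue
            e = expect_value(aln.score, len(q), n_space)
            if e >= e_ceiling:
                continue
            counts = aln.counts()
            aligned_cols = aln.length
            pid = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
            qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
            ss, se = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
            hits.append(
                SimilarityHit(
                    query_protein_id=qid,
                    subject_id=sid,
                    subject_species_id=subject_species_id,
                    e_value=e,
                    bit_score=bit_score(aln.score),
                    percent_identity=pid,
                    mode=mode,
                    length=aligned_cols,
                    mismatch=int(counts.mismatches),
                    gapopen=int(
                        counts.open_internal_insertions + counts.open_internal_deletions
                    ),
                    qstart=qs + 1,
                    qend=qe,
                    sstart=ss + 1,
                    send=se,
                )
            )
    hits.sort(key=lambda h: (h.query_protein_id, h.e_value, h.subject_id))
    return hits
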