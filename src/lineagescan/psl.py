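"""PSL transcript-to-genome alignments.

Standard 21-column PSL: matches, misMatches, repMatches, nCount,
qNumInsert, qBaseInsert, tNumInsert, tBaseInsert, strand, qName, qSize,
qStart, qEnd, tName, tSize, tStart, tEnd, blockCount, blockSizes,
qStarts, tStarts.  Target coordinates are 0-based half-open.  The
alignment score is the UCSC BLAT score,
matches + repMatches - misMatches - qNumInsert - tNumInsert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

PSL_COLUMNS = 21


@dataclass
class TranscriptAlignment:
    transcript_id: str
    transcript_length: int
    chromosome: str
    strand: str
    t_start: int  # 0-based half-open
    t_end: int
    matches: int
    mismatches: int
    block_sizes: list[int] = field(default_factory=list)
    t_starts: list[int] = field(default_factory=list)
    rep_matches: int = 0
    n_count: int = 0
    q_num_insert: int = 0
    q_base_insert: int = 0
    t_num_insert: int = 0
    t_base_insert: int = 0
    q_start: int = 0
    q_end: int = 0
    t_size: int = 0

    def __post_init__(self) -> None:
        if self.transcript_length <= 0:
            raise ValueError(f"{self.transcript_id}: transcript length must be positive")
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(f"{self.transcript_id}: bad target span")
        if len(self.block_sizes) != len(self.t_starts):
            raise ValueError(f"{self.transcript_id}: block arrays differ in length")
        for (s1, w1), s2 in zip(zip(self.t_starts, self.block_sizes), self.t_starts[1:]):
            if s2 < s1 + w1:
                raise ValueError(f"{self.transcript_id}: unsorted/overlapping blocks")
        if self.matches + self.mismatches > self.mapping_length:
            raise ValueError(
                f"{self.transcript_id}: matches+mismatches exceed aligned bases"
            )

    @property
    def mapping_length(self) -> int:
        """Total aligned bases: sum of block sizes."""
        return sum(self.block_sizes)

    @property
    def score(self) -> int:
        """UCSC BLAT score."""
        return (
            self.matches
            + self.rep_matches
            - self.mismatches
            - self.q_num_insert
            - self.t_num_insert
        )


def read_psl(path: str | Path) -> list[TranscriptAlignment]:
    out: list[TranscriptAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue  # optional PSL header block
            f = line.split("\t")
            if len(f) != PSL_COLUMNS:
                raise ValueError(f"{path}:{lineno}: expected {PSL_COLUMNS} PSL columns")
            out.append(
                TranscriptAlignment(
                    matches=int(f[0]),
                    mismatches=int(f[1]),
                    rep_matches=int(f[2]),
                    n_count=int(f[3]),
                    q_num_insert=int(f[4]),
                    q_base_insert=int(f[5]),
                    t_num_insert=int(f[6]),
                    t_base_insert=int(f[7]),
                    strand=f[8],
                    transcript_id=f[9],
                    transcript_length=int(f[10]),
                    q_start=int(f[11]),
                    q_end=int(f[12]),
                    chromosome=f[13],
                    t_size=int(f[14]),
                    t_start=int(f[15]),
                    t_end=int(f[16]),
                    block_sizes=[int(x) for x in f[18].rstrip(",").split(",") if x],
                    t_starts=[int(x) for x in f[20].rstrip(",").split(",") if x],
                )
            )
    return out


def write_psl(alignments: Iterable[TranscriptAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            q_starts = []
            pos = a.q_start
            for w in a.block_sizes:  # contiguous query blocks; fine for fixtures
                q_starts.append(pos)
                pos += w
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        a.matches, a.mismatches, a.rep_matches, a.n_count,
                        a.q_num_insert, a.q_base_insert, a.t_num_insert,
                        a.t_base_insert, a.strand, a.transcript_id,
                        a.transcript_length, a.q_start, a.q_end, a.chromosome,
                        a.t_size, a.t_start, a.t_end, len(a.block_sizes),
                        ",".join(map(str, a.block_sizes)) + ",",
                        ",".join(map(str, q_starts)) + ",",
                        ",".join(map(str, a.t_starts)) + ",",
                    ]
                )
                + "\n"
            )
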