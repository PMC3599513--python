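"""Gene models and GTF input/output.

Coordinates follow the GTF convention: 1-based, inclusive on both ends.
Only the feature types this package consumes (``exon`` and ``CDS``) are
read; everything else in a GTF passes through untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

Interval = tuple[int, int]  # 1-based inclusive


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for a, b in self.exons + self.cds:
            if a > b:
                raise ValueError(f"{self.transcript_id}: interval {a}-{b} reversed")
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    start: int  # 1-based inclusive genomic span
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    def exon_union_length(self) -> int:
        """Length of the union of all exons over all transcripts."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        if not ivs:
            return 0
        total = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        return total


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from a GTF file, keyed by gene id."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = f
            if ftype not in ("exon", "CDS"):
                continue
            a = _parse_attributes(attrs)
            gid, tid = a.get("gene_id"), a.get("transcript_id")
            if gid is None or tid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id/transcript_id")
            g = genes.setdefault(
                gid, {"chromosome": chrom, "strand": strand, "transcripts": {}}
            )
            t = g["transcripts"].setdefault(tid, {"exons": [], "cds": []})
            iv = (int(start), int(end))
            t["exons" if ftype == "exon" else "cds"].append(iv)

    out: dict[str, GeneModel] = {}
    for gid, g in genes.items():
        transcripts = [
            Transcript(transcript_id=tid, exons=t["exons"], cds=t["cds"])
            for tid, t in sorted(g["transcripts"].items())
        ]
        all_iv = [iv for t in transcripts for iv in t.exons]
        out[gid] = GeneModel(
            gene_id=gid,
            chromosome=g["chromosome"],
            strand=g["strand"],
            start=min(s for s, _ in all_iv),
            end=max(e for _, e in all_iv),
            transcripts=transcripts,
        )
    return out


def write_gtf(models: Mapping[str, GeneModel] | Iterable[GeneModel], path: str | Path,
              source: str = "lineagescan") -> None:
    if isinstance(models, Mapping):
        models = list(models.values())
    with open(path, "w") as fh:
        for g in sorted(models, key=lambda m: (m.chromosome, m.start, m.gene_id)):
            for t in g.transcripts:
                for ftype, ivs in (("exon", t.exons), ("CDS", t.cds)):
                    for s, e in ivs:
                        attrs = (
                            f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                        )
                        fh.write(
                            f"{g.chromosome}\t{source}\t{ftype}\t{s}\t{e}\t.\t"
                            f"{g.strand}\t.\t{attrs}\n"
                        )
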