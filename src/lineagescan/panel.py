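"""Clade-structured species panel.

The homology cascade needs to know, for every reference species, whether
it sits inside the focal lineage's in-group clade or outside it, and
whether an annotated proteome is available (species with a genome but no
proteome are searched in translated-genome mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

FOCAL = "FOCAL"
INGROUP = "INGROUP"
OUTGROUP = "OUTGROUP"
CLADES = (FOCAL, INGROUP, OUTGROUP)


@dataclass
class SpeciesTaxon:
    species_id: str
    clade: str
    has_proteome: bool = True
    proteome_path: Optional[str] = None
    genome_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"{self.species_id}: unknown clade {self.clade!r}")
        if not self.has_proteome and self.genome_path is None:
            raise ValueError(
                f"{self.species_id}: a genome path is required when no proteome is available"
            )


@dataclass
class SpeciesPanel:
    """The full reference panel; exactly one focal species."""

    species: list[SpeciesTaxon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("empty species panel")
        n_focal = sum(1 for s in self.species if s.clade == FOCAL)
        if n_focal != 1:
            raise ValueError(f"panel must contain exactly one FOCAL species, got {n_focal}")
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids in panel")

    @property
    def focal(self) -> SpeciesTaxon:
        return next(s for s in self.species if s.clade == FOCAL)

    def by_clade(self, clade: str) -> list[SpeciesTaxon]:
        return [s for s in self.species if s.clade == clade]

    def __getitem__(self, species_id: str) -> SpeciesTaxon:
        for s in self.species:
            if s.species_id == species_id:
                return s
        raise KeyError(f"unknown species id {species_id!r}")

    def __contains__(self, species_id: str) -> bool:
        return any(s.species_id == species_id for s in self.species)

    def __iter__(self) -> Iterable[SpeciesTaxon]:
        return iter(self.species)


def write_panel(panel: SpeciesPanel, path: str | Path) -> None:
    doc = {
        "species": [
            {
                "species_id": s.species_id,
                "clade": s.clade,
                "has_proteome": s.has_proteome,
                "proteome_path": s.proteome_path,
                "genome_path": s.genome_path,
            }
            for s in panel.species
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_panel(path: str | Path) -> SpeciesPanel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = Path(path).parent

    def _resolve(p: Optional[str]) -> Optional[str]:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    return SpeciesPanel(
        species=[
            SpeciesTaxon(
                species_id=d["species_id"],
                clade=d["clade"],
                has_proteome=bool(d.get("has_proteome", True)),
                proteome_path=_resolve(d.get("proteome_path")),
                genome_path=_resolve(d.get("genome_path")),
            )
            for d in doc["species"]
        ]
    )
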