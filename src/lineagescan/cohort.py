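"""Self-contained synthetic cohort with planted ground truth.

Generates everything the downstream stages consume — focal gene models
and sequences, a clade-structured species panel with planted homologs,
a threshold-straddling PSL fixture, a stage-structured count matrix and
a paralog table — together with the planted labels, so the whole
pipeline is testable without any external download.

Design of the planted signal:

* conserved (EC) genes get a per-site-mutated copy of one isoform
  planted in at least one out-group species (a subset only in the
  out-group species that has a genome but no proteome, to exercise the
  translated-genome search path) and in one in-group species;
* clade-specific (CTSG) genes get mutated copies in in-group species
  only;
* orphan genes are i.i.d. draws from a background amino-acid
  distribution, rejected and redrawn if the built-in search finds any
  cross-species hit below the cutoff;
* orphan gene models are short and exon-poor relative to conserved
  genes, so the structural contrasts have a planted direction;
* EC genes get stage-uniform expression, lineage-specific genes are
  stage-restricted to one (late) stage;
* a subset of lineage-specific genes gets an EC paralog partner with
  low similarity, the rest non-conserved partners with high similarity.

Counts are negative binomial (mean/dispersion parameterization,
``var = mu + dispersion * mu**2``); ``nb_dispersion = 0`` is the
noiseless limit in which each count equals its rounded mean.  Library
sizes are drawn log-uniformly over a 4-fold range so RPKM normalization
is actually exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .aligner import MODE_GENOME, MODE_PROT, builtin_search
from .gtfio import GeneModel, Transcript, write_gtf
from .panel import FOCAL, INGROUP, OUTGROUP, SpeciesPanel, SpeciesTaxon, write_panel
from .psl import TranscriptAlignment, write_psl
from .seqio import write_fasta
from .transcript_map import DISCARD_AMBIGUOUS, FAIL, PASS

UNIFORM = "UNIFORM"
STAGE_RESTRICTED = "STAGE_RESTRICTED"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# background amino-acid frequencies (rounded vertebrate averages)
AA_FREQS = np.array(
    [0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
     0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_CODON_ALT = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "TTA", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAG", "R": "AGA", "S": "AGC", "T": "ACA", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}

TISSUE_POOL = ["gonad", "brain", "liver", "kidney", "sense_organ"]


class CohortSelfTestError(RuntimeError):
    """Planted homologs are not recoverable under the configured cutoff."""


@dataclass
class CohortConfig:
    seed: int = 1
    n_ec: int = 12
    n_ctsg: int = 8
    n_orphan: int = 6
    n_ingroup_species: int = 3
    n_outgroup_species: int = 3
    protein_len_range: tuple[int, int] = (80, 160)
    mutation_rate_homolog: float = 0.10
    n_paralog_pairs: int = 10
    n_chromosomes: int = 4
    n_stages: int = 15
    n_tissues: int = 5
    stage_boundary_index: int = 7  # stages >= this index are LATE
    nb_dispersion: float = 0.3
    e_cutoff: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("n_ec", "n_ctsg", "n_orphan", "n_ingroup_species",
                     "n_outgroup_species", "n_paralog_pairs", "n_chromosomes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.mutation_rate_homolog < 1.0:
            raise ValueError("mutation_rate_homolog must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_stages < 2:
            raise ValueError("need at least 2 stages")
        if not 0 < self.stage_boundary_index < self.n_stages:
            raise ValueError("stage_boundary_index must split the stage series")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues (reproductive + brain)")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")

    @property
    def stage_names(self) -> list[str]:
        return [f"stage{i:02d}" for i in range(self.n_stages)]

    @property
    def tissue_names(self) -> list[str]:
        base = TISSUE_POOL[: min(self.n_tissues, len(TISSUE_POOL))]
        extra = [f"tissue{i}" for i in range(len(base), self.n_tissues)]
        return base + extra


@dataclass
class PlantedTruth:
    gene_class: dict[str, str] = field(default_factory=dict)
    temporal_pattern: dict[str, tuple[str, Optional[int]]] = field(default_factory=dict)
    #: (gene, partner, similarity, partner_is_conserved)
    paralog_pairs: list[tuple[str, str, float, bool]] = field(default_factory=list)
    support: dict[str, bool] = field(default_factory=dict)
    #: per-transcript QC status and violated criteria
    qc_status: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    #: transcript -> source gene, for assignable ESTs
    est_gene: dict[str, str] = field(default_factory=dict)
    #: transcript -> tissue library label
    est_tissue: dict[str, str] = field(default_factory=dict)


@dataclass
class Cohort:
    config: CohortConfig
    truth: PlantedTruth
    panel: SpeciesPanel
    focal_proteins: dict[str, str]
    gene_isoforms: dict[str, list[str]]
    models: dict[str, GeneModel]
    focal_genome: dict[str, str]
    species_proteomes: dict[str, dict[str, str]]
    species_genomes: dict[str, dict[str, str]]
    alignments: list[TranscriptAlignment]
    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    paralogs: pd.DataFrame


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=AA_FREQS))


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = []
    for aa in protein:
        if rng.random() < rate:
            alt = AMINO_ACIDS.replace(aa, "")
            out.append(alt[rng.integers(len(alt))])
        else:
            out.append(aa)
    return "".join(out)


def _encode_cds(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        (_CODON_OF if rng.random() < 0.5 else _CODON_ALT)[aa] for aa in protein
    )


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ATGC"), size=length, p=p))


def _gene_architecture(cls: str, rng: np.random.Generator,
                       cfg: CohortConfig) -> tuple[int, int, tuple[int, int]]:
    """(protein length, exon count, intron length range) per class."""
    lo, hi = cfg.protein_len_range
    if cls == "EC":
        return int(rng.integers(lo, hi + 1)), int(rng.integers(4, 8)), (150, 400)
    if cls == "CTSG":
        return int(rng.integers(lo, max(lo + 1, int(0.8 * hi)))), int(rng.integers(2, 6)), (80, 250)
    return int(rng.integers(max(30, lo // 2), max(40, lo) + 1)), int(rng.integers(1, 3)), (50, 120)


def generate_cohort(config: CohortConfig, self_test: bool = True) -> Cohort:
    """Build the full synthetic cohort.

    With ``self_test=True`` every planted homolog pair is re-aligned
    with the built-in search and generation aborts if any pair fails to
    score below the e-value cutoff.
    """
    rng = np.random.default_rng(config.seed)
    truth = PlantedTruth()

    classes = (["EC"] * config.n_ec + ["CTSG"] * config.n_ctsg
               + ["ORPHAN"] * config.n_orphan)
    gene_ids = [f"g{i:04d}" for i in range(1, len(classes) + 1)]

    # --- species scaffolding -------------------------------------------
    ingroup_ids = [f"ig{i}" for i in range(1, config.n_ingroup_species + 1)]
    outgroup_ids = [f"og{i}" for i in range(1, config.n_outgroup_species + 1)]
    genome_only = outgroup_ids[-1] if outgroup_ids else None  # no proteome
    species_proteomes: dict[str, dict[str, str]] = {
        s: {} for s in ingroup_ids + outgroup_ids if s != genome_only
    }
    genome_only_proteins: list[str] = []

    # --- focal genes ----------------------------------------------------
    focal_proteins: dict[str, str] = {}
    gene_isoforms: dict[str, list[str]] = {}
    gene_seqs: dict[str, dict] = {}
    planted_pairs: list[tuple[str, str, str]] = []  # (protein_id, species, planted seq)

    forced_single_exon = False
    for gid, cls in zip(gene_ids, classes):
        if cls == "ORPHAN":
            protein = None
            for _ in range(20):  # label-purity rejection sampling
                plen, n_exons, intron_rng = _gene_architecture(cls, rng, config)
                cand = "M" + _random_protein(rng, plen - 1)
                subjects = {
                    pid: seq
                    for prot in species_proteomes.values()
                    for pid, seq in prot.items()
                }
                if not subjects:
                    protein = cand
                    break
                hits = builtin_search({gid: cand}, subjects, "panel", MODE_PROT,
                                      e_ceiling=config.e_cutoff)
                if not hits:
                    protein = cand
                    break
            if protein is None:
                raise CohortSelfTestError(
                    f"could not draw a hit-free orphan sequence for {gid}"
                )
            if not forced_single_exon:
                n_exons, forced_single_exon = 1, True
        else:
            plen, n_exons, intron_rng = _gene_architecture(cls, rng, config)
            protein = "M" + _random_protein(rng, plen - 1)

        truth.gene_class[gid] = cls
        pid = f"{gid}.t1"
        focal_proteins[pid] = protein
        gene_isoforms[gid] = [pid]
        gene_seqs[gid] = {
            "protein": protein,
            "n_exons": n_exons,
            "intron_range": intron_rng,
        }

        # plant homologs
        if cls == "EC":
            mutant = _mutate_protein(rng, protein, config.mutation_rate_homolog)
            idx = gene_ids.index(gid)
            proteome_outgroups = [s for s in outgroup_ids if s != genome_only]
            # a couple of EC genes are recoverable only via the
            # translated genome of the proteome-less out-group species
            genome_path_gene = genome_only is not None and idx < 2
            if genome_path_gene:
                genome_only_proteins.append(mutant)
                planted_pairs.append((pid, genome_only, mutant))
            elif proteome_outgroups:
                sp = proteome_outgroups[idx % len(proteome_outgroups)]
                species_proteomes[sp][f"{sp}_p{len(species_proteomes[sp]):03d}"] = mutant
                planted_pairs.append((pid, sp, mutant))
            elif genome_only is not None:
                genome_only_proteins.append(mutant)
                planted_pairs.append((pid, genome_only, mutant))
            if ingroup_ids:
                mut2 = _mutate_protein(rng, protein, config.mutation_rate_homolog)
                sp = ingroup_ids[idx % len(ingroup_ids)]
                species_proteomes[sp][f"{sp}_p{len(species_proteomes[sp]):03d}"] = mut2
        elif cls == "CTSG":
            if not ingroup_ids:
                raise ValueError("cannot plant CTSG genes without in-group species")
            idx = gene_ids.index(gid)
            for j in range(1 + idx % 2):  # one or two in-group copies
                sp = ingroup_ids[(idx + j) % len(ingroup_ids)]
                mutant = _mutate_protein(rng, protein, config.mutation_rate_homolog)
                species_proteomes[sp][f"{sp}_p{len(species_proteomes[sp]):03d}"] = mutant

    # second isoform for two EC genes (prefix truncation on an exon
    # boundary) to exercise the any-isoform rule end to end
    for gid in [g for g, c in truth.gene_class.items() if c == "EC"][:2]:
        if gene_seqs[gid]["n_exons"] >= 2:
            gene_seqs[gid]["second_isoform"] = True

    # decoy proteins so proteomes are not pure homolog lists
    for sp in sorted(species_proteomes):
        for d in range(3):
            species_proteomes[sp][f"{sp}_decoy{d}"] = "M" + _random_protein(
                rng, int(rng.integers(90, 160))
            )

    # --- focal genome assembly -----------------------------------------
    models: dict[str, GeneModel] = {}
    chrom_parts: dict[str, list[str]] = {
        f"chr{i}": [] for i in range(1, config.n_chromosomes + 1)
    }
    chrom_pos: dict[str, int] = {c: 0 for c in chrom_parts}

    for i, gid in enumerate(gene_ids):
        info = gene_seqs[gid]
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        strand = "+" if rng.random() < 0.5 else "-"
        protein, n_exons = info["protein"], info["n_exons"]
        cds = _encode_cds(rng, protein) + "TAA"
        n_codons = len(cds) // 3
        # split whole codons across exons
        cuts = sorted(rng.choice(np.arange(1, n_codons), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        bounds = [0] + [3 * c for c in cuts] + [len(cds)]
        exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        lo, hi = info["intron_range"]
        intron_seqs = [_random_dna(rng, int(rng.integers(lo, hi + 1)))
                       for _ in range(n_exons - 1)]

        region = exon_seqs[0]
        exon_local: list[tuple[int, int]] = [(0, len(exon_seqs[0]))]  # half-open local
        for intron, exon in zip(intron_seqs, exon_seqs[1:]):
            region += intron
            start = len(region)
            region += exon
            exon_local.append((start, len(region)))
        region_len = len(region)

        spacer = _random_dna(rng, int(rng.integers(200, 500)))
        chrom_parts[chrom].append(spacer)
        offset = chrom_pos[chrom] + len(spacer)
        if strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            chrom_parts[chrom].append(region.translate(comp)[::-1])
            exon_genomic = sorted(
                (offset + region_len - e + 1, offset + region_len - s)
                for s, e in exon_local
            )
        else:
            chrom_parts[chrom].append(region)
            exon_genomic = [(offset + s + 1, offset + e) for s, e in exon_local]
        chrom_pos[chrom] = offset + region_len

        transcripts = [Transcript(transcript_id=f"{gid}.t1",
                                  exons=exon_genomic, cds=exon_genomic)]
        if info.get("second_isoform"):
            # drop the transcriptionally last exon
            keep = (exon_genomic[:-1] if strand == "+" else exon_genomic[1:])
            if keep:
                tid2 = f"{gid}.t2"
                transcripts.append(Transcript(transcript_id=tid2,
                                              exons=list(keep), cds=list(keep)))
                kept_codons = sum(e - s + 1 for s, e in keep) // 3
                focal_proteins[tid2] = protein[:kept_codons]
                gene_isoforms[gid].append(tid2)
        models[gid] = GeneModel(
            gene_id=gid, chromosome=chrom, strand=strand,
            start=min(s for s, _ in exon_genomic),
            end=max(e for _, e in exon_genomic),
            transcripts=transcripts,
        )

    focal_genome = {
        c: "".join(parts) + _random_dna(rng, 200) for c, parts in chrom_parts.items()
    }

    # --- genome-only out-group species ---------------------------------
    species_genomes: dict[str, dict[str, str]] = {}
    if genome_only is not None:
        pieces = [_random_dna(rng, 400)]
        for prot in genome_only_proteins:
            pieces.append(_encode_cds(rng, prot) + "TAA")
            pieces.append(_random_dna(rng, int(rng.integers(150, 400))))
        species_genomes[genome_only] = {f"{genome_only}_scaf1": "".join(pieces)}

    # --- species panel --------------------------------------------------
    taxa = [SpeciesTaxon("focal", FOCAL, True, "focal_proteins.fa", "focal_genome.fa")]
    for s in ingroup_ids:
        taxa.append(SpeciesTaxon(s, INGROUP, True, f"{s}_proteins.fa", None))
    for s in outgroup_ids:
        if s == genome_only:
            taxa.append(SpeciesTaxon(s, OUTGROUP, False, None, f"{s}_genome.fa"))
        else:
            taxa.append(SpeciesTaxon(s, OUTGROUP, True, f"{s}_proteins.fa", None))
    panel = SpeciesPanel(species=taxa)

    # --- planted-homolog self-test --------------------------------------
    if self_test:
        for pid, sp, planted in planted_pairs:
            hits = builtin_search({pid: focal_proteins[pid]}, {"planted": planted},
                                  sp, MODE_PROT, e_ceiling=config.e_cutoff)
            if not hits:
                raise CohortSelfTestError(
                    f"planted homolog of {pid} in {sp} not recovered below "
                    f"e-value {config.e_cutoff:g}; lower mutation_rate_homolog"
                )

    # --- temporal patterns, counts, paralogs, support, PSL --------------
    # lineage-specific genes are stage-restricted; orphans skew late more
    # strongly than clade-specific genes, so the late-peak contrast has a
    # planted direction without degenerating to an all-late table
    late_prob = {"CTSG": 0.5, "ORPHAN": 0.8}
    for gid, cls in truth.gene_class.items():
        if cls == "EC":
            truth.temporal_pattern[gid] = (UNIFORM, None)
        else:
            if rng.random() < late_prob[cls]:
                stage = int(rng.integers(config.stage_boundary_index, config.n_stages))
            else:
                stage = int(rng.integers(0, config.stage_boundary_index))
            truth.temporal_pattern[gid] = (STAGE_RESTRICTED, stage)

    counts, sample_meta = generate_counts(config, truth, rng=rng)
    paralogs = _generate_paralogs(config, truth, rng)
    for gid, cls in truth.gene_class.items():
        p = {"EC": 0.85, "CTSG": 0.60, "ORPHAN": 0.35}[cls]
        truth.support[gid] = bool(rng.random() < p)
    alignments = generate_alignments(config, models, truth, rng)

    return Cohort(
        config=config, truth=truth, panel=panel,
        focal_proteins=focal_proteins, gene_isoforms=gene_isoforms,
        models=models, focal_genome=focal_genome,
        species_proteomes=species_proteomes, species_genomes=species_genomes,
        alignments=alignments, counts=counts, sample_meta=sample_meta,
        paralogs=paralogs,
    )


def generate_counts(
    config: CohortConfig,
    truth: PlantedTruth,
    rng: Optional[np.random.Generator] = None,
    equal_libraries: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-structured unique-read counts plus sample metadata.

    Uniform genes share one mean across stages; stage-restricted genes
    concentrate their mean at the planted stage.  Per-stage library-size
    factors are log-uniform over a 4-fold range; with
    ``nb_dispersion = 0`` counts equal their rounded means exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    stages = config.stage_names
    if equal_libraries:
        lib = np.ones(config.n_stages)
    else:
        lib = np.exp(rng.uniform(np.log(1.0), np.log(4.0), size=config.n_stages))
    base_uniform, base_peak, base_off = 40.0, 400.0, 0.5

    genes = sorted(truth.gene_class)
    mat = np.zeros((len(genes), config.n_stages), dtype=int)
    for i, gid in enumerate(genes):
        pattern, stage = truth.temporal_pattern[gid]
        if pattern == UNIFORM:
            mu = base_uniform * lib
        else:
            mu = base_off * lib.copy()
            mu[stage] = base_peak * lib[stage]
        if config.nb_dispersion == 0:
            mat[i] = np.rint(mu).astype(int)
        else:
            n_param = 1.0 / config.nb_dispersion
            p_param = n_param / (n_param + mu)
            mat[i] = rng.negative_binomial(n_param, p_param)

    counts = pd.DataFrame(mat, index=genes, columns=stages)
    col_sums = counts.sum(axis=0).to_numpy()
    totals = (col_sums + np.rint(5e4 * lib)).astype(int)
    hpf = np.round(np.linspace(0.75, 120.0, config.n_stages), 2)
    sample_meta = pd.DataFrame(
        {
            "sample_id": stages,
            "stage": stages,
            "hours_post_fertilization": hpf,
            "stage_class": [
                "EARLY" if i < config.stage_boundary_index else "LATE"
                for i in range(config.n_stages)
            ],
            "total_valid_reads": totals,
        }
    )
    return counts, sample_meta


def _generate_paralogs(
    config: CohortConfig, truth: PlantedTruth, rng: np.random.Generator
) -> pd.DataFrame:
    ls_genes = sorted(g for g, c in truth.gene_class.items() if c != "EC")
    ec_genes = sorted(g for g, c in truth.gene_class.items() if c == "EC")
    rows = []
    for k in range(config.n_paralog_pairs):
        if not ls_genes:
            break
        gene = ls_genes[k % len(ls_genes)]
        conserved = k % 3 == 0 and bool(ec_genes)  # every third pair: EC partner
        if conserved:
            partner = ec_genes[(k // 3) % len(ec_genes)]
            sim = float(np.round(rng.uniform(18.0, 38.0), 2))
        else:
            others = [g for g in ls_genes if g != gene]
            if not others:
                continue
            partner = others[k % len(others)]
            sim = float(np.round(rng.uniform(60.0, 92.0), 2))
        if any(
            {gene, partner} == {a, b} for a, b, _, _ in truth.paralog_pairs
        ):
            continue
        truth.paralog_pairs.append((gene, partner, sim, conserved))
        rows.append({"gene_id": gene, "paralog_id": partner, "similarity": sim})
    return pd.DataFrame(rows, columns=["gene_id", "paralog_id", "similarity"])


def generate_alignments(
    config: CohortConfig,
    models: dict[str, GeneModel],
    truth: Optional[PlantedTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[TranscriptAlignment]:
    """PSL fixture straddling every QC threshold, plus assignable ESTs.

    Every threshold gets one record just above and one just below it;
    one transcript has two near-equal best mappings (score gap 4%) and
    one has two well-separated mappings (gap 6%).  Planted verdicts land
    in ``truth.qc_status``; tissue-labelled assignable ESTs are planted
    so lineage-specific genes skew to the reproductive library.
    """
    if truth is None:
        truth = PlantedTruth()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if not models:
        raise ValueError("gene models required")
    genes = sorted(models)
    t_size = 10**6
    out: list[TranscriptAlignment] = []

    def _anchor(i: int) -> GeneModel:
        return models[genes[i % len(genes)]]

    def _single(tx: str, blocks: int, matches: int, mismatches: int,
                tx_len: int, status: str, failed: tuple[str, ...],
                anchor_idx: int) -> None:
        g = _anchor(anchor_idx)
        start = max(0, g.start - 1)
        out.append(
            TranscriptAlignment(
                transcript_id=tx, transcript_length=tx_len, chromosome=g.chromosome,
                strand=g.strand, t_start=start, t_end=start + blocks,
                matches=matches, mismatches=mismatches,
                block_sizes=[blocks], t_starts=[start], t_size=t_size,
                q_start=0, q_end=blocks,
            )
        )
        truth.qc_status[tx] = (status, failed)

    _single("est_len_pass", 100, 100, 0, 130, PASS, (), 0)
    _single("est_len_fail", 99, 99, 0, 130, FAIL, ("length",), 1)
    _single("est_id_pass", 1000, 960, 40, 1250, PASS, (), 2)
    _single("est_id_fail", 1000, 959, 41, 1250, FAIL, ("identity",), 3)
    _single("est_covmap_pass", 1000, 970, 0, 1250, PASS, (), 4)
    _single("est_covmap_fail", 1000, 969, 0, 1250, FAIL, ("coverage_mapping",), 5)
    _single("est_covtx_pass", 750, 750, 0, 1000, PASS, (), 6)
    _single("est_covtx_fail", 749, 749, 0, 1000, FAIL, ("coverage_transcript",), 7)

    def _pair(tx: str, second_matches: int, second_mm: int, status: str) -> None:
        g1, g2 = _anchor(0), _anchor(1)
        s1, s2 = max(0, g1.start - 1), max(0, g2.start - 1)
        out.append(TranscriptAlignment(
            transcript_id=tx, transcript_length=1250, chromosome=g1.chromosome,
            strand=g1.strand, t_start=s1, t_end=s1 + 1000, matches=1000,
            mismatches=0, block_sizes=[1000], t_starts=[s1], t_size=t_size,
            q_start=0, q_end=1000,
        ))
        out.append(TranscriptAlignment(
            transcript_id=tx, transcript_length=1250, chromosome=g2.chromosome,
            strand=g2.strand, t_start=s2, t_end=s2 + 1000, matches=second_matches,
            mismatches=second_mm, block_sizes=[1000], t_starts=[s2], t_size=t_size,
            q_start=0, q_end=1000,
        ))
        truth.qc_status[tx] = (status, ())

    _pair("est_ambiguous", 980, 20, DISCARD_AMBIGUOUS)   # score 960: 4% gap
    _pair("est_two_loci", 970, 30, PASS)                 # score 940: 6% gap

    # assignable, tissue-labelled ESTs fully inside gene spans
    tissues = config.tissue_names
    tissue_bias = {
        "ORPHAN": ["gonad", "gonad", "gonad", tissues[1 % len(tissues)]],
        "CTSG": ["brain", "brain", "gonad", tissues[2 % len(tissues)]],
        "EC": list(tissues),
    }
    est_no = 0
    for gid in genes:
        g = models[gid]
        cls = truth.gene_class.get(gid, "EC")
        span = g.end - g.start + 1
        if span < 160:
            continue
        n_est = 1 + int(rng.integers(0, 3))
        for _ in range(n_est):
            est_no += 1
            tx = f"est_g{est_no:04d}"
            length = int(min(span - 10, rng.integers(150, 400)))
            start0 = g.start - 1 + int(rng.integers(0, span - length))
            out.append(TranscriptAlignment(
                transcript_id=tx, transcript_length=length + 20,
                chromosome=g.chromosome, strand=g.strand,
                t_start=start0, t_end=start0 + length, matches=length,
                mismatches=0, block_sizes=[length], t_starts=[start0],
                t_size=t_size, q_start=0, q_end=length,
            ))
            pool = tissue_bias[cls]
            truth.qc_status[tx] = (PASS, ())
            truth.est_gene[tx] = gid
            truth.est_tissue[tx] = pool[int(rng.integers(len(pool)))]
    return out


def classify_cohort(cohort: Cohort, cutoff: Optional[float] = None):
    """Run the homology cascade on an in-memory cohort; returns calls."""
    from .phylostrat import classify_genes, search_cascade

    cutoff = cutoff if cutoff is not None else cohort.config.e_cutoff
    genomes = dict(cohort.species_genomes)
    genomes["focal"] = cohort.focal_genome
    hits = search_cascade(
        cohort.focal_proteins, cohort.gene_isoforms, cohort.panel, cutoff,
        proteomes=cohort.species_proteomes, genomes=genomes,
    )
    return classify_genes(hits, cohort.panel, cohort.gene_isoforms, cutoff)


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the whole cohort as plain-text files; returns the path map.

    Formats: FASTA (proteins, genomes), GTF (gene models), PSL
    (transcript alignments), TSV (counts, metadata, paralogs, support,
    tissue labels, planted truth) and a YAML panel manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    write_fasta(dict(sorted(cohort.focal_proteins.items())), _p("focal_proteins.fa"))
    write_fasta(dict(sorted(cohort.focal_genome.items())), _p("focal_genome.fa"))
    write_gtf(cohort.models, _p("genes.gtf"))
    for sp in sorted(cohort.species_proteomes):
        write_fasta(dict(sorted(cohort.species_proteomes[sp].items())),
                    _p(f"{sp}_proteins.fa"))
    for sp in sorted(cohort.species_genomes):
        write_fasta(cohort.species_genomes[sp], _p(f"{sp}_genome.fa"))
    write_panel(cohort.panel, _p("panel.yaml"))
    write_psl(cohort.alignments, _p("est.psl"))

    with open(_p("est_tissues.tsv"), "w") as fh:
        fh.write("transcript_id\ttissue\n")
        for tx in sorted(cohort.truth.est_tissue):
            fh.write(f"{tx}\t{cohort.truth.est_tissue[tx]}\n")

    cohort.counts.rename_axis("gene_id").to_csv(_p("counts.tsv"), sep="\t")
    cohort.sample_meta.to_csv(_p("samples.tsv"), sep="\t", index=False)
    cohort.paralogs.to_csv(_p("paralogs.tsv"), sep="\t", index=False)

    with open(_p("support.tsv"), "w") as fh:
        fh.write("gene_id\thas_transcript_support\n")
        for gid in sorted(cohort.truth.support):
            fh.write(f"{gid}\t{int(cohort.truth.support[gid])}\n")

    with open(_p("truth.tsv"), "w") as fh:
        fh.write("gene_id\tplanted_class\ttemporal_pattern\trestricted_stage\n")
        for gid in sorted(cohort.truth.gene_class):
            pattern, stage = cohort.truth.temporal_pattern.get(gid, ("NA", None))
            fh.write(
                f"{gid}\t{cohort.truth.gene_class[gid]}\t{pattern}\t"
                f"{stage if stage is not None else '.'}\n"
            )
    return paths
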