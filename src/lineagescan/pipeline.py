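"""End-to-end orchestration: classify -> characterize -> duplication ->
transcript mapping -> expression, from one YAML config.

Stages run in dependency order; a stage whose inputs are absent is
skipped and recorded in the report.  All statistics in the report carry
the test name, statistic, p-value and the exact inputs used, and every
table is written as TSV next to a single JSON summary, so a run is
reproducible from the echoed config alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort, write_cohort
from .duplication import (infer_origin, read_paralogs, similarity_contrast,
                          write_origin_summary)
from .expression import (SampleInfo, compute_rpkm, late_stage_enrichment,
                         mean_normalized_expression, peak_stage,
                         peak_stage_proportions, pool_replicates,
                         proportion_expressed, specificity_contrast,
                         specificity_scores)
from .genefeatures import (chromosome_distribution, compute_features,
                           feature_anova, transcript_support_rate,
                           write_features)
from .gtfio import read_gtf
from .hits import read_hits
from .panel import read_panel
from .phylostrat import (CATEGORIES, CTSG, EC, ORPHAN, classify_genes,
                         search_cascade, summarize_strata, write_calls)
from .psl import read_psl
from .seqio import read_fasta
from .stats import spearman_vs_length
from .transcript_map import (assign_to_genes, build_tissue_table, filter_chain,
                             tissue_enrichment, write_verdicts)

logger = logging.getLogger("lineagescan")


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Relative paths are resolved against the config file's directory.
    """

    out_dir: str
    panel: Optional[str] = None
    hits: Optional[str] = None
    validation_hits: Optional[str] = None
    gtf: Optional[str] = None
    genome_fasta: Optional[str] = None
    protein_fasta: Optional[str] = None
    psl: Optional[str] = None
    tissues: Optional[str] = None
    counts: Optional[str] = None
    samples: Optional[str] = None
    paralogs: Optional[str] = None
    support: Optional[str] = None
    e_cutoff: float = 1e-5
    ambiguity_gap: float = 0.05
    min_gene_overlap: int = 100
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        base = path.parent
        for name in ("out_dir", "panel", "hits", "validation_hits", "gtf",
                     "genome_fasta", "protein_fasta", "psl", "tissues",
                     "counts", "samples", "paralogs", "support"):
            v = getattr(cfg, name)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, name, str(base / v))
        return cfg

    def validate(self) -> list[str]:
        problems = []
        for name in ("panel", "hits", "validation_hits", "gtf", "genome_fasta",
                     "protein_fasta", "psl", "tissues", "counts", "samples",
                     "paralogs", "support"):
            v = getattr(self, name)
            if v is not None and not Path(v).exists():
                problems.append(f"{name}: path does not exist: {v}")
        if self.e_cutoff <= 0:
            problems.append("e_cutoff must be positive")
        if not 0 < self.ambiguity_gap < 1:
            problems.append("ambiguity_gap must be in (0, 1)")
        return problems


def _gene_isoforms_from_models(models) -> dict[str, list[str]]:
    return {
        gid: [t.transcript_id for t in m.transcripts] for gid, m in models.items()
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all runnable stages; returns (and writes) the run report."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid run config:\n  " + "\n  ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "software_version": __version__,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
    }

    def _stage(name: str):
        t0 = time.time()
        logger.info("stage %s: start", name)
        return t0

    def _done(name: str, t0: float, summary: Any) -> None:
        logger.info("stage %s: done in %.2fs", name, time.time() - t0)
        report["stages"][name] = summary

    def _skip(name: str, why: str) -> None:
        logger.info("stage %s: skipped (%s)", name, why)
        report["stages"][name] = {"skipped": True, "reason": why}

    models = read_gtf(config.gtf) if config.gtf else None
    gene_isoforms = _gene_isoforms_from_models(models) if models else None
    calls = None

    # -- classification --------------------------------------------------
    if config.panel and gene_isoforms:
        t0 = _stage("classify")
        panel = read_panel(config.panel)
        if config.hits:
            hits = read_hits(config.hits)
        else:
            proteins = read_fasta(config.protein_fasta)
            hits = search_cascade(proteins, gene_isoforms, panel, config.e_cutoff)
        vhits = read_hits(config.validation_hits) if config.validation_hits else None
        calls = classify_genes(hits, panel, gene_isoforms, config.e_cutoff, vhits)
        write_calls(calls, out / "calls.tsv")
        strata = summarize_strata(calls)
        _done("classify", t0, {"strata": strata, "n_hits": len(hits)})
    else:
        _skip("classify", "panel or GTF not provided")

    # -- characterization ------------------------------------------------
    support_map: dict[str, bool] = {}
    if config.support:
        sup = pd.read_csv(config.support, sep="\t")
        support_map = dict(
            zip(sup.iloc[:, 0], sup.iloc[:, 1].astype(int).astype(bool))
        )
    if calls and models and config.genome_fasta and config.protein_fasta:
        t0 = _stage("features")
        genome = read_fasta(config.genome_fasta)
        proteins = read_fasta(config.protein_fasta)
        rows = compute_features(models, genome, proteins, gene_isoforms, support_map)
        write_features(rows, out / "features.tsv")
        summaries = {}
        for feat in ("gene_size", "protein_size", "exon_number", "gc_content"):
            try:
                s = feature_anova(rows, calls, feat)
                summaries[feat] = {
                    "means": s.means, "se": s.standard_errors,
                    "anova_f": s.f_statistic, "anova_p": s.p_value,
                    "posthoc": s.posthoc_method,
                }
            except ValueError as exc:
                summaries[feat] = {"error": str(exc)}
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        dist = chromosome_distribution(calls, models)
        spearman = {}
        chroms = sorted(chrom_lengths)
        if len(chroms) >= 3:
            for cat in CATEGORIES:
                counts_vec = [dist[cat][c]["count"] for c in chroms]
                rho, p = spearman_vs_length(
                    counts_vec, [chrom_lengths[c] for c in chroms]
                )
                spearman[cat] = {"rho": rho, "p": p}
        _done("features", t0, {
            "anova": summaries,
            "transcript_support_pct": transcript_support_rate(rows, calls),
            "chromosome_distribution": dist,
            "spearman_vs_chromosome_length": spearman,
        })
    else:
        _skip("features", "calls, GTF, genome or proteins not provided")

    # -- duplication origin ----------------------------------------------
    if calls and config.paralogs:
        t0 = _stage("duplication")
        paralogs = read_paralogs(config.paralogs)
        summaries, contrasts = [], {}
        for cat in (ORPHAN, CTSG):
            s = infer_origin(paralogs, calls, cat)
            summaries.append(s)
            contrasts[cat] = similarity_contrast(paralogs, calls, cat)
        write_origin_summary(summaries, contrasts, out / "origin_summary.tsv")
        _done("duplication", t0, {
            s.category: {
                "n_total": s.n_total,
                "n_with_paralog": s.n_with_paralog,
                "n_with_conserved_paralog": s.n_with_conserved_paralog,
                "pct_with_paralog": 100 * s.fraction_with_paralog,
                "pct_duplication_origin": 100 * s.fraction_duplication_origin,
                "similarity_contrast": contrasts[s.category],
            }
            for s in summaries
        })
    else:
        _skip("duplication", "calls or paralog table not provided")

    # -- transcript mapping ----------------------------------------------
    tissue_table = None
    if models and config.psl:
        t0 = _stage("estmap")
        alignments = read_psl(config.psl)
        verdicts, kept, status = filter_chain(alignments, config.ambiguity_gap)
        write_verdicts(verdicts, out / "verdicts.tsv")
        assignments = assign_to_genes(kept, models, config.min_gene_overlap)
        with open(out / "assignments.tsv", "w") as fh:
            fh.write("transcript_id\tgene_id\n")
            for tx in sorted(assignments):
                fh.write(f"{tx}\t{assignments[tx]}\n")
        summary: dict[str, Any] = {
            "n_alignments": len(alignments),
            "n_pass": sum(1 for v in verdicts if v.status == "PASS"),
            "n_fail": sum(1 for v in verdicts if v.status == "FAIL"),
            "n_discarded_ambiguous": sum(
                1 for s in status.values() if s == "DISCARD_AMBIGUOUS"
            ),
            "n_assigned": len(assignments),
        }
        if config.tissues:
            lib = pd.read_csv(config.tissues, sep="\t")
            tissue_of = dict(zip(lib.iloc[:, 0], lib.iloc[:, 1]))
            tissue_table = build_tissue_table(assignments, tissue_of)
            tt = pd.DataFrame(tissue_table).T.fillna(0).astype(int)
            tt.rename_axis("gene_id").to_csv(out / "tissue_table.tsv", sep="\t")
            if calls:
                enrich = {}
                for tissue in sorted({t for d in tissue_table.values() for t in d}):
                    try:
                        table, p = tissue_enrichment(
                            tissue_table, calls, tissue, ORPHAN, EC
                        )
                        enrich[tissue] = {"table": list(table), "fisher_p": p}
                    except ValueError as exc:
                        enrich[tissue] = {"error": str(exc)}
                summary["orphan_tissue_enrichment_vs_EC"] = enrich
        _done("estmap", t0, summary)
    else:
        _skip("estmap", "PSL or GTF not provided")

    # -- expression -------------------------------------------------------
    if models and config.counts and config.samples:
        t0 = _stage("express")
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        meta = pd.read_csv(config.samples, sep="\t")
        samples = [
            SampleInfo(
                sample_id=str(r.sample_id), stage=str(r.stage),
                hours_post_fertilization=float(r.hours_post_fertilization),
                stage_class=str(r.stage_class),
                total_valid_reads=int(r.total_valid_reads),
            )
            for r in meta.itertuples()
        ]
        counts, samples = pool_replicates(counts, samples)
        exon_lengths = {gid: m.exon_union_length() for gid, m in models.items()}
        rpkm = compute_rpkm(counts, exon_lengths, samples)
        rpkm.rename_axis("gene_id").to_csv(
            out / "rpkm.tsv", sep="\t", float_format="%.6g"
        )
        scores = specificity_scores(rpkm)
        scores.rename("specificity").rename_axis("gene_id").to_csv(
            out / "specificity.tsv", sep="\t", float_format="%.6g"
        )
        summary = {"n_genes": int(len(rpkm)), "n_stages": int(rpkm.shape[1])}
        if calls:
            stage_class = dict(zip(meta["stage"].astype(str), meta["stage_class"]))
            sets = {
                cat: [g for g, c in calls.items() if c.category == cat]
                for cat in CATEGORIES
            }
            profiles = {}
            for cat, genes in sets.items():
                if genes:
                    profiles[cat] = {
                        "mean_normalized_expression":
                            mean_normalized_expression(rpkm, genes).round(4).to_dict(),
                        "proportion_expressed":
                            proportion_expressed(counts, genes).round(4).to_dict(),
                    }
            pd.DataFrame({
                (cat, key): pd.Series(vals)
                for cat, d in profiles.items() for key, vals in d.items()
            }).rename_axis("stage").to_csv(out / "profiles.tsv", sep="\t")
            peaks = {g: peak_stage(rpkm.loc[g]) for g in rpkm.index}
            try:
                enr = late_stage_enrichment(peaks, calls, stage_class, ORPHAN, CTSG)
            except ValueError as exc:
                enr = {"error": str(exc)}
            try:
                contrast = specificity_contrast(scores, calls)
                contrast_summary = {
                    "means": contrast.means,
                    "anova_f": contrast.f_statistic,
                    "anova_p": contrast.p_value,
                    "posthoc": contrast.posthoc_method,
                }
            except ValueError as exc:
                contrast_summary = {"error": str(exc)}
            summary.update({
                "profiles": profiles,
                "late_stage_enrichment_orphan_vs_ctsg": enr,
                "specificity_contrast": contrast_summary,
            })
        _done("express", t0, summary)
    else:
        _skip("express", "counts, samples or GTF not provided")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def make_demo(seed: int, outdir: str | Path) -> Path:
    """Write a complete synthetic workspace plus the config to run it."""
    out = Path(outdir)
    cohort = generate_cohort(CohortConfig(seed=seed))
    write_cohort(cohort, out)
    cfg = {
        "out_dir": "results",
        "panel": "panel.yaml",
        "gtf": "genes.gtf",
        "genome_fasta": "focal_genome.fa",
        "protein_fasta": "focal_proteins.fa",
        "psl": "est.psl",
        "tissues": "est_tissues.tsv",
        "counts": "counts.tsv",
        "samples": "samples.tsv",
        "paralogs": "paralogs.tsv",
        "support": "support.tsv",
        "e_cutoff": cohort.config.e_cutoff,
        "seed": seed,
    }
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out / "run.yaml"
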