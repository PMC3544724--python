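"""End-to-end pipeline on synthetic data: simulate → curate → cluster →
express → landscape → mc-overlap → bias → date-ltr → recent.

Every stage writes TSV (or FASTA/GFF3) outputs into one directory and the
run manifest records seeds, parameters and per-stage row counts. The whole
run is deterministic under the master seed. With ``resume=True`` stages
already marked complete in the manifest are skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .bias import bias_to_frame, proximity_bias_table
from .curation import DbHit, RepeatCandidate, curate, curation_report
from .dating import age_distribution, ages_to_frame, date_elements
from .expression import (
    calls_to_frame,
    expression_calls,
    expression_te_correlation,
    match_ests_to_features,
    scaffold_gene_expression,
    superfamily_expression_table,
)
from .families import (
    cluster_families,
    copy_histogram,
    copy_numbers_from_assembly,
    families_to_frame,
)
from .landscape import (
    binned_coverage,
    gene_te_correlation,
    genome_te_table,
    per_scaffold_coverage,
    tracks_to_frame,
)
from .mc import mcfdr_schedule, results_to_frame, units_from_annotations
from .recent import map_exact_copies, nearest_gene_bins, site_records, select_recent
from .sim import (
    build_te_library,
    default_regime,
    element_sequence,
    plant_sequences,
    sample_ests,
    simulate_genome,
    simulate_ltr_cohort,
)
from .align import find_copies
from .model import GeneAnnotation
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "curate", "cluster", "express", "landscape",
    "mc-overlap", "bias", "date-ltr", "recent",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    regimes: tuple[str, ...] = ("te_rich", "balanced", "gene_rich")
    scaffold_length: int = 200_000
    n_families: int = 12
    expressed_fraction: float = 0.3
    n_ests: int = 150
    est_length_range: tuple[int, int] = (150, 400)
    bin_size: int = 50_000
    est_coverage_threshold: float = 0.70
    family_identity_threshold: float = 0.80
    copy_coverage_threshold: float = 0.80
    # Desk-scale synthetic genomes plant only a handful of copies per family,
    # so the pipeline default is lower than the genome-scale value of 10 the
    # curation module defaults to.
    min_genome_hits: int = 2
    e_value_max: float = 1e-5
    mc_min_samples: int = 100
    mc_exceedance_threshold: int = 20
    mc_max_samples: int = 2_000
    mc_alpha: float = 0.05
    substitution_rate: float = 1.5e-8
    cohort_ages_mya: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    cohort_n_per_age: int = 10
    cohort_ltr_length: int = 1_000

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = json.load(handle)
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regimes", "cohort_ages_mya", "est_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    resume: bool = False,
) -> dict:
    """Run all stages; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    # JSON round-trip normalises tuples to lists so a reloaded manifest
    # compares equal to a fresh config.
    manifest: dict = {
        "version": __version__,
        "config": json.loads(json.dumps(asdict(config))),
        "stages": {},
    }
    if resume and manifest_path.exists():
        with open(manifest_path) as handle:
            previous = json.load(handle)
        if previous.get("config") == manifest["config"]:
            manifest["stages"] = previous.get("stages", {})
        else:
            logger.warning("config changed since previous run; restarting from scratch")

    def done(stage: str) -> bool:
        return stage in manifest["stages"]

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        with open(manifest_path, "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)

    rng = np.random.default_rng(config.seed)
    stage_seeds = {stage: int(rng.integers(0, 2**31 - 1)) for stage in STAGES}

    # ---- simulate (always re-executed in memory: later stages need objects) --
    library = build_te_library(
        config.n_families, seed=stage_seeds["simulate"]
    )
    regimes = [
        default_regime(kind, config.scaffold_length) for kind in config.regimes
    ]
    assembly, truth = simulate_genome(
        regimes, te_library=library, seed=stage_seeds["simulate"]
    )
    ests = sample_ests(
        truth,
        assembly,
        library,
        expressed_fraction=config.expressed_fraction,
        n_ests=config.n_ests,
        length_range=config.est_length_range,
        seed=stage_seeds["simulate"] + 1,
    )
    if not done("simulate"):
        io.write_fasta(assembly.sequences, outdir / "assembly.fasta")
        io.write_fasta(ests, outdir / "ests.fasta")
        io.write_gff3(truth.gene_annotations(), outdir / "genes.gff3")
        io.write_gff3(truth.te_annotations(), outdir / "tes.gff3")
        pd.DataFrame(
            [
                {
                    "te_index": i,
                    "scaffold_id": r.annotation.interval.scaffold_id,
                    "start": r.annotation.interval.start,
                    "end": r.annotation.interval.end,
                    "superfamily": r.annotation.superfamily,
                    "family_id": r.family_id,
                }
                for i, r in enumerate(truth.te_records)
            ]
        ).to_csv(outdir / "truth_tes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene_id": r.annotation.gene_id,
                    "scaffold_id": r.annotation.interval.scaffold_id,
                    "start": r.annotation.interval.start,
                    "end": r.annotation.interval.end,
                    "expressed_true": r.expressed,
                }
                for r in truth.gene_records
            ]
        ).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        record(
            "simulate",
            scaffolds=len(assembly.scaffolds),
            te_copies=len(truth.te_records),
            genes=len(truth.gene_records),
            ests=len(ests),
        )

    tes = truth.te_annotations()
    genes = truth.gene_annotations()

    # ---- curate ----
    if not done("curate"):
        copy_counts: dict[str, int] = {}
        for rec in truth.te_records:
            copy_counts[rec.family_id] = copy_counts.get(rec.family_id, 0) + 1
        candidates = [
            RepeatCandidate(
                repeat_id=fid,
                sequence=template.sequence,
                source_algorithm="LTR_finder" if template.is_ltr else "RepeatScout",
                genome_hit_count=copy_counts.get(fid, 0),
            )
            for fid, template in library.items()
        ]
        hits = []
        for fid, template in library.items():
            for db in ("repbase", "plant_repeat_db"):
                hits.append(DbHit(fid, db, template.superfamily, 1e-20))
        curated = curate(
            candidates, hits,
            min_hits=config.min_genome_hits, e_max=config.e_value_max,
        )
        curation_report(curated).to_csv(
            outdir / "curated_repeats.tsv", sep="\t", index=False
        )
        record("curate", candidates=len(candidates), retained=len(curated))

    # ---- cluster ----
    member_seqs: dict[str, dict[str, str]] = {}
    for fid, template in library.items():
        member_seqs.setdefault(template.superfamily, {})[fid] = template.sequence
    families = cluster_families(
        member_seqs, threshold=config.family_identity_threshold
    )
    rep_sequences = {
        fid: library[fid].sequence for fid in library
    }
    if not done("cluster"):
        copy_numbers_from_assembly(
            families, rep_sequences, assembly,
            coverage_threshold=config.copy_coverage_threshold,
        )
        families_to_frame(families).to_csv(
            outdir / "families.tsv", sep="\t", index=False
        )
        copy_histogram(families).to_csv(
            outdir / "copy_histogram.tsv", sep="\t", index=False
        )
        record("cluster", families=len(families))

    # ---- express ----
    family_superfamily = {f.representative_id: f.superfamily for f in families}
    feature_seqs = dict(rep_sequences)
    for gene in genes:
        iv = gene.interval
        feature_seqs[gene.gene_id] = assembly.sequences[iv.scaffold_id][iv.start:iv.end]
    est_hits = match_ests_to_features(feature_seqs, ests)
    calls = expression_calls(
        feature_seqs, est_hits, est_coverage_threshold=config.est_coverage_threshold
    )
    gene_expr = scaffold_gene_expression(genes, calls)
    te_cov = per_scaffold_coverage(tes, assembly)
    if not done("express"):
        calls_to_frame(calls).to_csv(
            outdir / "expression_calls.tsv", sep="\t", index=False
        )
        superfamily_expression_table(family_superfamily, calls).to_csv(
            outdir / "superfamily_expression.tsv", sep="\t", index=False
        )
        expr_corr = expression_te_correlation(gene_expr, te_cov)
        pd.DataFrame(
            [
                {
                    "scaffold_id": s,
                    "fraction_genes_expressed": gene_expr[s],
                    "te_coverage": te_cov[s],
                }
                for s in sorted(gene_expr)
            ]
        ).to_csv(outdir / "scaffold_expression.tsv", sep="\t", index=False)
        record(
            "express",
            features=len(calls),
            expressed=sum(c.expressed for c in calls.values()),
            expression_te_r=expr_corr.r if expr_corr.computable else None,
        )

    # ---- landscape ----
    if not done("landscape"):
        corr, cov_table = gene_te_correlation(genes, tes, assembly, min_scaffold_bp=0)
        cov_table.to_csv(outdir / "scaffold_coverage.tsv", sep="\t", index=False)
        genome_te_table(tes, assembly.total_bp).to_csv(
            outdir / "genome_te_table.tsv", sep="\t", index=False
        )
        tracks = []
        for scaffold_id, length in assembly.scaffolds.items():
            tracks.append(
                binned_coverage(tes, scaffold_id, length, config.bin_size, "all-TEs")
            )
            tracks.append(
                binned_coverage(genes, scaffold_id, length, config.bin_size, "genes")
            )
        tracks_to_frame(tracks).to_csv(
            outdir / "window_tracks.tsv", sep="\t", index=False
        )
        record(
            "landscape",
            scaffolds=len(assembly.scaffolds),
            gene_te_r=corr.r if corr.computable else None,
        )

    # ---- mc-overlap ----
    if not done("mc-overlap"):
        units = units_from_annotations(tes, genes, assembly)
        results = mcfdr_schedule(
            units,
            alpha=config.mc_alpha,
            min_samples=config.mc_min_samples,
            exceedance_threshold=config.mc_exceedance_threshold,
            max_samples=config.mc_max_samples,
            seed=stage_seeds["mc-overlap"],
        )
        results_to_frame(results).to_csv(
            outdir / "mc_overlap.tsv", sep="\t", index=False
        )
        record(
            "mc-overlap",
            units=len(results),
            rejections=sum(r.rejected for r in results),
        )

    # ---- bias ----
    if not done("bias"):
        bias_results = proximity_bias_table(tes, genes)
        bias_to_frame(bias_results).to_csv(
            outdir / "proximity_bias.tsv", sep="\t", index=False
        )
        record("bias", tests=len(bias_results))

    # ---- date-ltr ----
    elements, truth_ages = simulate_ltr_cohort(
        list(config.cohort_ages_mya),
        config.cohort_n_per_age,
        ltr_length=config.cohort_ltr_length,
        rate=config.substitution_rate,
        seed=stage_seeds["date-ltr"],
    )
    ages, excluded = date_elements(elements, rate=config.substitution_rate)
    if not done("date-ltr"):
        frame = ages_to_frame(ages)
        frame["age_true_mya"] = [truth_ages[a.element_id] for a in ages]
        frame.to_csv(outdir / "ltr_ages.tsv", sep="\t", index=False)
        age_distribution(ages).to_csv(
            outdir / "age_histogram.tsv", sep="\t", index=False
        )
        record("date-ltr", dated=len(ages), excluded_saturated=len(excluded))

    # ---- recent ----
    if not done("recent"):
        recent_rng = np.random.default_rng(stage_seeds["recent"])
        zero_age, _ = simulate_ltr_cohort(
            [0.0], 5, ltr_length=300, internal_length=700,
            rate=config.substitution_rate, seed=recent_rng,
        )
        inserts = [
            (el.element_id, element_sequence(el, "A" * 0), 1) for el in zero_age
        ]
        scaffold_seq, placements = plant_sequences(
            120_000, inserts, seed=recent_rng, scaffold_id="recent_scaffold"
        )
        recent_genes = [
            GeneAnnotation(GenomicInterval("recent_scaffold", s, s + 2_000), f"rgene{i}")
            for i, s in enumerate(range(5_000, 120_000, 30_000))
        ]
        for el in zero_age:
            el.ltr_similarity_pct = 100.0
        selected = select_recent(zero_age)
        sites = []
        for el in selected:
            seq = element_sequence(el, "")
            hits = find_copies(seq, scaffold_seq, target_id="recent_scaffold",
                               query_id=el.element_id)
            sites.extend(map_exact_copies(len(seq), hits))
        records = site_records(sites, recent_genes)
        nearest_gene_bins(records).to_csv(
            outdir / "recent_distance_bins.tsv", sep="\t", index=False
        )
        record("recent", recent_elements=len(selected), exact_sites=len(sites))

    return manifest
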