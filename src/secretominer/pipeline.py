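"""End-to-end orchestration: predict -> annotate -> cluster -> compare.

Reads the plain-TSV/FASTA layout written by the simulator (or assembled by a
user from real predictor outputs), runs every stage, and writes '#'-headed
TSV tables plus a run log recording every threshold in effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import annotation, clustering, compare, prediction, registry_io
from .models import ProteinRecord, SecretionDecision, SecretomeAnnotation, SpeciesRecord, StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of a full pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    ssp_threshold: int = 300
    identity_threshold: float = 0.70
    min_species: int = 3
    evalue_cutoff: float = 1e-5
    alpha: float = 0.01
    min_group_size: int = 5
    kdel_mode: str = "ps00014"
    identity_denominator: str = "shorter"
    protease_mapping_path: str | Path | None = None
    grouping_path: str | Path | None = None
    seed: int = 0

    def thresholds(self) -> dict:
        return {
            "ssp_threshold": self.ssp_threshold,
            "identity_threshold": self.identity_threshold,
            "min_species": self.min_species,
            "evalue_cutoff": self.evalue_cutoff,
            "alpha": self.alpha,
            "min_group_size": self.min_group_size,
            "kdel_mode": self.kdel_mode,
            "identity_denominator": self.identity_denominator,
        }


def decisions_frame(decisions: list[SecretionDecision]) -> pd.DataFrame:
    rows = [
        (
            d.protein_id,
            d.secreted,
            d.ssp,
            *(flag for _, flag in d.reasons.as_items()),
        )
        for d in decisions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "secreted",
            "ssp",
            "sp_present",
            "tm_ok",
            "targetp_ok",
            "wolfpsort_ok",
            "kdel_ok",
        ],
    )


def annotations_frame(annotations: list[SecretomeAnnotation]) -> pd.DataFrame:
    rows = [
        (
            a.protein_id,
            a.species,
            a.category,
            a.ssp,
            a.cazy_family or "",
            a.merops_family or "",
            a.protease_type,
            a.lipase_class or "",
            a.lipase_subfamily or "",
            ";".join(a.pfam_domains),
            round(a.cys_percent, 4),
            ";".join(f"{s}-{e}" for s, e in a.kr_rich_regions),
            a.nls_predicted,
        )
        for a in annotations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "species",
            "category",
            "ssp",
            "cazy_family",
            "merops_family",
            "protease_type",
            "lipase_class",
            "lipase_subfamily",
            "pfam_domains",
            "cys_percent",
            "kr_rich_regions",
            "nls_predicted",
        ],
    )


def summarize_secretomes(
    proteins: list[ProteinRecord],
    decisions: list[SecretionDecision],
    annotations: list[SecretomeAnnotation],
    registry: list[SpeciesRecord],
    specific_ssp_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Per-species summary: proteome/secretome sizes, SSP and category counts."""
    by_species: dict[str, list[ProteinRecord]] = {s.name: [] for s in registry}
    for protein in proteins:
        by_species.setdefault(protein.species, []).append(protein)
    decision_of = {d.protein_id: d for d in decisions}
    category_of = {a.protein_id: a.category for a in annotations}
    rows = []
    for species in sorted(by_species):
        members = by_species[species]
        if not members:
            raise StageError(f"species {species!r} has zero proteins")
        secretome = [p for p in members if decision_of[p.protein_id].secreted]
        ssps = [p for p in secretome if decision_of[p.protein_id].ssp]
        counts = {"CAZyme": 0, "Protease": 0, "Lipase": 0, "SSP": 0, "Other": 0}
        for p in secretome:
            counts[category_of.get(p.protein_id, "Other")] += 1
        n_specific = (
            sum(1 for p in ssps if p.protein_id in specific_ssp_ids)
            if specific_ssp_ids is not None
            else 0
        )
        rows.append(
            (
                species,
                len(members),
                len(secretome),
                100.0 * len(secretome) / len(members),
                len(ssps),
                n_specific,
                counts["CAZyme"],
                counts["Protease"],
                counts["Lipase"],
                counts["SSP"],
                counts["Other"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "proteome_size",
            "secretome_size",
            "secretome_pct",
            "ssp_count",
            "species_specific_ssp_count",
            "n_cazyme",
            "n_protease",
            "n_lipase",
            "n_ssp_category",
            "n_other",
        ],
    )


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline over an input directory; returns every table.

    Expects ``species.tsv``, one ``<Species_name>.fasta`` per species,
    ``evidence.tsv`` and optionally ``hits.tsv`` under ``config.input_dir``.
    Writes decisions, annotations, summary, cluster, Venn, enrichment and
    statistics tables under ``config.output_dir``.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"thresholds: {config.thresholds()}"]

    def stage(name: str):
        logger.info("stage %s", name)
        log_lines.append(f"stage: {name}")

    try:
        stage("load")
        registry = registry_io.load_species_registry(indir / "species.tsv")
        proteins: list[ProteinRecord] = []
        for sp in registry:
            fasta = indir / f"{sp.name.replace(' ', '_')}.fasta"
            if not fasta.exists():
                raise StageError(f"load: missing proteome FASTA for {sp.name!r}")
            proteins.extend(registry_io.read_fasta(fasta, species=sp.name))
        evidence = registry_io.read_evidence_table(indir / "evidence.tsv")
        hits_path = indir / "hits.tsv"
        hits = registry_io.read_hit_table(hits_path) if hits_path.exists() else []
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"load: {exc}") from exc

    try:
        stage("predict")
        pcfg = prediction.PredictConfig(
            kdel_mode=config.kdel_mode, ssp_threshold=config.ssp_threshold
        )
        decisions = prediction.predict_secretome(proteins, evidence, pcfg)
        log_lines.append(
            f"predict: {sum(d.secreted for d in decisions)} secreted of {len(decisions)}"
        )
    except Exception as exc:
        raise StageError(f"predict: {exc}") from exc

    try:
        stage("annotate")
        protease_mapping = registry_io.load_protease_types(config.protease_mapping_path)
        acfg = annotation.AnnotationConfig(evalue_cutoff=config.evalue_cutoff)
        annotations = annotation.annotate_secretome(
            proteins, decisions, hits, protease_mapping, acfg
        )
    except Exception as exc:
        raise StageError(f"annotate: {exc}") from exc

    try:
        stage("cluster")
        decision_of = {d.protein_id: d for d in decisions}
        scoring = clustering.ScoringConfig(denominator=config.identity_denominator)
        ssps = [p for p in proteins if decision_of[p.protein_id].ssp]
        clusters = clustering.greedy_cluster(
            ssps, threshold=config.identity_threshold, scoring=scoring
        )
        kept = clustering.filter_clusters(clusters, min_species=config.min_species)
        specific = clustering.species_specific_ssps(
            ssps, evalue_cutoff=config.evalue_cutoff, scoring=scoring
        ) if ssps else set()
        log_lines.append(
            f"cluster: {len(ssps)} SSPs -> {len(clusters)} clusters, "
            f"{len(kept)} with >= {config.min_species} species, "
            f"{len(specific)} species-specific SSPs"
        )
    except Exception as exc:
        raise StageError(f"cluster: {exc}") from exc

    try:
        stage("compare")
        grouping = registry_io.load_lifestyle_groups(config.grouping_path)
        profiles = [
            compare.lifestyle_profile(c, registry, grouping) for c in kept
        ]
        venn = compare.venn_partition(profiles)
        summary = summarize_secretomes(
            proteins, decisions, annotations, registry, specific
        )
        enrichment_rows = []
        lifestyle_of = {s.name: s.lifestyle for s in registry}
        lifestyles_with_data = sorted({lifestyle_of[a.species] for a in annotations})
        if annotations:
            for lifestyle in lifestyles_with_data:
                for res in compare.pfam_enrichment(
                    annotations, registry, lifestyle, alpha=config.alpha
                ):
                    enrichment_rows.append(
                        (
                            res.lifestyle,
                            res.pfam,
                            res.a,
                            res.b,
                            res.c,
                            res.d,
                            res.p_value,
                            res.adjusted_p,
                            res.enriched,
                        )
                    )
        enrichment = pd.DataFrame(
            enrichment_rows,
            columns=["lifestyle", "pfam", "a", "b", "c", "d", "p_value", "adjusted_p", "enriched"],
        )
        sizes = summary.copy()
        correlation = compare.size_correlation(sizes, registry)
        group_sizes = pd.Series(
            [s.lifestyle for s in registry]
        ).value_counts()
        proportions = None
        if (group_sizes >= config.min_group_size).sum() >= 2:
            proportions = compare.ssp_proportion_stats(
                summary, registry, config.min_group_size, config.alpha
            )
        else:
            log_lines.append(
                "compare: fewer than two lifestyles meet min_group_size; "
                "proportion statistics not computed"
            )
    except Exception as exc:
        raise StageError(f"compare: {exc}") from exc

    stage("write")
    meta = {str(k): v for k, v in config.thresholds().items()}
    tables: dict[str, pd.DataFrame] = {
        "decisions": decisions_frame(decisions),
        "annotations": annotations_frame(annotations),
        "summary": summary,
        "clusters": clustering.clusters_frame(clusters),
        "cluster_summary": clustering.cluster_summary_frame(kept),
        "venn_regions": pd.DataFrame(
            [("+".join(region), count) for region, count in sorted(venn.items())],
            columns=["region", "n_clusters"],
        ),
        "cluster_specificity": pd.DataFrame(
            [(p.cluster_id, "+".join(sorted(p.lifestyles)), p.specificity) for p in profiles],
            columns=["cluster_id", "lifestyles", "specificity"],
        ),
        "enrichment": enrichment,
        "size_correlation": correlation,
    }
    if proportions is not None:
        tables["proportions_stats"] = proportions.pairwise
        tables["proportions_per_species"] = proportions.per_species
    for name, frame in tables.items():
        registry_io.write_table(frame, outdir / f"{name}.tsv", metadata=meta)
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return tables
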