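"""End-to-end orchestration: genotypes -> loci -> prioritized variants.

A single key-value (YAML) configuration names the inputs and every
parameter; the pipeline logs per-stage counts and writes a machine-readable
report (JSON) beside BED-like region and annotated variant TSVs.  An empty
candidate list is a reported outcome, not an error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .io import (
    GeneticMap,
    GenotypeDataset,
    Pedigree,
    Variant,
    normalize_chromosome,
    read_genetic_map,
    read_genotypes,
    read_regions,
    read_variant_table,
    write_regions,
    write_variant_table,
)
from .mapping import (
    CandidateRegion,
    MappingConfig,
    exclude_unaffected,
    filter_by_genetic_length,
    shared_autozygous_regions,
)
from .prioritize import PrioritizationConfig, intersect_and_filter, rank_variants
from .roh import ROHParams

logger = logging.getLogger("autozyg")


@dataclass
class MappingReport:
    candidate_regions: list[CandidateRegion]
    variants_in_regions: list[tuple[Variant, dict]]
    top_candidate: Variant | None
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "candidate_regions": [
                {
                    "chromosome": r.chromosome,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "genetic_length_cM": round(r.genetic_length_cM, 6),
                    "n_markers": r.n_markers,
                    "concordance": round(r.concordance, 6),
                }
                for r in self.candidate_regions
            ],
            "variants_in_regions": [
                {
                    "chromosome": v.chromosome,
                    "position_bp": v.position_bp,
                    "gene": v.gene,
                    "cdna_change": v.cdna_change,
                    "protein_change": v.protein_change,
                    "population_maf": v.population_maf,
                    "known_polymorphism": v.known_polymorphism,
                    **ann,
                }
                for v, ann in self.variants_in_regions
            ],
            "top_candidate": None
            if self.top_candidate is None
            else {
                "chromosome": self.top_candidate.chromosome,
                "position_bp": self.top_candidate.position_bp,
                "gene": self.top_candidate.gene,
                "cdna_change": self.top_candidate.cdna_change,
                "protein_change": self.top_candidate.protein_change,
            },
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _covered_bp(regions: list[CandidateRegion]) -> int:
    return sum(r.length_bp for r in regions)


def load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{config_path}: configuration must be a mapping")
    return cfg


def _build_params(cfg: dict) -> tuple[ROHParams, MappingConfig, PrioritizationConfig]:
    roh = ROHParams(**cfg.get("roh", {}))
    mapping_kwargs = dict(cfg.get("mapping", {}))
    mapping = MappingConfig(roh_params=roh, **mapping_kwargs)
    prio = PrioritizationConfig(**cfg.get("prioritization", {}))
    return roh, mapping, prio


def map_regions(
    dataset: GenotypeDataset,
    pedigree: Pedigree,
    gmap: GeneticMap,
    mapping: MappingConfig,
) -> tuple[list[CandidateRegion], dict]:
    """Run the three mapping stages; returns regions and a stage-count ledger."""
    counts: dict[str, object] = {}
    shared = shared_autozygous_regions(
        dataset,
        pedigree,
        mapping.roh_params,
        containment=mapping.containment,
        require_identity=mapping.require_affected_identity,
    )
    counts["shared_regions"] = len(shared)
    counts["shared_regions_bp"] = _covered_bp(shared)
    logger.info("shared autozygous regions: %d (%d bp)", len(shared), _covered_bp(shared))

    after_excl = exclude_unaffected(shared, dataset, pedigree, mapping)
    counts["after_unaffected_exclusion"] = len(after_excl)
    counts["after_unaffected_exclusion_bp"] = _covered_bp(after_excl)
    logger.info(
        "after unaffected exclusion (%s): %d (%d bp)",
        mapping.exclusion_mode,
        len(after_excl),
        _covered_bp(after_excl),
    )

    final = filter_by_genetic_length(after_excl, gmap, mapping)
    counts["after_length_filter"] = len(final)
    counts["after_length_filter_bp"] = _covered_bp(final)
    logger.info(
        "after >= %.1f cM filter: %d (%d bp)",
        mapping.min_genetic_length_cM,
        len(final),
        _covered_bp(final),
    )
    return final, counts


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> MappingReport:
    """Execute read -> ROH -> shared regions -> exclusion -> length filter ->
    variant intersection/filters -> segregation -> ranking, and write outputs."""
    cfg = load_config(config_path)
    base = Path(config_path).parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    out = Path(out_dir) if out_dir is not None else resolve(cfg.get("output", "autozyg_out"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        roh, mapping, prio = _build_params(cfg)
        counts: dict[str, object] = {}

        gmap = (
            read_genetic_map(resolve(cfg["genetic_map"]))
            if cfg.get("genetic_map")
            else GeneticMap(fallback_rate_cM_per_Mb=cfg.get("fallback_rate_cM_per_Mb", 1.0))
        )

        pedigree: Pedigree | None = None
        regions: list[CandidateRegion]
        if cfg.get("genotypes"):
            try:
                ped_path = resolve(cfg["genotypes"]["ped"])
                map_path = resolve(cfg["genotypes"]["map"])
            except (KeyError, TypeError):
                raise ConfigurationError("genotypes must name 'ped' and 'map' files")
            pedigree, dataset = read_genotypes(ped_path, map_path)
            logger.info(
                "read %d samples x %d markers", len(dataset.samples), dataset.n_markers
            )
            regions, map_counts = map_regions(dataset, pedigree, gmap, mapping)
            counts.update(map_counts)
        elif cfg.get("regions"):
            regions = read_regions(resolve(cfg["regions"]))
            regions = filter_by_genetic_length(regions, gmap, mapping)
            counts["supplied_regions"] = len(regions)
            logger.info("using %d supplied candidate regions", len(regions))
        else:
            raise ConfigurationError("config must provide either 'genotypes' or 'regions'")

        if cfg.get("pedigree") and pedigree is None:
            pedigree, _ = read_genotypes(resolve(cfg["pedigree"]), resolve(cfg["pedigree_map"]))

        if cfg.get("normalize_chromosomes"):
            regions = [
                CandidateRegion(
                    chromosome=normalize_chromosome(r.chromosome),
                    start_bp=r.start_bp,
                    end_bp=r.end_bp,
                    genetic_length_cM=r.genetic_length_cM,
                    n_markers=r.n_markers,
                    concordance=r.concordance,
                )
                for r in regions
            ]

        ranked: list[tuple[Variant, dict]] = []
        top: Variant | None = None
        if cfg.get("variants"):
            variants = read_variant_table(resolve(cfg["variants"]))
            if cfg.get("normalize_chromosomes"):
                for v in variants:
                    v.chromosome = normalize_chromosome(v.chromosome)
            counts["variants_total"] = len(variants)
            surviving = intersect_and_filter(variants, regions, prio)
            counts["variants_in_regions_passing_filters"] = len(surviving)
            logger.info(
                "variants: %d total, %d in regions passing filters",
                len(variants),
                len(surviving),
            )
            ranked = rank_variants(surviving, pedigree)
            for v, ann in ranked:
                if ann["segregates"] is not False:
                    top = v
                    break
            counts["segregation_consistent"] = sum(
                1 for _, a in ranked if a["segregates"] is True
            )

        report = MappingReport(
            candidate_regions=regions,
            variants_in_regions=ranked,
            top_candidate=top,
            provenance={"config": cfg, "stage_counts": counts},
        )

        write_regions(regions, out / "regions.tsv")
        if ranked:
            write_variant_table(
                [v for v, _ in ranked],
                out / "variants_ranked.tsv",
                annotations={i: ann for i, (_, ann) in enumerate(ranked)},
            )
        (out / "report.json").write_text(report.to_json())
        if top is not None:
            logger.info(
                "top candidate: %s %s:%d %s",
                top.gene,
                top.chromosome,
                top.position_bp,
                top.cdna_change,
            )
        else:
            logger.info("no top candidate")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
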