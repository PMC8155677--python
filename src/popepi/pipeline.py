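"""End-to-end orchestration: intersect -> classify -> freq-compare ->
selection-scan, with a single config, deterministic outputs, and a run
manifest.

Outputs (all machine-readable, written into ``output_dir``):

- ``venn.json`` / ``venn_regions.tsv`` — three-way compendium/cohort overlap
- ``classifications.tsv`` — per-variant ACMG verdicts and rule labels
- ``freq_compare.tsv`` — per-(variant, population) frequencies vs reference
  with Fisher p, odds ratio and significance tier
- ``carrier_summary.json`` — per-population cumulative carrier frequency of
  the pathogenic/likely-pathogenic variants (both aggregations and both
  carrier definitions)
- ``selection.tsv`` / ``genes.json`` — per-site iHS scan with outlier flags
  and the flagged-gene hit list
- ``run_manifest.json`` — config echo, seed, version, per-stage counts

A stage failure aborts the run with a stage-named error and removes the
partial outputs already written.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acmg import EvidenceProfile, Mode, combine_criteria
from .compendium import (
    Source,
    filter_by_genes,
    read_compendium_tsv,
    venn_counts,
    venn_regions,
    write_region_tsv,
    write_venn_json,
)
from .io import (
    attach_genetic_map,
    cohort_variant_keys,
    read_cohort_vcf,
    read_genetic_map,
    read_haplotype_tsv,
    read_haplotype_vcf,
    read_reference_panel,
    read_sample_map,
)
from .popfreq import (
    CarrierMethod,
    FrequencyRecord,
    bonferroni,
    carrier_frequency,
    compare_to_reference,
    compute_frequencies,
    cumulative_carrier_frequency,
)
from .selection import flag_outliers, ihs_scan, map_to_genes, read_bed_genes, standardize_ihs
from .variants import normalize_variant

logger = logging.getLogger("popepi")


class ConfigError(ValueError):
    """Invalid pipeline configuration (missing file, bad cutoffs)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs. Paths may be None to skip a stage's
    optional inputs, but the four stages require their primary inputs."""

    clinvar_tsv: str
    infevers_tsv: str
    hgmd_tsv: str
    genes_file: str
    cohort_vcf: str
    sample_map_tsv: str
    evidence_tsv: str
    reference_panel_tsv: str
    haplotypes: str                      # phased VCF or haplotype TSV
    gene_bed: str
    output_dir: str
    genetic_map_tsv: str | None = None
    haplotype_groups_tsv: str | None = None  # pseudo-sample -> population
    reference_population: str = "ALL"
    acmg_mode: str = "PAPER"
    red_cutoff: float = 0.01
    yellow_cutoff: float = 0.05
    ehh_cutoff: float = 0.05
    maf_floor: float = 0.05
    min_carriers: int = 2
    n_bins: int = 50
    min_sites_per_bin: int = 10
    top_pct: float = 0.01
    z_threshold: float = 2.0
    seed: int = 0

    REQUIRED_PATHS = (
        "clinvar_tsv", "infevers_tsv", "hgmd_tsv", "genes_file", "cohort_vcf",
        "sample_map_tsv", "evidence_tsv", "reference_panel_tsv", "haplotypes",
        "gene_bed",
    )

    def validate(self) -> None:
        if not (0.0 < self.red_cutoff <= self.yellow_cutoff <= 1.0):
            raise ConfigError("cutoffs must satisfy 0 < red <= yellow <= 1")
        if not 0.0 < self.top_pct < 1.0:
            raise ConfigError("top_pct must be in (0, 1)")
        Mode(self.acmg_mode)
        for name in self.REQUIRED_PATHS:
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigError(f"input {name} missing or not found: {p!r}")
        if self.genetic_map_tsv and not Path(self.genetic_map_tsv).exists():
            raise ConfigError(f"genetic map not found: {self.genetic_map_tsv!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def stage_seed(seed: int, stage_index: int) -> int:
    """Per-stage derived seed so stages can be rerun in isolation."""
    return (seed * 101 + stage_index) % (2**31 - 1)


# ---------------------------------------------------------------------------
# stages


def run_intersect(config: PipelineConfig, out: Path) -> dict[str, int]:
    genes = {
        line.strip() for line in Path(config.genes_file).read_text().splitlines()
        if line.strip()
    }
    sets = {}
    for path, source in (
        (config.clinvar_tsv, Source.CLINVAR_LIKE),
        (config.infevers_tsv, Source.INFEVERS_LIKE),
        (config.hgmd_tsv, Source.HGMD_LIKE),
    ):
        records = filter_by_genes(read_compendium_tsv(path, source=source), genes)
        sets[source] = {r.key for r in records}
    cohort_keys = cohort_variant_keys(config.cohort_vcf)
    overlaps = {src: keys & cohort_keys for src, keys in sets.items()}
    v = venn_counts(
        overlaps[Source.CLINVAR_LIKE],
        overlaps[Source.HGMD_LIKE],
        overlaps[Source.INFEVERS_LIKE],
    )
    regions = venn_regions(
        overlaps[Source.CLINVAR_LIKE],
        overlaps[Source.HGMD_LIKE],
        overlaps[Source.INFEVERS_LIKE],
    )
    write_venn_json(v, out / "venn.json")
    write_region_tsv(regions, out / "venn_regions.tsv")
    return {
        "cohort_variants": len(cohort_keys),
        "union": v.union,
        **{f"overlap_{src.value.lower()}": len(keys) for src, keys in overlaps.items()},
    }


def run_classify(config: PipelineConfig, out: Path) -> dict[str, int]:
    mode = Mode(config.acmg_mode)
    df = pd.read_csv(config.evidence_tsv, sep="\t", dtype={"chrom": str})
    rows = []
    for r in df.itertuples(index=False):
        key = normalize_variant(r.chrom, int(r.pos), r.ref, r.alt)
        cls = combine_criteria(EvidenceProfile.from_string(str(r.criteria)), mode)
        rows.append({
            "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
            "gene": r.gene, "criteria": r.criteria,
            "verdict": cls.verdict.value, "rule_label": cls.rule_label,
            "conflict": cls.conflict,
        })
    result = pd.DataFrame(rows)
    result.to_csv(out / "classifications.tsv", sep="\t", index=False)
    tally = result["verdict"].value_counts().to_dict() if rows else {}
    return {"variants_classified": len(rows), **{f"n_{k}": v for k, v in tally.items()}}


def run_freq_compare(config: PipelineConfig, out: Path) -> dict[str, int]:
    sample_map = read_sample_map(config.sample_map_tsv)
    cohort = read_cohort_vcf(config.cohort_vcf, sample_map)
    panel = read_reference_panel(config.reference_panel_tsv)
    records = compute_frequencies(cohort)
    ref_pop = config.reference_population

    rows = []
    for rec in records:
        if rec.AN == 0:
            continue
        entry = panel.entries.get((ref_pop, rec.key))
        if entry is None:
            continue
        ref_rec = FrequencyRecord.from_allele_counts(ref_pop, rec.key, *entry)
        if ref_rec.AN == 0:
            continue
        res = compare_to_reference(
            rec, ref_rec, red=config.red_cutoff, yellow=config.yellow_cutoff
        )
        rows.append({
            "chrom": rec.key.chrom, "pos": rec.key.pos,
            "ref": rec.key.ref, "alt": rec.key.alt,
            "population": rec.population, "AC": rec.AC, "AN": rec.AN,
            "AF": rec.AF,
            "carrier_freq_observed": carrier_frequency(rec, CarrierMethod.OBSERVED),
            "carrier_freq_hwe": carrier_frequency(rec, CarrierMethod.HWE),
            "reference_population": ref_pop,
            "ref_AC": ref_rec.AC, "ref_AN": ref_rec.AN, "ref_AF": ref_rec.AF,
            "odds_ratio": res.odds_ratio, "p": res.p_two_sided,
            "tier": res.tier.value,
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_bonferroni"] = bonferroni(table["p"])
    table.to_csv(out / "freq_compare.tsv", sep="\t", index=False)

    # cumulative carrier frequency of P/LP variants per population
    summary: dict[str, dict[str, float]] = {}
    cls_path = out / "classifications.tsv"
    if cls_path.exists():
        cls = pd.read_csv(cls_path, sep="\t", dtype={"chrom": str})
        plp = cls[cls["verdict"].isin(["PATHOGENIC", "LIKELY_PATHOGENIC"])]
        plp_keys = {
            normalize_variant(r.chrom, int(r.pos), r.ref, r.alt)
            for r in plp.itertuples(index=False)
        }
        by_pop: dict[str, list[FrequencyRecord]] = {}
        for rec in records:
            if rec.key in plp_keys and rec.AN > 0:
                by_pop.setdefault(rec.population, []).append(rec)
        for pop, recs in sorted(by_pop.items()):
            summary[pop] = {
                "n_variants": len(recs),
                "sum_observed": cumulative_carrier_frequency(
                    recs, CarrierMethod.OBSERVED, "SUM"),
                "sum_hwe": cumulative_carrier_frequency(
                    recs, CarrierMethod.HWE, "SUM"),
                "complement_observed": cumulative_carrier_frequency(
                    recs, CarrierMethod.OBSERVED, "COMPLEMENT"),
                "complement_hwe": cumulative_carrier_frequency(
                    recs, CarrierMethod.HWE, "COMPLEMENT"),
            }
    (out / "carrier_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"comparisons": len(rows), "populations": int(table["population"].nunique()) if len(table) else 0}


def run_selection_scan(config: PipelineConfig, out: Path) -> dict[str, int]:
    path = Path(config.haplotypes)
    if path.suffix in (".vcf", ".gz"):
        h = read_haplotype_vcf(path)
    else:
        h = read_haplotype_tsv(path)
    if config.genetic_map_tsv:
        h = attach_genetic_map(h, read_genetic_map(config.genetic_map_tsv))

    scan = ihs_scan(
        h, cutoff=config.ehh_cutoff, min_carriers=config.min_carriers,
        maf_floor=config.maf_floor,
    )
    std = standardize_ihs(
        scan["unihs"].to_numpy(), scan["daf"].to_numpy(),
        n_bins=config.n_bins, min_sites_per_bin=config.min_sites_per_bin,
    )
    scan["std_ihs"] = std
    if np.isfinite(std).any():
        top, gt = flag_outliers(std, pct=config.top_pct, z=config.z_threshold)
    else:
        top = gt = np.zeros(len(scan), dtype=bool)
    scan["top1pct"] = top
    scan["abs_gt2"] = gt
    scan.insert(0, "chrom", h.chrom)

    # per-population-pair Fst columns when haplotype groups are declared
    if config.haplotype_groups_tsv:
        from itertools import combinations

        from .selection import Estimator, fst_pair, haplotypes_to_genotypes

        groups = read_sample_map(config.haplotype_groups_tsv)
        n_ind = h.n_hap // 2
        names = [f"H{i:04d}" for i in range(n_ind)]
        unknown = set(groups) - set(names)
        if unknown:
            raise ValueError(
                f"haplotype groups name unknown pseudo-samples: {sorted(unknown)}"
            )
        genos = {}
        for pop in sorted(set(groups.values())):
            rows = [i for i, nm in enumerate(names) if groups.get(nm) == pop]
            hap_rows = np.concatenate([[2 * i, 2 * i + 1] for i in rows])
            genos[pop] = haplotypes_to_genotypes(h.haplotypes[hap_rows])
        for p1, p2 in combinations(sorted(genos), 2):
            scan[f"fst_wc_{p1}_{p2}"] = fst_pair(genos[p1], genos[p2], Estimator.WC)
            scan[f"fst_wright_{p1}_{p2}"] = fst_pair(
                genos[p1], genos[p2], Estimator.WRIGHT)

    scan.to_csv(out / "selection.tsv", sep="\t", index=False)

    genes = read_bed_genes(config.gene_bed)
    flagged_pos = scan.loc[scan["top1pct"], "pos_bp"].to_numpy()
    hits = map_to_genes(flagged_pos, genes, chrom=h.chrom)
    (out / "genes.json").write_text(json.dumps(hits, indent=2, sort_keys=True) + "\n")
    return {
        "sites_scanned": len(scan),
        "sites_defined": int(np.isfinite(std).sum()),
        "sites_top1pct": int(top.sum()),
        "genes_flagged": len(hits),
    }


_STAGES = (
    ("intersect", run_intersect),
    ("classify", run_classify),
    ("freq_compare", run_freq_compare),
    ("selection_scan", run_selection_scan),
)

_OUTPUTS = (
    "venn.json", "venn_regions.tsv", "classifications.tsv", "freq_compare.tsv",
    "carrier_summary.json", "selection.tsv", "genes.json", "run_manifest.json",
)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all four stages; returns the manifest dictionary.

    Identical config + seed produce byte-identical outputs. On stage failure
    every output written so far is removed and :class:`StageError` raised.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "popepi_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    try:
        for idx, (name, fn) in enumerate(_STAGES):
            t0 = time.monotonic()
            logger.info("stage %s starting (seed %d)", name, stage_seed(config.seed, idx))
            counts = fn(config, out)
            elapsed = time.monotonic() - t0
            logger.info("stage %s done in %.2fs: %s", name, elapsed, counts)
            # timings go to the log only, keeping outputs byte-identical
            manifest["stages"][name] = {"counts": counts}
    except Exception as exc:
        for fname in _OUTPUTS:
            (out / fname).unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(name, exc) from exc
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
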