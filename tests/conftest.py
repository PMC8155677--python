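"""Shared fixtures: a small self-contained pipeline workspace generated at
test time (no stored data files)."""

from __future__ import annotations

from pathlib import Path

import pytest
import yaml

from popepi.compendium import CompendiumRecord, Source, write_compendium_tsv
from popepi.io import (
    write_cohort_vcf,
    write_haplotype_vcf,
    write_reference_panel,
    write_sample_map,
)
from popepi.simulate import (
    CohortSpec,
    SweepSpec,
    core_site_index,
    simulate_cohort,
    simulate_haplotypes,
    simulate_reference_panel,
)
from popepi.variants import VariantKey

GENES = ["MVK", "RAB27A", "NOD2", "NLRP12", "TNFAIP3", "AP1S3", "IL1RN"]

# seven curated variants mirroring the published pathogenic/likely-pathogenic
# table (positions on their real hg19 chromosomes, criteria strings verbatim)
CURATED = [
    ("2", 224642579, "A", "C", "AP1S3", "PS3;PM1;PP3;BS4"),
    ("6", 138196060, "C", "T", "TNFAIP3", "PS3;PM1;PP3"),
    ("12", 110034320, "G", "A", "MVK", "PS4;PM3;PP1;PP5;BP4"),
    ("15", 55520906, "G", "A", "RAB27A", "PM1;PM2;PP3;PP5"),
    ("16", 50750810, "A", "G", "NOD2", "PS3;PM3;PP3"),
    ("19", 54313859, "G", "A", "NLRP12", "PS3;PM1;PP3;PP5"),
    ("19", 54314063, "G", "A", "NLRP12", "PVS1;PM1;PP5"),
]


def curated_keys() -> list[VariantKey]:
    return [VariantKey(c, p, r, a) for c, p, r, a, _, _ in CURATED]


@pytest.fixture(scope="session")
def demo_workspace(tmp_path_factory) -> dict:
    """Build every pipeline input in a temp directory: compendium TSVs,
    cohort VCF + sample map, evidence TSV, reference panel, a swept
    haplotype panel, gene BED, and a YAML config."""
    root = tmp_path_factory.mktemp("workspace")
    keys = curated_keys()

    # --- compendium tables: overlap patterns across the three sources
    records = []
    for i, (c, p, r, a, gene, _) in enumerate(CURATED):
        key = VariantKey(c, p, r, a)
        sources = [Source.INFEVERS_LIKE]
        if i % 2 == 0:
            sources.append(Source.HGMD_LIKE)
        if i < 2:
            sources.append(Source.CLINVAR_LIKE)
        for src in sources:
            records.append(CompendiumRecord(key=key, gene=gene, source=src))
    # one curated variant absent from the cohort, one with a foreign gene
    records.append(CompendiumRecord(
        key=VariantKey("3", 777, "T", "C"), gene="NLRP3", source=Source.HGMD_LIKE))
    records.append(CompendiumRecord(
        key=VariantKey("5", 888, "G", "T"), gene="NOTAGENE",
        source=Source.CLINVAR_LIKE))
    paths = {}
    for src, name in ((Source.CLINVAR_LIKE, "clinvar"),
                      (Source.INFEVERS_LIKE, "infevers"),
                      (Source.HGMD_LIKE, "hgmd")):
        p_out = root / f"{name}.tsv"
        write_compendium_tsv([r for r in records if r.source == src], p_out)
        paths[name] = p_out

    genes_file = root / "genes.txt"
    genes_file.write_text("\n".join(GENES) + "\n")

    # --- cohort: three subpopulations, curated variants at distinct freqs
    freqs = {
        "ARB": [0.004, 0.016, 0.008, 0.027, 0.002, 0.008, 0.005],
        "SAF": [0.002, 0.001, 0.001, 0.001, 0.001, 0.001, 0.029],
        "EUR": [0.001, 0.001, 0.002, 0.001, 0.001, 0.125, 0.005],
    }
    spec = CohortSpec(
        subpopulations=(("ARB", 120), ("SAF", 100), ("EUR", 80)),
        variant_panel=tuple(
            (k, {pop: fs[i] for pop, fs in freqs.items()})
            for i, k in enumerate(keys)
        ),
        missingness_rate=0.02,
        seed=7,
    )
    cohort = simulate_cohort(spec)
    cohort_vcf = root / "cohort.vcf"
    sample_map = root / "samples.tsv"
    write_cohort_vcf(cohort, cohort_vcf)
    write_sample_map(cohort.subpopulations, sample_map)

    # --- evidence table (published criteria strings)
    evidence = root / "evidence.tsv"
    with open(evidence, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tcriteria\n")
        for c, p, r, a, gene, crit in CURATED:
            fh.write(f"{c}\t{p}\t{r}\t{a}\t{gene}\t{crit}\n")

    # --- reference panel: rare everywhere (gnomAD-all analogue)
    panel = simulate_reference_panel(
        {"ALL": 100_000},
        {("ALL", k): 0.0005 for k in keys},
        seed=11,
    )
    panel_tsv = root / "reference_panel.tsv"
    write_reference_panel(panel, panel_tsv)

    # --- haplotype panel with a sweep, plus a gene over the core
    # fast demo scale: higher rates so EHH decays inside the short window
    hspec = SweepSpec(n_haplotypes=80, pop_size=500, chrom_length_bp=400_000,
                      n_sites=1200, mutation_rate=1e-7, recombination_rate=3e-7,
                      s=0.05, seed=13)
    hap = simulate_haplotypes(hspec)
    hap_vcf = root / "haplotypes.vcf"
    write_haplotype_vcf(hap, hap_vcf)
    # gene interval spanning the swept region (top-1% signal spreads over
    # the hitchhiking neighborhood, not only the core site itself)
    core_pos = int(hap.positions_bp[core_site_index(hap)])
    gene_bed = root / "genes.bed"
    gene_bed.write_text(
        f"1\t{max(0, core_pos - 150_000)}\t{core_pos + 150_000}\tRAB27A\n"
        "1\t10\t2000\tIL1RN\n"
    )

    # haplotype pseudo-sample grouping for per-pair Fst in the scan output
    hap_groups = root / "hap_groups.tsv"
    n_pseudo = hap.n_hap // 2
    with open(hap_groups, "w") as fh:
        fh.write("sample\tsubpopulation\n")
        for i in range(n_pseudo):
            fh.write(f"H{i:04d}\t{'ARB' if i < n_pseudo // 2 else 'SAF'}\n")

    config = {
        "clinvar_tsv": str(paths["clinvar"]),
        "infevers_tsv": str(paths["infevers"]),
        "hgmd_tsv": str(paths["hgmd"]),
        "genes_file": str(genes_file),
        "cohort_vcf": str(cohort_vcf),
        "sample_map_tsv": str(sample_map),
        "evidence_tsv": str(evidence),
        "reference_panel_tsv": str(panel_tsv),
        "haplotypes": str(hap_vcf),
        "haplotype_groups_tsv": str(hap_groups),
        "gene_bed": str(gene_bed),
        "output_dir": str(root / "out"),
        "maf_floor": 0.05,
        "n_bins": 20,
        "min_sites_per_bin": 5,
        "seed": 1,
    }
    config_path = root / "config.yaml"
    config_path.write_text(yaml.safe_dump(config))
    return {
        "root": root, "config": config, "config_path": config_path,
        "cohort": cohort, "hap": hap, "keys": keys,
    }
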