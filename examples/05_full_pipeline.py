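"""End-to-end pipeline run on a self-generated workspace.

Generates every input the pipeline needs — curated-variant tables, a
stratified cohort VCF with sample map, an evidence table, a gnomAD-like
reference panel, a swept haplotype panel and a gene BED — then runs
intersect -> classify -> freq-compare -> selection-scan and prints the
manifest counts. Outputs land in ./pipeline_demo_output.
"""

import json
import tempfile
from pathlib import Path

from popepi.compendium import CompendiumRecord, Source, write_compendium_tsv
from popepi.io import (
    write_cohort_vcf,
    write_haplotype_vcf,
    write_reference_panel,
    write_sample_map,
)
from popepi.pipeline import PipelineConfig, run_pipeline
from popepi.simulate import (
    CohortSpec,
    SweepSpec,
    core_site_index,
    simulate_cohort,
    simulate_haplotypes,
    simulate_reference_panel,
)
from popepi.variants import VariantKey

CURATED = [
    ("2", 224642579, "A", "C", "AP1S3", "PS3;PM1;PP3;BS4"),
    ("6", 138196060, "C", "T", "TNFAIP3", "PS3;PM1;PP3"),
    ("12", 110034320, "G", "A", "MVK", "PS4;PM3;PP1;PP5;BP4"),
    ("15", 55520906, "G", "A", "RAB27A", "PM1;PM2;PP3;PP5"),
    ("16", 50750810, "A", "G", "NOD2", "PS3;PM3;PP3"),
    ("19", 54313859, "G", "A", "NLRP12", "PS3;PM1;PP3;PP5"),
    ("19", 54314063, "G", "A", "NLRP12", "PVS1;PM1;PP5"),
]

root = Path(tempfile.mkdtemp(prefix="popepi_demo_"))
keys = [VariantKey(c, p, r, a) for c, p, r, a, _, _ in CURATED]

records = []
for i, (c, p, r, a, gene, _) in enumerate(CURATED):
    key = VariantKey(c, p, r, a)
    for src in ([Source.INFEVERS_LIKE]
                + ([Source.HGMD_LIKE] if i % 2 == 0 else [])
                + ([Source.CLINVAR_LIKE] if i < 2 else [])):
        records.append(CompendiumRecord(key=key, gene=gene, source=src))
for src, name in ((Source.CLINVAR_LIKE, "clinvar"),
                  (Source.INFEVERS_LIKE, "infevers"),
                  (Source.HGMD_LIKE, "hgmd")):
    write_compendium_tsv([x for x in records if x.source == src],
                         root / f"{name}.tsv")
(root / "genes.txt").write_text(
    "\n".join(sorted({g for _, _, _, _, g, _ in CURATED})) + "\n")

cohort = simulate_cohort(CohortSpec(
    subpopulations=(("ARB", 120), ("SAF", 100), ("EUR", 80)),
    variant_panel=tuple(
        (k, {"ARB": 0.015, "SAF": 0.002, "EUR": 0.002}) for k in keys),
    missingness_rate=0.02, seed=7,
))
write_cohort_vcf(cohort, root / "cohort.vcf")
write_sample_map(cohort.subpopulations, root / "samples.tsv")

with open(root / "evidence.tsv", "w") as fh:
    fh.write("chrom\tpos\tref\talt\tgene\tcriteria\n")
    for c, p, r, a, gene, crit in CURATED:
        fh.write(f"{c}\t{p}\t{r}\t{a}\t{gene}\t{crit}\n")

panel = simulate_reference_panel({"ALL": 100_000},
                                 {("ALL", k): 0.0005 for k in keys}, seed=11)
write_reference_panel(panel, root / "reference_panel.tsv")

hap = simulate_haplotypes(SweepSpec(
    n_haplotypes=80, pop_size=500, chrom_length_bp=400_000, n_sites=1200,
    mutation_rate=1e-7, recombination_rate=3e-7, s=0.05, seed=13))
write_haplotype_vcf(hap, root / "haplotypes.vcf")
core_pos = int(hap.positions_bp[core_site_index(hap)])
(root / "genes.bed").write_text(
    f"1\t{max(0, core_pos - 150_000)}\t{core_pos + 150_000}\tRAB27A\n")

config = PipelineConfig(
    clinvar_tsv=str(root / "clinvar.tsv"),
    infevers_tsv=str(root / "infevers.tsv"),
    hgmd_tsv=str(root / "hgmd.tsv"),
    genes_file=str(root / "genes.txt"),
    cohort_vcf=str(root / "cohort.vcf"),
    sample_map_tsv=str(root / "samples.tsv"),
    evidence_tsv=str(root / "evidence.tsv"),
    reference_panel_tsv=str(root / "reference_panel.tsv"),
    haplotypes=str(root / "haplotypes.vcf"),
    gene_bed=str(root / "genes.bed"),
    output_dir="pipeline_demo_output",
    n_bins=20, min_sites_per_bin=5,
    seed=1,
)
manifest = run_pipeline(config)
print(json.dumps(manifest["stages"], indent=2))
print("\nreports written to ./pipeline_demo_output "
      "(venn.json, classifications.tsv, freq_compare.tsv, selection.tsv, "
      "genes.json, run_manifest.json)")
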