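"""File formats: VCF cohorts and haplotype panels, sample maps, reference
panels, haplotype matrices, and genetic maps.

Cohort genotypes are written as VCF v4.2 with unphased GT ("/"); phased
haplotype panels use "|". Reading goes through cyvcf2; multi-allelic records
are decomposed into per-alt normalized keys on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .selection import HaplotypeMatrix
from .simulate import CohortGenotypes, ReferencePanel
from .variants import VariantKey, normalize_variant

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _contig_lines(chroms: Iterable[str], length: int = 2_000_000_000) -> str:
    return "".join(f"##contig=<ID={c},length={length}>\n" for c in dict.fromkeys(chroms))


# ---------------------------------------------------------------------------
# Cohort VCF (diploid, unphased)

_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_cohort_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write diploid cohort genotypes as a VCF v4.2 with unphased GT."""
    chroms = [k.chrom for k in cohort.variants]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(chroms))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(cohort.samples) + "\n")
        order = sorted(
            range(len(cohort.variants)),
            key=lambda j: (cohort.variants[j].chrom, cohort.variants[j].pos),
        )
        for j in order:
            k = cohort.variants[j]
            gts = "\t".join(_GT_UNPHASED[int(g)] for g in cohort.genotypes[:, j])
            fh.write(f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_sample_map(subpopulations: Mapping[str, str], path: str | Path) -> None:
    """Two-column sample -> subpopulation TSV (with header)."""
    pd.DataFrame(
        {"sample": list(subpopulations), "subpopulation": list(subpopulations.values())}
    ).to_csv(path, sep="\t", index=False)


def read_sample_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_cohort_vcf(
    path: str | Path, sample_map: Mapping[str, str] | None = None
) -> CohortGenotypes:
    """Read diploid genotypes from a VCF; multi-allelic records are
    decomposed into per-alt keys (other alts count as non-carrier calls)."""
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        gt = np.asarray(rec.genotype.array())[:, :2]  # (n_samples, 2) allele idx
        for ai, alt in enumerate(rec.ALT, start=1):
            key = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
            alt_count = (gt == ai).sum(axis=1)
            missing = (gt < 0).any(axis=1)
            col = np.where(missing, -1, alt_count).astype(np.int8)
            keys.append(key)
            cols.append(col)
    g = (
        np.stack(cols, axis=1)
        if cols else np.zeros((len(samples), 0), dtype=np.int8)
    )
    sub = dict(sample_map) if sample_map else {s: "ALL" for s in samples}
    missing_samples = set(samples) - set(sub)
    if sample_map is not None and missing_samples:
        raise KeyError(f"samples missing from map: {sorted(missing_samples)}")
    return CohortGenotypes(
        samples=samples, subpopulations={s: sub[s] for s in samples},
        variants=keys, genotypes=g,
    )


def cohort_variant_keys(path: str | Path) -> set[VariantKey]:
    """Normalized keys of every alt allele in a VCF (no genotypes needed)."""
    vcf = VCF(str(path))
    keys: set[VariantKey] = set()
    for rec in vcf:
        for alt in rec.ALT:
            keys.add(normalize_variant(rec.CHROM, rec.POS, rec.REF, alt))
    return keys


# ---------------------------------------------------------------------------
# Phased haplotype panels

_NUCS = ("A", "C", "G", "T")


def write_haplotype_vcf(h: HaplotypeMatrix, path: str | Path) -> None:
    """Write a haplotype panel as a phased VCF (pairs of haplotypes form
    pseudo-individuals; REF/ALT are placeholder alleles A/C)."""
    n_ind = h.n_hap // 2
    if 2 * n_ind != h.n_hap:
        raise ValueError("need an even number of haplotypes for phased VCF")
    names = [f"H{i:04d}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines([h.chrom]))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        ids = h.site_ids or tuple(f"s{j}" for j in range(h.n_sites))
        for j in range(h.n_sites):
            a = h.haplotypes[:, j]
            gts = "\t".join(f"{a[2*i]}|{a[2*i+1]}" for i in range(n_ind))
            fh.write(
                f"{h.chrom}\t{h.positions_bp[j]}\t{ids[j]}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_haplotype_vcf(path: str | Path) -> HaplotypeMatrix:
    """Read a phased VCF into a haplotype matrix (alt allele = derived)."""
    vcf = VCF(str(path))
    cols: list[np.ndarray] = []
    pos: list[int] = []
    ids: list[str] = []
    chrom = "1"
    for rec in vcf:
        gt = np.asarray(rec.genotype.array())
        if not bool(np.all(gt[:, 2] == 1)):  # third column is phasing flag
            raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        cols.append(gt[:, :2].reshape(-1))
        pos.append(rec.POS)
        ids.append(rec.ID or f"s{len(ids)}")
        chrom = rec.CHROM
    if not cols:
        raise ValueError("no sites in haplotype VCF")
    return HaplotypeMatrix(
        haplotypes=np.stack(cols, axis=1).astype(np.uint8),
        positions_bp=np.asarray(pos), site_ids=tuple(ids), chrom=chrom,
    )


def write_haplotype_tsv(h: HaplotypeMatrix, path: str | Path) -> None:
    """Plain-text haplotype matrix: one row per site (site_id, pos_bp, then
    one 0/1 column per haplotype)."""
    ids = h.site_ids or tuple(f"s{j}" for j in range(h.n_sites))
    cols = {f"hap{i}": h.haplotypes[i] for i in range(h.n_hap)}
    df = pd.DataFrame({"site": ids, "pos_bp": h.positions_bp, **cols})
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path: str | Path, chrom: str = "1") -> HaplotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    hap_cols = [c for c in df.columns if c.startswith("hap")]
    return HaplotypeMatrix(
        haplotypes=df[hap_cols].to_numpy().T.astype(np.uint8),
        positions_bp=df["pos_bp"].to_numpy(),
        site_ids=tuple(df["site"].astype(str)),
        chrom=chrom,
    )


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """Genetic-map TSV with columns pos_bp, cM."""
    df = pd.read_csv(path, sep="\t")
    if not {"pos_bp", "cM"} <= set(df.columns):
        raise ValueError("genetic map needs columns pos_bp and cM")
    return df


def attach_genetic_map(h: HaplotypeMatrix, gmap: pd.DataFrame) -> HaplotypeMatrix:
    """Interpolate cM coordinates for the panel's sites from a genetic map."""
    cm = np.interp(h.positions_bp, gmap["pos_bp"], gmap["cM"])
    return HaplotypeMatrix(
        haplotypes=h.haplotypes, positions_bp=h.positions_bp,
        positions_cm=cm, site_ids=h.site_ids, chrom=h.chrom,
    )


# ---------------------------------------------------------------------------
# Reference panels


def write_reference_panel(panel: ReferencePanel, path: str | Path) -> None:
    rows = [
        {
            "population": pop, "chrom": key.chrom, "pos": key.pos,
            "ref": key.ref, "alt": key.alt, "AC": ac, "AN": an,
        }
        for (pop, key), (ac, an) in sorted(
            panel.entries.items(), key=lambda kv: (kv[0][0], kv[0][1])
        )
    ]
    pd.DataFrame(
        rows, columns=["population", "chrom", "pos", "ref", "alt", "AC", "AN"]
    ).to_csv(path, sep="\t", index=False)


def read_reference_panel(path: str | Path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    entries = {
        (str(r.population), normalize_variant(r.chrom, int(r.pos), r.ref, r.alt)):
        (int(r.AC), int(r.AN))
        for r in df.itertuples(index=False)
    }
    return ReferencePanel(entries=entries)
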