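"""Curated disease-variant compendia and cohort intersection.

Models three curated-variant sources (ClinVar-like, Infevers-like, HGMD-like)
as flat record tables keyed by normalized variant identity, filters them to a
disease-gene list, intersects each source with the variants observed in a
cohort, and produces the exclusive-region accounting of a three-set Venn
diagram over the per-source cohort overlaps.

Duplicate records for one variant within a source collapse to a single
membership: the Venn counts distinct variants, not records.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import VariantKey, normalize_variant


class Source(str, enum.Enum):
    """Curated-variant source database (schema emulations, not live dumps)."""

    CLINVAR_LIKE = "CLINVAR_LIKE"
    INFEVERS_LIKE = "INFEVERS_LIKE"
    HGMD_LIKE = "HGMD_LIKE"


class Inheritance(str, enum.Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class CompendiumRecord:
    """One curated disease-variant entry."""

    key: VariantKey
    gene: str
    source: Source
    protein_change: str = ""
    cdna_change: str = ""
    rsid: str | None = None
    disease: str = ""
    omim: str | None = None
    inheritance: Inheritance = Inheritance.UNKNOWN

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be nonempty")
        if not isinstance(self.source, Source):
            object.__setattr__(self, "source", Source(self.source))
        if not isinstance(self.inheritance, Inheritance):
            object.__setattr__(self, "inheritance", Inheritance(self.inheritance))


@dataclass(frozen=True)
class VennCounts:
    """Exclusive region counts of a three-set Venn diagram.

    ``a_only``/``b_only``/``c_only`` are elements unique to one set,
    ``ab_only`` etc. to exactly one pairwise overlap, ``abc`` to all three.
    ``union`` is the distinct-element total and always equals the sum of the
    seven exclusive regions.
    """

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int
    union: int = field(default=-1)

    def __post_init__(self) -> None:
        regions = (
            self.a_only, self.b_only, self.c_only,
            self.ab_only, self.ac_only, self.bc_only, self.abc,
        )
        if any(r < 0 for r in regions):
            raise ValueError("Venn region counts must be nonnegative")
        total = sum(regions)
        if self.union == -1:
            object.__setattr__(self, "union", total)
        elif self.union != total:
            raise ValueError(
                f"union ({self.union}) != sum of exclusive regions ({total})"
            )

    @property
    def a_total(self) -> int:
        return self.a_only + self.ab_only + self.ac_only + self.abc

    @property
    def b_total(self) -> int:
        return self.b_only + self.ab_only + self.bc_only + self.abc

    @property
    def c_total(self) -> int:
        return self.c_only + self.ac_only + self.bc_only + self.abc

    def to_dict(self) -> dict[str, int]:
        return {
            "a_only": self.a_only, "b_only": self.b_only, "c_only": self.c_only,
            "ab_only": self.ab_only, "ac_only": self.ac_only,
            "bc_only": self.bc_only, "abc": self.abc, "union": self.union,
        }


def filter_by_genes(
    records: Sequence[CompendiumRecord], genes: Iterable[str]
) -> list[CompendiumRecord]:
    """Keep records whose gene symbol is in ``genes``, preserving input order."""
    gene_set = set(genes)
    return [r for r in records if r.gene in gene_set]


def intersect_with_cohort(
    records: Sequence[CompendiumRecord], cohort_keys: set[VariantKey]
) -> dict[Source, set[VariantKey]]:
    """Per-source sets of curated variants also observed in the cohort.

    Both sides must hold normalized keys (see :func:`normalize_variant`);
    sources without any record map to the empty set.
    """
    out: dict[Source, set[VariantKey]] = {s: set() for s in Source}
    for rec in records:
        if rec.key in cohort_keys:
            out[rec.source].add(rec.key)
    return out


def venn_counts(
    set_a: set[VariantKey], set_b: set[VariantKey], set_c: set[VariantKey]
) -> VennCounts:
    """Exclusive three-set Venn region counts for the given variant sets."""
    abc = set_a & set_b & set_c
    ab = (set_a & set_b) - abc
    ac = (set_a & set_c) - abc
    bc = (set_b & set_c) - abc
    a_only = set_a - set_b - set_c
    b_only = set_b - set_a - set_c
    c_only = set_c - set_a - set_b
    return VennCounts(
        a_only=len(a_only), b_only=len(b_only), c_only=len(c_only),
        ab_only=len(ab), ac_only=len(ac), bc_only=len(bc), abc=len(abc),
    )


def venn_regions(
    set_a: set[VariantKey], set_b: set[VariantKey], set_c: set[VariantKey]
) -> dict[str, set[VariantKey]]:
    """The seven exclusive regions as variant sets (for per-region reporting)."""
    abc = set_a & set_b & set_c
    return {
        "abc": abc,
        "ab_only": (set_a & set_b) - abc,
        "ac_only": (set_a & set_c) - abc,
        "bc_only": (set_b & set_c) - abc,
        "a_only": set_a - set_b - set_c,
        "b_only": set_b - set_a - set_c,
        "c_only": set_c - set_a - set_b,
    }


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = [
    "source", "chrom", "pos", "ref", "alt", "gene",
    "protein_change", "disease", "omim", "inheritance", "rsid",
]


def read_compendium_tsv(
    path: str | Path, source: Source | str | None = None
) -> list[CompendiumRecord]:
    """Read a curated-variant TSV with header into records.

    Expected columns: source, chrom, pos, ref, alt, gene, protein_change,
    disease, omim, inheritance, rsid (missing optional columns tolerated).
    ``source`` overrides the file's source column when given. Keys are
    normalized on read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[CompendiumRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        src = Source(source) if source is not None else Source(d["source"])
        records.append(
            CompendiumRecord(
                key=normalize_variant(d["chrom"], int(d["pos"]), d["ref"], d["alt"]),
                gene=d["gene"],
                source=src,
                protein_change=d.get("protein_change", ""),
                disease=d.get("disease", ""),
                omim=d.get("omim") or None,
                inheritance=Inheritance(d.get("inheritance") or "UNKNOWN"),
                rsid=d.get("rsid") or None,
            )
        )
    return records


def write_compendium_tsv(records: Sequence[CompendiumRecord], path: str | Path) -> None:
    rows = [
        {
            "source": r.source.value, "chrom": r.key.chrom, "pos": r.key.pos,
            "ref": r.key.ref, "alt": r.key.alt, "gene": r.gene,
            "protein_change": r.protein_change, "disease": r.disease,
            "omim": r.omim or "", "inheritance": r.inheritance.value,
            "rsid": r.rsid or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_venn_json(counts: VennCounts, path: str | Path) -> None:
    Path(path).write_text(json.dumps(counts.to_dict(), indent=2) + "\n")


def write_region_tsv(
    regions: Mapping[str, set[VariantKey]], path: str | Path
) -> None:
    """Long-format TSV listing every union variant with its exclusive region."""
    rows = [
        {"region": region, "chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt}
        for region, keys in sorted(regions.items())
        for k in sorted(keys)
    ]
    pd.DataFrame(rows, columns=["region", "chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )
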