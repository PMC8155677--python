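"""Normalized genomic variant identity.

A variant is identified by (chrom, pos, ref, alt) with 1-based coordinates,
after minimal left-aligned normalization: the shared allele suffix is trimmed
first, then the shared prefix, advancing ``pos`` by one for every prefix base
removed. This is the representation used to match variants across curated
databases and cohort VCFs; rsIDs and transcript-level descriptions are
metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass

_ALLELE_ALPHABET = frozenset("ACGTN")


class VariantError(ValueError):
    """Raised for malformed or degenerate variant representations."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of a biallelic variant.

    Attributes
    ----------
    chrom : str
        Chromosome name (no coordinate-system prefix handling; "15" and
        "chr15" are distinct).
    pos : int
        1-based position of the first retained ref base.
    ref, alt : str
        Minimal reference and alternate alleles over {A, C, G, T, N}.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantError("ref and alt alleles must be nonempty")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ALLELE_ALPHABET:
                raise VariantError(f"allele {allele!r} not over ACGTN")
        if self.ref == self.alt:
            raise VariantError(
                f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}: not a variant"
            )

    def __str__(self) -> str:  # paperish "chrom-pos ref>alt" display form
        return f"{self.chrom}-{self.pos} {self.ref}>{self.alt}"


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Return the minimal left-aligned :class:`VariantKey` for an allele pair.

    The shared suffix of ``ref`` and ``alt`` is trimmed first (never emptying
    either allele), then the shared prefix, advancing ``pos`` per trimmed
    prefix base. Trimming is idempotent: normalizing a normalized key is a
    no-op.

    Raises
    ------
    VariantError
        If alleles are empty, contain characters outside ACGTN, or are equal
        (before or after trimming).
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise VariantError("ref and alt alleles must be nonempty")
    if ref == alt:
        raise VariantError(f"ref == alt ({ref!r}): not a variant")
    # Trim shared suffix, keeping at least one base in each allele.
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref = ref[:-1]
        alt = alt[:-1]
    # Trim shared prefix, advancing pos.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return VariantKey(chrom=str(chrom), pos=int(pos), ref=ref, alt=alt)
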