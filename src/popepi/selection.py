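"""Haplotype-based natural-selection statistics: EHH, iHH, iHS, and Fst.

Extended haplotype homozygosity (EHH) at a distal site x, for the carriers of
one allele at a core site, is the probability that two randomly drawn carrier
haplotypes are identical over the interval core..x. Integrating EHH outward
from the core over map distance until it decays below a cutoff gives iHH for
each core allele; the unstandardized score is

    uniHS = ln(iHH_ancestral / iHH_derived)

which is then z-scored within derived-allele-frequency (DAF) bins so that
scores are comparable across frequencies. Sites in the extreme tail
(|iHS| > 2, or the top percentile of |iHS|) are candidate targets of recent
positive selection: a sweeping derived allele sits on unusually long
homozygous haplotypes, inflating iHH_derived and driving uniHS negative.

Population differentiation is measured per site by Wright's fixation index
F_ST = (H_T - H_S)/H_T or by the Weir-Cockerham (1984) variance-component
estimator a/(a+b+c) (the form computed by the PLINK workflow this package
mirrors).

Distances are genetic (cM) when a map is supplied and physical (kb)
otherwise; with the uniform recombination of the synthetic panels the two
are proportional.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class EdgePolicy(str, enum.Enum):
    """What to do when EHH integration reaches a chromosome edge above cutoff."""

    DROP = "DROP"                  # site's iHS is undefined (default)
    INTEGRATE_TO_EDGE = "INTEGRATE_TO_EDGE"


class Estimator(str, enum.Enum):
    WC = "WC"          # Weir-Cockerham 1984 variance components
    WRIGHT = "WRIGHT"  # (H_T - H_S) / H_T


@dataclass(frozen=True)
class HaplotypeMatrix:
    """Phased binary haplotypes: rows are haplotypes, columns are sites.

    0 encodes the ancestral allele, 1 the derived allele. ``positions_bp``
    are strictly increasing 1-based physical positions; ``positions_cm`` is
    an optional strictly increasing genetic map.
    """

    haplotypes: np.ndarray
    positions_bp: np.ndarray
    positions_cm: np.ndarray | None = None
    site_ids: tuple[str, ...] | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        h = np.ascontiguousarray(np.asarray(self.haplotypes, dtype=np.uint8))
        object.__setattr__(self, "haplotypes", h)
        pos = np.asarray(self.positions_bp, dtype=np.int64)
        object.__setattr__(self, "positions_bp", pos)
        if h.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if h.shape[0] < 4:
            raise ValueError("need at least 4 haplotypes")
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if pos.shape[0] != h.shape[1]:
            raise ValueError("positions length must match site count")
        if pos.shape[0] and not (np.diff(pos) > 0).all():
            raise ValueError("positions_bp must be strictly increasing")
        if self.positions_cm is not None:
            cm = np.asarray(self.positions_cm, dtype=float)
            object.__setattr__(self, "positions_cm", cm)
            if cm.shape[0] != pos.shape[0]:
                raise ValueError("positions_cm length must match site count")
            if cm.shape[0] and not (np.diff(cm) > 0).all():
                raise ValueError("positions_cm must be strictly increasing")
        if self.site_ids is not None and len(self.site_ids) != pos.shape[0]:
            raise ValueError("site_ids length must match site count")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def daf(self) -> np.ndarray:
        """Derived allele frequency per site."""
        return self.haplotypes.mean(axis=0)

    def distances(self) -> np.ndarray:
        """Per-site distance coordinate: cM if mapped, else kb."""
        if self.positions_cm is not None:
            return self.positions_cm.astype(float)
        return self.positions_bp.astype(float) / 1000.0


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive gene interval."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"malformed interval for {self.gene}: start > end")


# ---------------------------------------------------------------------------
# EHH / iHH / iHS


def _check_core(h: HaplotypeMatrix, core_site: int, core_allele: int) -> np.ndarray:
    col = h.haplotypes[:, core_site]
    carriers = np.flatnonzero(col == core_allele)
    if carriers.size < 2:
        raise ValueError(
            f"fewer than 2 haplotypes carry allele {core_allele} at site {core_site}"
        )
    return carriers


def ehh(h: HaplotypeMatrix, core_site: int, core_allele: int, x: int) -> float:
    """EHH of ``core_allele`` carriers at target site ``x``.

    Carriers are grouped by identity of their haplotype substring spanning
    core..x inclusive; EHH = sum_g C(n_g, 2) / C(n_c, 2).
    """
    carriers = _check_core(h, core_site, core_allele)
    lo, hi = min(core_site, x), max(core_site, x)
    block = h.haplotypes[np.ix_(carriers, np.arange(lo, hi + 1))]
    _, counts = np.unique(block, axis=0, return_counts=True)
    n_c = carriers.size
    return float((counts * (counts - 1)).sum() / (n_c * (n_c - 1)))


def _ehh_decay(
    h: HaplotypeMatrix, core_site: int, carriers: np.ndarray, direction: int
) -> Iterator[tuple[int, float]]:
    """Yield (site_index, EHH) stepping outward from the core.

    Group identity is extended one site at a time, so each step costs
    O(n_carriers) instead of re-hashing the whole substring.
    """
    n_c = carriers.size
    denom = n_c * (n_c - 1)
    groups = np.zeros(n_c, dtype=np.int64)
    n_sites = h.n_sites
    x = core_site + direction
    while 0 <= x < n_sites:
        keys = groups * 2 + h.haplotypes[carriers, x]
        _, groups, counts = np.unique(keys, return_inverse=True, return_counts=True)
        yield x, float((counts * (counts - 1)).sum() / denom)
        if counts.size == n_c:  # all singletons: EHH is 0 from here on
            x += direction
            while 0 <= x < n_sites:
                yield x, 0.0
                x += direction
            return
        x += direction


@dataclass(frozen=True)
class IhhResult:
    area: float
    truncated: bool
    truncated_left: bool = False
    truncated_right: bool = False


def ihh(
    h: HaplotypeMatrix,
    core_site: int,
    core_allele: int,
    cutoff: float = 0.05,
) -> IhhResult:
    """Integrated EHH for one core allele.

    EHH is evaluated at successive sites outward from the core in each
    direction and integrated by the trapezoid rule over distance (cM if a
    map is present, else kb). A trapezoid segment is accumulated while the
    EHH at its inner end exceeds ``cutoff`` — so the segment in which EHH
    first crosses below the cutoff is included, and integration stops there.
    A side that exhausts the chromosome while EHH is still >= cutoff is
    flagged truncated.
    """
    carriers = _check_core(h, core_site, core_allele)
    dist = h.distances()
    area = 0.0
    trunc = [False, False]
    for side, direction in enumerate((-1, 1)):
        e_prev = 1.0
        d_prev = dist[core_site]
        exhausted = True
        for x, e in _ehh_decay(h, core_site, carriers, direction):
            if e_prev <= cutoff:
                exhausted = False
                break
            area += 0.5 * (e_prev + e) * abs(dist[x] - d_prev)
            e_prev, d_prev = e, dist[x]
        else:
            exhausted = e_prev > cutoff  # ran off the edge still above cutoff
        if exhausted and e_prev > cutoff:
            trunc[side] = True
    return IhhResult(
        area=area, truncated=any(trunc),
        truncated_left=trunc[0], truncated_right=trunc[1],
    )


@dataclass(frozen=True)
class IhsSite:
    site: int
    daf: float
    ihh_a: float = float("nan")
    ihh_d: float = float("nan")
    unihs: float = float("nan")
    reason: str = ""  # nonempty iff uniHS is undefined

    @property
    def defined(self) -> bool:
        return not self.reason


def ihs_unstandardized(
    h: HaplotypeMatrix,
    core_site: int,
    cutoff: float = 0.05,
    min_carriers: int = 2,
    maf_floor: float = 0.05,
    edge_policy: EdgePolicy | str = EdgePolicy.DROP,
) -> IhsSite:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at one core site.

    The site is skipped (``reason`` set) when either allele has fewer than
    ``min_carriers`` carriers, the DAF is outside [maf_floor, 1 - maf_floor],
    either iHH is 0, or (under the default DROP edge policy) either side's
    integration hit a chromosome edge before decaying below the cutoff.
    """
    edge_policy = EdgePolicy(edge_policy)
    col = h.haplotypes[:, core_site]
    n_derived = int(col.sum())
    daf = n_derived / h.n_hap
    if n_derived == 0 or n_derived == h.n_hap:
        raise ValueError(f"core site {core_site} is monomorphic")
    if n_derived < min_carriers or h.n_hap - n_derived < min_carriers:
        return IhsSite(core_site, daf, reason="min_carriers")
    if daf < maf_floor or daf > 1.0 - maf_floor:
        return IhsSite(core_site, daf, reason="maf_floor")
    res_a = ihh(h, core_site, 0, cutoff=cutoff)
    res_d = ihh(h, core_site, 1, cutoff=cutoff)
    if edge_policy is EdgePolicy.DROP and (res_a.truncated or res_d.truncated):
        return IhsSite(core_site, daf, res_a.area, res_d.area, reason="truncated")
    if res_a.area == 0.0 or res_d.area == 0.0:
        return IhsSite(core_site, daf, res_a.area, res_d.area, reason="zero_ihh")
    return IhsSite(
        core_site, daf, res_a.area, res_d.area,
        unihs=float(np.log(res_a.area / res_d.area)),
    )


def ihs_scan(
    h: HaplotypeMatrix,
    cutoff: float = 0.05,
    min_carriers: int = 2,
    maf_floor: float = 0.05,
    edge_policy: EdgePolicy | str = EdgePolicy.DROP,
) -> pd.DataFrame:
    """Per-site unstandardized iHS over every polymorphic site.

    Returns a DataFrame with columns site, pos_bp, daf, ihh_a, ihh_d, unihs,
    reason (monomorphic sites get reason "monomorphic").
    """
    rows = []
    counts = h.haplotypes.sum(axis=0)
    for j in range(h.n_sites):
        if counts[j] == 0 or counts[j] == h.n_hap:
            rows.append(IhsSite(j, counts[j] / h.n_hap, reason="monomorphic"))
        else:
            rows.append(
                ihs_unstandardized(
                    h, j, cutoff=cutoff, min_carriers=min_carriers,
                    maf_floor=maf_floor, edge_policy=edge_policy,
                )
            )
    df = pd.DataFrame(
        {
            "site": [r.site for r in rows],
            "pos_bp": h.positions_bp,
            "daf": [r.daf for r in rows],
            "ihh_a": [r.ihh_a for r in rows],
            "ihh_d": [r.ihh_d for r in rows],
            "unihs": [r.unihs for r in rows],
            "reason": [r.reason for r in rows],
        }
    )
    return df


def standardize_ihs(
    unihs: np.ndarray | Sequence[float],
    daf: np.ndarray | Sequence[float],
    n_bins: int = 50,
    min_sites_per_bin: int = 10,
) -> np.ndarray:
    """Z-score uniHS within derived-allele-frequency bins.

    Sites are binned by DAF into ``n_bins`` equal-width bins on [0, 1]; bins
    holding fewer than ``min_sites_per_bin`` defined scores are merged with
    their nearest (by bin center) populated neighbor before standardizing.
    Returns an array aligned with the input, NaN where uniHS is undefined or
    the (merged) bin has zero variance.

    Sites may be pooled from several panels (the usual genome-wide practice)
    before calling; standardization only needs (uniHS, DAF) pairs.
    """
    u = np.asarray(unihs, dtype=float)
    d = np.asarray(daf, dtype=float)
    if u.shape != d.shape:
        raise ValueError("unihs and daf must be aligned")
    defined = np.isfinite(u)
    if not defined.any():
        raise ValueError("no defined uniHS scores to standardize")
    out = np.full(u.shape, np.nan)

    bin_of = np.clip((d * n_bins).astype(int), 0, n_bins - 1)
    # merge sparse bins into their nearest populated neighbor
    merged = {b: b for b in range(n_bins)}
    counts = np.bincount(bin_of[defined], minlength=n_bins)

    # iterative nearest-neighbor merging on the current label set
    while True:
        label_counts: dict[int, int] = {}
        for b in range(n_bins):
            if counts[b] > 0:
                label_counts[merged[b]] = label_counts.get(merged[b], 0) + counts[b]
        small = [
            lab for lab, c in sorted(label_counts.items()) if c < min_sites_per_bin
        ]
        if not small or len(label_counts) <= 1:
            break
        lab = small[0]
        others = [x for x in label_counts if x != lab]
        target = min(others, key=lambda x: (abs(x - lab), x))
        for b in range(n_bins):
            if merged[b] == lab:
                merged[b] = target

    labels = np.array([merged[b] for b in bin_of])
    for lab in np.unique(labels[defined]):
        mask = defined & (labels == lab)
        vals = u[mask]
        mu = vals.mean()
        sd = vals.std(ddof=0)
        if sd == 0.0:
            warnings.warn(
                f"DAF bin {lab}: zero variance, {mask.sum()} site(s) left unstandardized",
                stacklevel=2,
            )
            continue
        out[mask] = (u[mask] - mu) / sd
    return out


def flag_outliers(
    std_ihs: np.ndarray | Sequence[float], pct: float = 0.01, z: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag extreme |iHS| sites.

    Returns (top1pct, abs_gt2) boolean arrays: ``top1pct`` marks sites with
    |std_iHS| at or above the (1 - pct) quantile of the defined |std_iHS|
    (ties included); ``abs_gt2`` marks |std_iHS| > z. Undefined scores are
    never flagged.
    """
    s = np.abs(np.asarray(std_ihs, dtype=float))
    defined = np.isfinite(s)
    if not defined.any():
        raise ValueError("no defined std_iHS scores")
    q = np.quantile(s[defined], 1.0 - pct)
    top = defined & (s >= q)
    gt = defined & (s > z)
    return top, gt


def map_to_genes(
    positions_bp: np.ndarray | Sequence[int],
    genes: Sequence[GeneInterval],
    chrom: str | None = None,
) -> dict[str, int]:
    """Count flagged-site positions falling inside each gene interval.

    Intervals are 1-based inclusive on both ends; a gene is reported iff it
    contains at least one position. ``chrom`` restricts matching to genes on
    that chromosome (None matches any).
    """
    pos = np.asarray(positions_bp, dtype=np.int64)
    hits: dict[str, int] = {}
    for g in genes:
        if chrom is not None and g.chrom != chrom:
            continue
        n = int(((pos >= g.start) & (pos <= g.end)).sum())
        if n > 0:
            hits[g.gene] = hits.get(g.gene, 0) + n
    return hits


def read_bed_genes(path: str | Path) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open, converted to 1-based
    inclusive). Columns: chrom, start, end, name."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3], dtype=str,
    )
    return [
        GeneInterval(gene=str(row[3]), chrom=str(row[0]),
                     start=int(row[1]) + 1, end=int(row[2]))
        for row in df.itertuples(index=False, name=None)
    ]


# ---------------------------------------------------------------------------
# Fst


def _allele_stats(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_called, alt-allele freq, observed het proportion) per site for a
    diploid genotype matrix coded 0/1/2 with -1 missing."""
    g = np.asarray(geno)
    called = g >= 0
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=0) / (2.0 * n)
        het = np.where(called, g == 1, False).sum(axis=0) / n
    return n, p, het


def fst_pair(
    geno1: np.ndarray,
    geno2: np.ndarray,
    estimator: Estimator | str = Estimator.WC,
) -> np.ndarray:
    """Per-site two-population Fst from diploid genotype matrices.

    ``geno1``/``geno2`` are (n_individuals x n_sites) alt-allele-count
    matrices (0/1/2, -1 = missing). WRIGHT computes (H_T - H_S)/H_T with
    H_S the unweighted mean within-population expected heterozygosity and
    H_T from the unweighted mean allele frequency. WC computes the
    Weir-Cockerham (1984) variance-component estimator a/(a + b + c), which
    uses sample sizes and observed heterozygote counts and may be slightly
    negative. Sites monomorphic in the combined sample (or with < 2 called
    samples in either population) are NaN.
    """
    estimator = Estimator(estimator)
    n1, p1, h1 = _allele_stats(geno1)
    n2, p2, h2 = _allele_stats(geno2)
    usable = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator is Estimator.WRIGHT:
            p_bar = (p1 + p2) / 2.0
            h_t = 2.0 * p_bar * (1.0 - p_bar)
            h_s = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
            fst = (h_t - h_s) / h_t
            fst = np.where(usable & (h_t > 0), fst, np.nan)
        else:
            r = 2.0
            n_tot = n1 + n2
            n_bar = n_tot / r
            n_c = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1.0)
            p_bar = (n1 * p1 + n2 * p2) / n_tot
            h_bar = (n1 * h1 + n2 * h2) / n_tot
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
            pq = p_bar * (1.0 - p_bar)
            a = (n_bar / n_c) * (
                s2 - (pq - ((r - 1.0) / r) * s2 - h_bar / 4.0) / (n_bar - 1.0)
            )
            b = (n_bar / (n_bar - 1.0)) * (
                pq - ((r - 1.0) / r) * s2 - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
            )
            c = h_bar / 2.0
            denom = a + b + c
            fst = np.where(usable & (denom != 0), a / denom, np.nan)
            poly = (p_bar > 0) & (p_bar < 1)
            fst = np.where(poly, fst, np.nan)
    return fst


def haplotypes_to_genotypes(hap: np.ndarray) -> np.ndarray:
    """Pair consecutive haplotype rows into diploid genotypes (random union).

    An odd trailing haplotype is dropped. Useful for running the genotype
    Fst estimators on phased haplotype panels.
    """
    h = np.asarray(hap)
    n = (h.shape[0] // 2) * 2
    return (h[0:n:2] + h[1:n:2]).astype(np.int8)
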