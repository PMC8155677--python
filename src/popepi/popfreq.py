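"""Stratified allele, genotype and carrier frequencies, and exact-test
comparison against reference panels.

Allele frequency is AC/AN with missing genotypes excluded from AN. Carrier
frequency is either observed (fraction of called individuals with at least
one alternate allele) or the Hardy-Weinberg expectation 2p(1-p). Cumulative
carrier frequency over a variant set is reported both as the plain sum and
as the complement product 1 - prod(1 - c_i); SUM >= COMPLEMENT always, with
equality iff at most one c_i is nonzero.

Study/reference comparisons use Fisher's exact test on the 2x2 allele-count
table, two-sided by the point-probability (minimum-likelihood) rule, with
significance tiers RED (p < 0.01), YELLOW (0.01 <= p < 0.05), BLUE
(p >= 0.05). The odds ratio uses the Haldane 0.5 continuity correction only
when a zero cell occurs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .variants import VariantKey

ALL_POPULATION = "ALL"

#: Relative tie tolerance for the point-probability two-sided rule.
_TIE_REL_TOL = 1e-7
#: Largest hypergeometric support evaluated with exact integer arithmetic.
_EXACT_SUPPORT_LIMIT = 2048


class CarrierMethod(str, enum.Enum):
    OBSERVED = "OBSERVED"
    HWE = "HWE"


class Aggregation(str, enum.Enum):
    SUM = "SUM"
    COMPLEMENT = "COMPLEMENT"


class Tier(str, enum.Enum):
    RED = "RED"        # p < 0.01
    YELLOW = "YELLOW"  # 0.01 <= p < 0.05
    BLUE = "BLUE"      # p >= 0.05


@dataclass(frozen=True)
class FrequencyRecord:
    """Per-(variant, population) allele and genotype counts."""

    population: str
    key: VariantKey
    hom_ref: int
    het: int
    hom_alt: int
    missing: int = 0

    def __post_init__(self) -> None:
        if min(self.hom_ref, self.het, self.hom_alt, self.missing) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def AC(self) -> int:
        return self.het + 2 * self.hom_alt

    @property
    def AN(self) -> int:
        return 2 * (self.hom_ref + self.het + self.hom_alt)

    @property
    def AF(self) -> float:
        if self.AN == 0:
            raise ZeroDivisionError(f"AF undefined: AN=0 for {self.key}")
        return self.AC / self.AN

    @property
    def n_called(self) -> int:
        return self.hom_ref + self.het + self.hom_alt

    @property
    def carrier_count(self) -> int:
        return self.het + self.hom_alt

    @classmethod
    def from_allele_counts(
        cls, population: str, key: VariantKey, ac: int, an: int
    ) -> "FrequencyRecord":
        """Build a record from AC/AN only (reference panels print no genotypes).

        Alleles are distributed as if carried by het individuals where
        possible; genotype-level fields are then nominal, but AC, AN and AF
        are exact, which is all a reference comparison uses.
        """
        if an % 2 != 0:
            raise ValueError("AN must be even (diploid alleles)")
        if not 0 <= ac <= an:
            raise ValueError(f"need 0 <= AC <= AN, got AC={ac}, AN={an}")
        n_ind = an // 2
        het = min(ac, 2 * n_ind - ac)
        hom_alt = (ac - het) // 2
        return cls(population, key, hom_ref=n_ind - het - hom_alt,
                   het=het, hom_alt=hom_alt)


@dataclass(frozen=True)
class ComparisonResult:
    study: FrequencyRecord
    reference: FrequencyRecord
    odds_ratio: float
    p_two_sided: float
    tier: Tier


def tier_for_p(p: float, red: float = 0.01, yellow: float = 0.05) -> Tier:
    if p < red:
        return Tier.RED
    if p < yellow:
        return Tier.YELLOW
    return Tier.BLUE


# ---------------------------------------------------------------------------
# Frequency computation


def compute_frequencies(
    cohort: "CohortGenotypes",
    stratify: Mapping[str, str] | str | None = None,
    include_all: bool = True,
) -> list[FrequencyRecord]:
    """Per-(variant, population) frequency records from a genotype matrix.

    Parameters
    ----------
    cohort
        A :class:`popepi.simulate.CohortGenotypes` (genotypes coded 0/1/2,
        -1 for missing).
    stratify
        sample -> subpopulation map; ``"ALL"`` to pool everything; ``None``
        to use the cohort's own map. Unknown samples in the map raise.
    include_all
        Also emit a pooled ``ALL`` record per variant (sum of subpopulation
        counts).
    """
    g = cohort.genotypes  # (n_samples, n_variants), int8
    samples = list(cohort.samples)
    if stratify is None:
        labels = [cohort.subpopulations[s] for s in samples]
    elif stratify == ALL_POPULATION or (
        isinstance(stratify, str) and stratify.upper() == ALL_POPULATION
    ):
        labels = [ALL_POPULATION] * len(samples)
        include_all = False
    else:
        unknown = set(stratify) - set(samples)
        if unknown:
            raise KeyError(f"stratification map names unknown samples: {sorted(unknown)}")
        labels = [stratify[s] for s in samples]

    pops = sorted(set(labels))
    records: list[FrequencyRecord] = []
    label_arr = np.asarray(labels)
    for j, key in enumerate(cohort.variants):
        col = g[:, j]
        per_pop: list[FrequencyRecord] = []
        for pop in pops:
            sub = col[label_arr == pop]
            per_pop.append(
                FrequencyRecord(
                    population=pop, key=key,
                    hom_ref=int(np.sum(sub == 0)), het=int(np.sum(sub == 1)),
                    hom_alt=int(np.sum(sub == 2)), missing=int(np.sum(sub == -1)),
                )
            )
        records.extend(per_pop)
        if include_all and pops != [ALL_POPULATION]:
            records.append(
                FrequencyRecord(
                    population=ALL_POPULATION, key=key,
                    hom_ref=sum(r.hom_ref for r in per_pop),
                    het=sum(r.het for r in per_pop),
                    hom_alt=sum(r.hom_alt for r in per_pop),
                    missing=sum(r.missing for r in per_pop),
                )
            )
    return records


def carrier_frequency(
    rec: FrequencyRecord, method: CarrierMethod | str = CarrierMethod.OBSERVED
) -> float:
    """Proportion of individuals carrying >= 1 alternate allele.

    OBSERVED counts carriers among called individuals; HWE returns the
    random-mating expectation 2 * AF * (1 - AF).
    """
    method = CarrierMethod(method)
    if rec.AN == 0:
        raise ZeroDivisionError(f"carrier frequency undefined: AN=0 for {rec.key}")
    if method is CarrierMethod.OBSERVED:
        return rec.carrier_count / rec.n_called
    af = rec.AF
    return 2.0 * af * (1.0 - af)


def cumulative_carrier_frequency(
    records: Sequence[FrequencyRecord],
    method: CarrierMethod | str = CarrierMethod.OBSERVED,
    aggregation: Aggregation | str = Aggregation.SUM,
) -> float:
    """Aggregate carrier frequency over a set of variants in one population.

    SUM adds the per-variant carrier frequencies (the conventional additive
    report for mutually rare variants); COMPLEMENT computes
    1 - prod(1 - c_i), the probability of carrying at least one of them
    under independence.
    """
    if not records:
        raise ValueError("cumulative carrier frequency of an empty record list")
    pops = {r.population for r in records}
    if len(pops) > 1:
        raise ValueError(f"records span multiple populations: {sorted(pops)}")
    aggregation = Aggregation(aggregation)
    cs = [carrier_frequency(r, method) for r in records]
    if aggregation is Aggregation.SUM:
        return float(sum(cs))
    return float(1.0 - math.prod(1.0 - c for c in cs))


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p_two_sided)``. The p-value sums, over all tables
    with the observed margins, the hypergeometric point probabilities that do
    not exceed the observed table's (ties admitted within relative tolerance
    1e-7). Small supports are evaluated in exact integer arithmetic; large
    ones fall back to log-space hypergeometric pmf.

    The odds ratio is the sample (a*d)/(b*c), with 0.5 added to every cell
    iff any cell is zero (Haldane-Anscombe).
    """
    for name, x in zip("abcd", (a, b, c, d)):
        if x < 0 or x != int(x):
            raise ValueError(f"cell {name} must be a nonnegative integer, got {x}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all four cells are zero")

    if min(a, b, c, d) == 0:
        odds_ratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds_ratio = (a * d) / (b * c)

    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    if lo == hi:  # degenerate margins: a single possible table
        return odds_ratio, 1.0

    support = hi - lo + 1
    if support <= _EXACT_SUPPORT_LIMIT:
        p = _fisher_p_exact_int(a, row1, col1, n, lo, hi)
    else:
        p = _fisher_p_log(a, row1, col1, n, lo, hi)
    return odds_ratio, min(1.0, p)


def _fisher_p_exact_int(a: int, row1: int, col1: int, n: int, lo: int, hi: int) -> float:
    """Exact-integer point-probability rule: one float division at the end."""
    weights = [math.comb(col1, k) * math.comb(n - col1, row1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    scale = 10 ** 9  # integer guard band encoding the 1e-7 relative tie tolerance
    thresh = w_obs * (scale + 100)
    num = sum(w for w in weights if w * scale <= thresh)
    return num / math.comb(n, row1)


def _fisher_p_log(a: int, row1: int, col1: int, n: int, lo: int, hi: int) -> float:
    ks = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(ks, n, col1, row1)
    log_obs = logp[a - lo]
    keep = logp <= log_obs + math.log1p(_TIE_REL_TOL)
    return float(np.exp(logp[keep]).sum())


def compare_to_reference(
    study: FrequencyRecord,
    reference: FrequencyRecord,
    red: float = 0.01,
    yellow: float = 0.05,
) -> ComparisonResult:
    """Fisher-exact comparison of study vs reference allele counts.

    The 2x2 table is [[study.AC, study.AN - study.AC],
    [ref.AC, ref.AN - ref.AC]]; the tier encodes the significance coloring
    (RED p < ``red``, YELLOW below ``yellow``, else BLUE).
    """
    if study.AN == 0 or reference.AN == 0:
        raise ZeroDivisionError("comparison undefined: AN=0 on one side")
    odds_ratio, p = fisher_exact_2x2(
        study.AC, study.AN - study.AC, reference.AC, reference.AN - reference.AC
    )
    return ComparisonResult(
        study=study, reference=reference, odds_ratio=odds_ratio,
        p_two_sided=p, tier=tier_for_p(p, red, yellow),
    )


def bonferroni(p_values: Iterable[float]) -> list[float]:
    """Bonferroni-adjusted p-values (reported for transparency; tiers always
    use the raw p)."""
    ps = list(p_values)
    m = len(ps)
    return [min(1.0, p * m) for p in ps]
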