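"""Synthetic inputs for the pipeline: stratified HWE cohorts, reference
panels, and neutral or swept phased haplotype panels.

The cohort generator draws diploid genotypes per subpopulation under
Hardy-Weinberg equilibrium at specified alt-allele frequencies — sufficient
for everything downstream, which depends only on genotype and haplotype
counts. The haplotype generator models a finite Wright-Fisher diploid
population: its neutral equilibrium is drawn from the exact coalescent of
that population (msprime), and selection is simulated forward in time on a
fixed site grid — per-generation mutation under an infinite-sites
approximation, uniform recombination, fitness 1 + s per copy of the derived
core allele — until the core first reaches a target frequency, restarting
the selection phase with a fresh random stream whenever the allele is lost.

All generators are deterministic for a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .selection import HaplotypeMatrix
from .variants import VariantKey


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Cohort genotypes


@dataclass(frozen=True)
class CohortSpec:
    """Stratified-cohort specification.

    subpopulations
        (label, n_individuals) pairs; labels must be unique.
    variant_panel
        (VariantKey, {label: alt-allele frequency}) pairs; every variant
        needs a frequency in [0, 1] for every subpopulation.
    missingness_rate
        Per-genotype probability of a missing call, in [0, 1).
    """

    subpopulations: tuple[tuple[str, int], ...]
    variant_panel: tuple[tuple[VariantKey, Mapping[str, float]], ...]
    missingness_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        subs = tuple((str(l), int(n)) for l, n in self.subpopulations)
        object.__setattr__(self, "subpopulations", subs)
        object.__setattr__(
            self, "variant_panel",
            tuple((k, dict(f)) for k, f in self.variant_panel),
        )
        if not subs:
            raise ValueError("subpopulation list is empty")
        labels = [l for l, _ in subs]
        if len(set(labels)) != len(labels):
            raise ValueError("subpopulation labels must be unique")
        if any(n <= 0 for _, n in subs):
            raise ValueError("subpopulation sizes must be positive")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0, 1)")
        for key, freqs in self.variant_panel:
            for label in labels:
                if label not in freqs:
                    raise ValueError(f"variant {key} lacks a frequency for {label!r}")
                p = freqs[label]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"frequency {p} outside [0, 1] for {key}/{label}")


@dataclass
class CohortGenotypes:
    """Diploid genotypes for a stratified cohort.

    ``genotypes`` is (n_samples, n_variants) int8 of alt-allele counts
    (0/1/2) with -1 for missing calls.
    """

    samples: list[str]
    subpopulations: dict[str, str]  # sample -> subpopulation label
    variants: list[VariantKey]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.shape != (len(self.samples), len(self.variants)):
            raise ValueError("genotype matrix shape mismatch")
        if not np.isin(g, (-1, 0, 1, 2)).all():
            raise ValueError("genotypes must be in {-1, 0, 1, 2}")
        self.genotypes = g


def simulate_cohort(spec: CohortSpec) -> CohortGenotypes:
    """Draw HWE genotypes per subpopulation: alt-count ~ Binomial(2, p_kv).

    Missing genotypes are set independently at ``missingness_rate``.
    Reproducible for a fixed spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[str] = []
    sub_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    keys = [k for k, _ in spec.variant_panel]
    for label, n in spec.subpopulations:
        names = [f"{label}_{i:04d}" for i in range(n)]
        samples.extend(names)
        sub_of.update({s: label for s in names})
        ps = np.array([freqs[label] for _, freqs in spec.variant_panel])
        blocks.append(rng.binomial(2, ps, size=(n, len(keys))).astype(np.int8))
    g = np.vstack(blocks) if blocks else np.zeros((0, len(keys)), dtype=np.int8)
    if spec.missingness_rate > 0.0:
        miss = rng.random(g.shape) < spec.missingness_rate
        g[miss] = -1
    return CohortGenotypes(samples=samples, subpopulations=sub_of,
                           variants=keys, genotypes=g)


# ---------------------------------------------------------------------------
# Reference panels


@dataclass(frozen=True)
class ReferencePanel:
    """gnomAD-like allele-count table: (population, variant) -> (AC, AN)."""

    entries: Mapping[tuple[str, VariantKey], tuple[int, int]]

    def populations(self) -> list[str]:
        return sorted({pop for pop, _ in self.entries})

    def ac_an(self, population: str, key: VariantKey) -> tuple[int, int]:
        return self.entries[(population, key)]

    def af(self, population: str, key: VariantKey) -> float:
        ac, an = self.entries[(population, key)]
        return ac / an


def simulate_reference_panel(
    panel_sizes: Mapping[str, int],
    afs: Mapping[tuple[str, VariantKey], float],
    seed: int = 0,
) -> ReferencePanel:
    """Draw reference allele counts AC ~ Binomial(AN, af) per (population,
    variant); AC/AN are stored exactly."""
    rng = np.random.default_rng(seed)
    entries: dict[tuple[str, VariantKey], tuple[int, int]] = {}
    for (pop, key), af in sorted(afs.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        an = int(panel_sizes[pop])
        if an < 2 or an % 2 != 0:
            raise ValueError(f"AN for {pop!r} must be even and >= 2, got {an}")
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"af {af} outside [0, 1] for {pop}/{key}")
        entries[(pop, key)] = (int(rng.binomial(an, af)), an)
    return ReferencePanel(entries=entries)


# ---------------------------------------------------------------------------
# Wright-Fisher haplotype panels


@dataclass(frozen=True)
class SweepSpec:
    """Wright-Fisher haplotype-panel specification.

    The defaults are the package's desk-scale study conditions: a
    4,000-diploid population, mutation rate 2.5e-8 and recombination rate
    5e-8 per bp per generation on 1 Mb (theta = 400 and rho = 800 per Mb, so
    panels segregate ~2,300 sampled sites and haplotype homozygosity decays
    well inside the window), a site-grid capacity of 5,000, and a
    200-haplotype output sample. The neutral equilibrium state is drawn from
    the exact coalescent of this population; with ``s`` > 0 a new derived
    mutation is introduced at the grid site nearest the chromosome midpoint
    and the population evolves forward in time — fitness 1 + s per derived
    copy, per-generation mutation and uniform recombination — until the
    core's population frequency first reaches ``core_target_daf``
    (2Ns = 400 at the defaults, a canonically detectable sweep). The output
    sample is drawn stratified on the core allele so the sample DAF matches
    the target to within 1/n_haplotypes.
    """

    n_haplotypes: int = 200
    n_sites: int = 5000          # site-grid capacity
    chrom_length_bp: int = 1_000_000
    mutation_rate: float = 2.5e-8
    recombination_rate: float = 5e-8
    s: float = 0.0
    core_target_daf: float = 0.6
    seed: int = 0
    pop_size: int = 4000         # diploid individuals
    max_restarts: int = 500

    def __post_init__(self) -> None:
        if self.n_haplotypes <= 0 or self.n_haplotypes % 2 != 0:
            raise ValueError("n_haplotypes must be a positive even integer")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.chrom_length_bp < self.n_sites:
            raise ValueError("chrom_length_bp must be >= n_sites")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0.0 < self.core_target_daf < 1.0:
            raise ValueError("core_target_daf must be in (0, 1)")
        if self.n_haplotypes > 2 * self.pop_size:
            raise ValueError("cannot sample more haplotypes than the population holds")


class _WrightFisher:
    """Mutable forward-simulation state over a fixed site grid."""

    REFRESH = 2  # generations between fixation-recycling sweeps; must be
    # small relative to the per-generation mutation influx or the free-site
    # list starves and the realized mutation rate drops below spec

    def __init__(
        self, spec: SweepSpec, pop: np.ndarray, positions: np.ndarray
    ):
        self.spec = spec
        self.n_hap = pop.shape[0]
        self.positions = positions
        self.pop = pop
        self.u_total = spec.mutation_rate * spec.chrom_length_bp
        self.r_total = spec.recombination_rate * spec.chrom_length_bp
        self.n_sites = pop.shape[1]
        self.free: list[int] = []
        self.core: int | None = None
        self._since_refresh = 0
        self.refresh_free_sites()

    # -- bookkeeping

    def refresh_free_sites(self) -> None:
        counts = self.pop.sum(axis=0, dtype=np.int64)
        fixed = counts == self.n_hap
        if self.core is not None:
            fixed[self.core] = False
        if fixed.any():  # recycle fixed-derived columns as ancestral
            self.pop[:, fixed] = 0
            counts[fixed] = 0
        free = np.flatnonzero(counts == 0)
        if self.core is not None:
            free = free[free != self.core]
        self.free = free.tolist()
        self._since_refresh = 0

    # -- one generation

    def step(self, rng: np.random.Generator, fitness_core: bool = False) -> None:
        n_hap, n_ind = self.n_hap, self.n_hap // 2
        if fitness_core and self.core is not None and self.spec.s > 0:
            g = (
                self.pop[0:n_hap:2, self.core].astype(np.int64)
                + self.pop[1:n_hap:2, self.core]
            )
            w = (1.0 + self.spec.s) ** g
            parents = rng.choice(n_ind, size=n_hap, p=w / w.sum())
        else:
            parents = rng.integers(0, n_ind, size=n_hap)
        start = rng.integers(0, 2, size=n_hap)
        children = self.pop[2 * parents + start]
        n_cross = rng.poisson(self.r_total, size=n_hap)
        single = np.flatnonzero(n_cross == 1)
        if single.size:  # vectorized: the bulk of crossover meioses
            cuts_bp = rng.integers(1, self.spec.chrom_length_bp + 1, size=single.size)
            cuts = np.searchsorted(self.positions, cuts_bp)
            before = np.arange(self.n_sites) < cuts[:, None]
            hap_a = self.pop[2 * parents[single] + start[single]]
            hap_b = self.pop[2 * parents[single] + 1 - start[single]]
            children[single] = np.where(before, hap_a, hap_b)
        for i in np.flatnonzero(n_cross >= 2):
            cuts_bp = rng.integers(1, self.spec.chrom_length_bp + 1, size=n_cross[i])
            cuts = np.unique(np.searchsorted(self.positions, cuts_bp))
            hapA = self.pop[2 * parents[i] + start[i]]
            hapB = self.pop[2 * parents[i] + 1 - start[i]]
            gamete = hapA.copy()
            use_b = False
            prev = 0
            for c in list(cuts) + [self.n_sites]:
                if use_b:
                    gamete[prev:c] = hapB[prev:c]
                use_b = not use_b
                prev = c
            children[i] = gamete
        self.pop = children
        # mutation: each event hits a currently-ancestral grid site
        n_mut = rng.poisson(self.u_total * n_hap)
        if n_mut > 0:
            n_mut = min(n_mut, len(self.free))
            if n_mut:
                site_idx = rng.choice(len(self.free), size=n_mut, replace=False)
                sites = [self.free[j] for j in site_idx]
                rows = rng.integers(0, n_hap, size=n_mut)
                self.pop[rows, sites] = 1
                taken = set(sites)
                self.free = [s for s in self.free if s not in taken]
        self._since_refresh += 1
        if self._since_refresh >= self.REFRESH:
            self.refresh_free_sites()

    def core_count(self) -> int:
        assert self.core is not None
        return int(self.pop[:, self.core].sum())


def _derived_seed(seed: int, salt: int) -> int:
    return (abs(seed) * 1_000_003 + salt) % (2**31 - 2) + 1


def _coalescent_state(
    spec: SweepSpec, n_haplotypes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral Wright-Fisher equilibrium state from the exact coalescent.

    Returns (haplotype matrix, integer bp positions). Mutations follow an
    infinite-sites binary model on a continuous genome; positions are
    floored to integer bp and the rare collisions dropped.
    """
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_haplotypes // 2,
        population_size=spec.pop_size,
        sequence_length=spec.chrom_length_bp,
        recombination_rate=spec.recombination_rate,
        random_seed=_derived_seed(spec.seed, 1_111),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=spec.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=_derived_seed(spec.seed, 2_222),
    )
    pos = np.floor(mts.sites_position).astype(np.int64) + 1
    geno = mts.genotype_matrix().T.astype(np.uint8)  # (n_hap, n_sites)
    keep = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.array([], bool)
    return np.ascontiguousarray(geno[:, keep]), pos[keep]


def simulate_haplotypes(spec: SweepSpec) -> HaplotypeMatrix:
    """Simulate a phased haplotype panel of the Wright-Fisher population.

    The neutral equilibrium state is drawn from the exact coalescent of the
    specified population (so no forward burn-in is needed). With s = 0 that
    sample of ``n_haplotypes`` is the panel. With s > 0 the whole population
    is instantiated and a derived allele is introduced at a reserved grid
    site nearest the chromosome midpoint; the population then evolves
    forward in time (per-generation mutation into free grid slots, uniform
    recombination, fitness 1 + s per derived core copy) until the core's
    population frequency first reaches ``core_target_daf``. If the allele is
    lost, the selection phase restarts from the saved equilibrium state with
    an incremented random stream; :class:`SimulationError` is raised after
    ``max_restarts`` failures. The output sample is stratified on the core
    allele so the sample DAF matches the target to within 1/n_haplotypes.

    The returned matrix contains every grid site (0 = ancestral); the core
    site, when one exists, has site id ``"core"`` (see
    :func:`core_site_index`).
    """
    srng = np.random.default_rng(_derived_seed(spec.seed, 999_999))

    if spec.s == 0:
        haps, positions = _coalescent_state(spec, spec.n_haplotypes)
        if haps.shape[1] > spec.n_sites:
            raise SimulationError(
                f"{haps.shape[1]} segregating sites exceed the n_sites grid "
                f"capacity ({spec.n_sites}); raise n_sites or lower mutation_rate"
            )
        ids = tuple(f"s{j}" for j in range(haps.shape[1]))
        return HaplotypeMatrix(
            haplotypes=haps, positions_bp=positions, site_ids=ids, chrom="1"
        )

    # --- selective sweep: instantiate the whole population
    pop0, init_pos = _coalescent_state(spec, 2 * spec.pop_size)
    n_spare = spec.n_sites - init_pos.size - 1
    if n_spare < 0:
        raise SimulationError(
            f"{init_pos.size} population segregating sites exceed the n_sites "
            f"grid capacity ({spec.n_sites}); raise n_sites or lower mutation_rate"
        )
    # reserve the core at the free bp position nearest the midpoint, plus
    # spare all-ancestral columns to receive forward-time mutations
    grng = np.random.default_rng(_derived_seed(spec.seed, 3_333))
    occupied = set(init_pos.tolist())
    free_bp = np.setdiff1d(
        grng.integers(1, spec.chrom_length_bp + 1, size=4 * spec.n_sites),
        init_pos,
    )
    if free_bp.size < n_spare + 1:
        raise SimulationError("could not place spare grid sites")
    core_bp = int(free_bp[np.argmin(np.abs(free_bp - spec.chrom_length_bp // 2))])
    spare_bp = grng.choice(free_bp[free_bp != core_bp], size=n_spare, replace=False)
    all_bp = np.concatenate([init_pos, [core_bp], spare_bp])
    order = np.argsort(all_bp)
    positions = all_bp[order]
    n_grid = positions.size
    pop_full = np.zeros((2 * spec.pop_size, n_grid), dtype=np.uint8)
    inv = np.empty(n_grid, dtype=np.int64)
    inv[order] = np.arange(n_grid)
    pop_full[:, inv[: init_pos.size]] = pop0
    core = int(inv[init_pos.size])  # column of the reserved core site

    target = spec.core_target_daf * 2 * spec.pop_size
    wf = None
    for attempt in range(spec.max_restarts):
        arng = np.random.default_rng(_derived_seed(spec.seed, 10_000 + attempt))
        wf = _WrightFisher(spec, pop_full.copy(), positions)
        wf.core = core
        wf.free = [s for s in wf.free if s != core]
        wf.pop[int(arng.integers(0, wf.n_hap)), core] = 1
        reached = False
        while True:
            wf.step(arng, fitness_core=True)
            cc = wf.core_count()
            if cc == 0:
                break
            if cc >= target:
                reached = True
                break
        if reached:
            break
    else:
        raise SimulationError(
            f"sweep failed to establish in {spec.max_restarts} restarts"
        )

    # stratified output sample: fix the core count at the target frequency
    col = wf.pop[:, core]
    carriers = np.flatnonzero(col == 1)
    non = np.flatnonzero(col == 0)
    n_car = min(int(round(spec.core_target_daf * spec.n_haplotypes)), carriers.size)
    n_non = spec.n_haplotypes - n_car
    if n_non > non.size:
        raise SimulationError("not enough non-carrier haplotypes to sample")
    rows = np.sort(np.concatenate([
        srng.choice(carriers, size=n_car, replace=False),
        srng.choice(non, size=n_non, replace=False),
    ]))
    ids = tuple("core" if j == core else f"s{j}" for j in range(n_grid))
    return HaplotypeMatrix(
        haplotypes=wf.pop[rows], positions_bp=positions, site_ids=ids, chrom="1"
    )


def core_site_index(h: HaplotypeMatrix) -> int | None:
    """Index of the sweep core site in a simulated panel, if one exists."""
    if h.site_ids is None:
        return None
    try:
        return h.site_ids.index("core")
    except ValueError:
        return None


def filter_segregating(h: HaplotypeMatrix) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Drop monomorphic columns; returns the filtered matrix and the kept
    original column indices."""
    counts = h.haplotypes.sum(axis=0)
    keep = np.flatnonzero((counts > 0) & (counts < h.n_hap))
    ids = tuple(h.site_ids[j] for j in keep) if h.site_ids is not None else None
    return (
        HaplotypeMatrix(
            haplotypes=h.haplotypes[:, keep],
            positions_bp=h.positions_bp[keep],
            positions_cm=None if h.positions_cm is None else h.positions_cm[keep],
            site_ids=ids,
            chrom=h.chrom,
        ),
        keep,
    )


def binomial_ci(p: float, n: int, confidence: float = 0.99) -> tuple[float, float]:
    """Exact (Clopper-Pearson-free) normal-free binomial CI on the *count*
    scale, returned as frequency bounds: the central probability interval of
    Binomial(n, p) at the given confidence, divided by n.

    Used as the closed-form oracle for allele-frequency recovery checks:
    a realized frequency from Binomial(n, p)/n falls inside this interval
    with probability >= ``confidence``.
    """
    from scipy.stats import binom

    alpha = 1.0 - confidence
    lo = binom.ppf(alpha / 2, n, p)
    hi = binom.isf(alpha / 2, n, p)
    return float(lo / n), float(hi / n)
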