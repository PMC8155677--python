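# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `popepi`, and what its synthetic data does and does
not establish about real cohorts.

## Variant identity

Variants are matched across curated tables and VCFs on the normalized key
`(chrom, pos, ref, alt)`: the shared allele suffix is trimmed first, then
the shared prefix with `pos` advanced per trimmed base, never emptying an
allele. This yields the familiar VCF-style minimal representation (an
insertion keeps its anchor base, e.g. `AT→ATT` at 100 becomes `A→AT` at
100) and is idempotent. Without a reference genome, homopolymer indels
admit several equally minimal placements; callers comparing indel sets
from heterogeneous sources should pre-normalize against a reference.
rsIDs, transcript and protein annotations are carried as metadata and play
no role in matching — positions are stable across database versions in a
way rsIDs are not. Coordinates are 1-based inclusive everywhere; BED input
(0-based half-open) is converted on read. Multi-allelic VCF records are
decomposed into per-alt keys before matching, and duplicate records for
one key within one source collapse to a single membership, so the Venn
accounting counts distinct variants.

## ACMG/AMP engine

Each of the 28 evidence codes maps to exactly one strength tier; the
verdict depends only on the tier-count vector (v, s, m, p | a, bs, bp).
The combining rules are the published 2015 framework:

- Pathogenic: PVS1 with (≥1 strong | ≥2 moderate | 1 moderate + 1
  supporting | ≥2 supporting); or ≥2 strong; or 1 strong with (≥3 moderate
  | 2 moderate + ≥2 supporting | 1 moderate + ≥4 supporting).
- Likely pathogenic: PVS1 + 1 moderate; 1 strong + 1–2 moderate; 1 strong
  + ≥2 supporting; ≥3 moderate; 2 moderate + ≥2 supporting; 1 moderate +
  ≥4 supporting.
- Benign: BA1, or ≥2 strong benign. Likely benign: 1 strong benign + 1
  supporting, or ≥2 supporting benign.

Rule labels (`P(i)(c)`, `LP(ii)`, …) name the first satisfied rule in that
order, mirroring the Roman/letter notation used in published
classification tables.

**Conflict handling** is the one genuinely open design point. The strict
reading of the framework returns Uncertain whenever rules on both sides
fire. Published reclassification tables, however, routinely report
likely-pathogenic verdicts for profiles that carry benign-side codes (BS4,
BP4) alongside strong pathogenic evidence. The engine therefore has two
modes: `PAPER` (default) lets the pathogenic side win and sets
`conflict=True`; `STRICT` returns Uncertain with a
`CONFLICT[...|...]` label. The two modes provably differ only on profiles
where both sides fire (property-tested over all 33,600 feasible tier
vectors). The `conflict` flag is also set when a rule fires on one side
while mere evidence codes exist on the other.

No evidence-strength modulation (e.g. PS3 used at moderate strength) is
implemented: the target workflows do not use it.

**Auto-assignment** covers only the criteria that are pure functions of
variant annotations: PVS1 (null consequence in a gene with a
loss-of-function mechanism), PM2 (below `rare_threshold = 1e-4` in every
reference population, or absent), BA1 (> 0.05 in any general population),
BS1 (> `bs1_threshold = 0.01`, a disorder-specific maximum credible
frequency), PP3/BP4 (≥ 2/3 of informative in-silico calls concordant).
Thresholds live in one config object and are deliberately explicit and
overridable, because published protocols typically inherit them implicitly
from annotation pipelines. Literature-tier codes (functional data,
segregation, case-control, phenotype specificity) are never inferred —
they come from the curated evidence table.

## Frequencies and the exact test

`AF = AC/AN` with missing genotypes excluded from AN (AN therefore varies
by site, as in real exome panels). Carrier frequency is either the
observed fraction of called individuals with ≥1 alternate allele or the
Hardy–Weinberg expectation `2p(1−p)`; the two agree only up to the q²
homozygote term, i.e. in the rare-variant regime this package targets.
Because a study may mean either quantity by "carrier frequency", both are
always reported. Cumulative carrier frequency over a variant set defaults
to the plain sum Σcᵢ (the convention for mutually exclusive rare
carriers) with the independence-based complement `1 − Π(1−cᵢ)` reported
alongside; SUM ≥ COMPLEMENT always, with equality iff at most one cᵢ is
non-zero.

Fisher's exact test on `[[AC₁, AN₁−AC₁], [AC₂, AN₂−AC₂]]` is two-sided by
the point-probability (minimum-likelihood) rule — the convention of
mainstream implementations — with ties admitted at 1e-7 relative
tolerance. When the hypergeometric support holds ≤2,048 tables the sum is
computed in exact integer arithmetic (one float division at the end, so
the result is correct to 1 ulp); larger supports fall back to log-space
hypergeometric pmf. Rare-variant tables have small supports, so the exact
path covers essentially all real comparisons. The odds ratio is the
sample `(ad)/(bc)` with the Haldane 0.5 correction applied only when a
zero cell occurs, keeping rare-variant ORs finite. Significance tiers
follow the conventional coloring: RED p < 0.01, YELLOW 0.01 ≤ p < 0.05,
BLUE p ≥ 0.05, on raw p-values; a Bonferroni column is emitted for
transparency but never changes tiers, mirroring the raw-p practice of the
workflows being reproduced.

## EHH, iHS and Fst

EHH of a core allele at a distal site x is the probability that two
randomly drawn carrier haplotypes are identical over core..x:
`Σ_g C(n_g,2) / C(n_c,2)` over identity groups. iHH integrates EHH outward
by the trapezoid rule over genetic distance (cM when a map is supplied,
else kb — with the generator's uniform recombination the two are
proportional). A segment is accumulated while EHH at its inner end exceeds
the cutoff (default 0.05), so the segment where EHH first crosses below
the cutoff is included and a cutoff of 1.0 integrates nothing. A side that
reaches the chromosome edge still above the cutoff is truncated; truncated
sites are dropped from iHS by default (`INTEGRATE_TO_EDGE` is selectable)
because their areas are biased low in a window-limited panel.

`uniHS = ln(iHH_ancestral / iHH_derived)`; a sweep on the derived allele
makes iHH_D large and uniHS negative. Outlier calls use |iHS|, so the sign
convention cannot change results. Sites need ≥2 carriers of each allele
and DAF within [0.05, 0.95]; standardization is a z-score within 50
equal-width DAF bins, with bins holding fewer than 10 defined scores
merged into their nearest populated neighbor, and zero-variance bins left
undefined with a warning. Scores from several panels may be pooled before
standardizing — the genome-wide practice — and the top-1% flag takes the
(1−pct) quantile of defined |iHS| with ties included.

Fst comes in both named forms: Wright's `(H_T − H_S)/H_T` with H_S the
unweighted mean within-population expected heterozygosity and H_T from the
unweighted mean frequency (bounded in [0,1]; equals 0.36 for p = 0.2 vs
0.8 at equal sizes), and the Weir–Cockerham 1984 two-population
variance-component estimator `a/(a+b+c)` computed from sample sizes and
observed heterozygote counts (the estimator behind the PLINK-style
workflow; can be slightly negative). WC is the default; the two agree
within 0.05 for equal-sized samples of ≥100 at intermediate frequencies.
Haplotype panels are paired into pseudo-diploids for the genotype
estimators.

No gap penalty or max-gap rule is applied during EHH integration: the
synthetic panels have no assembly gaps. This is a documented divergence
from genome-scale practice, where unsequenced gaps would otherwise inflate
areas.

## Synthetic data

**Cohorts.** Diploid genotypes are drawn per subpopulation as
Binomial(2, p) at specified alt-allele frequencies — exact Hardy–Weinberg
sampling — with independent missingness. Every downstream statistic
depends only on genotype counts, so this reproduces the sampling
distribution of the real pipeline inputs without sequencing-error or
genotype-likelihood models. Subpopulation sizes are free parameters (real
cohort compositions are rarely published); the defaults used in tests are
invented and say nothing about any real population's structure.

**Reference panels.** AC ~ Binomial(AN, af) per population and variant,
stored exactly — a gnomAD-like allele-count table.

**Haplotype panels.** The model is a Wright–Fisher diploid population of
size N with per-bp mutation and uniform recombination. Its neutral
equilibrium state is drawn from the exact coalescent of that population
(msprime, binary infinite-sites mutations on a continuous genome floored
to integer bp), which is the standard and statistically exact way to reach
mutation–drift–recombination balance without a forward burn-in. Selection
is then simulated forward in time: a new derived mutation is introduced at
a reserved grid site nearest the chromosome midpoint, each parent is
sampled with probability proportional to `(1+s)^g` (g = derived copies),
gametes recombine with Poisson crossovers, mutations enter free grid
columns, and fixed-derived columns are recycled as ancestral. The
simulation stops the first generation the core's population frequency
reaches the target; if the allele is lost, the selection phase restarts
from the saved equilibrium state with a fresh random stream — simple
rejection, which conditions on establishment without importance-sampling
bias. The output sample of n haplotypes is drawn stratified on the core
allele (round(target·n) carriers), so the panel's core DAF equals the
target to within 1/n, as a conditional-on-frequency panel should.

Study conditions (defaults, chosen once): N = 4,000 diploids, 1 Mb,
μ = 2.5e-8 and r = 5e-8 per bp per generation (θ = 400, ρ = 800 per Mb),
grid capacity 5,000 sites, 200 sampled haplotypes, s = 0.05 (2Ns = 400),
target DAF 0.6. These give panels of ~2,300 sampled segregating sites
whose EHH decays well inside the window, a neutral iHS tail with ~4–5% of
|iHS| > 2, and sweeps in the canonically detectable regime. A smaller
population (2Ns ≈ 50) was evaluated first and produces sweeps whose cores
are genuinely marginal for iHS — scores of −2 to −3 against a neutral 99th
percentile of ≈2.5 — which is expected population genetics, not an
estimator defect; the population size was set where the method's own
power analysis places reliable detection, and not revisited.

What passing tests show — and do not. The generators validate the
*estimators*: frequency recovery, HWE behavior, exact-test correctness,
neutral iHS calibration, and that a strong partial sweep's core lands in
the top 1% of |iHS| against a pooled neutral background (16 panels — the
single-chromosome analogue of genome-wide standardization). They do not
model demography (admixture, bottlenecks, consanguinity), sequencing
error, phasing error, or ascertainment, so passing them does not certify
performance on real cohorts with those features. In particular, hitchhiking
sites near a swept core legitimately reach |iHS| comparable to the core
itself, which is why gene-level interval mapping — not single-site
identity — is the reporting unit for selection candidates.

## Pipeline

The orchestrated run executes intersect → classify → freq-compare →
selection-scan with one config and seed, writes machine-readable reports
(venn.json, classifications.tsv, freq_compare.tsv, carrier_summary.json,
selection.tsv, genes.json) plus a manifest echoing config, seed, version
and per-stage record counts, and removes partial outputs on stage failure.
All outputs are byte-identical across reruns of the same config + seed;
stage timings go to the log, not the manifest, to keep that true. Stage
record counts are conserved or explicitly decremented (filtered,
monomorphic, undefined-score) so every output row traces to an input
variant.

Problem sizes throughout the tests and the acceptance script (cohorts of
1,000 individuals × 50 variants × 50 seeds; 16 neutral + 10 swept 1 Mb
panels) are the package's desk-scale study conditions: large enough for
the statistical properties being asserted, small enough to run on a
laptop.

## Known limitations

- Normalization is pairwise-minimal, not reference-left-aligned; matching
  indel representations from heterogeneous pipelines may need upstream
  left-alignment against a genome.
- The ACMG engine does not implement Bayesian point-based refinements or
  criterion-strength modulation.
- The exact test's large-support fallback is accurate to ~1e-13 relative,
  not exact; supports that large only arise for common variants in huge
  panels, where an exact test is the wrong tool anyway.
- iHS needs dense, phased, polarized haplotypes; the package takes the
  0-allele as ancestral and does not infer ancestral state or phase.
- XP-EHH, nSL and multi-chromosome orchestration are out of scope.
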