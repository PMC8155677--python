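"""EHH/iHH/iHS mechanics, Fst estimators, outlier flags, gene mapping."""

import numpy as np
import pytest

from popepi.selection import (
    EdgePolicy,
    Estimator,
    GeneInterval,
    HaplotypeMatrix,
    ehh,
    flag_outliers,
    fst_pair,
    haplotypes_to_genotypes,
    ihh,
    ihs_scan,
    ihs_unstandardized,
    map_to_genes,
    read_bed_genes,
    standardize_ihs,
)


def _matrix(rows, positions=None):
    h = np.asarray(rows, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, h.shape[1] + 1) * 1000
    return HaplotypeMatrix(haplotypes=h, positions_bp=np.asarray(positions))


# ---------------------------------------------------------------------------
# EHH


def test_ehh_at_core_is_one():
    h = _matrix([[1, 0], [1, 1], [0, 0], [0, 1]])
    assert ehh(h, 0, 1, 0) == 1.0
    assert ehh(h, 0, 0, 0) == 1.0


def test_ehh_two_identical_pairs_gives_one_third():
    # 4 carriers split into two identical pairs over core..x
    h = _matrix([
        [1, 0, 0],
        [1, 0, 0],
        [1, 1, 1],
        [1, 1, 1],
    ])
    assert ehh(h, 0, 1, 2) == pytest.approx((1 + 1) / 6)


def test_ehh_all_distinct_is_zero():
    h = _matrix([
        [1, 0, 0],
        [1, 0, 1],
        [1, 1, 0],
        [1, 1, 1],
    ])
    assert ehh(h, 0, 1, 2) == 0.0


def test_ehh_requires_two_carriers():
    h = _matrix([[1, 0], [0, 0], [0, 1], [0, 0]])
    with pytest.raises(ValueError):
        ehh(h, 0, 1, 1)


def test_ehh_non_increasing_outward():
    rng = np.random.default_rng(0)
    h = _matrix(rng.integers(0, 2, size=(20, 40)))
    core = 20
    for allele in (0, 1):
        left = [ehh(h, core, allele, x) for x in range(core, -1, -1)]
        right = [ehh(h, core, allele, x) for x in range(core, 40)]
        assert all(a >= b - 1e-12 for a, b in zip(left, left[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(right, right[1:]))


# ---------------------------------------------------------------------------
# iHH


def test_ihh_single_interval_trapezoid():
    # two core carriers identical at the core, distinct at the next right
    # site: EHH drops 1 -> 0 across a single 100 kb interval, so the right
    # side contributes the hand trapezoid 0.5 * 100 kb-units.
    h = _matrix(
        [
            [0, 1, 0, 0],
            [0, 1, 1, 0],
            [0, 0, 0, 0],
            [0, 0, 1, 1],
        ],
        positions=[1_000, 2_000, 102_000, 302_000],
    )
    res = ihh(h, 1, 1, cutoff=0.05)
    # left side: both carriers share allele 0 at site 0 (EHH stays 1 over
    # that 1 kb segment, then the edge is hit)
    assert res.area == pytest.approx(0.5 * 100 + 1.0)
    assert res.truncated_left and not res.truncated_right


def test_ihh_cutoff_one_gives_zero_area():
    h = _matrix([[1, 0, 0], [1, 0, 1], [0, 1, 0], [0, 1, 1]])
    res = ihh(h, 0, 1, cutoff=1.0)
    assert res.area == 0.0


def test_ihh_truncation_flagged_at_edge():
    # identical carriers to the chromosome end: EHH stays 1, never < cutoff
    h = _matrix([
        [1, 1, 1],
        [1, 1, 1],
        [0, 0, 1],
        [0, 1, 0],
    ])
    res = ihh(h, 0, 1, cutoff=0.05)
    assert res.truncated and res.truncated_right
    # left side of site 0 has no sites at all: also an edge
    assert res.truncated_left


def test_ihh_matches_direct_summation_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n_sites = 30
        h = _matrix(
            rng.integers(0, 2, size=(12, n_sites)),
            positions=np.cumsum(rng.integers(500, 5000, size=n_sites)),
        )
        core = 15
        for allele in (0, 1):
            if (h.haplotypes[:, core] == allele).sum() < 2:
                continue
            got = ihh(h, core, allele, cutoff=0.05)
            # oracle: EHH at every site via the standalone function + trapezoid
            dist = h.positions_bp / 1000.0
            area = 0.0
            for direction in (-1, 1):
                e_prev, d_prev = 1.0, dist[core]
                x = core + direction
                while 0 <= x < n_sites and e_prev > 0.05:
                    e = ehh(h, core, allele, x)
                    area += 0.5 * (e_prev + e) * abs(dist[x] - d_prev)
                    e_prev, d_prev = e, dist[x]
                    x += direction
            assert got.area == pytest.approx(area, rel=1e-12)


# ---------------------------------------------------------------------------
# iHS


def test_unihs_zero_for_mirror_image_structure():
    # ancestral and derived classes with identical internal haplotype trees
    block = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0], [1, 1, 1]], dtype=np.uint8)
    h = np.hstack([block, np.zeros((4, 1), np.uint8), block])
    h = np.vstack([h, h])
    core = 4
    h[:4, core] = 1
    h[4:, core] = 0
    # derived rows (0-3) and ancestral rows (4-7) carry identical flanks
    m = _matrix(h)
    site = ihs_unstandardized(m, core, maf_floor=0.0)
    assert site.defined
    assert site.unihs == pytest.approx(0.0, abs=1e-12)


def test_unihs_negative_when_derived_haplotypes_homogeneous():
    rng = np.random.default_rng(1)
    n_sites = 41
    core = 20
    anc = rng.integers(0, 2, size=(10, n_sites)).astype(np.uint8)
    der = np.tile(rng.integers(0, 2, size=(1, n_sites)), (10, 1)).astype(np.uint8)
    h = np.vstack([anc, der])
    h[:10, core] = 0
    h[10:, core] = 1
    m = _matrix(h)
    # identical derived haplotypes keep EHH at 1 to the chromosome edge, so
    # integrate to the edge rather than dropping the (synthetic) site
    site = ihs_unstandardized(m, core, maf_floor=0.0,
                              edge_policy=EdgePolicy.INTEGRATE_TO_EDGE)
    assert site.defined and site.unihs < 0


def test_allele_swap_negates_unihs():
    rng = np.random.default_rng(5)
    for _ in range(10):
        h = rng.integers(0, 2, size=(16, 31)).astype(np.uint8)
        m = _matrix(h)
        swapped = _matrix(1 - h)
        core = 15
        a = ihs_unstandardized(m, core, maf_floor=0.0)
        b = ihs_unstandardized(swapped, core, maf_floor=0.0)
        if a.defined and b.defined:
            assert a.unihs == pytest.approx(-b.unihs, rel=1e-12)


def test_monomorphic_core_raises():
    h = _matrix(np.zeros((4, 5), dtype=np.uint8))
    with pytest.raises(ValueError):
        ihs_unstandardized(h, 2)


# ---------------------------------------------------------------------------
# standardization


def test_standardize_single_bin_equals_global_zscore():
    rng = np.random.default_rng(2)
    u = rng.normal(size=200)
    d = rng.uniform(0.1, 0.9, size=200)
    std = standardize_ihs(u, d, n_bins=1, min_sites_per_bin=1)
    assert std == pytest.approx((u - u.mean()) / u.std())


def test_standardize_degenerate_bin_warns_and_yields_nan():
    u = np.array([1.0, 1.0, 1.0])
    d = np.array([0.5, 0.5, 0.5])
    with pytest.warns(UserWarning):
        std = standardize_ihs(u, d, n_bins=1, min_sites_per_bin=1)
    assert np.isnan(std).all()


def test_standardize_merges_sparse_bins():
    rng = np.random.default_rng(3)
    u = rng.normal(size=30)
    d = np.concatenate([np.full(29, 0.2), [0.9]])  # lone site in the 0.9 bin
    std = standardize_ihs(u, d, n_bins=10, min_sites_per_bin=5)
    assert np.isfinite(std).all()  # lone site merged, not dropped


def test_standardize_preserves_undefined_sites():
    u = np.array([0.5, np.nan, -0.5, 1.0, -1.0])
    d = np.full(5, 0.4)
    std = standardize_ihs(u, d, n_bins=1, min_sites_per_bin=1)
    assert np.isnan(std[1]) and np.isfinite(std[[0, 2, 3, 4]]).all()


# ---------------------------------------------------------------------------
# flag_outliers


def test_top_percent_flags_highest_site():
    rng = np.random.default_rng(4)
    s = rng.normal(size=100)
    top, gt2 = flag_outliers(s, pct=0.01, z=2.0)
    assert top.sum() == 1
    assert top[np.argmax(np.abs(s))]
    assert (gt2 == (np.abs(s) > 2.0)).all()


def test_all_equal_scores_all_flagged():
    s = np.full(50, 1.5)
    top, gt2 = flag_outliers(s)
    assert top.all()
    assert not gt2.any()


def test_flags_match_sort_oracle():
    rng = np.random.default_rng(6)
    s = rng.normal(size=503)
    s[rng.integers(0, 503, size=20)] = np.nan
    top, _ = flag_outliers(s, pct=0.05)
    absd = np.abs(s[np.isfinite(s)])
    thresh = np.quantile(absd, 0.95)
    expect = np.isfinite(s) & (np.abs(s) >= thresh)
    assert (top == expect).all()


# ---------------------------------------------------------------------------
# gene mapping


def test_no_flagged_sites_no_genes():
    genes = [GeneInterval("MVK", "1", 100, 200)]
    assert map_to_genes([], genes) == {}


def test_inclusive_boundaries():
    genes = [GeneInterval("NOD2", "1", 100, 200)]
    assert map_to_genes([100], genes) == {"NOD2": 1}
    assert map_to_genes([200], genes) == {"NOD2": 1}
    assert map_to_genes([99], genes) == {}
    assert map_to_genes([201], genes) == {}


def test_mapping_matches_brute_force():
    rng = np.random.default_rng(8)
    genes = []
    for i in range(30):
        start = int(rng.integers(1, 10_000))
        genes.append(GeneInterval(f"G{i}", "1", start, start + int(rng.integers(0, 500))))
    sites = rng.integers(1, 10_500, size=200)
    got = map_to_genes(sites, genes, chrom="1")
    expect = {}
    for g in genes:
        n = sum(1 for p in sites if g.start <= p <= g.end)
        if n:
            expect[g.gene] = n
    assert got == expect


def test_malformed_interval_rejected():
    with pytest.raises(ValueError):
        GeneInterval("X", "1", 10, 5)


def test_bed_read_converts_to_one_based_inclusive(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("1\t99\t200\tNOD2\n2\t0\t50\tMVK\n")
    genes = read_bed_genes(bed)
    assert genes[0] == GeneInterval("NOD2", "1", 100, 200)
    assert genes[1] == GeneInterval("MVK", "2", 1, 50)


# ---------------------------------------------------------------------------
# Fst


def _geno_from_freqs(p, n, rng):
    return rng.binomial(2, p, size=n).reshape(n, 1).astype(np.int8)


def test_wright_fst_zero_for_identical_frequencies():
    g = np.array([[0], [1], [2], [1]], dtype=np.int8)
    fst = fst_pair(g, g.copy(), Estimator.WRIGHT)
    assert fst[0] == pytest.approx(0.0)


def test_wright_fst_one_for_fixed_difference():
    g1 = np.zeros((5, 1), dtype=np.int8)
    g2 = np.full((5, 1), 2, dtype=np.int8)
    fst = fst_pair(g1, g2, Estimator.WRIGHT)
    assert fst[0] == pytest.approx(1.0)


def test_wright_fst_hand_value_for_02_08():
    # p1=0.2, p2=0.8 equal sizes: H_T = 2*0.5*0.5 = 0.5,
    # H_S = (0.32+0.32)/2 = 0.32, so Fst = (0.5-0.32)/0.5 = 0.36
    g1 = np.array([[1], [1], [1], [1], [0], [0], [0], [0], [0], [0]], dtype=np.int8)
    g2 = np.array([[1], [1], [1], [1], [2], [2], [2], [2], [2], [2]], dtype=np.int8)
    assert np.mean(g1) / 2 == pytest.approx(0.2)
    assert np.mean(g2) / 2 == pytest.approx(0.8)
    fst = fst_pair(g1, g2, Estimator.WRIGHT)
    assert fst[0] == pytest.approx(0.36)


def _wc_oracle(g1, g2):
    """Direct transcription of the 1984 two-population variance-component
    estimator, scalar per site, coded independently of the vectorized path."""
    out = []
    for j in range(g1.shape[1]):
        x1 = g1[:, j][g1[:, j] >= 0]
        x2 = g2[:, j][g2[:, j] >= 0]
        n1, n2 = len(x1), len(x2)
        r = 2
        p1, p2 = x1.sum() / (2 * n1), x2.sum() / (2 * n2)
        h1, h2 = np.mean(x1 == 1), np.mean(x2 == 1)
        n_bar = (n1 + n2) / r
        n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
        if p_bar <= 0 or p_bar >= 1:
            out.append(np.nan)
            continue
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        a = (n_bar / n_c) * (
            s2 - 1 / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        out.append(a / (a + b + c) if (a + b + c) != 0 else np.nan)
    return np.array(out)


def test_wc_matches_variance_component_oracle():
    rng = np.random.default_rng(11)
    n_sites = 1000
    p1 = rng.uniform(0.02, 0.98, size=n_sites)
    p2 = rng.uniform(0.02, 0.98, size=n_sites)
    g1 = rng.binomial(2, p1, size=(60, n_sites)).astype(np.int8)
    g2 = rng.binomial(2, p2, size=(40, n_sites)).astype(np.int8)
    got = fst_pair(g1, g2, Estimator.WC)
    want = _wc_oracle(g1, g2)
    both = np.isfinite(got) & np.isfinite(want)
    assert (np.isfinite(got) == np.isfinite(want)).all()
    assert np.abs(got[both] - want[both]).max() < 1e-10


def test_wc_and_wright_agree_at_large_equal_samples():
    rng = np.random.default_rng(12)
    p = rng.uniform(0.2, 0.8, size=300)
    shift = rng.uniform(-0.1, 0.1, size=300)
    g1 = rng.binomial(2, p, size=(150, 300)).astype(np.int8)
    g2 = rng.binomial(2, np.clip(p + shift, 0.05, 0.95), size=(150, 300)).astype(np.int8)
    wc = fst_pair(g1, g2, Estimator.WC)
    wright = fst_pair(g1, g2, Estimator.WRIGHT)
    both = np.isfinite(wc) & np.isfinite(wright)
    assert np.abs(wc[both] - wright[both]).max() < 0.05


def test_wright_fst_bounded():
    rng = np.random.default_rng(13)
    g1 = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
    g2 = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
    fst = fst_pair(g1, g2, Estimator.WRIGHT)
    ok = np.isfinite(fst)
    assert (fst[ok] >= 0).all() and (fst[ok] <= 1).all()


def test_haplotype_pairing_helper():
    hap = np.array([[1, 0], [1, 1], [0, 0], [0, 1], [1, 1]], dtype=np.uint8)
    g = haplotypes_to_genotypes(hap)
    assert g.shape == (2, 2)
    assert (g == np.array([[2, 1], [0, 1]])).all()
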