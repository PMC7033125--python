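"""Closed-form population statistics and their simulation-based contrasts."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from syntenypop.popstats import (
    SnpMatrix,
    co_enrichment_from_counts,
    co_enrichment_test,
    deleterious_contrast,
    haplotype_diversity,
    ld_hot_contrast,
    ld_r2,
    maf_by_region_class,
    mean_pairwise_r2,
    nucleotide_diversity,
    rank_sum_test,
)
from syntenypop.regions import RegionSet
from syntenypop.simpop import (
    simulate_block_genotypes,
    simulate_deleterious_flags,
)


def snps_from(positions, genotypes, chrom="Chr1", samples=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(genotypes.shape[1])]
    return SnpMatrix(chrom, positions, genotypes, samples)


# -- nucleotide diversity ------------------------------------------------------


def test_monomorphic_window_zero():
    snps = snps_from([10, 20], np.zeros((2, 8)))
    prof = nucleotide_diversity(snps, windows=[(0, 100)])
    assert prof.data["value"].tolist() == [0.0]


def test_balanced_split_closed_form():
    gt = np.array([[0, 0, 0, 0, 1, 1, 1, 1]])
    snps = snps_from([50], gt)
    prof = nucleotide_diversity(snps, windows=[(0, 100)])
    assert prof.data["value"].iloc[0] == pytest.approx(32 / 56)
    per_bp = nucleotide_diversity(snps, windows=[(0, 100)], per_bp=True)
    assert per_bp.data["value"].iloc[0] == pytest.approx(32 / 56 / 100)


def test_singleton_sites_each_contribute_quarter():
    gt = np.eye(8, dtype=np.int8)[:4]  # 4 singleton sites over 8 accessions
    snps = snps_from([10, 20, 30, 40], gt)
    prof = nucleotide_diversity(snps, windows=[(0, 100)])
    assert prof.data["value"].iloc[0] == pytest.approx(2 * 7 / 56)
    assert prof.data["n_sites"].iloc[0] == 4


def test_diversity_invariant_to_allele_swap_and_sample_order():
    rng = np.random.default_rng(0)
    gt = (rng.random((20, 8)) < 0.4).astype(np.int8)
    pos = np.arange(20) * 10
    base = nucleotide_diversity(snps_from(pos, gt), windows=[(0, 200)])
    swapped = nucleotide_diversity(snps_from(pos, 1 - gt), windows=[(0, 200)])
    shuffled = nucleotide_diversity(
        snps_from(pos, gt[:, ::-1]), windows=[(0, 200)]
    )
    assert base.data["value"].iloc[0] == pytest.approx(swapped.data["value"].iloc[0])
    assert base.data["value"].iloc[0] == pytest.approx(shuffled.data["value"].iloc[0])


# -- haplotype diversity -------------------------------------------------------


def test_haplotype_diversity_closed_forms():
    pos = [10, 20, 30]
    identical = np.zeros((3, 8), dtype=np.int8)
    prof = haplotype_diversity(snps_from(pos, identical), windows=[(0, 100)])
    assert prof.data["value"].iloc[0] == 0.0

    distinct = np.array(
        [[int(b) for b in format(i, "03b")] for i in range(8)]
    ).T  # 3 sites giving 8 distinct haplotypes
    prof2 = haplotype_diversity(snps_from(pos, distinct), windows=[(0, 100)])
    assert prof2.data["value"].iloc[0] == pytest.approx(1.0)

    two_classes = np.array([[0, 0, 0, 0, 1, 1, 1, 1]])
    prof3 = haplotype_diversity(snps_from([10], two_classes), windows=[(0, 100)])
    assert prof3.data["value"].iloc[0] == pytest.approx(4 / 7)


def test_haplotype_diversity_flags_all_missing_window():
    gt = np.full((2, 4), -1, dtype=np.int8)
    gt[:, 0] = 0  # only one complete accession
    prof = haplotype_diversity(snps_from([10, 20], gt), windows=[(0, 100)])
    assert math.isnan(prof.data["value"].iloc[0])


# -- LD ------------------------------------------------------------------------


def test_r2_identical_orthogonal_complementary():
    a = np.array([0, 0, 1, 1, 0, 0, 1, 1])
    b = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)
    assert ld_r2(a, 1 - a) == pytest.approx(1.0)  # sign invariance


def test_r2_equals_d_squared_normalization():
    """r^2 matches D^2 / (pA pa pB pb) on complete-data toy vectors."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = (rng.random(12) < 0.5).astype(int)
        b = (rng.random(12) < 0.5).astype(int)
        if a.std() == 0 or b.std() == 0:
            continue
        pa, pb = a.mean(), b.mean()
        d = (a & b).mean() - pa * pb
        expected = d * d / (pa * (1 - pa) * pb * (1 - pb))
        assert ld_r2(a, b) == pytest.approx(expected, rel=1e-10)


def test_r2_monomorphic_after_missing_intersection_flagged():
    a = np.array([0, 1, 1, -1])
    b = np.array([-1, 1, 1, 0])  # joint non-missing: a constant at sites 1,2
    assert math.isnan(ld_r2(a, b))


def test_ld_contrast_suppressed_recombination_inside_hotspots():
    """Markers copying a block partition inside regions, independent
    outside: within-region LD exceeds across-border LD and the pooled
    one-sided test rejects."""
    n_acc = 32
    regions = []
    positions = np.arange(0, 200_000, 250)
    blocks = [(s, s + 6000) for s in range(10_000, 200_000, 20_000)]
    gts = simulate_block_genotypes(n_acc, positions, blocks, seed=9)
    snps = snps_from(positions, gts, samples=[f"s{i}" for i in range(n_acc)])
    hot = RegionSet.from_rows(
        [("Chr1", s, e, "HOT", 1.0, 1.0) for s, e in blocks]
    )
    df, res = ld_hot_contrast(snps, hot)
    ok = df.dropna(subset=["within_r2", "across_r2"])
    assert (ok["within_r2"] > ok["across_r2"]).mean() > 0.8
    assert res.pvalue < 0.001


def test_ld_contrast_single_block_everywhere_non_significant():
    n_acc = 16
    positions = np.arange(0, 30_000, 500)
    gts = simulate_block_genotypes(
        n_acc, positions, [(0, 30_000)], switch_prob=0.0, seed=1
    )
    snps = snps_from(positions, gts, samples=[f"s{i}" for i in range(n_acc)])
    hot = RegionSet.from_rows([("Chr1", 10_000, 20_000, "HOT", 1.0, 1.0)])
    df, res = ld_hot_contrast(snps, hot)
    assert df["within_r2"].iloc[0] == pytest.approx(1.0)
    assert df["across_r2"].iloc[0] == pytest.approx(1.0)
    assert res.pvalue > 0.05


def test_ld_near_zero_when_markers_shuffled_independently():
    rng = np.random.default_rng(7)
    n_acc = 64
    positions = np.arange(0, 20_000, 200)
    gts = (rng.random((len(positions), n_acc)) < 0.5).astype(np.int8)
    snps = snps_from(positions, gts, samples=[f"s{i}" for i in range(n_acc)])
    hot = RegionSet.from_rows([("Chr1", 8000, 12_000, "HOT", 1.0, 1.0)])
    df, _ = ld_hot_contrast(snps, hot)
    assert df["within_r2"].iloc[0] < 0.1
    assert df["across_r2"].iloc[0] < 0.1


def test_ld_contrast_errors_without_usable_regions():
    snps = snps_from([10], np.array([[0, 1, 0, 1]]))
    hot = RegionSet.from_rows([("Chr1", 5000, 6000, "HOT", 1.0, 1.0)])
    with pytest.raises(ValueError):
        ld_hot_contrast(snps, hot)


# -- MAF by region class -------------------------------------------------------


def maf_snps():
    # 8 accessions; derived counts 1..4 give MAF 0.125..0.5
    rows = []
    positions = []
    for i, k in enumerate([1, 2, 3, 4, 2, 2]):
        row = np.zeros(8, dtype=np.int8)
        row[:k] = 1
        rows.append(row)
        positions.append(100 + i * 100)
    return snps_from(positions, np.array(rows))


def test_maf_assignment_and_medians():
    snps = maf_snps()
    classes = RegionSet.from_rows(
        [
            ("Chr1", 0, 350, "HOT", 1.0, 1.0),
            ("Chr1", 350, 600, "SYN", 0.0, 0.0),
        ]
    )
    df, med = maf_by_region_class(snps, classes)
    assert df["label"].tolist() == ["HOT", "HOT", "HOT", "SYN", "SYN", "unclassified"]
    assert med["HOT"] == pytest.approx(0.25)


def test_maf_filter_boundary_strict():
    n = 1000
    row_at = np.zeros(n, dtype=np.int8)
    row_at[:5] = 1  # MAF exactly 0.005
    row_above = np.zeros(n, dtype=np.int8)
    row_above[:6] = 1  # MAF 0.006
    snps = snps_from([10, 20], np.array([row_at, row_above]),
                     samples=[f"s{i}" for i in range(n)])
    classes = RegionSet.from_rows([("Chr1", 0, 100, "SYN", 0.0, 0.0)])
    df, _ = maf_by_region_class(snps, classes, maf_gt=0.005)
    assert df["pos"].tolist() == [20]


def test_hotspot_singleton_excess_lowers_hot_median(hot_pop):
    """Simulated hotspot SNPs are singleton-biased, so the HOT-class MAF
    median falls below the collinear-class median."""
    from syntenypop.regions import classify_windows
    from syntenypop.syndiv import sliding_profile

    masks = hot_pop.mask_set()
    classes = classify_windows(sliding_profile(masks))
    snps = SnpMatrix(
        "Chr1",
        hot_pop.snp_frame_positions("acc1"),
        hot_pop.observed_genotypes,
        list(hot_pop.accessions),
    )
    _, med = maf_by_region_class(snps, classes)
    assert med["HOT"] < med["SYN"]


# -- crossover enrichment ------------------------------------------------------


def test_worked_chi_square_example_rejects_depletion():
    res = co_enrichment_from_counts(15_683, 64, 0.24)
    assert res.expected == pytest.approx(15_683 * 0.24)
    assert res.observed < res.expected
    assert res.pvalue < 0.001


def test_chi_square_equality_gives_zero_statistic_p_one():
    res = co_enrichment_from_counts(1000, 250, 0.25)
    assert res.chi2 == pytest.approx(0.0)
    assert res.pvalue == 1.0


def test_chi_square_maximal_depletion():
    res = co_enrichment_from_counts(1000, 0, 0.24)
    expected_chi2 = 240**2 / 240 + 240**2 / 760
    assert res.chi2 == pytest.approx(expected_chi2)
    assert res.pvalue < 1e-10


def test_chi_square_excess_direction_large_p():
    res = co_enrichment_from_counts(1000, 400, 0.25)
    assert res.pvalue > 0.999


def test_co_overlap_counting_against_mask():
    syn = {"Chr1": np.ones(10_000, dtype=bool)}
    syn["Chr1"][4000:6000] = False
    cos = [
        ("Chr1", 100, 600),      # fully syntenic
        ("Chr1", 3900, 4100),    # partially overlaps non-syntenic
        ("Chr1", 4500, 5000),    # inside non-syntenic
        ("Chr1", 100, 600),      # duplicate: dropped
        ("Chr1", 0, 9000),       # too long: dropped
    ]
    res = co_enrichment_test(cos, syn)
    assert res.n_total == 3
    assert res.observed == 2
    assert res.nonsyn_fraction == pytest.approx(0.2)


def test_simulated_crossovers_depleted_in_rearranged_regions(hot_pop):
    """Simulated crossovers are placed only in collinear sequence, so the
    depletion test rejects strongly."""
    masks = hot_pop.mask_set()
    syn = {
        c: np.logical_and.reduce([masks.mask(a, b)[c] for a, b in masks.pairs()])
        for c in masks.chrom_lengths
    }
    res = co_enrichment_test(hot_pop.crossovers_frame("acc1"), syn)
    assert res.observed < res.expected
    assert res.pvalue < 0.001


# -- deleterious contrast ------------------------------------------------------


def contrast_classes(n_per_class=200, size=1000):
    rows = []
    pos = 0
    for i in range(n_per_class):
        rows.append(("Chr1", pos, pos + size, "HOT", 1.0, 1.0))
        pos += 2 * size
        rows.append(("Chr1", pos, pos + size, "SYN", 0.0, 0.0))
        pos += 2 * size
    return RegionSet.from_rows(rows)


def variants_in(classes, per_region=20, seed=0):
    rng = np.random.default_rng(seed)
    chroms, pos = [], []
    for row in classes.data.itertuples(index=False):
        p = rng.integers(row.start, row.end, size=per_region)
        pos.extend(sorted(p))
        chroms.extend([row.chrom] * per_region)
    return np.array(chroms), np.array(pos)


def test_equal_rates_non_significant():
    classes = contrast_classes(50)
    chroms, pos = variants_in(classes)
    rng = np.random.default_rng(1)
    flags = rng.random(len(pos)) < 0.1
    df, res = deleterious_contrast(
        pd.DataFrame({"chrom": chroms, "pos": pos, "deleterious": flags}), classes
    )
    assert res.pvalue > 0.01


def test_planted_threefold_rate_detected():
    classes = contrast_classes(200)
    chroms, pos = variants_in(classes)
    flags = simulate_deleterious_flags(
        chroms, pos, classes, base_rate=0.05, hot_multiplier=3.0, seed=2
    )
    df, res = deleterious_contrast(
        pd.DataFrame({"chrom": chroms, "pos": pos, "deleterious": flags}), classes
    )
    hot_mean = df[df["label"] == "HOT"]["burden"].mean()
    syn_mean = df[df["label"] == "SYN"]["burden"].mean()
    assert hot_mean > syn_mean
    assert res.pvalue < 0.001


def test_empty_hot_class_is_error():
    classes = RegionSet.from_rows(
        [("Chr1", 0, 1000, "HOT", 1, 1), ("Chr1", 2000, 3000, "SYN", 0, 0)]
    )
    variants = pd.DataFrame(
        {"chrom": ["Chr1"] * 3, "pos": [2100, 2200, 2300], "deleterious": [True] * 3}
    )
    with pytest.raises(ValueError):
        deleterious_contrast(variants, classes)


# -- rank-sum oracle -----------------------------------------------------------


def exhaustive_rank_sum_p(x, y, alternative="greater"):
    """Enumerate all group assignments of the pooled sample and count
    rank-sums as or more extreme than observed."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n1].sum()
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(idx)].sum()
        if alternative == "greater":
            count += s >= obs - 1e-12
        else:
            count += s <= obs + 1e-12
        total += 1
    return count / total


@pytest.mark.parametrize(
    "x, y, alternative",
    [
        ([5.2, 6.1, 7.9, 8.3], [1.1, 2.0, 3.5, 4.2], "greater"),
        ([1.5, 2.5, 9.0], [3.0, 4.0, 5.0, 6.0], "less"),
        ([10, 20, 30, 40, 50], [15, 25, 35], "greater"),
    ],
)
def test_rank_sum_matches_exhaustive_permutation(x, y, alternative):
    res = rank_sum_test(x, y, alternative)
    assert res.pvalue == pytest.approx(
        exhaustive_rank_sum_p(np.array(x, float), np.array(y, float), alternative)
    )


# -- VCF ingestion -------------------------------------------------------------


def test_vcf_round_trip_and_het_handling(tmp_path, small_pop):
    p = tmp_path / "s.vcf"
    small_pop.write_vcf(p)
    by_chrom = SnpMatrix.from_vcf(p)
    snps = by_chrom["Chr1"]
    assert snps.samples == list(small_pop.accessions)
    np.testing.assert_array_equal(
        snps.positions, small_pop.snp_frame_positions("acc1")
    )
    np.testing.assert_array_equal(snps.genotypes, small_pop.observed_genotypes)
    # diploid het record becomes missing
    q = tmp_path / "het.vcf"
    q.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=Chr1,length=100>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
        "Chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n"
    )
    het = SnpMatrix.from_vcf(q)["Chr1"]
    assert het.genotypes.tolist() == [[-1, 1]]


def test_filter_sites_inclusive_vs_strict():
    gt = np.zeros((2, 20), dtype=np.int8)
    gt[0, :1] = 1  # MAF 0.05
    gt[1, :2] = 1  # MAF 0.10
    snps = snps_from([10, 20], gt, samples=[f"s{i}" for i in range(20)])
    assert len(snps.filter_sites(maf_ge=0.05)) == 2
    assert len(snps.filter_sites(maf_gt=0.05)) == 1
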