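"""Population-genetic statistics around rearrangement hotspots.

Genotypes are haploid-coded (inbred accessions); heterozygous calls in
input VCFs are treated as missing. Implements windowed nucleotide and
haplotype diversity, pairwise LD (r^2), the LD contrast within / across
hotspot borders (one-sided Mann-Whitney U), minor-allele-frequency
spectra by region class, the crossover-vs-synteny chi-square enrichment
test, and the deleterious-variant contrast between hotspot and syntenic
regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionSet
from .syndiv import WindowProfile, make_windows

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    n1: int
    n2: int
    alternative: str


# -- genotype container -------------------------------------------------------

class SnpMatrix:
    """Haploid SNP genotypes on one chromosome.

    genotypes: (sites x accessions) int8 with 0 ancestral/reference,
    1 derived/alternate, -1 missing. Positions strictly increasing.
    """

    def __init__(self, chrom: str, positions, genotypes, samples: Sequence[str]):
        self.chrom = chrom
        self.positions = np.asarray(positions, dtype=np.int64)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.samples = list(samples)
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if len(self.positions) > 1 and (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def missing_rate(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=1)

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency among non-missing calls (in [0, 0.5])."""
        called = self.genotypes >= 0
        n = called.sum(axis=1)
        alt = (self.genotypes == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        return np.minimum(p, 1.0 - p)

    def filter_sites(
        self,
        maf_gt: float | None = None,
        maf_ge: float | None = None,
        missing_lt: float | None = None,
    ) -> "SnpMatrix":
        """Subset sites by MAF (strict > or inclusive >=) and missing rate (<)."""
        keep = np.ones(len(self), dtype=bool)
        if maf_gt is not None:
            keep &= self.maf > maf_gt
        if maf_ge is not None:
            keep &= self.maf >= maf_ge
        if missing_lt is not None:
            keep &= self.missing_rate < missing_lt
        return SnpMatrix(
            self.chrom, self.positions[keep], self.genotypes[keep], self.samples
        )

    def sites_in(self, start: int, end: int) -> np.ndarray:
        return np.flatnonzero((self.positions >= start) & (self.positions < end))

    @classmethod
    def from_vcf(cls, path) -> dict[str, "SnpMatrix"]:
        from .synio import read_vcf

        chroms, positions, gts, samples, n_het = read_vcf(path)
        if n_het:
            logger.info("treated %d heterozygous calls as missing", n_het)
        out = {}
        for chrom in dict.fromkeys(chroms):
            sel = chroms == chrom
            out[chrom] = cls(chrom, positions[sel], gts[sel], samples)
        return out


# -- diversity ----------------------------------------------------------------

def _site_pi(genotypes: np.ndarray) -> np.ndarray:
    """Unbiased per-site nucleotide diversity 2 j (n - j) / (n (n - 1))."""
    called = genotypes >= 0
    n = called.sum(axis=1)
    j = (genotypes == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * j * (n - j) / (n * np.maximum(n - 1, 1)), 0.0)
    return pi


def _resolve_windows(snps, windows, window_size, step, length):
    if windows is not None:
        win = np.asarray(windows, dtype=np.int64).reshape(-1, 2)
    else:
        if length is None:
            length = int(snps.positions[-1]) + 1 if len(snps) else window_size
        win = make_windows(length, window_size, step)
    return win


def nucleotide_diversity(
    snps: SnpMatrix,
    windows=None,
    window_size: int = 5000,
    step: int = 1000,
    length: int | None = None,
    per_bp: bool = False,
) -> WindowProfile:
    """Windowed nucleotide diversity.

    Per-site mode (default) averages per-site values over the sites in
    each window; per-bp mode sums them and divides by window length.
    Windows without usable sites report 0 with n_sites = 0.
    """
    win = _resolve_windows(snps, windows, window_size, step, length)
    site_pi = _site_pi(snps.genotypes)
    values, counts = [], []
    for s, e in win:
        idx = snps.sites_in(s, e)
        idx = idx[(snps.genotypes[idx] >= 0).sum(axis=1) >= 2] if len(idx) else idx
        if len(idx) == 0:
            values.append(0.0)
            counts.append(0)
            continue
        total = float(site_pi[idx].sum())
        values.append(total / (e - s) if per_bp else total / len(idx))
        counts.append(len(idx))
    data = pd.DataFrame(
        {
            "chrom": snps.chrom,
            "start": win[:, 0],
            "end": win[:, 1],
            "value": values,
            "n_sites": counts,
        }
    )
    wsize = int(win[0, 1] - win[0, 0]) if windows is not None else window_size
    return WindowProfile(data, wsize, step, name="pi")


def haplotype_diversity(
    snps: SnpMatrix,
    windows=None,
    window_size: int = 5000,
    step: int = 1000,
    length: int | None = None,
) -> WindowProfile:
    """Windowed haplotype diversity (n / (n - 1)) (1 - sum p_h^2).

    Haplotype strings are formed from accessions without missing calls
    in the window; windows where fewer than two accessions are complete
    are flagged missing (NaN). Windows without sites have a single
    shared (empty) haplotype and report 0.
    """
    win = _resolve_windows(snps, windows, window_size, step, length)
    values, counts = [], []
    for s, e in win:
        idx = snps.sites_in(s, e)
        if len(idx) == 0:
            values.append(0.0)
            counts.append(0)
            continue
        block = snps.genotypes[idx]
        complete = (block >= 0).all(axis=0)
        k = int(complete.sum())
        if k < 2:
            values.append(np.nan)
            counts.append(len(idx))
            continue
        haps = block[:, complete].T
        _, freq = np.unique(haps, axis=0, return_counts=True)
        p = freq / k
        values.append((k / (k - 1)) * (1.0 - float((p**2).sum())))
        counts.append(len(idx))
    data = pd.DataFrame(
        {
            "chrom": snps.chrom,
            "start": win[:, 0],
            "end": win[:, 1],
            "value": values,
            "n_sites": counts,
        }
    )
    wsize = int(win[0, 1] - win[0, 0]) if windows is not None else window_size
    return WindowProfile(data, wsize, step, name="haplotype_diversity")


# -- linkage disequilibrium ---------------------------------------------------

def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two haploid genotype vectors over
    jointly non-missing accessions; NaN if either site is monomorphic
    after the missing-data intersection."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 >= 0) & (g2 >= 0)
    a, b = g1[ok], g2[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def mean_pairwise_r2(genotypes: np.ndarray) -> float:
    """Mean r^2 over all site pairs of a (sites x accessions) block."""
    m = genotypes.shape[0]
    if m < 2:
        return float("nan")
    vals = [
        ld_r2(genotypes[i], genotypes[j])
        for i in range(m)
        for j in range(i + 1, m)
    ]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _cross_border_r2(snps: SnpMatrix, border: int, half: int) -> float:
    """Mean r^2 of marker pairs straddling a border, within a window of
    2*half bp centered on it."""
    left = snps.sites_in(border - half, border)
    right = snps.sites_in(border, border + half)
    if len(left) == 0 or len(right) == 0:
        return float("nan")
    vals = [
        ld_r2(snps.genotypes[i], snps.genotypes[j]) for i in left for j in right
    ]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def ld_hot_contrast(
    snps: SnpMatrix,
    hot: RegionSet,
    flank: int = 4000,
    min_markers: int = 2,
) -> tuple[pd.DataFrame, TestResult]:
    """LD in 4-kb windows in and around each hotspot region.

    Per region: mean pairwise r^2 of markers within the region
    (``within``), within the two flanking windows (``flank``), and of
    pairs straddling each border within a window centered on it
    (``across``). Regions lacking usable markers in a category are
    excluded (and counted via NaN rows). The pooled one-sided
    Mann-Whitney U test asks whether across-border LD is lower than
    within-region LD.
    """
    rows = []
    for row in hot.data.itertuples(index=False):
        if row.chrom != snps.chrom:
            continue
        inside = snps.sites_in(row.start, row.end)
        within = (
            mean_pairwise_r2(snps.genotypes[inside])
            if len(inside) >= min_markers
            else float("nan")
        )
        flank_vals = []
        for fs, fe in ((row.start - flank, row.start), (row.end, row.end + flank)):
            idx = snps.sites_in(max(fs, 0), fe)
            if len(idx) >= min_markers:
                flank_vals.append(mean_pairwise_r2(snps.genotypes[idx]))
        flank_r2 = float(np.nanmean(flank_vals)) if flank_vals else float("nan")
        across_vals = [
            _cross_border_r2(snps, b, flank // 2) for b in (row.start, row.end)
        ]
        across_vals = [v for v in across_vals if not np.isnan(v)]
        across = float(np.mean(across_vals)) if across_vals else float("nan")
        rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "within_r2": within,
                "flank_r2": flank_r2,
                "across_r2": across,
                "n_markers": len(inside),
            }
        )
    df = pd.DataFrame(rows)
    usable = df.dropna(subset=["within_r2", "across_r2"]) if len(df) else df
    if len(usable) == 0:
        raise ValueError("no hotspot region with sufficient markers for LD contrast")
    if usable["across_r2"].nunique() <= 1 and usable["within_r2"].nunique() <= 1 and (
        usable["across_r2"] == usable["within_r2"]
    ).all():
        # degenerate all-equal case: no evidence either way
        test = TestResult(float("nan"), 1.0, len(usable), len(usable), "across < within")
        return df, test
    stat, p = stats.mannwhitneyu(
        usable["across_r2"], usable["within_r2"], alternative="less"
    )
    return df, TestResult(float(stat), float(p), len(usable), len(usable), "across < within")


# -- MAF spectra by region class ----------------------------------------------

def maf_by_region_class(
    snps: SnpMatrix,
    classes: RegionSet,
    maf_gt: float = 0.005,
    missing_lt: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assign filtered markers to region classes and summarize MAF.

    Filters are strict: MAF > maf_gt, missing rate < missing_lt.
    Markers outside every class are labelled 'unclassified'.
    """
    filtered = snps.filter_sites(maf_gt=maf_gt, missing_lt=missing_lt)
    labels = np.full(len(filtered), "unclassified", dtype=object)
    sub = classes.data[classes.data["chrom"] == filtered.chrom]
    for row in sub.itertuples(index=False):
        idx = filtered.sites_in(row.start, row.end)
        labels[idx] = row.label
    df = pd.DataFrame(
        {"pos": filtered.positions, "maf": filtered.maf, "label": labels}
    )
    medians = df.groupby("label")["maf"].median().to_dict()
    return df, medians


# -- crossover enrichment -----------------------------------------------------

@dataclass
class CoEnrichmentResult:
    observed: int
    expected: float
    n_total: int
    nonsyn_fraction: float
    chi2: float
    pvalue: float  # one-sided, alternative: crossovers depleted in non-syntenic


def co_enrichment_from_counts(
    n_total: int, observed_nonsyn: int, nonsyn_fraction: float
) -> CoEnrichmentResult:
    """One-sided chi-square for crossover depletion in non-syntenic regions.

    Expected counts follow the genomic span fraction; the 1-df statistic
    compares (non-syntenic, syntenic) counts against expectation. The
    one-sided p is half the two-sided tail when observed < expected,
    1 - half-tail when observed > expected, and 1.0 at exact equality
    (no evidence for the depletion alternative).
    """
    if not (0.0 < nonsyn_fraction < 1.0):
        raise ValueError("non-syntenic fraction must be in (0, 1)")
    exp_non = n_total * nonsyn_fraction
    exp_syn = n_total - exp_non
    if exp_non < 5 or exp_syn < 5:
        logger.warning(
            "expected count below 5 (%.2f / %.2f); chi-square approximation is questionable",
            exp_non,
            exp_syn,
        )
    obs_syn = n_total - observed_nonsyn
    chi2 = (observed_nonsyn - exp_non) ** 2 / exp_non + (obs_syn - exp_syn) ** 2 / exp_syn
    tail = float(stats.chi2.sf(chi2, df=1))
    if observed_nonsyn == exp_non:
        p = 1.0
    elif observed_nonsyn < exp_non:
        p = tail / 2.0
    else:
        p = 1.0 - tail / 2.0
    return CoEnrichmentResult(
        int(observed_nonsyn), float(exp_non), int(n_total), float(nonsyn_fraction),
        float(chi2), float(p),
    )


def co_enrichment_test(
    crossovers: Sequence[tuple[str, int, int]],
    syn_mask: Mapping[str, np.ndarray],
    max_interval: int = 5000,
    unique_only: bool = True,
) -> CoEnrichmentResult:
    """Crossover-overlap test against a genome-wide syntenic mask.

    Only unique crossover intervals shorter than ``max_interval`` are
    used; an interval counts as overlapping the non-syntenic space if it
    intersects at least one non-syntenic base. The genomic non-syntenic
    fraction of the mask sets the expectation.
    """
    cos = [c for c in crossovers if c[2] - c[1] < max_interval]
    if unique_only:
        cos = list(dict.fromkeys(cos))
    if not cos:
        raise ValueError("no usable crossover intervals after filtering")
    total_len = sum(len(m) for m in syn_mask.values())
    nonsyn_len = sum(int((~np.asarray(m, dtype=bool)).sum()) for m in syn_mask.values())
    frac = nonsyn_len / total_len
    observed = 0
    for chrom, s, e in cos:
        m = syn_mask[chrom]
        if not m[s:e].all():
            observed += 1
    return co_enrichment_from_counts(len(cos), observed, frac)


# -- deleterious-variant contrast ---------------------------------------------

def deleterious_contrast(
    variants: pd.DataFrame,
    classes: RegionSet,
    hot_label: str = "HOT",
    syn_label: str = "SYN",
    mode: str = "fraction",
) -> tuple[pd.DataFrame, TestResult]:
    """Per-region deleterious burden and one-sided rank-sum contrast.

    ``variants`` needs columns chrom, pos, deleterious (bool); the flag
    is produced upstream by a variant-effect annotator. Burden per
    region is the deleterious fraction of its variants (``fraction``) or
    deleterious variants per kb (``per_kb``). Regions without variants
    are excluded with a warning. The Mann-Whitney U alternative is
    hotspot burden > syntenic burden.
    """
    if mode not in ("fraction", "per_kb"):
        raise ValueError("mode must be 'fraction' or 'per_kb'")
    rows = []
    skipped = 0
    for row in classes.data.itertuples(index=False):
        if row.label not in (hot_label, syn_label):
            continue
        sel = variants[
            (variants["chrom"] == row.chrom)
            & (variants["pos"] >= row.start)
            & (variants["pos"] < row.end)
        ]
        if len(sel) == 0:
            skipped += 1
            continue
        n_del = int(sel["deleterious"].sum())
        burden = (
            n_del / len(sel)
            if mode == "fraction"
            else 1000.0 * n_del / (row.end - row.start)
        )
        rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "label": row.label,
                "n_variants": len(sel),
                "n_deleterious": n_del,
                "burden": burden,
            }
        )
    if skipped:
        logger.warning("excluded %d regions without variants", skipped)
    df = pd.DataFrame(rows)
    hot_vals = df[df["label"] == hot_label]["burden"] if len(df) else pd.Series(dtype=float)
    syn_vals = df[df["label"] == syn_label]["burden"] if len(df) else pd.Series(dtype=float)
    if len(hot_vals) == 0 or len(syn_vals) == 0:
        raise ValueError("a class has no regions with variants; cannot test")
    stat, p = stats.mannwhitneyu(hot_vals, syn_vals, alternative="greater")
    return df, TestResult(float(stat), float(p), len(hot_vals), len(syn_vals), "HOT > SYN")


def rank_sum_test(x, y, alternative: str = "greater") -> TestResult:
    """Mann-Whitney U wrapper (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    stat, p = stats.mannwhitneyu(x, y, alternative=alternative)
    return TestResult(float(stat), float(p), len(x), len(y), alternative)
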