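#!/usr/bin/env python
"""Population-genetic contrasts between hotspot and collinear regions.

Computes windowed nucleotide and haplotype diversity from the simulated
SNPs, the MAF spectrum by region class, the crossover-depletion
chi-square, the LD contrast across hotspot borders (on block-structured
genotypes emulating suppressed recombination inside hotspots), and the
deleterious-burden contrast with a planted 3x rate in hotspots.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, study_population

from syntenypop.popstats import (
    SnpMatrix,
    co_enrichment_test,
    deleterious_contrast,
    haplotype_diversity,
    ld_hot_contrast,
    maf_by_region_class,
    nucleotide_diversity,
)
from syntenypop.regions import classify_windows
from syntenypop.simpop import simulate_block_genotypes, simulate_deleterious_flags
from syntenypop.syndiv import sliding_profile


def main():
    pop = study_population()
    frame = pop.accessions[0]
    masks = pop.mask_set(frame)
    profile = sliding_profile(masks, 5_000, 1_000)
    classes = classify_windows(profile, hot_threshold=0.5)
    hot = classes.select("HOT")
    outdir = RESULTS / "popstats"
    outdir.mkdir(parents=True, exist_ok=True)

    snps = SnpMatrix(
        "Chr1",
        pop.snp_frame_positions(frame),
        pop.observed_genotypes,
        list(pop.accessions),
    )
    informative = snps.filter_sites(maf_ge=0.05, missing_lt=0.2)
    length = masks.chrom_lengths["Chr1"]
    pi = nucleotide_diversity(informative, window_size=5_000, step=1_000, length=length)
    hap = haplotype_diversity(informative, window_size=5_000, step=1_000, length=length)
    pi.to_tsv(outdir / "pi_5kb.tsv")
    hap.to_tsv(outdir / "haplotype_diversity_5kb.tsv")
    print(f"informative markers (MAF >= 0.05, missing < 0.2): {len(informative)}")

    maf_df, medians = maf_by_region_class(snps, classes, maf_gt=0.005, missing_lt=0.2)
    maf_df.to_csv(outdir / "maf_by_class.tsv", sep="\t", index=False)
    print("median MAF by region class:")
    for label, med in sorted(medians.items()):
        print(f"  {label:12s} {med:.3f}")

    syn_genomewide = {
        c: np.logical_and.reduce([masks.mask(a, b)[c] for a, b in masks.pairs()])
        for c in masks.chrom_lengths
    }
    co = co_enrichment_test(pop.crossovers_frame(frame), syn_genomewide)
    print(
        f"crossovers: {co.observed} of {co.n_total} overlap non-syntenic sequence "
        f"(expected {co.expected:.1f} from a {co.nonsyn_fraction:.1%} non-syntenic "
        f"genome); chi2 = {co.chi2:.1f}, one-sided p = {co.pvalue:.3g}"
    )

    # LD needs many haplotypes; emulate a large panel whose recombination
    # is suppressed inside the called HOT regions
    panel = 96
    positions = np.arange(0, length, 800)
    blocks = [(int(r.start), int(r.end)) for r in hot.data.itertuples(index=False)]
    gts = simulate_block_genotypes(panel, positions, blocks, seed=pop.config.seed)
    panel_snps = SnpMatrix("Chr1", positions, gts, [f"p{i}" for i in range(panel)])
    ld_df, ld_res = ld_hot_contrast(panel_snps, hot, flank=4_000)
    ld_df.to_csv(outdir / "ld_hot_contrast.tsv", sep="\t", index=False)
    ok = ld_df.dropna(subset=["within_r2", "across_r2"])
    print(
        f"LD (r2) around {len(ok)} HOT regions: within {ok['within_r2'].mean():.2f}, "
        f"flank {ok['flank_r2'].mean():.2f}, across border {ok['across_r2'].mean():.2f}; "
        f"one-sided U p = {ld_res.pvalue:.3g}"
    )

    flags = simulate_deleterious_flags(
        np.full(len(snps), "Chr1"), snps.positions, classes,
        base_rate=0.05, hot_multiplier=3.0, seed=pop.config.seed,
    )
    variants = pd.DataFrame(
        {"chrom": "Chr1", "pos": snps.positions, "deleterious": flags}
    )
    del_df, del_res = deleterious_contrast(variants, classes)
    del_df.to_csv(outdir / "deleterious_by_region.tsv", sep="\t", index=False)
    hot_burden = del_df[del_df["label"] == "HOT"]["burden"].mean()
    syn_burden = del_df[del_df["label"] == "SYN"]["burden"].mean()
    print(
        f"deleterious fraction: HOT {hot_burden:.3f} vs SYN {syn_burden:.3f}; "
        f"one-sided U p = {del_res.pvalue:.3g}"
    )


if __name__ == "__main__":
    main()
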