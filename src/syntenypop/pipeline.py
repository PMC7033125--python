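"""Pipeline orchestration: simulate -> masks -> profile -> regions ->
pan-genome -> population statistics, with a checksummed output manifest.

A single structured config (YAML) drives all stages; identical config
and seed yield byte-identical outputs. Stages never mutate another
stage's inputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pangenome, popstats, regions, simpop, syndiv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.manifest = manifest or {}


def demo_config(seed: int = 7, outdir: str = "results/demo") -> dict:
    """Bundled demo: 8 accessions, one 1-Mb chromosome, 3 hotspots."""
    return {
        "outdir": outdir,
        "seed": seed,
        "frame": "acc1",
        "window": 5000,
        "step": 1000,
        "threshold": 0.5,
        "merge_dist": 2000,
        "convention": "pairwise_mean",
        "simulate": {
            "n_accessions": 8,
            "chrom_lengths": [1_000_000],
            "hotspot_loci": [
                ["Chr1", 150_000, 180_000],
                ["Chr1", 450_000, 485_000],
                ["Chr1", 750_000, 775_000],
            ],
        },
        "popstats": {"enabled": True},
        "pangenome": {"enabled": True},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> dict:
    cfg = dict(config)
    cfg.setdefault("frame", None)
    cfg.setdefault("window", 5000)
    cfg.setdefault("step", 1000)
    cfg.setdefault("threshold", 0.5)
    cfg.setdefault("merge_dist", 2000)
    cfg.setdefault("convention", "pairwise_mean")
    cfg.setdefault("popstats", {"enabled": False})
    cfg.setdefault("pangenome", {"enabled": False})
    if "outdir" not in cfg:
        raise ValueError("config needs an output directory ('outdir')")
    if "simulate" not in cfg:
        # file-driven mode: check referenced inputs up front, before any
        # stage runs
        if "annotations" not in cfg:
            raise ValueError("config needs either 'simulate' or 'annotations'")
        if cfg["popstats"].get("enabled") and "vcf" not in cfg["popstats"]:
            raise ValueError("popstats enabled but no VCF configured")
        for key in ("vcf", "crossovers"):
            p = cfg["popstats"].get(key)
            if p and not Path(p).exists():
                raise ValueError(f"configured {key} file {p!r} does not exist")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute all configured stages; returns the output manifest."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    seed = int(cfg.get("seed", 0))

    def record(stage: str, *paths):
        manifest.setdefault(stage, {})
        for p in paths:
            manifest[stage][str(Path(p).relative_to(outdir))] = _sha256(Path(p))

    stage = "simulate"
    try:
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"])
            sim_kwargs["chrom_lengths"] = tuple(sim_kwargs.get("chrom_lengths", (1_000_000,)))
            sim_kwargs["hotspot_loci"] = tuple(
                (c, int(s), int(e)) for c, s, e in sim_kwargs.get("hotspot_loci", ())
            )
            sim_kwargs["seed"] = seed
            sim_config = simpop.SimulationConfig(**sim_kwargs)
            pop = simpop.simulate_population(sim_config)
            frame = cfg["frame"] or pop.accessions[0]
            fasta_paths = pop.write_fasta_dir(outdir / "fasta")
            truth_path = outdir / "truth_events.tsv"
            pop.write_truth(truth_path)
            vcf_path = outdir / "snps.vcf"
            pop.write_vcf(vcf_path, frame)
            co_path = outdir / "crossovers.bed"
            pop.write_crossovers(co_path, frame)
            ann_paths = pop.write_annotations(outdir / "annotations", frame)
            config_path = outdir / "config_used.yaml"
            with open(config_path, "w") as fh:
                yaml.safe_dump(dataclasses.asdict(sim_config), fh, sort_keys=True)
            record(stage, *fasta_paths, truth_path, vcf_path, co_path, *ann_paths, config_path)
        else:
            pop = None
            frame = cfg["frame"]

        stage = "masks"
        if pop is not None:
            masks = pop.mask_set(frame)
        else:
            from .synio import build_masks, read_annotation

            anns = [read_annotation(p) for p in sorted(map(str, cfg["annotations"]))]
            chrom_lengths = {c: int(n) for c, n in cfg["chrom_lengths"].items()}
            masks = build_masks(anns, frame=frame, chrom_lengths=chrom_lengths)
        syn_rows = [
            {"pair": f"{a},{b}", "chrom": c, "syn_fraction": masks.syn_fraction(a, b, c)}
            for (a, b) in masks.pairs()
            for c in masks.chrom_lengths
        ]
        masks_path = outdir / "syn_fraction.tsv"
        pd.DataFrame(syn_rows).to_csv(masks_path, sep="\t", index=False)
        record(stage, masks_path)

        stage = "profile"
        profile = syndiv.sliding_profile(
            masks, cfg["window"], cfg["step"], cfg["convention"]
        )
        profile_tsv = outdir / "pi_syn_profile.tsv"
        profile.to_tsv(profile_tsv)
        profile_bg = outdir / "pi_syn_profile.bedgraph"
        profile.to_bedgraph(profile_bg)
        record(stage, profile_tsv, profile_bg)

        stage = "regions"
        hot = regions.call_hot_regions(profile, cfg["threshold"], cfg["merge_dist"])
        hot_path = outdir / "hot_regions.bed"
        hot.to_bed(hot_path)
        classified = regions.classify_windows(profile, cfg["threshold"])
        class_path = outdir / "region_classes.bed"
        classified.to_bed(class_path)
        record(stage, hot_path, class_path)

        stage = "pangenome"
        if cfg["pangenome"].get("enabled") and pop is not None:
            points = pangenome.enumerate_curve(
                pop.nonaligned_intervals(), pop.genome_sizes(), list(pop.accessions)
            )
            curve_path = outdir / "pan_curve.tsv"
            pangenome.curve_frame(points).to_csv(curve_path, sep="\t", index=False)
            med = pangenome.per_n_medians(points)
            fits = []
            for side in ("pan", "core"):
                fit = pangenome.fit_exponential(med["n"], med[side], side=side)
                fits.append(
                    {"side": side, "A": fit.A, "B": fit.B, "C": fit.C, "rss": fit.rss}
                )
            fit_path = outdir / "pan_fit.tsv"
            pd.DataFrame(fits).to_csv(fit_path, sep="\t", index=False)
            record(stage, curve_path, fit_path)

        stage = "popstats"
        if cfg["popstats"].get("enabled"):
            if pop is not None:
                snps_by_chrom = popstats.SnpMatrix.from_vcf(outdir / "snps.vcf")
                cos = pop.crossovers_frame(frame)
            else:
                snps_by_chrom = popstats.SnpMatrix.from_vcf(cfg["popstats"]["vcf"])
                from .synio import read_bed

                cos = read_bed(cfg["popstats"]["crossovers"])
            paths = []
            for chrom, snps in snps_by_chrom.items():
                informative = snps.filter_sites(maf_ge=0.05, missing_lt=0.2)
                length = masks.chrom_lengths[chrom]
                pi = popstats.nucleotide_diversity(
                    informative, window_size=cfg["window"], step=cfg["step"], length=length
                )
                hap = popstats.haplotype_diversity(
                    informative, window_size=cfg["window"], step=cfg["step"], length=length
                )
                p1 = outdir / f"{chrom}_pi.tsv"
                p2 = outdir / f"{chrom}_haplotype_diversity.tsv"
                pi.to_tsv(p1)
                hap.to_tsv(p2)
                paths.extend([p1, p2])
            syn_mask_genomewide = {
                c: np.logical_and.reduce(
                    [masks.mask(a, b)[c] for (a, b) in masks.pairs()]
                )
                for c in masks.chrom_lengths
            }
            co_res = popstats.co_enrichment_test(cos, syn_mask_genomewide)
            co_path = outdir / "co_enrichment.json"
            with open(co_path, "w") as fh:
                json.dump(dataclasses.asdict(co_res), fh, indent=1, sort_keys=True)
            paths.append(co_path)
            maf_path = outdir / "maf_by_class.tsv"
            chrom0 = next(iter(snps_by_chrom))
            maf_df, _ = popstats.maf_by_region_class(snps_by_chrom[chrom0], classified)
            maf_df.to_csv(maf_path, sep="\t", index=False)
            paths.append(maf_path)
            record(stage, *paths)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc), manifest) from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
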