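"""Shared study conditions for the analysis scripts.

One desk-scale population: eight inbred accessions, a 1-Mb chromosome,
five tandem-duplication hotspots with conserved borders, default event
rates, seed 11. Scripts rebuild the population deterministically rather
than passing files around.
"""
from pathlib import Path

from syntenypop.simpop import SimulationConfig, simulate_population

RESULTS = Path(__file__).resolve().parent.parent / "results"

HOTSPOTS = (
    ("Chr1", 120_000, 150_000),
    ("Chr1", 300_000, 335_000),
    ("Chr1", 480_000, 505_000),
    ("Chr1", 650_000, 690_000),
    ("Chr1", 860_000, 890_000),
)


def study_config(seed: int = 11) -> SimulationConfig:
    return SimulationConfig(
        chrom_lengths=(1_000_000,),
        hotspot_loci=HOTSPOTS,
        seed=seed,
    )


def study_population(seed: int = 11):
    return simulate_population(study_config(seed))
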