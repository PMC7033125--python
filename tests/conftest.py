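"""Shared fixtures: synthetic populations at several scales and an
independent per-position oracle for syntenic status."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from syntenypop.simpop import (
    SimulationConfig,
    simulate_population,
    _events_by_accession,
    _in_hotspot,
)


def brute_force_nonsyn(pop, frame, i, j, chrom):
    """Independent per-position recomputation of non-syntenic status for
    pair (i, j) in frame coordinates, straight from the truth events.

    Walks every event and marks its frame-projected positions one
    convention at a time; shares no code with the annotation emitter
    beyond the coordinate maps.
    """
    events = _events_by_accession(pop.truth)
    hs = pop.config.hotspot_loci
    m = pop.maps[frame][chrom]
    out = np.zeros(m.derived_length, dtype=bool)
    for acc in {i, j}:
        for ev in events.get(acc, {}).get(chrom, []):
            spans = []
            if ev.kind in ("inversion", "deletion"):
                spans = [(ev.start, ev.end)]
            elif ev.kind == "translocation":
                spans = [(ev.start, ev.end), (ev.partner_start, ev.partner_end)]
            elif ev.kind == "tandem_duplication" and (
                ev.hotspot or _in_hotspot(ev, hs)
            ):
                spans = [(ev.start, ev.end)]
            for s, e in spans:
                fs, fe = m.project_interval(s, e)
                out[fs:fe] = True
    for ev in events.get(frame, {}).get(chrom, []):
        if ev.kind == "insertion":
            out[m.to_derived(ev.start, False) : m.to_derived(ev.start, True)] = True
        elif (
            ev.kind == "tandem_duplication"
            and not (ev.hotspot or _in_hotspot(ev, pop.config.hotspot_loci))
            and frame in (i, j)
        ):
            out[m.to_derived(ev.end, False) : m.to_derived(ev.end, True)] = True
    return out


def brute_force_pi_syn(pop, frame, chrom, start, end):
    """Per-position, per-ordered-pair recomputation of pairwise-mean
    synteny diversity over [start, end)."""
    accs = pop.accessions
    total = 0.0
    n_pairs = 0
    for i, j in itertools.combinations(accs, 2):
        nonsyn = brute_force_nonsyn(pop, frame, i, j, chrom)[start:end]
        total += nonsyn.mean()
        n_pairs += 1
    return total / n_pairs


@pytest.fixture(scope="session")
def small_pop():
    """10-kb chromosome with one hotspot; fast, rich in event types."""
    cfg = SimulationConfig(
        chrom_lengths=(10_000,),
        hotspot_loci=(("Chr1", 3_000, 5_000),),
        inversion_length=(500, 1_500),
        translocation_length=(300, 800),
        indel_length=(150, 400),
        tandem_dup_unit_range=(200, 600),
        seed=3,
    )
    return simulate_population(cfg)


HOTSPOTS_1MB = (
    ("Chr1", 120_000, 150_000),
    ("Chr1", 300_000, 335_000),
    ("Chr1", 480_000, 505_000),
    ("Chr1", 650_000, 690_000),
    ("Chr1", 860_000, 890_000),
)


@pytest.fixture(scope="session")
def hot_pop():
    """1-Mb chromosome, 8 accessions, 5 planted hotspots (the package's
    standard desk-scale study conditions)."""
    cfg = SimulationConfig(
        chrom_lengths=(1_000_000,),
        hotspot_loci=HOTSPOTS_1MB,
        seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def hot_masks(hot_pop):
    return hot_pop.mask_set()


@pytest.fixture(scope="session")
def hot_profile(hot_pop, hot_masks):
    from syntenypop.syndiv import sliding_profile

    return sliding_profile(hot_masks)
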