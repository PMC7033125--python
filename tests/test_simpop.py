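"""Simulator: determinism, truth bookkeeping, and annotation emission."""
import itertools

import numpy as np
import pytest

from syntenypop.simpop import (
    PlacementError,
    SimulationConfig,
    SimulatedPopulation,
    TruthEvent,
    build_maps,
    read_truth_events,
    simulate_population,
    truth_to_annotations,
    write_truth_events,
)
from syntenypop.syndiv import pi_syn_window

from conftest import brute_force_nonsyn, brute_force_pi_syn


def quiet_config(**kwargs):
    base = dict(
        chrom_lengths=(20_000,),
        inversion_rate=0.0,
        translocation_rate=0.0,
        tandem_dup_rate=0.0,
        indel_rate=0.0,
        crossover_rate=10.0,
        snp_density=1.0,
        seed=0,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(chrom_lengths=(0,))
    with pytest.raises(ValueError):
        SimulationConfig(hotspot_loci=(("ChrX", 0, 10),))
    with pytest.raises(ValueError):
        SimulationConfig(
            chrom_lengths=(10_000,),
            hotspot_loci=(("Chr1", 0, 5000), ("Chr1", 4000, 9000)),
        )
    with pytest.raises(ValueError):
        SimulationConfig(inversion_rate=-1)
    with pytest.raises(ValueError):
        SimulationConfig(n_accessions=1)


def test_truth_event_validation():
    with pytest.raises(ValueError):
        TruthEvent("a", "tandem_duplication", "Chr1", 0, 100, copies=1)
    with pytest.raises(ValueError):
        TruthEvent("a", "inversion", "Chr1", 100, 100)
    with pytest.raises(ValueError):
        TruthEvent("a", "insertion", "Chr1", 100, 100)  # no sequence
    with pytest.raises(ValueError):
        TruthEvent("a", "translocation", "Chr1", 0, 100)  # no partner


def test_zero_rates_identity_case():
    pop = simulate_population(quiet_config())
    assert pop.truth == []
    for acc in pop.accessions:
        for chrom, anc in pop.ancestor.items():
            # sequences may differ from the ancestor only at SNP sites
            diff = np.flatnonzero(pop.sequences[acc][chrom] != anc)
            carried = pop.snp_positions[pop.true_genotypes[:, pop.accessions.index(acc)] == 1]
            assert set(diff) == set(carried)
    no_snps = simulate_population(quiet_config(snp_density=0.0, crossover_rate=0.0))
    for acc in no_snps.accessions:
        assert np.array_equal(no_snps.sequences[acc]["Chr1"], no_snps.ancestor["Chr1"])


def test_determinism_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(
        chrom_lengths=(30_000,),
        hotspot_loci=(("Chr1", 10_000, 16_000),),
        hotspot_carriers=7,
        tandem_dup_unit_range=(300, 800),
        seed=42,
    )
    outs = []
    for run in ("r1", "r2"):
        pop = simulate_population(cfg)
        d = tmp_path / run
        pop.write_fasta_dir(d / "fasta")
        pop.write_truth(d / "truth.tsv")
        pop.write_vcf(d / "snps.vcf")
        pop.write_crossovers(d / "cos.bed")
        pop.write_annotations(d / "ann")
        outs.append(d)
    files1 = sorted(p.relative_to(outs[0]) for p in outs[0].rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(outs[1]) for p in outs[1].rglob("*") if p.is_file())
    assert files1 == files2
    for rel in files1:
        assert (outs[0] / rel).read_bytes() == (outs[1] / rel).read_bytes()


def test_single_inversion_chains_to_analytic_outlier_value():
    """One 10-kb inversion in accession 1 only: exactly one truth event,
    and window synteny diversity over the inverted interval equals the
    one-of-eight outlier value 7/28."""
    truth = [TruthEvent("acc1", "inversion", "Chr1", 100_000, 110_000)]
    cfg = SimulationConfig(chrom_lengths=(200_000,))
    pop = SimulatedPopulation(
        config=cfg,
        ancestor={},
        sequences={a: {} for a in cfg.accessions},
        truth=truth,
        snp_chroms=np.array([]),
        snp_positions=np.array([], dtype=np.int64),
        snp_ref=np.array([]),
        snp_alt=np.array([]),
        true_genotypes=np.zeros((0, 8), dtype=np.int8),
        observed_genotypes=np.zeros((0, 8), dtype=np.int8),
        crossovers=[],
        maps=build_maps(truth, cfg.lengths, cfg.accessions),
    )
    anns = {
        (a, b): truth_to_annotations(truth, (a, b), cfg.lengths, frame="acc1")
        for a, b in itertools.combinations(cfg.accessions, 2)
    }
    from syntenypop.synio import build_masks

    masks = build_masks(
        anns.values(), "acc1", cfg.lengths, accessions=list(cfg.accessions)
    )
    assert pi_syn_window(masks, "Chr1", 100_000, 110_000) == pytest.approx(7 / 28)
    assert pi_syn_window(masks, "Chr1", 0, 100_000) == 0.0


def test_identical_pair_single_syn_block():
    truth = []
    ann = truth_to_annotations(truth, ("a", "b"), {"Chr1": 50_000})
    assert len(ann.records) == 1
    rec = ann.records[0]
    assert rec.kind == "SYN"
    assert (rec.ref_start, rec.ref_end) == (0, 50_000)


def test_inversion_record_flanked_by_syn():
    truth = [TruthEvent("a", "inversion", "Chr1", 100_000, 110_000)]
    ann = truth_to_annotations(truth, ("a", "b"), {"Chr1": 200_000})
    kinds = [r.kind for r in ann.records]
    assert kinds == ["SYN", "INV", "SYN"]
    inv = ann.records[1]
    assert (inv.ref_start, inv.ref_end) == (100_000, 110_000)


def test_isolated_tandem_dup_extra_copies_annotation():
    """A 3-copy duplication of a 2-kb unit in the reference accession:
    DUP records cover the two extra copies (4 kb of non-SYN span in the
    carrier), the source unit keeps its syntenic backbone."""
    truth = [
        TruthEvent("a", "tandem_duplication", "Chr1", 10_000, 12_000, copies=3)
    ]
    ann = truth_to_annotations(truth, ("a", "b"), {"Chr1": 50_000})
    dups = [r for r in ann.records if r.kind == "DUP"]
    assert sum(r.ref_end - r.ref_start for r in dups) == 4000
    assert dups[0].ref_start == 12_000 and dups[0].ref_end == 16_000
    syn_span = sum(
        r.ref_end - r.ref_start for r in ann.records if r.kind == "SYN"
    )
    assert syn_span == 50_000  # backbone intact around the extra copies
    # carrier as query, partner as reference frame: source stays SYN,
    # extra copies reported on the query side
    ann2 = truth_to_annotations(truth, ("b", "a"), {"Chr1": 50_000})
    assert [r.kind for r in ann2.records if r.ref_end - r.ref_start > 0][0] == "SYN"
    dup2 = [r for r in ann2.records if r.kind == "DUP"]
    assert len(dup2) == 1
    assert (dup2[0].qry_start, dup2[0].qry_end) == (12_000, 16_000)


def test_masks_match_per_position_truth_oracle(small_pop):
    masks = small_pop.mask_set()
    for i, j in itertools.combinations(small_pop.accessions, 2):
        got = ~masks.mask(i, j)["Chr1"]
        expected = brute_force_nonsyn(small_pop, "acc1", i, j, "Chr1")
        np.testing.assert_array_equal(got, expected)


def test_masks_match_oracle_in_non_default_frame(small_pop):
    frame = "acc4"
    masks = small_pop.mask_set(frame)
    for i, j in itertools.combinations(small_pop.accessions, 2):
        got = ~masks.mask(i, j)["Chr1"]
        expected = brute_force_nonsyn(small_pop, frame, i, j, "Chr1")
        np.testing.assert_array_equal(got, expected)


def test_sequence_length_changes_match_truth_deltas(small_pop):
    for acc in small_pop.accessions:
        expected = sum(
            ev.length_delta() for ev in small_pop.truth if ev.accession == acc
        )
        got = small_pop.genome_size(acc) - sum(small_pop.config.chrom_lengths)
        assert got == expected


def test_hotspot_carrier_counts(hot_pop):
    carriers_by_hotspot = {}
    for ev in hot_pop.truth:
        if ev.hotspot:
            for hc, hs, he in hot_pop.config.hotspot_loci:
                if hc == ev.chrom and hs <= ev.start < he:
                    carriers_by_hotspot.setdefault((hc, hs, he), set()).add(
                        ev.accession
                    )
    assert len(carriers_by_hotspot) == len(hot_pop.config.hotspot_loci)
    for carriers in carriers_by_hotspot.values():
        assert len(carriers) == hot_pop.config.hotspot_carriers


def test_events_respect_hotspot_boundaries(hot_pop):
    for ev in hot_pop.truth:
        if ev.hotspot:
            assert any(
                hc == ev.chrom and hs <= ev.start and ev.end <= he
                for hc, hs, he in hot_pop.config.hotspot_loci
            )
        elif ev.kind != "insertion":
            for hc, hs, he in hot_pop.config.hotspot_loci:
                if hc == ev.chrom:
                    assert ev.end <= hs or ev.start >= he


def test_crossovers_only_in_unrearranged_sequence(hot_pop):
    blocked = []
    for ev in hot_pop.truth:
        blocked.append((ev.start, ev.end))
        if ev.kind == "translocation":
            blocked.append((ev.partner_start, ev.partner_end))
    for hc, hs, he in hot_pop.config.hotspot_loci:
        blocked.append((hs, he))
    for chrom, s, e in hot_pop.crossovers:
        assert not any(s < be and e > bs for bs, be in blocked)


def test_placement_failure_raises_named_error():
    cfg = SimulationConfig(
        chrom_lengths=(10_000,),
        inversion_rate=2000.0,  # impossible to place without overlap
        inversion_length=(4000, 5000),
        translocation_rate=0.0,
        tandem_dup_rate=0.0,
        indel_rate=0.0,
        max_retries=50,
        seed=0,
    )
    with pytest.raises(PlacementError, match="inversion"):
        simulate_population(cfg)


def test_truth_tsv_round_trip(tmp_path, small_pop):
    p = tmp_path / "truth.tsv"
    write_truth_events(small_pop.truth, p)
    back = read_truth_events(p)
    assert back == small_pop.truth


def test_event_rates_to_zero_drive_pi_syn_to_zero():
    pop = simulate_population(quiet_config())
    masks = pop.mask_set()
    from syntenypop.syndiv import sliding_profile

    prof = sliding_profile(masks, 2000, 1000)
    assert (prof.data["value"] == 0).all()


def test_coordinate_map_round_trip(small_pop):
    for acc in small_pop.accessions:
        m = small_pop.maps[acc]["Chr1"]
        assert m.derived_length == len(small_pop.sequences[acc]["Chr1"])
        for pos in range(0, 10_000, 137):
            d = m.to_derived(pos)
            back = m.to_ancestral(d)
            deleted = any(
                ev.kind == "deletion" and ev.start <= pos < ev.end
                for ev in small_pop.truth
                if ev.accession == acc and ev.chrom == "Chr1"
            )
            if not deleted:
                assert back == pos
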