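"""Synthetic genome populations with planted structural rearrangements.

The generator emulates a small population of inbred (haploid-coded)
accessions derived from a shared ancestor: accession-specific
inversions, balanced intra-chromosomal translocations, indels, SNPs
with a neutral-like 1/k frequency spectrum, crossover intervals
confined to collinear sequence, and — the defining feature —
tandem-duplication hotspots with conserved borders, where several
accessions independently carry distinct forward-duplication haplotypes.

Everything downstream (masks, synteny diversity, hotspot calling,
pan-genome curves, population statistics) can therefore be exercised
against known truth. Coordinates are tracked in three systems: the
ancestral genome, each accession's derived genome, and a chosen
analysis frame; :class:`CoordinateMap` projects between them.

Structural choices (documented in the methods note):

* at most two accessions are rearranged at any position outside hotspot
  loci, and indels never overlap another accession's event — multiple
  independent non-collinear haplotypes arise only at planted hotspots;
* translocations are reciprocal equal-length segment swaps
  (length-neutral, exact bookkeeping);
* tandem duplications are forward-oriented by default and confined to
  hotspot loci, tiling each hotspot so carrier haplotypes share borders.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import intervals as iv
from .synio import (
    PairwiseSyntenyAnnotation,
    SyntenyRecord,
    build_masks,
    write_annotation,
    write_bed,
    write_fasta,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMPLEMENT[_a] = _b

EVENT_KINDS = (
    "inversion",
    "translocation",
    "tandem_duplication",
    "insertion",
    "deletion",
)

_PAINT_CODES = {"NOTAL": 1, "DUP": 2, "TRANS": 3, "INV": 4}
_PAINT_NAMES = {v: k for k, v in _PAINT_CODES.items()}


class PlacementError(RuntimeError):
    """Raised when an event cannot be placed after bounded retries."""


@dataclass(frozen=True)
class TruthEvent:
    """One planted structural event in ancestral coordinates.

    Insertions have start == end (anchor point) and carry the inserted
    sequence; translocations carry the reciprocal partner interval;
    tandem duplications carry the copy count (>= 2) and orientation of
    the extra copies ('+' forward by default).
    """

    accession: str
    kind: str
    chrom: str
    start: int
    end: int
    copies: int = 1
    orientation: str = "+"
    partner_start: int | None = None
    partner_end: int | None = None
    hotspot: bool = False
    inserted_seq: str | None = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "insertion":
            if self.start != self.end or not self.inserted_seq:
                raise ValueError("insertion needs start == end and a sequence")
        elif self.start >= self.end:
            raise ValueError(f"empty interval for {self.kind}")
        if self.kind == "tandem_duplication" and self.copies < 2:
            raise ValueError("tandem duplication needs copy count >= 2")
        if self.kind == "translocation" and (
            self.partner_start is None or self.partner_end is None
        ):
            raise ValueError("translocation needs a partner interval")

    @property
    def unit_length(self) -> int:
        return self.end - self.start

    def length_delta(self) -> int:
        if self.kind == "tandem_duplication":
            return (self.copies - 1) * self.unit_length
        if self.kind == "insertion":
            return len(self.inserted_seq)
        if self.kind == "deletion":
            return -self.unit_length
        return 0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population.

    Rates are events per Mb per accession; lengths in bp. Defaults model
    a desk-scale version of an eight-accession inbred population with a
    1-Mb chromosome: a few large accession-specific inversions and
    translocations, scattered indels, hotspot loci tiled by independent
    forward tandem-duplication haplotypes in most accessions, ~2 SNPs
    per kb with a 1/k allele-frequency spectrum, and crossover intervals
    only in sequence untouched by any rearrangement.
    """

    n_accessions: int = 8
    chrom_lengths: tuple[int, ...] = (1_000_000,)
    chrom_names: tuple[str, ...] | None = None
    hotspot_loci: tuple[tuple[str, int, int], ...] = ()
    hotspot_carriers: int = 6
    inversion_rate: float = 2.0
    translocation_rate: float = 1.0
    tandem_dup_rate: float = 5.0
    indel_rate: float = 2.0
    inversion_length: tuple[int, int] = (5_000, 50_000)
    translocation_length: tuple[int, int] = (2_000, 10_000)
    indel_length: tuple[int, int] = (200, 2_000)
    tandem_dup_unit_range: tuple[int, int] = (500, 2_000)
    tandem_dup_copy_range: tuple[int, int] = (2, 4)
    inverted_dup_fraction: float = 0.0
    hotspot_repeats: bool = True
    snp_density: float = 2.0
    hotspot_snp_density: float = 3.0
    snp_missing_rate: float = 0.05
    allele_frequency_model: str = "one_over_k"
    crossover_rate: float = 50.0
    crossover_length: tuple[int, int] = (500, 4_000)
    max_background_overlap: int = 2
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_accessions < 2:
            raise ValueError("need at least two accessions")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.chrom_names is None:
            self.chrom_names = tuple(
                f"Chr{i + 1}" for i in range(len(self.chrom_lengths))
            )
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names/chrom_lengths mismatch")
        lengths = dict(zip(self.chrom_names, self.chrom_lengths))
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.hotspot_loci:
            if chrom not in lengths:
                raise ValueError(f"hotspot on unknown chromosome {chrom!r}")
            if not (0 <= s < e <= lengths[chrom]):
                raise ValueError(f"hotspot {chrom}:{s}-{e} out of bounds")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, locs in by_chrom.items():
            locs.sort()
            for (s1, e1), (s2, e2) in zip(locs, locs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping hotspots on {chrom}")
        for rate in (
            self.inversion_rate,
            self.translocation_rate,
            self.tandem_dup_rate,
            self.indel_rate,
            self.snp_density,
            self.hotspot_snp_density,
            self.crossover_rate,
        ):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if not (0 < self.hotspot_carriers <= self.n_accessions):
            raise ValueError("hotspot_carriers must be in 1..n_accessions")

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(f"acc{i + 1}" for i in range(self.n_accessions))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


class CoordinateMap:
    """Monotone map between ancestral and derived coordinates of one
    accession chromosome, built from its length-changing edits."""

    def __init__(self, length: int, edits: Sequence[tuple[int, int, int]]):
        # edits: (anc_start, anc_end, delta); deletions span an interval,
        # insertions/duplication-expansions are point edits (start == end).
        self.length = int(length)
        edits = sorted(edits)
        self.starts = np.array([e[0] for e in edits], dtype=np.int64)
        self.ends = np.array([e[1] for e in edits], dtype=np.int64)
        self.deltas = np.array([e[2] for e in edits], dtype=np.int64)
        self.cum = np.concatenate(([0], np.cumsum(self.deltas)))
        self.derived_length = self.length + int(self.deltas.sum())
        # identity segments for the inverse map
        segs, novel = [], []
        anc, der = 0, 0
        for s, e, d in zip(self.starts, self.ends, self.deltas):
            if s > anc:
                segs.append((der, der + (s - anc), anc))
                der += s - anc
                anc = s
            if e > s:  # deletion
                anc = e
            else:  # insertion / duplication expansion
                novel.append((der, der + d))
                der += d
        if anc < self.length:
            segs.append((der, der + (self.length - anc), anc))
        self._segs = np.array(segs, dtype=np.int64).reshape(-1, 3)
        self._novel = np.array(novel, dtype=np.int64).reshape(-1, 2)

    def to_derived(self, pos: int, include_at: bool = True) -> int:
        """Derived coordinate of ancestral ``pos``.

        ``include_at`` controls whether point edits anchored exactly at
        ``pos`` are applied (True: map past inserted material). Positions
        inside a deletion collapse to the deletion site.
        """
        side = "right" if include_at else "left"
        k = int(np.searchsorted(self.ends, pos, side=side))
        j = int(np.searchsorted(self.starts, pos, side="right")) - 1
        if j >= 0 and self.starts[j] < self.ends[j] and pos < self.ends[j]:
            return int(self.starts[j] + self.cum[j])  # inside a deletion
        return int(pos + self.cum[k])

    def to_ancestral(self, pos: int, up: bool = True) -> int:
        """Ancestral coordinate of derived ``pos``; positions inside novel
        (inserted/duplicated) material clip to the next (up) or previous
        ancestral position."""
        if len(self._segs):
            j = int(np.searchsorted(self._segs[:, 0], pos, side="right")) - 1
            if j >= 0 and pos < self._segs[j, 1]:
                return int(self._segs[j, 2] + (pos - self._segs[j, 0]))
            nxt = j + 1 if up else j
            if up:
                if nxt < len(self._segs):
                    return int(self._segs[nxt, 2])
                return self.length
            if j >= 0:
                seg = self._segs[j]
                return int(seg[2] + (seg[1] - seg[0]))
            return 0
        return 0 if up else self.length

    def project_interval(self, start: int, end: int) -> tuple[int, int]:
        """Derived image of ancestral [start, end); expansions anchored at
        ``end`` are included (a duplicated unit maps to its full span)."""
        return self.to_derived(start, include_at=True), self.to_derived(end, include_at=True)


def _revcomp(seq: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[seq[::-1]]


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _derived_count_weights(n: int, model: str) -> np.ndarray:
    k = np.arange(1, n)
    if model == "one_over_k":
        w = 1.0 / k
    elif model == "singleton_biased":
        w = 1.0 / k**2
    elif model == "uniform":
        w = np.ones_like(k, dtype=float)
    else:
        raise ValueError(f"unknown allele frequency model {model!r}")
    return w / w.sum()


@dataclass
class SimulatedPopulation:
    """Output bundle of :func:`simulate_population`."""

    config: SimulationConfig
    ancestor: dict[str, np.ndarray]
    sequences: dict[str, dict[str, np.ndarray]]
    truth: list[TruthEvent]
    snp_chroms: np.ndarray
    snp_positions: np.ndarray  # ancestral coordinates
    snp_ref: np.ndarray
    snp_alt: np.ndarray
    true_genotypes: np.ndarray  # sites x accessions, 0/1
    observed_genotypes: np.ndarray  # with -1 missing
    crossovers: list[tuple[str, int, int]]  # ancestral coordinates
    maps: dict[str, dict[str, CoordinateMap]] = field(repr=False, default_factory=dict)

    @property
    def accessions(self) -> tuple[str, ...]:
        return self.config.accessions

    def sequence_str(self, accession: str, chrom: str) -> str:
        return self.sequences[accession][chrom].tobytes().decode()

    def derived_chrom_lengths(self, accession: str) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences[accession].items()}

    def genome_size(self, accession: str) -> int:
        return sum(self.derived_chrom_lengths(accession).values())

    # -- frame projections ----------------------------------------------------

    def frame_positions(self, positions, chrom: str, frame: str) -> np.ndarray:
        m = self.maps[frame][chrom]
        return np.array([m.to_derived(int(p)) for p in positions], dtype=np.int64)

    def frame_chrom_lengths(self, frame: str) -> dict[str, int]:
        return self.derived_chrom_lengths(frame)

    def snp_frame_positions(self, frame: str) -> np.ndarray:
        out = np.empty(len(self.snp_positions), dtype=np.int64)
        for chrom in self.config.chrom_names:
            sel = self.snp_chroms == chrom
            out[sel] = self.frame_positions(self.snp_positions[sel], chrom, frame)
        return out

    def hotspots_frame(self, frame: str | None = None) -> list[tuple[str, int, int]]:
        """Planted hotspot loci projected into frame coordinates (frame
        carriers expand their hotspots by the duplicated copies)."""
        frame = frame or self.accessions[0]
        out = []
        for chrom, s, e in self.config.hotspot_loci:
            m = self.maps[frame][chrom]
            out.append((chrom, m.to_derived(s), m.to_derived(e)))
        return out

    def crossovers_frame(self, frame: str) -> list[tuple[str, int, int]]:
        out = []
        for chrom, s, e in self.crossovers:
            m = self.maps[frame][chrom]
            out.append((chrom, m.to_derived(s), m.to_derived(e)))
        return out

    # -- downstream inputs ----------------------------------------------------

    def annotations(self, frame: str | None = None) -> dict[tuple[str, str], PairwiseSyntenyAnnotation]:
        frame = frame or self.accessions[0]
        out = {}
        for a, b in itertools.combinations(self.accessions, 2):
            out[(a, b)] = truth_to_annotations(
                self.truth,
                (a, b),
                self.config.lengths,
                frame=frame,
                hotspot_loci=self.config.hotspot_loci,
                maps=self.maps,
            )
        return out

    def mask_set(self, frame: str | None = None, **kwargs):
        frame = frame or self.accessions[0]
        return build_masks(
            self.annotations(frame).values(),
            frame=frame,
            chrom_lengths=self.frame_chrom_lengths(frame),
            accessions=list(self.accessions),
            **kwargs,
        )

    def nonaligned_intervals(self) -> dict[tuple[str, str], np.ndarray]:
        """Per ordered pair (g, h): intervals of g (linearized derived
        coordinates) without a counterpart in h — g's novel insertions,
        g's haplotype-specific tandem-duplication copies, and h's
        deletions projected into g. Duplication haplotypes are
        accession-specific, so extra copies have no partner allele in
        any other genome."""
        events = _events_by_accession(self.truth)
        out = {}
        for g in self.accessions:
            offsets = {}
            off = 0
            for chrom in self.config.chrom_names:
                offsets[chrom] = off
                off += len(self.sequences[g][chrom])
            for h in self.accessions:
                if g == h:
                    continue
                pieces = []
                for chrom in self.config.chrom_names:
                    m = self.maps[g][chrom]
                    base = offsets[chrom]
                    for ev in events.get(g, {}).get(chrom, []):
                        if ev.kind == "insertion":
                            s = m.to_derived(ev.start, include_at=False)
                            e = m.to_derived(ev.start, include_at=True)
                            pieces.append((base + s, base + e))
                        elif ev.kind == "tandem_duplication":
                            s = m.to_derived(ev.end, include_at=False)
                            e = m.to_derived(ev.end, include_at=True)
                            pieces.append((base + s, base + e))
                    for ev in events.get(h, {}).get(chrom, []):
                        if ev.kind == "deletion":
                            s, e = m.project_interval(ev.start, ev.end)
                            if e > s:
                                pieces.append((base + s, base + e))
                out[(g, h)] = iv.merge(np.array(pieces, dtype=np.int64).reshape(-1, 2))
        return out

    def genome_sizes(self) -> dict[str, int]:
        return {a: self.genome_size(a) for a in self.accessions}

    # -- writers --------------------------------------------------------------

    def write_fasta_dir(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for acc in self.accessions:
            p = outdir / f"{acc}.fa"
            write_fasta(
                {c: self.sequence_str(acc, c) for c in self.config.chrom_names}, p
            )
            paths.append(p)
        return paths

    def write_truth(self, path) -> None:
        write_truth_events(self.truth, path)

    def write_vcf(self, path, frame: str | None = None) -> None:
        frame = frame or self.accessions[0]
        positions = self.snp_frame_positions(frame)
        write_vcf(
            path,
            self.frame_chrom_lengths(frame),
            list(self.snp_chroms),
            list(positions),
            list(self.snp_ref),
            list(self.snp_alt),
            self.observed_genotypes,
            list(self.accessions),
        )

    def write_crossovers(self, path, frame: str | None = None) -> None:
        frame = frame or self.accessions[0]
        write_bed(self.crossovers_frame(frame), path)

    def write_annotations(self, outdir, frame: str | None = None) -> list[Path]:
        frame = frame or self.accessions[0]
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for (a, b), ann in sorted(self.annotations(frame).items()):
            p = outdir / f"{a}_{b}.syn.tsv"
            write_annotation(ann, p)
            paths.append(p)
        return paths


def write_truth_events(truth: Sequence[TruthEvent], path) -> None:
    cols = (
        "accession kind chrom start end copies orientation "
        "partner_start partner_end hotspot inserted_seq"
    ).split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ev in truth:
            fh.write(
                "\t".join(
                    str(x) if x is not None else "-"
                    for x in (
                        ev.accession,
                        ev.kind,
                        ev.chrom,
                        ev.start,
                        ev.end,
                        ev.copies,
                        ev.orientation,
                        ev.partner_start,
                        ev.partner_end,
                        int(ev.hotspot),
                        ev.inserted_seq,
                    )
                )
                + "\n"
            )


def read_truth_events(path) -> list[TruthEvent]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            (acc, kind, chrom, s, e, copies, orient, ps, pe, hot, ins) = line.rstrip(
                "\n"
            ).split("\t")
            out.append(
                TruthEvent(
                    acc,
                    kind,
                    chrom,
                    int(s),
                    int(e),
                    int(copies),
                    orient,
                    None if ps == "-" else int(ps),
                    None if pe == "-" else int(pe),
                    bool(int(hot)),
                    None if ins == "-" else ins,
                )
            )
    return out


def _events_by_accession(truth: Sequence[TruthEvent]):
    out: dict[str, dict[str, list[TruthEvent]]] = {}
    for ev in truth:
        out.setdefault(ev.accession, {}).setdefault(ev.chrom, []).append(ev)
    return out


def build_maps(
    truth: Sequence[TruthEvent], chrom_lengths: Mapping[str, int], accessions
) -> dict[str, dict[str, CoordinateMap]]:
    events = _events_by_accession(truth)
    maps = {}
    for acc in accessions:
        maps[acc] = {}
        for chrom, length in chrom_lengths.items():
            edits = []
            for ev in events.get(acc, {}).get(chrom, []):
                if ev.kind == "tandem_duplication":
                    edits.append((ev.end, ev.end, (ev.copies - 1) * ev.unit_length))
                elif ev.kind == "insertion":
                    edits.append((ev.start, ev.start, len(ev.inserted_seq)))
                elif ev.kind == "deletion":
                    edits.append((ev.start, ev.end, -ev.unit_length))
            maps[acc][chrom] = CoordinateMap(length, edits)
    return maps


# -- event placement ----------------------------------------------------------

def _place_interval(
    rng, length, event_len, forbidden, cover, depth_limit, max_retries, what
):
    for _ in range(max_retries):
        s = int(rng.integers(0, length - event_len))
        e = s + event_len
        if forbidden[s:e].any():
            continue
        if (cover[s:e] >= depth_limit).any():
            continue
        cover[s:e] += 1
        return s, e
    raise PlacementError(
        f"could not place {what} of {event_len} bp after {max_retries} retries"
    )


def _hotspot_haplotype(rng, cfg, acc, chrom, hs_start, hs_end) -> list[TruthEvent]:
    """Tile a hotspot locus with forward tandem-duplication units; the
    tiling conserves the hotspot borders while unit boundaries and copy
    numbers differ between carriers."""
    unit_min, unit_max = cfg.tandem_dup_unit_range
    cmin, cmax = cfg.tandem_dup_copy_range
    events = []
    pos = hs_start
    while pos < hs_end:
        remaining = hs_end - pos
        if remaining <= unit_max:
            unit_len = remaining
        else:
            unit_len = int(rng.integers(unit_min, unit_max + 1))
        if unit_len < 50:
            break
        copies = int(rng.integers(cmin, cmax + 1))
        orientation = "-" if rng.random() < cfg.inverted_dup_fraction else "+"
        events.append(
            TruthEvent(
                acc,
                "tandem_duplication",
                chrom,
                pos,
                pos + unit_len,
                copies,
                orientation,
                hotspot=True,
            )
        )
        pos += unit_len
    return events


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Generate a population; deterministic for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    accs = cfg.accessions
    lengths = cfg.lengths

    # ancestor, optionally with repeat arrays seeded inside hotspots
    # (tandem repeats are the proposed substrate of non-allelic
    # homologous recombination at these loci)
    ancestor: dict[str, np.ndarray] = {}
    for chrom, L in lengths.items():
        seq = _random_bases(rng, L)
        if cfg.hotspot_repeats:
            for hc, hs, he in cfg.hotspot_loci:
                if hc != chrom:
                    continue
                unit = _random_bases(rng, 200)
                tiled = np.tile(unit, (he - hs) // len(unit) + 1)[: he - hs]
                mut = rng.random(he - hs) < 0.02
                tiled = tiled.copy()
                tiled[mut] = _random_bases(rng, int(mut.sum()))
                seq[hs:he] = tiled
        ancestor[chrom] = seq

    forbidden = {c: np.zeros(L, dtype=bool) for c, L in lengths.items()}
    for hc, hs, he in cfg.hotspot_loci:
        forbidden[hc][hs:he] = True
    cover = {c: np.zeros(L, dtype=np.uint8) for c, L in lengths.items()}

    truth: list[TruthEvent] = []
    for acc in accs:
        for chrom, L in lengths.items():
            mb = L / 1e6
            for _ in range(rng.poisson(cfg.inversion_rate * mb)):
                elen = int(rng.integers(*_clipped(cfg.inversion_length, L)))
                s, e = _place_interval(
                    rng, L, elen, forbidden[chrom], cover[chrom],
                    cfg.max_background_overlap, cfg.max_retries,
                    f"inversion for {acc} on {chrom}",
                )
                truth.append(TruthEvent(acc, "inversion", chrom, s, e))
            for _ in range(rng.poisson(cfg.translocation_rate * mb)):
                elen = int(rng.integers(*_clipped(cfg.translocation_length, L)))
                s1, e1 = _place_interval(
                    rng, L, elen, forbidden[chrom], cover[chrom],
                    cfg.max_background_overlap, cfg.max_retries,
                    f"translocation for {acc} on {chrom}",
                )
                s2, e2 = _place_interval(
                    rng, L, elen, forbidden[chrom], cover[chrom],
                    cfg.max_background_overlap, cfg.max_retries,
                    f"translocation partner for {acc} on {chrom}",
                )
                if s2 < s1:
                    (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
                truth.append(
                    TruthEvent(
                        acc, "translocation", chrom, s1, e1,
                        partner_start=s2, partner_end=e2,
                    )
                )
            for _ in range(rng.poisson(cfg.indel_rate * mb)):
                elen = int(rng.integers(*_clipped(cfg.indel_length, L)))
                # indels are globally exclusive: depth limit 1
                s, e = _place_interval(
                    rng, L, elen, forbidden[chrom], cover[chrom], 1,
                    cfg.max_retries, f"indel for {acc} on {chrom}",
                )
                if rng.random() < 0.5:
                    truth.append(
                        TruthEvent(
                            acc, "insertion", chrom, s, s,
                            inserted_seq=_random_bases(rng, elen).tobytes().decode(),
                        )
                    )
                else:
                    truth.append(TruthEvent(acc, "deletion", chrom, s, e))

    # hotspot haplotypes: distinct tandem-duplication tilings in a
    # configurable number of carriers per hotspot
    if cfg.tandem_dup_rate > 0:
        for hc, hs, he in cfg.hotspot_loci:
            carriers = sorted(
                rng.choice(accs, size=cfg.hotspot_carriers, replace=False)
            )
            for acc in carriers:
                truth.extend(_hotspot_haplotype(rng, cfg, acc, hc, hs, he))

    maps = build_maps(truth, lengths, accs)

    # SNPs: background sites outside every rearranged interval, plus a
    # singleton-biased set inside hotspot loci
    event_union = {c: [] for c in lengths}
    for ev in truth:
        if ev.kind == "insertion":
            event_union[ev.chrom].append((max(ev.start - 1, 0), ev.start + 1))
        else:
            event_union[ev.chrom].append((ev.start, ev.end))
            if ev.kind == "translocation":
                event_union[ev.chrom].append((ev.partner_start, ev.partner_end))
    n = len(accs)
    bg_weights = _derived_count_weights(n, cfg.allele_frequency_model)
    hot_weights = _derived_count_weights(n, "singleton_biased")

    snp_rows = []  # (chrom, pos, k_weights_id)
    for chrom, L in lengths.items():
        blocked = iv.merge(
            np.array(
                event_union[chrom]
                + [(hs, he) for hc, hs, he in cfg.hotspot_loci if hc == chrom],
                dtype=np.int64,
            ).reshape(-1, 2)
        )
        clean = iv.complement(blocked, L)
        clean_positions = np.concatenate(
            [np.arange(s, e) for s, e in clean]
        ) if len(clean) else np.array([], dtype=np.int64)
        n_bg = rng.poisson(cfg.snp_density * L / 1000)
        n_bg = min(n_bg, len(clean_positions))
        if n_bg > 0:
            pos = rng.choice(clean_positions, size=n_bg, replace=False)
            snp_rows.extend((chrom, int(p), "bg") for p in pos)
        for hc, hs, he in cfg.hotspot_loci:
            if hc != chrom:
                continue
            n_hot = rng.poisson(cfg.hotspot_snp_density * (he - hs) / 1000)
            if n_hot > 0:
                pos = rng.choice(np.arange(hs, he), size=min(n_hot, he - hs), replace=False)
                snp_rows.extend((chrom, int(p), "hot") for p in pos)
    snp_rows.sort(key=lambda r: (list(lengths).index(r[0]), r[1]))
    # drop duplicate positions (possible only at hotspot borders)
    seen = set()
    snp_rows = [r for r in snp_rows if (r[0], r[1]) not in seen and not seen.add((r[0], r[1]))]

    m_sites = len(snp_rows)
    snp_chroms = np.array([r[0] for r in snp_rows])
    snp_positions = np.array([r[1] for r in snp_rows], dtype=np.int64)
    true_gt = np.zeros((m_sites, n), dtype=np.int8)
    snp_ref, snp_alt = [], []
    base_str = "ACGT"
    for i, (chrom, pos, kind) in enumerate(snp_rows):
        w = bg_weights if kind == "bg" else hot_weights
        k = int(rng.choice(np.arange(1, n), p=w))
        carriers = rng.choice(n, size=k, replace=False)
        true_gt[i, carriers] = 1
        ref = chr(ancestor[chrom][pos])
        alt = base_str[(base_str.index(ref) + int(rng.integers(1, 4))) % 4]
        snp_ref.append(ref)
        snp_alt.append(alt)
    observed = true_gt.copy()
    if cfg.snp_missing_rate > 0 and m_sites:
        miss = rng.random((m_sites, n)) < cfg.snp_missing_rate
        observed[miss] = -1

    # crossovers: uniform within sequence untouched by any event
    crossovers: list[tuple[str, int, int]] = []
    for chrom, L in lengths.items():
        blocked = iv.merge(
            np.array(
                event_union[chrom]
                + [(hs, he) for hc, hs, he in cfg.hotspot_loci if hc == chrom],
                dtype=np.int64,
            ).reshape(-1, 2)
        )
        clean = iv.complement(blocked, L)
        clean = clean[(clean[:, 1] - clean[:, 0]) >= cfg.crossover_length[1]]
        if len(clean) == 0:
            continue
        weights = (clean[:, 1] - clean[:, 0]).astype(float)
        weights /= weights.sum()
        n_co = rng.poisson(cfg.crossover_rate * L / 1e6)
        for _ in range(n_co):
            seg = clean[rng.choice(len(clean), p=weights)]
            clen = int(rng.integers(*cfg.crossover_length))
            s = int(rng.integers(seg[0], seg[1] - clen))
            crossovers.append((chrom, s, s + clen))
    crossovers = sorted(set(crossovers))

    # derived sequences
    events = _events_by_accession(truth)
    alt_bytes = np.frombuffer("".join(snp_alt).encode(), dtype=np.uint8) if m_sites else None
    sequences: dict[str, dict[str, np.ndarray]] = {}
    for ai, acc in enumerate(accs):
        sequences[acc] = {}
        for chrom, L in lengths.items():
            seq = ancestor[chrom].copy()
            sel = (snp_chroms == chrom) & (true_gt[:, ai] == 1)
            if sel.any():
                seq[snp_positions[sel]] = alt_bytes[np.flatnonzero(sel)]
            evs = events.get(acc, {}).get(chrom, [])
            for ev in evs:
                if ev.kind == "inversion":
                    seq[ev.start : ev.end] = _revcomp(seq[ev.start : ev.end])
                elif ev.kind == "translocation":
                    tmp = seq[ev.start : ev.end].copy()
                    seq[ev.start : ev.end] = seq[ev.partner_start : ev.partner_end]
                    seq[ev.partner_start : ev.partner_end] = tmp
            for ev in sorted(
                (e for e in evs if e.length_delta() != 0),
                key=lambda e: e.start,
                reverse=True,
            ):
                if ev.kind == "tandem_duplication":
                    unit = seq[ev.start : ev.end]
                    extra = unit if ev.orientation == "+" else _revcomp(unit)
                    extras = np.tile(extra, ev.copies - 1)
                    seq = np.concatenate([seq[: ev.end], extras, seq[ev.end :]])
                elif ev.kind == "insertion":
                    ins = np.frombuffer(ev.inserted_seq.encode(), dtype=np.uint8)
                    seq = np.concatenate([seq[: ev.start], ins, seq[ev.start :]])
                elif ev.kind == "deletion":
                    seq = np.concatenate([seq[: ev.start], seq[ev.end :]])
            sequences[acc][chrom] = seq

    return SimulatedPopulation(
        config=cfg,
        ancestor=ancestor,
        sequences=sequences,
        truth=truth,
        snp_chroms=snp_chroms,
        snp_positions=snp_positions,
        snp_ref=np.array(snp_ref),
        snp_alt=np.array(snp_alt),
        true_genotypes=true_gt,
        observed_genotypes=observed,
        crossovers=crossovers,
        maps=maps,
    )


def _clipped(length_range: tuple[int, int], L: int) -> tuple[int, int]:
    lo, hi = length_range
    hi = min(hi, max(L // 4, 2))
    lo = min(lo, hi)
    return lo, hi + 1  # rng.integers upper bound is exclusive


# -- truth -> pairwise annotations --------------------------------------------

def _event_paint_intervals(ev: TruthEvent, hotspot_loci) -> list[tuple[int, int, str]]:
    """Non-syntenic ancestral intervals contributed by one event.

    Isolated tandem duplications (outside hotspot loci) keep a syntenic
    backbone over the source unit — only their extra copies, which live
    in the carrier's coordinates, are non-syntenic — so they paint
    nothing here and are handled separately.
    """
    if ev.kind == "inversion":
        return [(ev.start, ev.end, "INV")]
    if ev.kind == "translocation":
        return [
            (ev.start, ev.end, "TRANS"),
            (ev.partner_start, ev.partner_end, "TRANS"),
        ]
    if ev.kind == "deletion":
        return [(ev.start, ev.end, "NOTAL")]
    if ev.kind == "tandem_duplication":
        if ev.hotspot or _in_hotspot(ev, hotspot_loci):
            return [(ev.start, ev.end, "DUP")]
        return []
    return []  # insertions are zero-width ancestrally


def _in_hotspot(ev: TruthEvent, hotspot_loci) -> bool:
    return any(
        hc == ev.chrom and hs <= ev.start and ev.end <= he
        for hc, hs, he in hotspot_loci
    )


def truth_to_annotations(
    truth: Sequence[TruthEvent],
    pair: tuple[str, str],
    chrom_lengths: Mapping[str, int],
    frame: str | None = None,
    hotspot_loci=(),
    maps: Mapping[str, Mapping[str, CoordinateMap]] | None = None,
) -> PairwiseSyntenyAnnotation:
    """Emit the pairwise comparison a structural annotator would report.

    Reference-side coordinates are expressed in ``frame`` (default: the
    first accession of the pair); the simulator owns the ancestral truth
    and can therefore lift any pair's comparison into any frame, the way
    a real pipeline lifts comparisons onto one reference genome.

    Conventions: a frame position is non-syntenic for the pair wherever
    either member carries a structural event (hotspot duplication
    haplotypes, inversions, translocation segments, deletions); the
    frame genome's own insertions are unalignable novel sequence (NOTAL
    for every pair); isolated tandem duplications keep their syntenic
    backbone, with DUP records covering the extra copies; non-frame
    insertions are invisible in frame coordinates (zero width).
    """
    ref_acc, qry_acc = pair
    frame = frame or ref_acc
    accessions = sorted({ev.accession for ev in truth} | set(pair) | {frame})
    if maps is None:
        maps = build_maps(truth, chrom_lengths, accessions)
    events = _events_by_accession(truth)
    records: list[SyntenyRecord] = []
    for chrom, L in chrom_lengths.items():
        fmap = maps[frame][chrom]
        qmap = maps[qry_acc][chrom]
        Lf = fmap.derived_length
        paint = np.zeros(Lf, dtype=np.uint8)
        isolated_dups: list[TruthEvent] = []
        for acc in dict.fromkeys(pair):
            for ev in events.get(acc, {}).get(chrom, []):
                if ev.kind == "tandem_duplication" and not (
                    ev.hotspot or _in_hotspot(ev, hotspot_loci)
                ):
                    isolated_dups.append(ev)
                    continue
                for s, e, kind in _event_paint_intervals(ev, hotspot_loci):
                    fs, fe = fmap.project_interval(s, e)
                    if fe > fs:
                        seg = paint[fs:fe]
                        np.maximum(seg, _PAINT_CODES[kind], out=seg)
        # frame's own novel insertions are unalignable for every pair
        for ev in events.get(frame, {}).get(chrom, []):
            if ev.kind == "insertion":
                fs = fmap.to_derived(ev.start, include_at=False)
                fe = fmap.to_derived(ev.start, include_at=True)
                seg = paint[fs:fe]
                np.maximum(seg, _PAINT_CODES["NOTAL"], out=seg)
        # frame-carried isolated duplications: extra copies are frame
        # sequence without a partner counterpart
        for ev in isolated_dups:
            if ev.accession == frame:
                fs = fmap.to_derived(ev.end, include_at=False)
                fe = fmap.to_derived(ev.end, include_at=True)
                seg = paint[fs:fe]
                np.maximum(seg, _PAINT_CODES["DUP"], out=seg)
        # run-length encode into records
        if Lf == 0:
            continue
        edges = np.flatnonzero(np.diff(paint)) + 1
        bounds = np.concatenate(([0], edges, [Lf]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            code = int(paint[s])
            kind = "SYN" if code == 0 else _PAINT_NAMES[code]
            anc_s = fmap.to_ancestral(int(s), up=True)
            anc_e = fmap.to_ancestral(int(e), up=False)
            if anc_e > anc_s:
                qs, qe = qmap.project_interval(anc_s, anc_e)
            else:
                qs = qe = None
            records.append(
                SyntenyRecord(
                    chrom, int(s), int(e),
                    chrom if qs is not None and qe > qs else None,
                    qs if qs is not None and qe > qs else None,
                    qe if qs is not None and qe > qs else None,
                    kind,
                )
            )
        # isolated duplications carried by the query: extra copies exist
        # only in query coordinates; the source unit stays syntenic
        for ev in isolated_dups:
            if ev.accession == qry_acc and qry_acc != frame:
                fs, fe = (
                    fmap.to_derived(ev.start, include_at=True),
                    fmap.to_derived(ev.end, include_at=False),
                )
                qs = qmap.to_derived(ev.end, include_at=False)
                qe = qmap.to_derived(ev.end, include_at=True)
                if fe > fs and qe > qs:
                    records.append(
                        SyntenyRecord(chrom, fs, fe, chrom, qs, qe, "DUP")
                    )
    records.sort(key=lambda r: (r.ref_chrom, r.ref_start, r.kind))
    return PairwiseSyntenyAnnotation(
        ref=ref_acc, qry=qry_acc, records=records, frame=frame
    )


# -- auxiliary synthetic inputs ----------------------------------------------

def simulate_orthogroup_table(
    accessions: Sequence[str],
    n_conserved: int = 200,
    n_variable: int = 60,
    n_shared_nonref: int = 20,
    n_specific_nonref: int = 10,
    reference: str | None = None,
    seed: int = 0,
):
    """Synthetic gene-family copy-number table with known composition.

    Families are conserved (identical counts everywhere), variable
    (copy-number differences), shared non-reference (absent from the
    reference, in >= 2 others) or accession-specific non-reference.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    accessions = list(accessions)
    reference = reference or accessions[0]
    others = [a for a in accessions if a != reference]
    rows, names = [], []
    fam = itertools.count(1)
    for _ in range(n_conserved):
        c = int(rng.integers(1, 4))
        rows.append({a: c for a in accessions})
        names.append(f"OG{next(fam):05d}")
    for _ in range(n_variable):
        base = int(rng.integers(1, 4))
        row = {a: base for a in accessions}
        changed = rng.choice(accessions, size=int(rng.integers(1, 3)), replace=False)
        for a in changed:
            row[a] = base + int(rng.integers(1, 4))
        rows.append(row)
        names.append(f"OG{next(fam):05d}")
    for _ in range(n_shared_nonref):
        row = {a: 0 for a in accessions}
        carriers = rng.choice(others, size=int(rng.integers(2, len(others) + 1)), replace=False)
        for a in carriers:
            row[a] = int(rng.integers(1, 3))
        rows.append(row)
        names.append(f"OG{next(fam):05d}")
    for _ in range(n_specific_nonref):
        row = {a: 0 for a in accessions}
        row[str(rng.choice(others))] = int(rng.integers(1, 3))
        rows.append(row)
        names.append(f"OG{next(fam):05d}")
    table = pd.DataFrame(rows, index=pd.Index(names, name="family"))[accessions]
    return table


def simulate_block_genotypes(
    n_accessions: int,
    positions: np.ndarray,
    blocks: Sequence[tuple[int, int]],
    switch_prob: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Marker genotypes with haplotype-block LD structure.

    Markers inside a block copy that block's binary accession partition
    (with a small per-site switch probability), giving high pairwise
    r^2 within blocks; markers outside blocks are independent draws —
    the genotype signature of recombination suppressed inside regions
    and free outside.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions)
    gts = np.zeros((len(positions), n_accessions), dtype=np.int8)
    block_patterns = []
    for _ in blocks:
        k = int(rng.integers(2, n_accessions - 1))
        pattern = np.zeros(n_accessions, dtype=np.int8)
        pattern[rng.choice(n_accessions, size=k, replace=False)] = 1
        block_patterns.append(pattern)
    for i, pos in enumerate(positions):
        hit = next(
            (b for b, (s, e) in enumerate(blocks) if s <= pos < e), None
        )
        if hit is None:
            k = int(rng.integers(1, n_accessions))
            row = np.zeros(n_accessions, dtype=np.int8)
            row[rng.choice(n_accessions, size=k, replace=False)] = 1
            gts[i] = row
        else:
            row = block_patterns[hit].copy()
            flip = rng.random(n_accessions) < switch_prob
            row[flip] = 1 - row[flip]
            gts[i] = row
    return gts


def simulate_deleterious_flags(
    variants_chrom: np.ndarray,
    variants_pos: np.ndarray,
    classes,
    base_rate: float = 0.05,
    hot_multiplier: float = 3.0,
    hot_label: str = "HOT",
    seed: int = 0,
) -> np.ndarray:
    """Boolean deleterious flags with an elevated rate inside hotspot
    regions, emulating the output of a variant-effect annotator."""
    rng = np.random.default_rng(seed)
    rate = np.full(len(variants_pos), base_rate)
    for row in classes.data.itertuples(index=False):
        if row.label != hot_label:
            continue
        sel = (
            (variants_chrom == row.chrom)
            & (variants_pos >= row.start)
            & (variants_pos < row.end)
        )
        rate[sel] = min(base_rate * hot_multiplier, 1.0)
    return rng.random(len(variants_pos)) < rate
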