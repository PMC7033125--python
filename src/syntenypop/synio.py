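"""I/O for pairwise structural annotations and standard genomic formats.

The central input is the tab-separated pairwise whole-genome comparison
dialect produced by structural-annotation tools (SYN / INV / TRANS /
INVTR / DUP / INVDP / NOTAL blocks with coordinates in both genomes,
1-based inclusive on disk). Internally everything is 0-based half-open.

From one annotation per unordered genome pair, expressed in a single
coordinate frame, :func:`build_masks` derives per-pair boolean
syntenic-status vectors — the substrate of the synteny-diversity
statistic in :mod:`syntenypop.syndiv`.
"""
from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

STRUCTURAL_CLASSES = ("SYN", "INV", "TRANS", "INVTR", "DUP", "INVDP", "NOTAL")


class AnnotationParseError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class SyntenyRecord:
    """One block of a pairwise comparison, 0-based half-open.

    ``ref_*`` coordinates live in the annotation's coordinate-frame
    genome; ``qry_*`` in the query genome (None for unaligned NOTAL
    blocks). ``parent`` is None for top-level structural records; nested
    records (local variants inside a block) carry their parent's id and
    never drive masks.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str | None
    qry_start: int | None
    qry_end: int | None
    kind: str
    parent: str | None = None

    @property
    def top_level(self) -> bool:
        return self.parent is None

    def __post_init__(self):
        if self.ref_end < self.ref_start:
            raise CoordinateError(
                f"record end < start on reference side: {self.ref_start}..{self.ref_end}"
            )


@dataclass
class PairwiseSyntenyAnnotation:
    """All records of one ordered genome-pair comparison.

    ``frame`` names the genome whose coordinates the reference-side
    columns use; it defaults to ``ref``. A simulator (which owns the
    ancestral truth) may express the comparison of any pair in a third
    genome's frame, emulating the lift-to-reference step of a real
    pipeline.
    """

    ref: str
    qry: str
    records: list[SyntenyRecord] = field(default_factory=list)
    frame: str | None = None

    def __post_init__(self):
        if self.frame is None:
            self.frame = self.ref

    @property
    def pair(self) -> tuple[str, str]:
        return (self.ref, self.qry)

    def top_level(self, kinds: Sequence[str] | None = None):
        for rec in self.records:
            if rec.top_level and (kinds is None or rec.kind in kinds):
                yield rec


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_annotation(path, ref: str | None = None, qry: str | None = None) -> PairwiseSyntenyAnnotation:
    """Read a pairwise annotation TSV (1-based inclusive on disk).

    Columns: ref_chrom, ref_start, ref_end, qry_chrom, qry_start,
    qry_end, class[, parent]. A '-' in query columns marks unaligned
    records. Header comments of the form ``#key=value`` may carry
    ref/qry/frame accession ids; explicit arguments override them.
    """
    meta: dict[str, str] = {}
    records: list[SyntenyRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 7:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected >= 7 columns, got {len(parts)}"
                )
            try:
                ref_chrom = parts[0]
                ref_start = int(parts[1]) - 1  # 1-based inclusive -> 0-based half-open
                ref_end = int(parts[2])
                if parts[3] == "-":
                    qc, qs, qe = None, None, None
                else:
                    qc = parts[3]
                    # inverted alignments may list query coords high-to-low
                    lo, hi = sorted((int(parts[4]), int(parts[5])))
                    qs, qe = lo - 1, hi
                kind = parts[6]
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            parent = None
            if len(parts) >= 8 and parts[7] not in ("-", ""):
                parent = parts[7]
            if ref_end < ref_start:
                raise CoordinateError(
                    f"{path}:{lineno}: reference end < start after normalization"
                )
            records.append(
                SyntenyRecord(ref_chrom, ref_start, ref_end, qc, qs, qe, kind, parent)
            )
    ann = PairwiseSyntenyAnnotation(
        ref=ref or meta.get("ref", "ref"),
        qry=qry or meta.get("qry", "qry"),
        records=records,
        frame=meta.get("frame"),
    )
    return ann


def write_annotation(ann: PairwiseSyntenyAnnotation, path) -> None:
    """Write the TSV dialect (1-based inclusive), with a metadata header."""
    with _open_text(path, "wt") as fh:
        fh.write(f"#ref={ann.ref} qry={ann.qry} frame={ann.frame}\n")
        for rec in ann.records:
            if rec.qry_chrom is None:
                qc, qs, qe = "-", "-", "-"
            else:
                qc, qs, qe = rec.qry_chrom, rec.qry_start + 1, rec.qry_end
            fh.write(
                f"{rec.ref_chrom}\t{rec.ref_start + 1}\t{rec.ref_end}\t"
                f"{qc}\t{qs}\t{qe}\t{rec.kind}\t{rec.parent or '-'}\n"
            )


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class SyntenyMaskSet:
    """Per-pair boolean syntenic-status vectors in one coordinate frame.

    ``mask(a, b)[chrom][pos]`` is True where the pair (a, b) is covered
    by a top-level SYN record. Pairs are unordered; arrays are read-only
    once built. Equal accession frequencies x_i = 1/n by default.
    """

    def __init__(
        self,
        frame: str,
        accessions: Sequence[str],
        chrom_lengths: Mapping[str, int],
        masks: Mapping[tuple[str, str], Mapping[str, np.ndarray]],
        frequencies: Sequence[float] | None = None,
    ):
        self.frame = frame
        self.accessions = list(accessions)
        self.chrom_lengths = dict(chrom_lengths)
        if frequencies is None:
            frequencies = np.full(len(self.accessions), 1.0 / len(self.accessions))
        self.frequencies = np.asarray(frequencies, dtype=float)
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("accession frequencies must sum to 1")
        self._masks: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for (a, b), per_chrom in masks.items():
            key = _pair_key(a, b)
            store: dict[str, np.ndarray] = {}
            for chrom, arr in per_chrom.items():
                arr = np.asarray(arr, dtype=bool)
                if len(arr) != self.chrom_lengths[chrom]:
                    raise CoordinateError(
                        f"mask length {len(arr)} != chromosome length "
                        f"{self.chrom_lengths[chrom]} for {chrom}"
                    )
                arr = arr.copy()
                arr.setflags(write=False)
                store[chrom] = arr
            self._masks[key] = store

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._masks)

    def mask(self, a: str, b: str) -> Mapping[str, np.ndarray]:
        return self._masks[_pair_key(a, b)]

    def syn_fraction(self, a: str, b: str, chrom: str) -> float:
        m = self.mask(a, b)[chrom]
        return float(m.mean()) if len(m) else 0.0


def build_masks(
    annotations: Iterable[PairwiseSyntenyAnnotation],
    frame: str,
    chrom_lengths: Mapping[str, int],
    accessions: Sequence[str] | None = None,
    frequencies: Sequence[float] | None = None,
    inversions_syntenic: bool = False,
) -> SyntenyMaskSet:
    """Build per-pair syntenic masks from one annotation per unordered pair.

    A frame position is syntenic for a pair iff covered by a top-level
    SYN record; everything else (NOTAL, DUP, INV, TRANS, gaps between
    records) is non-syntenic. ``inversions_syntenic=True`` additionally
    counts INV blocks (same position, reversed orientation) as syntenic.
    """
    anns = list(annotations)
    by_pair: dict[tuple[str, str], PairwiseSyntenyAnnotation] = {}
    for ann in anns:
        if ann.frame != frame:
            raise ValueError(
                f"annotation for pair {ann.pair} is in frame {ann.frame!r}, "
                f"expected {frame!r}"
            )
        by_pair[_pair_key(ann.ref, ann.qry)] = ann
    if accessions is None:
        accessions = sorted({acc for ann in anns for acc in ann.pair})
    expected = {_pair_key(a, b) for a, b in itertools.combinations(accessions, 2)}
    missing = sorted(expected - set(by_pair))
    if missing:
        raise ValueError(f"missing pairwise annotations: {missing}")

    syn_kinds = ("SYN", "INV") if inversions_syntenic else ("SYN",)
    masks = {}
    for key in sorted(expected):
        ann = by_pair[key]
        per_chrom = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
        for rec in ann.top_level(syn_kinds):
            if rec.ref_chrom not in per_chrom:
                raise CoordinateError(f"unknown chromosome {rec.ref_chrom!r}")
            if rec.ref_end > chrom_lengths[rec.ref_chrom]:
                raise CoordinateError(
                    f"record {rec.ref_chrom}:{rec.ref_start}-{rec.ref_end} exceeds "
                    f"chromosome length {chrom_lengths[rec.ref_chrom]}"
                )
            per_chrom[rec.ref_chrom][rec.ref_start : rec.ref_end] = True
        masks[key] = per_chrom
    return SyntenyMaskSet(frame, accessions, chrom_lengths, masks, frequencies)


# -- FASTA / BED / VCF helpers -------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write BED3 (or BED6 when rows carry name/score/strand)."""
    with _open_text(path, "wt") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_vcf(
    path,
    chrom_lengths: Mapping[str, int],
    chroms: Sequence[str],
    positions: Sequence[int],
    ref_alleles: Sequence[str],
    alt_alleles: Sequence[str],
    genotypes: np.ndarray,
    samples: Sequence[str],
) -> None:
    """Minimal haploid VCF 4.2 with GT fields; -1 genotypes become '.'."""
    genotypes = np.asarray(genotypes)
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, n in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, (c, pos) in enumerate(zip(chroms, positions)):
            gts = "\t".join(
                "." if g < 0 else str(int(g)) for g in genotypes[i]
            )
            fh.write(
                f"{c}\t{pos + 1}\t.\t{ref_alleles[i]}\t{alt_alleles[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a VCF with pysam; returns (chroms, positions, gts, samples).

    Haploid-coded inbred genotypes: 0 reference, 1 alternate, -1 missing.
    Heterozygous diploid calls are treated as missing (and counted): the
    analysis assumes inbred, effectively haploid accessions.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chroms, positions, rows = [], [], []
    n_het = 0
    for rec in vf:
        row = np.full(len(samples), -1, dtype=np.int8)
        for k, s in enumerate(samples):
            gt = rec.samples[s].get("GT", (None,))
            alleles = [a for a in gt if a is not None]
            if not alleles:
                continue
            if len(set(alleles)) > 1:
                n_het += 1
                continue
            row[k] = 1 if alleles[0] >= 1 else 0
        chroms.append(rec.chrom)
        positions.append(rec.pos - 1)  # back to 0-based
        rows.append(row)
    gts = (
        np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return np.array(chroms), np.array(positions, dtype=np.int64), gts, samples, n_het
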