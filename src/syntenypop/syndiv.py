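r"""Synteny diversity.

Synteny diversity quantifies how well genome collinearity is conserved
in a population, by analogy with nucleotide diversity: for every
unordered pair of genomes (i, j), :math:`\pi_{ij}` is the fraction of
positions in a region that are non-syntenic between i and j, and the
region's value combines the pairwise fractions.

Two conventions are supported:

``pairwise_mean`` (default)
    mean of :math:`\pi_{ij}` over the n(n-1)/2 unordered pairs — the
    "average fraction of non-syntenic sites within all pairwise genome
    comparisons". With one of eight genomes non-collinear to the other
    seven (which are mutually collinear) this gives 7/28 = 0.25.

``frequency_weighted``
    :math:`\sum_{ij} x_i x_j \pi_{ij}` over ordered pairs with
    :math:`\pi_{ii} = 0` and genome frequencies :math:`x_i` (1/n each by
    default). For equal frequencies the two conventions differ by
    exactly n/(n-1).

Values range from 0 (all genomes collinear) to 1 (complete absence of
collinearity between any pair, pairwise-mean convention).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synio import SyntenyMaskSet, _open_text, _pair_key

logger = logging.getLogger(__name__)

CONVENTIONS = ("pairwise_mean", "frequency_weighted")


@dataclass
class WindowProfile:
    """Windowed values along chromosomes (0-based half-open windows)."""

    data: pd.DataFrame  # columns: chrom, start, end, value [, extras]
    window_size: int
    step: int
    name: str = "pi_syn"

    def __post_init__(self):
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"profile frame needs columns {sorted(required)}")

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))

    def chrom_extent(self, chrom: str) -> int:
        sub = self.data[self.data["chrom"] == chrom]
        return int(sub["end"].max()) if len(sub) else 0

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write(f'track type=bedGraph name="{self.name}"\n')
            for row in self.data.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")

    @classmethod
    def from_tsv(cls, path, window_size: int, step: int, name: str = "pi_syn"):
        return cls(pd.read_csv(path, sep="\t"), window_size, step, name)


def make_windows(length: int, window_size: int, step: int) -> np.ndarray:
    """Sliding-window starts/ends over [0, length); the final window may be
    truncated and is normalized by its actual length downstream."""
    if step <= 0 or window_size < step:
        raise ValueError("require window_size >= step > 0")
    if window_size >= length:
        if window_size > length:
            logger.warning(
                "window size %d exceeds chromosome length %d; using one window",
                window_size,
                length,
            )
        return np.array([[0, length]], dtype=np.int64)
    n = int(np.ceil((length - window_size) / step)) + 1
    starts = step * np.arange(n, dtype=np.int64)
    ends = np.minimum(starts + window_size, length)
    return np.stack([starts, ends], axis=1)


def pair_weights(
    masks: SyntenyMaskSet, convention: str
) -> tuple[dict[tuple[str, str], float], float]:
    """(weight per unordered pair, final divisor) for a convention.

    Summing weight * pi_ij and dividing by the norm keeps the
    pairwise-mean exact for rational values (e.g. 7/28 = 0.25).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; one of {CONVENTIONS}")
    accs = masks.accessions
    if len(accs) < 2:
        raise ValueError("synteny diversity needs at least two accessions")
    if convention == "pairwise_mean":
        n_pairs = len(accs) * (len(accs) - 1) // 2
        weights = {
            _pair_key(a, b): 1.0 for a, b in itertools.combinations(accs, 2)
        }
        return weights, float(n_pairs)
    freq = dict(zip(accs, masks.frequencies))
    # ordered-pair sum with pi_ii = 0 collapses to 2 x_i x_j per unordered pair
    weights = {
        _pair_key(a, b): 2.0 * freq[a] * freq[b]
        for a, b in itertools.combinations(accs, 2)
    }
    return weights, 1.0


def pi_syn_window(
    masks: SyntenyMaskSet,
    chrom: str,
    start: int,
    end: int,
    convention: str = "pairwise_mean",
) -> float:
    """Synteny diversity of one interval [start, end) in frame coordinates."""
    length = masks.chrom_lengths[chrom]
    if not (0 <= start < end <= length):
        raise ValueError(
            f"interval [{start}, {end}) invalid on {chrom} of length {length}"
        )
    weights, norm = pair_weights(masks, convention)
    span = end - start
    value = 0.0
    for (a, b), w in weights.items():
        m = masks.mask(a, b)[chrom]
        nonsyn = span - int(m[start:end].sum())
        value += w * (nonsyn / span)
    return value / norm


def sliding_profile(
    masks: SyntenyMaskSet,
    window_size: int = 5000,
    step: int = 1000,
    convention: str = "pairwise_mean",
    chroms: Sequence[str] | None = None,
) -> WindowProfile:
    """Sliding-window synteny diversity across the genome.

    Defaults match the fine-scale analysis (5-kb windows, 1-kb step); a
    coarse overview uses 100-kb windows with a 50-kb step.
    """
    weights, norm = pair_weights(masks, convention)
    if chroms is None:
        chroms = list(masks.chrom_lengths)
    frames = []
    for chrom in chroms:
        length = masks.chrom_lengths[chrom]
        win = make_windows(length, window_size, step)
        starts, ends = win[:, 0], win[:, 1]
        spans = (ends - starts).astype(float)
        acc = np.zeros(len(win), dtype=float)
        for (a, b), w in weights.items():
            m = masks.mask(a, b)[chrom]
            cs = np.concatenate(([0], np.cumsum(~m, dtype=np.int64)))
            acc += w * (cs[ends] - cs[starts]) / spans
        acc /= norm
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": acc}
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return WindowProfile(data, window_size, step, name=f"pi_syn_{convention}")
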