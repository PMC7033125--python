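"""Region calling on windowed profiles.

HOT regions — hotspots of rearrangement — are runs of sliding windows
whose synteny diversity exceeds 0.5, with neighbouring runs merged when
closer than 2 kb. Window classification splits the genome into syntenic
(value 0), partially syntenic (0 < value <= 0.5) and HOT (> 0.5)
regions; the boundary rule at overlapping windows resolves toward the
higher-diversity label. Collapsed assembly regions are flagged from
normalized short-read coverage in 100-bp windows (>= 2-fold).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .synio import _open_text
from .syndiv import WindowProfile

LABELS = ("HOT", "SYN", "PARTIAL", "COLLAPSED")
_CLASS_PRIORITY = {"SYN": 0, "PARTIAL": 1, "HOT": 2}


@dataclass
class RegionSet:
    """Labelled genomic intervals with per-region window summaries."""

    data: pd.DataFrame  # columns: chrom, start, end, label, max_value, mean_value

    COLUMNS = ("chrom", "start", "end", "label", "max_value", "mean_value")

    def __post_init__(self):
        if len(self.data) == 0:
            self.data = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"RegionSet missing columns {sorted(missing)}")
        if (self.data["start"] >= self.data["end"]).any():
            raise ValueError("region start >= end")

    def __len__(self) -> int:
        return len(self.data)

    def select(self, label: str) -> "RegionSet":
        return RegionSet(self.data[self.data["label"] == label].reset_index(drop=True))

    def intervals(self, chrom: str, label: str | None = None) -> np.ndarray:
        sub = self.data[self.data["chrom"] == chrom]
        if label is not None:
            sub = sub[sub["label"] == label]
        return sub[["start", "end"]].to_numpy(dtype=np.int64).reshape(-1, 2)

    def total_span(self, label: str | None = None) -> int:
        sub = self.data if label is None else self.data[self.data["label"] == label]
        return int((sub["end"] - sub["start"]).sum())

    def to_bed(self, path) -> None:
        """BED6; score = 1000 * max window value, clipped to [0, 1000]."""
        with _open_text(path, "wt") as fh:
            for row in self.data.itertuples(index=False):
                score = int(np.clip(round(1000 * row.max_value), 0, 1000))
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\t{score}\t.\n"
                )

    @classmethod
    def from_rows(cls, rows) -> "RegionSet":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))


def _window_stats(windows: pd.DataFrame, start: int, end: int) -> tuple[float, float]:
    hit = windows[(windows["start"] < end) & (windows["end"] > start)]
    if len(hit) == 0:
        return float("nan"), float("nan")
    return float(hit["value"].max()), float(hit["value"].mean())


def call_hot_regions(
    profile: WindowProfile,
    threshold: float = 0.5,
    merge_dist: int = 2000,
    label: str = "HOT",
) -> RegionSet:
    """Call hotspot regions from a synteny-diversity profile.

    Seed intervals are the union of full spans of windows with value
    strictly above ``threshold``; seeds closer than ``merge_dist`` bp are
    merged. ``merge_dist=0`` reduces to the plain union of qualifying
    window spans.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if merge_dist < 0:
        raise ValueError("merge_dist must be >= 0")
    rows = []
    for chrom in profile.chroms():
        sub = profile.data[profile.data["chrom"] == chrom]
        qual = sub[sub["value"] > threshold]
        if len(qual) == 0:
            continue
        spans = qual[["start", "end"]].to_numpy(dtype=np.int64)
        merged = iv.merge(spans, merge_below=max(1, merge_dist))
        for s, e in merged:
            mx, mn = _window_stats(qual, s, e)
            rows.append((chrom, int(s), int(e), label, mx, mn))
    return RegionSet.from_rows(rows)


def classify_windows(
    profile: WindowProfile,
    hot_threshold: float = 0.5,
) -> RegionSet:
    """Partition each chromosome into SYN / PARTIAL / HOT regions.

    Default rule: SYN where the window value is 0, PARTIAL for values in
    (0, hot_threshold], HOT above. Overlapping windows with conflicting
    labels are resolved per position toward the higher-diversity label,
    and same-label runs are merged.
    """
    rows = []
    for chrom in profile.chroms():
        sub = profile.data[profile.data["chrom"] == chrom]
        extent = int(sub["end"].max())
        paint = np.zeros(extent, dtype=np.uint8)  # 0 SYN, 1 PARTIAL, 2 HOT
        for row in sub.itertuples(index=False):
            if row.value > hot_threshold:
                code = 2
            elif row.value > 0:
                code = 1
            else:
                continue
            seg = paint[row.start : row.end]
            np.maximum(seg, code, out=seg)
        # run-length encode the label track
        edges = np.flatnonzero(np.diff(paint)) + 1
        bounds = np.concatenate(([0], edges, [extent]))
        inv_priority = {v: k for k, v in _CLASS_PRIORITY.items()}
        for s, e in zip(bounds[:-1], bounds[1:]):
            label = inv_priority[int(paint[s])]
            mx, mn = _window_stats(sub, int(s), int(e))
            rows.append((chrom, int(s), int(e), label, mx, mn))
    return RegionSet.from_rows(rows)


def collapsed_regions(
    coverage,
    chrom: str = "chr1",
    window: int = 100,
    threshold: float = 2.0,
) -> RegionSet:
    """Collapsed-assembly candidates from a mean-normalized coverage track.

    ``coverage`` holds one value per non-overlapping ``window``-bp bin,
    normalized so the genome-wide expectation is 1.0. Bins at or above
    ``threshold`` (two-fold by default) are flagged and adjacent flagged
    bins merged.
    """
    cov = np.asarray(coverage, dtype=float)
    if (cov < 0).any():
        raise ValueError("negative coverage values")
    flagged = cov >= threshold
    rows = []
    if flagged.any():
        padded = np.concatenate(([False], flagged, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            vals = cov[s:e]
            rows.append(
                (chrom, int(s * window), int(e * window), "COLLAPSED",
                 float(vals.max()), float(vals.mean()))
            )
    return RegionSet.from_rows(rows)
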