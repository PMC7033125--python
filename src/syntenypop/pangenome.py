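"""Pan- and core-genome estimation and gene copy-number summaries.

Sequence level: the pan-genome of a genome subset starts from one
genome and iteratively adds, for each further genome, the sequence not
aligned (at >90% identity) to any previously added genome; non-aligned
pieces must stay longer than 100 bp, re-filtered after every
intersection. The core genome is the first genome minus everything it
fails to align against any other subset member. One point is evaluated
per non-empty subset (2^n - 1 points; 255 for eight genomes, i.e. the
sum of binomial coefficients C(8, n)), and per-n medians are fitted
with the saturating exponential y = A * exp(B * x) + C by damped least
squares.

Gene level: families from an orthogroup copy-number table; pan =
families present in at least one subset member, core = families present
in all of them.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import intervals as iv


class FitConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PanCurvePoint:
    n: int
    subset: tuple[str, ...]
    pan: int
    core: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("subset size must be >= 1")
        if self.core > self.pan:
            raise ValueError("core size exceeds pan size")


@dataclass
class PanCurveFit:
    A: float
    B: float
    C: float
    rss: float
    side: str
    n_obs: int
    converged: bool = True

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.A * np.exp(self.B * x) + self.C


def _pair_nonaligned(nonaligned, query: str, partner: str, min_len: int):
    try:
        raw = nonaligned[(query, partner)]
    except KeyError as exc:
        raise KeyError(
            f"missing non-aligned intervals for ordered pair ({query}, {partner})"
        ) from exc
    return iv.filter_longer(iv.merge(raw), min_len)


def pan_core_sequence(
    nonaligned: Mapping[tuple[str, str], np.ndarray],
    genome_sizes: Mapping[str, int],
    subset: Sequence[str],
    min_len: int = 100,
) -> PanCurvePoint:
    """Pan/core sizes (bp) for one ordered genome subset.

    ``nonaligned[(q, p)]`` are the intervals of genome q (q's own
    coordinates) without an alignment to genome p. The first subset
    member seeds the pan-genome and is the frame for the core.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("empty genome subset")
    first = subset[0]
    pan = int(genome_sizes[first])
    for k, g in enumerate(subset[1:], start=1):
        intersected = iv.intersect_many(
            [_pair_nonaligned(nonaligned, g, h, min_len) for h in subset[:k]]
        )
        novel = iv.filter_longer(intersected, min_len)  # re-filter after intersection
        pan += iv.total_length(novel)
    if len(subset) == 1:
        core = int(genome_sizes[first])
    else:
        lost = iv.merge(
            np.vstack(
                [_pair_nonaligned(nonaligned, first, h, min_len) for h in subset[1:]]
            )
        )
        core = int(genome_sizes[first]) - iv.total_length(lost)
    return PanCurvePoint(len(subset), subset, pan, core)


def enumerate_curve(
    nonaligned: Mapping[tuple[str, str], np.ndarray],
    genome_sizes: Mapping[str, int],
    accessions: Sequence[str] | None = None,
    min_len: int = 100,
    max_n: int = 12,
    force: bool = False,
) -> list[PanCurvePoint]:
    """One pan/core point per non-empty subset, in canonical sorted order."""
    if accessions is None:
        accessions = sorted(genome_sizes)
    accessions = list(accessions)
    if len(accessions) > max_n and not force:
        raise ValueError(
            f"{len(accessions)} genomes means {2 ** len(accessions) - 1} subsets; "
            "pass force=True to enumerate anyway"
        )
    points = []
    for n in range(1, len(accessions) + 1):
        for subset in itertools.combinations(accessions, n):
            points.append(pan_core_sequence(nonaligned, genome_sizes, subset, min_len))
    return points


def curve_frame(points: Sequence[PanCurvePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n": [p.n for p in points],
            "subset": [",".join(p.subset) for p in points],
            "pan": [p.pan for p in points],
            "core": [p.core for p in points],
        }
    )


def per_n_medians(points: Sequence[PanCurvePoint]) -> pd.DataFrame:
    df = curve_frame(points)
    med = df.groupby("n")[["pan", "core"]].median().reset_index()
    return med


def fit_exponential(x, y, side: str = "pan") -> PanCurveFit:
    """Least-squares fit of y = A * exp(B * x) + C to per-n medians.

    Initialization: C0 = last median, A0 = first median - C0, B0 = -0.3
    for the pan side or a log-slope estimate for the core side; then a
    Levenberg-style damped least squares (tolerance 1e-10, up to 10,000
    function evaluations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need medians at >= 4 distinct subset sizes")
    c0 = float(y[-1])
    a0 = float(y[0] - c0)
    if np.allclose(y, y.mean(), rtol=0, atol=1e-12 * max(1.0, abs(float(y.mean())))):
        # degenerate constant curve: amplitude zero, asymptote recovered
        c = float(y.mean())
        rss = float(((y - c) ** 2).sum())
        return PanCurveFit(0.0, -0.3, c, rss, side, len(y))
    b0 = -0.3
    if side == "core":
        resid = np.abs(y - c0)
        ok = resid > 0
        if ok.sum() >= 2:
            slope = np.polyfit(x[ok], np.log(resid[ok]), 1)[0]
            if np.isfinite(slope) and slope < 0:
                b0 = float(slope)

    def model(xv, a, b, c):
        return a * np.exp(b * xv) + c

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=[a0, b0, c0],
            method="lm",
            maxfev=10000,
            ftol=1e-10,
            xtol=1e-10,
            gtol=1e-10,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"exponential fit did not converge (p0=({a0}, {b0}, {c0})): {exc}"
        ) from exc
    rss = float(((y - model(x, *popt)) ** 2).sum())
    return PanCurveFit(float(popt[0]), float(popt[1]), float(popt[2]), rss, side, len(y))


# -- gene level ---------------------------------------------------------------

def read_orthogroup_table(path) -> pd.DataFrame:
    """Read a long-format TSV (family, accession, count) into a
    family x accession copy-count matrix."""
    long = pd.read_csv(path, sep="\t")
    table = long.pivot_table(
        index="family", columns="accession", values="count", fill_value=0
    ).astype(int)
    return _validated_table(table)


def write_orthogroup_table(table: pd.DataFrame, path) -> None:
    long = (
        table.stack()
        .rename_axis(["family", "accession"])
        .reset_index(name="count")
    )
    long.to_csv(path, sep="\t", index=False)


def _validated_table(table: pd.DataFrame) -> pd.DataFrame:
    if (table < 0).any().any():
        raise ValueError("negative copy counts")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("orthogroup table has families absent from every accession")
    return table


def gene_pan_core(table: pd.DataFrame, subset: Sequence[str]) -> PanCurvePoint:
    """Gene-family pan/core counts for one subset of accessions."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("empty accession subset")
    missing = [a for a in subset if a not in table.columns]
    if missing:
        raise KeyError(f"accessions absent from orthogroup table: {missing}")
    present = table[list(subset)] > 0
    pan = int(present.any(axis=1).sum())
    core = int(present.all(axis=1).sum())
    return PanCurvePoint(len(subset), subset, pan, core)


def gene_curve(table: pd.DataFrame, max_n: int = 12, force: bool = False) -> list[PanCurvePoint]:
    accs = sorted(table.columns)
    if len(accs) > max_n and not force:
        raise ValueError(f"{len(accs)} accessions; pass force=True to enumerate")
    return [
        gene_pan_core(table, subset)
        for n in range(1, len(accs) + 1)
        for subset in itertools.combinations(accs, n)
    ]


@dataclass
class CnvSummary:
    conserved: int
    variable: int
    shared_nonref: int
    specific_nonref: dict[str, int]

    @property
    def total_nonref(self) -> int:
        return self.shared_nonref + sum(self.specific_nonref.values())


def cnv_summary(table: pd.DataFrame, reference: str) -> CnvSummary:
    """Copy-number-variation summary relative to a reference accession.

    Conserved families have identical copy counts in every accession;
    the rest are variable. Non-reference families (absent from the
    reference, present elsewhere) split into shared (present in >= 2
    other accessions) and accession-specific (exactly one carrier).
    """
    table = _validated_table(table)
    if reference not in table.columns:
        raise KeyError(f"reference accession {reference!r} not in table")
    arr = table.to_numpy()
    conserved = int((arr == arr[:, :1]).all(axis=1).sum())
    variable = len(table) - conserved
    nonref = table[table[reference] == 0]
    carriers = (nonref.drop(columns=[reference]) > 0).sum(axis=1)
    shared = int((carriers >= 2).sum())
    specific: dict[str, int] = {}
    singles = nonref[carriers == 1]
    for acc in table.columns:
        if acc == reference:
            continue
        specific[acc] = int((singles[acc] > 0).sum())
    return CnvSummary(conserved, variable, shared, specific)
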