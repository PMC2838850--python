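"""Partition scored genes into QTL vs non-QTL regions and test score strata.

Genes are classified ``inside`` when their interval shares at least one base
with the union of QTL intervals on the same chromosome (1-based inclusive
coordinates).  Filtered genes are then stratified into half-open CGC-score
bins and each bin's inside/outside split is tested with a 1-df Pearson
goodness-of-fit against the genome-wide inside:outside proportion.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .cgc_scoring import DEFAULT_MIN_SCORE, ScoredGene, filter_min_score
from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneLocus",
    "QTLRegion",
    "ScoreBin",
    "DEFAULT_BIN_EDGES",
    "merged_qtl_intervals",
    "classify_gene",
    "classify_catalog",
    "bin_by_score",
    "bin_proportion_test",
    "partition_report",
    "PartitionReport",
    "load_catalog",
    "write_catalog",
    "load_qtls",
    "write_qtls",
]

#: lower edges of the CGC-score strata; the last bin is open-ended
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.1, 10, 20, 30, 50, 100, 200)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named chromosome."""

    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"interval start {self.start} < 1 (coordinates are 1-based)")
        if self.stop < self.start:
            raise ValidationError(f"interval stop {self.stop} < start {self.start}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.stop
            and other.start <= self.stop
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.stop <= self.stop
        )

    def __len__(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class GeneLocus:
    symbol: str
    interval: GenomicInterval


@dataclass(frozen=True)
class QTLRegion:
    symbol: str
    interval: GenomicInterval
    cross_id: str
    lod: float | None = None
    p_value: float | None = None


@dataclass
class ScoreBin:
    """A half-open CGC-score stratum [lower, upper) with its inside/outside split."""

    lower: float
    upper: float  # math.inf for the open-ended top bin
    n_inside: int = 0
    n_outside: int = 0
    chi2: float = math.nan
    p: float = math.nan
    testable: bool = False

    @property
    def n_total(self) -> int:
        return self.n_inside + self.n_outside

    @property
    def label(self) -> str:
        if math.isinf(self.upper):
            return f"{self.lower:g} -"
        return f"{self.lower:g} - {self.upper:g}"


def merged_qtl_intervals(qtls: Iterable[QTLRegion]) -> dict[str, list[tuple[int, int]]]:
    """Flatten possibly-overlapping QTLs into a sorted disjoint union per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for q in qtls:
        by_chrom.setdefault(q.interval.chrom, []).append((q.interval.start, q.interval.stop))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def classify_gene(
    locus: GeneLocus,
    qtls: Iterable[QTLRegion],
    *,
    overlap: str = "any",
) -> str:
    """Return ``"inside"`` or ``"outside"``.

    ``overlap="any"`` (default): inside iff the gene shares >= 1 base with at
    least one QTL on the same chromosome.  ``overlap="full"``: the gene must be
    entirely contained in the merged QTL union.  A gene overlapping several
    QTLs is inside exactly once either way.
    """
    merged = merged_qtl_intervals(qtls)
    return _classify_merged(locus, merged, overlap)


def _classify_merged(
    locus: GeneLocus, merged: Mapping[str, list[tuple[int, int]]], overlap: str
) -> str:
    if overlap not in ("any", "full"):
        raise ValidationError(f"unknown overlap mode {overlap!r}")
    ivs = merged.get(locus.interval.chrom)
    if not ivs:
        return "outside"
    g0, g1 = locus.interval.start, locus.interval.stop
    starts = [s for s, _ in ivs]
    i = bisect_right(starts, g1) - 1  # last block starting at or before the gene end
    if i < 0:
        return "outside"
    s, e = ivs[i]
    if overlap == "any":
        return "inside" if e >= g0 else "outside"
    return "inside" if (s <= g0 and g1 <= e) else "outside"


def classify_catalog(
    catalog: Iterable[GeneLocus],
    qtls: Iterable[QTLRegion],
    *,
    overlap: str = "any",
) -> dict[str, bool]:
    """Map each gene symbol to True when inside the QTL union."""
    merged = merged_qtl_intervals(qtls)
    return {g.symbol: _classify_merged(g, merged, overlap) == "inside" for g in catalog}


def bin_by_score(
    scored: Sequence[ScoredGene],
    inside: Mapping[str, bool],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> list[ScoreBin]:
    """Stratify already-filtered genes into half-open bins [lower, upper).

    ``edges`` are the ascending lower bounds; the last bin is open above.  A
    score below the lowest edge raises: the minimum-score filter must run
    first.
    """
    edges = sorted(edges)
    if len(edges) < 1:
        raise ValidationError("at least one bin edge required")
    bins = [
        ScoreBin(lower=lo, upper=(edges[i + 1] if i + 1 < len(edges) else math.inf))
        for i, lo in enumerate(edges)
    ]
    for s in scored:
        if s.cgc_score < edges[0]:
            raise ValidationError(
                f"gene {s.symbol!r} score {s.cgc_score} below lowest bin edge "
                f"{edges[0]}; apply filter_min_score first"
            )
        i = bisect_right(edges, s.cgc_score) - 1
        b = bins[i]
        if inside[s.symbol]:
            b.n_inside += 1
        else:
            b.n_outside += 1
    return bins


def bin_proportion_test(
    bin_: ScoreBin, total_inside: int, total_outside: int
) -> tuple[float, float]:
    """1-df Pearson goodness-of-fit of a bin's split against the overall proportion.

    Expected counts are the bin total apportioned by
    ``total_inside : total_outside``; no continuity correction.  An empty bin
    is flagged untestable (NaN, NaN) rather than raising.
    """
    total = total_inside + total_outside
    if total <= 0:
        raise ValidationError("totals must be positive")
    n = bin_.n_total
    if n == 0:
        bin_.chi2, bin_.p, bin_.testable = math.nan, math.nan, False
        return math.nan, math.nan
    exp_in = n * total_inside / total
    exp_out = n * total_outside / total
    if exp_in == 0 or exp_out == 0:
        # degenerate overall proportion: any split matches it trivially or not at all
        chi2 = 0.0 if (bin_.n_inside == n * (total_inside > 0)) else math.inf
        p = 1.0 if chi2 == 0.0 else 0.0
    else:
        chi2 = (bin_.n_inside - exp_in) ** 2 / exp_in + (bin_.n_outside - exp_out) ** 2 / exp_out
        p = float(stats.chi2.sf(chi2, df=1))
    bin_.chi2, bin_.p, bin_.testable = float(chi2), float(p), True
    return float(chi2), float(p)


@dataclass
class PartitionReport:
    """Per-bin inside/outside counts with test results plus the totals row."""

    bins: list[ScoreBin]
    total_inside: int
    total_outside: int
    excluded: list[str] = field(default_factory=list)

    @property
    def inside_percent(self) -> int:
        total = self.total_inside + self.total_outside
        if total == 0:
            return 0
        return round(100 * self.total_inside / total)

    @property
    def outside_percent(self) -> int:
        total = self.total_inside + self.total_outside
        if total == 0:
            return 0
        return 100 - self.inside_percent

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cgc_score": b.label,
                "n_inside": b.n_inside,
                "n_outside": b.n_outside,
                "chi2": b.chi2,
                "p": b.p,
            }
            for b in reversed(self.bins)  # highest stratum first, as conventionally printed
        ]
        rows.append(
            {
                "cgc_score": "Total",
                "n_inside": self.total_inside,
                "n_outside": self.total_outside,
                "chi2": math.nan,
                "p": math.nan,
            }
        )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_text(self) -> str:
        df = self.to_frame()
        lines = [df.to_string(index=False, na_rep="-", float_format=lambda v: f"{v:.4g}")]
        lines.append(
            f"inside: {self.inside_percent}%  outside: {self.outside_percent}%"
        )
        if self.excluded:
            lines.append(f"excluded (not in catalog): {', '.join(self.excluded)}")
        return "\n".join(lines)

    def summary(self) -> dict:
        return {
            "total_inside": self.total_inside,
            "total_outside": self.total_outside,
            "inside_percent": self.inside_percent,
            "bins": [
                {
                    "range": b.label,
                    "n_inside": b.n_inside,
                    "n_outside": b.n_outside,
                    "chi2": None if math.isnan(b.chi2) else b.chi2,
                    "p": None if math.isnan(b.p) else b.p,
                    "testable": b.testable,
                }
                for b in reversed(self.bins)
            ],
            "excluded": list(self.excluded),
        }


def partition_report(
    catalog: Sequence[GeneLocus],
    qtls: Sequence[QTLRegion],
    scored: Sequence[ScoredGene],
    *,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    min_score: float = DEFAULT_MIN_SCORE,
    overlap: str = "any",
) -> PartitionReport:
    """Classify, stratify and test all scored genes; the Table-1 style surface.

    Scored genes absent from the catalog are excluded with a warning and
    listed in ``report.excluded``.
    """
    known = {g.symbol for g in catalog}
    excluded = sorted({s.symbol for s in scored} - known)
    if excluded:
        logger.warning("%d scored genes missing from catalog: %s", len(excluded), excluded)
    usable = [s for s in scored if s.symbol in known]
    usable = filter_min_score(usable, min_score)
    inside = classify_catalog(catalog, qtls, overlap=overlap)
    total_inside = sum(1 for s in usable if inside[s.symbol])
    total_outside = len(usable) - total_inside
    bins = bin_by_score(usable, inside, edges)
    for b in bins:
        bin_proportion_test(b, total_inside, total_outside)
    return PartitionReport(
        bins=bins,
        total_inside=total_inside,
        total_outside=total_outside,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# catalog / QTL file I/O


def load_catalog(path: str | Path) -> list[GeneLocus]:
    """Read a gene catalog.

    TSV ``symbol<TAB>chrom<TAB>start<TAB>stop`` (1-based inclusive) by
    default; files ending in ``.bed`` are parsed as 6-column BED (0-based
    half-open, name in column 4) and converted.
    """
    path = Path(path)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 4:
            raise ValidationError(f"{path}: BED catalog needs >= 4 columns")
        for row in df.itertuples(index=False):
            chrom, start0, stop, name = row[0], int(row[1]), int(row[2]), str(row[3])
            loci.append(GeneLocus(name, GenomicInterval(str(chrom), start0 + 1, stop)))
    else:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["symbol", "chrom", "start", "stop"], dtype=str, skip_blank_lines=True,
        )
        for row in df.itertuples(index=False):
            loci.append(
                GeneLocus(str(row.symbol), GenomicInterval(str(row.chrom), int(row.start), int(row.stop)))
            )
    for g in loci:
        if g.symbol in seen:
            raise ValidationError(f"{path}: duplicate gene symbol {g.symbol!r}")
        seen.add(g.symbol)
    return loci


def write_catalog(catalog: Iterable[GeneLocus], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# symbol\tchrom\tstart\tstop\n")
        for g in catalog:
            fh.write(f"{g.symbol}\t{g.interval.chrom}\t{g.interval.start}\t{g.interval.stop}\n")


def load_qtls(path: str | Path) -> list[QTLRegion]:
    """Read a QTL table: ``symbol<TAB>cross_id<TAB>chrom<TAB>start<TAB>stop[<TAB>lod<TAB>p]``."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str, skip_blank_lines=True,
    )
    if df.shape[1] not in (5, 6, 7):
        raise ValidationError(f"{path}: QTL table needs 5-7 columns, got {df.shape[1]}")
    qtls: list[QTLRegion] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        vals = list(row)
        symbol, cross, chrom, start, stop = vals[:5]
        lod = float(vals[5]) if len(vals) > 5 and not pd.isna(vals[5]) else None
        p = float(vals[6]) if len(vals) > 6 and not pd.isna(vals[6]) else None
        key = (str(symbol), str(cross))
        if key in seen:
            raise ValidationError(f"{path}: duplicate QTL {key}")
        seen.add(key)
        qtls.append(
            QTLRegion(
                symbol=str(symbol),
                interval=GenomicInterval(str(chrom), int(start), int(stop)),
                cross_id=str(cross),
                lod=lod,
                p_value=p,
            )
        )
    if not qtls:
        raise DataError(f"{path}: no QTL rows")
    return qtls


def write_qtls(qtls: Iterable[QTLRegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# symbol\tcross\tchrom\tstart\tstop\tlod\tp\n")
        for q in qtls:
            lod = "" if q.lod is None else f"{q.lod:g}"
            p = "" if q.p_value is None else f"{q.p_value:g}"
            fh.write(
                f"{q.symbol}\t{q.cross_id}\t{q.interval.chrom}\t{q.interval.start}"
                f"\t{q.interval.stop}\t{lod}\t{p}\n"
            )
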