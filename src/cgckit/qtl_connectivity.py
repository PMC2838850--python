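"""Cross-referenced gene pairs connecting QTLs from two different crosses.

Record hyperlinks are folded into an undirected, deduplicated gene graph
restricted to genes lying inside QTLs.  For every QTL pair with one member
from each cross the observed number of connecting gene pairs is compared to
the number expected from QTL gene counts and the total cross-cross
connection count, via a Yates-corrected 2x2 chi-square.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cgc_scoring import GeneRecord, ScoredGene
from .errors import DataError, ValidationError
from .genome_partition import GeneLocus, QTLRegion, classify_catalog

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectionGraph",
    "QTLPairResult",
    "build_graph",
    "count_pairs",
    "expected_pairs",
    "yates_chisq_2x2",
    "holm_adjust",
    "significant_qtl_pairs",
    "connecting_gene_pairs",
    "filter_high_score_pairs",
    "pairs_to_frame",
    "write_pairs_tsv",
    "write_gene_pairs_tsv",
]

DEFAULT_SCORE_THRESHOLD = 50.0


@dataclass(frozen=True)
class _GraphStats:
    """One-pass aggregation over the edge set (cached on the graph)."""

    total_cross_cross: int
    # (q1, q2) -> number of distinct connecting gene pairs
    observed: dict[tuple[str, str], int]
    # q -> cross-cross edges with one endpoint in q, other endpoint in the opposite cross
    incident_q1: dict[str, int]
    incident_q2: dict[str, int]


@dataclass
class ConnectionGraph:
    """Undirected link graph over genes annotated with QTL membership.

    ``qtl_genes`` maps QTL symbol to its member gene symbols (by genomic
    overlap with the catalog); ``qtl_crosses`` maps QTL symbol to the cross
    labels it was mapped in (usually one, occasionally both).
    """

    cross1: str
    cross2: str
    qtl_genes: dict[str, frozenset[str]]
    qtl_crosses: dict[str, frozenset[str]]
    edges: frozenset[frozenset[str]]
    dropped_links: tuple[tuple[str, str], ...] = ()

    _gene_q1: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)
    _gene_q2: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)
    _stats: _GraphStats | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.cross1 == self.cross2:
            raise ValidationError("the two crosses must have distinct labels")
        g1: dict[str, list[str]] = {}
        g2: dict[str, list[str]] = {}
        for q in sorted(self.qtl_genes):
            crosses = self.qtl_crosses[q]
            for g in self.qtl_genes[q]:
                if self.cross1 in crosses:
                    g1.setdefault(g, []).append(q)
                if self.cross2 in crosses:
                    g2.setdefault(g, []).append(q)
        self._gene_q1 = {g: tuple(qs) for g, qs in g1.items()}
        self._gene_q2 = {g: tuple(qs) for g, qs in g2.items()}
        self._stats = None

    def qtls_of_cross(self, cross: str) -> list[str]:
        return sorted(q for q, cs in self.qtl_crosses.items() if cross in cs)

    def enumerate_pairs(self) -> list[tuple[str, str]]:
        """All (cross1 QTL, cross2 QTL) pairs, excluding a QTL paired with itself."""
        return [
            (q1, q2)
            for q1 in self.qtls_of_cross(self.cross1)
            for q2 in self.qtls_of_cross(self.cross2)
            if q1 != q2
        ]

    def stats(self) -> _GraphStats:
        if self._stats is not None:
            return self._stats
        observed = {pair: 0 for pair in self.enumerate_pairs()}
        inc1 = {q: 0 for q in self.qtls_of_cross(self.cross1)}
        inc2 = {q: 0 for q in self.qtls_of_cross(self.cross2)}
        total = 0
        empty: tuple[str, ...] = ()
        for e in self.edges:
            a, b = tuple(e)
            pairs_hit = set()
            qs1 = set()
            qs2 = set()
            for x, y in ((a, b), (b, a)):
                for q1 in self._gene_q1.get(x, empty):
                    for q2 in self._gene_q2.get(y, empty):
                        if q1 != q2:
                            pairs_hit.add((q1, q2))
                            qs1.add(q1)
                            qs2.add(q2)
            if not pairs_hit:
                continue
            total += 1
            for pair in pairs_hit:
                observed[pair] += 1
            for q in qs1:
                inc1[q] += 1
            for q in qs2:
                inc2[q] += 1
        self._stats = _GraphStats(
            total_cross_cross=total, observed=observed, incident_q1=inc1, incident_q2=inc2
        )
        return self._stats


def build_graph(
    records: Iterable[GeneRecord],
    qtls: Sequence[QTLRegion],
    catalog: Sequence[GeneLocus],
    *,
    crosses: tuple[str, str] | None = None,
    overlap: str = "any",
) -> ConnectionGraph:
    """Fold record hyperlinks into an undirected graph over in-QTL genes.

    Link targets that do not resolve to a catalog gene are logged and
    dropped; edges with an endpoint outside every QTL are discarded.  The two
    cross labels are taken from the QTL table unless given explicitly.
    """
    labels = sorted({q.cross_id for q in qtls})
    if crosses is None:
        if len(labels) != 2:
            raise DataError(f"expected QTLs from exactly two crosses, found {labels}")
        crosses = (labels[0], labels[1])

    known = {g.symbol for g in catalog}
    # a QTL mapped in both crosses appears once per cross in the table;
    # merge to a single node carrying both labels
    qtl_genes: dict[str, set[str]] = {}
    qtl_crosses: dict[str, set[str]] = {}
    for q in qtls:
        inside = classify_catalog(catalog, [q], overlap=overlap)
        members = {g for g, ok in inside.items() if ok}
        if q.symbol in qtl_genes and qtl_genes[q.symbol] != members:
            raise DataError(f"QTL {q.symbol!r} listed twice with different coordinates")
        qtl_genes.setdefault(q.symbol, set()).update(members)
        qtl_crosses.setdefault(q.symbol, set()).add(q.cross_id)

    in_any_qtl = set().union(*qtl_genes.values()) if qtl_genes else set()
    edges: set[frozenset[str]] = set()
    dropped: list[tuple[str, str]] = []
    for rec in records:
        for target in rec.links:
            if target not in known:
                dropped.append((rec.symbol, target))
                continue
            if rec.symbol in in_any_qtl and target in in_any_qtl:
                edges.add(frozenset((rec.symbol, target)))
    if dropped:
        logger.warning("dropped %d unresolvable link targets", len(dropped))
    return ConnectionGraph(
        cross1=crosses[0],
        cross2=crosses[1],
        qtl_genes={q: frozenset(g) for q, g in qtl_genes.items()},
        qtl_crosses={q: frozenset(c) for q, c in qtl_crosses.items()},
        edges=frozenset(edges),
        dropped_links=tuple(dropped),
    )


def _require_opposite(graph: ConnectionGraph, qtl1: str, qtl2: str) -> None:
    c1 = graph.qtl_crosses.get(qtl1)
    c2 = graph.qtl_crosses.get(qtl2)
    if c1 is None or c2 is None:
        raise ValidationError(f"unknown QTL in pair ({qtl1!r}, {qtl2!r})")
    if qtl1 == qtl2 or not any(a != b for a in c1 for b in c2):
        raise ValidationError(f"QTLs {qtl1!r} and {qtl2!r} are not from opposite crosses")


def _as_pair_key(graph: ConnectionGraph, qtl1: str, qtl2: str) -> tuple[str, str]:
    observed = graph.stats().observed
    if (qtl1, qtl2) in observed:
        return (qtl1, qtl2)
    if (qtl2, qtl1) in observed:
        return (qtl2, qtl1)
    raise ValidationError(f"({qtl1!r}, {qtl2!r}) is not a cross1 x cross2 QTL pair")


def count_pairs(graph: ConnectionGraph, qtl1: str, qtl2: str) -> int:
    """Distinct unordered gene pairs (one gene per QTL) joined by an edge."""
    _require_opposite(graph, qtl1, qtl2)
    return graph.stats().observed[_as_pair_key(graph, qtl1, qtl2)]


def _pair_weights(graph: ConnectionGraph) -> dict[tuple[str, str], int]:
    return {
        (q1, q2): len(graph.qtl_genes[q1]) * len(graph.qtl_genes[q2])
        for q1, q2 in graph.enumerate_pairs()
    }


def expected_pairs(graph: ConnectionGraph, qtl1: str, qtl2: str) -> float:
    """Expected connecting pairs under proportional allocation.

    The total cross-cross connection count T is spread over all
    cross1 x cross2 QTL pairs proportionally to the product of their gene
    counts, so the expectations sum back to T.  Returns NaN (untestable)
    when T is zero.
    """
    _require_opposite(graph, qtl1, qtl2)
    t = graph.stats().total_cross_cross
    if t == 0:
        return math.nan
    weights = _pair_weights(graph)
    denom = sum(weights.values())
    if denom == 0:
        return math.nan
    return t * weights[_as_pair_key(graph, qtl1, qtl2)] / denom


def yates_chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table [[a, b], [c, d]].

    ``chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))`` with the
    statistic clamped to 0 when ``|ad - bc| <= N/2``; p from the 1-df
    chi-square.  A zero margin forces ``ad - bc = 0``, so such tables fall
    under the clamp and score (0, 1) -- a degenerate table (e.g. a single
    QTL pair holding every edge) is trivially null rather than an error.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValidationError("2x2 cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValidationError("2x2 table is empty")
    diff = abs(a * d - b * c)
    if diff <= n / 2:
        return 0.0, 1.0
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * (diff - n / 2) ** 2 / margins
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values; NaNs pass through untouched."""
    idx = [i for i, p in enumerate(pvals) if not math.isnan(p)]
    m = len(idx)
    out = [math.nan] * len(pvals)
    order = sorted(idx, key=lambda i: pvals[i])
    running = 0.0
    for rank, i in enumerate(order):
        adj = min(1.0, (m - rank) * pvals[i])
        running = max(running, adj)
        out[i] = running
    return out


@dataclass
class QTLPairResult:
    qtl1: str
    qtl2: str
    n1: int
    n2: int
    observed: int
    expected: float
    chi2_yates: float
    p: float
    p_holm: float = math.nan
    flag: str = ""  # "significant", "near_miss", "untestable" or ""


def significant_qtl_pairs(
    graph: ConnectionGraph,
    alpha: float = 0.05,
    near_miss: float = 0.06,
) -> list[QTLPairResult]:
    """Test every cross1 x cross2 QTL pair for an excess of connecting pairs.

    The 2x2 table for a pair (q1, q2) splits the cross-cross edges into:
    between q1 and q2 (a); from q1 elsewhere (b); into q2 from elsewhere (c);
    all remaining (d).  Pairs with observed > expected and p < alpha are
    flagged ``significant``; alpha <= p < near_miss gives ``near_miss``.
    Results are sorted by ascending p; Holm-adjusted p-values are reported
    alongside but do not drive the flags.
    """
    st = graph.stats()
    t = st.total_cross_cross
    weights = _pair_weights(graph)
    denom = sum(weights.values())
    results: list[QTLPairResult] = []
    for q1, q2 in graph.enumerate_pairs():
        n1 = len(graph.qtl_genes[q1])
        n2 = len(graph.qtl_genes[q2])
        a = st.observed[(q1, q2)]
        exp = t * weights[(q1, q2)] / denom if (t > 0 and denom > 0) else math.nan
        if t == 0:
            results.append(
                QTLPairResult(q1, q2, n1, n2, a, exp, math.nan, math.nan, flag="untestable")
            )
            continue
        b = st.incident_q1[q1] - a
        c = st.incident_q2[q2] - a
        d = t - a - b - c
        if min(b, c, d) < 0:  # multi-membership can over-count margins; flag, don't test
            results.append(
                QTLPairResult(q1, q2, n1, n2, a, exp, math.nan, math.nan, flag="untestable")
            )
            continue
        chi2, p = yates_chisq_2x2(a, b, c, d)
        flag = ""
        if math.isnan(p):
            flag = "untestable"
        elif a > exp and p < alpha:
            flag = "significant"
        elif a > exp and p < near_miss:
            flag = "near_miss"
        results.append(QTLPairResult(q1, q2, n1, n2, a, exp, chi2, p, flag=flag))
    adj = holm_adjust([r.p for r in results])
    for r, ph in zip(results, adj):
        r.p_holm = ph
    results.sort(key=lambda r: (math.inf if math.isnan(r.p) else r.p, r.qtl1, r.qtl2))
    return results


def connecting_gene_pairs(graph: ConnectionGraph, qtl1: str, qtl2: str) -> list[tuple[str, str]]:
    """The actual connecting gene pairs behind ``count_pairs``."""
    _require_opposite(graph, qtl1, qtl2)
    q1, q2 = _as_pair_key(graph, qtl1, qtl2)
    m1, m2 = graph.qtl_genes[q1], graph.qtl_genes[q2]
    out = []
    for e in graph.edges:
        a, b = tuple(e)
        if a in m1 and b in m2:
            out.append((a, b))
        elif b in m1 and a in m2:
            out.append((b, a))
    return sorted(out)


def filter_high_score_pairs(
    pairs: Iterable[tuple[str, str]],
    scores: Mapping[str, float] | Mapping[str, ScoredGene],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[tuple[str, str]]:
    """Keep gene pairs where at least one member scores >= threshold (inclusive)."""

    def score_of(sym: str) -> float:
        try:
            v = scores[sym]
        except KeyError as exc:
            raise DataError(f"gene {sym!r} has no CGC score") from exc
        return v.cgc_score if isinstance(v, ScoredGene) else float(v)

    return [p for p in pairs if max(score_of(p[0]), score_of(p[1])) >= threshold]


# ---------------------------------------------------------------------------
# tabular output


def pairs_to_frame(results: Sequence[QTLPairResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "qtl1": r.qtl1,
                "n1": r.n1,
                "qtl2": r.qtl2,
                "n2": r.n2,
                "observed": r.observed,
                "expected": r.expected,
                "chi2": r.chi2_yates,
                "p": r.p,
                "p_holm": r.p_holm,
                "flag": r.flag,
            }
            for r in results
        ],
        columns=["qtl1", "n1", "qtl2", "n2", "observed", "expected", "chi2", "p", "p_holm", "flag"],
    )


def write_pairs_tsv(results: Sequence[QTLPairResult], path: str | Path) -> None:
    pairs_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_gene_pairs_tsv(
    graph: ConnectionGraph,
    results: Sequence[QTLPairResult],
    scores: Mapping[str, float],
    path: str | Path,
    *,
    threshold: float | None = None,
) -> None:
    """Per-pair connecting genes with their scores.

    When ``threshold`` is given, only gene pairs whose best member reaches it
    are written.
    """
    rows = []
    for r in results:
        gps = connecting_gene_pairs(graph, r.qtl1, r.qtl2)
        if threshold is not None:
            gps = filter_high_score_pairs(gps, scores, threshold)
        for g1, g2 in gps:
            rows.append(
                {
                    "qtl1": r.qtl1,
                    "gene1": g1,
                    "score1": scores.get(g1, np.nan),
                    "qtl2": r.qtl2,
                    "gene2": g2,
                    "score2": scores.get(g2, np.nan),
                }
            )
    pd.DataFrame(
        rows, columns=["qtl1", "gene1", "score1", "qtl2", "gene2", "score2"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
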