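"""Seeded generators for gene catalogs, QTL sets, record corpora and link tables.

Every stage draws from its own substream of a single seed, so regenerating
one stage never perturbs another.  The generated files use exactly the
formats the analysis modules consume, with controllable enrichment effects:
``inside_enrichment`` raises keyword rates for genes inside QTLs and
``pair_excess`` plants an edge-rate excess between designated QTL pairs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._wordlist import FILLER_WORDS
from .cgc_scoring import GeneRecord
from .errors import DataError, ValidationError
from .genome_partition import GeneLocus, GenomicInterval, QTLRegion, classify_catalog
from .keyword_model import Keyword

__all__ = ["SyntheticConfig", "generate_genome", "generate_corpus", "generate_links", "simulate"]

_GENOME_STREAM, _CORPUS_STREAM, _LINKS_STREAM = 11, 22, 33


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic universe; defaults give a mid-sized null model."""

    n_chromosomes: int = 5
    chrom_length: int = 10_000_000
    n_genes: int = 500
    n_qtls_per_cross: tuple[int, int] = (4, 4)
    qtl_coverage_fraction: float = 0.5
    keyword_set_size: int = 49
    # log-uniform weight distribution over [low, high]
    keyword_weight_low: float = 0.5
    keyword_weight_high: float = 90.0
    baseline_keyword_rate: float = 0.05
    inside_enrichment: float = 1.0
    edge_count: int = 500
    pair_excess: Mapping[tuple[str, str], float] = field(default_factory=dict)
    gene_length: int = 5_000
    filler_tokens_mean: float = 25.0
    n_overlapping_qtls: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.qtl_coverage_fraction <= 1.0:
            raise ValidationError("qtl_coverage_fraction must be in (0, 1]")
        if self.baseline_keyword_rate < 0 or self.inside_enrichment < 0:
            raise ValidationError("rates must be non-negative")
        if not 0 < self.keyword_weight_low <= self.keyword_weight_high <= 100:
            raise ValidationError("keyword weights must satisfy 0 < low <= high <= 100")
        if min(self.n_chromosomes, self.n_genes) < 1:
            raise ValidationError("need at least one chromosome and one gene")
        object.__setattr__(self, "n_qtls_per_cross", tuple(self.n_qtls_per_cross))
        object.__setattr__(self, "pair_excess", dict(self.pair_excess))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["pair_excess"] = {f"{k[0]}|{k[1]}": v for k, v in self.pair_excess.items()}
        return d


def _split_integer(rng: np.random.Generator, total: int, parts: int, minimum: int) -> np.ndarray:
    """Random composition of ``total`` into ``parts`` integers, each >= minimum."""
    if parts == 0:
        return np.zeros(0, dtype=np.int64)
    spare = total - parts * minimum
    if spare < 0:
        raise DataError(f"cannot split {total} into {parts} parts of at least {minimum}")
    cuts = rng.multinomial(spare, np.full(parts, 1.0 / parts))
    return cuts + minimum


def generate_genome(config: SyntheticConfig) -> tuple[list[GeneLocus], list[QTLRegion]]:
    """Place genes uniformly and tile QTL blocks to hit the coverage target.

    The union of QTL intervals covers ``qtl_coverage_fraction`` of the genome
    almost exactly: non-overlapping backbone blocks are laid down per
    chromosome with random gaps, then ``n_overlapping_qtls`` extra QTLs are
    nested inside random backbone blocks so that some QTLs deliberately
    overlap without changing the union.
    """
    rng = config.rng(_GENOME_STREAM)
    n_chrom, length = config.n_chromosomes, config.chrom_length
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]

    gene_len = min(config.gene_length, length)
    genes: list[GeneLocus] = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        chrom = chroms[rng.integers(n_chrom)]
        start = int(rng.integers(1, length - gene_len + 2))
        genes.append(
            GeneLocus(
                symbol=f"g{i + 1:0{width}d}",
                interval=GenomicInterval(chrom, start, start + gene_len - 1),
            )
        )

    k1, k2 = config.n_qtls_per_cross
    total_qtls = k1 + k2
    if total_qtls == 0:
        return genes, []

    n_nested = min(config.n_overlapping_qtls, total_qtls - 1)
    n_blocks = total_qtls - n_nested
    covered_total = round(config.qtl_coverage_fraction * n_chrom * length)

    # spread backbone blocks over chromosomes; each loaded chromosome gets the
    # same coverage fraction so no chromosome overflows
    order = rng.permutation(n_chrom)
    blocks_per_chrom = np.zeros(n_chrom, dtype=int)
    for i in range(n_blocks):
        blocks_per_chrom[order[i % n_chrom]] += 1
    loaded = blocks_per_chrom > 0
    per_chrom_cover = np.zeros(n_chrom, dtype=np.int64)
    if loaded.sum() == 0:
        raise DataError("no QTL blocks to place")
    share = covered_total / loaded.sum()
    if share > length:
        raise DataError(
            f"coverage target infeasible: {covered_total} bases over "
            f"{int(loaded.sum())} chromosome(s) of length {length}"
        )
    per_chrom_cover[loaded] = int(share)
    # distribute rounding remainder
    rem = covered_total - int(per_chrom_cover.sum())
    for idx in np.flatnonzero(loaded):
        if rem <= 0:
            break
        add = min(rem, length - per_chrom_cover[idx])
        per_chrom_cover[idx] += add
        rem -= add

    min_block = max(1, min(1000, length // (2 * max(1, n_blocks))))
    intervals: list[GenomicInterval] = []
    for ci, chrom in enumerate(chroms):
        b = int(blocks_per_chrom[ci])
        if b == 0:
            continue
        cover = int(per_chrom_cover[ci])
        block_lens = _split_integer(rng, cover, b, min(min_block, cover // b or 1))
        gap_total = length - cover
        gaps = _split_integer(rng, gap_total, b + 1, 0)
        pos = 1
        for j in range(b):
            pos += int(gaps[j])
            intervals.append(GenomicInterval(chrom, pos, pos + int(block_lens[j]) - 1))
            pos += int(block_lens[j])

    # nested QTLs: strict sub-intervals of random backbone blocks
    for _ in range(n_nested):
        host = intervals[rng.integers(len(intervals))]
        span = len(host)
        sub_len = max(1, int(span * rng.uniform(0.4, 0.9)))
        off = int(rng.integers(0, span - sub_len + 1))
        intervals.append(
            GenomicInterval(host.chrom, host.start + off, host.start + off + sub_len - 1)
        )

    perm = rng.permutation(total_qtls)
    qtls: list[QTLRegion] = []
    for rank, idx in enumerate(perm):
        cross = "cross1" if rank < k1 else "cross2"
        num = rank + 1 if rank < k1 else rank - k1 + 1
        lod = float(np.round(rng.uniform(2.0, 12.0), 1))
        qtls.append(
            QTLRegion(
                symbol=f"Q{1 if cross == 'cross1' else 2}_{num:02d}",
                interval=intervals[idx],
                cross_id=cross,
                lod=lod,
                p_value=float(10.0 ** -rng.uniform(2.0, 8.0)),
            )
        )
    return genes, qtls


def _keyword_terms(n: int) -> list[str]:
    # every 7th term is a two-token phrase to exercise multi-word matching;
    # base tokens never collide with single-token terms or filler words
    return [
        f"kw{i:03d} syndrome" if i % 7 == 0 else f"kw{i:03d}"
        for i in range(n)
    ]


def generate_corpus(
    config: SyntheticConfig,
    catalog: Sequence[GeneLocus],
    qtls: Sequence[QTLRegion],
) -> tuple[list[Keyword], list[GeneRecord]]:
    """Draw a keyword set and per-gene keyword-bearing text.

    Keyword ``k`` enters a gene's text with probability
    ``baseline_keyword_rate * inside_enrichment`` (capped at 1) when the gene
    lies inside the QTL union, else ``baseline_keyword_rate``.  Text is a
    shuffled bag of included keyword phrases plus filler tokens.
    """
    rng = config.rng(_CORPUS_STREAM)
    k = config.keyword_set_size
    terms = _keyword_terms(k)
    low, high = config.keyword_weight_low, config.keyword_weight_high
    weights = np.exp(rng.uniform(math.log(low), math.log(high), size=k))
    keywords = [Keyword(term=t, weight=float(np.round(w, 3))) for t, w in zip(terms, weights)]

    inside = classify_catalog(catalog, qtls)
    p_out = min(1.0, config.baseline_keyword_rate)
    p_in = min(1.0, config.baseline_keyword_rate * config.inside_enrichment)

    records: list[GeneRecord] = []
    for gene in catalog:
        p = p_in if inside[gene.symbol] else p_out
        mask = rng.random(k) < p
        units = [terms[i] for i in np.flatnonzero(mask)]
        n_filler = int(rng.poisson(config.filler_tokens_mean))
        units.extend(rng.choice(FILLER_WORDS, size=n_filler, replace=True))
        rng.shuffle(units)
        records.append(GeneRecord(symbol=gene.symbol, text=" ".join(units)))
    return keywords, records


def generate_links(
    config: SyntheticConfig,
    catalog: Sequence[GeneLocus],
    qtls: Sequence[QTLRegion],
) -> list[tuple[str, str]]:
    """Sample ``edge_count`` distinct undirected cross-cross gene pairs.

    Candidate pairs are (gene in a cross1 QTL) x (gene in a cross2 QTL);
    sampling weight is 1, multiplied by the ``pair_excess`` factor of any
    designated (QTL1, QTL2) pair containing the genes (max over designations;
    ``inf`` confines all edges to that pair).  Weighted sampling without
    replacement uses Gumbel top-k keys.
    """
    rng = config.rng(_LINKS_STREAM)
    if config.edge_count == 0:
        return []
    symbols = [g.symbol for g in catalog]
    sym_index = {s: i for i, s in enumerate(symbols)}
    qtl_members: dict[str, list[int]] = {}
    cross_of: dict[str, set[str]] = {}
    for q in qtls:
        m = classify_catalog(catalog, [q])
        qtl_members.setdefault(q.symbol, sorted(sym_index[s] for s, ok in m.items() if ok))
        cross_of.setdefault(q.symbol, set()).add(q.cross_id)

    side1 = sorted({i for q, cs in cross_of.items() if "cross1" in cs for i in qtl_members[q]})
    side2 = sorted({i for q, cs in cross_of.items() if "cross2" in cs for i in qtl_members[q]})
    if not side1 or not side2:
        raise DataError("no candidate genes on one of the crosses; cannot place links")

    a = np.repeat(np.array(side1), len(side2))
    b = np.tile(np.array(side2), len(side1))
    keep = a != b
    a, b = a[keep], b[keep]
    # canonical unordered encoding; genes in both crosses would otherwise
    # produce the same pair twice
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    codes = lo.astype(np.int64) * len(symbols) + hi
    codes, first = np.unique(codes, return_index=True)
    lo, hi = lo[first], hi[first]

    w = np.ones(len(codes))
    for (q1, q2), factor in config.pair_excess.items():
        if q1 not in qtl_members or q2 not in qtl_members:
            raise DataError(f"pair_excess names unknown QTL pair ({q1!r}, {q2!r})")
        if factor < 0:
            raise ValidationError("pair_excess factors must be >= 0")
        m1 = np.zeros(len(symbols), dtype=bool)
        m1[qtl_members[q1]] = True
        m2 = np.zeros(len(symbols), dtype=bool)
        m2[qtl_members[q2]] = True
        hit = (m1[lo] & m2[hi]) | (m2[lo] & m1[hi])
        w[hit] = np.maximum(w[hit], factor)

    eligible = w > 0
    n_eligible = int(eligible.sum())
    if config.edge_count > n_eligible:
        raise DataError(
            f"edge_count {config.edge_count} exceeds {n_eligible} distinct candidate pairs"
        )
    with np.errstate(divide="ignore"):
        keys = np.where(np.isinf(w), np.inf, np.log(np.where(eligible, w, 1.0)))
    keys = keys + rng.gumbel(size=len(codes))
    keys[~eligible] = -np.inf
    top = np.argpartition(-keys, config.edge_count - 1)[: config.edge_count]
    pairs = sorted((symbols[int(lo[i])], symbols[int(hi[i])]) for i in top)
    return pairs


def attach_links(
    records: Sequence[GeneRecord], links: Iterable[tuple[str, str]]
) -> list[GeneRecord]:
    """Embed undirected links into record ``links`` fields (on the first symbol)."""
    outgoing: dict[str, list[str]] = {}
    for a, b in links:
        outgoing.setdefault(a, []).append(b)
    return [
        GeneRecord(
            symbol=r.symbol,
            text=r.text,
            links=tuple(sorted(set(outgoing.get(r.symbol, ())))),
        )
        for r in records
    ]


def simulate(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate all stages and write them in the pipeline's file formats."""
    from .cgc_scoring import write_corpus_jsonl, write_links_tsv
    from .genome_partition import write_catalog, write_qtls
    from .keyword_model import write_keywords

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog, qtls = generate_genome(config)
    keywords, records = generate_corpus(config, catalog, qtls)
    links = generate_links(config, catalog, qtls) if qtls else []
    records = attach_links(records, links)

    paths = {
        "catalog": out / "catalog.tsv",
        "qtls": out / "qtls.tsv",
        "keywords": out / "keywords.tsv",
        "corpus": out / "corpus.jsonl",
        "links": out / "links.tsv",
        "manifest": out / "manifest.json",
    }
    write_catalog(catalog, paths["catalog"])
    if qtls:
        write_qtls(qtls, paths["qtls"])
    else:
        paths["qtls"].write_text("# symbol\tcross\tchrom\tstart\tstop\tlod\tp\n")
    write_keywords(keywords, paths["keywords"])
    write_corpus_jsonl(records, paths["corpus"])
    write_links_tsv(links, paths["links"])
    paths["manifest"].write_text(json.dumps(config.to_manifest(), indent=2) + "\n")
    return paths
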