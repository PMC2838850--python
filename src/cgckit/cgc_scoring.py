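"""Score gene records by summed keyword weights (the CGC score) and rank them.

Each record is free descriptive text plus outgoing hyperlinks to other gene
symbols.  A keyword contributes its weight at most once per record no matter
how often it occurs; matching is case-insensitive on whole-token boundaries
by default (multi-word keywords match as contiguous token runs), with a
``substring`` mode available.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .keyword_model import Keyword

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "ScoredGene",
    "tokenize",
    "cgc_score",
    "rank_genes",
    "filter_min_score",
    "load_corpus_jsonl",
    "write_corpus_jsonl",
    "load_corpus_dir",
    "load_links_tsv",
    "write_links_tsv",
    "write_scored_tsv",
    "load_scored_tsv",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

DEFAULT_MIN_SCORE = 0.1


@dataclass(frozen=True)
class GeneRecord:
    """A gene's descriptive text and its outgoing hyperlinks."""

    symbol: str
    text: str = ""
    links: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene record symbol must be non-empty")
        links = tuple(self.links)
        if len(set(links)) != len(links):
            raise ValidationError(f"record {self.symbol!r}: duplicate links")
        if self.symbol in links:
            raise ValidationError(f"record {self.symbol!r}: self-link not allowed")
        object.__setattr__(self, "links", links)


@dataclass(frozen=True)
class ScoredGene:
    symbol: str
    cgc_score: float
    matched_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "matched_terms", frozenset(self.matched_terms))


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens; everything else is a separator."""
    return _TOKEN_RE.findall(text.lower())


def _match_token(kw_tokens: Sequence[str], tokens: Sequence[str], token_set: set[str]) -> bool:
    if len(kw_tokens) == 1:
        return kw_tokens[0] in token_set
    if not all(t in token_set for t in kw_tokens):
        return False
    k = len(kw_tokens)
    first = kw_tokens[0]
    return any(
        tokens[i] == first and tuple(tokens[i : i + k]) == tuple(kw_tokens)
        for i in range(len(tokens) - k + 1)
    )


def cgc_score(
    record: GeneRecord,
    keywords: Iterable[Keyword],
    *,
    match: str = "token",
) -> ScoredGene:
    """Sum the weights of all distinct keywords found in the record text.

    Parameters
    ----------
    record
        The gene record to score; empty text scores 0.
    keywords
        A validated keyword set.
    match
        ``"token"`` (default) requires whole-token matches, so ``arthritis``
        does not hit inside ``osteoarthritis``; ``"substring"`` is a plain
        case-insensitive substring search.
    """
    if match not in ("token", "substring"):
        raise ValidationError(f"unknown match mode {match!r}")
    matched: set[str] = set()
    score = 0.0
    if match == "token":
        tokens = tokenize(record.text)
        token_set = set(tokens)
        for kw in keywords:
            if _match_token(tokenize(kw.term), tokens, token_set):
                matched.add(kw.term)
                score += kw.weight
    else:
        text = record.text.lower()
        for kw in keywords:
            if kw.term in text:
                matched.add(kw.term)
                score += kw.weight
    return ScoredGene(symbol=record.symbol, cgc_score=score, matched_terms=frozenset(matched))


def rank_genes(
    records: Iterable[GeneRecord],
    keywords: Iterable[Keyword],
    *,
    match: str = "token",
) -> list[ScoredGene]:
    """Score every record and sort descending by score, ties by symbol."""
    keywords = tuple(keywords)
    scored = [cgc_score(r, keywords, match=match) for r in records]
    scored.sort(key=lambda s: (-s.cgc_score, s.symbol))
    return scored


def filter_min_score(
    scored: Iterable[ScoredGene], min_score: float = DEFAULT_MIN_SCORE
) -> list[ScoredGene]:
    """Keep genes whose score is at least ``min_score`` (inclusive)."""
    if min_score < 0:
        raise ValidationError("min_score must be >= 0")
    return [s for s in scored if s.cgc_score >= min_score]


# ---------------------------------------------------------------------------
# corpus / scored-gene I/O


def load_corpus_jsonl(path: str | Path) -> list[GeneRecord]:
    """Read a JSON-lines corpus: one ``{"symbol", "text", "links"}`` per line."""
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            rec = GeneRecord(
                symbol=obj["symbol"],
                text=obj.get("text", ""),
                links=tuple(obj.get("links", ())),
            )
            if rec.symbol in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate symbol {rec.symbol!r}")
            seen.add(rec.symbol)
            records.append(rec)
    return records


def write_corpus_jsonl(records: Iterable[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {"symbol": rec.symbol, "text": rec.text, "links": list(rec.links)}
                )
                + "\n"
            )


def load_corpus_dir(directory: str | Path, links_path: str | Path | None = None) -> list[GeneRecord]:
    """Read a directory of per-gene ``<symbol>.txt`` files plus an optional links TSV."""
    directory = Path(directory)
    links: dict[str, list[str]] = {}
    if links_path is not None:
        for frm, to in load_links_tsv(links_path):
            links.setdefault(frm, []).append(to)
    records = []
    for txt in sorted(directory.glob("*.txt")):
        symbol = txt.stem
        records.append(
            GeneRecord(symbol=symbol, text=txt.read_text(), links=tuple(links.get(symbol, ())))
        )
    return records


def load_links_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["from", "to"], dtype=str,
        skip_blank_lines=True,
    )
    return [(str(a), str(b)) for a, b in zip(df["from"], df["to"])]


def write_links_tsv(links: Iterable[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# from\tto\n")
        for a, b in links:
            fh.write(f"{a}\t{b}\n")


def write_scored_tsv(scored: Iterable[ScoredGene], path: str | Path) -> None:
    """Write ``symbol<TAB>cgc_score<TAB>matched_terms`` (terms semicolon-joined)."""
    with Path(path).open("w") as fh:
        fh.write("symbol\tcgc_score\tmatched_terms\n")
        for s in scored:
            fh.write(f"{s.symbol}\t{s.cgc_score:g}\t{';'.join(sorted(s.matched_terms))}\n")


def load_scored_tsv(path: str | Path) -> list[ScoredGene]:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "matched_terms": str})
    out = []
    for row in df.itertuples(index=False):
        terms = row.matched_terms
        terms = () if (not isinstance(terms, str) or not terms) else tuple(terms.split(";"))
        out.append(ScoredGene(symbol=row.symbol, cgc_score=float(row.cgc_score), matched_terms=frozenset(terms)))
    return out


def scores_by_symbol(scored: Iterable[ScoredGene]) -> Mapping[str, float]:
    """Convenience mapping ``symbol -> cgc_score``."""
    return {s.symbol: s.cgc_score for s in scored}
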