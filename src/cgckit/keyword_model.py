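"""Keyword weights ("relevance indices") from literature co-occurrence counts.

A keyword's weight is the percentage of abstracts mentioning the keyword that
also mention a fixed reference term (by default ``arthritis``).  Weights are
normally supplied as a two-column TSV; when raw co-occurrence counts are
available the weights can be recomputed from them instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import UndefinedWeightError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_TERM = "arthritis"

__all__ = [
    "Keyword",
    "CoOccurrenceCounts",
    "relevance_index",
    "load_keywords",
    "write_keywords",
    "load_cooccurrence",
    "weights_from_cooccurrence",
    "validate_keywords",
    "DEFAULT_REFERENCE_TERM",
]


@dataclass(frozen=True, order=True)
class Keyword:
    """A lowercase search term with a percentage weight in [0, 100]."""

    term: str
    weight: float

    def __post_init__(self) -> None:
        if not self.term:
            raise ValidationError("keyword term must be non-empty")
        if self.term != self.term.lower():
            object.__setattr__(self, "term", self.term.lower())
        if not 0.0 <= self.weight <= 100.0:
            raise ValidationError(
                f"keyword {self.term!r}: weight {self.weight} outside [0, 100]"
            )


@dataclass(frozen=True)
class CoOccurrenceCounts:
    """Abstract counts for one keyword against the reference term.

    ``n_keyword`` is the number of abstracts containing the keyword alone,
    ``n_joint`` the number containing both keyword and reference term.
    """

    term: str
    n_keyword: int
    n_joint: int

    def __post_init__(self) -> None:
        if self.n_keyword < 0 or self.n_joint < 0:
            raise ValidationError(f"counts for {self.term!r} must be non-negative")
        if self.n_joint > self.n_keyword:
            raise ValidationError(
                f"counts for {self.term!r}: joint count {self.n_joint} exceeds "
                f"keyword-alone count {self.n_keyword}"
            )


def relevance_index(counts: CoOccurrenceCounts) -> float:
    """Percentage of keyword-bearing abstracts that also carry the reference term.

    Returns ``100 * n_joint / n_keyword``.  Raises
    :class:`~cgckit.errors.UndefinedWeightError` when ``n_keyword`` is zero,
    since the ratio is undefined for a keyword with no literature hits.
    """
    if counts.n_keyword == 0:
        raise UndefinedWeightError(
            f"keyword {counts.term!r} has no abstracts; relevance index undefined"
        )
    return 100.0 * counts.n_joint / counts.n_keyword


def validate_keywords(keywords: Iterable[Keyword]) -> tuple[Keyword, ...]:
    """Check case-insensitive term uniqueness; return keywords sorted by term."""
    seen: dict[str, Keyword] = {}
    dupes: list[str] = []
    for kw in keywords:
        if kw.term in seen:
            dupes.append(kw.term)
        seen[kw.term] = kw
    if dupes:
        raise ValidationError(f"duplicate keyword terms: {sorted(set(dupes))}")
    return tuple(sorted(seen.values()))


def load_keywords(path: str | Path) -> tuple[Keyword, ...]:
    """Read a two-column TSV ``term<TAB>weight`` (``#`` comments allowed).

    Terms are lowercased; duplicates (case-insensitive) raise
    :class:`~cgckit.errors.ValidationError` listing the offenders.  An empty
    file yields an empty tuple with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["term", "weight"],
        dtype={"term": str},
        skip_blank_lines=True,
    )
    if df.empty:
        logger.warning("keyword file %s is empty", path)
        return ()
    try:
        weights = df["weight"].astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric weight column: {exc}") from exc
    kws = [Keyword(term=str(t).strip().lower(), weight=w) for t, w in zip(df["term"], weights)]
    return validate_keywords(kws)


def write_keywords(keywords: Iterable[Keyword], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# term\tweight\n")
        for kw in sorted(keywords):
            fh.write(f"{kw.term}\t{kw.weight:g}\n")


def load_cooccurrence(path: str | Path) -> tuple[CoOccurrenceCounts, ...]:
    """Read a three-column TSV ``term<TAB>n_keyword<TAB>n_joint``."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["term", "n_keyword", "n_joint"],
        dtype={"term": str},
        skip_blank_lines=True,
    )
    if df.empty:
        logger.warning("co-occurrence file %s is empty", path)
        return ()
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CoOccurrenceCounts(
                term=str(row.term).strip().lower(),
                n_keyword=int(row.n_keyword),
                n_joint=int(row.n_joint),
            )
        )
    return tuple(out)


def weights_from_cooccurrence(
    counts: Sequence[CoOccurrenceCounts],
) -> tuple[Keyword, ...]:
    """Turn raw co-occurrence counts into a validated keyword set."""
    kws = [Keyword(term=c.term, weight=relevance_index(c)) for c in counts]
    return validate_keywords(kws)
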