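"""Offline reported/unreported classification of genes against heart terms.

Given an abstract corpus (one record per publication: identifier, title,
abstract) and a gene symbol list, a gene is *reported* when at least one
record mentions the symbol as a whole token (case-insensitive) in the
title or abstract together with at least one heart term.  Heart terms are
matched at word starts so the stem-like terms generalise ("cardio"
matches "cardiovascular") without matching inside words ("cardium" does
not match "myocardium" under the default); substring matching anywhere is
available as an option.

Records where the symbol and a heart term both occur but never within the
same sentence are additionally flagged ``needs_review``, mirroring the
manual-review step of text-mining protocols.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import pandas as pd

__all__ = [
    "HEART_TERMS",
    "LitStatus",
    "read_corpus",
    "write_corpus",
    "classify_genes",
]

# the standard seven-term heart query (title/abstract fields)
HEART_TERMS = (
    "heart",
    "atrial",
    "ventricle",
    "cardio",
    "cardiac",
    "coronary",
    "cardium",
)


@dataclass
class LitStatus:
    """Literature status of one gene symbol."""

    symbol: str
    status: str  # reported | unreported
    matching_ids: tuple[str, ...] = field(default_factory=tuple)
    needs_review: bool = False

    def __post_init__(self) -> None:
        if (self.status == "reported") != bool(self.matching_ids):
            raise ValueError("reported status must match non-empty record ids")


def read_corpus(path_or_buffer) -> pd.DataFrame:
    """Read a corpus TSV with columns ``pmid``, ``title``, ``abstract``."""
    corpus = pd.read_csv(
        path_or_buffer, sep="\t", dtype=str, keep_default_na=False
    )
    missing = {"pmid", "title", "abstract"} - set(corpus.columns)
    if missing:
        raise ValueError(f"corpus missing columns: {sorted(missing)}")
    if corpus["pmid"].duplicated().any():
        raise ValueError("duplicate record identifiers in corpus")
    return corpus


def write_corpus(corpus: pd.DataFrame, path_or_buffer) -> None:
    corpus.to_csv(path_or_buffer, sep="\t", index=False)


def _symbol_pattern(symbol: str) -> re.Pattern:
    # whole-token: no word character on either side; hyphenated symbols work
    return re.compile(rf"(?<!\w){re.escape(symbol)}(?!\w)", re.IGNORECASE)


def _term_pattern(terms: Sequence[str], word_start: bool) -> re.Pattern:
    alternatives = "|".join(re.escape(t) for t in terms)
    prefix = r"\b" if word_start else ""
    return re.compile(rf"{prefix}(?:{alternatives})", re.IGNORECASE)


def classify_genes(
    corpus: pd.DataFrame,
    gene_symbols: Iterable[str],
    heart_terms: Sequence[str] = HEART_TERMS,
    word_start: bool = True,
) -> list[LitStatus]:
    """Classify each gene symbol as reported or unreported.

    A record matches a gene iff the symbol occurs as a whole token AND a
    heart term occurs (word-start match by default) anywhere in the
    record's title or abstract.  ``needs_review`` marks reported genes
    whose matching records never place the symbol and a heart term in the
    same period-delimited sentence.
    """
    if not heart_terms:
        raise ValueError("heart term list is empty")
    texts = (corpus["title"].fillna("") + ". " + corpus["abstract"].fillna("")).tolist()
    ids = corpus["pmid"].tolist()
    term_re = _term_pattern(heart_terms, word_start)
    term_hits = [bool(term_re.search(text)) for text in texts]

    statuses: list[LitStatus] = []
    for symbol in gene_symbols:
        if not symbol:
            raise ValueError("empty gene symbol")
        sym_re = _symbol_pattern(symbol)
        matches = []
        sentence_ok = False
        for pmid, text, has_term in zip(ids, texts, term_hits):
            if not (has_term and sym_re.search(text)):
                continue
            matches.append(pmid)
            if not sentence_ok:
                for sentence in text.split("."):
                    if sym_re.search(sentence) and term_re.search(sentence):
                        sentence_ok = True
                        break
        statuses.append(
            LitStatus(
                symbol=symbol,
                status="reported" if matches else "unreported",
                matching_ids=tuple(matches),
                needs_review=bool(matches) and not sentence_ok,
            )
        )
    return statuses


def statuses_to_frame(statuses: Sequence[LitStatus]) -> pd.DataFrame:
    """Tabulate statuses for TSV export (symbol, status, n_records, pmids)."""
    return pd.DataFrame(
        {
            "symbol": [s.symbol for s in statuses],
            "status": [s.status for s in statuses],
            "n_records": [len(s.matching_ids) for s in statuses],
            "pmids": [";".join(s.matching_ids) for s in statuses],
            "needs_review": [s.needs_review for s in statuses],
        }
    ).set_index("symbol")
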