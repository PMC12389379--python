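"""Author-keyword normalisation and frequency tables (the word-cloud data).

Raw author keywords are noisy: casing varies, dashes come as hyphen,
en-dash or em-dash, and the same concept appears under several variants
("EMT" vs "epithelial-mesenchymal transition"). A one-step thesaurus maps
variants to preferred terms, and an exclusion set removes the terms that
defined the literature search itself (and their synonyms), which would
otherwise dominate every frequency table.

Counting is at the article level: a keyword counts once per article no
matter how often it repeats in that article's keyword list.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corpus import Corpus

_WS = re.compile(r"\s+")
_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})

EXCLUDED = None  # sentinel return of normalize_keyword for excluded terms


@dataclass
class Thesaurus:
    """One-step synonym map plus post-normalisation exclusion set.

    The map must be one-step: preferred terms never map onward. Exclusion
    is tested after synonym mapping, so excluding a preferred term also
    removes all of its variants.
    """

    synonym_map: dict[str, str] = field(default_factory=dict)
    exclusion_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.synonym_map = {
            _basic_normalize(k): _basic_normalize(v) for k, v in self.synonym_map.items()
        }
        chained = [k for k, v in self.synonym_map.items() if v in self.synonym_map and v != k]
        if chained:
            raise ValueError(f"thesaurus is not one-step; chained variants: {chained[:5]}")
        self.exclusion_set = {_basic_normalize(t) for t in self.exclusion_set}


def _basic_normalize(raw: str) -> str:
    """Lowercase, fold unicode dashes to '-', trim, collapse whitespace."""
    return _WS.sub(" ", raw.translate(_DASHES).lower().strip())


def normalize_keyword(raw: str, thesaurus: Thesaurus | None = None) -> str | None:
    """Normalised form of a keyword, or ``None`` when excluded/empty.

    Pipeline: lowercase + dash folding + whitespace collapse, one synonym
    step, then the exclusion test. Idempotent: feeding the result back in
    returns it unchanged.
    """
    term = _basic_normalize(raw)
    if not term:
        return EXCLUDED
    if thesaurus is not None:
        term = thesaurus.synonym_map.get(term, term)
        if term in thesaurus.exclusion_set:
            return EXCLUDED
    return term


def record_keywords(record, thesaurus: Thesaurus | None = None) -> set[str]:
    """Distinct normalised, non-excluded keywords of one record."""
    out = set()
    for raw in record.author_keywords:
        term = normalize_keyword(raw, thesaurus)
        if term is not None:
            out.add(term)
    return out


def keyword_frequencies(
    corpus: Corpus, thesaurus: Thesaurus | None = None, top_n: int | None = 100
) -> pd.DataFrame:
    """Article-level keyword frequency table, descending, ties lexicographic."""
    counter: Counter[str] = Counter()
    for rec in corpus:
        counter.update(record_keywords(rec, thesaurus))
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        rows = rows[:top_n]
    return pd.DataFrame(rows, columns=["keyword", "frequency"])


def load_thesaurus(
    synonyms_path: str | Path | None = None, exclusions_path: str | Path | None = None
) -> Thesaurus:
    """Thesaurus from a 2-column TSV (variant TAB preferred) and a one-term-per-line exclusion file."""
    synonym_map: dict[str, str] = {}
    if synonyms_path is not None:
        for line in Path(synonyms_path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            variant, _, preferred = line.partition("\t")
            if preferred:
                synonym_map[variant] = preferred
    exclusion_set: set[str] = set()
    if exclusions_path is not None:
        for line in Path(exclusions_path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                exclusion_set.add(line)
    return Thesaurus(synonym_map=synonym_map, exclusion_set=exclusion_set)
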