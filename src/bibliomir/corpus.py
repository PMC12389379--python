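"""Reading, screening and summarising bibliographic corpora in Scopus export format.

A corpus is an ordered collection of :class:`BibRecord`. Records are keyed by
DOI when one is present (lowercased), otherwise by a stable hash of first
author surname, year and normalised title, so that free-text reference
strings can be matched back to records for local-citation scoring.

The manual relevance screen is consumed as a plain keep-list of record ids;
it is an input artifact of the study design, never re-derived here.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

#: Columns a Scopus CSV export must carry for ingestion to proceed.
MANDATORY_COLUMNS = ("Title", "Year", "Cited by")

#: Full column set emitted by :func:`write_scopus_csv`.
SCOPUS_COLUMNS = (
    "Authors",
    "Authors with affiliations",
    "Title",
    "Year",
    "Source title",
    "Cited by",
    "DOI",
    "Author Keywords",
    "Abstract",
    "Affiliations",
    "Correspondence Address",
    "References",
    "Document Type",
    "Language of Original Document",
)

_ALNUM = re.compile(r"[a-z0-9]+")


def normalize_title(title: str) -> str:
    """Lowercased alphanumeric-token form of a title, used for identity and matching."""
    return " ".join(_ALNUM.findall(title.lower()))


def title_tokens(text: str) -> frozenset[str]:
    return frozenset(_ALNUM.findall(text.lower()))


@dataclass
class BibRecord:
    """One bibliographic record (one article)."""

    record_id: str
    title: str
    year: int | None
    abstract: str = ""
    author_keywords: list[str] = field(default_factory=list)
    #: ordered (author name, list of affiliation strings) pairs
    authors: list[tuple[str, list[str]]] = field(default_factory=list)
    correspondence_address: str | None = None
    source_title: str = ""
    global_citations: int = 0
    references: list[str] = field(default_factory=list)
    doi: str | None = None
    doc_type: str = "Article"
    language: str = "English"
    #: set when mandatory fields could not be parsed; such records are kept,
    #: never dropped, so completeness statistics stay computable
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.global_citations < 0:
            raise ValueError(f"global_citations must be >= 0, got {self.global_citations}")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"year {self.year} outside [1900, 2100]")

    @property
    def first_author_surname(self) -> str:
        if not self.authors:
            return ""
        return self.authors[0][0].split(",")[0].split()[0].strip(".")


@dataclass
class Corpus:
    """Ordered, duplicate-free collection of records with provenance."""

    records: list[BibRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in corpus: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BibRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> BibRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]


@dataclass
class ScreeningList:
    """Keep-list of record ids plus optional automatic filter flags."""

    keep_ids: set[str]
    exclude_doc_types: frozenset[str] = frozenset()
    require_language: str | None = None


def make_record_id(
    doi: str | None, first_author_surname: str, year: int | None, title: str
) -> str:
    """Stable record key: lowercased DOI when present, else a content hash."""
    if doi:
        return doi.strip().lower()
    key = f"{first_author_surname.lower()}|{year}|{normalize_title(title)}"
    return "rec:" + hashlib.sha1(key.encode("utf-8")).hexdigest()[:16]


def _parse_authors_with_affiliations(cell: str) -> list[tuple[str, list[str]]]:
    """Parse Scopus's 'Surname I., Affil; Surname I., Affil' author column.

    The name is the text before the first ', '; repeated names accumulate
    affiliations (an author listed under two institutions).
    """
    authors: list[tuple[str, list[str]]] = []
    index: dict[str, int] = {}
    for segment in cell.split("; "):
        segment = segment.strip()
        if not segment:
            continue
        name, _, affil = segment.partition(", ")
        name = name.strip()
        affil = affil.strip()
        if name in index:
            if affil:
                authors[index[name]][1].append(affil)
        else:
            index[name] = len(authors)
            authors.append((name, [affil] if affil else []))
    return authors


def _row_to_record(row: Mapping[str, str], seen_ids: set[str]) -> BibRecord:
    title = row.get("Title", "").strip()
    raw_year = row.get("Year", "").strip()
    incomplete = False
    year: int | None
    try:
        year = int(raw_year)
        if not (1900 <= year <= 2100):
            raise ValueError
    except ValueError:
        year, incomplete = None, True

    raw_cited = row.get("Cited by", "").strip()
    try:
        gcs = max(0, int(raw_cited)) if raw_cited else 0
    except ValueError:
        gcs, incomplete = 0, True

    authors = _parse_authors_with_affiliations(row.get("Authors with affiliations", ""))
    if not authors:
        names = [n.strip() for n in row.get("Authors", "").split(";") if n.strip()]
        authors = [(n, []) for n in names]
    if not authors:
        incomplete = True

    doi = row.get("DOI", "").strip() or None
    surname = authors[0][0].split(",")[0].split()[0] if authors else ""
    record_id = make_record_id(doi, surname, year, title)
    if record_id in seen_ids:  # duplicate DOI/hash: disambiguate, keep both rows
        suffix = 2
        while f"{record_id}#{suffix}" in seen_ids:
            suffix += 1
        record_id = f"{record_id}#{suffix}"

    corr = row.get("Correspondence Address", "").strip() or None
    keywords = [k.strip() for k in row.get("Author Keywords", "").split(";") if k.strip()]
    references = [s.strip() for s in row.get("References", "").split("; ") if s.strip()]
    language = (
        row.get("Language of Original Document", "").strip()
        or row.get("Language", "").strip()
        or "English"
    )

    return BibRecord(
        record_id=record_id,
        title=title,
        year=year,
        abstract=row.get("Abstract", "").strip(),
        author_keywords=keywords,
        authors=authors,
        correspondence_address=corr,
        source_title=row.get("Source title", "").strip(),
        global_citations=gcs,
        references=references,
        doi=doi,
        doc_type=row.get("Document Type", "").strip() or "Article",
        language=language,
        incomplete=incomplete,
    )


def read_scopus_csv(path: str | Path) -> Corpus:
    """Read a Scopus-style CSV export into a :class:`Corpus`.

    Missing optional columns become empty/absent fields; missing mandatory
    columns are fatal. Rows with unparseable years are kept and flagged
    incomplete rather than dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Scopus export is missing mandatory columns: {missing}")
    records: list[BibRecord] = []
    seen: set[str] = set()
    for row in df.to_dict(orient="records"):
        rec = _row_to_record(row, seen)
        seen.add(rec.record_id)
        records.append(rec)
    return Corpus(records=records, provenance=str(path))


def _record_to_row(rec: BibRecord) -> dict[str, str]:
    awa = "; ".join(
        "; ".join(f"{name}, {affil}" for affil in (affils or [""])) if affils else name
        for name, affils in rec.authors
    )
    affiliations = sorted({a for _, affils in rec.authors for a in affils})
    return {
        "Authors": "; ".join(name for name, _ in rec.authors),
        "Authors with affiliations": awa,
        "Title": rec.title,
        "Year": "" if rec.year is None else str(rec.year),
        "Source title": rec.source_title,
        "Cited by": str(rec.global_citations),
        "DOI": rec.doi or "",
        "Author Keywords": "; ".join(rec.author_keywords),
        "Abstract": rec.abstract,
        "Affiliations": "; ".join(affiliations),
        "Correspondence Address": rec.correspondence_address or "",
        "References": "; ".join(rec.references),
        "Document Type": rec.doc_type,
        "Language of Original Document": rec.language,
    }


def write_scopus_csv(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to the Scopus CSV column set (read/write round-trips)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(SCOPUS_COLUMNS), quoting=csv.QUOTE_ALL)
        writer.writeheader()
        for rec in corpus:
            writer.writerow(_record_to_row(rec))


def apply_screening(
    corpus: Corpus, screen: ScreeningList
) -> tuple[Corpus, dict[str, int]]:
    """Apply the manual keep-list and automatic document-type/language filters.

    Returns the screened corpus (input order preserved) and a removal report
    counting exclusions per reason; kept + removed always sums to the input
    size. Records failing several filters are counted once, under the first
    reason in (keep-list, doc-type, language) order.
    """
    unknown = screen.keep_ids - set(corpus.ids)
    if unknown:
        warnings.warn(
            f"{len(unknown)} screening ids not present in corpus "
            f"(e.g. {sorted(unknown)[:3]})",
            stacklevel=2,
        )
    report = {"not_in_keep_list": 0, "doc_type": 0, "language": 0}
    kept: list[BibRecord] = []
    for rec in corpus:
        if rec.record_id not in screen.keep_ids:
            report["not_in_keep_list"] += 1
        elif rec.doc_type in screen.exclude_doc_types:
            report["doc_type"] += 1
        elif screen.require_language and rec.language != screen.require_language:
            report["language"] += 1
        else:
            kept.append(rec)
    report["removed_total"] = sum(report.values())
    report["kept"] = len(kept)
    if not kept:
        warnings.warn("screening removed every record", stacklevel=2)
    provenance = f"{corpus.provenance} | screened ({report['removed_total']} removed)"
    return Corpus(records=kept, provenance=provenance), report


def corpus_summary(corpus: Corpus) -> dict:
    """Completeness and per-year summary of a corpus.

    Percentages are round-half-up; the integer-precision missing-correspondence
    share mirrors how corresponding-author exclusions are reported in
    bibliometric studies ("41 articles (5% of the total)").
    """
    from ._format import format_percent, share_pct

    n = len(corpus)
    per_year: dict[int, int] = {}
    for rec in corpus:
        if rec.year is not None:
            per_year[rec.year] = per_year.get(rec.year, 0) + 1
    if n == 0:
        return {
            "n_records": 0,
            "records_per_year": {},
            "pct_with_abstract": 0.0,
            "pct_with_correspondence": 0.0,
            "pct_with_references": 0.0,
            "missing_correspondence": 0,
            "missing_correspondence_pct": "0%",
        }
    with_abstract = sum(1 for r in corpus if r.abstract)
    with_corr = sum(1 for r in corpus if r.correspondence_address)
    with_refs = sum(1 for r in corpus if r.references)
    return {
        "n_records": n,
        "records_per_year": dict(sorted(per_year.items())),
        "pct_with_abstract": share_pct(with_abstract, n),
        "pct_with_correspondence": share_pct(with_corr, n),
        "pct_with_references": share_pct(with_refs, n),
        "missing_correspondence": n - with_corr,
        "missing_correspondence_pct": format_percent(n - with_corr, n, ndigits=0),
    }


# ---------------------------------------------------------------------------
# JSON serialisation (used by the CLI to pass corpora between stages)

def corpus_to_json(corpus: Corpus, path: str | Path | None = None) -> str:
    payload = {
        "provenance": corpus.provenance,
        "records": [
            {
                "record_id": r.record_id,
                "title": r.title,
                "year": r.year,
                "abstract": r.abstract,
                "author_keywords": r.author_keywords,
                "authors": [[name, affils] for name, affils in r.authors],
                "correspondence_address": r.correspondence_address,
                "source_title": r.source_title,
                "global_citations": r.global_citations,
                "references": r.references,
                "doi": r.doi,
                "doc_type": r.doc_type,
                "language": r.language,
                "incomplete": r.incomplete,
            }
            for r in corpus
        ],
    }
    text = json.dumps(payload, indent=1, ensure_ascii=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def corpus_from_json(source: str | Path) -> Corpus:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json")):
        payload = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        payload = json.loads(source)
    records = [
        BibRecord(
            record_id=d["record_id"],
            title=d["title"],
            year=d["year"],
            abstract=d.get("abstract", ""),
            author_keywords=list(d.get("author_keywords", [])),
            authors=[(name, list(affils)) for name, affils in d.get("authors", [])],
            correspondence_address=d.get("correspondence_address"),
            source_title=d.get("source_title", ""),
            global_citations=int(d.get("global_citations", 0)),
            references=list(d.get("references", [])),
            doi=d.get("doi"),
            doc_type=d.get("doc_type", "Article"),
            language=d.get("language", "English"),
            incomplete=bool(d.get("incomplete", False)),
        )
        for d in payload["records"]
    ]
    return Corpus(records=records, provenance=payload.get("provenance", ""))
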