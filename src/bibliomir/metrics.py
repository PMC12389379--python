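"""Annual production, growth and citation scoring.

Two citation scores are computed per document: the global citation score
(GCS) is the count reported by the indexing database ("Cited by"), while
the local citation score (LCS) counts citations received from other
documents *inside* the analysed corpus, recovered by matching each
record's free-text reference strings back to corpus records.

Citation-years are inclusive of both the publication year and the
reference year (``ref_year - pub_year + 1``), the convention under which
per-year citation rates of landmark CRC-miRNA papers (92.72, 77.5, 49.44
citations/year for the top three) reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from ._format import round_half_up, share_pct
from .corpus import Corpus, title_tokens


@dataclass
class AnnualStats:
    year: int
    NP: int
    pct: float
    TC: int
    TC_per_NP: float | None


def annual_production(corpus: Corpus) -> list[AnnualStats]:
    """One row per year from the earliest to the latest publication year.

    Years with no publications appear with NP=0 and an undefined (None)
    TC/NP. ``pct`` is the share of total publications, round-half-up to
    one decimal. TC/NP is plain total-citations over publications.
    """
    years = [r.year for r in corpus if r.year is not None]
    if not years:
        return []
    total = len(years)
    np_by_year: dict[int, int] = {}
    tc_by_year: dict[int, int] = {}
    for rec in corpus:
        if rec.year is None:
            continue
        np_by_year[rec.year] = np_by_year.get(rec.year, 0) + 1
        tc_by_year[rec.year] = tc_by_year.get(rec.year, 0) + rec.global_citations
    out: list[AnnualStats] = []
    for year in range(min(years), max(years) + 1):
        np_ = np_by_year.get(year, 0)
        tc = tc_by_year.get(year, 0)
        out.append(
            AnnualStats(
                year=year,
                NP=np_,
                pct=share_pct(np_, total, ndigits=1),
                TC=tc,
                TC_per_NP=None if np_ == 0 else round_half_up(tc / np_, 2),
            )
        )
    return out


@dataclass
class GrowthRate:
    first_year: int
    last_year: int
    NP_first: int
    NP_last: int
    rate_pct: float


def cagr(NP_by_year: Mapping[int, int], first_year: int, last_year: int) -> GrowthRate:
    """Annualised geometric growth of yearly publication counts, in percent.

    ``((NP_last / NP_first) ** (1 / (last_year - first_year)) - 1) * 100``;
    intermediate zero years are irrelevant to the endpoint-based rate.
    """
    if last_year <= first_year:
        raise ValueError("last_year must be after first_year")
    np_first = NP_by_year.get(first_year, 0)
    np_last = NP_by_year.get(last_year, 0)
    if np_first <= 0:
        raise ValueError("growth rate undefined: zero publications in the first year")
    rate = ((np_last / np_first) ** (1.0 / (last_year - first_year)) - 1.0) * 100.0
    return GrowthRate(first_year, last_year, np_first, np_last, rate)


def tc_per_year(TC: int, pub_year: int, ref_year: int) -> float:
    """Average citations per year over the inclusive citation window."""
    if ref_year < pub_year:
        raise ValueError("ref_year must be >= pub_year")
    return TC / (ref_year - pub_year + 1)


@dataclass
class CitationScores:
    record_id: str
    GCS: int
    LCS: int
    TC_per_year: float


def _title_similarity(title: str, reference: str) -> float:
    """Containment of the title's alphanumeric tokens in the reference string."""
    t = title_tokens(title)
    if not t:
        return 0.0
    r = title_tokens(reference)
    return len(t & r) / len(t)


def local_citation_scores(
    corpus: Corpus, match_threshold: float = 0.90
) -> dict[str, int]:
    """LCS per record: in-corpus citations recovered from reference strings.

    A reference string matches a corpus record when it contains the
    record's DOI (case-insensitive substring); for records without a DOI,
    when it contains the first author's surname and the publication year
    and its normalised-title similarity reaches ``match_threshold``.
    References to out-of-corpus work match nothing and are ignored;
    self-citations of a record to itself are excluded.
    """
    lcs = {rec.record_id: 0 for rec in corpus}
    doi_index = {rec.doi.lower(): rec.record_id for rec in corpus if rec.doi}
    fuzzy_targets = [rec for rec in corpus if not rec.doi]
    for citing in corpus:
        cited_here: set[str] = set()
        for ref in citing.references:
            ref_low = ref.lower()
            matched = None
            for doi, rid in doi_index.items():
                if doi in ref_low:
                    matched = rid
                    break
            if matched is None:
                for target in fuzzy_targets:
                    if target.year is None or str(target.year) not in ref:
                        continue
                    surname = target.first_author_surname.lower()
                    if not surname or surname not in ref_low:
                        continue
                    if _title_similarity(target.title, ref) >= match_threshold:
                        matched = target.record_id
                        break
            if matched is not None and matched != citing.record_id:
                cited_here.add(matched)
        for rid in cited_here:
            lcs[rid] += 1
    return lcs


def citation_scores(
    corpus: Corpus, ref_year: int, match_threshold: float = 0.90
) -> list[CitationScores]:
    """Per-document GCS, LCS and TC/Y table."""
    lcs = local_citation_scores(corpus, match_threshold)
    out = []
    for rec in corpus:
        tcy = (
            tc_per_year(rec.global_citations, rec.year, ref_year)
            if rec.year is not None and rec.year <= ref_year
            else 0.0
        )
        out.append(
            CitationScores(
                record_id=rec.record_id,
                GCS=rec.global_citations,
                LCS=lcs[rec.record_id],
                TC_per_year=tcy,
            )
        )
    return out


def top_documents(
    scores: list[CitationScores],
    corpus: Corpus,
    key: Literal["GCS", "LCS", "TC_per_year"] = "GCS",
    n: int = 10,
) -> pd.DataFrame:
    """Top-n documents by the chosen citation score.

    Descending by score; ties broken by earlier publication year, then
    record id. Both GCS and LCS columns are always emitted so the global
    and local views can be compared side by side.
    """
    year_of = {rec.record_id: rec.year for rec in corpus}
    ranked = sorted(
        scores,
        key=lambda s: (
            -getattr(s, key),
            year_of.get(s.record_id) if year_of.get(s.record_id) is not None else 10_000,
            s.record_id,
        ),
    )
    rows = [
        {
            "record_id": s.record_id,
            "year": year_of.get(s.record_id),
            "GCS": s.GCS,
            "LCS": s.LCS,
            "TC_per_year": round_half_up(s.TC_per_year, 2),
        }
        for s in ranked[:n]
    ]
    return pd.DataFrame(rows)
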