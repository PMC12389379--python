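"""Country-level production and collaboration indices.

Two complementary country attributions are computed. Author-appearance
counting attributes an article to the country of every co-author
affiliation (so one article can contribute to several countries, and an
author with two affiliations contributes twice). Corresponding-author
counting attributes each article to exactly one country — that of the
correspondence address — and splits it into single-country publications
(SCP: every co-author shares that country) and multiple-country
publications (MCP: at least one co-author is affiliated elsewhere).

Records whose correspondence address is absent or unresolvable are
excluded from SCP/MCP with the reason logged, never silently pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from ._format import share_pct
from .corpus import BibRecord, Corpus

logger = logging.getLogger(__name__)


def load_country_aliases(path: str | Path | None = None) -> dict[str, str]:
    """Alias -> canonical country table (bundled TSV by default)."""
    if path is None:
        text = (
            resources.files("bibliomir")
            .joinpath("data/country_aliases.tsv")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, _, canonical = line.partition("\t")
        if canonical:
            table[alias.strip().lower()] = canonical.strip()
    return table


def parse_affiliation_country(
    affiliation: str, country_table: dict[str, str]
) -> str | None:
    """Country of an affiliation string: the last comma-separated token,
    resolved through the alias table. Unresolved -> None, never guessed."""
    if not affiliation:
        return None
    candidate = affiliation.rsplit(",", 1)[-1].strip().rstrip(".").strip()
    return country_table.get(candidate.lower()) or country_table.get(
        (candidate + ".").lower()
    )


def record_author_countries(
    record: BibRecord, country_table: dict[str, str]
) -> list[str]:
    """Resolved country of every (author, affiliation) pair, with repeats."""
    out: list[str] = []
    for _, affils in record.authors:
        for affil in affils:
            country = parse_affiliation_country(affil, country_table)
            if country is not None:
                out.append(country)
    return out


def corresponding_country(
    record: BibRecord, country_table: dict[str, str]
) -> str | None:
    """Country of the correspondence address; None when absent/unresolved.

    There is deliberately no fallback to the first author: articles
    without a resolvable correspondence country are excluded from the
    SCP/MCP analysis, and the exclusion is logged.
    """
    if not record.correspondence_address:
        logger.info("scp_mcp_excluded id=%s reason=missing_correspondence", record.record_id)
        return None
    country = parse_affiliation_country(record.correspondence_address, country_table)
    if country is None:
        logger.info("scp_mcp_excluded id=%s reason=unresolved_country", record.record_id)
    return country


@dataclass
class CountryStats:
    country: str
    appearances: int = 0
    appearance_share: float = 0.0
    corr_articles: int = 0
    SCP: int = 0
    MCP: int = 0
    MCP_pct: float | None = None


def author_appearance_counts(
    corpus: Corpus, country_table: dict[str, str] | None = None
) -> pd.DataFrame:
    """Author-affiliation appearances per country, with percentage shares.

    Every (author, affiliation) pair with a resolvable country contributes
    one appearance; shares are percentages of the total appearance count,
    round-half-up to two decimals.
    """
    if country_table is None:
        country_table = load_country_aliases()
    counts: dict[str, int] = {}
    for rec in corpus:
        for country in record_author_countries(rec, country_table):
            counts[country] = counts.get(country, 0) + 1
    total = sum(counts.values())
    rows = [
        {
            "country": c,
            "appearances": n,
            "appearance_share": share_pct(n, total) if total else 0.0,
        }
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["country", "appearances", "appearance_share"])


def scp_mcp_counts(
    corpus: Corpus,
    country_table: dict[str, str] | None = None,
    mcp_pct_digits: int = 1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Corresponding-author country table with SCP/MCP split.

    Per record with corresponding country c: MCP when any co-author's
    resolved affiliation country differs from c, else SCP; the article is
    attributed to c only. Returns the table (sorted by corr_articles
    descending) and an exclusion report.
    """
    if country_table is None:
        country_table = load_country_aliases()
    stats: dict[str, CountryStats] = {}
    excluded = {"missing_correspondence": 0, "unresolved_country": 0}
    for rec in corpus:
        if not rec.correspondence_address:
            excluded["missing_correspondence"] += 1
            continue
        c = corresponding_country(rec, country_table)
        if c is None:
            excluded["unresolved_country"] += 1
            continue
        entry = stats.setdefault(c, CountryStats(country=c))
        entry.corr_articles += 1
        author_countries = set(record_author_countries(rec, country_table))
        if any(other != c for other in author_countries):
            entry.MCP += 1
        else:
            entry.SCP += 1
    rows = []
    for entry in sorted(stats.values(), key=lambda e: (-e.corr_articles, e.country)):
        entry.MCP_pct = (
            share_pct(entry.MCP, entry.corr_articles, ndigits=mcp_pct_digits)
            if entry.corr_articles
            else None
        )
        rows.append(
            {
                "country": entry.country,
                "corr_articles": entry.corr_articles,
                "SCP": entry.SCP,
                "MCP": entry.MCP,
                "MCP_pct": entry.MCP_pct,
            }
        )
    return (
        pd.DataFrame(rows, columns=["country", "corr_articles", "SCP", "MCP", "MCP_pct"]),
        excluded,
    )
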