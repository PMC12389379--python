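"""miRNA mention extraction, nomenclature normalisation and catalog validation.

Mentions are pulled from title, author keywords and abstract with a
nomenclature grammar (miR/mir/miRNA/microRNA stems plus the let-7 family),
folded to a canonical id (``miR-34a``, ``miR-195-5p``, ``let-7a``) and
validated against the union of several miRBase-style releases, so that
non-standard or outdated identifiers are excluded. Annual occurrence is
counted at the article level: a record contributes at most once per miRNA
per year no matter how many fields mention it.

Arm-level identity is preserved throughout: ``miR-195`` and ``miR-195-5p``
are distinct ids, ranked separately.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import pandas as pd

from .corpus import Corpus

#: token grammar: optional 3-letter species prefix, a stem with optional
#: hyphen/space separator, number, letter suffix, paralog ("-1") and arm
#: ("-5p"/"-3p"); plus the let-7 family which carries no number of its own.
#: The paralog lookahead keeps "-5p" from being eaten as a paralog "-5".
_GRAMMAR = r"""
    (?P<prefix>[a-z]{3}-)?
    (?:
        (?P<stem>microRNA|miRNA|miR)
        [- ]?
        (?P<num>\d+)
        (?P<letter>[a-z])?
        (?P<paralog>-\d+(?!p))?
        (?P<arm>-[35]p)?
    |
        let-7
        (?P<letter2>[a-z])?
        (?P<arm2>-[35]p)?
    )
"""
_TOKEN_RE = re.compile(
    rf"(?<![A-Za-z0-9]){_GRAMMAR}(?![A-Za-z0-9])",
    re.IGNORECASE | re.VERBOSE,
)
_FULL_RE = re.compile(rf"{_GRAMMAR}$", re.IGNORECASE | re.VERBOSE)


class RawToken(NamedTuple):
    """A grammar match in free text, with its character span."""

    text: str
    start: int
    end: int


@dataclass
class MirnaCatalog:
    """Union of valid miRNA names over one or more nomenclature releases.

    Names are stored case-folded so mature (miR) and precursor (mir)
    casings are interchangeable at lookup time. ``alias_map`` resolves
    superseded names (earlier entries on an aliases line) to the current
    name (the last entry on that line).
    """

    releases: list[str]
    names_by_release: dict[str, set[str]]
    alias_map: dict[str, str] = field(default_factory=dict)

    @property
    def names_union(self) -> set[str]:
        out: set[str] = set()
        for names in self.names_by_release.values():
            out |= names
        return out

    def __contains__(self, name: str) -> bool:
        low = name.lower()
        return low in self.names_union or low in self.alias_map

    def resolve(self, name: str) -> str | None:
        """Current name for ``name``, following one alias step; None if unknown."""
        low = name.lower()
        if low in self.alias_map:
            return self.alias_map[low]
        if low in self.names_union:
            return low
        return None


def load_catalog(paths: Sequence[str | Path]) -> MirnaCatalog:
    """Load aliases-format files (accession TAB semicolon-separated names).

    One file per release; the release label is the file stem. Malformed
    lines are skipped with a warning naming the line number.
    """
    releases: list[str] = []
    names_by_release: dict[str, set[str]] = {}
    alias_map: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        label = path.stem
        releases.append(label)
        names: set[str] = set()
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip(";"):
                warnings.warn(f"{path.name}:{lineno}: malformed aliases line skipped")
                continue
            entry_names = [n.strip().lower() for n in parts[1].split(";") if n.strip()]
            names.update(entry_names)
            current = entry_names[-1]
            for old in entry_names[:-1]:
                if old != current:
                    alias_map[old] = current
        names_by_release[label] = names
    return MirnaCatalog(releases=releases, names_by_release=names_by_release, alias_map=alias_map)


def bundled_catalog() -> MirnaCatalog:
    """The packaged three-release human catalog subset (synthetic fixture)."""
    root = resources.files("bibliomir").joinpath("data")
    paths = [root.joinpath(f"aliases_rel{v}.txt") for v in (20, 21, 22)]
    return load_catalog([str(p) for p in paths])


def extract_mirna_tokens(text: str) -> list[RawToken]:
    """All grammar matches in ``text``, non-overlapping, leftmost-longest."""
    return [RawToken(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text or "")]


def canonicalize_token(raw: str) -> str:
    """Fold a grammar match to its canonical id.

    Strips any species prefix, folds the stem to ``miR`` (or ``let-7``),
    lowercases the letter suffix and preserves paralog and arm suffixes:
    ``"MIR-34A"`` -> ``"miR-34a"``, ``"microRNA 21"`` -> ``"miR-21"``,
    ``"hsa-miR-195-5p"`` -> ``"miR-195-5p"``.

    Raises ``ValueError`` for input that does not match the grammar —
    only extractor output may be passed here.
    """
    m = _FULL_RE.match(raw.strip())
    if m is None:
        raise ValueError(f"not a miRNA token: {raw!r}")
    if m.group("num") is not None:
        parts = ["miR-", m.group("num")]
        if m.group("letter"):
            parts.append(m.group("letter").lower())
        if m.group("paralog"):
            parts.append(m.group("paralog"))
        if m.group("arm"):
            parts.append(m.group("arm").lower())
        return "".join(parts)
    parts = ["let-7"]
    if m.group("letter2"):
        parts.append(m.group("letter2").lower())
    if m.group("arm2"):
        parts.append(m.group("arm2").lower())
    return "".join(parts)


def validate_mention(
    canonical_id: str, catalog: MirnaCatalog, species_prefix: str = "hsa"
) -> bool:
    """True iff the species-prefixed form exists in the release union or alias map.

    Lookup is case-insensitive, so mature (``hsa-miR-21``) and precursor
    (``hsa-mir-21``) casings both count.
    """
    return f"{species_prefix}-{canonical_id}" in catalog


@dataclass
class MirnaMention:
    record_id: str
    canonical_id: str
    raw_token: str
    field_of_origin: Literal["title", "keywords", "abstract"]
    valid: bool


def extract_record_mentions(
    record, catalog: MirnaCatalog, species_prefix: str = "hsa"
) -> list[MirnaMention]:
    """All mentions of one record across title, author keywords and abstract."""
    fields: list[tuple[str, str]] = [
        ("title", record.title),
        ("keywords", "; ".join(record.author_keywords)),
        ("abstract", record.abstract),
    ]
    mentions: list[MirnaMention] = []
    for origin, text in fields:
        for tok in extract_mirna_tokens(text):
            canonical = canonicalize_token(tok.text)
            mentions.append(
                MirnaMention(
                    record_id=record.record_id,
                    canonical_id=canonical,
                    raw_token=tok.text,
                    field_of_origin=origin,  # type: ignore[arg-type]
                    valid=validate_mention(canonical, catalog, species_prefix),
                )
            )
    return mentions


@dataclass
class AnnualMirnaMatrix:
    """miRNA x year article counts plus the two ranking metrics.

    ``mean_since_first`` divides the cumulative total by the inclusive year
    span from first appearance to the analysis window end (both endpoints
    counted), e.g. a miRNA first seen 2008 with window end 2024 divides
    by 17.
    """

    counts: dict[tuple[str, int], int]
    window_end: int

    @property
    def mirnas(self) -> list[str]:
        return sorted({mid for mid, _ in self.counts})

    @property
    def years(self) -> list[int]:
        return sorted({year for _, year in self.counts})

    @property
    def totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (mid, _), n in self.counts.items():
            out[mid] = out.get(mid, 0) + n
        return out

    @property
    def first_year(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (mid, year), n in self.counts.items():
            if n > 0 and (mid not in out or year < out[mid]):
                out[mid] = year
        return out

    @property
    def mean_since_first(self) -> dict[str, float]:
        firsts = self.first_year
        return {
            mid: total / (self.window_end - firsts[mid] + 1)
            for mid, total in self.totals.items()
            if mid in firsts
        }

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: one row per miRNA, year columns plus Total and Mean."""
        years = self.years
        rows = []
        means = self.mean_since_first
        for mid in self.mirnas:
            row = {"miRNA": mid}
            for y in years:
                row[y] = self.counts.get((mid, y), 0)
            row["Total"] = self.totals[mid]
            row["Mean"] = means[mid]
            rows.append(row)
        return pd.DataFrame(rows)


def annual_mirna_matrix(
    corpus: Corpus,
    catalog: MirnaCatalog,
    species_prefix: str = "hsa",
    window_end: int | None = None,
) -> AnnualMirnaMatrix:
    """Article-level miRNA x year counts over a corpus.

    Only catalog-valid mentions count; a record contributes at most 1 to a
    (miRNA, year) cell regardless of how many fields or repeated tokens
    mention that miRNA. Records without a parseable year are skipped.
    """
    counts: dict[tuple[str, int], int] = {}
    max_year = 0
    for record in corpus:
        if record.year is None:
            continue
        max_year = max(max_year, record.year)
        valid_ids = {
            m.canonical_id
            for m in extract_record_mentions(record, catalog, species_prefix)
            if m.valid
        }
        for mid in valid_ids:
            key = (mid, record.year)
            counts[key] = counts.get(key, 0) + 1
    if window_end is None:
        window_end = max_year if max_year else 0
    return AnnualMirnaMatrix(counts=counts, window_end=window_end)


def rank_mirnas(
    matrix: AnnualMirnaMatrix,
    top_n: int | None = 10,
    metric: Literal["total", "mean_since_first"] = "total",
) -> pd.DataFrame:
    """Ranked miRNA table, descending by the chosen metric.

    Ties break by earlier first appearance year, then lexicographic id.
    """
    totals = matrix.totals
    firsts = matrix.first_year
    means = matrix.mean_since_first
    rows = [
        {
            "miRNA": mid,
            "total": totals[mid],
            "first_year": firsts[mid],
            "mean_since_first": means[mid],
        }
        for mid in matrix.mirnas
    ]
    rows.sort(key=lambda r: (-r[metric], r["first_year"], r["miRNA"]))
    df = pd.DataFrame(rows)
    if top_n is not None:
        df = df.head(top_n)
    return df.reset_index(drop=True)
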