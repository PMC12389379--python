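"""Seeded synthetic Scopus-style corpora with known ground truth.

The generator emulates the statistical structure of the CRC-miRNA
literature so every pipeline stage is testable without any download:

* per-year publication counts spanning three growth phases (sparse early
  years, steep growth to a peak, then decline), apportioned from a
  year-weight table whose default follows the observed annual counts of
  the 828-article study corpus;
* a country mixture heavily skewed toward one country (default China at
  0.857 of corresponding authorships) with occasional multi-country
  author lists and occasionally missing correspondence addresses;
* Zipf-distributed miRNA mentions planted into titles, author keywords
  and abstracts, rendered with noisy but grammar-valid case/spacing
  variants, plus a controlled rate of catalog-invalid identifiers;
* Zipf-distributed author keywords with planted head frequencies and two
  thematic co-occurrence blocks (tumour-progression vs therapy-response);
* a backward-in-time within-corpus citation graph (so local citation
  scores are non-zero) with global citation counts inflated above the
  in-corpus in-degree, guaranteeing LCS <= GCS.

Everything is driven by one integer seed; the same config yields
byte-identical CSV output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus import BibRecord, Corpus
from .corpus import write_scopus_csv as write_scopus_csv  # re-exported surface
from .keywords import _basic_normalize
from .mirna import MirnaCatalog, bundled_catalog, canonicalize_token, validate_mention

#: observed annual publication counts of the study corpus (2008-2024);
#: used as apportionment weights, so n_records=828 reproduces them exactly
STUDY_YEAR_COUNTS: dict[int, int] = {
    2008: 2, 2009: 1, 2010: 0, 2011: 5, 2012: 7, 2013: 10, 2014: 21,
    2015: 31, 2016: 44, 2017: 62, 2018: 96, 2019: 87, 2020: 125,
    2021: 115, 2022: 89, 2023: 71, 2024: 62,
}

#: corresponding-author country mixture (sums to 1; China at 0.857)
DEFAULT_COUNTRY_MIXTURE: dict[str, float] = {
    "China": 0.857, "Iran": 0.022, "Japan": 0.014, "Italy": 0.013,
    "United States": 0.011, "Germany": 0.009, "United Kingdom": 0.009,
    "India": 0.009, "Canada": 0.008, "South Korea": 0.008,
    "Australia": 0.008, "France": 0.008, "Spain": 0.008, "Sweden": 0.008,
    "Malaysia": 0.008,
}

#: planted head-keyword article counts at the reference corpus size of 828
#: (word-cloud head of the study corpus); scaled proportionally otherwise.
#: chemoresistance/oxaliplatin/5-fluorouracil sizes are generator choices
#: that give the therapy-response block enough mass to cluster.
HEAD_KEYWORD_COUNTS: dict[str, int] = {
    "proliferation": 117, "metastasis": 79, "invasion": 77, "migration": 64,
    "apoptosis": 51, "chemoresistance": 40, "epithelial-mesenchymal transition": 27,
    "exosomes": 27, "oxaliplatin": 25, "5-fluorouracil": 22,
    "wnt/β-catenin": 19, "angiogenesis": 13, "cell cycle": 12, "autophagy": 12,
    "glycolysis": 11, "tp53": 10, "methylation": 10, "pten": 10,
    "tumorigenesis": 10, "ferroptosis": 8, "cerna": 8, "kras": 7,
    "malat1": 6, "pd-l1": 5, "radiosensitivity": 5, "lncrna xist": 5,
}

#: thematic co-occurrence blocks used to bias keyword placement
RED_BLOCK = {
    "proliferation", "metastasis", "invasion", "migration", "apoptosis",
    "epithelial-mesenchymal transition", "cell cycle", "tumorigenesis",
    "wnt/β-catenin", "tp53", "pten",
}
GREEN_BLOCK = {
    "chemoresistance", "oxaliplatin", "5-fluorouracil", "autophagy",
    "exosomes", "angiogenesis", "glycolysis", "ferroptosis", "radiosensitivity",
}

#: most-studied miRNAs get the head of the Zipf distribution
MIRNA_HEAD = [
    "miR-21", "miR-34a", "miR-195-5p", "miR-27a-3p", "miR-133b",
    "miR-19a-3p", "let-7a", "miR-181a-5p", "miR-200c-3p", "miR-934",
]

#: query terms present on most records and removed by the exclusion list
QUERY_TERMS = ["colorectal cancer", "microrna"]


@dataclass
class SynthConfig:
    """Knobs of the synthetic corpus; the seed fully determines the output."""

    n_records: int = 828
    seed: int = 20240925
    year_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(STUDY_YEAR_COUNTS)
    )
    country_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_MIXTURE)
    )
    collab_prob: float = 0.05
    missing_correspondence_rate: float = 41 / 828
    mirna_zipf: float = 1.2
    mention_case_rate: float = 0.15
    mention_spacing_rate: float = 0.10
    mention_prefix_rate: float = 0.10
    invalid_mention_rate: float = 0.05
    keyword_head_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(HEAD_KEYWORD_COUNTS)
    )
    #: flat-ish, long tail: rare free-text descriptors must stay below the
    #: planted word-cloud head, as in the study corpus
    keyword_zipf: float = 0.5
    n_tail_keywords: int = 300
    citation_density: float = 1.0
    gcs_inflation: float = 5.0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        total = sum(self.country_mixture.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"country mixture must sum to 1, sums to {total}")
        for name in (
            "collab_prob", "missing_correspondence_rate", "mention_case_rate",
            "mention_spacing_rate", "mention_prefix_rate", "invalid_mention_rate",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.citation_density > self.n_records / 4:
            raise ValueError(
                "infeasible config: citation_density too high for n_records "
                "(backward-in-time citations cannot supply enough targets)"
            )


@dataclass
class GroundTruth:
    """Planted quantities recorded during generation, for exact recovery tests."""

    per_year: dict[int, int]
    corresponding: dict[str, str]          # drawn for every record
    missing_correspondence: set[str]       # records whose address was omitted
    mcp: dict[str, bool]                   # multi-country author list planted
    appearances: dict[str, int]            # country -> author-affiliation count
    in_degree: dict[str, int]              # within-corpus citations received
    mirna_mentions: dict[str, set[str]]    # record -> planted valid canonical ids
    mirna_year_counts: dict[tuple[str, int], int]
    noise_tokens: dict[str, list[str]]     # record -> planted invalid tokens
    keyword_counts: Counter                # planted non-excluded keyword -> articles
    themes: dict[str, str]                 # record -> "red" | "green"


def _apportion(n: int, weights: Mapping[int, float]) -> dict[int, int]:
    """Largest-remainder apportionment of n items over weighted bins."""
    years = sorted(weights)
    total = float(sum(weights.values()))
    raw = {y: n * weights[y] / total for y in years}
    counts = {y: int(raw[y]) for y in years}
    short = n - sum(counts.values())
    for y in sorted(years, key=lambda y: (raw[y] - counts[y], -y), reverse=True)[:short]:
        counts[y] += 1
    return counts


def _mirna_pool(catalog: MirnaCatalog) -> list[str]:
    """Canonical ids derivable from the catalog, head-ordered then sorted."""
    pool: set[str] = set()
    for name in catalog.names_union:
        try:
            canonical = canonicalize_token(name)
        except ValueError:
            continue
        if validate_mention(canonical, catalog):
            pool.add(canonical)
    tail = sorted(pool - set(MIRNA_HEAD))
    return [m for m in MIRNA_HEAD if m in pool] + tail


def _render_mention(canonical: str, rng: np.random.Generator, cfg: SynthConfig) -> str:
    """Grammar-valid noisy rendering that canonicalises back to ``canonical``."""
    text = canonical
    if rng.random() < cfg.mention_case_rate:
        text = text.upper() if rng.random() < 0.5 else text.lower()
    if canonical.startswith("miR-") and rng.random() < cfg.mention_spacing_rate:
        stem = "microRNA" if rng.random() < 0.5 else "miRNA"
        sep = " " if rng.random() < 0.5 else "-"
        text = stem + sep + text.split("-", 1)[1]
    if rng.random() < cfg.mention_prefix_rate:
        text = "hsa-" + text
    return text


def generate_corpus(config: SynthConfig | None = None) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus the ground truth planted into it."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    catalog = bundled_catalog()
    pool = _mirna_pool(catalog)
    zipf_p = np.array([(k + 1.0) ** -cfg.mirna_zipf for k in range(len(pool))])
    zipf_p /= zipf_p.sum()

    year_counts = _apportion(cfg.n_records, cfg.year_weights)
    years: list[int] = []
    for y in sorted(year_counts):
        years.extend([y] * year_counts[y])

    countries = list(cfg.country_mixture)
    country_p = np.array([cfg.country_mixture[c] for c in countries])
    tail_vocab = [f"topic {k:02d}" for k in range(cfg.n_tail_keywords)]
    tail_p = np.array([(k + 1.0) ** -cfg.keyword_zipf for k in range(len(tail_vocab))])
    tail_p /= tail_p.sum()

    n = cfg.n_records
    truth = GroundTruth(
        per_year=dict(year_counts), corresponding={}, missing_correspondence=set(),
        mcp={}, appearances={}, in_degree={}, mirna_mentions={},
        mirna_year_counts={}, noise_tokens={}, keyword_counts=Counter(), themes={},
    )

    ids = [f"10.9999/synth.{i:04d}" for i in range(n)]
    themes = np.where(rng.random(n) < 0.55, "red", "green")
    n_missing = round(cfg.missing_correspondence_rate * n)
    missing_idx = set(
        int(j) for j in rng.choice(n, size=min(n, n_missing), replace=False)
    )

    # --- plant head keywords: exact article counts, biased to theme blocks
    planted_keywords: list[set[str]] = [set() for _ in range(n)]
    scale = n / 828.0
    for kw, count828 in cfg.keyword_head_counts.items():
        target = min(n, max(1, round(count828 * scale)))
        if kw in RED_BLOCK:
            candidates = [i for i in range(n) if themes[i] == "red"]
        elif kw in GREEN_BLOCK:
            candidates = [i for i in range(n) if themes[i] == "green"]
        else:
            candidates = list(range(n))
        if len(candidates) < target:
            extras = [i for i in range(n) if i not in set(candidates)]
            candidates = candidates + extras
        chosen = rng.choice(len(candidates), size=target, replace=False)
        for c in chosen:
            planted_keywords[candidates[int(c)]].add(kw)

    # --- per-record fields
    records: list[BibRecord] = []
    out_refs: list[list[int]] = []
    for i in range(n):
        rid = ids[i]
        year = years[i]
        truth.themes[rid] = str(themes[i])

        # miRNA mentions
        k_mentions = min(len(pool), 1 + int(rng.poisson(0.8)))
        mention_idx = rng.choice(len(pool), size=k_mentions, replace=False, p=zipf_p)
        mentions = [pool[int(j)] for j in mention_idx]
        renders = [_render_mention(mid, rng, cfg) for mid in mentions]
        truth.mirna_mentions[rid] = set(mentions)
        for mid in set(mentions):
            key = (mid, year)
            truth.mirna_year_counts[key] = truth.mirna_year_counts.get(key, 0) + 1
        noise: list[str] = []
        if rng.random() < cfg.invalid_mention_rate:
            noise.append(f"miR-{int(rng.integers(9000, 9999))}")
        truth.noise_tokens[rid] = noise

        title = f"{renders[0]} modulates colorectal tumour phenotype in cohort {i:04d}"
        abstract_bits = [
            f"We examined {', '.join(renders)} in colorectal cancer specimens."
        ]
        if noise:
            abstract_bits.append(
                f"A previously reported identifier {noise[0]} could not be confirmed."
            )
        abstract_bits.append("Expression levels correlated with clinical outcome.")
        abstract = " ".join(abstract_bits)

        # countries and authors
        corr_country = countries[int(rng.choice(len(countries), p=country_p))]
        truth.corresponding[rid] = corr_country
        n_authors = 2 + int(rng.integers(0, 4))
        author_countries = [corr_country] * n_authors
        is_mcp = bool(rng.random() < cfg.collab_prob)
        if is_mcp:
            others = [c for c in countries if c != corr_country]
            other_p = np.array([cfg.country_mixture[c] for c in others])
            other_p /= other_p.sum()
            foreign = others[int(rng.choice(len(others), p=other_p))]
            author_countries[int(rng.integers(1, n_authors))] = foreign
        truth.mcp[rid] = is_mcp
        authors = []
        for j, country in enumerate(author_countries):
            name = f"Auth{i:04d}{chr(65 + j)} S."
            affil = f"Department of Oncology, University Hospital {i % 40:02d}, {country}"
            authors.append((name, [affil]))
            truth.appearances[country] = truth.appearances.get(country, 0) + 1
        if i in missing_idx:
            corr_address = None
            truth.missing_correspondence.add(rid)
        else:
            corr_address = (
                f"{authors[0][0]}; Department of Oncology, "
                f"University Hospital {i % 40:02d}, {corr_country}"
            )

        # keywords: planted head + query terms + Zipf tail
        kws = set(planted_keywords[i])
        n_tail = 1 + int(rng.integers(0, 3))
        tail_idx = rng.choice(len(tail_vocab), size=n_tail, replace=False, p=tail_p)
        kws |= {tail_vocab[int(j)] for j in tail_idx}
        truth.keyword_counts.update(kws)
        keyword_list = sorted(kws)
        if rng.random() < 0.15:  # mentions also surface as author keywords
            keyword_list.append(renders[0])
            truth.keyword_counts.update([_basic_normalize(renders[0])])
        if rng.random() < 0.8:
            keyword_list = QUERY_TERMS + keyword_list

        # backward-in-time citations (targets filled in below)
        earlier = [j for j in range(i) if years[j] < year]
        n_out = min(len(earlier), int(rng.poisson(cfg.citation_density)))
        targets: list[int] = []
        if n_out:
            gap = np.array([year - years[j] for j in earlier], dtype=float)
            pref = 1.0 / (gap + 1.0)
            pref /= pref.sum()
            chosen = rng.choice(len(earlier), size=n_out, replace=False, p=pref)
            targets = [earlier[int(j)] for j in chosen]
        out_refs.append(targets)
        for j in targets:
            truth.in_degree[ids[j]] = truth.in_degree.get(ids[j], 0) + 1

        records.append(
            BibRecord(
                record_id=rid,
                title=title,
                year=year,
                abstract=abstract,
                author_keywords=keyword_list,
                authors=authors,
                correspondence_address=corr_address,
                source_title=f"Journal of Synthetic Oncology {i % 6 + 1}",
                global_citations=0,  # set after the citation pass
                references=[],
                doi=rid,
                doc_type="Article",
                language="English",
            )
        )

    truth.in_degree = {rid: truth.in_degree.get(rid, 0) for rid in ids}

    # fill reference strings and global citations (GCS >= in-corpus in-degree)
    for i, rec in enumerate(records):
        rec.references = [
            f"Auth{j:04d}A S. et al., synthetic reference ({years[j]}) "
            f"DOI: {ids[j]}"
            for j in sorted(out_refs[i])
        ]
        rec.global_citations = truth.in_degree[rec.record_id] + int(
            rng.poisson(cfg.gcs_inflation)
        )

    corpus = Corpus(records=records, provenance=f"synthetic seed={cfg.seed} n={n}")
    return corpus, truth


def study_like_config(seed: int = 20240925, n_records: int = 828) -> SynthConfig:
    """The default preset: study-corpus scale and structure."""
    return SynthConfig(n_records=n_records, seed=seed)
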