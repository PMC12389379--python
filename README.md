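# bibliomir

Bibliometrics for the microRNA–colorectal cancer (CRC) literature: a
tested, scriptable re-implementation of the analysis pipeline behind
bibliometric studies of this field, built for anyone who wants the
numbers such studies print — publication growth, citation scores,
country production, miRNA identifier rankings, keyword maps — as
reproducible code rather than point-and-click tool output.

## What it computes

Given a bibliographic corpus in Scopus CSV export format (plus a manual
relevance keep-list), the package produces:

- **Annual production and growth** — publications per year (NP), total
  citations (TC), TC/NP, and the annualised geometric growth rate
  `((NP_last/NP_first)^(1/(y_last−y_first)) − 1) · 100`.
- **Citation scores per document** — the *global* citation score (GCS,
  the database's "Cited by" count), the *local* citation score (LCS,
  citations received from other documents inside the corpus, recovered
  by matching free-text reference strings via DOI or
  surname+year+title-similarity), and TC/Y = TC divided by the
  inclusive citation-year span `ref_year − pub_year + 1`.
- **miRNA identifier analytics** — mentions extracted from title,
  author keywords and abstract with a nomenclature grammar
  (miR/mir/miRNA/microRNA stems, letter/paralog/arm suffixes, the let-7
  family), canonicalised (`MIR-34A → miR-34a`), validated against the
  union of several miRBase-style releases with alias resolution, and
  counted article-level into a miRNA × year matrix ranked by cumulative
  count and by mean articles/year since first appearance.
- **Country indicators** — author-appearance counts (one per resolved
  author affiliation), corresponding-author attribution, and the
  SCP/MCP split (single- vs multiple-country publications).
- **Networks** — country collaboration (full counting) and keyword
  co-occurrence (full or fractional counting) graphs, association-
  strength normalisation `s_ij = 2m·c_ij/(w_i·w_j)`, Walktrap and
  resolution-parameterised (VOS-style) community detection with
  minimum-cluster-size merging, and reporting prunes.
- **Keyword frequencies** — thesaurus-normalised, exclusion-filtered,
  article-level top-N tables (word-cloud data).

A seeded synthetic-corpus generator (`bibliomir.synth`) emulates the
statistical structure of the real 828-article corpus — three-phase year
distribution, one dominant country, Zipf miRNA mentions with noisy
variants, planted keyword blocks, a backward-in-time citation graph —
and returns the planted ground truth, so the whole pipeline is testable
end to end without any database access.

## Worked example

```python
import bibliomir as bm
from bibliomir.metrics import annual_production
from bibliomir.geo import author_appearance_counts

corpus, truth = bm.generate_corpus(bm.study_like_config(seed=1))

rows = annual_production(corpus)
np_by_year = {r.year: r.NP for r in rows if r.NP > 0}
growth = bm.cagr(np_by_year, min(np_by_year), max(np_by_year))
print(f"growth rate: {bm.round_half_up(growth.rate_pct, 2)}%")

matrix = bm.annual_mirna_matrix(corpus, bm.bundled_catalog())
print(bm.rank_mirnas(matrix, top_n=3).to_string(index=False))

lcs = bm.local_citation_scores(corpus)
print(f"LCS == planted in-degree: {lcs == truth.in_degree}")
print(author_appearance_counts(corpus).head(3).to_string(index=False))
```

prints

```
growth rate: 23.94%
     miRNA  total  first_year  mean_since_first
    miR-21    374        2009         23.375000
   miR-34a    176        2013         14.666667
miR-195-5p    111        2009          6.937500
LCS == planted in-degree: True
country  appearances  appearance_share
  China         2472             85.12
   Iran           60              2.07
 Sweden           47              1.62
```

The growth rate is 23.94% because the generator apportions its 828
records over 2008–2024 exactly as the study corpus (2 articles in 2008,
62 in 2024). miR-21 tops the ranking because it heads the generator's
Zipf mention distribution, mirroring its dominance in the real
literature. `LCS == planted in-degree` confirms that reference-string
matching recovers the planted within-corpus citation graph exactly, and
the country table shows the planted China-dominant mixture.

A CLI mirrors the library (`bibliomir ingest | mirna | metrics | geo |
network | keywords | synth | run`); `bibliomir run --config run.toml`
executes every stage and writes TSV/JSON/GraphML artifacts stamped with
the config hash and seed.

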