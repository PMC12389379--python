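# Methods

This note records the models, conventions and numerical choices behind
`bibliomir`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, which
defaults matter, and what the synthetic test bed does and does not show.

## Corpus model and record identity

A corpus is an ordered list of bibliographic records in the Scopus
export column set. Record identity is the lowercased DOI when present;
otherwise a SHA-1 hash of (first author surname, year, normalised
title), where title normalisation keeps lowercased alphanumeric tokens
only. A stable key is required because local-citation scoring must match
free-text reference strings back to records. Rows with unparseable
years or empty author lists are kept and flagged `incomplete` rather
than dropped, so completeness statistics (e.g. the share of records
lacking a correspondence address) remain computable over the full
corpus. The manual relevance screen is consumed as a keep-list of
record ids and never re-derived: relevance screening is human judgment,
an input to the analysis, not part of it.

## Citation scores

- **GCS** is read directly from the export ("Cited by").
- **LCS** counts corpus records whose reference list matches the
  document. Matching is DOI-substring first (case-insensitive); for
  records without a DOI, a reference matches when it contains the first
  author's surname and the publication year and the containment of the
  title's alphanumeric tokens in the reference string reaches the
  `match_threshold` (default 0.90). The threshold is exposed because
  reference strings are free text; the default was chosen as strict
  enough that distractor references in the synthetic noise suite never
  match. Self-citations of a record to itself are excluded; references
  to out-of-corpus work match nothing and are ignored.
- **TC/Y** divides total citations by the inclusive citation-year span
  `ref_year − pub_year + 1`. Inclusive counting is this package's
  declared convention: it is the convention under which the per-year
  rates of all ten top-cited CRC–miRNA articles (92.72, 77.5, 49.44, …)
  reproduce exactly at reference year 2025, which the test suite
  asserts row by row.
- **Growth rate** is the endpoint-based annualised geometric rate; it
  is undefined when the first year has zero publications, and
  intermediate zero years do not enter the formula.
- **TC/NP** is reported as plain division. Published year tables in
  this literature occasionally print TC/NP values inconsistent with
  plain division (e.g. 53.89 for TC=108, NP=2); we do not imitate an
  undocumented divisor.

Displayed percentages and rates use round-half-up at the displayed
precision, applied only at formatting time.

## miRNA extraction and validation

The mention grammar accepts an optional three-letter species prefix, a
stem in {miR, mir, miRNA, microRNA} with an optional hyphen/space
separator, a number, an optional letter suffix, an optional numeric
paralog suffix, and an optional `-5p`/`-3p` arm; the let-7 family is a
separate branch (no number of its own). Matching is case-insensitive,
non-overlapping, leftmost-longest, and bounded so that gene symbols
such as `MIR155HG` are rejected. Canonicalisation strips the species
prefix, folds the stem to `miR` (or `let-7`) and lowercases the letter
suffix while preserving paralog and arm suffixes.

Validation prefixes the canonical id with the configured species
(default `hsa`) and looks it up case-folded in the union of all loaded
catalog releases plus the alias map, so mature (`hsa-miR-21`) and
precursor (`hsa-mir-21`) casings are interchangeable and renamed
entries (e.g. `mir-203` → `mir-203a`) still validate through their
aliases. Releases are unioned rather than ordered by precedence: a name
valid in any loaded release passes. Arm-level identity is preserved
(`miR-195` ≠ `miR-195-5p`) because the literature ranks arm-resolved
ids as distinct entries.

Counting is article-level: a record contributes at most 1 to a
(miRNA, year) cell regardless of how many fields mention the id. The
`mean_since_first` ranking metric divides the cumulative article count
by the inclusive span from first appearance to the analysis window end
(a miRNA first seen 2008 with window end 2024 divides by 17); the
inclusive-span convention is declared and tested as such.

The bundled catalog is a hand-curated, synthetic three-release subset
(~50 entries per release) in the aliases file format, sufficient for
desk-scale analysis and testing; real full-release dumps can be passed
in the same format.

## Country attribution

The country of an affiliation is its last comma-separated token
resolved through an editable alias table ("PR China" → China, "USA" →
United States, …); unresolved strings are excluded with a logged
reason, never guessed or pooled. Appearance counting is
affiliation-level: an author listed under institutions in two countries
contributes one appearance to each. SCP/MCP classification uses the
corresponding-author country only (no first-author fallback); a record
is MCP when any co-author's resolved country differs from it. The
headline MCP rate is printed at integer precision, other shares at one
or two decimals (precision is a formatting option).

## Networks and clustering

Collaboration networks use full counting (node weight = articles with
at least one author from the country; edge weight = articles containing
the country pair). Keyword co-occurrence supports full and fractional
counting; under fractional counting an article with k kept keywords
adds `1/(k−1)` to each of its keyword pairs, so each keyword
distributes exactly unit weight per article — the unit-distribution
property the tests check. Fractional counting is the default for
keyword maps, full counting for collaboration maps.

Association-strength normalisation is `s_ij = 2m·c_ij/(w_i·w_j)` with
`m` the total link weight; it preserves node weights and edge support.

Walktrap community detection delegates to igraph's Pons–Latapy
implementation (walk length 4 by default), run per connected component
and cut at maximum modularity, so disconnected graphs and isolates are
handled deterministically.

The resolution-parameterised clusterer maximises
`Σ_{i<j, same cluster} (s_ij − γ·w_i·w_j/(2m))` — observed minus a
resolution-scaled configuration-model expectation on node occurrence
weights — by multi-level local moving (greedy node moves, then cluster
aggregation, repeated to convergence) with 10 seeded random restarts
(default seed 20240925), keeping the best-quality restart. In the γ→0
limit this yields one cluster per connected component, which the tests
assert. Clusters below `min_cluster_size` (default 10) are merged,
smallest first, into the neighbouring cluster with the largest
connecting weight; small clusters with no connection are flagged
*residual* rather than silently merged or hidden. Ties everywhere break
deterministically (lexicographic node/cluster order).

Pruning for reporting keeps the `max_nodes` heaviest nodes (ties
lexicographic) and then iteratively removes nodes below the minimum
degree, eliminating isolates. Force-directed layout parameters of
visualisation tools are out of scope.

## Keyword normalisation

Keywords are lowercased, unicode dashes folded to hyphen, whitespace
collapsed, then mapped through a one-step thesaurus (chained synonym
maps are rejected at construction) and finally tested against the
exclusion set — exclusion after mapping, so excluding a preferred term
removes all its variants, including the literature-search query terms
that would otherwise dominate every table. Counting is article-level.

## Synthetic corpus generator

The generator is first-class, tested code: it defines the conditions
under which the pipeline's correctness is demonstrated.

Defaults, chosen once to emulate the study corpus:

| parameter | default | rationale |
|---|---|---|
| `n_records` | 828 | study corpus size |
| `year_weights` | observed 2008–2024 annual counts | reproduces the three phases exactly at n=828 (largest-remainder apportionment), including the zero year 2010 |
| `country_mixture` | China 0.857 + published minor shares | corresponding-authorship distribution of the study corpus |
| `collab_prob` | 0.05 | the dominant country's MCP rate is ≈3% |
| `missing_correspondence_rate` | 41/828 | planted as an exact count, so the integer-precision share prints 5% |
| `mirna_zipf` | 1.2 | strongly head-dominated mention distribution (miR-21 first) |
| mention noise rates | 0.15/0.10/0.10 case/spacing/prefix | realistic token variants, all grammar-valid by construction |
| `invalid_mention_rate` | 0.05 | catalog-invalid ids (`miR-9xxx`) planted as negative controls |
| keyword head counts | published word-cloud counts (proliferation 117, metastasis 79, …) | planted as exact article counts at n=828; the therapy-response block sizes (chemoresistance 40, oxaliplatin 25, 5-FU 22) are generator choices giving that block enough mass to cluster |
| `keyword_zipf`, `n_tail_keywords` | 0.5, 300 | a flat, long tail of rare descriptors that stays below the planted head, as in the real word cloud |
| `citation_density` | 1.0 | expected within-corpus citations per record |
| `gcs_inflation` | 5.0 | out-of-corpus citations, guaranteeing GCS ≥ in-corpus in-degree |

Within-corpus citations are drawn backward in time only (a record cites
strictly earlier years), preferring recent targets (weight
`1/(gap+1)`), which produces the realistic asymmetry that older records
accumulate local citations. Reference strings embed the cited record's
DOI, so LCS recovery is exact by construction of the matcher's DOI
path; the fuzzy path is exercised separately on DOI-less fixtures.

What the generator does **not** emulate: real titles and author names,
multi-affiliation authors at realistic rates, reference-string
formatting diversity (it emits one clean style), indexing errors,
duplicate records, and non-English documents. Passing tests therefore
demonstrate the pipeline's arithmetic and matching logic under clean,
known-truth conditions — not robustness to the full messiness of real
database exports, for which the configurable thresholds (title
similarity, alias tables, thesauri) are the intended adjustment points.

## Problem sizes and determinism

The test suite and acceptance script run at the study's own scale
(828-record corpora; a 1385-record screening re-enactment; a 500-record
corpus for citation-graph recovery; 24–30-node planted partition
graphs), which this pipeline processes in seconds. Every stochastic
component — corpus generation, planted graphs, clustering restarts —
is driven by explicit integer seeds; the pipeline stamps every artifact
with a hash of the analysis parameters plus the seed, and a rerun with
the same config is byte-identical.

## Known limitations

- Reference matching assumes DOIs, when present, appear verbatim in
  reference strings; mangled DOIs fall through to the fuzzy path only
  for DOI-less target records.
- Country resolution depends on the alias table; affiliations whose
  final token is a city or postal code resolve to nothing and are
  excluded (logged), which can undercount countries in poorly formatted
  exports.
- The resolution clusterer optimises a modularity-variant objective by
  local moving; like all such heuristics it is not guaranteed globally
  optimal, which restarts mitigate but do not eliminate.
- The bundled miRNA catalog is a representative subset; analyses of
  real corpora should load full release files.
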