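"""Shared fixtures: published table inputs and a session-scoped synthetic corpus."""

from __future__ import annotations

import pytest

from bibliomir import generate_corpus, study_like_config
from bibliomir.keywords import Thesaurus
from bibliomir.synth import QUERY_TERMS

#: annual publication (NP) and citation (TC) counts of the 828-article
#: CRC-miRNA study corpus, 2008-2024 (published descriptive table)
ANNUAL_NP = {
    2008: 2, 2009: 1, 2010: 0, 2011: 5, 2012: 7, 2013: 10, 2014: 21,
    2015: 31, 2016: 44, 2017: 62, 2018: 96, 2019: 87, 2020: 125,
    2021: 115, 2022: 89, 2023: 71, 2024: 62,
}
ANNUAL_TC = {
    2008: 108, 2009: 11, 2010: 0, 2011: 52, 2012: 42, 2013: 72, 2014: 124,
    2015: 157, 2016: 184, 2017: 401, 2018: 552, 2019: 545, 2020: 664,
    2021: 409, 2022: 224, 2023: 117, 2024: 20,
}

#: top-10 most globally cited articles: (label, year, total citations,
#: published TC/Y at reference year 2025)
TOP_CITED = [
    ("Asangani IA", 2008, 1669, 92.72),
    ("Zhao S", 2020, 465, 77.5),
    ("Han P", 2017, 445, 49.44),
    ("Vogt M", 2011, 299, 19.93),
    ("Grady WM", 2008, 271, 15.06),
    ("Toiyama Y", 2014, 261, 21.75),
    ("Zhang X", 2017, 206, 22.89),
    ("Zhao L", 2016, 192, 19.2),
    ("Schimanski CC", 2009, 186, 10.94),
    ("Karaayvaz M", 2013, 180, 13.85),
]


@pytest.fixture(scope="session")
def synthetic():
    """Paper-like synthetic corpus (828 records) with its ground truth."""
    return generate_corpus(study_like_config(seed=1234))


@pytest.fixture(scope="session")
def synthetic_corpus(synthetic):
    return synthetic[0]


@pytest.fixture(scope="session")
def ground_truth(synthetic):
    return synthetic[1]


@pytest.fixture(scope="session")
def query_thesaurus():
    """Thesaurus excluding the literature-search query terms."""
    return Thesaurus(exclusion_set=set(QUERY_TERMS))
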