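"""The backend lookup tables: who mentions what, where, with what trend.

All association statistics downstream are *article-level*: a genus
mentioned five times in one abstract counts once, and co-occurrence
strength is the number of distinct PMIDs where two entities are both
mentioned.  Articles with no mapped entity stay in the corpus and in
``N`` — the statistical universe is the indexed corpus (switchable to
mapped-articles-only when building contingency tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable

from .corpus_io import Article
from .lexicon import DiseaseEntry, GenusLexicon
from . import ner_normalize as ner

logger = logging.getLogger(__name__)

SCOPES = ("global", "any_disease", "disease")


class UnknownEntityError(KeyError):
    """Entity not present in the lexicons the index was built with."""


@dataclass
class PipelineConfig:
    """Knobs for index construction.

    max_edit: Levenshtein budget for fuzzy genus matching (0 disables).
    trend_window: token window for trend keyword attachment.
    extract_keywords: store per-article keyword counts (word-cloud data).
    """

    max_edit: int = 1
    trend_window: int = 8
    extract_keywords: bool = True


@dataclass
class PairCounts:
    count_g1: int
    count_g2: int
    count_both: int


@dataclass
class EvidenceStats:
    """Occurrence counts of a genus pair at the three evidence scopes."""

    given_disease: PairCounts
    any_disease: PairCounts
    global_: PairCounts

    def as_dict(self) -> dict:
        return {
            "given_disease": asdict(self.given_disease),
            "any_disease": asdict(self.any_disease),
            "global": asdict(self.global_),
        }


@dataclass
class BackendIndex:
    articles: dict[str, Article] = field(default_factory=dict)
    genus_pmids: dict[str, set[str]] = field(default_factory=dict)
    disease_pmids: dict[str, set[str]] = field(default_factory=dict)
    pmid_genera: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    pmid_diseases: dict[str, list[str]] = field(default_factory=dict)
    pmid_keywords: dict[str, dict[str, int]] = field(default_factory=dict)
    known_genera: set[str] = field(default_factory=set)
    known_diseases: set[str] = field(default_factory=set)
    build_params: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.articles)

    def all_pmids(self) -> set[str]:
        return set(self.articles)

    def mapped_pmids(self) -> set[str]:
        """PMIDs with at least one recognized genus."""
        return {p for p, gs in self.pmid_genera.items() if gs}

    def any_disease_pmids(self) -> set[str]:
        out: set[str] = set()
        for ps in self.disease_pmids.values():
            out |= ps
        return out

    def pmids_for(self, entity: str) -> set[str]:
        """PMID set of a known genus or disease (error if not in lexicon)."""
        if entity in self.known_genera:
            return self.genus_pmids.get(entity, set())
        if entity in self.known_diseases:
            return self.disease_pmids.get(entity, set())
        raise UnknownEntityError(
            f"{entity!r} is not in the lexicons of this index"
        )


def build_index(
    articles: Iterable[Article],
    genus_lexicon: GenusLexicon,
    disease_lexicon: list[DiseaseEntry],
    config: PipelineConfig | None = None,
) -> BackendIndex:
    """Run recognition over every article and populate all backend tables."""
    config = config or PipelineConfig()
    index = BackendIndex(
        known_genera=set(genus_lexicon.genera),
        known_diseases={e.canonical for e in disease_lexicon},
        build_params={
            "max_edit": config.max_edit,
            "trend_window": config.trend_window,
            "extract_keywords": config.extract_keywords,
        },
    )
    for art in articles:
        if art.pmid in index.articles:
            logger.warning("duplicate PMID %s dropped at build", art.pmid)
            continue
        index.articles[art.pmid] = art

        g_mentions = ner.recognize_genera(art, genus_lexicon, config.max_edit)
        d_mentions = ner.recognize_diseases(art, disease_lexicon)
        trends = ner.detect_trends(art, g_mentions, window=config.trend_window)
        trend_by_genus = {t.genus: t.trend for t in trends}

        genera = sorted({m.canonical for m in g_mentions})
        diseases = sorted({m.canonical for m in d_mentions})
        if genera:
            index.pmid_genera[art.pmid] = [
                (g, trend_by_genus.get(g, 0)) for g in genera
            ]
            for g in genera:
                index.genus_pmids.setdefault(g, set()).add(art.pmid)
        if diseases:
            index.pmid_diseases[art.pmid] = diseases
            for d in diseases:
                index.disease_pmids.setdefault(d, set()).add(art.pmid)
        if config.extract_keywords:
            kws = ner.extract_noun_keywords(art)
            if kws:
                index.pmid_keywords[art.pmid] = dict(kws)
    return index


def _scope_pmids(index: BackendIndex, scope) -> set[str]:
    """Resolve a scope spec to a PMID set.

    ``scope`` is ``"global"``, ``"any_disease"``, or ``("disease", name)``.
    """
    if scope == "global":
        return index.all_pmids()
    if scope == "any_disease":
        return index.any_disease_pmids()
    if isinstance(scope, tuple) and len(scope) == 2 and scope[0] == "disease":
        disease = scope[1]
        if disease not in index.known_diseases:
            raise UnknownEntityError(f"{disease!r} is not a lexicon disease")
        return index.disease_pmids.get(disease, set())
    raise ValueError(f"invalid scope {scope!r}")


def count_occurrence(index: BackendIndex, entity: str, scope="global") -> int:
    """Number of articles containing ``entity`` within ``scope``."""
    return len(index.pmids_for(entity) & _scope_pmids(index, scope))


def count_cooccurrence(index: BackendIndex, e1: str, e2: str, scope="global") -> int:
    """Number of articles containing both entities within ``scope``.

    Symmetric; the degenerate call with ``e1 == e2`` returns
    ``count_occurrence(e1)``.
    """
    p1, p2 = index.pmids_for(e1), index.pmids_for(e2)
    return len(p1 & p2 & _scope_pmids(index, scope))


def evidence_stats(index: BackendIndex, g1: str, g2: str, disease: str) -> EvidenceStats:
    """All nine occurrence counts of a genus pair at the three scopes."""
    def counts(scope) -> PairCounts:
        return PairCounts(
            count_g1=count_occurrence(index, g1, scope),
            count_g2=count_occurrence(index, g2, scope),
            count_both=count_cooccurrence(index, g1, g2, scope),
        )

    return EvidenceStats(
        given_disease=counts(("disease", disease)),
        any_disease=counts("any_disease"),
        global_=counts("global"),
    )


def search_pmids(
    index: BackendIndex,
    disease: str | None = None,
    genera: Iterable[str] | None = None,
    free_text_keyword: str | None = None,
) -> set[str]:
    """PMIDs satisfying the conjunction of the given constraints."""
    result = index.all_pmids()
    if disease is not None:
        result &= _scope_pmids(index, ("disease", disease))
    if genera:
        for g in genera:
            result &= index.pmids_for(g)
    if free_text_keyword:
        kw = free_text_keyword.lower()
        result = {
            p for p in result
            if kw in index.pmid_keywords.get(p, {})
            or kw in index.articles[p].text.lower()
        }
    return result


def keyword_frequencies(
    index: BackendIndex,
    pmids: set[str],
    secondary_term: str | None = None,
) -> list[tuple[str, int]]:
    """Summed keyword counts over a PMID set (word-cloud data).

    ``secondary_term`` first narrows the articles to those whose text
    contains the term (case-insensitive).  Ties are broken alphabetically.
    """
    unknown = pmids - index.all_pmids()
    if unknown:
        raise KeyError(f"pmids not in index: {sorted(unknown)[:5]}")
    if secondary_term:
        t = secondary_term.lower()
        pmids = {p for p in pmids if t in index.articles[p].text.lower()}
    totals: dict[str, int] = {}
    for p in pmids:
        for k, c in index.pmid_keywords.get(p, {}).items():
            totals[k] = totals.get(k, 0) + c
    return sorted(totals.items(), key=lambda kc: (-kc[1], kc[0]))
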