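"""The five query workflows over a built backend index.

1.  ``genus_ego_network`` — all genera associated with a query genus, as a
    star network ranked by co-occurrence strength (top 100 by default),
    optionally restricted to articles mentioning selected diseases.
2a. ``disease_association_view`` — top genera for a disease with Fisher
    significance flags.
2b. ``genus_disease_view`` — the mirror: all diseases for a genus.
3a. ``validate_network`` — literature evidence for a user-uploaded edge
    list: supporting PMIDs, keywords and the nine evidence counts per edge.
3b. ``validate_list`` — evidence for a differential-genera list against a
    disease, plus hypergeometric enrichment over the disease sets.

Every ranked output is deterministic: count descending, alphabetical
tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import assoc_stats as stats
from .backend_index import (
    BackendIndex,
    EvidenceStats,
    UnknownEntityError,
    count_cooccurrence,
    evidence_stats,
    keyword_frequencies,
)
from .lexicon import normalize_genus

DEFAULT_TOP_EDGES = 100
DEFAULT_TOP_GENERA = 30


class EdgeListError(ValueError):
    """Malformed user edge list."""


@dataclass
class Edge:
    genus_1: str
    genus_2: str
    weight: float | None = None


@dataclass
class EdgeInfo:
    neighbor: str
    evidence_count: int
    p_fisher: float
    p_chi2: float
    significant: bool


@dataclass
class RankedNetwork:
    center: str
    edges: list[EdgeInfo]
    truncated: bool


def genus_ego_network(
    index: BackendIndex,
    genus: str,
    top_n: int = DEFAULT_TOP_EDGES,
    disease_filter: Iterable[str] | None = None,
    filter_mode: str = "any",
    alpha: float = stats.DEFAULT_ALPHA,
) -> RankedNetwork:
    """Star network of genera co-occurring with ``genus``.

    With ``disease_filter``, only articles mentioning any (default) or all
    (``filter_mode="all"``) of the given diseases are considered, and the
    contingency universe becomes that article set.
    """
    if genus not in index.known_genera:
        raise UnknownEntityError(f"{genus!r} is not a lexicon genus")
    if disease_filter is not None:
        scope: set[str] = set()
        diseases = list(disease_filter)
        for i, d in enumerate(diseases):
            if d not in index.known_diseases:
                raise UnknownEntityError(f"{d!r} is not a lexicon disease")
            dp = index.disease_pmids.get(d, set())
            if filter_mode == "any":
                scope |= dp
            elif filter_mode == "all":
                scope = dp if i == 0 else scope & dp
            else:
                raise ValueError(f"invalid filter_mode {filter_mode!r}")
    else:
        scope = index.all_pmids()

    pq = index.genus_pmids.get(genus, set()) & scope
    neighbors = []
    for other, po in index.genus_pmids.items():
        if other == genus:
            continue
        count = len(pq & po & scope)
        if count > 0:
            neighbors.append((other, count))
    neighbors.sort(key=lambda nc: (-nc[1], nc[0]))
    truncated = len(neighbors) > top_n
    edges = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.SmallCountWarning)
        warnings.simplefilter("ignore", stats.DegenerateTableWarning)
        for other, count in neighbors[:top_n]:
            # table over the scoped universe, entity sets restricted to it
            po = index.genus_pmids.get(other, set()) & scope
            a = len(pq & po)
            t = stats.ContingencyTable2x2(
                a, len(pq) - a, len(po) - a,
                len(scope) - len(pq) - len(po) + a,
            )
            p_f, _ = stats.fisher_exact_test(t)
            _, p_c = stats.chi2_test(t)
            edges.append(
                EdgeInfo(neighbor=other, evidence_count=count,
                         p_fisher=p_f, p_chi2=p_c, significant=p_f < alpha)
            )
    return RankedNetwork(center=genus, edges=edges, truncated=truncated)


def disease_association_view(
    index: BackendIndex,
    disease: str,
    top_k: int = DEFAULT_TOP_GENERA,
    alpha: float = stats.DEFAULT_ALPHA,
) -> list[stats.AssociationResult]:
    """Top genera associated with a disease, with significance flags."""
    return stats.disease_genus_significance(index, disease, alpha)[:top_k]


def genus_disease_view(
    index: BackendIndex,
    genus: str,
    alpha: float = stats.DEFAULT_ALPHA,
) -> list[stats.AssociationResult]:
    """All diseases associated with a genus, ranked by evidence count."""
    if genus not in index.known_genera:
        raise UnknownEntityError(f"{genus!r} is not a lexicon genus")
    pg = index.genus_pmids.get(genus, set())
    tested = sorted(
        d for d, ps in index.disease_pmids.items() if ps & pg
    )
    m = len(tested)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.SmallCountWarning)
        warnings.simplefilter("ignore", stats.DegenerateTableWarning)
        for d in tested:
            t = stats.make_contingency(index, genus, d)
            p_f, odds = stats.fisher_exact_test(t)
            _, p_c = stats.chi2_test(t)
            results.append(
                stats.AssociationResult(
                    entity_pair=(genus, d),
                    cooccurrence_count=t.a,
                    odds_ratio=odds,
                    p_fisher=p_f,
                    p_chi2=p_c,
                    p_bonferroni=stats.bonferroni_adjust(p_f, m),
                    significant=p_f < alpha,
                )
            )
    results.sort(key=lambda r: (-r.cooccurrence_count, r.entity_pair[1]))
    return results


def association_pmids(index: BackendIndex, e1: str, e2: str) -> list[str]:
    """Sorted PMIDs in which both entities co-occur (globally)."""
    return sorted(index.pmids_for(e1) & index.pmids_for(e2))


# --- Module 3a: edge-list validation ---------------------------------------

def parse_edge_list(source: str | Path | Iterable[str]) -> list[Edge]:
    """Parse a TSV edge list: 2 or 3 columns (genus, genus, optional
    weight), ``#`` comment lines, case-normalized genus names.

    Self-loops and duplicate unordered pairs are rejected.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = list(source)
    edges: list[Edge] = []
    seen: set[frozenset[str]] = set()
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) == 1:  # allow whitespace-separated fallback
            parts = line.split()
        if len(parts) not in (2, 3):
            raise EdgeListError(f"line {lineno}: expected 2 or 3 columns")
        g1, g2 = normalize_genus(parts[0]), normalize_genus(parts[1])
        if g1 == g2:
            raise EdgeListError(f"line {lineno}: self-loop {g1!r}")
        key = frozenset((g1, g2))
        if key in seen:
            raise EdgeListError(
                f"line {lineno}: duplicate pair {g1!r}-{g2!r}"
            )
        seen.add(key)
        weight = None
        if len(parts) == 3:
            try:
                weight = float(parts[2])
            except ValueError as exc:
                raise EdgeListError(
                    f"line {lineno}: invalid weight {parts[2]!r}"
                ) from exc
            if weight < 0:
                raise EdgeListError(f"line {lineno}: negative weight")
        edges.append(Edge(genus_1=g1, genus_2=g2, weight=weight))
    return edges


@dataclass
class EdgeReport:
    edge: Edge
    stats: EvidenceStats | None
    supporting_pmids: list[str] = field(default_factory=list)
    keywords: list[tuple[str, int]] = field(default_factory=list)
    no_literature_evidence: bool = False
    unmapped_genera: list[str] = field(default_factory=list)


def validate_network(
    index: BackendIndex, edges: list[Edge], disease: str
) -> list[EdgeReport]:
    """Literature evidence report for every edge of a user network.

    Edges whose genera are outside the lexicon are kept with null stats and
    the offending names listed; edges with zero global co-occurrence are
    flagged ``no_literature_evidence``.
    """
    if disease not in index.known_diseases:
        raise UnknownEntityError(f"{disease!r} is not a lexicon disease")
    d_pmids = index.disease_pmids.get(disease, set())
    reports = []
    for edge in edges:
        unmapped = [g for g in (edge.genus_1, edge.genus_2)
                    if g not in index.known_genera]
        if unmapped:
            reports.append(EdgeReport(edge=edge, stats=None,
                                      unmapped_genera=unmapped))
            continue
        es = evidence_stats(index, edge.genus_1, edge.genus_2, disease)
        support = sorted(
            index.genus_pmids.get(edge.genus_1, set())
            & index.genus_pmids.get(edge.genus_2, set())
            & d_pmids
        )
        kws = keyword_frequencies(index, set(support)) if support else []
        reports.append(
            EdgeReport(
                edge=edge, stats=es, supporting_pmids=support,
                keywords=kws,
                no_literature_evidence=es.global_.count_both == 0,
            )
        )
    return reports


# --- Module 3b: differential-list validation -------------------------------

@dataclass
class GenusEvidence:
    genus: str
    cooccurrence_count: int
    p_fisher: float
    p_bonferroni: float
    significant: bool
    supporting_pmids: list[str]
    other_diseases: list[stats.AssociationResult]


@dataclass
class ListValidationReport:
    disease: str
    per_genus: list[GenusEvidence]
    unmapped: list[str]
    enrichment: list[tuple[str, int, float]]


def validate_list(
    index: BackendIndex,
    genera: Iterable[str],
    disease: str,
    sets: dict[str, set[str]] | None = None,
    alpha: float = stats.DEFAULT_ALPHA,
    enrichment_universe: set[str] | None = None,
) -> ListValidationReport:
    """Evidence + enrichment for a differentially-abundant genera list.

    Unknown genera are reported under ``unmapped`` and excluded from the
    tests.  The enrichment universe defaults to the genera observed in the
    corpus (plus the mapped query genera); disease sets default to the
    Fisher-significant sets built from this index at ``alpha``.
    """
    raw = [normalize_genus(g) for g in genera]
    if not raw:
        raise ValueError("empty genus list: nothing to validate")
    if disease not in index.known_diseases:
        raise UnknownEntityError(f"{disease!r} is not a lexicon disease")
    mapped = [g for g in raw if g in index.known_genera]
    unmapped = [g for g in raw if g not in index.known_genera]

    d_pmids = index.disease_pmids.get(disease, set())
    m = max(len(mapped), 1)
    per_genus = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.SmallCountWarning)
        warnings.simplefilter("ignore", stats.DegenerateTableWarning)
        for g in mapped:
            t = stats.make_contingency(index, g, disease)
            p_f, _ = stats.fisher_exact_test(t)
            support = sorted(index.genus_pmids.get(g, set()) & d_pmids)
            per_genus.append(
                GenusEvidence(
                    genus=g,
                    cooccurrence_count=t.a,
                    p_fisher=p_f,
                    p_bonferroni=stats.bonferroni_adjust(p_f, m),
                    significant=p_f < alpha,
                    supporting_pmids=support,
                    other_diseases=genus_disease_view(index, g, alpha),
                )
            )
    per_genus.sort(key=lambda r: (-r.cooccurrence_count, r.genus))

    if sets is None:
        sets = stats.build_disease_sets(index, alpha)
    if enrichment_universe is None:
        enrichment_universe = set(index.genus_pmids) | set(mapped)
    enrichment = stats.enrich(set(mapped), sets, enrichment_universe) if mapped else []
    return ListValidationReport(
        disease=disease, per_genus=per_genus,
        unmapped=unmapped, enrichment=enrichment,
    )
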