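"""Statistical assessment of literature co-occurrence.

Association between two entities is tested on a 2x2 article-count
contingency table

    a = articles with both      b = with the first only
    c = with the second only    d = with neither

against the indexed-corpus universe (cell ``d`` includes articles with no
mapped entity; a mapped-only universe is available).  The Fisher exact test
is the exact hypergeometric tail of ``a`` — one-sided "greater" by default,
matching the association/enrichment reading — and the chi-square test is
the Pearson statistic on 1 df (Yates correction optional, off by default).
Multiple testing uses the Bonferroni correction ``min(1, p*m)``.

Disease sets — the genera significantly associated with each disease —
feed a hypergeometric enrichment test for user genus lists:
``P(X >= |query ∩ set|)`` drawing ``|query|`` genera without replacement
from the universe of observed genera.

Disease similarity within an organ category uses the co-occurrence count
matrix of the globally top-m "persistent" genera, rows normalized to unit
sum, clustered bidirectionally with UPGMA (average linkage) on Euclidean
distances.  The UPGMA implementation is deterministic: among equal-distance
merge candidates the lexicographically smallest pair of clusters merges
first, so dendrograms are reproducible across runs and platforms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .backend_index import BackendIndex, UnknownEntityError
from .lexicon import DiseaseEntry, diseases_by_category

DEFAULT_ALPHA = 0.05


class SmallCountWarning(UserWarning):
    """An expected cell below 5; the chi-square approximation is rough."""


class DegenerateTableWarning(UserWarning):
    """Empty or zero-margin table; the test result is a convention."""


# --- contingency tables ----------------------------------------------------

@dataclass
class ContingencyTable2x2:
    a: int  # both
    b: int  # first only
    c: int  # second only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def make_contingency(
    index: BackendIndex,
    entity_a: str,
    entity_b: str,
    universe="indexed_corpus",
) -> ContingencyTable2x2:
    """2x2 article-count table for two entities.

    ``universe`` is ``"indexed_corpus"`` (all indexed articles, default),
    ``"mapped_only"`` (articles with at least one recognized genus), or an
    explicit PMID set, which must cover both entities' articles.
    """
    if entity_a == entity_b:
        raise ValueError("contingency requires two distinct entities")
    pa, pb = index.pmids_for(entity_a), index.pmids_for(entity_b)
    if universe == "indexed_corpus":
        uni = index.all_pmids()
    elif universe == "mapped_only":
        uni = index.mapped_pmids() | pa | pb
    else:
        uni = set(universe)
        missing = (pa | pb) - uni
        if missing:
            raise ValueError(
                f"universe does not cover {len(missing)} article(s) "
                f"mentioning the entities"
            )
    pa, pb = pa & uni, pb & uni
    a = len(pa & pb)
    b = len(pa) - a
    c = len(pb) - a
    d = len(uni) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


# --- tests -----------------------------------------------------------------

def fisher_exact_test(
    table: ContingencyTable2x2, alternative: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test; returns ``(p_value, odds_ratio)``.

    ``alternative`` is ``"greater"`` (default — excess co-occurrence) or
    ``"two_sided"``.  The odds ratio is the sample ratio ``ad/bc``
    (``inf`` when ``bc == 0`` and ``ad > 0``).  An empty table yields
    ``p = 1`` by convention with a :class:`DegenerateTableWarning`.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.N == 0:
        warnings.warn("empty contingency table", DegenerateTableWarning,
                      stacklevel=2)
        return 1.0, math.nan
    alt = "two-sided" if alternative == "two_sided" else "greater"
    _, p = sps.fisher_exact(table.as_array(), alternative=alt)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return float(p), odds


def chi2_test(
    table: ContingencyTable2x2, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on 1 df; returns ``(statistic, p_value)``.

    A zero row or column margin makes the statistic undefined: ``(nan,
    nan)`` is returned with a :class:`DegenerateTableWarning`.  Expected
    cells below 5 raise a :class:`SmallCountWarning`.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin: chi-square undefined",
                      DegenerateTableWarning, stacklevel=2)
        return math.nan, math.nan
    stat, p, _, expected = sps.chi2_contingency(arr, correction=yates)
    if (expected < 5).any():
        warnings.warn("expected cell below 5", SmallCountWarning, stacklevel=2)
    return float(stat), float(p)


def bonferroni_adjust(p: float, m: int) -> float:
    """``min(1, p * m)`` for a family of ``m`` tests."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p * m)


# --- per-disease association screens --------------------------------------

@dataclass
class AssociationResult:
    entity_pair: tuple[str, str]
    cooccurrence_count: int
    odds_ratio: float
    p_fisher: float
    p_chi2: float
    p_bonferroni: float
    significant: bool


def disease_genus_significance(
    index: BackendIndex,
    disease: str,
    alpha: float = DEFAULT_ALPHA,
    universe="indexed_corpus",
) -> list[AssociationResult]:
    """Fisher screen of every genus co-occurring with a disease.

    One result per genus with nonzero co-occurrence, Bonferroni family =
    number of genera tested for this disease, sorted by co-occurrence count
    descending (alphabetical tie-break).  ``significant`` is the raw
    one-sided Fisher p against ``alpha``.
    """
    if disease not in index.known_diseases:
        raise UnknownEntityError(f"{disease!r} is not a lexicon disease")
    d_pmids = index.disease_pmids.get(disease, set())
    if not d_pmids:
        return []
    tested = sorted(
        g for g, ps in index.genus_pmids.items() if ps & d_pmids
    )
    m = len(tested)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallCountWarning)
        warnings.simplefilter("ignore", DegenerateTableWarning)
        for g in tested:
            t = make_contingency(index, g, disease, universe=universe)
            p_f, odds = fisher_exact_test(t, "greater")
            _, p_c = chi2_test(t)
            results.append(
                AssociationResult(
                    entity_pair=(g, disease),
                    cooccurrence_count=t.a,
                    odds_ratio=odds,
                    p_fisher=p_f,
                    p_chi2=p_c,
                    p_bonferroni=bonferroni_adjust(p_f, m),
                    significant=p_f < alpha,
                )
            )
    results.sort(key=lambda r: (-r.cooccurrence_count, r.entity_pair[0]))
    return results


def build_disease_sets(
    index: BackendIndex, alpha: float = DEFAULT_ALPHA
) -> dict[str, set[str]]:
    """Disease → significantly associated genera, for every lexicon disease."""
    return {
        d: {r.entity_pair[0]
            for r in disease_genus_significance(index, d, alpha)
            if r.significant}
        for d in sorted(index.known_diseases)
    }


# --- enrichment ------------------------------------------------------------

def enrich(
    query_genera: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
) -> list[tuple[str, int, float]]:
    """Hypergeometric enrichment of a genus list against disease sets.

    For each disease set K: ``p = P(X >= |query ∩ K|)`` with X
    hypergeometric(|universe|, |K|, |query|).  Sorted by p ascending
    (alphabetical tie-break).
    """
    offenders = sorted(set(query_genera) - set(universe))
    if offenders:
        raise ValueError(f"query genera outside universe: {offenders}")
    M, n_draw = len(universe), len(query_genera)
    out = []
    for disease, K in sets.items():
        K = set(K) & set(universe)
        k_obs = len(set(query_genera) & K)
        p = float(sps.hypergeom.sf(k_obs - 1, M, len(K), n_draw))
        out.append((disease, k_obs, min(p, 1.0)))
    out.sort(key=lambda r: (r[2], r[0]))
    return out


# --- per-category summary (organ-level view) -------------------------------

@dataclass
class CategoryGenusRow:
    genus: str
    article_count: int
    p_fisher: float
    p_bonferroni: float
    significant: bool
    significant_bonferroni: bool


def category_top_genera(
    index: BackendIndex,
    disease_lexicon: list[DiseaseEntry],
    k: int = 10,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, list[CategoryGenusRow]]:
    """Top-k genera per organ category with significance flags.

    Each category pools the article sets of its diseases; genera are ranked
    by article count within the pool and tested (Fisher, greater) for
    association with the pooled set, Bonferroni family = genera tested in
    that category.
    """
    by_cat = diseases_by_category(disease_lexicon)
    out: dict[str, list[CategoryGenusRow]] = {}
    N_universe = index.all_pmids()
    for category, diseases in by_cat.items():
        pool: set[str] = set()
        for d in diseases:
            pool |= index.disease_pmids.get(d, set())
        if not pool:
            out[category] = []
            continue
        counts = {
            g: len(ps & pool)
            for g, ps in index.genus_pmids.items()
            if ps & pool
        }
        m = len(counts)
        ranked = sorted(counts.items(), key=lambda gc: (-gc[1], gc[0]))[:k]
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallCountWarning)
            for g, cnt in ranked:
                pg = index.genus_pmids[g]
                a = cnt
                b = len(pg) - a
                c = len(pool) - a
                d = len(N_universe) - a - b - c
                p_f, _ = fisher_exact_test(ContingencyTable2x2(a, b, c, d))
                p_b = bonferroni_adjust(p_f, m)
                rows.append(
                    CategoryGenusRow(
                        genus=g, article_count=cnt, p_fisher=p_f,
                        p_bonferroni=p_b,
                        significant=p_f < alpha,
                        significant_bonferroni=p_b < alpha,
                    )
                )
        out[category] = rows
    return out


# --- UPGMA and disease similarity ------------------------------------------

@dataclass
class UPGMATree:
    """Result of average-linkage clustering.

    ``merges`` follows the scipy linkage convention: row i merges cluster
    ids ``(left, right)`` at ``height`` into new cluster ``n_leaves + i``
    of size ``size``.  ``leaf_order`` is the left-to-right dendrogram leaf
    sequence; ``newick`` renders the ultrametric tree with branch lengths
    ``(parent_height - child_height) / 2``.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[str]
    newick: str


def upgma(labels: list[str], dist: np.ndarray) -> UPGMATree:
    """Deterministic UPGMA over a symmetric distance matrix.

    Cluster distance is the arithmetic mean of all leaf-pair distances
    (classic average linkage, Lance–Williams update).  Ties merge the
    lexicographically smallest pair of clusters, keyed by each cluster's
    smallest leaf label, so output is independent of input order effects.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")

    # active clusters: id -> (key, size, height, members)
    active: dict[int, dict] = {
        i: {"key": labels[i], "size": 1, "height": 0.0, "node": labels[i]}
        for i in range(n)
    }
    D = {
        (i, j): float(dist[i, j])
        for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    children: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}

    while len(active) > 1:
        best = None
        for (i, j), dij in D.items():
            ki, kj = active[i]["key"], active[j]["key"]
            pair_key = (min(ki, kj), max(ki, kj))
            cand = (dij, pair_key, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        dij, _, (i, j) = best
        si, sj = active[i]["size"], active[j]["size"]
        new = {
            "key": min(active[i]["key"], active[j]["key"]),
            "size": si + sj,
            "height": dij,
        }
        children[next_id] = (i, j)
        heights[next_id] = dij
        merges.append((i, j, dij, si + sj))
        # Lance-Williams average-linkage update
        for k in list(active):
            if k in (i, j):
                continue
            dik = D[(min(i, k), max(i, k))]
            djk = D[(min(j, k), max(j, k))]
            D[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        for k in list(D):
            if i in k or j in k:
                del D[k]
        del active[i], active[j]
        active[next_id] = new
        next_id += 1

    root = next(iter(active))

    def walk(node: int) -> tuple[list[str], str]:
        if node < n:
            return [labels[node]], labels[node].replace(" ", "_")
        left, right = children[node]
        # left-to-right order: cluster with the smaller key first
        lkey = min(labels[i] for i in _leaves(left, children, n))
        rkey = min(labels[i] for i in _leaves(right, children, n))
        if rkey < lkey:
            left, right = right, left
        lleaves, lnwk = walk(left)
        rleaves, rnwk = walk(right)
        h = heights[node]
        lb = (h - heights[left]) / 2.0
        rb = (h - heights[right]) / 2.0
        return lleaves + rleaves, f"({lnwk}:{lb:g},{rnwk}:{rb:g})"

    leaf_order, nwk = walk(root)
    return UPGMATree(labels=list(labels), merges=merges,
                     leaf_order=leaf_order, newick=nwk + ";")


def _leaves(node: int, children: dict[int, tuple[int, int]], n: int) -> list[int]:
    if node < n:
        return [node]
    l, r = children[node]
    return _leaves(l, children, n) + _leaves(r, children, n)


@dataclass
class DiseaseSimilarity:
    category: str
    matrix: np.ndarray            # row-normalized counts, diseases x genera
    raw_counts: np.ndarray
    diseases: list[str]
    genera: list[str]
    zero_rows: list[str] = field(default_factory=list)
    disease_tree: UPGMATree | None = None
    genus_tree: UPGMATree | None = None


def persistent_genera(index: BackendIndex, top_m: int = 20) -> list[str]:
    """Globally top-m genera by total evidence count (summed co-occurrence
    article counts over all lexicon diseases)."""
    totals: dict[str, int] = {}
    for g, pg in index.genus_pmids.items():
        total = sum(len(pg & pd) for pd in index.disease_pmids.values())
        if total > 0:
            totals[g] = total
    ranked = sorted(totals.items(), key=lambda gt: (-gt[1], gt[0]))
    return [g for g, _ in ranked[:top_m]]


def disease_similarity(
    index: BackendIndex,
    disease_lexicon: list[DiseaseEntry],
    category: str,
    top_m: int = 20,
) -> DiseaseSimilarity:
    """Row-normalized co-occurrence matrix and bidirectional UPGMA trees
    for the diseases of one organ category.

    Requires at least 2 diseases of the category with nonzero article
    counts; zero rows (a disease never co-occurring with any persistent
    genus) are kept at zero and flagged.
    """
    by_cat = diseases_by_category(disease_lexicon)
    if category not in by_cat:
        raise ValueError(f"unknown category {category!r}")
    diseases = [
        d for d in sorted(by_cat[category])
        if index.disease_pmids.get(d)
    ]
    if len(diseases) < 2:
        raise ValueError(
            f"category {category!r} has fewer than 2 diseases with articles"
        )
    genera = persistent_genera(index, top_m)
    raw = np.zeros((len(diseases), len(genera)))
    for i, d in enumerate(diseases):
        pd_ = index.disease_pmids[d]
        for j, g in enumerate(genera):
            raw[i, j] = len(index.genus_pmids.get(g, set()) & pd_)
    norm = raw.copy()
    zero_rows = []
    for i, d in enumerate(diseases):
        s = raw[i].sum()
        if s > 0:
            norm[i] = raw[i] / s
        else:
            zero_rows.append(d)

    def euclid(mat: np.ndarray) -> np.ndarray:
        diff = mat[:, None, :] - mat[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    disease_tree = upgma(diseases, euclid(norm))
    genus_tree = upgma(genera, euclid(norm.T)) if len(genera) >= 2 else None
    return DiseaseSimilarity(
        category=category, matrix=norm, raw_counts=raw,
        diseases=diseases, genera=genera, zero_rows=zero_rows,
        disease_tree=disease_tree, genus_tree=genus_tree,
    )
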