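"""Synthetic abstract corpora with planted association structure.

Real abstract corpora cannot ship with the package, so every pipeline
stage is exercised on generated MEDLINE-format abstracts whose entity
content is known exactly.  Each article draws its entities independently
at configurable baseline frequencies, except for *planted pairs*: a pair
(entity_1, entity_2, odds_ratio) is drawn from the 2x2 Bernoulli joint
distribution whose margins are the baselines and whose odds ratio is the
requested value (independence when OR = 1).  Planted pairs must be
entity-disjoint — each pair is calibrated against independent backgrounds,
which keeps the joint model exact without log-linear fitting.

Surface realism knobs: with ``trend_injection_prob`` a genus sentence
carries an increase/decrease keyword (direction recorded in the ground
truth); with ``misspelling_rate`` the genus surface receives one random
edit after the first character (guaranteed not to collide with another
genus within the fuzzy budget); with ``abbreviation_rate`` a second,
abbreviated "X. epithet" mention is appended.  Distractor capitalized
words are validated at construction time to be outside fuzzy range of the
genus vocabulary, so recognizer precision is measurable against the truth.

The generator is deterministic: identical spec + seed give byte-identical
MEDLINE output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .corpus_io import Article

_INCREASE = ("increased", "elevated", "enriched", "higher")
_DECREASE = ("decreased", "reduced", "depleted", "lower")
_EPITHETS = ("coli", "fragilis", "longum", "plantarum", "aureus",
             "mutans", "jejuni", "pylori")

_DISTRACTOR_SENTENCES = (
    "Samples were processed at the Central Research Hospital.",
    "The Institutional Review Board approved the Protocol.",
    "Community profiles were compared between the Case and Control groups.",
    "Sequencing was performed at the University Genomics Laboratory.",
)

DEFAULT_GENUS_BASELINE = 0.08
DEFAULT_DISEASE_BASELINE = 0.10


@dataclass
class CorpusSpec:
    """Study conditions of one synthetic corpus (seed mandatory)."""

    n_articles: int
    seed: int
    genus_vocab: list[str]
    disease_vocab: list[str] = field(default_factory=list)
    genus_baseline: float = DEFAULT_GENUS_BASELINE
    disease_baseline: float = DEFAULT_DISEASE_BASELINE
    baseline_overrides: dict[str, float] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    trend_injection_prob: float = 0.3
    misspelling_rate: float = 0.0
    abbreviation_rate: float = 0.0
    lexicon_genera: list[str] | None = None  # reference list for collision checks

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusSpec":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "planted_pairs" in data:
            data["planted_pairs"] = [tuple(p) for p in data["planted_pairs"]]
        return cls(**data)

    def baseline_of(self, entity: str) -> float:
        if entity in self.baseline_overrides:
            return self.baseline_overrides[entity]
        if entity in self.genus_vocab:
            return self.genus_baseline
        return self.disease_baseline


@dataclass
class ArticleTruth:
    entities: set[str]
    trends: dict[str, int]


@dataclass
class PairTruth:
    entity_1: str
    entity_2: str
    odds_ratio: float
    a: int = 0  # both
    b: int = 0  # first only
    c: int = 0  # second only
    d: int = 0  # neither


@dataclass
class GroundTruth:
    articles: dict[str, ArticleTruth] = field(default_factory=dict)
    pairs: list[PairTruth] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "articles": {
                p: {"entities": sorted(t.entities), "trends": t.trends}
                for p, t in self.articles.items()
            },
            "pairs": [asdict(p) for p in self.pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def pair_cell_probs(p1: float, p2: float, odds_ratio: float) -> tuple[float, float, float, float]:
    """Joint Bernoulli cell probabilities (p11, p10, p01, p00) with the
    given margins and odds ratio.

    Raises ``ValueError`` when no joint distribution with these margins can
    achieve the requested odds ratio.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio == 1.0:
        p11 = p1 * p2
    elif not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError(
            "odds ratio unachievable: margins must lie strictly in (0, 1) "
            "for a non-unit odds ratio"
        )
    else:
        s = 1.0 + (p1 + p2) * (odds_ratio - 1.0)
        disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p1 * p2
        if disc < 0:
            raise ValueError("odds ratio unachievable with given margins")
        p11 = (s - math.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError(
            f"odds ratio {odds_ratio} unachievable with margins {p1}, {p2}"
        )
    p11 = min(max(p11, lo), hi)
    return p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11


def _validate_spec(spec: CorpusSpec) -> set[str]:
    """Pre-generation checks; returns the genus reference set used for
    surface-collision accounting."""
    if spec.n_articles < 0:
        raise ValueError("n_articles must be >= 0")
    for e, p in spec.baseline_overrides.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"baseline for {e!r} outside [0, 1]")
    for p in (spec.genus_baseline, spec.disease_baseline,
              spec.trend_injection_prob, spec.misspelling_rate,
              spec.abbreviation_rate):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")

    vocab = set(spec.genus_vocab) | set(spec.disease_vocab)
    used: set[str] = set()
    for e1, e2, oratio in spec.planted_pairs:
        if e1 not in vocab or e2 not in vocab:
            raise ValueError(f"planted pair ({e1}, {e2}) outside vocab")
        if e1 == e2:
            raise ValueError("planted pair entities must differ")
        if e1 in used or e2 in used:
            raise ValueError(
                "planted pairs must be entity-disjoint (one pair per entity)"
            )
        used |= {e1, e2}
        pair_cell_probs(spec.baseline_of(e1), spec.baseline_of(e2), oratio)

    genus_ref = set(spec.genus_vocab)
    if spec.lexicon_genera:
        genus_ref |= set(spec.lexicon_genera)

    # distractor capitalized words must not be recognizable as genera
    import re
    for sentence in _DISTRACTOR_SENTENCES + ("Synthetic cohort survey",):
        for token in re.findall(r"\b[A-Z][a-z]+\b", sentence):
            if token in genus_ref:
                raise ValueError(f"distractor token {token!r} is a genus")
            if len(token) >= 6 and any(
                g[0] == token[0] and _edit_distance(token, g) <= 1
                for g in genus_ref
            ):
                raise ValueError(
                    f"distractor token {token!r} within fuzzy range of a genus"
                )
    return genus_ref


def _edit_distance(a: str, b: str) -> int:
    if abs(len(a) - len(b)) > 2:
        return 3  # large enough; exact value not needed
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _misspell(genus: str, rng: np.random.Generator, genus_ref: set[str]) -> str:
    """One random edit after the first character, guaranteed not to land
    within edit distance 1 of a *different* genus (falls back to the exact
    surface when no safe edit is found)."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    for _ in range(8):
        op = rng.integers(3)
        pos = int(rng.integers(1, len(genus)))
        if op == 0:  # substitute
            ch = letters[rng.integers(26)]
            cand = genus[:pos] + ch + genus[pos + 1:]
        elif op == 1:  # delete
            cand = genus[:pos] + genus[pos + 1:]
        else:  # insert
            ch = letters[rng.integers(26)]
            cand = genus[:pos] + ch + genus[pos:]
        if cand == genus or cand in genus_ref:
            continue
        collision = any(
            g != genus and g[0] == cand[0] and _edit_distance(cand, g) <= 1
            for g in genus_ref
        )
        if not collision:
            return cand
    return genus


def generate_corpus(spec: CorpusSpec) -> tuple[list[Article], GroundTruth]:
    """Generate articles and their exact ground truth.

    The emitted records parse losslessly with
    :func:`evilit.corpus_io.read_medline` after
    :func:`evilit.corpus_io.write_medline`.
    """
    genus_ref = _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)

    planted_entities = {e for e1, e2, _ in spec.planted_pairs for e in (e1, e2)}
    independents = [e for e in (*spec.genus_vocab, *spec.disease_vocab)
                    if e not in planted_entities]
    pair_probs = [
        (e1, e2, pair_cell_probs(spec.baseline_of(e1), spec.baseline_of(e2), o))
        for e1, e2, o in spec.planted_pairs
    ]

    truth = GroundTruth(
        pairs=[PairTruth(e1, e2, o) for e1, e2, o in spec.planted_pairs]
    )
    articles: list[Article] = []

    for i in range(spec.n_articles):
        pmid = str(90000001 + i)
        present: set[str] = set()
        for e1, e2, (p11, p10, p01, _) in pair_probs:
            u = rng.random()
            if u < p11:
                present |= {e1, e2}
            elif u < p11 + p10:
                present.add(e1)
            elif u < p11 + p10 + p01:
                present.add(e2)
        for e in independents:
            if rng.random() < spec.baseline_of(e):
                present.add(e)

        genera = [g for g in spec.genus_vocab if g in present]
        diseases = [d for d in spec.disease_vocab if d in present]
        trends: dict[str, int] = {}
        sentences: list[str] = []
        entities = set(genera) | set(diseases)

        for d in diseases:
            sentences.append(f"Patients with {d} were recruited for this cohort.")
            # a disease surface may embed a genus name ("Clostridium
            # difficile infection"): that genus is then truly in the text
            for token in d.split():
                if token in genus_ref:
                    entities.add(token)
                    trends.setdefault(token, 0)

        for g in genera:
            surface = g
            if spec.misspelling_rate > 0 and rng.random() < spec.misspelling_rate \
                    and len(g) >= 6:
                surface = _misspell(g, rng, genus_ref)
            if rng.random() < spec.trend_injection_prob:
                direction = 1 if rng.random() < 0.5 else -1
                pool = _INCREASE if direction == 1 else _DECREASE
                kw = pool[rng.integers(len(pool))]
                sentences.append(
                    f"{surface} abundance was significantly {kw} in cases "
                    f"relative to controls."
                )
                trends[g] = direction
            else:
                sentences.append(
                    f"The genus {surface} was detected in the collected samples."
                )
                trends[g] = 0
            if spec.abbreviation_rate > 0 and rng.random() < spec.abbreviation_rate:
                epithet = _EPITHETS[rng.integers(len(_EPITHETS))]
                sentences.append(
                    f"{g[0]}. {epithet} counts were recorded for comparison."
                )

        n_distract = int(rng.integers(0, 3))
        for _ in range(n_distract):
            sentences.append(
                _DISTRACTOR_SENTENCES[rng.integers(len(_DISTRACTOR_SENTENCES))]
            )

        articles.append(
            Article(
                pmid=pmid,
                title=f"Synthetic cohort survey of microbial communities, "
                      f"record {pmid}.",
                abstract=" ".join(sentences),
                journal="Synthetic Microbiology Reports",
                year=2021,
                authors=["Doe J"],
            )
        )
        truth.articles[pmid] = ArticleTruth(entities=entities, trends=trends)

    # realized 2x2 margins per planted pair
    for pt in truth.pairs:
        for t in truth.articles.values():
            has1, has2 = pt.entity_1 in t.entities, pt.entity_2 in t.entities
            if has1 and has2:
                pt.a += 1
            elif has1:
                pt.b += 1
            elif has2:
                pt.c += 1
            else:
                pt.d += 1
    return articles, truth
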