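"""Entity recognition and normalization over titles + abstracts.

Bacterial genera are recognized with a dictionary matcher backed by the
genus master list, extended with two normalization rules that collapse the
common surface variants onto one canonical genus:

* approximate matching — capitalized tokens of length >= 6 within a small
  Levenshtein distance (default 1) of a *unique* master-list genus sharing
  the first letter are accepted as near-misspellings ("Eschericia" ->
  "Escherichia");
* abbreviation resolution — "E. coli"-style forms resolve to the unique
  genus with that initial already mentioned earlier in the same article.

Species epithets ("coli" after "Escherichia") are recorded on the mention
but never become independent entities: all downstream counts are at the
genus level.

Disease names are matched case-insensitively on word boundaries with
longest-synonym-first precedence, so "type 2 diabetes" is never double
counted as "diabetes".  All-caps abbreviation synonyms (IBS, CDI, HIV, ...)
are matched case-sensitively to keep precision on short tokens.

Per-genus abundance trends are tagged from a small keyword lexicon: within
each sentence, the nearest increase/decrease keyword within a token window
(default 8) of a genus mention sets the sentence signal, and the article
tag is the sign of the summed sentence signals — +1 increase, -1 decrease,
0 none or conflicting.  Negation ("did not increase") is not modelled.

Keyword extraction is a deterministic rule-based tokenizer: lower-cased
alphabetic tokens of length >= 3 minus a packaged stop list of function
words and common reporting verbs.  No statistical tagger is involved, so
identical input always yields identical keywords.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import edlib

from .corpus_io import Article
from .lexicon import DiseaseEntry, GenusLexicon, _data_path

# --- token patterns --------------------------------------------------------

_CAP_TOKEN_RE = re.compile(r"(?<![A-Za-z])([A-Z][a-z]+)(?![A-Za-z])")
_ABBREV_RE = re.compile(r"(?<![A-Za-z])([A-Z])\. ?([a-z]{2,})(?![A-Za-z])")
_WORD_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*")
_KEYWORD_RE = re.compile(r"(?<![a-z0-9])[a-z][a-z0-9\-]{2,}(?![a-z0-9])")

#: lower-case tokens never recorded as species epithets
_EPITHET_STOP = frozenset(
    "was were is are and or in of the with to has have had can may by from as "
    "at on an a that this but not also be been which while than for into "
    "during after before spp sp strain strains species isolates".split()
)


@dataclass
class EntityMention:
    """A recognized, normalized entity occurrence.

    Offsets are 0-based half-open over ``article.text``
    (title + ``"\\n"`` + abstract); ``surface`` equals the text slice.
    """

    pmid: str
    surface: str
    start: int
    end: int
    canonical: str
    entity_kind: str  # "genus" | "disease"
    match_kind: str   # "exact" | "fuzzy" | "abbreviation" | "synonym"
    species_epithet: str | None = None


@dataclass
class TrendTag:
    pmid: str
    genus: str
    trend: int  # +1 increase, -1 decrease, 0 none/conflict


# --- sentence splitting ----------------------------------------------------

def split_sentences(text: str) -> list[tuple[int, int]]:
    """Spans of sentences over ``text`` (rule-based, deterministic).

    Boundaries are newlines and runs of ``.!?`` followed by whitespace and a
    capital, except when the period terminates a single-capital genus
    abbreviation ("E. coli").
    """
    cuts = [0]
    for m in re.finditer(r"[.!?]+(?=\s+[A-Z])|\n", text):
        if m.group() == "\n":
            cuts.append(m.end())
            continue
        i = m.start()
        # protect "E." style abbreviations: single capital before the period
        if i >= 1 and text[i - 1].isupper() and (i < 2 or not text[i - 2].isalpha()):
            continue
        cuts.append(m.end())
    cuts.append(len(text))
    spans = []
    for s, e in zip(cuts, cuts[1:]):
        # trim surrounding whitespace
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            spans.append((s, e))
    return spans


# --- genus recognition -----------------------------------------------------

def _fuzzy_resolve(token: str, lexicon: GenusLexicon, max_edit: int) -> str | None:
    """Unique master-list genus within ``max_edit`` of ``token``, or None.

    Guardrails: token length >= 6, first letter must agree, and the hit must
    be unique among all genera within range — ambiguous hits are dropped.
    """
    cache: dict[tuple[str, int], str | None]
    cache = lexicon.__dict__.setdefault("_fuzzy_cache", {})
    key = (token, max_edit)
    if key in cache:
        return cache[key]
    hits = []
    for g in lexicon.genera:
        if g[0] != token[0] or abs(len(g) - len(token)) > max_edit:
            continue
        d = edlib.align(token, g, task="distance", k=max_edit)["editDistance"]
        if 0 <= d <= max_edit:
            hits.append(g)
    result = hits[0] if len(hits) == 1 else None
    cache[key] = result
    return result


def _epithet_after(text: str, end: int) -> str | None:
    m = re.match(r" ([a-z]{2,})(?![A-Za-z])", text[end:])
    if m and m.group(1) not in _EPITHET_STOP:
        return m.group(1)
    return None


def recognize_genera(
    article: Article, lexicon: GenusLexicon, max_edit: int = 1
) -> list[EntityMention]:
    """Recognize genus mentions in an article's title + abstract."""
    if max_edit < 0:
        raise ValueError("max_edit must be >= 0")
    text = article.text
    events: list[tuple[int, str, re.Match]] = []
    for m in _CAP_TOKEN_RE.finditer(text):
        events.append((m.start(), "token", m))
    for m in _ABBREV_RE.finditer(text):
        events.append((m.start(), "abbrev", m))
    events.sort(key=lambda e: e[0])

    mentions: list[EntityMention] = []
    for start, kind, m in events:
        if kind == "token":
            token = m.group(1)
            canonical = None
            match_kind = None
            if token in lexicon.genera:
                canonical, match_kind = token, "exact"
            elif token in lexicon.aliases:
                canonical, match_kind = lexicon.aliases[token], "synonym"
            elif max_edit > 0 and len(token) >= 6:
                hit = _fuzzy_resolve(token, lexicon, max_edit)
                if hit is not None:
                    canonical, match_kind = hit, "fuzzy"
            if canonical is None:
                continue
            mentions.append(
                EntityMention(
                    pmid=article.pmid, surface=token,
                    start=m.start(1), end=m.end(1),
                    canonical=canonical, entity_kind="genus",
                    match_kind=match_kind,
                    species_epithet=_epithet_after(text, m.end(1)),
                )
            )
        else:  # abbreviation "X. epithet"
            initial, epithet = m.group(1), m.group(2)
            prior = {mn.canonical for mn in mentions
                     if mn.start < start and mn.canonical[0] == initial}
            if len(prior) != 1:
                continue
            mentions.append(
                EntityMention(
                    pmid=article.pmid, surface=m.group(0),
                    start=m.start(), end=m.end(),
                    canonical=next(iter(prior)), entity_kind="genus",
                    match_kind="abbreviation", species_epithet=epithet,
                )
            )
    return mentions


# --- disease recognition ---------------------------------------------------

def _is_abbrev(term: str) -> bool:
    return re.fullmatch(r"[A-Z]{2,}", term) is not None


@lru_cache(maxsize=8)
def _disease_matcher(lex_key: tuple) -> tuple[re.Pattern, dict, dict]:
    """Compiled longest-first alternation plus surface → canonical maps."""
    surfaces: list[tuple[str, str]] = []  # (surface, canonical)
    for canonical, syns in lex_key:
        surfaces.append((canonical, canonical))
        for s in syns:
            surfaces.append((s, canonical))
    surfaces.sort(key=lambda sc: (-len(sc[0]), sc[0]))
    ci_map: dict[str, str] = {}
    cs_map: dict[str, str] = {}
    alts = []
    for surf, canonical in surfaces:
        pat = re.escape(surf).replace(r"\ ", r"\s+")
        if _is_abbrev(surf):
            cs_map[surf] = canonical
            alts.append(pat)
        else:
            ci_map[surf.lower()] = canonical
            alts.append(f"(?i:{pat})")
    pattern = re.compile(
        r"(?<![A-Za-z0-9])(?:" + "|".join(alts) + r")(?![A-Za-z0-9])"
    )
    return pattern, ci_map, cs_map


def recognize_diseases(
    article: Article, lexicon: list[DiseaseEntry]
) -> list[EntityMention]:
    """Recognize disease mentions (longest-synonym-first, word-bounded)."""
    lex_key = tuple((e.canonical, tuple(e.synonyms)) for e in lexicon)
    pattern, ci_map, cs_map = _disease_matcher(lex_key)
    text = article.text
    mentions = []
    for m in pattern.finditer(text):
        surf = m.group(0)
        canonical = cs_map.get(surf)
        if canonical is None:
            canonical = ci_map.get(" ".join(surf.lower().split()))
        if canonical is None:  # pragma: no cover - maps cover the pattern
            continue
        match_kind = "exact" if surf.lower() == canonical.lower() else "synonym"
        mentions.append(
            EntityMention(
                pmid=article.pmid, surface=surf, start=m.start(), end=m.end(),
                canonical=canonical, entity_kind="disease", match_kind=match_kind,
            )
        )
    return mentions


# --- trend tagging ---------------------------------------------------------

@lru_cache(maxsize=2)
def load_trend_lexicon(path: str | None = None) -> dict[str, int]:
    """Keyword → direction map (2-column TSV; packaged default)."""
    if path is None:
        text = _data_path("trend_keywords.tsv").read_text(encoding="utf-8")
    else:
        from pathlib import Path
        text = Path(path).read_text(encoding="utf-8")
    out: dict[str, int] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        word, direction = line.split("\t")
        out[word.strip().lower()] = int(direction)
    return out


def _sign(x: int) -> int:
    return (x > 0) - (x < 0)


def detect_trends(
    article: Article,
    genus_mentions: list[EntityMention],
    trend_lexicon: dict[str, int] | None = None,
    window: int = 8,
) -> list[TrendTag]:
    """Tag each mentioned genus with an article-level abundance trend."""
    if trend_lexicon is None:
        trend_lexicon = load_trend_lexicon()
    text = article.text
    sentences = split_sentences(text)
    genera = sorted({m.canonical for m in genus_mentions
                     if m.entity_kind == "genus"})
    if not genera:
        return []

    # per-sentence token stream with positions
    sent_tokens: list[list[tuple[int, str]]] = []
    for s, e in sentences:
        sent_tokens.append(
            [(m.start() + s, m.group().lower())
             for m in _WORD_RE.finditer(text[s:e])]
        )

    def sentence_of(pos: int) -> int | None:
        for i, (s, e) in enumerate(sentences):
            if s <= pos < e:
                return i
        return None

    # mention signal: nearest trend keyword within `window` tokens
    sent_signals: dict[str, dict[int, int]] = {g: {} for g in genera}
    for mention in genus_mentions:
        si = sentence_of(mention.start)
        if si is None:
            continue
        tokens = sent_tokens[si]
        tok_idx = None
        for j, (tstart, tok) in enumerate(tokens):
            if tstart <= mention.start < tstart + len(tok):
                tok_idx = j
                break
        if tok_idx is None:
            continue
        best_dist, best_dirs = None, set()
        for j, (_, tok) in enumerate(tokens):
            d = trend_lexicon.get(tok)
            if d is None:
                continue
            dist = abs(j - tok_idx)
            if dist > window:
                continue
            if best_dist is None or dist < best_dist:
                best_dist, best_dirs = dist, {d}
            elif dist == best_dist:
                best_dirs.add(d)
        signal = next(iter(best_dirs)) if len(best_dirs) == 1 else 0
        g = mention.canonical
        sent_signals[g][si] = sent_signals[g].get(si, 0) + signal

    tags = []
    for g in genera:
        total = sum(_sign(v) for v in sent_signals[g].values())
        tags.append(TrendTag(pmid=article.pmid, genus=g, trend=_sign(total)))
    return tags


# --- keyword extraction ----------------------------------------------------

@lru_cache(maxsize=2)
def load_stopwords(path: str | None = None) -> frozenset[str]:
    if path is None:
        text = _data_path("stopwords.txt").read_text(encoding="utf-8")
    else:
        from pathlib import Path
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def extract_noun_keywords(
    article: Article, stopwords: frozenset[str] | None = None
) -> list[tuple[str, int]]:
    """Per-article keyword counts, sorted by count desc then alphabetically."""
    if stopwords is None:
        stopwords = load_stopwords()
    counts: dict[str, int] = {}
    for tok in _KEYWORD_RE.findall(article.text.lower()):
        if tok in stopwords:
            continue
        counts[tok] = counts.get(tok, 0) + 1
    return sorted(counts.items(), key=lambda kc: (-kc[1], kc[0]))
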