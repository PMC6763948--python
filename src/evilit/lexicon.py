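"""Genus master list and the curated human-disease dictionary.

Association counts in this package are aggregated at the genus level
("Escherichia" subsumes "E. coli"), so the genus lexicon is the complete
output vocabulary of bacterial entity recognition.  The packaged default is
a 50-genus test list; production use supplies the full master list built
from 16S reference taxonomies (one genus per line, optional alias column).

The disease dictionary covers 51 widely reported microbiome-associated
human diseases grouped by the organ system they affect (gut, skin, lungs,
brain, urogenital, systemic).  Entries carry curated surface synonyms:
"colorectal carcinoma" also matches "colorectal cancer", and parenthesized
abbreviations (IBS, IBD, CD, CDI, ESRD, HIV, AIDS) are word-bounded,
case-sensitive synonyms.  "diabetes" is deliberately a separate entry from
"type 1 diabetes" and "type 2 diabetes" — longest-match recognition keeps
them distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

CATEGORIES = ("gut", "skin", "lungs", "brain", "urogenital", "systemic")


class LexiconError(ValueError):
    """Invalid or inconsistent lexicon file."""


def _data_path(name: str):
    return resources.files("evilit.data").joinpath(name)


def normalize_genus(name: str) -> str:
    """Canonical genus capitalization: leading capital, rest lower-case."""
    name = name.strip()
    return name[:1].upper() + name[1:].lower()


@dataclass
class GenusLexicon:
    """The genus master list plus alias → canonical mapping."""

    genera: set[str] = field(default_factory=set)
    aliases: dict[str, str] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        n = normalize_genus(name)
        return n in self.genera or n in self.aliases

    def resolve(self, name: str) -> str | None:
        """Canonical genus for a surface name, or None if unknown."""
        n = normalize_genus(name)
        if n in self.genera:
            return n
        return self.aliases.get(n)

    def __len__(self) -> int:
        return len(self.genera)


@dataclass
class DiseaseEntry:
    canonical: str
    category: str
    synonyms: list[str] = field(default_factory=list)


def load_genus_lexicon(path: str | Path | None = None) -> GenusLexicon:
    """Load a genus master list.

    Format: UTF-8 plain text, one genus per line; an optional second
    tab-separated column gives an alias that resolves to that genus.
    ``path=None`` loads the packaged 50-genus default.
    """
    if path is None:
        text = _data_path("genera_default.txt").read_text(encoding="utf-8")
        src = "<packaged default>"
    else:
        text = Path(path).read_text(encoding="utf-8")
        src = str(path)

    lex = GenusLexicon()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        genus = normalize_genus(parts[0])
        if genus in lex.genera:
            logger.warning("duplicate genus %r in %s collapsed", genus, src)
        lex.genera.add(genus)
        for alias_raw in parts[1:]:
            alias = normalize_genus(alias_raw)
            if alias in lex.genera and alias != genus:
                raise LexiconError(
                    f"alias {alias!r} collides with a different genus in {src}"
                )
            if alias in lex.aliases and lex.aliases[alias] != genus:
                raise LexiconError(
                    f"alias {alias!r} maps to two genera in {src}"
                )
            if alias != genus:
                lex.aliases[alias] = genus
    if not lex.genera:
        raise LexiconError(f"genus lexicon {src} is empty")
    # aliases equal to a genus name are no-ops and were skipped above
    return lex


def load_disease_lexicon(path: str | Path | None = None) -> list[DiseaseEntry]:
    """Load the disease dictionary.

    Format: 3-column UTF-8 TSV — canonical name, organ category (one of
    gut/skin/lungs/brain/urogenital/systemic), pipe-separated synonyms
    (optional).  ``path=None`` loads the packaged 51-disease default.
    """
    if path is None:
        text = _data_path("diseases.tsv").read_text(encoding="utf-8")
        src = "<packaged default>"
    else:
        text = Path(path).read_text(encoding="utf-8")
        src = str(path)

    entries: list[DiseaseEntry] = []
    seen_canonical: set[str] = set()
    seen_surfaces: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise LexiconError(f"{src}:{lineno}: expected at least 2 columns")
        canonical = parts[0].strip()
        category = parts[1].strip().lower()
        if category not in CATEGORIES:
            raise LexiconError(
                f"{src}:{lineno}: unknown category {category!r} "
                f"(expected one of {', '.join(CATEGORIES)})"
            )
        key = canonical.lower()
        if key in seen_canonical:
            raise LexiconError(f"{src}:{lineno}: duplicate canonical {canonical!r}")
        seen_canonical.add(key)
        synonyms = []
        if len(parts) > 2 and parts[2].strip():
            synonyms = [s.strip() for s in parts[2].split("|") if s.strip()]
        for surf in synonyms:
            skey = surf.lower()
            if skey in seen_surfaces and seen_surfaces[skey] != canonical:
                raise LexiconError(
                    f"{src}:{lineno}: synonym {surf!r} already used by "
                    f"{seen_surfaces[skey]!r}"
                )
            seen_surfaces[skey] = canonical
        entries.append(DiseaseEntry(canonical=canonical, category=category,
                                    synonyms=synonyms))
    if not entries:
        raise LexiconError(f"disease lexicon {src} is empty")
    return entries


def category_counts(entries: list[DiseaseEntry]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for e in entries:
        counts[e.category] += 1
    return counts


def diseases_by_category(entries: list[DiseaseEntry]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for e in entries:
        out[e.category].append(e.canonical)
    return out
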