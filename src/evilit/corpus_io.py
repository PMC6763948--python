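"""Reading PubMed abstract corpora and persisting the backend index.

Two standard exchange formats are supported: the MEDLINE tag-based flat
file (``PMID-``, ``TI  -``, ``AB  -`` ... records) and PubMed XML
(``PubmedArticleSet``).  Both produce the same :class:`Article` records, so
downstream entity recognition never needs to know where a corpus came from.

The built backend index is persisted as a directory of UTF-8 TSV tables
plus a JSON manifest — portable, diff-able and easy to inspect.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import Medline
from lxml import etree

if TYPE_CHECKING:  # pragma: no cover
    from .backend_index import BackendIndex

logger = logging.getLogger(__name__)

INDEX_FORMAT_VERSION = 1

#: files making up an on-disk index directory
INDEX_FILES = (
    "manifest.json",
    "articles.tsv",
    "genus_pmids.tsv",
    "disease_pmids.tsv",
    "pmid_entities.tsv",
    "pmid_keywords.tsv",
)


class IndexVersionError(RuntimeError):
    """Stored index layout has a different format version than this code."""


@dataclass
class Article:
    """One abstract record retained from a PubMed export.

    ``year`` is ``None`` when no 4-digit year could be parsed from the date
    field.  ``abstract`` may be empty — titles also carry entities, so such
    records are kept.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    journal: str = ""
    year: int | None = None
    authors: list[str] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Title and abstract joined with a newline; the NER input."""
        return self.title + "\n" + self.abstract


def _parse_year(date_field: str) -> int | None:
    m = re.search(r"\b(\d{4})\b", date_field or "")
    return int(m.group(1)) if m else None


def _dedupe(articles: Iterable[Article]) -> list[Article]:
    seen: set[str] = set()
    out: list[Article] = []
    for art in articles:
        if art.pmid in seen:
            logger.warning("duplicate PMID %s: keeping first occurrence", art.pmid)
            continue
        seen.add(art.pmid)
        out.append(art)
    return out


def read_medline(path: str | Path) -> list[Article]:
    """Parse a MEDLINE flat file into :class:`Article` records.

    Continuation lines are joined with single spaces (Biopython's parser),
    records without a PMID are skipped with a warning, duplicate PMIDs keep
    the first occurrence, and records lacking an abstract are retained with
    ``abstract == ""``.
    """
    path = Path(path)
    articles: list[Article] = []
    n_no_abstract = 0
    with open(path, encoding="utf-8") as handle:
        for rec in Medline.parse(handle):
            pmid = rec.get("PMID", "").strip()
            if not pmid:
                logger.warning("MEDLINE record without PMID skipped in %s", path)
                continue
            abstract = rec.get("AB", "") or ""
            if not abstract:
                n_no_abstract += 1
            articles.append(
                Article(
                    pmid=pmid,
                    title=rec.get("TI", "") or "",
                    abstract=abstract,
                    journal=rec.get("JT", "") or "",
                    year=_parse_year(rec.get("DP", "")),
                    authors=list(rec.get("AU", []) or []),
                )
            )
    articles = _dedupe(articles)
    logger.info(
        "read %d articles from %s (%d without abstract)",
        len(articles), path, n_no_abstract,
    )
    return articles


def write_medline(articles: Iterable[Article], path: str | Path) -> None:
    """Write articles back out as a MEDLINE flat file (round-trips with
    :func:`read_medline`)."""

    def tagged(tag: str, value: str) -> list[str]:
        # wrap long values onto continuation lines indented with 6 spaces
        words = value.split()
        if not words:
            return [f"{tag:<4}- "]
        lines, cur = [], f"{tag:<4}- {words[0]}"
        for w in words[1:]:
            if len(cur) + 1 + len(w) > 80:
                lines.append(cur)
                cur = "      " + w
            else:
                cur += " " + w
        lines.append(cur)
        return lines

    with open(path, "w", encoding="utf-8") as fh:
        for art in articles:
            out: list[str] = []
            out += tagged("PMID", art.pmid)
            if art.year is not None:
                out += tagged("DP", str(art.year))
            if art.title:
                out += tagged("TI", art.title)
            if art.abstract:
                out += tagged("AB", art.abstract)
            if art.journal:
                out += tagged("JT", art.journal)
            for au in art.authors:
                out += tagged("AU", au)
            fh.write("\n".join(out) + "\n\n")


def read_pubmed_xml(path: str | Path) -> list[Article]:
    """Parse PubMed XML (``PubmedArticleSet``) into :class:`Article` records.

    Structured abstracts (multiple ``AbstractText`` sections) are
    concatenated in document order, separated by single spaces.  Malformed
    XML raises ``ValueError`` naming the position reported by the parser.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(
            f"malformed PubMed XML in {path} at line {exc.lineno}, "
            f"column {exc.position[1]}: {exc.msg}"
        ) from exc
    articles: list[Article] = []
    for elem in tree.iter("PubmedArticle"):
        pmid_el = elem.find(".//MedlineCitation/PMID")
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        if not pmid:
            logger.warning("PubmedArticle without PMID skipped in %s", path)
            continue
        title_el = elem.find(".//Article/ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        sections = [
            " ".join("".join(ab.itertext()).split())
            for ab in elem.findall(".//Article/Abstract/AbstractText")
        ]
        abstract = " ".join(s for s in sections if s)
        journal_el = elem.find(".//Article/Journal/Title")
        journal = (journal_el.text or "").strip() if journal_el is not None else ""
        year = None
        for tag in (".//JournalIssue/PubDate/Year", ".//JournalIssue/PubDate/MedlineDate"):
            el = elem.find(tag)
            if el is not None and el.text:
                year = _parse_year(el.text)
                if year:
                    break
        authors = []
        for au in elem.findall(".//AuthorList/Author"):
            last = au.findtext("LastName") or ""
            initials = au.findtext("Initials") or ""
            name = f"{last} {initials}".strip()
            if name:
                authors.append(name)
        articles.append(
            Article(pmid=pmid, title=title, abstract=abstract,
                    journal=journal, year=year, authors=authors)
        )
    return _dedupe(articles)


# ---------------------------------------------------------------------------
# Index persistence: directory of TSV tables + JSON manifest
# ---------------------------------------------------------------------------

def save_index(index: "BackendIndex", path: str | Path) -> None:
    """Persist a backend index to ``path`` (created if missing)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "format_version": INDEX_FORMAT_VERSION,
        "n_articles": index.N,
        "known_genera": sorted(index.known_genera),
        "known_diseases": sorted(index.known_diseases),
        "build_params": index.build_params,
    }
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=1, ensure_ascii=False), encoding="utf-8"
    )

    def write_tsv(name: str, header: list[str], rows: Iterable[list[str]]) -> None:
        with open(path / name, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(header)
            w.writerows(rows)

    write_tsv(
        "articles.tsv",
        ["pmid", "title", "abstract", "journal", "year", "authors"],
        (
            [a.pmid, a.title, a.abstract, a.journal,
             "" if a.year is None else str(a.year), "|".join(a.authors)]
            for a in (index.articles[p] for p in sorted(index.articles))
        ),
    )
    write_tsv(
        "genus_pmids.tsv", ["genus", "pmids"],
        ([g, ",".join(sorted(ps))] for g, ps in sorted(index.genus_pmids.items())),
    )
    write_tsv(
        "disease_pmids.tsv", ["disease", "pmids"],
        ([d, ",".join(sorted(ps))] for d, ps in sorted(index.disease_pmids.items())),
    )
    write_tsv(
        "pmid_entities.tsv", ["pmid", "genera_trends", "diseases"],
        (
            [p,
             ";".join(f"{g}:{t:+d}" for g, t in index.pmid_genera.get(p, [])),
             "|".join(index.pmid_diseases.get(p, []))]
            for p in sorted(index.articles)
        ),
    )
    write_tsv(
        "pmid_keywords.tsv", ["pmid", "keywords"],
        (
            [p, ",".join(f"{k}:{c}" for k, c in sorted(index.pmid_keywords.get(p, {}).items()))]
            for p in sorted(index.articles)
        ),
    )


def load_index(path: str | Path) -> "BackendIndex":
    """Load an index previously written by :func:`save_index`."""
    from .backend_index import BackendIndex

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text(encoding="utf-8"))
    if manifest.get("format_version") != INDEX_FORMAT_VERSION:
        raise IndexVersionError(
            f"index at {path} has format_version={manifest.get('format_version')}, "
            f"expected {INDEX_FORMAT_VERSION}"
        )

    def read_tsv(name: str) -> list[list[str]]:
        with open(path / name, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        return rows[1:]  # drop header

    articles: dict[str, Article] = {}
    for pmid, title, abstract, journal, year, authors in read_tsv("articles.tsv"):
        articles[pmid] = Article(
            pmid=pmid, title=title, abstract=abstract, journal=journal,
            year=int(year) if year else None,
            authors=authors.split("|") if authors else [],
        )

    genus_pmids = {
        g: set(ps.split(",")) if ps else set() for g, ps in read_tsv("genus_pmids.tsv")
    }
    disease_pmids = {
        d: set(ps.split(",")) if ps else set() for d, ps in read_tsv("disease_pmids.tsv")
    }
    pmid_genera: dict[str, list[tuple[str, int]]] = {}
    pmid_diseases: dict[str, list[str]] = {}
    for pmid, gt, ds in read_tsv("pmid_entities.tsv"):
        if gt:
            pairs = []
            for item in gt.split(";"):
                g, t = item.rsplit(":", 1)
                pairs.append((g, int(t)))
            pmid_genera[pmid] = pairs
        if ds:
            pmid_diseases[pmid] = ds.split("|")
    pmid_keywords: dict[str, dict[str, int]] = {}
    for pmid, kws in read_tsv("pmid_keywords.tsv"):
        if kws:
            counts = {}
            for item in kws.split(","):
                k, c = item.rsplit(":", 1)
                counts[k] = int(c)
            pmid_keywords[pmid] = counts

    return BackendIndex(
        articles=articles,
        genus_pmids=genus_pmids,
        disease_pmids=disease_pmids,
        pmid_genera=pmid_genera,
        pmid_diseases=pmid_diseases,
        pmid_keywords=pmid_keywords,
        known_genera=set(manifest["known_genera"]),
        known_diseases=set(manifest["known_diseases"]),
        build_params=manifest.get("build_params", {}),
    )


def roundtrip_index(index: "BackendIndex", path: str | Path) -> "BackendIndex":
    """Save ``index`` to ``path`` and load it back (identity on every table)."""
    save_index(index, path)
    return load_index(path)
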