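# Methods

This note documents the models, rules and numerical choices behind
`evilit`, what the synthetic corpus generator does and does not emulate,
and the known limitations.

## Corpus model

An article is the unit of evidence throughout. Records come from MEDLINE
flat files (parsed with Biopython's `Medline` reader; continuation lines
joined with single spaces) or PubMed XML (lxml; structured abstracts
concatenated in document order). Records without an abstract are kept —
titles carry entities too — and duplicate PMIDs keep the first occurrence
with a warning, since a well-formed export has unique PMIDs. The year is
the first 4-digit token of the date field, unknown otherwise.

Entity recognition runs over `title + "\n" + abstract`. All counts
downstream are **article-level**: a genus mentioned five times in one
abstract contributes one article, and the co-occurrence strength of a pair
is the number of distinct PMIDs mentioning both.

## Genus recognition and normalization

The output vocabulary is exactly the genus master list (packaged default:
a 50-genus test list; production use supplies a full list, one genus per
line with optional alias column). Recognition has three rules, applied to
word-bounded capitalized tokens in reading order:

1. **Exact** dictionary hits (and alias hits) map to themselves; fuzzy
   matching can never rewrite an exact hit.
2. **Fuzzy**: tokens of length ≥ 6 within Levenshtein distance
   `max_edit` (default 1, via edlib) of a master-list genus are accepted
   only when the first letter agrees and the hit is unique among all
   genera in range; ambiguous hits are dropped. The length and
   first-letter guardrails keep short common words from aliasing onto
   short genus names.
3. **Abbreviation**: a pattern `X. epithet` (single capital, period,
   lower-case token) resolves to the unique genus with initial `X`
   mentioned earlier in the same article; with zero or several prior
   candidates the pattern is ignored.

A lower-case token immediately following a genus mention is recorded as a
species epithet (`coli` after `Escherichia`), except for a small closed
set of function words (`was`, `is`, `and`, ..., plus `sp`/`spp`/`strain`),
so ordinary verbs are never mistaken for epithets. Species are metadata on
the mention; they are never independent statistical entities — everything
aggregates to the genus.

## Disease recognition

The packaged dictionary holds 51 diseases in six organ categories
(gut 20, skin 7, lungs 5, brain 5, urogenital 4, systemic 10). Synonyms
are curated per entry: `colorectal carcinoma` ↔ `colorectal cancer`, the
parenthesized abbreviations ESRD, IBS, CD, CDI, IBD, and the tokens HIV
and AIDS for the combined HIV/AIDS entry. `diabetes`, `type 1 diabetes`
and `type 2 diabetes` are deliberately distinct entries.

Matching is word-bounded and longest-synonym-first: all surfaces are
compiled into one alternation ordered by decreasing length, so
`type 2 diabetes` consumes its span before the embedded `diabetes` can
match, and `ulcerative colitis` wins over `colitis`. Multi-word terms
tolerate arbitrary whitespace. Matching is case-insensitive **except** for
all-caps abbreviation synonyms (IBS, CDI, HIV, ...), which are matched
case-sensitively — a lower-case "cd" in running text is not Crohn disease.
This is a precision guardrail on short tokens; the cost is missing an
abbreviation typed in lower case, which is rare in abstracts.

## Trend tagging

A small keyword lexicon (2-column TSV, config-exposed) defines increase
words (`increase(d/s)`, `elevated`, `enriched`, `higher`, `abundant`) and
decrease words (`decrease(d/s)`, `reduced`, `depleted`, `lower`,
`diminished`). Sentences are split by a pinned rule — `.!?` followed by
whitespace and a capital, with single-capital abbreviations (`E.`)
protected — never by a statistical model. Within a sentence, each genus
mention takes the direction of the nearest keyword within a window of
8 tokens (default; ties between opposite directions cancel to 0); the
sentence signal is the sign of the summed mention signals and the
article-level tag is the sign of the summed sentence signals: +1, −1,
or 0 for none/conflict. Negation (“did not increase”) is **not**
modelled; a negated increase tags as +1. This is a documented limitation
of keyword-window tagging.

## Keywords

The per-article keyword table (word-cloud data) is produced by a
deterministic rule-based extractor: lower-cased alphanumeric tokens of
length ≥ 3, minus a packaged stop list of function words and common
reporting verbs. No statistical part-of-speech model is involved, so the
output is identical across runs and machines. Non-noun content words can
survive the filter; for ranking repeated domain terms (the intended use)
this is immaterial.

## Association statistics

For entities A and B over a universe of N articles the 2×2 table is
`a = |P_A ∩ P_B|`, `b = |P_A \ P_B|`, `c = |P_B \ P_A|`, `d = N−a−b−c`.
The default universe is the **whole indexed corpus**, including articles
with no mapped entity; a mapped-articles-only universe is a switch. The
rationale: the corpus defines the sampling frame in which both entities
could have been mentioned, and dropping unmapped articles inflates
marginal rates asymmetrically.

* **Fisher exact test** — the exact hypergeometric tail of `a`. Default
  alternative is one-sided `greater`, the association/enrichment reading;
  two-sided is available. The empty table returns p = 1 with a degenerate
  flag. The reported odds ratio is the sample ratio `ad/bc` (∞ when
  `bc = 0` and `ad > 0`).
* **χ² test** — Pearson statistic on 1 df, Yates correction off by
  default (documented, switchable); zero-margin tables return NaN with a
  warning, expected cells < 5 raise a small-count warning. Fisher and χ²
  are both reported because they answer the same independence question
  with exact vs asymptotic machinery; the Fisher p drives significance
  flags.
* **Multiple testing** — Bonferroni, `min(1, p·m)`. The family `m` is the
  number of genera actually tested for the disease at hand (or per
  category table), exposed as a parameter since other family choices are
  defensible.
* **Enrichment** — for a query set Q against a disease set K in universe
  U: `p = P(X ≥ |Q ∩ K|)`, X ~ Hypergeometric(|U|, |K|, |Q|). The
  default universe is the genera observed in the corpus (not the full
  master list): genera that literature never mentions cannot be drawn as
  evidence and would dilute every test. Switchable.
* **Disease sets** — per disease, the genera with one-sided Fisher
  p < α (default 0.05) on the indexed corpus.

## Category summaries and disease similarity

The per-category view pools the article sets of a category's diseases,
ranks genera by article count in the pool (top 10 by default) and tests
each genus against the pooled set (Fisher greater, raw and
Bonferroni-corrected flags). Pooling, rather than per-disease testing
followed by aggregation, makes the category table a single well-defined
family; this was a genuinely open design point and is documented here as
the package's choice.

Disease similarity within a category uses the co-occurrence count matrix
of the **persistent genera** — the top 20 genera by total evidence count
summed over all 51 diseases — with rows (diseases) normalized to unit
sum (zero rows kept at zero and flagged). Both diseases (Euclidean
distance on rows) and genera (on columns) are clustered with UPGMA.

UPGMA is implemented directly (O(n³), Lance–Williams average-linkage
update) so that tie-breaking is deterministic: among equal-distance
candidates, the pair of clusters whose smallest leaf labels sort first
merges first, and the left child of every merge is the cluster with the
smaller key. Dendrogram heights are the average linkage distances;
Newick branch lengths are `(parent_height − child_height)/2`, making the
tree ultrametric. scipy's `linkage` agrees on tie-free inputs but leaves
tie order unspecified, which is why the package carries its own
implementation.

## Synthetic corpus generator

The generator emulates the features of abstract text the pipeline keys
on: capitalized genus surfaces (full, single-edit-misspelled, and
`X. epithet` abbreviated forms), disease terms, increase/decrease
phrasing near the genus name, and distractor capitalized words. It does
**not** emulate scientific prose, negation, anaphora, novel entities
outside the lexicon, or correlated multi-pair association structure —
passing tests therefore demonstrate correctness of the recognition and
counting rules under their stated assumptions, not NER performance on
real PubMed text.

Entity inclusion per article is Bernoulli at per-entity baselines.
Defaults are 0.08 for genera and 0.10 for diseases — the regime of
widely reported entities, chosen so that 2×2 tables at a 2,000-article
corpus are populated enough for the exact test's discreteness not to
dominate (the one-sided Fisher test is conservative; at much rarer
margins its realized size drops well below nominal). A planted pair
(e₁, e₂, OR) is drawn jointly from the 2×2 Bernoulli distribution with
those margins and that odds ratio, obtained in closed form from the
standard quadratic in p₁₁; a requested OR incompatible with the margins
(degenerate margins with non-unit OR) raises before generation. Planted
pairs must be entity-disjoint — each pair is calibrated against
independent backgrounds, avoiding joint log-linear fitting. Overlapping
planted structures are a stated non-feature.

Misspellings apply one random edit (substitution/deletion/insertion)
after the first character — genus initials are essentially never
mistyped in practice, and the recognizer's first-letter guardrail makes
an initial edit unrecoverable by design. An edit that would land within
distance 1 of a *different* genus is re-drawn, so recognizer precision
is measurable as exactly 1.0 against the truth; ambiguity-driven recall
loss remains possible (e.g. a deletion shortening a 6-letter genus below
the fuzzy length threshold) and is why misspelling recall is specified
as ≥ 0.95 rather than 1.0. Distractor capitalized words in the sentence
templates are validated at construction time to be outside fuzzy range
of the genus vocabulary. When a disease surface embeds a genus name
(`Clostridium difficile infection`), that genus is truly present in the
text and is added to the article's ground-truth entity set.

Identical spec + seed yields byte-identical MEDLINE output.

## Problem sizes and reproducibility

The shipped checks run at desk scale, chosen as the smallest sizes at
which each property is sharply testable: exact-test agreement is
enumerated over all 46,376 tables with N ≤ 30; the null calibration uses
six 2,000-article corpora (3,000 genus–disease pairs); power uses 50
replicate 2,000-article corpora with a planted OR = 10 pair at ~100-article
margins; NER and trend checks use 600–800-article corpora over the full
packaged lexicon; UPGMA agreement uses 100 random tied matrices of up to
8 leaves; round-trip identity uses 50 randomized 20-article corpora.
`scripts/acceptance.py` recomputes all of these from a single `--seed`.

## Known limitations

* Dictionary-bounded recall: entities absent from the master list are
  invisible; there is no model-based discovery of novel names.
* No negation or relation extraction; trend tags are keyword-window
  heuristics and co-occurrence is not interaction.
* Evidence counts are coverage-biased: heavily studied organisms and
  diseases dominate raw strengths, which is exactly why the exact tests,
  not the counts, carry the significance flags.
* The enrichment universe and the Bonferroni family are conventions;
  both are parameters, and conclusions sensitive to them should be
  checked under the alternatives.
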