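# evilit

Literature-evidence mining of microbe–microbe and microbe–disease
associations from PubMed abstracts.

Microbiome case–control studies routinely produce lists of differentially
abundant bacterial genera and co-occurrence networks inferred from 16S
abundance data. Both are noisy, and the natural sanity check — "has anyone
actually reported these two organisms together, or this organism with this
disease?" — means mining decades of biomedical abstracts. `evilit` builds
that evidence backend and answers those queries reproducibly:

* **Corpus ingestion** — MEDLINE flat files and PubMed XML parse into one
  article record type (PMID, title, abstract, journal, year, authors).
* **Entity recognition** — bacterial genera are matched against a master
  list with normalization of surface variants: `Escherichia coli`,
  `E. coli` and the misspelling `Eschericia` all collapse onto
  *Escherichia* (exact dictionary hits, Levenshtein distance ≤ 1 with
  first-letter agreement and unique-hit guardrails, and abbreviation
  resolution within an article). Diseases are matched against a packaged
  51-entry dictionary spanning six organ categories (gut, skin, lungs,
  brain, urogenital, systemic) with longest-synonym-first word-bounded
  matching. Each genus is also tagged with an abundance trend
  (+1 increase / −1 decrease / 0) from nearby keywords, and per-article
  noun keywords are stored for word-cloud summaries.
* **Statistics** — association between two entities is tested on the 2×2
  article-count table with Fisher's exact test (one-sided by default) and
  the Pearson χ² test, with Bonferroni correction across the tested
  family. The genera significantly associated with each disease form
  "disease sets" used for hypergeometric enrichment of user genus lists,
  `p = P(X ≥ |query ∩ set|)`. Disease similarity within an organ category
  is computed by bidirectional UPGMA clustering of the row-normalized
  co-occurrence matrix of the top persistent genera (Euclidean distance).
* **Query workflows** — genus ego-networks (top-100 co-occurring genera),
  disease→genera and genus→diseases ranked views, edge-list validation
  with nine-count evidence statistics (given disease / any disease /
  global), and differential-list validation with enrichment.
* **Synthetic corpora** — a generator emits MEDLINE-format abstracts with
  exactly known entity content, planted pairwise odds ratios, injected
  trends, misspellings and abbreviations, so the whole pipeline is testable
  without any download.

## Worked example

```bash
# 1. simulate a corpus with a planted Prevotella-asthma association (OR=8)
cat > spec.yaml <<EOF
n_articles: 150
seed: 0
genus_vocab: [Escherichia, Lactobacillus, Prevotella, Veillonella]
disease_vocab: [asthma, ulcer]
genus_baseline: 0.25
disease_baseline: 0.25
planted_pairs: [[Prevotella, asthma, 8.0]]
EOF
evilit simulate --config spec.yaml --seed 42 --out sim
evilit build --corpus sim/corpus.medline --format medline --out idx
evilit query-disease asthma --index idx
```

On this simulated corpus the query prints (TSV, abridged):

```
entity	count	odds_ratio	p_fisher	p_chi2	p_bonferroni	significant
Prevotella	22	8.97	1.98e-07	3.61e-08	7.93e-07	True
Escherichia	10	1.13	0.468	0.78	1	False
Lactobacillus	8	0.803	0.756	0.628	1	False
Veillonella	8	0.844	0.72	0.709	1	False
```

`count` is the number of articles mentioning both the genus and asthma;
the planted genus is the only one whose one-sided Fisher p (here
2.0 × 10⁻⁷ on 150 articles) survives the screen — the decoys sit at their
background co-occurrence rates. The same index serves the other
workflows, e.g.
`evilit validate-list genera.txt --index idx --disease asthma` for a
differential-abundance list with enrichment, or
`evilit query-genus Prevotella --index idx` for its ego network.

The library API mirrors the CLI: `build_index`, `genus_ego_network`,
`disease_association_view`, `validate_network`, `validate_list`,
`disease_similarity`, `enrich`, and so on — see `docs/methods.md` for the
statistical definitions and design choices.

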