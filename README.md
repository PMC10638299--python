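# dreamgraphs

Speech-graph analysis of dream reports: turn free-text dream narratives into
directed word-adjacency multigraphs, quantify their structure, and test how
that structure differs between dream conditions — non-lucid dreams, lucid
dreams, and out-of-body experiences (OBEs).

The package is for researchers in computational psycholinguistics and sleep
science who collect dream journals and want a reproducible, fully tested
pipeline from raw text to fitted models, without depending on a particular
pretrained NLP model or on access to anyone's private journal corpus.

## The method

1. **Annotation.** Each report is tokenized, POS-tagged and lemmatized.
   Only content words — tokens tagged NOUN, VERB or ADJ — are kept, as
   lowercased lemmas in narrative order. Annotation is a pluggable
   contract: a deterministic lexicon-based annotator (packaged, ~200-entry
   Spanish toy lexicon) is the default; a spaCy-backed annotator is an
   optional extra.
2. **Speech graphs.** Each distinct lemma is a node; every consecutive
   lemma pair contributes one directed edge, repeats included (a
   multigraph). Fourteen attributes are computed per report: N, E, PE
   (parallel edges), L1/L2/L3 (loops of one, two, three nodes, from powers
   of the multiplicity adjacency matrix A: L1 = tr A, L2 = ⌊tr A²/2⌋,
   L3 = ⌊tr A³/3⌋), LSC (largest strongly connected component), ATD = 2E/N,
   density = E/(N(N−1)), diameter and ASP (directed shortest paths over
   reachable ordered pairs), mean clustering CC, mean betweenness
   centrality, and mean average-neighbor degree.
3. **Aggregation.** Per-dream attributes are averaged per (dreamer,
   condition); rows whose mean N or mean E lie more than 3 MADs from their
   condition's median are excluded (MAD = 1.4826 × median absolute
   deviation).
4. **Models.** Weighted linear models with per-dreamer weights
   w = ln(n_dreams + 1): omnibus condition comparisons
   (attribute ~ condition) with Type II F tests and pairwise contrasts, and
   attribute-pair association models
   (response ~ covariate × condition) with per-condition slopes.
5. **Co-occurrence networks.** Sentence-adjacency co-occurrence counts over
   the top-k frequent words, with weighted-degree centrality ranking.
6. **Synthetic corpora.** A seeded generator produces labelled corpora
   whose structural statistics mimic dream journals: Zipf-weighted
   vocabulary, per-dreamer verbosity, and a recurrence parameter ρ (urn-style
   resampling of the report's own past tokens) that controls graph
   compactness, so the OBE compactness signature can be planted and
   recovered end to end.

## Worked example

`examples/attribute_associations.py` runs one replicate of the packaged
recurrence-signature experiment — two cohorts of 20 dreamers differing only
in recurrence (ρ = 0.10 vs 0.45), full pipeline, then the interaction model
ASP ~ E × condition:

```
$ python examples/attribute_associations.py
weighted mean density: low-recurrence 0.0256, high-recurrence 0.0522
ASP ~ E interaction: F = 17.49, P = 1.77e-04
slope of ASP on E: low-recurrence +0.0317, high-recurrence -0.0120
signature recovered: True
```

The high-recurrence cohort's graphs are twice as dense, and its ASP-vs-edges
slope is **negative** — longer, more edge-rich reports have *shorter*
average paths because they loop back onto their own vocabulary — while the
control cohort's slope is positive. This sign reversal, confirmed by the
interaction F test, is the structural signature reported for out-of-body
dream reports.

Other examples: `build_speech_graph.py` (one report to attributes),
`compare_conditions.py` (omnibus comparisons), `cooccurrence_network.py`
(frequency and centrality tables), `simulate_corpus.py` (generator ground
truth and monotonicity claims).

A thin CLI wraps the same stages and composes file-to-file:

```
dreamgraphs simulate --out corpus.jsonl --seed 1
dreamgraphs annotate --in corpus.jsonl --out seqs.jsonl
dreamgraphs graphs   --in seqs.jsonl   --out per_dream.csv
dreamgraphs aggregate --in per_dream.csv --out per_dreamer.csv
dreamgraphs associate --in per_dreamer.csv --response ASP --covariate E --out assoc.json
```

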