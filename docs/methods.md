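# Methods

This note documents the models and conventions the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical edge cases.

## Speech graphs

A report's graph is built from its content-lemma sequence (tokens tagged
NOUN/VERB/ADJ, lowercased lemmas, narrative order): nodes are the distinct
lemmas, and each consecutive pair contributes one directed edge, so
E = sequence length − 1 and repeats are kept. E counts multiplicity;
density = E/(N(N−1)) therefore may exceed 1 on highly repetitive toy
inputs. This is deliberate: reporting E and PE (repeats beyond the first
per ordered pair) as separate attributes requires retaining multiplicity.

Loop counts come from powers of the multiplicity adjacency matrix:
L1 = tr A, L2 = ⌊tr A²/2⌋, L3 = ⌊tr A³/3⌋. The division is integer
division. On self-loop-free graphs these equal exhaustive enumeration of
distinct directed 2- and 3-cycles (counting parallel-edge combinations) —
a tested invariant. On graphs mixing self-loops with reciprocal edges the
traces count closed *walks* and can over-count relative to simple-cycle
enumeration (never under-count); the test suite enumerates these
contamination cases explicitly. This convention follows the established
speech-graph tradition of computing loop measures from matrix powers.

Projection conventions: shortest paths, strong connectivity and
betweenness use the directed simple projection (multiplicities collapsed,
self-loops dropped — neither affects reachability); clustering and
average-neighbor degree use the undirected simple projection, where those
quantities are conventionally defined. Diameter and ASP are taken over
reachable ordered pairs u ≠ v only, and are 0 when no such pair exists, so
disconnected or single-node graphs never produce infinities that would
poison per-dreamer averages. Density is 0 for N < 2, and all
path/centrality attributes are 0 in degenerate cases.

Betweenness normalization: raw directed pair-dependencies are divided by
(N−1)(N−2)/2, so the middle node of a directed path graph scores exactly 1;
the reported attribute is the mean over nodes, 0 for N < 3. On strongly
bidirectional graphs individual node scores can in principle exceed 1 under
this scaling; on word-adjacency graphs they do not in practice, and the
scale matches the small (≪ 1) mean values typical of this literature.

## Aggregation and exclusion

Per-dream attributes are averaged per (dreamer, condition) — the "average
graph" — with dream count n and model weight ln(n + 1). The natural
logarithm is a free choice: any base rescales all weights equally and
leaves weighted-least-squares estimates unchanged.

The outlier screen runs within each condition on mean N and mean E:
flag |x − median| > 3 × MAD with MAD = 1.4826 × median(|x − median|); the
constant makes MAD estimate the standard deviation under normality, and
both numbers are the documented defaults of the robust-outlier routine
this screen reproduces. The screen is a single pass (no iteration until
stable), strict at the boundary, and disabled with a warning when a group
has fewer than three rows or zero MAD (a constant vector would otherwise
flag everything). A dreamer excluded in one condition keeps their rows in
other conditions, because the rule operates per participant *and* dream
type.

## Weighted linear models

Both analyses are weighted least squares with the ln(n+1) weights, fitted
exactly (estimates are tested against the closed-form weighted normal
equations to 1e-10). The condition factor uses treatment coding with NN —
the non-lucid control — as reference whenever present, so "the NN slope"
is the bare covariate coefficient. Association models are the full
interaction design: intercept, condition dummies, covariate, and
condition × covariate terms; per-condition slopes are the covariate
coefficient plus that condition's interaction coefficient, with standard
errors from the coefficient covariance and df equal to the model's
residual df.

F tests use Type II sums of squares by default (the default of the
standard ANOVA routine in this literature): a term is tested by comparing
the model without it to the model with it, respecting marginality — a main
effect is never tested while its own interaction stays in the model.
Type III is available by configuration. Pairwise contrasts are differences
of adjusted condition means, evaluated at the weighted grand mean of the
covariate when one is present; their P values are reported **unadjusted**
by default because that is how such contrasts are usually reported in this
setting, with Bonferroni and Holm available as configuration hooks. All P
values are two-sided.

Null calibration: with responses whose variance is inversely proportional
to the fit weights (the design the weights assume), the condition F test's
P values are uniform — verified by a 1000-replicate simulation
(Kolmogorov–Smirnov) with type-I error within [0.03, 0.07] at α = 0.05.

## Co-occurrence networks

Co-occurrence is immediate adjacency within a sentence — not windowed or
similarity-based co-occurrence. Each adjacent pair of retained words adds
one to their undirected edge; adjacency never crosses sentence boundaries;
self-pairs are ignored; the network is restricted to the top-k most
frequent words (ties broken lexicographically). The content filter is on
by default but can be disabled, since the most central words of real dream
corpora include auxiliaries (*haber*, *ser*, *estar*) that the filter
removes. Centrality is a word's summed edge weight divided by the
network's total edge weight; betweenness is available as an alternative.

## The synthetic generator

The generator emulates the *structural statistics* of dream journals, not
their semantics. Each report is a token stream: with probability
(1 − content_fraction) a function word (fixed Spanish list, tagged
non-content by the packaged annotator); otherwise a content lemma, drawn
fresh from a Zipf-weighted lexicon — or, with probability ρ, resampled
uniformly from the report's own past tokens (an urn scheme). Tokens are
assembled into sentences of Poisson-distributed length (mean 12, min 3).
Everything is driven by one seeded generator; identical seeds give
byte-identical corpora.

Defaults and rationale:

* **Report length**: mean 217.3 tokens, within-dreamer sd 53.2 — the
  printed scale of real non-lucid dream reports. Each dreamer additionally
  draws a personal mean length uniformly from mean ± 0.8 × mean:
  verbosity is a stable personal trait, and this between-dreamer spread is
  what gives per-dreamer averages a usable range of mean edge counts for
  the association models.
* **Content fraction 0.55**: roughly the content-word share of Spanish
  narrative prose.
* **Lexicon**: 2000 lemmas (the packaged toy lexicon's readable Spanish
  lemmas first, generated forms after), Zipf exponent 0.6. Content-word
  vocabularies are flatter than whole-text Zipf curves, whose steep head
  is function words.
* **Recurrence–length coupling**: the per-report recurrence is
  ρ_r = min(0.9, ρ · (L/L̄)^0.5), where L̄ is the corpus mean length. The
  group parameter ρ is thus the recurrence *at the reference length*, and
  longer reports from a high-recurrence cohort are proportionally more
  repetitive. This coupling is what produces the within-group signature —
  a negative ASP-vs-edges slope in the high-ρ cohort — and is the reason
  the ground-truth table records a per-report ρ. With a length-independent
  ρ the slope signs cannot come out as observed in real OBE reports: the
  ASP-versus-length trend at fixed ρ is governed by lexicon saturation,
  which is *stronger* in low-ρ cohorts (more fresh draws), inverting the
  pattern. Modelling repetitiveness as increasing with narrative length
  resolves this, and is psychologically natural: a narrator circling a
  single intense experience revisits its core vocabulary more the longer
  they go on.
* **Study-shaped default cohorts** (`default_params`): 13 non-lucid, 24
  lucid and 15 OBE-contributing dreamers (the post-exclusion composition
  of the study sample this emulates), 5–15 dreams each, baseline ρ = 0.15
  with ρ = 0.30 in the OBE cohort.

What passing tests on this generator do and do not show: they validate the
pipeline's mechanics and the direction of the recurrence→compactness
mechanism; they say nothing about semantics, themes, syntax, coreference,
or whether real lucid/OBE reports differ — the generator has no model of
meaning, and its function-word stream is unstructured.

## The signature experiment

The packaged experiment (`dreamgraphs.experiments`) uses two cohorts of 20
dreamers (ρ = 0.10 vs 0.45), 5–10 dreams each, reports of 150 ± 15 tokens
within dreamer, chosen as a desk-scale corpus that one pipeline pass
processes in a couple of seconds. Across 50 seeded replicates the pipeline
recovers higher density in the high-ρ cohort and the (negative,
non-negative) slope pair in ≥ 90% of replicates, and the interaction F
rejects at α = 0.05 in ≥ 80% — the quantities `scripts/acceptance.py`
recomputes.

## Known limitations

* The lexicon annotator is a fixture: real Spanish morphology (clitics,
  irregular inflection, ambiguity) needs the spaCy-backed annotator.
* No coreference or synonym handling: pronouns and synonyms stay distinct
  nodes, as in the tradition this implements.
* L2/L3 walk-contamination on self-loop-adjacent structures is documented
  rather than corrected, to stay within the matrix-power convention.
* Pairwise contrast P values are unadjusted by default; use the
  configuration hook if familywise control is needed.
* The generator's monotonicity claims (density up, N/diameter/ASP down in
  ρ) are Monte-Carlo facts about its own distributions, not theorems.
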