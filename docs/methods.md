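# Methods

## Recommendation model

`ontorec` ranks candidate ontologies for an input text by aggregating four
criterion scores, each normalized to [0, 1] over the candidate pool of the
current run, into a relevance score

    score(o, t) = w_c·coverage + w_a·acceptance + w_d·detail + w_s·specialization

with default weights (0.55, 0.15, 0.15, 0.15). Coverage dominates because
the primary use case is annotation: an ontology that does not cover the
input is of little use regardless of its pedigree. Ontologies producing no
annotations at all are removed before scoring; when nothing matches, the
run returns an empty ranking with an explanatory status rather than failing.

Normalization is always pool-relative: a score of 1 means "best among the
candidates evaluated in this run", not an absolute judgment. Re-running
with a different candidate pool legitimately changes normalized scores.

### Annotation and coverage

The annotator builds a dictionary of all preferred names and synonyms,
normalized to case-folded token sequences (tokens are maximal runs of
letters/digits; hyphens and underscores separate). Every token window of
the input equal to a dictionary term yields one annotation per (span,
class, match type); matching is exact — no stemming or lemmatization, which
keeps behavior transparent and reproducible. When a class's preferred name
and one of its synonyms normalize to the same term, only the PREF
annotation is emitted for that class and span. In keyword mode
(comma-delimited input) an annotation survives only if it covers all words
of exactly one keyword; partial and straddling matches are discarded, since
the commas carry term-boundary information.

Each annotation scores `(typeScore + multiWordScore) · annotatedWords`
(PREF 10, SYN 5, multi-word bonus 3). Overlap resolution keeps, per
overlapping fragment, only the best annotation: annotations are sorted by
score descending with a deterministic tie-break (PREF before SYN, longer
span, smaller start, class id, acronym) and swept greedily, keeping each
annotation iff it overlaps no kept one. Overlap means character-span
intersection. Greedy per-fragment selection — not a globally optimal
weighted interval schedule — is the documented behavior: it reproduces the
intended "best annotation per fragment" semantics, and the discarded-
dominance invariant (every discarded annotation overlaps a kept one of
equal or higher score) holds by construction.

Coverage is the selected-point sum divided by the pool maximum. The pool
maximum is the larger of (a) the greedy selection over all candidates'
pooled annotations and (b) the best single candidate's selection. The
safeguard (b) exists because a greedy union sweep can, in rare layouts — a
high-scoring middle span suppressing two flanking spans that one ontology
covers separately — fall below a member's own selection; taking the max
keeps every normalized coverage within [0, 1].

### Acceptance

`acceptance = w_presence·presenceScore + w_visits·visitsScore` (defaults
0.5/0.5). presenceScore is a weighted sum of per-repository presence flags;
visitsScore weights per-repository visit counts divided by the pool maximum
for that repository (a repository with zero recorded visits contributes
nothing rather than dividing by zero). The metadata file carries one
cumulative visit count per repository; no recency windowing is applied.
Runs without metadata score acceptance as 0 for all candidates, which
cancels out of the ranking.

### Detail

Per selected annotation, detail is the mean of three saturated ratios:
`min(|D|/k_d, 1)`, `min(|S|/k_s, 1)`, `min(|P|/k_p, 1)` with defaults
k = (1, 4, 10) — one definition, four synonyms and ten properties already
represent a well-documented class. The ontology's detail is the mean over
its *selected* annotations (0 when none). The denominator is deliberately
the number of selected annotations, not the full annotation count: detail
measures the quality of the classes actually used to cover the input, and
averaging over all annotations would double-penalize ontologies whose
redundant matches were already discarded by overlap resolution.

### Specialization

`spec_raw(o) = Σ_a (annScore(a) + 2·depth(a)) / log10(|o|)` over **all**
annotations: multiple classes matching the same fragment are evidence of
domain fit, so the pre-selection set is the right domain signal. `depth` is
1-based (root = 1) and uses the shortest parent-path for multi-parent
classes — the most conservative granularity claim, deterministic and
order-independent. `|o|` is the declared size, which may exceed the number
of loaded classes for partial dictionaries; sizes below 2 are rejected
(non-positive log). The raw value is divided by the pool maximum, so
exactly one candidate scores 1 barring exact ties. Note that a displayed
specialization uses a denominator at full precision; quoting intermediate
values rounded to two decimals can shift the quotient by ~0.1%.

### Legacy scorer

`score_v1` implements the predecessor formula —
`Σ_a (annScore_v1(a) + 2·hierarchyLevel(a)) / log10(|o|)` with PREF 10 /
SYN 8, no overlap resolution and no normalization — for comparison studies.
Its hierarchy level is 0-based by default (root = 0), switchable to 1-based
via `depth_base`. Because every annotation contributes, an ontology with
many duplicate classes on few terms can outscore one with broad coverage;
the test suite reproduces this divergence qualitatively against the current
ranking.

### Ontology sets

All combinations of 2..max_set_size (default 3) surviving candidates are
enumerated. A set is pruned when two members cover identical selected
fragments, or when its pooled selected points do not strictly exceed those
of some proper subset — "no strict gain" subsumes the natural equal-points
rule and guarantees that every surviving set strictly improves on each of
its members. Set coverage is the pooled selection normalized as usual; each
selected annotation is attributed to the member that supplied it (the
selection tie-break resolves shared-term attribution deterministically, no
double counting), and acceptance, detail and specialization are member
scores averaged by these coverage contributions. Recomputing detail over
the pooled selection instead of averaging by contribution would be a
defensible alternative; the proportional rule was chosen so that a member's
influence on every criterion tracks the coverage it actually supplies.

## Numerical choices

- Scores are kept at full float precision throughout; only display values
  are rounded, half-up via `Decimal` (so 0.125 → 0.13), to one decimal on
  the 0–100 display scale and two decimals where quoted.
- Weight sums are validated to 1 within 1e-9; contribution sums likewise.
- Ties everywhere break deterministically (documented sort keys); ranking
  ties break by coverage, then acceptance, then acronym.
- Degenerate inputs: empty documents annotate to nothing; a pool with no
  annotations raises an explicit undefined-coverage error at the scorer
  level and is converted to an empty-ranking status by the pipeline.

## Synthetic repository generator

`generate_synthetic_repository` emulates the recommender's operating
environment at desk scale: a term vocabulary (default 200 terms, 30%
multi-word) shared across ontologies with controlled overlap (default 30%
of each ontology's 40 terms), classes with random synonym (0–5),
definition (0–2) and property (0–15) counts, random parent chains up to
depth 8, three repositories with random presence flags and visit counts up
to 5000, and 120-word documents in which roughly half the words come from
vocabulary terms. A 20% fraction of classes alias another vocabulary term
as a synonym, producing the duplicate-span matches that overlap resolution
must handle. All draws flow from one seed and identical seeds produce
byte-identical files.

What it does not emulate: real lexical variation (morphology, typos,
abbreviations), realistic term-frequency and hierarchy-shape distributions,
semantic relatedness between terms, and real repository popularity
dynamics. Passing tests on synthetic data therefore demonstrate the
correctness and determinism of the scoring machinery, not annotation
quality on real biomedical text.

## Problem sizes

The default test and reproduction runs use toy scenarios (two ontologies,
single sentences) and synthetic repositories of 2–5 ontologies with 8–40
terms each; property suites run tens of randomized instances with up to 20
tokens and 12 dictionary terms (annotator oracle) or 6 candidates (set
pruning brute force). These sizes fully exercise every code path while
keeping the whole suite under a minute.

## Known limitations

- The annotator is purely lexical; no fuzzy matching, abbreviation
  expansion or semantic-type filtering.
- Property counts from OBO files approximate "other properties" as the
  count of stanza tag-value lines outside id/name/def/synonym/is_a; OWL
  semantics are out of scope.
- Set search is exhaustive over 2–3 members with pruning, not an optimal
  set-cover algorithm.
- Acceptance requires externally supplied repository metadata; the package
  performs no live repository queries.
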