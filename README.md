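# ontorec

Multi-criteria recommendation of biomedical ontologies for annotating text.

Researchers who want to annotate a corpus or a list of keywords with
ontology classes face a practical question: *which of the hundreds of
available biomedical ontologies should I use?* `ontorec` answers it locally.
Given an input (free text or comma-delimited keywords) and a repository of
ontologies on disk (OBO files or a simple dictionary format), it ranks
single ontologies — and small ontology sets — by a weighted combination of
four criteria:

- **coverage** — how much of the input the ontology annotates,
- **acceptance** — how trusted the ontology is (presence in repositories,
  recent page visits),
- **detail** — how richly documented the matched classes are (definitions,
  synonyms, properties),
- **specialization** — how tailored the ontology is to the input's domain
  (deep matches in small ontologies score high).

## The model

A built-in dictionary annotator finds every match of every class preferred
name (PREF) and synonym (SYN) against the input, including overlapping
matches. Each annotation *a* is scored

```
annScore(a) = (typeScore(a) + multiWordScore(a)) * annotatedWords(a)
typeScore   = 10 (PREF) | 5 (SYN)
multiWordScore = 3 if annotatedWords(a) > 1 else 0
```

so a preferred-name match on a two-word term is worth (10+3)·2 = 26 points.
Within each overlapping text fragment only the highest-scoring annotation
is *selected*; coverage is the sum of selected scores, normalized by the
best achievable over the whole candidate pool. Detail averages, over the
selected annotations, `(min(|D|/k_d,1) + min(|S|/k_s,1) + min(|P|/k_p,1))/3`
with saturation constants k = (1, 4, 10). Acceptance combines weighted
per-repository presence flags with visit counts normalized per repository.
Specialization uses **all** annotations (not just selected ones):

```
spec(o) = norm( Σ_a (annScore(a) + 2·depth(a)) / log10(|o|) )
```

where `depth` is the matched class's 1-based hierarchy level and |o| the
ontology's declared size. The relevance score is

```
score(o) = 0.55·coverage + 0.15·acceptance + 0.15·detail + 0.15·specialization
```

(weights configurable, must sum to 1). Ontology sets of 2–3 members are
enumerated, pruned when they add no coverage over a subset, scored with the
pooled-selection coverage, and their other criteria averaged over members
weighted by each member's coverage contribution. A legacy scorer
(`score_v1`, PREF 10 / SYN 8, no overlap resolution) is included for
comparison; it reproduces the failure mode where many duplicate matches on
a few terms outrank broad coverage.

## Worked example

```python
import ontorec as rc

fx = rc.worked_examples()["blood_cell"]          # six-class toy ontology
anns = rc.annotate(fx.document, fx.ontologies)   # "A thrombocyte is a kind of blood cell"
sel = rc.select_annotations(anns)
print(len(anns), sel.raw_coverage_points)        # -> 6 31.0
```

The annotator finds 6 annotations (platelet via synonym *thrombocyte*;
*blood cell*, *blood*, *cell* via preferred names; *cell* twice more via
synonyms). Overlap resolution keeps the synonym match *thrombocyte* (5
points) and the two-word preferred match *blood cell* (26 points): raw
coverage 5 + 26 = 31.

From the shell, on the second built-in scenario (*"Penicillin is an
antibiotic used to treat tonsillitis"* against a large well-documented
ontology O1 and a small deep ontology O2):

```
$ ontorec fixtures --name penicillin --out fx
$ ontorec recommend --input fx/penicillin/input.txt \
    --ontology fx/penicillin/O1.dict --ontology fx/penicillin/O2.dict \
    --metadata fx/penicillin/metadata.tsv --format tsv
rank  subject  relevance  coverage  acceptance  detail  specialization  annotation_count
1     O1       66.2       60.0      100.0       86.7    34.7            2
2     O2       54.4       60.0      30.0        12.5    100.0           2
```

(scores displayed on the 0–100 scale). With `--output sets` the pair
{O1, O2} wins with coverage 100.0 — together they cover *penicillin*,
*antibiotic* and *tonsillitis*. A seeded synthetic repository for larger
experiments is available via `ontorec synth --seed N --out DIR`.

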