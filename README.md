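# cutext

Automated content-unit scoring of picture-description language samples.

`cutext` quantifies *what* a person managed to say or write about an
elicitation picture (such as the Western Aphasia Battery picnic scene), for
research on language production in primary progressive aphasia (PPA) and
related neurodegenerative syndromes.  Manual content-unit annotation of a
single transcript takes 20–30 minutes; a dictionary-driven scorer does it in
seconds and makes the counting rules exactly reproducible.

## The measures

Given a scene-specific **content-unit (CU) dictionary** — an inventory of the
picture's entities, actions and properties, each entry grouping the
morphological/synonym variants that credit it ("girl" and "daughter" are one
entry) — the scorer computes per sample:

- **CU** — number of dictionary entries credited; an entry counts at most
  once no matter how often it is mentioned.  Matching is by
  (lemma, part-of-speech class) after inflectional lemmatization, so *run,
  ran, running* all credit the same action.
- **U (units)** — every word, non-word and false start.  Contractions count
  as two units ("they're" = 2); unintelligible/illegible stretches count as
  units but never as CUs.
- **CU/U ratio** — CU ÷ U, a content-density measure (elsewhere called
  "informativeness").  Telegraphic output ("Woman pouring drink") drives it
  toward 1; empty or tangential language drives it toward 0.
- **Unambiguous vs ambiguous CU** — whether the entry denotes exactly one
  scene element (fixed per dictionary entry, never context-resolved) — and
  **self-referential pronouns** (*I, we, us*), counted per occurrence.

Around the scorer the package provides the accompanying study machinery: a
validity protocol against manual annotation (Pearson r expressed as a
percentage, Fisher-z CI, discrepancy taxonomy), a statistics harness
(one-way ANOVA with Tukey HSD and Cohen's d, one-between/one-within
split-plot ANOVA for written-vs-spoken designs, Pearson correlations,
one-covariate ANCOVA), and a synthetic-cohort generator that emits raw texts
with exact ground truth for every metric.

## Worked example

```python
from cutext import analyze_text, load_packaged_dictionary

d = load_packaged_dictionary()   # 64-entry picnic-scene inventory
text = ("The man is reading a book and the woman pours a drink. "
        "I think their dog and the boy are running.")
r = analyze_text(text, d)
m = r.metrics
print(f"units = {m.unit_count}")
print(f"content units = {m.cu_count} "
      f"(unambiguous {m.unambiguous_cu}, ambiguous {m.ambiguous_cu})")
print(f"CU/U ratio = {m.cu_u_ratio:.3f}")
print(f"self-referential pronouns = {m.self_ref_count}")
```

prints

```
units = 21
content units = 9 (unambiguous 8, ambiguous 1)
CU/U ratio = 0.429
self-referential pronouns = 1
```

21 units (every word counts once; *reading*, *pours*, *running* lemmatize to
dictionary actions), 9 distinct CUs — *man, woman, boy, dog, book, drink,
read, pour, run* — of which only *run* is ambiguous (two scene elements
run), one first-person pronoun (*I*), and a content density of 9/21 ≈ 0.43.

The packaged picnic dictionary is a synthetic stand-in with the same
structure (64 entries, grouped variants, ambiguity labels) as published
picnic-scene CU inventories, which are not redistributable; supply your own
TSV/JSON dictionary to score a different corpus or scene.

## Command line

```sh
cutext simulate --preset paper_tables_written --seed 42 --out sim
cutext analyze sim/transcripts.csv --out scored
cutext stats scored/metrics.csv
```

```
[written] one-way ANOVA on cu_u_ratio: F(3,91) = 4.292, p = 0.00702
    control vs lvPPA: diff = -0.029, Tukey p = 0.8288, d = -0.43
    control vs nfvPPA: diff = -0.106, Tukey p = 0.01521, d = -1.15
    ...
```

`cutext analyze` also accepts a directory of `.txt` files; further
subcommands: `compile-dict` (build a dictionary from control mentions with
the ≥3-controls criterion), `validate` (score automated output against a
manual-annotation CSV).

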