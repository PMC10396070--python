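# Methods

This note documents the scoring model, the counting conventions, the
synthetic-data generator and the statistical procedures implemented in
`cutext`, together with the design decisions taken where more than one
reasonable convention exists.

## Content-unit scoring model

A **CU dictionary** enumerates the content units of one elicitation picture.
Each entry carries a category (entity / action / property), a fixed
ambiguity label, and a non-empty set of (lemma, pos_class) variants with
five coarse POS classes (noun, verb, adjective, adverb, other).  Two
structural invariants are enforced at load time: entry ids are unique, and
every (lemma, pos_class) pair belongs to exactly one entry.  The second
invariant is what makes `cu_count <= unit_count` a theorem rather than an
observation: each token can credit at most one entry, and each entry is
credited at most once.

A sample credits an entry when at least one of its word tokens normalizes
to one of the entry's variants.  Repetitions and distinct variants of the
same entry ("girl" … "daughter") never add CUs, only units.  The ambiguity
label of a credited CU is copied from its entry; no context disambiguation
is attempted, because ambiguity is defined as a property of the term with
respect to the scene, not of its use in a sentence.

`compile_dictionary` implements the standard corpus-construction criterion:
a candidate becomes an entry when at least `min_controls` (default 3)
distinct healthy controls mentioned it.  Compiled entry ids follow
lexicographic label order for determinism.

### Dictionary fixture

The packaged 64-entry picnic-scene dictionary is a **synthetic stand-in**:
published picnic-scene CU inventories are not redistributable, so the
package ships an inventory with the same structure and the canonical worked
examples embedded (entry #12 groups girl/daughter; "dog" is an unambiguous
entity; "run" is an ambiguous action, since both the dog and the boy run).
Results on this fixture exercise the machinery, not the published corpus.

## Unit counting

A unit is every word, non-word (filled pauses: *um, uh, …*), false start
and unintelligible/illegible stretch; punctuation is never a unit.
Conventions chosen where the field's descriptions are silent, all
configurable per corpus:

- **Contractions** count as two units via a closed suffix table
  (*n't, 're, 've, 'll, 'd, 'm*, and *'s* after a closed list of
  pronoun-like bases: *it's, that's, he's, let's, …*).  Possessive *'s* on
  nouns is one unit.  A closed table keeps counts reproducible; heuristic
  contraction detection would not be.
- **False starts** are marked with a trailing hyphen (`pi-`).  Transcription
  practice varies and the convention used in source corpora is typically
  unstated; this is a repository convention.
- **Unintelligible/illegible** stretches are `xxx`, `[unintelligible]` or
  `[illegible]` (configurable).  They count as units, never as CUs.
- Hyphenated compounds without a trailing hyphen are one unit; numerals are
  word units; case and punctuation never change unit counts.

## Normalization (lemmatizer + tagger)

Matching needs inflectional lemmatization and a coarse POS class only, so
the normalizer is a self-contained rule system: closed function-word table
(tagged `other`, never matchable), irregular noun/verb exception tables,
and lexicon-validated suffix rules (*-s/-es/-ies, -ing, -ed, -er/-est* with
consonant-doubling and silent-e restoration), over a packaged content-word
lexicon.  Unknown words lemmatize to themselves with class `other` and
therefore cannot credit CUs.  This mirrors the failure mode reported for
parser-based scorers — wrong POS assignment — and the package exposes
per-sample POS override files (sample_id, char span, forced class) so that
manual corrections are reproducible data rather than undocumented edits.

Self-referential pronouns are counted **per occurrence** over the surface
forms *I, we, us* (extensible via configuration).  Per-occurrence counting
is the only reading consistent with cohort means of the order of several
pronouns per sample.

## Per-sample and cohort metrics

`cu_u_ratio = cu_count / unit_count`, undefined (NaN, excluded from
aggregates, warned) for empty samples.  Cohort tables report the **mean of
per-sample ratios**, not pooled CU over pooled U, matching how group tables
are computed in picture-description studies; the two differ whenever unit
counts vary across samples.  SDs use the n−1 denominator; single-sample
cells report SD as NaN.  Outlier flagging marks samples at least k·SD
(default 1) below or above the cohort mean of a chosen metric; with the
printed cohort values mean 0.364, SD 0.151 the low threshold is 0.213.
(When a printed mean + SD pair disagrees with a printed threshold in the
third decimal — 0.515 vs 0.516 — the package computes from unrounded values;
such discrepancies are rounding artifacts of the source tables.)  With zero
spread nothing is flagged.

## Validity protocol

Validity is 100·r (Pearson) between automated and manual per-sample CU
counts, with a 95% CI from the Fisher z transform (n−3 denominator, the
standard correlation CI; sources typically print the CI without a formula).
Unit validity is computed the same way.  Discrepancies are broken down per
group × modality stratum into unambiguous-CU, ambiguous-CU and
self-reference categories from symmetric set differences of credited entry
ids.  Pooled validity is the headline figure; per-stratum correlations are
also reported.  On synthetic cohorts with ground truth fed back as "manual",
validity is exactly 100% — published sub-100% validity figures reflect
parser errors on natural text, which generated token-bag text cannot and
should not reproduce.

## Statistical harness

All procedures are computed from explicit sums of squares with exact
reference distributions from scipy, and are cross-checked in the test suite
against independent implementations (scipy `f_oneway` / `tukey_hsd`,
pingouin `mixed_anova`, statsmodels OLS ANOVA) to 1e-9 on fixed datasets:

- **One-way ANOVA**: classic between/within decomposition.  All-constant
  input is reported as degenerate (0/0), not an error.
- **Tukey HSD** (Tukey–Kramer under unequal n): studentized-range p-values
  and simultaneous 95% CIs with the pooled within-group mean square.  The
  multiplicity guarantee — Tukey p ≥ unadjusted pairwise t p — holds
  against the t-test sharing the same pooled error term (Fisher's LSD);
  a two-sample t with its own variance estimate is not comparable.
- **Cohen's d**: pooled-SD with (n−1) weighting.  Note that printed d
  values in source tables cannot generally be reproduced from printed
  summary statistics (rounding); only the formula is contractual.
- **Mixed (split-plot) ANOVA** for one between-subjects factor and the
  two-level written/spoken factor: group tested against subject-within-group
  MS; modality and interaction against the modality-by-subject residual.
  With unequal group sizes the modality/interaction sums use
  subject-weighted means; packages differ in unbalanced conventions, and
  equality with pingouin is asserted on balanced designs.  With one group
  the modality F equals the squared paired t.  Written-vs-spoken contrasts
  within each group use the within error term with the studentized range
  over all 2g cell means (the convention behind per-group "Tukey HSD 95%
  CI" columns); this is an approximate simultaneous procedure.
- **ANCOVA** (one covariate, common slope): model-comparison F for the
  group effect adjusted for the covariate; a constant covariate reduces
  exactly to the one-way ANOVA.
- **Pearson r** with the two-sided t-transform p (n−2 df); zero-variance
  input reported as undefined.

Parametric tests are used without normality screening, mirroring standard
practice for these cohort sizes; distributional screening is out of scope.

## Synthetic cohort generator

Each sample plants its CU count k and its ratio ρ directly:

1. k ~ round(Normal(cu_mean, cu_sd)), resampled into
   [cu_mean − 2·SD, cu_mean + 2·SD] ∩ [0, |dictionary|];
2. ρ ~ Normal(ratio_mean, ratio_sd), resampled into
   [ratio_mean − 1.5·SD, ratio_mean + 1.5·SD] ∩ (0, 1];
3. k distinct entries are drawn, split between the unambiguous and
   ambiguous pools by the profile's `unambiguous_share`; each is realized
   as one variant surface, optionally inflected through a curated table the
   normalizer provably inverts;
4. the sample is padded to round(k/ρ) units with (in planted proportions)
   repeated CU mentions, first-person pronouns (Poisson with the profile's
   mean), contractions (2 units each), false starts, unintelligible markers
   and filler words, then shuffled.

Planting ρ rather than independent CU and unit draws makes cohort-mean
ratio recovery well-posed; unit count is the derived quantity k/ρ.  The
truncation bands are symmetric so the planted means stay unbiased; the
lower ρ bound exists because an unbounded 1/ρ tail would occasionally
produce written descriptions with many hundreds of units, a sample no
cohort table exhibits, and would make cohort unit means unrepresentative of
the planted tables.  The residual truncation bias (from the boundary
intersections at 0 and |dictionary|) is small relative to the two-standard-
error tolerance used in recovery tests.  The implied CU–unit covariance
(via shared k) is a modeling choice; source tables do not report it.

Padding vocabulary is hygienic by construction and by test: filler words
normalize outside every dictionary variant, contraction realizations avoid
first-person forms, and false starts/markers are non-lexical.  This is what
makes the round-trip law exact: for every generated sample the pipeline
recovers the truth CU set, unit count and pronoun count with 100% agreement,
which in turn is the surface on which the matcher is checked against a
brute-force quadratic reference.

The packaged `paper_tables` preset instantiates the group × modality cells
of published picnic-scene cohort tables: written controls (n=20, CU
18.5 ± 9.32, ratio 0.30 ± 0.05) and the three PPA variants in both
modalities at their paired-design sizes (n=26/28/15), with ambiguity shares
and self-reference means from the corresponding ambiguity table.
`paper_tables_written` holds the written-only cells at full size
(n=20/28/30/17).  Spoken control CU/ratio values are not printed in the
source tables; the preset uses plausible values (CU 19.5 ± 5.5, ratio
0.20 ± 0.05) chosen once for realism (spoken descriptions are longer and
less dense than written ones).  Disfluency rates (repeats, false starts,
contractions, unintelligible) are likewise modest modality-appropriate
choices; they cancel out of CU and ratio recovery because every injected
element is counted into the planted unit target.

**What the generator does not emulate**: grammar (samples are shuffled token
bags), spelling errors and their correction, discourse structure,
within-subject correlation between modalities (cells are drawn
independently, so written-vs-spoken correlation coefficients are near zero
by construction and are not recovery targets), and natural-text parser
errors (hence synthetic validity is exactly 100%, not the sub-100% figures
reported for real transcripts).  Passing recovery tests therefore
demonstrates correctness of counting, matching and aggregation — not
robustness to natural language.

## Problem sizes and determinism

Recovery tests use the preset cohort sizes above (89–178 samples per
cohort); the cross-seed contrast check runs 100 seeds of the written
preset; null calibration of the ANOVA uses 10,000 simulated 4 × 20
datasets.  All randomness flows through `numpy.random.default_rng` seeded
explicitly; identical inputs, configuration and seed give byte-identical
CSV outputs.
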