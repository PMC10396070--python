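"""Generator determinism, round-trip exactness, vocabulary hygiene, presets."""

import numpy as np
import pytest

from cutext import analyze_table, analyze_text, generate_cohort, generate_sample
from cutext.lexicon import analyze
from cutext.synthetic import (
    CONTRACTION_SURFACES,
    FALSE_START_SURFACES,
    INFLECTIONS,
    GenerationError,
    GroupProfile,
    check_filler_disjoint,
    load_profiles,
)
from cutext.tokenizer import tokenize


def profile(**kw):
    base = dict(
        name="g", modality="written", n=1, cu_mean=5, cu_sd=2,
        ratio_mean=0.4, ratio_sd=0.1,
    )
    base.update(kw)
    return GroupProfile(**base)


class TestGenerateSample:
    def test_telegraphic_profile_yields_pure_cu_list(self, picnic, rng):
        p = profile(cu_mean=3, cu_sd=0, ratio_mean=1.0, ratio_sd=0)
        s = generate_sample(p, picnic, rng)
        r = analyze_text(s.raw_text, picnic)
        assert r.metrics.cu_count == 3
        assert r.metrics.unit_count == 3
        assert r.metrics.cu_u_ratio == 1.0

    def test_zero_cu_profile(self, picnic, rng):
        p = profile(cu_mean=0, cu_sd=0, ratio_mean=0.5, ratio_sd=0)
        s = generate_sample(p, picnic, rng)
        r = analyze_text(s.raw_text, picnic)
        assert r.metrics.cu_count == 0
        assert r.metrics.cu_u_ratio == 0.0

    def test_same_seed_identical_sample(self, picnic):
        p = profile(self_ref_rate=1.0, contraction_rate=0.05,
                    false_start_rate=0.02, unintelligible_rate=0.02)
        a = generate_sample(p, picnic, np.random.default_rng(9))
        b = generate_sample(p, picnic, np.random.default_rng(9))
        assert a.raw_text == b.raw_text
        assert a.truth_cu_ids == b.truth_cu_ids

    def test_unit_target_sanity_cap(self, picnic):
        p = profile(cu_mean=30, cu_sd=0, ratio_mean=0.001, ratio_sd=0)
        with pytest.raises(GenerationError, match="sanity cap"):
            generate_sample(p, picnic, np.random.default_rng(0))

    def test_ambiguity_mix_follows_share(self, picnic, rng):
        p = profile(cu_mean=10, cu_sd=0, unambiguous_share=1.0)
        s = generate_sample(p, picnic, rng)
        amb = {e.entry_id for e in picnic.entries if e.ambiguity == "ambiguous"}
        assert not (s.truth_cu_ids & amb)


class TestRoundTrip:
    def test_pipeline_reproduces_truth_exactly(self, picnic, profiles):
        transcripts, truth = generate_cohort(profiles, picnic, seed=77)
        results = analyze_table(transcripts, picnic)
        for r, row in zip(results, truth.itertuples(index=False)):
            ids = {int(x) for x in row.cu_ids.split(";") if x}
            assert r.annotation.matched_entries == ids
            assert r.metrics.unit_count == row.unit_count
            assert r.annotation.self_ref_count == row.self_ref_count


class TestVocabularyHygiene:
    def test_fillers_and_pronouns_disjoint_from_dictionary(self, picnic):
        assert check_filler_disjoint(picnic) == []

    def test_inflection_table_round_trips_through_normalizer(self):
        for (lemma, pos), surfaces in INFLECTIONS.items():
            for surface in surfaces:
                assert analyze(surface) == (lemma, pos), surface

    def test_every_packaged_variant_is_a_normalizer_fixed_point(self, picnic):
        for entry in picnic.entries:
            for lemma, pos in entry.variants:
                assert analyze(lemma) == (lemma, pos), (entry.entry_id, lemma)

    def test_contraction_surfaces_tokenize_to_two_safe_units(self, picnic):
        vm = picnic.variant_map()
        for surface in CONTRACTION_SURFACES:
            toks = tokenize(surface).tokens
            assert len(toks) == 2, surface
            for t in toks:
                assert analyze(t.surface) not in vm
                assert t.surface.lower() not in {"i", "we", "us"}

    def test_false_start_surfaces_classified(self):
        for surface in FALSE_START_SURFACES:
            (tok,) = tokenize(surface).tokens
            assert tok.kind == "false_start"


class TestGenerateCohort:
    def test_paper_tables_preset_shape(self, profiles, picnic):
        transcripts, truth = generate_cohort(profiles, picnic, seed=5)
        sizes = transcripts.groupby(["group", "modality"]).size()
        assert sizes[("control", "written")] == 20
        assert sizes[("control", "spoken")] == 20
        assert sizes[("nfvPPA", "written")] == 26
        assert sizes[("lvPPA", "spoken")] == 28
        assert sizes[("svPPA", "written")] == 15
        assert len(transcripts) == len(truth) == 178

    def test_paired_modalities_share_subject_ids(self, profiles, picnic):
        transcripts, _ = generate_cohort(profiles, picnic, seed=5)
        nfv = transcripts[transcripts.group == "nfvPPA"]
        written = set(nfv[nfv.modality == "written"].subject_id)
        spoken = set(nfv[nfv.modality == "spoken"].subject_id)
        assert written == spoken and len(written) == 26

    def test_single_profile_n1(self, picnic):
        transcripts, truth = generate_cohort([profile(n=1)], picnic, seed=3)
        assert len(transcripts) == 1 and len(truth) == 1

    def test_two_seeds_differ_with_same_schema(self, picnic):
        p = [profile(n=4)]
        a, _ = generate_cohort(p, picnic, seed=1)
        b, _ = generate_cohort(p, picnic, seed=2)
        assert list(a.columns) == list(b.columns)
        assert list(a.sample_id) == list(b.sample_id)
        assert any(x != y for x, y in zip(a.text, b.text))

    def test_duplicate_profile_rejected(self, picnic):
        with pytest.raises(GenerationError, match="duplicate"):
            generate_cohort([profile(), profile()], picnic, seed=0)

    def test_empty_profiles_rejected(self, picnic):
        with pytest.raises(GenerationError, match="no profiles"):
            generate_cohort([], picnic, seed=0)


class TestProfiles:
    def test_unknown_preset_rejected(self):
        with pytest.raises(GenerationError, match="unknown profile preset"):
            load_profiles("nope")

    def test_invalid_rates_rejected(self):
        with pytest.raises(GenerationError, match="ratio_mean"):
            profile(ratio_mean=0.0)
        with pytest.raises(GenerationError, match="repeat_rate"):
            profile(repeat_rate=1.5)

    def test_written_preset_cell_sizes(self, written_profiles):
        assert [(p.name, p.n) for p in written_profiles] == [
            ("control", 20), ("nfvPPA", 28), ("lvPPA", 30), ("svPPA", 17),
        ]
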