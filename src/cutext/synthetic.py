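"""Synthetic picture-description cohorts with exact ground truth.

Each generated sample plants its content-unit count k and its CU/U ratio
rho directly: k distinct dictionary entries are realized (optionally
inflected, optionally repeated), and the sample is padded to round(k/rho)
total units with filler function words, first-person pronouns, contractions,
false starts and unintelligible markers.  The planted ratio rather than
independent CU/unit draws is what makes cohort-level ratio recovery
well-posed.  Every injected element is chosen so the full pipeline
reproduces the recorded truth exactly (the round-trip law the oracle tests
rely on): filler vocabulary is disjoint from all dictionary variants under
lemmatization, contraction realizations avoid first-person forms, and CU
realizations are drawn from a curated inflection table the lemmatizer is
known to invert.

The packaged "paper_tables" preset instantiates group x modality profiles
from published picnic-scene cohort tables (written controls and the three
PPA variants in both modalities); the "paper_tables_written" preset holds
the written-only cohorts at their full sample sizes.  Generated text is a
bag of tokens, not grammatical English — see the methods note for what this
does and does not exercise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import lexicon
from .dictionary import CUDictionary, CUEntry

MAX_UNITS = 10_000

#: filler vocabulary: function words plus non-scene content words, all of
#: which normalize outside every packaged-dictionary (lemma, pos) variant
FILLER_WORDS = (
    "the a an and then also so there here it he she they them with on in at "
    "of to from over under near about around through very really quite just "
    "some many all both was were is are be been being had have has will "
    "would could should can that this these those other another again still "
    "now well went came come see saw look looking think thought say said "
    "get got put going goes gone one two three next while because "
).split()

#: first-person pronoun surfaces counted as self-referential
PRONOUN_SURFACES = ("I", "we", "us")

#: contraction realizations free of first-person parts and dictionary lemmas
CONTRACTION_SURFACES = (
    "they're", "it's", "there's", "that's", "he's", "she's", "don't",
    "doesn't", "didn't", "isn't", "wasn't", "can't", "won't", "they've",
    "they'll",
)

FALSE_START_SURFACES = ("pi-", "wa-", "ba-", "sa-", "fl-", "do-")

UNINTELLIGIBLE_SURFACE = "xxx"

#: (lemma, pos_class) -> inflected surfaces the normalizer maps back exactly
INFLECTIONS: dict[tuple[str, str], tuple[str, ...]] = {
    ("man", "noun"): ("men",),
    ("woman", "noun"): ("women",),
    ("boy", "noun"): ("boys",),
    ("dog", "noun"): ("dogs",),
    ("puppy", "noun"): ("puppies",),
    ("kite", "noun"): ("kites",),
    ("boat", "noun"): ("boats",),
    ("tree", "noun"): ("trees",),
    ("window", "noun"): ("windows",),
    ("branch", "noun"): ("branches",),
    ("child", "noun"): ("children",),
    ("kid", "noun"): ("kids",),
    ("lady", "noun"): ("ladies",),
    ("glass", "noun"): ("glasses",),
    ("cup", "noun"): ("cups",),
    ("shoe", "noun"): ("shoes",),
    ("daughter", "noun"): ("daughters",),
    ("person", "noun"): ("persons",),
    ("basket", "noun"): ("baskets",),
    ("book", "noun"): ("books",),
    ("flag", "noun"): ("flags",),
    ("song", "noun"): ("songs",),
    ("run", "verb"): ("running", "runs", "ran"),
    ("race", "verb"): ("racing", "races", "raced"),
    ("fly", "verb"): ("flying", "flies", "flew"),
    ("pour", "verb"): ("pouring", "pours", "poured"),
    ("read", "verb"): ("reading", "reads"),
    ("fish", "verb"): ("fishing", "fishes"),
    ("sail", "verb"): ("sailing", "sails", "sailed"),
    ("float", "verb"): ("floating", "floats"),
    ("play", "verb"): ("playing", "plays", "played"),
    ("sit", "verb"): ("sitting", "sits", "sat"),
    ("dig", "verb"): ("digging", "dug"),
    ("listen", "verb"): ("listening", "listens", "listened"),
    ("wave", "verb"): ("waving", "waves", "waved"),
    ("hold", "verb"): ("holding", "holds", "held"),
    ("wear", "verb"): ("wearing", "wears", "wore"),
    ("relax", "verb"): ("relaxing", "relaxes", "relaxed"),
    ("rest", "verb"): ("resting", "rests", "rested"),
    ("stand", "verb"): ("standing", "stands", "stood"),
    ("build", "verb"): ("building", "builds", "built"),
    ("smile", "verb"): ("smiling", "smiles", "smiled"),
    ("eat", "verb"): ("eating", "eats", "ate"),
    ("small", "adjective"): ("smaller",),
    ("happy", "adjective"): ("happier",),
}


class GenerationError(ValueError):
    pass


@dataclass
class GroupProfile:
    """Generating distribution for one group x modality cell."""

    name: str
    modality: str
    n: int
    cu_mean: float
    cu_sd: float
    ratio_mean: float
    ratio_sd: float
    self_ref_rate: float = 0.0
    unambiguous_share: float = 0.8
    repeat_rate: float = 0.0
    false_start_rate: float = 0.0
    contraction_rate: float = 0.0
    unintelligible_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio_mean <= 1.0):
            raise GenerationError(f"{self.name}/{self.modality}: ratio_mean must be in (0, 1]")
        if self.modality not in ("written", "spoken"):
            raise GenerationError(f"unknown modality {self.modality!r}")
        for rate_name in (
            "unambiguous_share", "repeat_rate", "false_start_rate",
            "contraction_rate", "unintelligible_rate",
        ):
            v = getattr(self, rate_name)
            if not (0.0 <= v <= 1.0):
                raise GenerationError(f"{self.name}/{self.modality}: {rate_name}={v} outside [0,1]")
        if self.self_ref_rate < 0:
            raise GenerationError(f"{self.name}/{self.modality}: negative self_ref_rate")


@dataclass
class SyntheticSample:
    sample_id: str
    subject_id: str
    group: str
    modality: str
    raw_text: str
    truth_cu_ids: set[int] = field(default_factory=set)
    truth_unit_count: int = 0
    truth_self_ref: int = 0


def load_profiles(preset: str = "paper_tables", path: str | Path | None = None) -> list[GroupProfile]:
    """Load a named profile preset (packaged) or a profiles JSON file."""
    if path is None:
        raw = resources.files("cutext.data").joinpath(
            "paper_tables_profiles.json"
        ).read_text(encoding="utf-8")
        payload = json.loads(raw)
    else:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    presets = payload.get("presets", payload)
    if preset not in presets:
        raise GenerationError(f"unknown profile preset {preset!r}; have {sorted(presets)}")
    return [GroupProfile(**p) for p in presets[preset]]


def _truncated_round_normal(rng: np.random.Generator, mean: float, sd: float,
                            lo: int, hi: int) -> int:
    """round(Normal(mean, sd)) resampled until inside [lo, hi]."""
    if sd <= 0:
        return int(np.clip(round(mean), lo, hi))
    for _ in range(10_000):
        k = round(float(rng.normal(mean, sd)))
        if lo <= k <= hi:
            return k
    raise GenerationError(f"could not draw round-normal({mean}, {sd}) in [{lo}, {hi}]")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10_000):
        x = float(rng.normal(mean, sd))
        if lo < x <= hi:
            return x
    raise GenerationError(f"could not draw normal({mean}, {sd}) in ({lo}, {hi}]")


def _realize_entry(entry: CUEntry, rng: np.random.Generator) -> str:
    lemma, pos = sorted(entry.variants)[int(rng.integers(len(entry.variants)))]
    forms = (lemma,) + INFLECTIONS.get((lemma, pos), ())
    return forms[int(rng.integers(len(forms)))]


def generate_sample(
    profile: GroupProfile,
    dictionary: CUDictionary,
    rng: np.random.Generator,
    *,
    sample_id: str = "synthetic",
    subject_id: str = "",
) -> SyntheticSample:
    """Generate one sample with exact planted truth.

    Draws k (CU count) and rho (CU/U ratio) from the profile's truncated
    normals, realizes k distinct entries split between the unambiguous and
    ambiguous pools per ``unambiguous_share``, then pads with repeats,
    pronouns, contractions, false starts, unintelligible markers and filler
    words until the unit target round(k/rho) is met.
    """
    # Draws are resampled into a symmetric +/-2 SD band (intersected with the
    # natural range): symmetric truncation keeps the planted means unbiased,
    # and bounding rho away from 0 avoids pathological 1/rho unit targets
    # (a written description with hundreds of units) that no cohort table
    # exhibits.
    k_lo = max(0, math.ceil(profile.cu_mean - 2 * profile.cu_sd))
    k_hi = min(len(dictionary), math.floor(profile.cu_mean + 2 * profile.cu_sd))
    k = _truncated_round_normal(rng, profile.cu_mean, profile.cu_sd, k_lo, k_hi)
    r_lo = max(1e-6, profile.ratio_mean - 1.5 * profile.ratio_sd)
    r_hi = min(1.0, profile.ratio_mean + 1.5 * profile.ratio_sd)
    rho = _truncated_normal(rng, profile.ratio_mean, profile.ratio_sd, r_lo, r_hi)
    target = round(k / rho) if k > 0 else max(1, round(1.0 / rho))
    if target > MAX_UNITS:
        raise GenerationError(
            f"unit target {target} exceeds sanity cap {MAX_UNITS} (k={k}, rho={rho:.4f})"
        )

    unamb = [e for e in dictionary.entries if e.ambiguity == "unambiguous"]
    amb = [e for e in dictionary.entries if e.ambiguity == "ambiguous"]
    n_unamb = min(len(unamb), round(k * profile.unambiguous_share))
    n_amb = min(len(amb), k - n_unamb)
    n_unamb = min(len(unamb), k - n_amb)  # rebalance if a pool ran short
    chosen: list[CUEntry] = []
    if n_unamb:
        idx = rng.choice(len(unamb), size=n_unamb, replace=False)
        chosen.extend(unamb[i] for i in idx)
    if n_amb:
        idx = rng.choice(len(amb), size=n_amb, replace=False)
        chosen.extend(amb[i] for i in idx)

    surfaces: list[str] = [_realize_entry(e, rng) for e in chosen]
    units_used = len(chosen)
    # optional second mention of a credited CU (still one CU, one more unit)
    for e in chosen:
        if units_used < target and rng.random() < profile.repeat_rate:
            surfaces.append(_realize_entry(e, rng))
            units_used += 1

    self_ref = int(rng.poisson(profile.self_ref_rate))
    self_ref = min(self_ref, max(0, target - units_used))
    for _ in range(self_ref):
        surfaces.append(PRONOUN_SURFACES[int(rng.integers(len(PRONOUN_SURFACES)))])
        units_used += 1

    while units_used < target:
        remaining = target - units_used
        u = float(rng.random())
        if remaining >= 2 and u < profile.contraction_rate:
            surfaces.append(
                CONTRACTION_SURFACES[int(rng.integers(len(CONTRACTION_SURFACES)))]
            )
            units_used += 2
        elif u < profile.contraction_rate + profile.false_start_rate:
            surfaces.append(
                FALSE_START_SURFACES[int(rng.integers(len(FALSE_START_SURFACES)))]
            )
            units_used += 1
        elif u < (profile.contraction_rate + profile.false_start_rate
                  + profile.unintelligible_rate):
            surfaces.append(UNINTELLIGIBLE_SURFACE)
            units_used += 1
        else:
            surfaces.append(FILLER_WORDS[int(rng.integers(len(FILLER_WORDS)))])
            units_used += 1

    order = rng.permutation(len(surfaces))
    shuffled = [surfaces[i] for i in order]
    text = " ".join(shuffled)
    if text:
        text = text[0].upper() + text[1:] + "."
    return SyntheticSample(
        sample_id=sample_id,
        subject_id=subject_id,
        group=profile.name,
        modality=profile.modality,
        raw_text=text,
        truth_cu_ids={e.entry_id for e in chosen},
        truth_unit_count=units_used,
        truth_self_ref=self_ref,
    )


def generate_cohort(
    profiles: list[GroupProfile],
    dictionary: CUDictionary,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate all profile cells; returns (transcripts, truth) frames.

    Transcript columns: sample_id, subject_id, group, modality, text.
    Truth columns: sample_id, cu_ids (';'-joined), unit_count,
    self_ref_count.  Written and spoken cells of the same group share
    subject ids, so paired written-vs-spoken designs are directly available.
    """
    if not profiles:
        raise GenerationError("no profiles supplied")
    keys = [(p.name, p.modality) for p in profiles]
    if len(set(keys)) != len(keys):
        raise GenerationError("duplicate (name, modality) profile")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_rows, truth_rows = [], []
    for profile in profiles:
        for i in range(profile.n):
            subject = f"{profile.name}_{i + 1:03d}"
            sid = f"{subject}_{profile.modality}"
            s = generate_sample(
                profile, dictionary, rng, sample_id=sid, subject_id=subject
            )
            t_rows.append(
                {
                    "sample_id": s.sample_id,
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "modality": s.modality,
                    "text": s.raw_text,
                }
            )
            truth_rows.append(
                {
                    "sample_id": s.sample_id,
                    "cu_ids": ";".join(str(x) for x in sorted(s.truth_cu_ids)),
                    "unit_count": s.truth_unit_count,
                    "self_ref_count": s.truth_self_ref,
                }
            )
    return pd.DataFrame(t_rows), pd.DataFrame(truth_rows)


def check_filler_disjoint(dictionary: CUDictionary) -> list[str]:
    """Filler/pronoun/contraction surfaces that would collide with dictionary variants.

    Empty list means the generator's padding vocabulary can never credit a
    CU in the given dictionary (checked in the test suite for the packaged
    fixture).
    """
    variant_map = dictionary.variant_map()
    collisions = []
    padding = list(FILLER_WORDS) + [p.lower() for p in PRONOUN_SURFACES]
    for word in padding:
        if lexicon.analyze(word) in variant_map:
            collisions.append(word)
    return collisions
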