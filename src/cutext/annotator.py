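"""Lemma/POS normalization, content-unit matching and self-reference counting.

A sample credits a dictionary entry when at least one of its word tokens
normalizes to a (lemma, pos_class) pair listed among the entry's variants.
Each entry is credited at most once per sample, no matter how many times or
through how many distinct variants it is mentioned — "girl" and "daughter"
under one entry still yield a single CU.  Non-word, false-start and
unintelligible tokens count toward units but can never match.

The ambiguity label of a credited CU is copied from the entry; context is
never used to disambiguate.  Self-referential pronouns (by default exactly
I, we, us) are counted per occurrence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from . import lexicon
from .dictionary import CUDictionary, DictionaryError, validate_dictionary
from .tokenizer import Token, TokenizedSample

DEFAULT_PRONOUNS = frozenset({"i", "we", "us"})


@dataclass(frozen=True)
class AnnotatedToken:
    token: Token
    lemma: str
    pos_class: str


@dataclass
class CUAnnotation:
    """The credited content units of one sample."""

    sample_id: str
    matched_entries: set[int] = field(default_factory=set)
    match_spans: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    ambiguous_matched: set[int] = field(default_factory=set)
    unambiguous_matched: set[int] = field(default_factory=set)
    self_ref_count: int = 0


# ---------------------------------------------------------------------------
# POS override files: reproducible manual corrections (sample_id, span, pos)

def load_overrides(path: str | Path) -> dict[str, dict[tuple[int, int], str]]:
    """Read a POS-override CSV (columns sample_id, start, end, pos_class)."""
    out: dict[str, dict[tuple[int, int], str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            span = (int(row["start"]), int(row["end"]))
            out.setdefault(row["sample_id"], {})[span] = row["pos_class"]
    return out


def normalize(
    sample: TokenizedSample,
    overrides: Mapping[tuple[int, int], str] | None = None,
) -> list[AnnotatedToken]:
    """Assign each token a lowercase lemma and coarse pos_class.

    Word tokens go through the rule-based lemmatizer; non-word, false-start
    and unintelligible tokens keep their lowercased surface as lemma and are
    always pos_class "other" (they can never credit a CU).  ``overrides``
    maps character spans to a forced pos_class, the reproducible stand-in for
    manual correction of tagger errors.
    """
    annotated: list[AnnotatedToken] = []
    for tok in sample.tokens:
        if tok.kind != "word":
            annotated.append(AnnotatedToken(tok, tok.surface.lower(), "other"))
            continue
        lemma, pos = lexicon.analyze(tok.surface)
        if overrides and tok.char_span in overrides:
            pos = overrides[tok.char_span]
        annotated.append(AnnotatedToken(tok, lemma, pos))
    return annotated


def match_content_units(
    tokens: Iterable[AnnotatedToken],
    dictionary: CUDictionary,
    *,
    sample_id: str = "",
    pronoun_set: frozenset[str] = DEFAULT_PRONOUNS,
) -> CUAnnotation:
    """Credit dictionary entries against normalized tokens (once each).

    Every occurrence's span is recorded in ``match_spans`` for auditability,
    but an entry contributes exactly one CU regardless of repetitions.
    """
    tokens = list(tokens)
    violations = validate_dictionary(dictionary)
    if violations:
        raise DictionaryError("; ".join(violations))
    variant_map = dictionary.variant_map()
    ambiguity = dictionary.ambiguity_of()
    ann = CUAnnotation(sample_id=sample_id)
    for at in tokens:
        if at.token.kind != "word":
            continue
        eid = variant_map.get((at.lemma, at.pos_class))
        if eid is None:
            continue
        ann.matched_entries.add(eid)
        ann.match_spans.setdefault(eid, []).append(at.token.char_span)
    for eid in ann.matched_entries:
        if ambiguity[eid] == "ambiguous":
            ann.ambiguous_matched.add(eid)
        else:
            ann.unambiguous_matched.add(eid)
    ann.self_ref_count = count_self_referential(tokens, pronoun_set)
    return ann


def count_self_referential(
    tokens: Iterable[AnnotatedToken],
    pronoun_set: frozenset[str] = DEFAULT_PRONOUNS,
) -> int:
    """Count first-person-pronoun occurrences (surface match, per occurrence)."""
    if not pronoun_set:
        raise ValueError("pronoun_set must be non-empty")
    wanted = {p.lower() for p in pronoun_set}
    return sum(
        1
        for at in tokens
        if at.token.kind == "word" and at.token.surface.lower() in wanted
    )


def brute_force_match(
    tokens: Iterable[AnnotatedToken], dictionary: CUDictionary
) -> set[int]:
    """Quadratic reference matcher: scan every entry against every token.

    Independent of the hash-lookup path in :func:`match_content_units`; used
    as the oracle in equivalence tests.
    """
    toks = [at for at in tokens if at.token.kind == "word"]
    matched: set[int] = set()
    for entry in dictionary.entries:
        for at in toks:
            if any(
                at.lemma == lemma and at.pos_class == pos
                for lemma, pos in entry.variants
            ):
                matched.add(entry.entry_id)
                break
    return matched
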