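"""Unit tokenization of picture-description samples.

A *unit* (U) is every word, non-word or false start in a sample.  The
counting conventions implemented here:

* contractions count as two units ("they're" = 2), split via an explicit
  contraction table; possessive 's on nouns is NOT a contraction (1 unit);
* unintelligible spoken / illegible written stretches count as units but are
  never lexical (default markers: "xxx", "[unintelligible]", "[illegible]");
* false starts — phonemic fragments followed by self-correction — count as
  units; the transcript convention is a trailing hyphen ("pi-");
* filled pauses ("um", "uh", ...) are non-word units;
* punctuation never becomes a token; hyphenated compounds are one unit;
  numerals are word units.

Unit count is therefore simply the number of tokens of all four kinds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

KINDS = ("word", "nonword", "false_start", "unintelligible")

#: suffix contractions, each expanding to exactly two unit tokens
CONTRACTION_SUFFIXES = ("n't", "'re", "'ve", "'ll", "'d", "'m")

#: bases after which 's is a contraction (is/has), not a possessive
S_CONTRACTION_BASES = frozenset(
    """it that this there here he she what who where when how one let
    everybody everyone somebody someone nobody anybody anyone""".split()
)

#: filled pauses and hesitations -> kind=nonword
DEFAULT_FILLED_PAUSES = frozenset(
    "um uh er erm hm hmm mm mhm uhm huh".split()
)

DEFAULT_UNINTELLIGIBLE_MARKERS = frozenset(
    {"xxx", "[unintelligible]", "[illegible]"}
)

_BRACKET_RE = re.compile(r"\[[^\]\s]+\]")
_CHUNK_RE = re.compile(r"\S+")
_LETTERISH_RE = re.compile(r"[A-Za-z0-9À-ɏ]")
# punctuation stripped from chunk edges; apostrophes/hyphens are kept inside
_STRIP_CHARS = ".,;:!?()\"“”‘’…/\\*_<>{}~`^=+#&%$@|"


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class Token:
    surface: str
    char_span: tuple[int, int]
    kind: str = "word"
    from_contraction: bool = False


@dataclass
class Conventions:
    """Transcript markup conventions (configurable per corpus)."""

    unintelligible_markers: frozenset[str] = DEFAULT_UNINTELLIGIBLE_MARKERS
    false_start_suffix: str = "-"
    filled_pauses: frozenset[str] = DEFAULT_FILLED_PAUSES
    split_contractions: bool = True

    @classmethod
    def from_mapping(cls, cfg: dict) -> "Conventions":
        kwargs = {}
        for key, value in cfg.items():
            if key == "unintelligible_markers":
                kwargs[key] = frozenset(v.lower() for v in value)
            elif key == "filled_pauses":
                kwargs[key] = frozenset(v.lower() for v in value)
            elif key in ("false_start_suffix", "split_contractions"):
                kwargs[key] = value
            else:
                raise TokenizationError(f"unknown convention key {key!r}")
        return cls(**kwargs)


@dataclass
class TokenizedSample:
    sample_id: str
    group: str
    modality: str
    raw_text: str
    tokens: list[Token] = field(default_factory=list)


def _normalize_apostrophes(s: str) -> str:
    return s.replace("’", "'").replace("‘", "'")


def _split_contraction(chunk: str, span: tuple[int, int]) -> list[Token] | None:
    """Return the two word tokens of a contraction, or None if not one."""
    low = _normalize_apostrophes(chunk.lower())
    if low == "let's":
        base_len = 3
        suffix = "'s"
    else:
        suffix = None
        for suf in CONTRACTION_SUFFIXES:
            if low.endswith(suf) and len(low) > len(suf):
                suffix = suf
                break
        if suffix is None and low.endswith("'s") and len(low) > 2:
            if low[:-2] in S_CONTRACTION_BASES:
                suffix = "'s"
        if suffix is None:
            return None
        base_len = len(low) - len(suffix)
    base = chunk[:base_len]
    tail = chunk[base_len:]
    if not _LETTERISH_RE.search(base):
        return None
    return [
        Token(base, span, "word", from_contraction=True),
        Token(tail, span, "word", from_contraction=True),
    ]


def _classify_chunk(
    chunk: str, start: int, end: int, conv: Conventions
) -> list[Token]:
    low = _normalize_apostrophes(chunk.lower())
    span = (start, end)
    if low in conv.unintelligible_markers:
        return [Token(chunk, span, "unintelligible")]
    # trailing-hyphen fragment = false start ("pi-")
    if (
        conv.false_start_suffix
        and low.endswith(conv.false_start_suffix)
        and _LETTERISH_RE.search(low[: -len(conv.false_start_suffix)] or "")
    ):
        return [Token(chunk, span, "false_start")]
    if low in conv.filled_pauses:
        return [Token(chunk, span, "nonword")]
    if conv.split_contractions:
        split = _split_contraction(chunk, span)
        if split is not None:
            return split
    return [Token(chunk, span, "word")]


def tokenize(
    text: str,
    conventions: Conventions | None = None,
    *,
    sample_id: str = "",
    group: str = "",
    modality: str = "",
) -> TokenizedSample:
    """Tokenize raw sample text into unit-countable tokens.

    Deterministic: identical input and conventions yield the identical token
    list.  Punctuation-only chunks are dropped; every surviving token counts
    as one unit except that a contraction chunk yields two tokens sharing the
    original character span.
    """
    if isinstance(text, bytes):  # defensive: callers should pass str
        try:
            text = text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise TokenizationError(f"input is not valid UTF-8: {exc}") from None
    conv = conventions or Conventions()
    tokens: list[Token] = []
    for m in _CHUNK_RE.finditer(text):
        chunk = m.group(0)
        start = m.start()
        low = _normalize_apostrophes(chunk.lower())
        # exact marker match first, so punctuation-only markers survive stripping
        if low in conv.unintelligible_markers:
            tokens.append(Token(chunk, (start, m.end()), "unintelligible"))
            continue
        if low.strip(_STRIP_CHARS.replace("[", "").replace("]", "")) in conv.unintelligible_markers:
            stripped = chunk.strip(_STRIP_CHARS.replace("[", "").replace("]", ""))
            offset = chunk.index(stripped)
            tokens.append(
                Token(stripped, (start + offset, start + offset + len(stripped)), "unintelligible")
            )
            continue
        # strip edge punctuation but keep a trailing false-start hyphen
        lstripped = chunk.lstrip(_STRIP_CHARS + "[]'-")
        core = lstripped.rstrip(_STRIP_CHARS + "[]")
        # do not let apostrophe-final strip eat "'-": trailing hyphen survives above
        core = core.rstrip("'")
        if not core or not _LETTERISH_RE.search(core):
            continue
        s = start + (len(chunk) - len(lstripped))
        tokens.extend(_classify_chunk(core, s, s + len(core), conv))
    return TokenizedSample(
        sample_id=sample_id,
        group=group,
        modality=modality,
        raw_text=text,
        tokens=tokens,
    )


def count_units(sample: TokenizedSample) -> int:
    """Total units: every word, non-word, false start and unintelligible token."""
    return len(sample.tokens)
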