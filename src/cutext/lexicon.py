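"""Rule-based English lemmatizer and coarse part-of-speech lexicon.

Dictionary matching is keyed on (lemma, pos_class) with five coarse POS
classes (noun, verb, adjective, adverb, other), so the normalizer only needs
inflectional lemmatization (plural -> singular, verb inflections -> base,
irregulars via exception tables) plus a lexicon-backed POS assignment.
Unknown words lemmatize to themselves with pos_class "other", which can never
credit a content unit.

All tables are closed and shipped with the package so that unit and CU
counts are exactly reproducible run to run.
"""

from __future__ import annotations

#: lemmas of the parts produced by contraction splitting
CONTRACTION_PART_LEMMAS: dict[str, str] = {
    "n't": "not",
    "'re": "be",
    "'ve": "have",
    "'ll": "will",
    "'d": "would",
    "'m": "be",
    "'s": "be",
    "ca": "can",
    "wo": "will",
    "sha": "shall",
    "ai": "be",
}

#: closed-class words -> lemma; all tagged pos_class "other"
FUNCTION_WORDS: dict[str, str] = {}
for _w in (
    "the a an and or but if because so while as with without within from into "
    "onto over under near beside behind between through during before after "
    "above below about around at in on to of for by up down out off "
    "i me my mine myself we us our ours ourselves you your yours yourself "
    "he him his himself she her hers herself it its itself they them their "
    "theirs themselves this that these those there here who whom whose what "
    "which when where why how one two three four five ten first second third "
    "next last not no yes nor than then now just very too also only even "
    "still again always often sometimes usually never maybe perhaps well "
    "some any many much few several all both each every other another same "
    "such more most less least lot okay oh let "
).split():
    FUNCTION_WORDS[_w] = _w
for _form, _lemma in {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be",
    "be": "be", "been": "be", "being": "be",
    "have": "have", "has": "have", "had": "have", "having": "have",
    "do": "do", "does": "do", "did": "do", "doing": "do", "done": "do",
    "will": "will", "would": "would", "can": "can", "could": "could",
    "shall": "shall", "should": "should", "may": "may", "might": "might",
    "must": "must",
}.items():
    FUNCTION_WORDS[_form] = _lemma

IRREGULAR_NOUNS: dict[str, str] = {
    "men": "man", "women": "woman", "children": "child", "people": "people",
    "feet": "foot", "teeth": "tooth", "mice": "mouse", "geese": "goose",
    "wives": "wife", "knives": "knife", "leaves": "leaf", "lives": "life",
    "shelves": "shelf",
}

IRREGULAR_VERBS: dict[str, str] = {
    "ran": "run", "ate": "eat", "eaten": "eat", "sat": "sit",
    "stood": "stand", "held": "hold", "wore": "wear", "worn": "wear",
    "flew": "fly", "flown": "fly", "built": "build", "dug": "dig",
    "saw": "see", "seen": "see", "went": "go", "gone": "go",
    "came": "come", "got": "get", "gotten": "get", "took": "take",
    "taken": "take", "made": "make", "said": "say", "thought": "think",
    "threw": "throw", "thrown": "throw", "drank": "drink", "drunk": "drink",
    "gave": "give", "given": "give", "lay": "lie", "lain": "lie",
    "blew": "blow", "blown": "blow",
}

#: open-class lemma -> coarse pos_class
CONTENT_LEXICON: dict[str, str] = {}
for _n in (
    "man husband father dad woman wife mother mom lady boy son dog puppy "
    "kite sailboat boat lake pond tree house home flag blanket girl daughter "
    "basket hamper picnic book radio pail bucket shovel spade sand pier dock "
    "wharf fisherman pole rod drink beverage lemonade cup glass shoe sneaker "
    "couple family people person child kid water garage door window branch "
    "shore beach bank grass lawn sky music song string wind breeze sunshine "
    "day park picture scene table food castle sandcastle foot tooth mouse "
    "goose knife leaf life shelf thing time place area side ground air sun "
    "cloud summer afternoon"
).split():
    CONTENT_LEXICON[_n] = "noun"
for _v in (
    "fly run race pour read fish sail float play sit dig listen wave hold "
    "wear relax rest stand build smile eat see look go come get take make "
    "say think throw give lie blow enjoy watch walk point carry put want "
    "like seem appear describe happen"
).split():
    CONTENT_LEXICON[_v] = "verb"
for _a in (
    "red barefoot sunny windy breezy little small young happy cheerful big "
    "old nice beautiful tall green blue warm calm busy quiet full empty "
    "pleasant lovely bright"
).split():
    CONTENT_LEXICON[_a] = "adjective"
for _r in "outside together nearby away here-and-there".split():
    CONTENT_LEXICON[_r] = "adverb"

_VOWELS = set("aeiou")


def _in_lexicon(stem: str) -> bool:
    return stem in CONTENT_LEXICON


def _try_stems(stems: list[str]) -> str | None:
    for s in stems:
        if s and _in_lexicon(s):
            return s
    return None


def _deinflect(word: str) -> str | None:
    """Lexicon-validated suffix stripping; None if no rule applies."""
    candidates: list[str] = []
    if word.endswith("ies") and len(word) > 4:
        candidates.append(word[:-3] + "y")
    if word.endswith("sses"):
        candidates.append(word[:-2])
    if word.endswith("es") and len(word) > 3:
        candidates.append(word[:-2])
        candidates.append(word[:-1])  # e.g. "houses" -> "house"
    if word.endswith("s") and not word.endswith("ss") and len(word) > 2:
        candidates.append(word[:-1])
    if word.endswith("ing") and len(word) > 4:
        stem = word[:-3]
        candidates.extend([stem, stem + "e"])
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            candidates.append(stem[:-1])
    if word.endswith("ed") and len(word) > 3:
        stem = word[:-2]
        candidates.extend([stem, word[:-1]])  # "poured" -> "pour", "raced" -> "race"
        if word.endswith("ied"):
            candidates.append(word[:-3] + "y")
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            candidates.append(stem[:-1])
    if word.endswith("iest") and len(word) > 5:
        candidates.append(word[:-4] + "y")
    if word.endswith("ier") and len(word) > 4:
        candidates.append(word[:-3] + "y")
    if word.endswith(("er", "est")):
        stem = word[:-2] if word.endswith("er") else word[:-3]
        candidates.extend([stem, stem + "e"])
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            candidates.append(stem[:-1])
    return _try_stems(candidates)


def analyze(surface: str) -> tuple[str, str]:
    """Map a lowercase word surface to (lemma, pos_class).

    Resolution order: possessive stripping, contraction-part table, closed
    function-word table, irregular inflection tables, direct lexicon lookup,
    lexicon-validated suffix rules, then the unknown-word fallback
    (identity lemma, pos_class "other"; "-ly" surfaces fall back as adverbs).
    """
    w = surface.lower().replace("’", "'")
    if w in CONTRACTION_PART_LEMMAS:
        return CONTRACTION_PART_LEMMAS[w], "other"
    # possessives: "dog's" -> dog, "dogs'" -> dogs (then plural rule)
    if w.endswith("'s"):
        w = w[:-2]
    elif w.endswith("'"):
        w = w[:-1]
    if not w:
        return surface.lower(), "other"
    if w in FUNCTION_WORDS:
        return FUNCTION_WORDS[w], "other"
    if w in IRREGULAR_NOUNS:
        return IRREGULAR_NOUNS[w], "noun"
    if w in IRREGULAR_VERBS:
        return IRREGULAR_VERBS[w], "verb"
    if w in CONTENT_LEXICON:
        return w, CONTENT_LEXICON[w]
    stem = _deinflect(w)
    if stem is not None:
        return stem, CONTENT_LEXICON[stem]
    if w.endswith("ly") and len(w) > 3:
        return w, "adverb"
    return w, "other"
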