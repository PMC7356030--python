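"""Porter's suffix-stripping stemmer (the classic 1980 algorithm).

Reduces English words to a common root so that inflectional variants
("foraging"/"forage" -> "forag", "colony"/"colonies" -> "coloni") collapse
to one keyword.  The implementation follows the original five-step rule
table; words shorter than three letters are returned unchanged, as in the
original description.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        # 'y' is a consonant at the start or after a vowel-acting letter
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions, Porter's m in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


# (suffix, replacement) tables for steps 2-4; the longest matching suffix
# is the only one considered, per the original algorithm.
_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _longest_rule(word: str, rules) -> tuple[str, str] | None:
    best = None
    for suffix, repl in rules:
        if word.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
            best = (suffix, repl)
    return best


def stem(word: str) -> str:
    """Stem a single lowercase-insensitive word; returns lowercase."""
    word = word.lower()
    if len(word) <= 2:
        return word

    # Step 1a: plurals
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith("ies"):
        word = word[:-2]
    elif word.endswith("ss"):
        pass
    elif word.endswith("s"):
        word = word[:-1]

    # Step 1b: -ed and -ing
    cleanup = False
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            word = word[:-1]
    elif word.endswith("ed"):
        if _contains_vowel(word[:-2]):
            word = word[:-2]
            cleanup = True
    elif word.endswith("ing"):
        if _contains_vowel(word[:-3]):
            word = word[:-3]
            cleanup = True
    if cleanup:
        if word.endswith(("at", "bl", "iz")):
            word += "e"
        elif _ends_double_consonant(word) and word[-1] not in "lsz":
            word = word[:-1]
        elif _measure(word) == 1 and _ends_cvc(word):
            word += "e"

    # Step 1c: y -> i
    if word.endswith("y") and _contains_vowel(word[:-1]):
        word = word[:-1] + "i"

    # Step 2
    rule = _longest_rule(word, _STEP2)
    if rule is not None:
        suffix, repl = rule
        if _measure(word[: -len(suffix)]) > 0:
            word = word[: -len(suffix)] + repl

    # Step 3
    rule = _longest_rule(word, _STEP3)
    if rule is not None:
        suffix, repl = rule
        if _measure(word[: -len(suffix)]) > 0:
            word = word[: -len(suffix)] + repl

    # Step 4
    rule = _longest_rule(word, [(s, "") for s in _STEP4])
    if rule is not None:
        suffix, _ = rule
        stem_part = word[: -len(suffix)]
        if _measure(stem_part) > 1:
            if suffix == "ion":
                if stem_part.endswith(("s", "t")):
                    word = stem_part
            else:
                word = stem_part

    # Step 5a: final -e
    if word.endswith("e"):
        stem_part = word[:-1]
        m = _measure(stem_part)
        if m > 1 or (m == 1 and not _ends_cvc(stem_part)):
            word = stem_part

    # Step 5b: -ll -> -l
    if _measure(word) > 1 and _ends_double_consonant(word) and word.endswith("l"):
        word = word[:-1]

    return word
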