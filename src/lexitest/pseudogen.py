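"""Pronounceable pseudoword generation from a subsyllabic transition chain.

Real words from a lexicon are segmented into (onset, nucleus, coda)
triples per syllable; transition counts between consecutive non-empty
elements form a first-order chain. A pseudoword is produced for a template
word by a seeded random walk over the chain constrained to the template's
syllable/element pattern, rejecting real words and the template itself.
The result is a nonword that looks and sounds plausible — the foil items
of a Yes-No vocabulary test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SubsyllabicSegmentation",
    "SegmentChain",
    "SegmentationError",
    "GenerationError",
    "segment_word",
    "build_chain",
    "generate_pseudoword",
]

_VOWELS = set("aeiou")

# element roles, in within-syllable order
ONSET, NUCLEUS, CODA = "onset", "nucleus", "coda"


class SegmentationError(ValueError):
    """Raised when a word cannot be split into syllables."""


class GenerationError(RuntimeError):
    """Raised when no acceptable pseudoword is found within the attempt cap."""


@dataclass(frozen=True)
class SubsyllabicSegmentation:
    """Ordered (onset, nucleus, coda) triples whose concatenation is the word."""

    syllables: tuple[tuple[str, str, str], ...]

    @property
    def word(self) -> str:
        return "".join("".join(syl) for syl in self.syllables)

    def slots(self) -> list[tuple[str, str]]:
        """Non-empty elements as (role, element), in left-to-right order."""
        out = []
        for onset, nucleus, coda in self.syllables:
            if onset:
                out.append((ONSET, onset))
            out.append((NUCLEUS, nucleus))
            if coda:
                out.append((CODA, coda))
        return out

    def pattern(self) -> tuple[tuple[bool, bool], ...]:
        """Per-syllable (onset present, coda present) structure."""
        return tuple((bool(o), bool(c)) for o, _, c in self.syllables)


@dataclass
class SegmentChain:
    """First-order transition counts between consecutive subsyllabic elements."""

    transitions: dict[str, dict[str, int]] = field(default_factory=dict)
    elements_by_role: dict[str, list[str]] = field(default_factory=dict)
    skipped: int = 0  # unsegmentable lexicon words

    def add(self, prev: str, nxt: str) -> None:
        self.transitions.setdefault(prev, {})[nxt] = (
            self.transitions.get(prev, {}).get(nxt, 0) + 1
        )

    def successors(self, element: str) -> dict[str, int]:
        return self.transitions.get(element, {})

    def total_transitions(self) -> int:
        return sum(sum(d.values()) for d in self.transitions.values())

    def __bool__(self) -> bool:
        return bool(self.transitions)


def _vowel_set(word: str) -> set[str]:
    # y acts as a vowel only in words with no other vowel letter ("rhythm")
    if _VOWELS.intersection(word):
        return _VOWELS
    return _VOWELS | {"y"}


def segment_word(word: str) -> SubsyllabicSegmentation:
    """Deterministic syllabification into (onset, nucleus, coda) triples.

    Maximal runs of vowel letters form the nuclei. Consonants before the
    first nucleus are the first onset; consonants after the last nucleus
    the final coda. Medial consonant clusters attach entirely to the
    following syllable's onset (maximal-onset convention).
    """
    if not word or not word.isalpha():
        raise SegmentationError(f"not a nonempty alphabetic string: {word!r}")
    word = word.lower()
    vowels = _vowel_set(word)

    # runs of (is_vowel, substring)
    runs: list[tuple[bool, str]] = []
    for ch in word:
        isv = ch in vowels
        if runs and runs[-1][0] == isv:
            runs[-1] = (isv, runs[-1][1] + ch)
        else:
            runs.append((isv, ch))

    nuclei_idx = [i for i, (isv, _) in enumerate(runs) if isv]
    if not nuclei_idx:
        raise SegmentationError(f"no vowel letters in {word!r}")

    # runs strictly alternate vowel/consonant, so the run preceding a
    # nucleus (when any) is a consonant cluster; maximal onset assigns it
    # wholly to that syllable. Only the final syllable can take a coda.
    syllables: list[tuple[str, str, str]] = []
    for k, i in enumerate(nuclei_idx):
        onset = runs[i - 1][1] if i > 0 else ""
        nucleus = runs[i][1]
        is_last = k == len(nuclei_idx) - 1
        coda = runs[i + 1][1] if is_last and i + 1 < len(runs) else ""
        syllables.append((onset, nucleus, coda))
    return SubsyllabicSegmentation(syllables=tuple(syllables))


def build_chain(lexicon: Iterable[str]) -> SegmentChain:
    """Accumulate element transition counts over a lexicon.

    Words that cannot be segmented (non-alphabetic, vowel-less) are counted
    in ``chain.skipped`` and otherwise ignored.
    """
    chain = SegmentChain()
    roles: dict[str, set[str]] = {ONSET: set(), NUCLEUS: set(), CODA: set()}
    n_ok = 0
    for word in lexicon:
        try:
            seg = segment_word(word)
        except SegmentationError:
            chain.skipped += 1
            continue
        n_ok += 1
        slots = seg.slots()
        for role, el in slots:
            roles[role].add(el)
        for (_, prev), (_, nxt) in zip(slots, slots[1:]):
            chain.add(prev, nxt)
    if n_ok == 0:
        raise SegmentationError("no segmentable words in lexicon")
    chain.elements_by_role = {r: sorted(els) for r, els in roles.items()}
    return chain


def generate_pseudoword(
    template: str,
    chain: SegmentChain,
    lexicon: set[str] | frozenset[str],
    rng_seed: int,
    max_attempts: int = 1000,
) -> str:
    """Generate a nonword matching the template's subsyllabic structure.

    A seeded random walk fills the template's non-empty element slots with
    elements of the same role drawn from the chain, requiring every
    consecutive pair to be an observed transition. Candidates equal to the
    template or present in the lexicon are rejected. Deterministic for a
    given (template, chain, seed).

    Raises
    ------
    GenerationError
        If no acceptable candidate is found within ``max_attempts``.
    """
    if not chain:
        raise GenerationError("empty transition chain")
    seg = segment_word(template)
    slots = seg.slots()
    roles = [role for role, _ in slots]
    rng = random.Random(rng_seed)
    template = template.lower()
    lexicon_lc = lexicon if isinstance(lexicon, (set, frozenset)) else set(lexicon)

    role_lists = {r: sorted(els) for r, els in chain.elements_by_role.items()}
    role_sets = {r: set(els) for r, els in role_lists.items()}
    for _ in range(max_attempts):
        candidate_elements: list[str] = []
        ok = True
        for i, role in enumerate(roles):
            if i == 0:
                pool = role_lists.get(role, [])
            else:
                prev = candidate_elements[-1]
                members = role_sets.get(role, set())
                pool = sorted(e for e in chain.successors(prev) if e in members)
            if not pool:
                ok = False
                break
            candidate_elements.append(rng.choice(pool))
        if not ok:
            continue
        candidate = "".join(candidate_elements)
        if candidate == template or candidate in lexicon_lc:
            continue
        # sanity: structure must round-trip to the template's pattern
        try:
            if segment_word(candidate).pattern() != seg.pattern():
                continue
        except SegmentationError:
            continue
        return candidate
    raise GenerationError(
        f"no pseudoword found for template {template!r} in {max_attempts} attempts"
    )
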