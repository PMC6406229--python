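"""Word-frequency vocabulary ingestion, item weighting, and frequency tiers.

A vocabulary is a list of :class:`VocabularyEntry` built from a plain
tab-separated frequency table (one ``word<TAB>count`` record per line).
An optional reference lexicon (one word per line) restricts the vocabulary
to recognised words, standing in for a dictionary filter applied to a
noisy corpus-derived word list.

Item weights are a logistic transform of standardised log counts: frequent
words, which nearly every fluent reader should recognise, carry weight
close to 1; rare words, uninformative about everyday reading ability,
carry weight close to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VocabularyEntry",
    "TierPartition",
    "VocabularyError",
    "VocabularyParseError",
    "load_vocabulary",
    "read_lexicon",
    "compute_item_weights",
    "partition_tiers",
]


class VocabularyError(ValueError):
    """Raised for invalid vocabulary contents or arguments."""


class VocabularyParseError(VocabularyError):
    """Raised when a frequency-table line cannot be parsed."""

    def __init__(self, path: str | Path, lineno: int, line: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: malformed frequency record: {line!r}")


@dataclass
class VocabularyEntry:
    """A word with its corpus frequency and derived item weight.

    ``rel_freq`` is the fraction of retained-corpus tokens this word
    accounts for; ``log_z`` the z-score of its natural-log count over the
    whole filtered vocabulary; ``weight`` the logistic item weight in
    (0, 1) before instrument-level normalisation.
    """

    word: str
    count: int
    rel_freq: float = 0.0
    log_z: float = float("nan")
    weight: float = float("nan")

    def __post_init__(self) -> None:
        if self.count < 0:
            raise VocabularyError(f"negative count for {self.word!r}")


@dataclass
class TierPartition:
    """Equal-size frequency bands of a vocabulary, tier 1 = most frequent."""

    n_tiers: int
    tiers: list[list[VocabularyEntry]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.tiers)

    def __len__(self) -> int:
        return self.n_tiers

    def tier_words(self, tier: int) -> list[str]:
        """Words in ``tier`` (1-based)."""
        return [e.word for e in self.tiers[tier - 1]]


def read_lexicon(path: str | Path) -> set[str]:
    """Read a one-word-per-line reference lexicon, lowercased."""
    words: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            w = line.strip().lower()
            if w and not w.startswith("#"):
                words.add(w)
    return words


def load_vocabulary(
    path: str | Path,
    lexicon: str | Path | set[str] | None = None,
) -> list[VocabularyEntry]:
    """Load a frequency table, filter against a lexicon, merge duplicates.

    Parameters
    ----------
    path
        Frequency table: UTF-8 text, one record per line, word and
        nonnegative integer count separated by whitespace (canonically a
        tab). Lines starting with ``#`` and blank lines are skipped.
    lexicon
        Optional reference word list (path or a pre-loaded set). Words not
        in the lexicon are dropped after case folding.

    Returns
    -------
    list of VocabularyEntry
        Sorted by descending count (ties broken alphabetically), with
        ``rel_freq`` computed over the retained entries.
    """
    if lexicon is not None and not isinstance(lexicon, set):
        lexicon = read_lexicon(lexicon)

    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise VocabularyParseError(path, lineno, line.rstrip("\n"))
            word = parts[0].lower()
            try:
                count = int(parts[1])
            except ValueError:
                raise VocabularyParseError(path, lineno, line.rstrip("\n")) from None
            if count < 0:
                raise VocabularyParseError(path, lineno, line.rstrip("\n"))
            if lexicon is not None and word not in lexicon:
                continue
            counts[word] = counts.get(word, 0) + count

    if not counts:
        raise VocabularyError(f"no vocabulary entries remain after filtering {path}")

    total = sum(counts.values())
    entries = [
        VocabularyEntry(word=w, count=c, rel_freq=c / total if total else 0.0)
        for w, c in counts.items()
    ]
    entries.sort(key=lambda e: (-e.count, e.word))
    return entries


def compute_item_weights(
    entries: Sequence[VocabularyEntry],
    slope: float = 1.0,
    center: float = 0.0,
) -> list[VocabularyEntry]:
    """Set logistic item weights from standardised log counts.

    ``log_z`` is the z-score of ``ln(count)`` over the full vocabulary and
    ``weight = 1 / (1 + exp(-slope * (log_z - center)))``. Standardising
    over the whole filtered vocabulary (rather than any sampled subset)
    keeps weights stable across instrument instantiations drawn from the
    same corpus. Entries are modified in place and returned.
    """
    if slope <= 0:
        raise VocabularyError("slope must be positive")
    if len(entries) < 2:
        raise VocabularyError("cannot standardise a vocabulary of size < 2")
    for e in entries:
        if e.count == 0:
            raise VocabularyError(f"zero count for {e.word!r}: log transform undefined")

    logs = np.log([e.count for e in entries])
    mu = logs.mean()
    sd = logs.std()  # population SD; any consistent convention works post-logistic
    if sd == 0:
        sd = 1.0  # all counts equal: every word gets the midpoint weight
    for e, lz in zip(entries, (logs - mu) / sd):
        e.log_z = float(lz)
        e.weight = 1.0 / (1.0 + math.exp(-slope * (lz - center)))
    return list(entries)


def partition_tiers(
    entries: Sequence[VocabularyEntry], n_tiers: int = 10
) -> TierPartition:
    """Split the vocabulary into ``n_tiers`` equal-size frequency bands.

    Entries are sorted by count descending (alphabetical tie-break) and cut
    into contiguous blocks whose sizes differ by at most one; earlier
    (higher-frequency) tiers receive the extra word when the size is not
    divisible.
    """
    if n_tiers < 1:
        raise VocabularyError("n_tiers must be >= 1")
    if len(entries) < n_tiers:
        raise VocabularyError(
            f"vocabulary of {len(entries)} words cannot fill {n_tiers} tiers"
        )
    ordered = sorted(entries, key=lambda e: (-e.count, e.word))
    base, extra = divmod(len(ordered), n_tiers)
    tiers: list[list[VocabularyEntry]] = []
    start = 0
    for t in range(n_tiers):
        size = base + (1 if t < extra else 0)
        tiers.append(ordered[start : start + size])
        start += size
    return TierPartition(n_tiers=n_tiers, tiers=tiers)
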