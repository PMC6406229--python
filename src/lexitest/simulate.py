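"""Synthetic vocabularies and simulated respondents.

The vocabulary generator emits a heavy-tailed (Zipf-like) frequency table
over unique pronounceable consonant-vowel strings, standing in for a
corpus-derived word list so the full pipeline runs without external data.

Respondents are simulated under a graded-response model: a latent ability
theta (standard normal across the population) is compared against each
true word's difficulty — the standardised negative log frequency, so rare
words are hard — through a logistic item response, and ordered thresholds
map the latent familiarity onto the 4-level Likert scale. Pseudowords
follow a false-alarm model in which the probability of claiming to know
a nonword decreases with ability. This is the minimal generative model
producing the ordinal data the scale defines; its parameters are
simulation fixtures, not claims about human respondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .instrument import (
    DesignConfig,
    Instrument,
    ResponseSheet,
    build_instrument,
    make_parallel_forms,
)
from .pseudogen import SegmentChain, build_chain
from .scoring import DisagreementWeights, score_batch
from .vocabulary import (
    TierPartition,
    VocabularyEntry,
    compute_item_weights,
    load_vocabulary,
    partition_tiers,
)

__all__ = [
    "SyntheticVocabularyConfig",
    "RespondentModel",
    "generate_vocabulary",
    "prepare_corpus",
    "simulate_responses",
    "parallel_form_experiment",
    "criterion_validity_experiment",
    "ceiling_report",
    "fisher_ci",
]

_ONSETS = list("bcdfghjklmnprstvwz") + ["bl", "br", "ch", "cl", "cr", "dr",
                                        "fl", "fr", "gl", "gr", "pl", "pr",
                                        "sh", "sk", "sl", "sm", "sn", "sp",
                                        "st", "sw", "th", "tr"]
_NUCLEI = list("aeiou") + ["ai", "ea", "ee", "oa", "oo", "ou"]
_CODAS = ["", "b", "d", "g", "k", "l", "m", "n", "p", "r", "s", "t",
          "ck", "ld", "nd", "ng", "nk", "nt", "rd", "rn", "st"]


@dataclass(frozen=True)
class SyntheticVocabularyConfig:
    """Parameters of the synthetic Zipf vocabulary."""

    n_words: int = 1000
    zipf_exponent: float = 1.0
    seed: int = 0
    min_count: int = 1
    top_count: int = 10_000_000  # count assigned to rank 1 before rounding

    def __post_init__(self) -> None:
        if self.n_words < 100:
            raise ValueError("n_words must be >= 100 for meaningful tiers")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass(frozen=True)
class RespondentModel:
    """Graded-response simulator parameters.

    ``a`` is the discrimination (slope) shared by all items; ``thresholds``
    the strictly increasing cuts mapping latent familiarity to Likert
    categories 1..4; ``pseudo_base`` the false-alarm ceiling for
    pseudowords and ``pseudo_slope`` how quickly false alarms vanish with
    ability.
    """

    a: float = 1.5
    thresholds: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    pseudo_base: float = 0.3
    pseudo_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("discrimination a must be positive")
        if not all(x < y for x, y in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not 0.0 <= self.pseudo_base <= 1.0:
            raise ValueError("pseudo_base must lie in [0, 1]")


def _make_surfaces(n: int, rng: np.random.Generator) -> list[str]:
    """n unique pronounceable strings of 1-3 consonant-vowel syllables."""
    surfaces: list[str] = []
    seen: set[str] = set()
    while len(surfaces) < n:
        n_syl = int(rng.integers(1, 4))
        parts = []
        for s in range(n_syl):
            onset = _ONSETS[rng.integers(len(_ONSETS))]
            nucleus = _NUCLEI[rng.integers(len(_NUCLEI))]
            coda = _CODAS[rng.integers(len(_CODAS))] if s == n_syl - 1 else ""
            parts.append(onset + nucleus + coda)
        w = "".join(parts)
        if w not in seen:
            seen.add(w)
            surfaces.append(w)
    return surfaces


def generate_vocabulary(
    config: SyntheticVocabularyConfig, path: str | Path | None = None
) -> list[VocabularyEntry]:
    """Generate a Zipf frequency table; optionally write it as TSV.

    Counts follow ``top_count * rank**(-zipf_exponent)``, rounded and
    floored at ``min_count``; surfaces are unique pronounceable strings.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    surfaces = _make_surfaces(config.n_words, rng)
    ranks = np.arange(1, config.n_words + 1, dtype=float)
    counts = np.maximum(
        np.rint(config.top_count * ranks ** (-config.zipf_exponent)).astype(np.int64),
        config.min_count,
    )
    total = int(counts.sum())
    entries = [
        VocabularyEntry(word=w, count=int(c), rel_freq=int(c) / total)
        for w, c in zip(surfaces, counts)
    ]
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# synthetic Zipf vocabulary\n")
            for e in entries:
                fh.write(f"{e.word}\t{e.count}\n")
    return entries


def prepare_corpus(
    vocab: str | Path | Sequence[VocabularyEntry],
    lexicon: str | Path | set[str] | None = None,
    n_tiers: int = 10,
    slope: float = 1.0,
    center: float = 0.0,
) -> tuple[list[VocabularyEntry], TierPartition, SegmentChain, set[str]]:
    """Load/weight/tier a vocabulary and build the pseudoword chain.

    ``vocab`` may be a frequency-table path or in-memory entries. The
    transition chain and the nonword-check lexicon are built from the
    vocabulary's own words (plus the reference lexicon when given).
    """
    if isinstance(vocab, (str, Path)):
        entries = load_vocabulary(vocab, lexicon=lexicon)
    else:
        entries = list(vocab)
    compute_item_weights(entries, slope=slope, center=center)
    partition = partition_tiers(entries, n_tiers=n_tiers)
    words = {e.word for e in entries}
    chain = build_chain(sorted(words))
    return entries, partition, chain, words


def simulate_responses(
    instrument: Instrument,
    thetas: Sequence[float],
    model: RespondentModel = RespondentModel(),
    seed: int = 0,
) -> list[ResponseSheet]:
    """Simulate one response sheet per ability value.

    True-word item n: latent ``x = a * (theta - b_n) + e`` with standard
    logistic noise ``e`` and difficulty ``b_n`` the item's standardised
    negative log frequency; the category is 1 plus the number of
    thresholds below x. Pseudoword: category >= 3 (a false alarm, split
    evenly between 3 and 4) with probability
    ``pseudo_base * (1 - expit(pseudo_slope * theta))``, else category 1.
    Respondent ids are ``r0001`` ... in theta order; deterministic under
    ``seed``.
    """
    thetas = np.asarray(list(thetas), dtype=float)
    if thetas.size == 0:
        raise ValueError("ability list is empty")
    rng = np.random.default_rng(seed)
    taus = np.asarray(model.thresholds)
    b = np.array([-it.log_z for it in instrument.items])
    is_pseudo = np.array([it.is_pseudoword for it in instrument.items])
    ids = instrument.item_ids

    width = max(4, len(str(thetas.size)))
    sheets = []
    for r, theta in enumerate(thetas, start=1):
        noise = rng.logistic(size=len(ids))
        x = model.a * (theta - b) + noise
        cats = 1 + (x[:, None] > taus[None, :]).sum(axis=1)

        p_fa = model.pseudo_base * (1.0 - expit(model.pseudo_slope * theta))
        fa = rng.random(size=len(ids)) < p_fa
        fa_cat = rng.integers(3, 5, size=len(ids))
        cats = np.where(is_pseudo, np.where(fa, fa_cat, 1), cats)

        sheets.append(
            ResponseSheet(
                respondent_id=f"r{r:0{width}d}",
                answers={iid: int(c) for iid, c in zip(ids, cats)},
            )
        )
    return sheets


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation."""
    if n < 4:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))


def parallel_form_experiment(
    vocab: str | Path | Sequence[VocabularyEntry],
    config: DesignConfig = DesignConfig(),
    n_respondents: int = 200,
    model: RespondentModel = RespondentModel(),
    seed: int = 0,
    v: DisagreementWeights = DisagreementWeights(),
    n_tiers: int = 10,
) -> dict:
    """Parallel-form reliability design: two disjoint forms, shared sample.

    Builds two item-disjoint instantiations from the same corpus, draws
    ``n_respondents`` abilities from N(0, 1), simulates each respondent on
    both forms, scores both against their master keys, and returns the
    per-respondent score pairs with the Pearson correlation and its
    Fisher-z 95% CI.
    """
    if n_respondents < 10:
        raise ValueError("n_respondents must be >= 10")
    _, partition, chain, words = prepare_corpus(vocab, n_tiers=n_tiers)
    ss = np.random.SeedSequence(seed)
    s_forms, s_theta, s_a, s_b = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    ]
    form_a, form_b = make_parallel_forms(partition, chain, words, config, seed=s_forms)
    thetas = np.random.default_rng(s_theta).standard_normal(n_respondents)
    sheets_a = simulate_responses(form_a, thetas, model, seed=s_a)
    sheets_b = simulate_responses(form_b, thetas, model, seed=s_b)
    scores_a = score_batch(sheets_a, form_a, v)["kappa"].to_numpy()
    scores_b = score_batch(sheets_b, form_b, v)["kappa"].to_numpy()
    r, _ = stats.pearsonr(scores_a, scores_b)
    lo, hi = fisher_ci(float(r), n_respondents)
    return {
        "theta": thetas,
        "scores_a": scores_a,
        "scores_b": scores_b,
        "pearson_r": float(r),
        "ci95": (lo, hi),
        "form_a": form_a,
        "form_b": form_b,
    }


def criterion_validity_experiment(
    vocab: str | Path | Sequence[VocabularyEntry],
    config: DesignConfig = DesignConfig(),
    n_respondents: int = 200,
    model: RespondentModel = RespondentModel(),
    criterion_noise_sd: float = 0.5,
    seed: int = 0,
    v: DisagreementWeights = DisagreementWeights(),
    n_tiers: int = 10,
) -> dict:
    """Criterion validity design: scores vs a noisy external measure.

    The external criterion is ``theta + N(0, criterion_noise_sd)`` — an
    independent instrument measuring the same latent ability with error.
    Returns kappa scores, the criterion, and their Pearson correlation.
    """
    if n_respondents < 10:
        raise ValueError("n_respondents must be >= 10")
    if criterion_noise_sd < 0:
        raise ValueError("criterion_noise_sd must be nonnegative")
    _, partition, chain, words = prepare_corpus(vocab, n_tiers=n_tiers)
    ss = np.random.SeedSequence(seed)
    s_form, s_theta, s_resp, s_crit = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    ]
    form = build_instrument(partition, chain, words, config, seed=s_form)
    thetas = np.random.default_rng(s_theta).standard_normal(n_respondents)
    sheets = simulate_responses(form, thetas, model, seed=s_resp)
    scores = score_batch(sheets, form, v)["kappa"].to_numpy()
    criterion = thetas + criterion_noise_sd * np.random.default_rng(
        s_crit
    ).standard_normal(n_respondents)
    r, _ = stats.pearsonr(scores, criterion)
    return {
        "theta": thetas,
        "scores": scores,
        "criterion": criterion,
        "pearson_r": float(r),
        "ci95": fisher_ci(float(r), n_respondents),
    }


def ceiling_report(scores: Sequence[float], max_score: float, tol: float = 1e-9) -> float:
    """Fraction of scores at the test's maximum (within ``tol``)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("empty score list")
    return float(np.mean(np.abs(arr - max_score) <= tol))
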