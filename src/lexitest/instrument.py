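"""Assembly, serialization, and keying of a complete test instantiation.

An instrument is one seeded draw from the framework: per frequency tier,
a fixed number of true words sampled uniformly and a fixed number of
pseudowords generated from distinct template words of the same tier
(templates disjoint from the selected true words). Default design:
10 tiers x 5 true words + 10 tiers x 2 pseudowords = 70 items.

Each true word carries its logistic frequency weight; each pseudoword is
assigned the arithmetic mean of the instrument's true-word weights; the
70 weights are then jointly normalised to sum to 1. The master key — the
idealised perfect respondent — answers every true word with the highest
Likert category and every pseudoword with the lowest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pseudogen import GenerationError, SegmentChain, generate_pseudoword
from .vocabulary import TierPartition, VocabularyEntry

__all__ = [
    "LIKERT_LABELS",
    "DesignConfig",
    "TestItem",
    "Instrument",
    "ResponseSheet",
    "BuildError",
    "build_instrument",
    "master_key",
    "make_parallel_forms",
    "filter_responses",
    "read_response_sheets",
    "write_response_sheets",
]

#: The 4-level Likert response scale, category -> label.
LIKERT_LABELS: dict[int, str] = {
    1: "I have never seen this word and do not know its meaning.",
    2: "I have seen this word but do not know its meaning.",
    3: "I think I know the word's meaning, but I am not sure.",
    4: "I am sure I know the word's meaning.",
}

LIKERT_MIN, LIKERT_MAX = 1, 4


class BuildError(RuntimeError):
    """Raised when an instrument cannot be assembled from the given corpus."""


@dataclass(frozen=True)
class DesignConfig:
    """Design counts of one instantiation."""

    words_per_tier: int = 5
    pseudos_per_tier: int = 2
    qc_items: int = 3  # quality-control items appended by the administrator

    def items_per_tier(self) -> int:
        return self.words_per_tier + self.pseudos_per_tier


@dataclass
class TestItem:
    """One instrument entry.

    ``weight`` is the normalised item weight (sums to 1 over the
    instrument); ``raw_weight`` the pre-normalisation logistic weight.
    ``template`` is set for pseudowords only; ``log_z`` carries the
    standardised log frequency of the word (or the pseudoword's template),
    used by the respondent simulator as an item-difficulty anchor.
    """

    item_id: str
    surface: str
    is_pseudoword: bool
    tier: int
    weight: float
    raw_weight: float
    template: str | None = None
    log_z: float = float("nan")


@dataclass
class Instrument:
    """An ordered, seeded instantiation with its design counts."""

    items: list[TestItem]
    n_tiers: int
    words_per_tier: int
    pseudos_per_tier: int
    seed: int

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def weights(self) -> np.ndarray:
        return np.array([it.weight for it in self.items])

    def true_items(self) -> list[TestItem]:
        return [it for it in self.items if not it.is_pseudoword]

    def pseudo_items(self) -> list[TestItem]:
        return [it for it in self.items if it.is_pseudoword]

    def to_dict(self, include_key: bool = True) -> dict:
        """JSON-compatible representation.

        With ``include_key`` the administrator section embeds the master
        key and per-item provenance; without it the export is respondent
        facing: surfaces and ids only, in presentation order.
        """
        if include_key:
            return {
                "design": {
                    "n_tiers": self.n_tiers,
                    "words_per_tier": self.words_per_tier,
                    "pseudos_per_tier": self.pseudos_per_tier,
                },
                "seed": self.seed,
                "likert_labels": {str(k): v for k, v in LIKERT_LABELS.items()},
                "items": [asdict(it) for it in self.items],
                "administrator": {"master_key": master_key(self)},
            }
        return {
            "likert_labels": {str(k): v for k, v in LIKERT_LABELS.items()},
            "items": [
                {"item_id": it.item_id, "surface": it.surface} for it in self.items
            ],
        }

    def save(self, path: str | Path, include_key: bool = True) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(include_key=include_key), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "Instrument":
        design = payload["design"]
        items = []
        for rec in payload["items"]:
            rec = dict(rec)
            rec.setdefault("log_z", float("nan"))
            items.append(TestItem(**rec))
        return cls(
            items=items,
            n_tiers=design["n_tiers"],
            words_per_tier=design["words_per_tier"],
            pseudos_per_tier=design["pseudos_per_tier"],
            seed=payload["seed"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "Instrument":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ResponseSheet:
    """One respondent's Likert category per item."""

    respondent_id: str
    answers: dict[str, int]

    def __post_init__(self) -> None:
        for item_id, cat in self.answers.items():
            if not (LIKERT_MIN <= int(cat) <= LIKERT_MAX):
                raise ValueError(
                    f"respondent {self.respondent_id}: category {cat} for "
                    f"{item_id} outside {LIKERT_MIN}..{LIKERT_MAX}"
                )


def master_key(instrument: Instrument) -> dict[str, int]:
    """item_id -> category of the idealised perfect respondent."""
    return {
        it.item_id: (LIKERT_MIN if it.is_pseudoword else LIKERT_MAX)
        for it in instrument.items
    }


def build_instrument(
    partition: TierPartition,
    chain: SegmentChain,
    lexicon: set[str],
    config: DesignConfig = DesignConfig(),
    seed: int = 0,
    max_attempts: int = 1000,
) -> Instrument:
    """Assemble one instantiation from a weighted, tiered vocabulary.

    Per tier, ``words_per_tier`` true words are sampled uniformly without
    replacement, then ``pseudos_per_tier`` pseudowords are generated from
    distinct template words of the same tier, with templates disjoint from
    the selected true words. Failing templates are retried against the
    remaining tier words before the build fails. Deterministic under
    ``seed``; the presentation order is a single global shuffle.

    The entries in ``partition`` must already carry logistic weights
    (``compute_item_weights``).
    """
    need = config.items_per_tier()
    for t, tier in enumerate(partition.tiers, start=1):
        if len(tier) < need:
            raise BuildError(
                f"tier {t} holds {len(tier)} words; design needs {need}"
            )
        for e in tier:
            if not np.isfinite(e.weight):
                raise BuildError(f"entry {e.word!r} has no item weight")

    rng = np.random.default_rng(seed)
    true_sel: list[tuple[int, VocabularyEntry]] = []
    pseudo_sel: list[tuple[int, str, VocabularyEntry]] = []  # tier, surface, template

    used_surfaces: set[str] = set()
    for t, tier in enumerate(partition.tiers, start=1):
        pool = [e for e in tier if e.word not in used_surfaces]
        if len(pool) < need:
            raise BuildError(f"tier {t}: too few unused words for the design")
        picks = rng.choice(len(pool), size=config.words_per_tier, replace=False)
        chosen = [pool[i] for i in sorted(picks)]
        for e in chosen:
            true_sel.append((t, e))
            used_surfaces.add(e.word)

        templates = [e for e in pool if e.word not in {c.word for c in chosen}]
        order = rng.permutation(len(templates))
        made = 0
        for idx in order:
            if made == config.pseudos_per_tier:
                break
            tmpl = templates[idx]
            sub_seed = int(rng.integers(0, 2**31 - 1))
            try:
                pw = generate_pseudoword(
                    tmpl.word, chain, lexicon, rng_seed=sub_seed,
                    max_attempts=max_attempts,
                )
            except GenerationError:
                continue
            if pw in used_surfaces:
                continue
            pseudo_sel.append((t, pw, tmpl))
            used_surfaces.add(pw)
            made += 1
        if made < config.pseudos_per_tier:
            raise BuildError(
                f"tier {t}: could not generate {config.pseudos_per_tier} pseudowords"
            )

    mean_true_weight = float(np.mean([e.weight for _, e in true_sel]))
    items: list[TestItem] = []
    per_tier_true: dict[int, int] = {}
    for t, e in true_sel:
        k = per_tier_true.get(t, 0) + 1
        per_tier_true[t] = k
        items.append(
            TestItem(
                item_id=f"t{t}_{k}",
                surface=e.word,
                is_pseudoword=False,
                tier=t,
                weight=float("nan"),
                raw_weight=e.weight,
                log_z=e.log_z,
            )
        )
    per_tier_pseudo: dict[int, int] = {}
    for t, pw, tmpl in pseudo_sel:
        k = per_tier_pseudo.get(t, 0) + 1
        per_tier_pseudo[t] = k
        items.append(
            TestItem(
                item_id=f"p{t}_{k}",
                surface=pw,
                is_pseudoword=True,
                tier=t,
                weight=float("nan"),
                raw_weight=mean_true_weight,
                template=tmpl.word,
                log_z=tmpl.log_z,
            )
        )

    total = sum(it.raw_weight for it in items)
    for it in items:
        it.weight = it.raw_weight / total

    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    return Instrument(
        items=items,
        n_tiers=partition.n_tiers,
        words_per_tier=config.words_per_tier,
        pseudos_per_tier=config.pseudos_per_tier,
        seed=seed,
    )


def make_parallel_forms(
    partition: TierPartition,
    chain: SegmentChain,
    lexicon: set[str],
    config: DesignConfig = DesignConfig(),
    seed: int = 0,
    max_attempts: int = 1000,
    max_retries: int = 20,
) -> tuple[Instrument, Instrument]:
    """Two instantiations from the same corpus sharing no surface form.

    Form B is built from tier pools with form A's surfaces (true words,
    templates, and pseudoword strings) removed, so the parallel forms are
    item-disjoint — shared items would inflate the parallel-form
    correlation. Deterministic under the master ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seed_a, *seeds_b = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(1 + max_retries)]
    form_a = build_instrument(partition, chain, lexicon, config, seed=seed_a,
                              max_attempts=max_attempts)
    taken = {it.surface for it in form_a.items} | {
        it.template for it in form_a.items if it.template
    }
    reduced = TierPartition(
        n_tiers=partition.n_tiers,
        tiers=[[e for e in tier if e.word not in taken] for tier in partition.tiers],
    )
    last_err: Exception | None = None
    for seed_b in seeds_b:
        try:
            form_b = build_instrument(reduced, chain, lexicon, config, seed=seed_b,
                                      max_attempts=max_attempts)
        except BuildError as err:
            last_err = err
            continue
        clash = {it.surface for it in form_b.items} & {it.surface for it in form_a.items}
        if not clash:
            return form_a, form_b
        last_err = BuildError(f"parallel forms share surfaces: {sorted(clash)[:5]}")
    raise BuildError(f"could not build disjoint parallel forms: {last_err}")


def filter_responses(
    sheets: Sequence[ResponseSheet],
    qc_items: Mapping[str, int],
) -> tuple[list[ResponseSheet], list[tuple[ResponseSheet, str]]]:
    """Split sheets into kept and rejected by quality-control answers.

    A sheet is rejected iff any quality-control answer is missing
    (reason ``"missing"``) or differs from the required category (reason
    ``"failed"``). Kept sheets are returned with the QC items stripped so
    downstream scoring sees only scored items.
    """
    kept: list[ResponseSheet] = []
    rejected: list[tuple[ResponseSheet, str]] = []
    for sheet in sheets:
        reason = None
        for qid, required in qc_items.items():
            if qid not in sheet.answers:
                reason = "missing"
                break
            if sheet.answers[qid] != required:
                reason = "failed"
                break
        if reason:
            rejected.append((sheet, reason))
        else:
            kept.append(
                ResponseSheet(
                    respondent_id=sheet.respondent_id,
                    answers={
                        k: v for k, v in sheet.answers.items() if k not in qc_items
                    },
                )
            )
    return kept, rejected


def read_response_sheets(path: str | Path) -> list[ResponseSheet]:
    """Read response sheets from CSV ``respondent_id,item_id,category``."""
    df = pd.read_csv(path, dtype={"respondent_id": str, "item_id": str})
    expected = {"respondent_id", "item_id", "category"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    sheets = []
    for rid, grp in df.groupby("respondent_id", sort=True):
        sheets.append(
            ResponseSheet(
                respondent_id=str(rid),
                answers=dict(zip(grp["item_id"], grp["category"].astype(int))),
            )
        )
    return sheets


def write_response_sheets(sheets: Iterable[ResponseSheet], path: str | Path) -> None:
    rows = [
        {"respondent_id": s.respondent_id, "item_id": iid, "category": cat}
        for s in sheets
        for iid, cat in s.answers.items()
    ]
    pd.DataFrame(rows, columns=["respondent_id", "item_id", "category"]).to_csv(
        path, index=False
    )
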