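"""Item-weighted generalisation of weighted Cohen's kappa.

A respondent is scored by their agreement with the master key over the
instrument's items,

    kappa = 1 - q_o / q_e,

where ``q_o`` is the observed weighted disagreement and ``q_e`` the
disagreement expected by chance. Classic weighted kappa treats all items
equally and works from the K x K contingency table of the two raters'
category assignments. Here each item ``n`` instead carries a weight
``u_n`` (normalised to sum to 1), so

    q_o = sum_n u_n * v(k_n, l_n)
    q_e = sum_i sum_j p1(i) * p2(j) * v(i, j)

with ``v(i, j)`` the disagreement weight between ordinal categories
(linear ``|i - j|`` by default), ``k, l`` the two raters' assignments, and
``p1, p2`` the item-weighted marginal category distributions of each
rater: ``p1(i) = sum_n u_n * [k_n = i]`` and likewise for ``p2``. With
uniform item weights ``u_n = 1/N`` this reduces exactly to textbook
weighted kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instrument import Instrument, LIKERT_MAX, LIKERT_MIN, ResponseSheet, master_key

__all__ = [
    "DisagreementWeights",
    "ScoreResult",
    "ScoringError",
    "observed_disagreement",
    "chance_disagreement",
    "generalized_kappa",
    "score_batch",
]

_NORM_TOL = 1e-9


class ScoringError(ValueError):
    """Raised on item misalignment or invalid weights."""


@dataclass(frozen=True)
class DisagreementWeights:
    """Disagreement weights v(i, j) between ordinal categories.

    ``linear`` gives v(i, j) = |i - j|; ``quadratic`` gives (i - j)^2.
    v is symmetric with zero diagonal in both schemes.
    """

    scheme: str = "linear"

    def __post_init__(self) -> None:
        if self.scheme not in ("linear", "quadratic"):
            raise ScoringError(f"unknown disagreement scheme {self.scheme!r}")

    def __call__(self, i: int, j: int) -> float:
        d = abs(i - j)
        return float(d if self.scheme == "linear" else d * d)

    def matrix(self, k: int = LIKERT_MAX) -> np.ndarray:
        """The full v matrix over categories 1..k."""
        cats = np.arange(1, k + 1)
        d = np.abs(cats[:, None] - cats[None, :]).astype(float)
        return d if self.scheme == "linear" else d**2


@dataclass(frozen=True)
class ScoreResult:
    """Observed/chance disagreement and the resulting kappa.

    ``kappa_raw`` may fall below 0 for strongly anti-key responding;
    ``kappa`` is the literacy score clamped to the [0, 1] range of the
    scale. ``degenerate`` flags the q_e = 0 case of two identical
    constant raters, where kappa is defined as 1.
    """

    respondent_id: str
    q_obs: float
    q_exp: float
    kappa_raw: float
    kappa: float
    n_items: int
    degenerate: bool = False


def _aligned(
    sheet: ResponseSheet,
    key: Mapping[str, int],
    u: Mapping[str, float] | Sequence[float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align sheet, key, and weights over identical item ids."""
    ids = sorted(key)
    if set(sheet.answers) != set(ids):
        missing = set(ids) - set(sheet.answers)
        extra = set(sheet.answers) - set(ids)
        raise ScoringError(
            f"respondent {sheet.respondent_id}: item mismatch "
            f"(missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
        )
    if isinstance(u, Mapping):
        weights = np.array([u[i] for i in ids], dtype=float)
    else:
        if len(u) != len(ids):
            raise ScoringError("weight vector length differs from item count")
        weights = np.asarray(u, dtype=float)
    if abs(weights.sum() - 1.0) > _NORM_TOL or (weights < 0).any():
        raise ScoringError("item weights must be nonnegative and sum to 1")
    k = np.array([key[i] for i in ids], dtype=int)
    l = np.array([sheet.answers[i] for i in ids], dtype=int)
    return weights, k, l


def observed_disagreement(
    sheet: ResponseSheet,
    key: Mapping[str, int],
    u: Mapping[str, float] | Sequence[float],
    v: DisagreementWeights = DisagreementWeights(),
) -> float:
    """q_o = sum_n u_n * v(k_n, l_n)."""
    weights, k, l = _aligned(sheet, key, u)
    vmat = v.matrix()
    return float(np.sum(weights * vmat[k - 1, l - 1]))


def chance_disagreement(
    sheet: ResponseSheet,
    key: Mapping[str, int],
    u: Mapping[str, float] | Sequence[float],
    v: DisagreementWeights = DisagreementWeights(),
) -> float:
    """q_e from the product of item-weighted marginal category distributions."""
    weights, k, l = _aligned(sheet, key, u)
    ncat = LIKERT_MAX - LIKERT_MIN + 1
    p1 = np.bincount(k - 1, weights=weights, minlength=ncat)
    p2 = np.bincount(l - 1, weights=weights, minlength=ncat)
    return float(p1 @ v.matrix(ncat) @ p2)


def generalized_kappa(
    sheet: ResponseSheet,
    key: Mapping[str, int],
    u: Mapping[str, float] | Sequence[float],
    v: DisagreementWeights = DisagreementWeights(),
) -> ScoreResult:
    """Score one sheet against the master key: kappa = 1 - q_o / q_e.

    ``kappa`` is ``kappa_raw`` clamped to [0, 1]; the cap at 1 is attained
    only at q_o = 0. When both raters are the same constant (q_e = 0 and
    q_o = 0) agreement is perfect and kappa is 1 with ``degenerate`` set.
    """
    q_o = observed_disagreement(sheet, key, u, v)
    q_e = chance_disagreement(sheet, key, u, v)
    if q_e == 0.0:
        if q_o > 0.0:
            raise AssertionError(
                "q_e = 0 with q_o > 0 cannot occur for symmetric v with zero diagonal"
            )
        return ScoreResult(
            respondent_id=sheet.respondent_id,
            q_obs=q_o, q_exp=q_e, kappa_raw=1.0, kappa=1.0,
            n_items=len(sheet.answers), degenerate=True,
        )
    raw = 1.0 - q_o / q_e
    return ScoreResult(
        respondent_id=sheet.respondent_id,
        q_obs=q_o, q_exp=q_e, kappa_raw=raw,
        kappa=min(max(raw, 0.0), 1.0),
        n_items=len(sheet.answers),
    )


def score_batch(
    sheets: Sequence[ResponseSheet],
    instrument: Instrument,
    v: DisagreementWeights = DisagreementWeights(),
) -> pd.DataFrame:
    """Score many sheets against an instrument's master key.

    Returns a DataFrame ordered by respondent_id with columns
    ``respondent_id, q_obs, q_exp, kappa_raw, kappa, n_items, error``;
    per-sheet failures are reported in ``error`` and the batch continues.
    """
    key = master_key(instrument)
    u = {it.item_id: it.weight for it in instrument.items}
    rows = []
    for sheet in sorted(sheets, key=lambda s: s.respondent_id):
        try:
            r = generalized_kappa(sheet, key, u, v)
            rows.append(
                {
                    "respondent_id": r.respondent_id,
                    "q_obs": r.q_obs,
                    "q_exp": r.q_exp,
                    "kappa_raw": r.kappa_raw,
                    "kappa": r.kappa,
                    "n_items": r.n_items,
                    "error": "",
                }
            )
        except (ScoringError, ValueError) as err:
            rows.append(
                {
                    "respondent_id": sheet.respondent_id,
                    "q_obs": np.nan,
                    "q_exp": np.nan,
                    "kappa_raw": np.nan,
                    "kappa": np.nan,
                    "n_items": len(sheet.answers),
                    "error": str(err),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["respondent_id", "q_obs", "q_exp", "kappa_raw", "kappa", "n_items", "error"],
    )
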