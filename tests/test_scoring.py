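import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from lexitest.instrument import ResponseSheet, master_key
from lexitest.scoring import (
    DisagreementWeights,
    ScoringError,
    chance_disagreement,
    generalized_kappa,
    observed_disagreement,
    score_batch,
)

LINEAR = DisagreementWeights("linear")

# worked 3-item example: u = (0.5, 0.3, 0.2), key = (4, 4, 1), sheet = (4, 3, 1)
IDS = ["i1", "i2", "i3"]
U3 = dict(zip(IDS, [0.5, 0.3, 0.2]))
KEY3 = dict(zip(IDS, [4, 4, 1]))
SHEET3 = ResponseSheet("w", dict(zip(IDS, [4, 3, 1])))


def _rand_case(rng, n):
    ids = [f"i{j}" for j in range(n)]
    key = dict(zip(ids, rng.integers(1, 5, n).tolist()))
    sheet = ResponseSheet("x", dict(zip(ids, rng.integers(1, 5, n).tolist())))
    w = rng.random(n)
    u = dict(zip(ids, (w / w.sum()).tolist()))
    return key, sheet, u


class TestObservedDisagreement:
    def test_zero_when_identical(self, default_instrument, default_key, default_weights):
        sheet = ResponseSheet("m", dict(default_key))
        assert observed_disagreement(sheet, default_key, default_weights) == 0.0

    def test_hand_worked_three_item_case(self):
        # 0.5*|4-4| + 0.3*|4-3| + 0.2*|1-1| = 0.3
        assert observed_disagreement(SHEET3, KEY3, U3, LINEAR) == pytest.approx(0.3)

    def test_uniform_weights_reduce_to_mean_disagreement(self):
        rng = np.random.default_rng(4)
        key, sheet, _ = _rand_case(rng, 12)
        u = {i: 1 / 12 for i in key}
        expected = np.mean([abs(key[i] - sheet.answers[i]) for i in key])
        assert observed_disagreement(sheet, key, u, LINEAR) == pytest.approx(expected)

    def test_item_mismatch_raises(self):
        with pytest.raises(ScoringError, match="item mismatch"):
            observed_disagreement(ResponseSheet("x", {"other": 1}), KEY3, U3)

    def test_unnormalized_weights_raise(self):
        bad = {i: 1.0 for i in IDS}
        with pytest.raises(ScoringError, match="sum to 1"):
            observed_disagreement(SHEET3, KEY3, bad)


class TestChanceDisagreement:
    def test_hand_worked_three_item_case(self):
        # p1 = {4: .8, 1: .2}, p2 = {4: .5, 3: .3, 1: .2} -> 1.14
        assert chance_disagreement(SHEET3, KEY3, U3, LINEAR) == pytest.approx(1.14)

    def test_equals_brute_force_double_sum(self):
        """Marginal-product formula vs explicit sum over all 16 category pairs."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            key, sheet, u = _rand_case(rng, int(rng.integers(3, 25)))
            for scheme in ("linear", "quadratic"):
                v = DisagreementWeights(scheme)
                p1 = {c: sum(u[i] for i in key if key[i] == c) for c in range(1, 5)}
                p2 = {c: sum(u[i] for i in key if sheet.answers[i] == c)
                      for c in range(1, 5)}
                brute = sum(
                    p1[i] * p2[j] * v(i, j)
                    for i in range(1, 5) for j in range(1, 5)
                )
                assert chance_disagreement(sheet, key, u, v) == pytest.approx(
                    brute, abs=1e-12
                )

    def test_zero_for_identical_constant_raters(self):
        key = {"a": 2, "b": 2}
        sheet = ResponseSheet("x", {"a": 2, "b": 2})
        assert chance_disagreement(sheet, key, {"a": 0.5, "b": 0.5}) == 0.0


class TestGeneralizedKappa:
    def test_master_scores_one(self, default_instrument, default_key, default_weights):
        sheet = ResponseSheet("m", dict(default_key))
        res = generalized_kappa(sheet, default_key, default_weights)
        assert res.kappa == 1.0 and res.kappa_raw == 1.0 and not res.degenerate

    def test_hand_worked_three_item_case(self):
        res = generalized_kappa(SHEET3, KEY3, U3, LINEAR)
        assert res.kappa_raw == pytest.approx(1 - 0.3 / 1.14)

    def test_all_category_one_responder_scores_zero(self, default_instrument,
                                                    default_key, default_weights):
        """Constant '1' responding: q_o = q_e = 3 * total true-word weight."""
        sheet = ResponseSheet("c1", {i: 1 for i in default_key})
        res = generalized_kappa(sheet, default_key, default_weights)
        w_true = sum(
            it.weight for it in default_instrument.items if not it.is_pseudoword
        )
        assert res.q_obs == pytest.approx(3 * w_true)
        assert res.q_exp == pytest.approx(3 * w_true)
        assert res.kappa_raw == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_identical_constant_raters(self):
        key = {"a": 3, "b": 3}
        sheet = ResponseSheet("x", {"a": 3, "b": 3})
        res = generalized_kappa(sheet, key, {"a": 0.5, "b": 0.5})
        assert res.kappa == 1.0 and res.degenerate

    def test_uniform_weights_match_textbook_weighted_kappa(self):
        """Independent oracle: sklearn's weighted Cohen kappa on the 4x4 table."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            key, sheet, _ = _rand_case(rng, n)
            u = {i: 1.0 / n for i in key}
            k = np.array([key[i] for i in sorted(key)])
            l = np.array([sheet.answers[i] for i in sorted(key)])
            for scheme in ("linear", "quadratic"):
                ref = cohen_kappa_score(k, l, labels=[1, 2, 3, 4], weights=scheme)
                if np.isnan(ref):  # degenerate table
                    continue
                res = generalized_kappa(sheet, key, u, DisagreementWeights(scheme))
                assert res.kappa_raw == pytest.approx(ref, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        key, sheet, u = _rand_case(rng, 15)
        base = generalized_kappa(sheet, key, u, LINEAR)
        perm = rng.permutation(sorted(key))
        key_p = {i: key[i] for i in perm}
        sheet_p = ResponseSheet("x", {i: sheet.answers[i] for i in perm})
        res = generalized_kappa(sheet_p, key_p, u, LINEAR)
        assert res.kappa_raw == pytest.approx(base.kappa_raw, abs=1e-14)

    @given(st.floats(min_value=0.1, max_value=50.0), st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_of_v(self, scale, case_seed):
        """Multiplying all v(i, j) by a constant cancels in q_o / q_e."""
        rng = np.random.default_rng(case_seed)
        key, sheet, u = _rand_case(rng, 10)
        base = generalized_kappa(sheet, key, u, LINEAR)
        q_o = observed_disagreement(sheet, key, u, LINEAR) * scale
        q_e = chance_disagreement(sheet, key, u, LINEAR) * scale
        if q_e > 0:
            assert 1 - q_o / q_e == pytest.approx(base.kappa_raw, rel=1e-12)

    def test_single_item_degradation_never_raises_kappa(self, default_key,
                                                        default_weights):
        """Moving one answer further from the key can only lower kappa_raw."""
        rng = np.random.default_rng(21)
        ids = sorted(default_key)
        for _ in range(100):
            answers = {i: int(c) for i, c in zip(ids, rng.integers(1, 5, len(ids)))}
            base = generalized_kappa(
                ResponseSheet("x", answers), default_key, default_weights
            )
            i = ids[rng.integers(len(ids))]
            k = default_key[i]
            cur = answers[i]
            further = [c for c in range(1, 5) if abs(c - k) > abs(cur - k)]
            if not further:
                continue
            answers2 = {**answers, i: further[rng.integers(len(further))]}
            worse = generalized_kappa(
                ResponseSheet("x", answers2), default_key, default_weights
            )
            assert worse.kappa_raw <= base.kappa_raw + 1e-12


class TestScoreBatch:
    def test_empty_batch(self, default_instrument):
        table = score_batch([], default_instrument)
        assert len(table) == 0

    def test_batch_matches_per_sheet_and_reports_errors(self, default_instrument,
                                                        default_key, default_weights):
        rng = np.random.default_rng(8)
        ids = sorted(default_key)
        sheets = [
            ResponseSheet(f"r{j}", {i: int(c) for i, c in
                                    zip(ids, rng.integers(1, 5, len(ids)))})
            for j in range(5)
        ]
        bad = ResponseSheet("zz_bad", {"nonexistent": 1})
        table = score_batch(sheets + [bad], default_instrument)
        assert len(table) == 6
        assert list(table["respondent_id"]) == sorted(s.respondent_id
                                                      for s in sheets + [bad])
        for _, row in table[table["error"] == ""].iterrows():
            sheet = next(s for s in sheets if s.respondent_id == row["respondent_id"])
            res = generalized_kappa(sheet, default_key, default_weights)
            assert row["kappa"] == pytest.approx(res.kappa)
        assert (table.loc[table["respondent_id"] == "zz_bad", "error"] != "").all()
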