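"""SVM-RFE, empirical AUC/pAUC and Boruta against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_curve

from consensusfs import (
    BorutaConfig,
    ExpressionMatrix,
    PhenotypeVector,
    RfeConfig,
    boruta_select,
    empirical_auc,
    empirical_pauc,
    roc_rank,
    roc_scores,
    svm_rfe_rank,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def auc_all_pairs(neg, pos):
    """Brute-force Mann-Whitney: count wins and half-credit ties."""
    wins = sum(1 for a in pos for b in neg if a > b)
    ties = sum(1 for a in pos for b in neg if a == b)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def pauc_threshold_sweep(neg, pos, t0):
    """Exhaustive-threshold ROC polygon (via an independent implementation)
    integrated trapezoidally on [0, t0]."""
    y = np.r_[np.zeros(len(neg)), np.ones(len(pos))]
    scores = np.r_[neg, pos]
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    if t0 < 1.0:
        tpr_t0 = np.interp(t0, fpr, tpr)
        keep = fpr < t0
        fpr = np.append(fpr[keep], t0)
        tpr = np.append(tpr[keep], tpr_t0)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# AUC / pAUC
# ---------------------------------------------------------------------------

class TestEmpiricalAuc:
    @pytest.mark.parametrize(
        "neg,pos,expected",
        [
            ([1, 2, 3], [4, 5, 6], 1.0),     # complete separation
            ([1, 3], [2, 4], 0.75),          # 3 wins of 4 pairs
            ([5, 5], [5, 5], 0.5),           # all ties -> half credit
            ([4, 5, 6], [1, 2, 3], 0.0),     # reversed separation
        ],
    )
    def test_known_values(self, neg, pos, expected):
        assert empirical_auc(neg, pos) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1.0])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        neg=st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=20),
        pos=st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=20),
    )
    def test_matches_all_pairs_counting(self, neg, pos):
        # integer scores force heavy ties; rank formula must agree exactly
        assert empirical_auc(neg, pos) == auc_all_pairs(neg, pos)


class TestEmpiricalPauc:
    def test_perfect_separation_saturates(self):
        for t0 in (0.05, 0.3, 1.0):
            assert empirical_pauc([1, 2, 3], [4, 5, 6], t0) == pytest.approx(t0)

    def test_t0_one_reduces_to_full_auc(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            neg = rng.normal(size=8)
            pos = rng.normal(0.5, size=8)
            assert empirical_pauc(neg, pos, 1.0) == pytest.approx(
                empirical_auc(neg, pos), abs=1e-12
            )

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            neg = np.round(rng.normal(size=8), 1)  # rounding induces ties
            pos = np.round(rng.normal(0.7, size=8), 1)
            t0 = float(rng.uniform(0.05, 1.0))
            assert empirical_pauc(neg, pos, t0) == pytest.approx(
                pauc_threshold_sweep(neg, pos, t0), abs=1e-12
            )

    def test_monotone_in_t0(self):
        rng = np.random.default_rng(3)
        neg, pos = rng.normal(size=10), rng.normal(0.3, size=10)
        paucs = [empirical_pauc(neg, pos, t) for t in np.linspace(0.01, 1.0, 25)]
        assert all(b >= a - 1e-15 for a, b in zip(paucs, paucs[1:]))

    def test_invalid_t0_rejected(self):
        with pytest.raises(ValueError):
            empirical_pauc([1.0], [2.0], 0.0)


class TestRocRank:
    def _dataset(self, rng, n=20, p=10):
        values = rng.normal(size=(p, n))
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        values[0] = np.where(y == 1, 5.0, 0.0) + 0.01 * rng.normal(size=n)
        m = ExpressionMatrix(
            [f"p{i}" for i in range(p)], [f"s{j}" for j in range(n)], values
        )
        return m, PhenotypeVector(list(m.sample_ids), y)

    def test_perfect_separator_ranks_first(self):
        m, y = self._dataset(np.random.default_rng(4))
        assert roc_rank(m, y).probe_ids[0] == "p0"

    def test_sign_inversion_does_not_change_rank(self):
        m, y = self._dataset(np.random.default_rng(5))
        ranked = roc_rank(m, y)
        flipped_values = m.values.copy()
        flipped_values[0] = -flipped_values[0]
        m_flipped = ExpressionMatrix(
            list(m.probe_ids), list(m.sample_ids), flipped_values
        )
        assert roc_rank(m_flipped, y).probe_ids[0] == ranked.probe_ids[0] == "p0"

    def test_all_constant_probes_keep_input_order(self):
        m = ExpressionMatrix(
            ["a", "b", "c"], ["s1", "s2", "s3", "s4"], np.ones((3, 4))
        )
        y = PhenotypeVector(["s1", "s2", "s3", "s4"], np.array([1, 1, 0, 0]))
        ranked = roc_rank(m, y)
        assert ranked.probe_ids == ["a", "b", "c"]
        assert ranked.scores == [0.5, 0.5, 0.5]

    def test_pauc_criterion_and_score_invariants(self):
        m, y = self._dataset(np.random.default_rng(6))
        for score in roc_scores(m, y, t0=0.2):
            assert 0.0 <= score.pauc <= score.t0 + 1e-12
            assert score.pauc <= score.auc + 1e-12
        assert roc_rank(m, y, t0=0.2, criterion="pauc").probe_ids[0] == "p0"


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

class TestSvmRfe:
    def test_informative_feature_outranks_noise(self):
        rng = np.random.default_rng(0)
        y = np.array([1, 0] * 10)
        feat_a = y + rng.normal(0, 0.1, size=20)
        feat_b = rng.normal(0, 1, size=20)
        m = ExpressionMatrix(
            ["A", "B"], [f"s{j}" for j in range(20)], np.stack([feat_a, feat_b])
        )
        labels = PhenotypeVector(list(m.sample_ids), y)
        ranked = svm_rfe_rank(m, labels)
        assert ranked.probe_ids == ["A", "B"]
        assert ranked.score_semantics == "rank position"

    def test_single_feature(self):
        m = ExpressionMatrix(["only"], ["s1", "s2"], np.array([[0.0, 1.0]]))
        y = PhenotypeVector(["s1", "s2"], np.array([0, 1]))
        assert svm_rfe_rank(m, y).probe_ids == ["only"]

    def test_duplicated_feature_tie_broken_by_column_order(self):
        rng = np.random.default_rng(1)
        y = np.array([1, 0] * 8)
        feat = y + rng.normal(0, 0.2, size=16)
        m = ExpressionMatrix(
            ["first", "second"],
            [f"s{j}" for j in range(16)],
            np.stack([feat, feat.copy()]),
        )
        labels = PhenotypeVector(list(m.sample_ids), y)
        # equal weights by symmetry: the earlier column is eliminated first,
        # so it ends up ranked after its twin
        assert svm_rfe_rank(m, labels).probe_ids == ["second", "first"]

    def test_output_is_permutation_and_deterministic(self, small_planted):
        m, y, truth = small_planted
        r1 = svm_rfe_rank(m, y, RfeConfig(step=3))
        r2 = svm_rfe_rank(m, y, RfeConfig(step=3))
        assert sorted(r1.probe_ids) == sorted(m.probe_ids)
        assert r1.probe_ids == r2.probe_ids
        assert truth <= set(r1.probe_ids[: max(2, len(m.probe_ids) // 10)])

    def test_single_class_rejected(self):
        m = ExpressionMatrix(["p1", "p2"], ["s1", "s2"], np.ones((2, 2)))
        y = PhenotypeVector(["s1", "s2"], np.array([1, 1]))
        with pytest.raises(ValueError, match="both classes"):
            svm_rfe_rank(m, y)

    def test_non_finite_values_rejected(self):
        m = ExpressionMatrix(
            ["p1", "p2"], ["s1", "s2"], np.array([[1.0, np.inf], [0.0, 1.0]])
        )
        y = PhenotypeVector(["s1", "s2"], np.array([0, 1]))
        with pytest.raises(ValueError, match="non-finite"):
            svm_rfe_rank(m, y)


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

class TestBoruta:
    def test_recovers_planted_probes_and_is_reproducible(self):
        rng_cfg = SimDataForBoruta()
        m, y, truth = rng_cfg.dataset()
        cfg = BorutaConfig(n_trees=150, seed=11)
        res1 = boruta_select(m, y, cfg)
        res2 = boruta_select(m, y, cfg)
        assert res1.decisions == res2.decisions  # seed-stable
        assert truth <= res1.confirmed
        noise = set(m.probe_ids) - truth
        undecided_noise = noise & (res1.confirmed | res1.tentative)
        assert len(undecided_noise) <= 0.1 * len(noise)
        assert res1.confirmed.isdisjoint(res1.rejected)
        assert set(res1.decisions) == set(m.probe_ids)

    def test_constant_matrix_confirms_nothing(self):
        m = ExpressionMatrix(
            [f"p{i}" for i in range(5)],
            [f"s{j}" for j in range(12)],
            np.ones((5, 12)),
        )
        y = PhenotypeVector(list(m.sample_ids), np.array([1] * 6 + [0] * 6))
        res = boruta_select(m, y, BorutaConfig(n_trees=50, max_iterations=30, seed=0))
        assert res.confirmed == set()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BorutaConfig(n_trees=0)
        with pytest.raises(ValueError):
            BorutaConfig(max_iterations=0)


class SimDataForBoruta:
    """40 samples x 50 probes with 3 probes shifted by 3 SD."""

    def dataset(self):
        from consensusfs import SimConfig, simulate_dataset

        return simulate_dataset(
            SimConfig(
                n_probes=50,
                n_informative=3,
                n_case=20,
                n_control=20,
                effect=3.0,
                seed=21,
            )
        )
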