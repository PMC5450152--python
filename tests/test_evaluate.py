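import itertools

import numpy as np
import pandas as pd
import pytest

from pgxsig import evaluate
from pgxsig.datatypes import DataError, SignatureModel, StructuralError

from conftest import make_clinical_row, make_clinical_table


def auc_pair_count_oracle(probs, truth):
    """Brute-force rank statistic: P(random positive outranks random
    negative), ties counted one half."""
    pos = [p for p, t in zip(probs, truth) if t == 1]
    neg = [p for p, t in zip(probs, truth) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def top_left_oracle(probs, truth):
    """Exhaustive distance minimization over all unique thresholds."""
    thresholds = sorted(set(probs), reverse=True)
    best = None
    for thr in thresholds:
        pred = [p >= thr for p in probs]
        tp = sum(1 for pr, t in zip(pred, truth) if pr and t == 1)
        tn = sum(1 for pr, t in zip(pred, truth) if not pr and t == 0)
        sens = tp / sum(1 for t in truth if t == 1)
        spec = tn / sum(1 for t in truth if t == 0)
        dist = np.hypot(1 - sens, 1 - spec)
        if best is None or dist < best[0] - 1e-12 or (
            abs(dist - best[0]) <= 1e-12 and thr < best[1]
        ):
            best = (dist, thr)
    return best[1]


def _model():
    return SignatureModel(
        snp_ids=["s1", "s2"],
        codings=["additive", "dominant"],
        coefficients=[-0.5, -1.0],
        intercept=1.2,
    )


class TestPredictProbs:
    @staticmethod
    def _genotypes(data):
        from pgxsig.datatypes import GenotypeMatrix

        snps = pd.DataFrame(
            {"ref": "A", "alt": "G", "coding": "additive"},
            index=pd.Index(["s1", "s2"], name="snp_id"),
        )
        subjects = [f"S{i}" for i in range(len(data))]
        return GenotypeMatrix(subjects, snps, np.array(data, dtype=float))

    def test_all_zero_codings_gives_intercept(self):
        geno = self._genotypes([[0, 0], [0, 0]])
        probs = evaluate.predict_probs(_model(), geno)
        expected = 1 / (1 + np.exp(-1.2))
        assert np.allclose(probs, expected)

    def test_monotone_decreasing_in_risk_alleles(self):
        geno = self._genotypes([[0, 0], [1, 0], [2, 0], [2, 2]])
        probs = evaluate.predict_probs(_model(), geno).to_numpy()
        assert (np.diff(probs) < 0).all()

    def test_hand_computed_linear_predictor(self):
        geno = self._genotypes([[1, 2]])
        # dominant coding of genotype 2 -> 1; lp = 1.2 - 0.5*1 - 1.0*1
        lp = 1.2 - 0.5 - 1.0
        probs = evaluate.predict_probs(_model(), geno)
        assert probs.iloc[0] == pytest.approx(1 / (1 + np.exp(-lp)), abs=1e-12)

    def test_missing_genotype_propagates(self):
        geno = self._genotypes([[np.nan, 0], [0, 0]])
        probs = evaluate.predict_probs(_model(), geno)
        assert np.isnan(probs.iloc[0]) and not np.isnan(probs.iloc[1])

    def test_absent_snp_rejected(self):
        geno = self._genotypes([[0, 0]])
        model = _model()
        model.snp_ids = ["s1", "missing"]
        with pytest.raises(StructuralError):
            evaluate.predict_probs(model, geno)


class TestRocAuc:
    def test_perfect_separation(self):
        roc = evaluate.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_all_ties_half(self):
        roc = evaluate.roc_auc([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert roc.auc == 0.5

    def test_six_subject_pair_count_oracle(self):
        probs = [0.9, 0.7, 0.7, 0.4, 0.3, 0.1]
        truth = [1, 1, 0, 1, 0, 0]
        roc = evaluate.roc_auc(probs, truth)
        assert roc.auc == pytest.approx(auc_pair_count_oracle(probs, truth), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(DataError):
            evaluate.roc_auc([0.5, 0.6], [1, 1])

    def test_trapezoid_equals_rank_statistic_property(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            probs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            truth = rng.integers(0, 2, size=n)
            if truth.min() == truth.max():
                continue
            roc = evaluate.roc_auc(probs, truth)
            assert roc.auc == pytest.approx(
                auc_pair_count_oracle(probs, truth), abs=1e-12
            )

    def test_curve_monotone(self, rng):
        probs = rng.random(50)
        truth = rng.integers(0, 2, size=50)
        roc = evaluate.roc_auc(probs, truth)
        assert (np.diff(roc.sensitivity) >= -1e-12).all()
        assert (np.diff(roc.specificity) <= 1e-12).all()


class TestTopLeftThreshold:
    def test_perfect_classifier_returns_smallest_positive_score(self):
        probs = [0.9, 0.8, 0.2, 0.1]
        truth = [1, 1, 0, 0]
        roc = evaluate.roc_auc(probs, truth)
        assert evaluate.top_left_threshold(roc) == 0.8

    def test_four_point_brute_force(self):
        probs = [0.9, 0.6, 0.4, 0.2, 0.65, 0.35]
        truth = [1, 1, 0, 0, 0, 1]
        roc = evaluate.roc_auc(probs, truth)
        assert evaluate.top_left_threshold(roc) == top_left_oracle(probs, truth)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 20))
            probs = np.round(rng.random(n), 2)
            truth = rng.integers(0, 2, size=n)
            if truth.min() == truth.max():
                continue
            roc = evaluate.roc_auc(probs, truth)
            assert evaluate.top_left_threshold(roc) == top_left_oracle(
                list(probs), list(truth)
            )

    def test_tie_break_smaller_threshold(self):
        # symmetric curve: two equidistant operating points
        probs = [0.8, 0.6, 0.4, 0.2]
        truth = [1, 0, 1, 0]
        roc = evaluate.roc_auc(probs, truth)
        assert evaluate.top_left_threshold(roc) == top_left_oracle(probs, truth)

    def test_classification_at_threshold_matches_roc_point(self):
        probs = np.array([0.9, 0.75, 0.6, 0.45, 0.3, 0.15])
        truth = np.array([1, 1, 0, 1, 0, 0])
        roc = evaluate.roc_auc(probs, truth)
        thr = roc.top_left_threshold
        pred = probs >= thr
        sens = (pred & (truth == 1)).sum() / (truth == 1).sum()
        spec = (~pred & (truth == 0)).sum() / (truth == 0).sum()
        assert sens == pytest.approx(roc.top_left_sens)
        assert spec == pytest.approx(roc.top_left_spec)


class TestClassifySignature:
    def test_meets_threshold_is_positive(self):
        labels = evaluate.classify_signature(np.array([0.5, 0.49]), 0.5)
        assert list(labels) == [evaluate.SIG_POS, evaluate.SIG_NEG]

    def test_minimum_threshold_all_positive(self):
        probs = np.array([0.2, 0.6, 0.9])
        labels = evaluate.classify_signature(probs, probs.min())
        assert (labels == evaluate.SIG_POS).all()

    def test_hand_labeled_fixture(self):
        probs = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.55])
        labels = evaluate.classify_signature(probs, 0.55)
        assert (labels == evaluate.SIG_POS).sum() == 5
        assert (labels == evaluate.SIG_NEG).sum() == 5

    def test_missing_prob_unclassified(self):
        labels = evaluate.classify_signature(np.array([np.nan, 0.7]), 0.5)
        assert labels.iloc[0] is None


class TestGroupArr:
    @staticmethod
    def _table_and_sig():
        rows = [
            make_clinical_row("P1", relapse_days=[100], exposure_years=2.0),
            make_clinical_row("N1", relapse_days=[60, 200], exposure_years=1.0),
        ]
        table = make_clinical_table(rows)
        sig = pd.Series(
            [evaluate.SIG_POS, evaluate.SIG_NEG], index=["P1", "N1"], name="signature"
        )
        return table, sig

    def test_direct_arithmetic(self):
        table, sig = self._table_and_sig()
        summary = evaluate.group_arr_change(sig, table)
        assert summary.arr_pos == pytest.approx(0.5)
        assert summary.arr_neg == pytest.approx(2.0)
        assert summary.percent_change == pytest.approx(-75.0)

    def test_identical_groups_zero_change(self):
        rows = [
            make_clinical_row("A", relapse_days=[100], exposure_years=1.0),
            make_clinical_row("B", relapse_days=[100], exposure_years=1.0),
        ]
        table = make_clinical_table(rows)
        sig = pd.Series([evaluate.SIG_POS, evaluate.SIG_NEG], index=["A", "B"])
        assert evaluate.group_arr_change(sig, table).percent_change == 0.0

    def test_empty_group_rejected(self):
        table, sig = self._table_and_sig()
        sig[:] = evaluate.SIG_NEG
        with pytest.raises(DataError):
            evaluate.group_arr_change(sig, table)

    def test_invariant_to_exposure_splitting(self):
        rows = [
            make_clinical_row("A", relapse_days=[100, 200], exposure_years=2.0),
            make_clinical_row("N", relapse_days=[60], exposure_years=1.0),
        ]
        split_rows = [
            make_clinical_row("A1", relapse_days=[100], exposure_years=1.0),
            make_clinical_row("A2", relapse_days=[200], exposure_years=1.0),
            make_clinical_row("N", relapse_days=[60], exposure_years=1.0),
        ]
        sig1 = pd.Series(
            [evaluate.SIG_POS, evaluate.SIG_NEG], index=["A", "N"]
        )
        sig2 = pd.Series(
            [evaluate.SIG_POS, evaluate.SIG_POS, evaluate.SIG_NEG],
            index=["A1", "A2", "N"],
        )
        s1 = evaluate.group_arr_change(sig1, make_clinical_table(rows))
        s2 = evaluate.group_arr_change(sig2, make_clinical_table(split_rows))
        assert s1.arr_pos == pytest.approx(s2.arr_pos)
        assert s1.percent_change == pytest.approx(s2.percent_change)


class TestAucBootstrap:
    def test_self_comparison_p_near_one(self, rng):
        probs = rng.random(150)
        truth = (rng.random(150) < probs).astype(float)
        p = evaluate.auc_bootstrap_difference(
            (probs, truth), (probs, truth), n_boot=400, seed=1
        )
        assert p > 0.5

    def test_power_on_separated_cohorts(self, rng):
        n = 200
        truth_a = rng.integers(0, 2, n).astype(float)
        probs_a = truth_a * 0.5 + 0.25  # AUC 1.0
        truth_b = rng.integers(0, 2, n).astype(float)
        probs_b = rng.random(n)  # AUC ~ 0.5
        p = evaluate.auc_bootstrap_difference(
            (probs_a, truth_a), (probs_b, truth_b), n_boot=2000, seed=2
        )
        assert p < 0.01

    def test_seed_determinism(self, rng):
        probs = rng.random(80)
        truth = rng.integers(0, 2, 80).astype(float)
        args = ((probs, truth), (1 - probs, truth))
        p1 = evaluate.auc_bootstrap_difference(*args, n_boot=200, seed=7)
        p2 = evaluate.auc_bootstrap_difference(*args, n_boot=200, seed=7)
        assert p1 == p2


class TestSubsetModels:
    @staticmethod
    def _design(rng, n=800, betas=(-0.8, -0.7, -0.9, -1.2)):
        X = rng.binomial(2, 0.3, size=(n, len(betas))).astype(float)
        lp = 1.0 + X @ np.asarray(betas)
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        return pd.DataFrame(X, columns=[f"s{j}" for j in range(len(betas))]), y

    def test_four_snp_model_has_four_subsets(self, rng):
        design, y = self._design(rng)
        table = evaluate.subset_model_eval(design, y)
        assert len(table) == 4
        assert set(table.index) == set(design.columns)

    def test_full_model_dominates_subsets(self, rng):
        from pgxsig.bma import refit_final

        design, y = self._design(rng, n=3000)
        model = refit_final(design, y)
        lp = model.intercept + design.to_numpy() @ np.asarray(model.coefficients)
        full_auc = evaluate.roc_auc(1 / (1 + np.exp(-lp)), y).auc
        table = evaluate.subset_model_eval(design, y)
        assert (table["auc"] <= full_auc + 0.01).all()

    def test_zero_coefficient_subset_equivalent(self, rng):
        design, y = self._design(rng, n=3000, betas=(-1.0, -1.0, 0.0))
        from pgxsig.bma import refit_final

        model = refit_final(design, y)
        lp = model.intercept + design.to_numpy() @ np.asarray(model.coefficients)
        full_auc = evaluate.roc_auc(1 / (1 + np.exp(-lp)), y).auc
        table = evaluate.subset_model_eval(design, y)
        assert abs(table.loc["s2", "auc"] - full_auc) < 0.02

    def test_too_few_snps_rejected(self, rng):
        with pytest.raises(DataError):
            evaluate.subset_model_eval(
                pd.DataFrame({"s0": np.arange(10.0)}), np.zeros(10)
            )
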