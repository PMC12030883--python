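"""Featurization, splitting, metrics, and the consensus classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from conftest import brute_force_auc
from respiscreen.consensus import (
    ConsensusClassifier,
    compute_auc,
    compute_metrics,
    consensus_std,
    cross_validate,
    featurize,
    load_model,
    metrics_from_scores,
    save_model,
    split_train_test,
)
from respiscreen.synthetic import generate_feature_separable_set


class TestFeaturize:
    def test_rows_are_deterministic_and_context_free(self):
        a = featurize(["CCO"], "morgan")
        b = featurize(["CCO", "c1ccccc1"], "morgan")
        assert np.array_equal(a.iloc[0].values, b.iloc[0].values)

    def test_identical_structures_get_identical_rows(self):
        m = featurize(["OCC", "CCO"], "maccs")
        assert np.array_equal(m.iloc[0].values, m.iloc[1].values)

    def test_physchem_is_finite_on_small_fixture(self):
        m = featurize(["CCO", "c1ccccc1", "CC(=O)O", "CCN", "C1CCCCC1"],
                      "physchem")
        assert np.isfinite(m.values).all()

    def test_unknown_scheme_is_usage_error(self):
        with pytest.raises(ValueError, match="unknown"):
            featurize(["CCO"], "dragon7")


class TestSplit:
    def test_default_split_of_100_is_80_20(self):
        y = [0] * 50 + [1] * 50
        plan = split_train_test(range(100), y, seed=0)
        assert (len(plan.train_ids), len(plan.test_ids)) == (80, 20)
        assert set(plan.train_ids).isdisjoint(plan.test_ids)
        assert set(plan.train_ids) | set(plan.test_ids) == set(range(100))

    def test_same_seed_reproduces_the_plan(self):
        y = [0, 1] * 5
        a = split_train_test(range(10), y, seed=7)
        b = split_train_test(range(10), y, seed=7)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_nine_records_split_seven_two(self):
        # round(0.8 * 9) = 7
        plan = split_train_test(range(9), [0, 1] * 4 + [0], seed=1)
        assert (len(plan.train_ids), len(plan.test_ids)) == (7, 2)

    def test_stratification_keeps_both_classes(self):
        y = [0] * 80 + [1] * 20
        plan = split_train_test(range(100), y, seed=3)
        test_labels = {y[i] for i in plan.test_ids}
        assert test_labels == {0, 1}

    def test_single_class_warns_and_splits(self):
        with pytest.warns(UserWarning, match="single-class"):
            plan = split_train_test(range(10), [1] * 10, seed=0)
        assert len(plan.train_ids) == 8

    def test_too_few_records_raise(self):
        with pytest.raises(ValueError):
            split_train_test(range(4), [0, 0, 1, 1])


class TestMetrics:
    @pytest.mark.parametrize("tp,fp,tn,fn,acc,sen,spe", [
        (10, 0, 10, 0, 1.0, 1.0, 1.0),
        (8, 2, 6, 4, 0.7, 2 / 3, 0.75),
        (0, 0, 5, 5, 0.5, 0.0, 1.0),
    ])
    def test_confusion_ratios(self, tp, fp, tn, fn, acc, sen, spe):
        report = compute_metrics(tp, fp, tn, fn)
        assert report.acc == pytest.approx(acc)
        assert report.sen == pytest.approx(sen)
        assert report.spe == pytest.approx(spe)

    def test_undefined_sensitivity_is_none(self):
        assert compute_metrics(0, 3, 7, 0).sen is None

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)

    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=4, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_accuracy_bounded_by_sen_and_spe(self, pairs):
        y = [p[0] for p in pairs]
        s = [p[1] for p in pairs]
        if len(set(y)) < 2:
            return
        r = metrics_from_scores(y, s)
        assert min(r.sen, r.spe) - 1e-12 <= r.acc <= max(r.sen, r.spe) + 1e-12


class TestAUC:
    def test_perfect_separation_gives_one(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_full_ties_give_half(self):
        assert compute_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_case_three_quarters(self):
        # actives 0.9, 0.4; inactives 0.6, 0.1 -> 3 of 4 pairs correct
        assert compute_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_is_undefined(self):
        with pytest.raises(ValueError):
            compute_auc([0.5, 0.6], [1, 1])

    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0])),
                    min_size=4, max_size=25))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_agrees_with_pairwise_oracle(self, pairs):
        y = [p[0] for p in pairs]
        s = [p[1] for p in pairs]
        if len(set(y)) < 2:
            return
        assert compute_auc(s, y) == pytest.approx(brute_force_auc(s, y))


class TestConsStd:
    def test_agreement_gives_zero(self):
        assert consensus_std([0.9, 0.9, 0.9]) == 0.0

    def test_hand_case_half(self):
        assert consensus_std([0.0, 1.0]) == 0.5

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=8))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_permutation_invariant_and_bounded(self, values):
        base = consensus_std(values)
        assert base == pytest.approx(consensus_std(list(reversed(values))))
        assert base >= 0.0
        if len(values) == 2:
            assert base <= 0.5 + 1e-12


@pytest.fixture(scope="module")
def separable_model():
    records = generate_feature_separable_set(120, separation=1.0, seed=0)
    y = np.array([1 if r.label == "active" else 0 for r in records])
    model = ConsensusClassifier(random_state=0).fit(records, y)
    return records, y, model


class TestConsensusClassifier:
    def test_consensus_of_identical_models_is_the_identity(self):
        records = generate_feature_separable_set(60, separation=1.0, seed=2)
        y = np.array([1 if r.label == "active" else 0 for r in records])
        members = [
            ("morgan", LogisticRegression(max_iter=1000)),
            ("morgan", LogisticRegression(max_iter=1000)),
        ]
        model = ConsensusClassifier(members=members, random_state=0).fit(records, y)
        details = model.predict_detail(records)
        for d in details:
            assert d.per_model[0] == pytest.approx(d.per_model[1])
            assert d.cons_std == pytest.approx(0.0)
            assert d.y_mean == pytest.approx(d.per_model[0])

    def test_cross_validation_partitions_training_set(self):
        records = generate_feature_separable_set(100, separation=1.0, seed=1)
        y = np.array([1 if r.label == "active" else 0 for r in records])
        est = ConsensusClassifier(n_members=2, random_state=0)
        oof, report = cross_validate(est, records, y, k=5, seed=0)
        assert not np.isnan(oof).any()          # everyone predicted once
        assert report.acc >= 0.9                # separable data, sane learner

    def test_cross_validation_is_seed_reproducible(self):
        records = generate_feature_separable_set(60, separation=1.0, seed=4)
        y = np.array([1 if r.label == "active" else 0 for r in records])
        est = ConsensusClassifier(n_members=2, random_state=0)
        a, _ = cross_validate(est, records, y, k=3, seed=5)
        b, _ = cross_validate(est, records, y, k=3, seed=5)
        assert np.array_equal(a, b)

    def test_cv_usage_errors(self):
        records = generate_feature_separable_set(20, separation=1.0, seed=0)
        y = [1 if r.label == "active" else 0 for r in records]
        est = ConsensusClassifier(n_members=2)
        with pytest.raises(ValueError):
            cross_validate(est, records, y, k=1)
        with pytest.raises(ValueError):
            cross_validate(est, records, y, k=21)

    def test_degenerate_labels_rejected(self):
        records = generate_feature_separable_set(20, separation=1.0, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            ConsensusClassifier(n_members=2).fit(records, np.ones(20, dtype=int))

    def test_ad_gate_forces_inconclusive(self, separable_model):
        records, y, model = separable_model
        strict = load_model_roundtrip(model)
        strict.ad_threshold_ = -1.0  # nothing is in-domain
        details = strict.predict_detail(records[:10])
        assert all(d.call == "Inconclusive" for d in details)

    def test_in_domain_calls_follow_threshold(self, separable_model):
        records, y, model = separable_model
        for d in model.predict_detail(records):
            if d.in_domain:
                expected = "Active" if d.y_mean >= 0.5 else "Inactive"
                assert d.call == expected
            else:
                assert d.call == "Inconclusive"

    def test_unparsable_molecule_is_inconclusive_with_reason(self, separable_model):
        _, _, model = separable_model
        detail = model.predict_detail(["this_is_not_smiles"])[0]
        assert detail.call == "Inconclusive"
        assert "featurization" in detail.reason

    def test_serialization_round_trip_preserves_predictions(
            self, separable_model, tmp_path):
        records, y, model = separable_model
        path = tmp_path / "model.bin"
        save_model(model, path)
        again = load_model(path)
        assert np.array_equal(model.predict_proba(records),
                              again.predict_proba(records))
        assert again.ad_threshold_ == model.ad_threshold_

    def test_greedy_selection_keeps_at_least_two_members(self):
        records = generate_feature_separable_set(80, separation=1.0, seed=3)
        y = np.array([1 if r.label == "active" else 0 for r in records])
        model = ConsensusClassifier(greedy_selection=True, random_state=0)
        model.fit(records, y)
        assert len(model.base_models_) >= 2

    def test_planted_fragment_recovery_sen_spe(self):
        # actives defined by planted alert substructures: the consensus must
        # recognize held-out actives and inactives well at n=400, zero noise
        from respiscreen.synthetic import GeneratorConfig, generate_dataset

        sens, spes = [], []
        for seed in range(10):
            records, _ = generate_dataset(GeneratorConfig(
                n_active=200, n_inactive=200, motifs_per_dataset=3, seed=seed))
            y = np.array([1 if r.label == "active" else 0 for r in records])
            plan = split_train_test(range(len(records)), y, seed=seed)
            model = ConsensusClassifier(n_members=4, random_state=seed)
            model.fit([records[i] for i in plan.train_ids], y[plan.train_ids])
            scores = model.predict_proba(
                [records[i] for i in plan.test_ids])[:, 1]
            report = metrics_from_scores(y[plan.test_ids], scores)
            sens.append(report.sen)
            spes.append(report.spe)
        assert all(s > 0.8 for s in sens), sens
        assert all(s > 0.8 for s in spes), spes


def load_model_roundtrip(model):
    import copy

    return copy.deepcopy(model)
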