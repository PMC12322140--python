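import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from oncofusion import (
    Cohort,
    ModelConfig,
    SimConfig,
    build_recurrence_labels,
    build_survival_labels,
    evaluate_protocol,
    fit_predict,
    generate_cohort,
    site_holdout_split,
    smote_resample,
)
from oncofusion.gasplit import SplitResult
from conftest import make_record


class TestRecurrenceLabels:
    def test_early_recurrence_positive(self):
        cohort = Cohort([make_record(recurrence_days=400)])
        assert build_recurrence_labels(cohort).states["0001"] == "positive"

    def test_no_recurrence_long_followup_negative(self):
        cohort = Cohort([make_record(recurrence_days=None, followup_days=1500)])
        assert build_recurrence_labels(cohort).states["0001"] == "negative"

    def test_short_followup_excluded(self):
        cohort = Cohort([make_record(recurrence_days=None, followup_days=700)])
        labels = build_recurrence_labels(cohort)
        assert labels.states["0001"] == "excluded"
        assert "follow-up" in labels.reasons["0001"]

    def test_late_recurrence_excluded(self):
        cohort = Cohort([make_record(recurrence_days=1300, followup_days=2000)])
        assert build_recurrence_labels(cohort).states["0001"] == "excluded"

    def test_boundary_day_1095_positive(self):
        cohort = Cohort([make_record(recurrence_days=1095)])
        assert build_recurrence_labels(cohort).states["0001"] == "positive"

    def test_early_death_without_recurrence_excluded(self):
        cohort = Cohort([make_record(recurrence_days=None, death_days=500,
                                     death_tumor_specific=True, followup_days=500)])
        assert build_recurrence_labels(cohort).states["0001"] == "excluded"


class TestSurvivalLabels:
    def test_tumor_specific_death_positive(self):
        cohort = Cohort([make_record(death_days=900, death_tumor_specific=True,
                                     followup_days=900)])
        assert build_survival_labels(cohort).states["0001"] == "positive"

    def test_unknown_cause_death_positive(self):
        cohort = Cohort([make_record(death_days=900, death_tumor_specific=None,
                                     followup_days=900)])
        assert build_survival_labels(cohort).states["0001"] == "positive"

    def test_alive_negative(self):
        cohort = Cohort([make_record()])
        assert build_survival_labels(cohort).states["0001"] == "negative"

    def test_non_tumor_death_excluded(self):
        cohort = Cohort([make_record(death_days=900, death_tumor_specific=False,
                                     followup_days=900)])
        labels = build_survival_labels(cohort)
        assert labels.states["0001"] == "excluded"

    def test_every_patient_gets_exactly_one_state(self, small_cohort):
        for build in (build_recurrence_labels, build_survival_labels):
            labels = build(small_cohort)
            assert set(labels.states) == set(small_cohort.patient_ids)
            assert set(labels.states.values()) <= {"positive", "negative", "excluded"}


class TestSmote:
    def test_classes_balanced_after_resampling(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        y = np.array([0] * 50 + [1] * 10)
        Xb, yb = smote_resample(X, y, seed=1)
        counts = np.bincount(yb)
        assert counts[0] == counts[1] == 50

    def test_synthetic_points_interpolate_minority(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, size=(40, 3)),
                       rng.normal(10, 0.5, size=(8, 3))])
        y = np.array([0] * 40 + [1] * 8)
        Xb, yb = smote_resample(X, y, seed=1)
        synth = Xb[48:]
        assert (synth.mean(axis=0) > 5).all()  # lies in the minority region

    def test_neighbor_reduction_for_tiny_minority(self):
        X = np.vstack([np.zeros((10, 2)), np.ones((3, 2))])
        y = np.array([0] * 10 + [1] * 3)
        with pytest.warns(UserWarning, match="reduced"):
            Xb, yb = smote_resample(X, y, seed=0, k=5)
        assert np.bincount(yb)[1] == 10

    def test_already_balanced_unchanged(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        y = np.array([0, 0, 1, 1])
        Xb, yb = smote_resample(X, y, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            smote_resample(np.zeros((4, 2)), np.zeros(4, int), seed=0)


def _separable_cohorts(n=200, seed=0):
    """Cohort where recurrence is a deterministic function of CD3 density."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        positive = i % 2 == 0
        dens = 1000.0 + rng.normal(0, 30) if positive else 100.0 + rng.normal(0, 30)
        recs.append(make_record(
            f"{i + 1:04d}",
            tma_density={"CD3_tumor_center": max(dens, 1.0),
                         "CD3_invasion_front": 150.0,
                         "CD8_tumor_center": 150.0,
                         "CD8_invasion_front": 150.0},
            recurrence_days=300 if positive else None,
            followup_days=2000,
        ))
    return Cohort(recs)


class TestFitPredict:
    def test_linearly_separable_task_reaches_auc_one(self):
        cohort = _separable_cohorts(n=400)
        labels = build_recurrence_labels(cohort)
        ids = cohort.patient_ids
        train = cohort.subset(ids[:300])
        test = cohort.subset(ids[300:])
        y_tr = labels.label_array(train.patient_ids).astype(int)
        y_te = labels.label_array(test.patient_ids).astype(int)
        scores = fit_predict(train, y_tr, test,
                             config=ModelConfig(n_estimators=100), seed=0)
        assert roc_auc_score(y_te, scores) == 1.0

    def test_permuted_labels_give_chance_auc(self):
        """Null check: random labels, 20 repeats, mean AUC in 0.5 +/- 0.1."""
        cohort = generate_cohort(SimConfig(n_patients=150, seed=5))
        ids = cohort.patient_ids
        train, test = cohort.subset(ids[:100]), cohort.subset(ids[100:])
        rng = np.random.default_rng(7)
        aucs = []
        for r in range(20):
            y_tr = rng.integers(0, 2, size=len(train))
            y_te = rng.integers(0, 2, size=len(test))
            if y_tr.min() == y_tr.max() or y_te.min() == y_te.max():
                continue
            scores = fit_predict(train, y_tr, test,
                                 config=ModelConfig(n_estimators=50), seed=r)
            aucs.append(roc_auc_score(y_te, scores))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_training_rejected(self, small_cohort):
        ids = small_cohort.patient_ids
        train, test = small_cohort.subset(ids[:40]), small_cohort.subset(ids[40:])
        with pytest.raises(ValueError):
            fit_predict(train, np.zeros(len(train), int), test, seed=0)

    def test_no_leakage_from_test_rows(self, small_cohort):
        """Perturbing one test patient leaves every other test patient's
        score unchanged: preprocessing is fitted on training data only."""
        import copy
        ids = small_cohort.patient_ids
        train, test = small_cohort.subset(ids[:50]), small_cohort.subset(ids[50:])
        labels = build_survival_labels(small_cohort)
        y_tr = np.nan_to_num(labels.label_array(train.patient_ids)).astype(int)
        base = fit_predict(train, y_tr, test, config=ModelConfig(n_estimators=50), seed=3)
        perturbed = copy.deepcopy(test)
        victim = perturbed.records[0]
        for entry in victim.blood.values():
            entry["value"] = 9999.0
        victim.tma_density = {k: 9999.0 for k in victim.tma_density}
        after = fit_predict(train, y_tr, perturbed,
                            config=ModelConfig(n_estimators=50), seed=3)
        assert np.array_equal(base[1:], after[1:])

    def test_deterministic_under_seed(self, small_cohort):
        ids = small_cohort.patient_ids
        train, test = small_cohort.subset(ids[:50]), small_cohort.subset(ids[50:])
        labels = build_survival_labels(small_cohort)
        y_tr = np.nan_to_num(labels.label_array(train.patient_ids)).astype(int)
        a = fit_predict(train, y_tr, test, config=ModelConfig(n_estimators=50), seed=3)
        b = fit_predict(train, y_tr, test, config=ModelConfig(n_estimators=50), seed=3)
        assert np.array_equal(a, b)


class TestSiteHoldout:
    def test_holdout_site_in_test_only(self, small_cohort):
        res = site_holdout_split(small_cohort, "oropharynx")
        sites = {r.patient_id: r.primary_site for r in small_cohort}
        assert all(sites[p] == "oropharynx" for p in res.test_ids)
        assert all(sites[p] != "oropharynx" for p in res.train_ids)
        assert sorted(res.train_ids + res.test_ids) == small_cohort.patient_ids

    def test_absent_site_rejected(self):
        cohort = Cohort([make_record("0001", primary_site="larynx")])
        with pytest.raises(ValueError):
            site_holdout_split(cohort, "cup")


@pytest.fixture(scope="module")
def cohort_and_split():
    cohort = generate_cohort(SimConfig(n_patients=150, seed=17))
    ids = cohort.patient_ids
    split = SplitResult(train_ids=ids[:110], test_ids=ids[110:],
                        best_fitness=0.0, fitness_trace=[])
    return cohort, split


class TestEvaluateProtocol:

    def test_five_aucs_per_cell(self, cohort_and_split):
        cohort, split = cohort_and_split
        rep = evaluate_protocol(cohort, {"random": split}, tasks=("recurrence",),
                                repeats=5, seed=0,
                                config=ModelConfig(n_estimators=50))
        report = rep[("random", "recurrence")]
        assert len(report.aucs) == 5
        assert all(0.0 <= a <= 1.0 for a in report.aucs)
        assert report.fpr_grid.size == report.mean_tpr.size == 101

    def test_identical_seeds_identical_report(self, cohort_and_split):
        cohort, split = cohort_and_split
        kw = dict(tasks=("survival",), repeats=2, seed=4,
                  config=ModelConfig(n_estimators=50))
        a = evaluate_protocol(cohort, {"s": split}, **kw)[("s", "survival")]
        b = evaluate_protocol(cohort, {"s": split}, **kw)[("s", "survival")]
        assert a.aucs == b.aucs
        assert np.array_equal(a.mean_tpr, b.mean_tpr)

    def test_unknown_ids_rejected(self, cohort_and_split):
        cohort, _ = cohort_and_split
        bad = SplitResult(train_ids=["9999"], test_ids=cohort.patient_ids[:5],
                          best_fitness=0.0, fitness_trace=[])
        with pytest.raises(ValueError):
            evaluate_protocol(cohort, {"bad": bad}, tasks=("recurrence",),
                              repeats=1, seed=0)
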