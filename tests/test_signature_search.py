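"""Dichotomization, linear-SVM signatures, filtration cascade and survival."""

import numpy as np
import pandas as pd
import pytest

from mircore.signature_search import (
    BREAST_SCHEME,
    COLORECTAL_SCHEME,
    RECURRED,
    RECURRENCE_FREE,
    UNKNOWN,
    CohortDataset,
    DichotomizationScheme,
    LabeledCohort,
    cross_validate,
    dichotomize,
    evaluate,
    exhaustive_search,
    fit_signature,
    km_logrank,
    read_cohort,
    risk_scores,
)


def make_cohort(rows, genes=("A", "B", "C"), role="training"):
    """rows: list of (status, time, expression tuple)."""
    idx = pd.Index([f"P{i}" for i in range(len(rows))], name="patient_id")
    return CohortDataset(
        expression=pd.DataFrame([r[2] for r in rows], index=idx, columns=list(genes)),
        status=pd.Series([r[0] for r in rows], index=idx),
        time_months=pd.Series([float(r[1]) for r in rows], index=idx),
        role=role,
    )


def separable_cohort(n_per_class=20, gap=6.0, seed=0, role="training"):
    """Two well-separated 3-gene clusters: events high, controls low."""
    rng = np.random.default_rng(seed)
    events = rng.normal(gap, 1.0, size=(n_per_class, 3))
    controls = rng.normal(0.0, 1.0, size=(n_per_class, 3))
    x = np.vstack([events, controls])
    idx = pd.Index([f"P{i}" for i in range(2 * n_per_class)], name="patient_id")
    return LabeledCohort(
        expression=pd.DataFrame(x, index=idx, columns=["A", "B", "C"]),
        event=pd.Series([True] * n_per_class + [False] * n_per_class, index=idx),
        role=role,
    )


class TestDichotomize:
    def test_colorectal_scheme_window_cases(self):
        cohort = make_cohort(
            [
                (RECURRED, 20, (0, 0, 0)),       # event: recurrence within 3 years
                (RECURRENCE_FREE, 50, (0, 0, 0)),  # control: follow-up >= 4 years
                (RECURRENCE_FREE, 40, (0, 0, 0)),  # grey zone: short follow-up
                (RECURRED, 0.5, (0, 0, 0)),       # first-month recurrence excluded
                (UNKNOWN, 70, (0, 0, 0)),         # unknown status excluded
                (RECURRED, 40, (0, 0, 0)),        # late recurrence: grey zone
            ]
        )
        labeled = dichotomize(cohort, COLORECTAL_SCHEME)
        assert labeled.n_events == 1 and labeled.n_controls == 1
        assert labeled.exclusions == {"unknown_status": 1, "early_event": 1, "grey_zone": 2}

    def test_breast_scheme_horizons(self):
        cohort = make_cohort(
            [
                (RECURRED, 59, (0, 0, 0)),
                (RECURRED, 61, (0, 0, 0)),
                (RECURRENCE_FREE, 85, (0, 0, 0)),
                (RECURRENCE_FREE, 83, (0, 0, 0)),
            ]
        )
        labeled = dichotomize(cohort, BREAST_SCHEME)
        assert labeled.n_events == 1 and labeled.n_controls == 1

    def test_empty_class_raises(self):
        cohort = make_cohort([(RECURRED, 20, (0, 0, 0)), (RECURRED, 22, (0, 0, 0))])
        with pytest.raises(ValueError, match="control"):
            dichotomize(cohort, COLORECTAL_SCHEME)

    def test_scheme_constraints(self):
        with pytest.raises(ValueError):
            DichotomizationScheme(48.0, 36.0)


class TestFitSignature:
    def test_separable_toy_perfect_training_metrics(self):
        cohort = separable_cohort()
        sig = fit_signature(cohort, ["A", "B", "C"])
        ev = evaluate(sig, cohort)
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0 and ev.auc == 1.0

    def test_scaling_contract_mean_zero_sd_one(self):
        cohort = separable_cohort(seed=3)
        sig = fit_signature(cohort, ["A", "B"])
        x = cohort.expression[["A", "B"]].to_numpy()
        z = (x - np.asarray(sig.scale_means)) / np.asarray(sig.scale_sds)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_gene_rejected(self):
        cohort = separable_cohort(seed=1)
        flat = LabeledCohort(
            expression=cohort.expression.assign(A=1.0),
            event=cohort.event,
        )
        with pytest.raises(ValueError, match="zero training variance"):
            fit_signature(flat, ["A", "B"])

    def test_boundary_score_zero_is_high_risk(self):
        from mircore.signature_search import LinearSignature

        # a signature and a patient giving R exactly 0 in float arithmetic
        sig = LinearSignature(
            genes=("A",), scale_means=(0.0,), scale_sds=(1.0,), weights=(1.0,), offset=2.0
        )
        row = pd.DataFrame({"A": [2.0]}, index=pd.Index(["Pz"]))
        r = float(risk_scores(sig, row).iloc[0])
        assert r == 0.0
        # a boundary patient of the event class counts as detected
        boundary = LabeledCohort(expression=row, event=pd.Series([True], index=row.index))
        assert evaluate(sig, boundary).sensitivity == 1.0

    def test_minority_duplication_keeps_boundary_on_symmetric_toy(self):
        # symmetric separable clusters; balanced class weights neutralise the
        # duplication of every minority patient
        base = separable_cohort(n_per_class=15, gap=8.0, seed=4)
        minority = base.expression[base.event]
        dup = LabeledCohort(
            expression=pd.concat([base.expression, minority], axis=0, ignore_index=True),
            event=pd.Series([*base.event.tolist(), *[True] * len(minority)]),
        )
        sig_base = fit_signature(base, ["A", "B", "C"])
        sig_dup = fit_signature(dup, ["A", "B", "C"])
        grid = base.expression
        assert (
            (risk_scores(sig_base, grid) >= 0) == (risk_scores(sig_dup, grid) >= 0)
        ).all()


class TestEvaluate:
    def test_constant_scores_give_auc_half(self):
        cohort = separable_cohort(seed=5)
        from mircore.signature_search import LinearSignature

        sig = LinearSignature(
            genes=("A",), scale_means=(0.0,), scale_sds=(1.0,), weights=(0.0,), offset=0.0
        )
        ev = evaluate(sig, cohort)
        assert ev.auc == 0.5

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        y = pd.Series(rng.random(80) < 0.5)
        scores = pd.Series(rng.normal(size=80) + y * 0.8)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, scores) == pytest.approx(
            roc_auc_score(y, np.exp(scores)), abs=1e-12
        )

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.normal(size=(n, 1))
        y = rng.random(n) < 0.5
        cohort = LabeledCohort(
            expression=pd.DataFrame(x, columns=["A"]),
            event=pd.Series(y),
        )
        sig = fit_signature(cohort, ["A"])
        ev = evaluate(sig, cohort)
        assert 0.45 <= ev.auc <= 0.55


class TestExhaustiveSearch:
    def test_single_candidate_when_universe_equals_size(self):
        train = separable_cohort(seed=8)
        res = exhaustive_search(train, [], ["A", "B", "C"], set_size=3)
        assert len(res) == 1 and res[0].genes == ("A", "B", "C")

    def test_result_invariant_to_universe_order(self):
        train = separable_cohort(seed=9)
        filt = separable_cohort(seed=10, role="filtration")
        res1 = exhaustive_search(train, [filt], ["A", "B", "C"], set_size=2)
        res2 = exhaustive_search(train, [filt], ["C", "A", "B"], set_size=2)
        assert [e.genes for e in res1] == [e.genes for e in res2]
        assert [e.mean_auc for e in res1] == [e.mean_auc for e in res2]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty gene universe"):
            exhaustive_search(separable_cohort(), [], [], set_size=1)

    def test_filtration_threshold_filters(self):
        train = separable_cohort(seed=11)
        # filtration cohort with labels flipped: the classifier must fail there
        flipped = LabeledCohort(
            expression=train.expression, event=~train.event, role="filtration"
        )
        assert exhaustive_search(train, [flipped], ["A", "B", "C"], set_size=3) == []


class TestScalingLeakage:
    def test_scaler_ignores_validation_data(self):
        train = separable_cohort(seed=12)
        sig = fit_signature(train, ["A", "B", "C"])
        val = separable_cohort(seed=13, role="validation")
        perturbed = LabeledCohort(
            expression=val.expression * 10 + 7, event=val.event, role="validation"
        )
        sig_again = fit_signature(train, ["A", "B", "C"])
        assert sig == sig_again  # fitting is a pure function of training data
        # scores on validation use training scaling only
        r1 = risk_scores(sig, val.expression)
        r2 = risk_scores(sig, perturbed.expression)
        assert not np.allclose(r1, r2)  # data changed, scores follow
        assert sig.scale_means == sig_again.scale_means


class TestKmLogrank:
    def test_identical_groups_p_one(self):
        t = [5.0, 10.0, 15.0, 20.0]
        e = [True, False, True, False]
        p, curves = km_logrank(t, e, t, e)
        assert p == pytest.approx(1.0)
        assert curves["group_a"] == curves["group_b"]

    def test_strong_hazard_separation_significant(self):
        rng = np.random.default_rng(14)
        fast = rng.exponential(10.0, size=200)
        slow = rng.exponential(50.0, size=200)
        p, _ = km_logrank(fast, np.ones(200, bool), slow, np.ones(200, bool))
        assert p < 0.001

    def test_matches_hand_computed_statistic(self):
        # fully observed samples; log-rank computed from first principles
        time_a = np.array([1.0, 3.0, 5.0])
        time_b = np.array([2.0, 4.0, 6.0])
        all_times = np.sort(np.concatenate([time_a, time_b]))
        observed_a = expected_a = variance = 0.0
        for t in all_times:
            na = (time_a >= t).sum()
            nb = (time_b >= t).sum()
            n = na + nb
            d = 1  # one event at each distinct time
            observed_a += (t in time_a)
            expected_a += d * na / n
            variance += d * (na / n) * (nb / n) * (n - d) / (n - 1) if n > 1 else 0.0
        chi2 = (observed_a - expected_a) ** 2 / variance
        from scipy import stats

        expected_p = stats.chi2.sf(chi2, df=1)
        p, _ = km_logrank(time_a, [True] * 3, time_b, [True] * 3)
        assert p == pytest.approx(expected_p, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([], [], [1.0], [True])


class TestCrossValidate:
    def test_separable_toy_perfect_in_every_fold(self):
        cohort = separable_cohort(n_per_class=15, seed=15)
        evals = cross_validate(cohort, ["A", "B", "C"], folds=3)
        assert len(evals) == 3
        assert all(e.sensitivity == 1.0 and e.specificity == 1.0 for e in evals)

    def test_leave_one_out_yields_n_evaluations(self):
        cohort = separable_cohort(n_per_class=5, seed=16)
        evals = cross_validate(cohort, ["A", "B"], folds=10)
        assert len(evals) == 10

    def test_class_smaller_than_folds_rejected(self):
        cohort = separable_cohort(n_per_class=4, seed=17)
        with pytest.raises(ValueError, match="smaller than the number of folds"):
            cross_validate(cohort, ["A"], folds=5)

    def test_fold_assignment_is_seeded(self):
        cohort = separable_cohort(seed=18)
        a = cross_validate(cohort, ["A", "B"], folds=4, seed=1)
        b = cross_validate(cohort, ["A", "B"], folds=4, seed=1)
        assert a == b


def test_cohort_reader_round_trip(tmp_path):
    cohort = make_cohort(
        [(RECURRED, 12, (0.1, 0.2, 0.3)), (RECURRENCE_FREE, 60, (1.0, 2.0, 3.0))]
    )
    path = tmp_path / "cohort.tsv"
    from mircore.synthetic_data import write_cohort_table

    write_cohort_table(cohort, path)
    loaded = read_cohort(path, "training")
    assert list(loaded.expression.columns) == ["A", "B", "C"]
    assert loaded.status.tolist() == [RECURRED, RECURRENCE_FREE]
    assert np.allclose(loaded.expression.to_numpy(), cohort.expression.to_numpy())
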