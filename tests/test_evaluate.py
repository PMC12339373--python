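"""Evaluation harness: CV partitioning, permutation machinery, band
comparison, transfer path, GAM associations, stratification, chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurofuse.evaluate import (
    EvalConfig,
    associate_clinical,
    chi_square_yates,
    compare_bands,
    compare_correlations,
    cross_validate,
    permutation_pvalue,
    permutation_test,
    pooled_r2,
    stratified_folds,
    stratify_patients,
    train_transfer_model,
    transfer_predict,
    _augment_training_set,
)
from neurofuse.model import FusionDataset, fast_model_config, latent_pairs, train_model
from neurofuse.synth import fast_config, gen_connectivity_cohort


class TestPooledR2:
    def test_perfect_predictor(self, rng):
        y = rng.normal(size=50)
        assert pooled_r2(y, y) == pytest.approx(1.0)
        r, _ = stats.pearsonr(y, y)
        assert r == pytest.approx(1.0)

    def test_mean_predictor_is_zero(self, rng):
        y = rng.normal(size=50)
        assert pooled_r2(y, np.full(50, y.mean())) == pytest.approx(0.0)


class TestFolds:
    def test_partition_is_disjoint_and_complete(self, rng):
        y = rng.normal(size=57)
        folds = stratified_folds(y, 10, seed=3)
        assert folds.shape == (57,)
        assert set(folds) == set(range(10))
        assert np.bincount(folds).min() >= 2

    def test_stratification_spans_outcome_range(self, rng):
        y = np.arange(100.0)
        folds = stratified_folds(y, 10, seed=0)
        for k in range(10):
            vals = y[folds == k]
            assert vals.min() < 20 and vals.max() > 80

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            stratified_folds(np.arange(15.0), 10, seed=0)


class TestAugmentationGuard:
    def test_augmented_samples_flagged_and_training_only(self, small_dataset):
        aug = _augment_training_set(small_dataset, (1, 2))
        assert len(aug) == 3 * len(small_dataset)
        assert aug.is_augmented.sum() == 2 * len(small_dataset)
        assert not aug.is_augmented[: len(small_dataset)].any()

    def test_cross_validation_never_tests_on_augmented(self, small_dataset):
        # out-of-fold predictions exist for exactly the real subjects
        cfg = EvalConfig(model=fast_model_config(20, epochs=4), n_folds=5, augment=True)
        run = cross_validate(small_dataset, cfg, [0])[0]
        assert len(run.y_pred) == len(small_dataset)
        assert set(run.fold_assignments) == set(range(5))


class TestCrossValidation:
    def test_ridge_backend_learns_planted_signal(self, fast_dataset):
        cfg = EvalConfig(backend="ridge", augment=False)
        run = cross_validate(fast_dataset, cfg, [0])[0]
        assert run.r2 > 0.3
        assert run.pearson_r > 0.6

    def test_shuffled_labels_center_r2_at_or_below_zero(self, small_dataset, rng):
        shuffled = FusionDataset(
            small_dataset.batch["fmri"]["x"], small_dataset.batch["fmri"]["a"],
            small_dataset.batch["eeg"]["x"], small_dataset.batch["eeg"]["a"],
            rng.permutation(small_dataset.labels), small_dataset.subject_ids,
        )
        cfg = EvalConfig(backend="ridge", augment=False, n_folds=5)
        r2s = [cross_validate(shuffled, cfg, [s])[0].r2 for s in range(10)]
        assert np.mean(r2s) <= 0.05


class TestPermutation:
    def test_pvalue_formula_bounds(self):
        null = np.linspace(0, 1, 999)
        assert permutation_pvalue(null, 2.0) == pytest.approx(1 / 1000)
        assert permutation_pvalue(null, -1.0) == 1.0

    def test_pvalue_monotone_in_observed(self, rng):
        null = rng.normal(size=200)
        ps = [permutation_pvalue(null, o) for o in np.linspace(-3, 3, 10)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_minimum_permutation_count_enforced(self, small_dataset):
        cfg = EvalConfig(backend="ridge", augment=False)
        with pytest.raises(ValueError, match="100"):
            permutation_test(small_dataset, cfg, b=10)

    def test_planted_signal_detected(self, fast_dataset):
        cfg = EvalConfig(backend="ridge", augment=False)
        p, null, obs = permutation_test(fast_dataset, cfg, b=100, seed=0)
        assert p <= 0.02
        assert obs.pearson_r > null["r"].max()


class TestBandComparison:
    def _runs(self, r2s):
        from neurofuse.evaluate import CvRunResult

        return [
            CvRunResult(i, np.zeros(1, int), np.zeros(1), np.zeros(1), r2, 0.0, 1.0)
            for i, r2 in enumerate(r2s)
        ]

    def test_identical_vectors_give_t0_p1(self):
        runs = {"alpha": self._runs([0.3, 0.25, 0.2]), "beta": self._runs([0.3, 0.25, 0.2])}
        table = compare_bands(runs)
        assert table.loc[0, "t"] == 0.0
        assert table.loc[0, "p"] == 1.0

    def test_degenerate_constant_shift_flags_p0(self):
        runs = {"alpha": self._runs([0.3, 0.4, 0.5]), "theta": self._runs([0.2, 0.3, 0.4])}
        table = compare_bands(runs)
        assert table.loc[0, "p"] == 0.0

    def test_matches_textbook_paired_t(self, rng):
        a = rng.normal(0.3, 0.05, size=10)
        b = rng.normal(0.25, 0.05, size=10)
        table = compare_bands({"alpha": self._runs(a), "gamma": self._runs(b)})
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert table.loc[0, "t"] == pytest.approx(t_expect, abs=1e-8)
        p_expect = 2 * stats.t.sf(abs(t_expect), df=9)
        assert table.loc[0, "p"] == pytest.approx(p_expect, abs=1e-8)

    def test_unequal_run_counts_rejected(self):
        runs = {"alpha": self._runs([0.3, 0.2]), "beta": self._runs([0.3])}
        with pytest.raises(ValueError, match="unequal"):
            compare_bands(runs)


class TestTransfer:
    @pytest.fixture(scope="class")
    def trained(self, small_dataset):
        params = train_model(small_dataset, fast_model_config(20, epochs=20), seed=1)
        tm = train_transfer_model(params, small_dataset, seed=1, epochs=100)
        return params, tm

    def test_identical_latents_give_identical_branch_predictions(self, small_dataset, trained):
        params, tm = trained
        # force both branches to produce the same latent
        forced = params.copy()
        for key in ("W1", "b1", "W2", "b2"):
            forced.gnn["eeg"][key] = forced.gnn["fmri"][key].copy()
        forced.scale["eeg"] = forced.scale["fmri"].copy()
        forced.proj["eeg"] = forced.proj["fmri"].copy()
        same = FusionDataset(
            small_dataset.batch["fmri"]["x"], small_dataset.batch["fmri"]["a"],
            small_dataset.batch["fmri"]["x"], small_dataset.batch["fmri"]["a"],
            small_dataset.labels, small_dataset.subject_ids,
        )
        pf = transfer_predict(tm, forced, same, "fmri")
        pe = transfer_predict(tm, forced, same, "eeg")
        assert np.array_equal(pf, pe)

    def test_deterministic_under_fixed_seed(self, small_dataset, trained):
        params, _ = trained
        tm1 = train_transfer_model(params, small_dataset, seed=9, epochs=50)
        tm2 = train_transfer_model(params, small_dataset, seed=9, epochs=50)
        p1 = transfer_predict(tm1, params, small_dataset, "eeg")
        p2 = transfer_predict(tm2, params, small_dataset, "eeg")
        assert np.array_equal(p1, p2)

    def test_unknown_modality_rejected(self, small_dataset, trained):
        params, tm = trained
        with pytest.raises(ValueError, match="modality"):
            transfer_predict(tm, params, small_dataset, "meg")


class TestClinicalAssociation:
    def test_linear_scale_recovered(self, rng):
        latents = rng.normal(size=(100, 4))
        scales = {"target": 2.0 * latents[:, 1] + 0.5}
        table = associate_clinical(latents, scales, seed=0)
        assert table.loc[0, "r"] > 0.95

    def test_independent_scale_not_significant(self, rng):
        latents = rng.normal(size=(100, 4))
        scales = {"noise": rng.normal(size=100)}
        table = associate_clinical(latents, scales, seed=0)
        assert abs(table.loc[0, "r"]) < 0.3

    def test_constant_scale_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            associate_clinical(rng.normal(size=(50, 2)), {"flat": np.ones(50)})


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations(0.4, 100, 0.4, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_value(self):
        # (atanh 0.58 - atanh 0.18) / sqrt(2/127)
        z, p = compare_correlations(0.58, 130, 0.18, 130)
        expect = (np.arctanh(0.58) - np.arctanh(0.18)) / np.sqrt(2 / 127)
        assert z == pytest.approx(expect, abs=1e-8)
        assert round(z, 2) == 3.83
        assert p < 0.001

    def test_antisymmetry(self):
        z1, _ = compare_correlations(0.5, 80, 0.2, 90)
        z2, _ = compare_correlations(0.2, 90, 0.5, 80)
        assert z1 == pytest.approx(-z2)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n > 3"):
            compare_correlations(0.5, 3, 0.2, 50)


class TestChiSquare:
    def test_reference_tables(self):
        chi2_s, p_s = chi_square_yates([[57, 42], [1, 30]])
        chi2_p, p_p = chi_square_yates([[30, 21], [12, 72]])
        assert round(chi2_s, 1) == 26.1
        assert round(chi2_p, 1) == 27.3
        assert p_s < 1e-4 and p_p < 1e-4

    def test_balanced_table_is_zero(self):
        chi2, p = chi_square_yates([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_scipy_and_bounded_by_uncorrected(self, rng):
        for _ in range(200):
            t = rng.integers(1, 40, size=(2, 2))
            chi2, p = chi_square_yates(t)
            ref = stats.chi2_contingency(t, correction=True)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            unc = stats.chi2_contingency(t, correction=False)
            assert chi2 <= unc.statistic + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_yates([[0, 0], [5, 3]])


class TestStratification:
    def _frame(self, arms, baseline, week8, ids):
        return pd.DataFrame(
            {"subject_id": ids, "arm": arms, "hamd_baseline": baseline, "hamd_week8": week8}
        )

    def test_planted_arm_effects_align_with_response(self):
        # two cohorts with different planted signatures play the two arms
        c_s = gen_connectivity_cohort(fast_config(seed=31, n_subjects=60))
        c_p = gen_connectivity_cohort(fast_config(seed=32, n_subjects=60,
                                                  planted_rois=tuple(range(10, 20))))
        ds_s = FusionDataset.from_cohort(c_s)
        ds_p = FusionDataset.from_cohort(c_p)
        cfg = fast_model_config(20, epochs=60)
        m_s = train_model(ds_s, cfg, seed=0)
        m_p = train_model(ds_p, cfg, seed=0)

        xs = {k: np.concatenate([ds_s.batch[k]["x"], ds_p.batch[k]["x"]]) for k in ("fmri", "eeg")}
        aas = {k: np.concatenate([ds_s.batch[k]["a"], ds_p.batch[k]["a"]]) for k in ("fmri", "eeg")}
        ids = [f"s{i}" for i in range(120)]
        merged = FusionDataset(xs["fmri"], aas["fmri"], xs["eeg"], aas["eeg"],
                               np.concatenate([c_s.outcomes, c_p.outcomes]), ids)
        frame = self._frame(
            ["sertraline"] * 60 + ["placebo"] * 60,
            np.concatenate([c_s.hamd_baseline, c_p.hamd_baseline]),
            np.concatenate([c_s.hamd_week8, c_p.hamd_week8]),
            ids,
        )
        res = stratify_patients(merged, frame, m_s, m_p)
        assert set(res.preferred) <= {"sertraline", "placebo"}
        for arm in ("sertraline", "placebo"):
            table = res.tables[arm]
            aligned_rate = table[0, 0] / max(table[0].sum(), 1)
            non_rate = table[1, 0] / max(table[1].sum(), 1)
            assert aligned_rate >= non_rate

    def test_tie_goes_to_sertraline(self, small_dataset):
        params = train_model(small_dataset, fast_model_config(20, epochs=3), seed=0)
        frame = self._frame(
            ["sertraline"] * 20 + ["placebo"] * 20,
            np.full(40, 20.0), np.full(40, 8.0), small_dataset.subject_ids,
        )
        res = stratify_patients(small_dataset, frame, params, params)
        assert np.all(res.preferred == "sertraline")

    def test_missing_baseline_rejected(self, small_dataset):
        params = train_model(small_dataset, fast_model_config(20, epochs=2), seed=0)
        frame = self._frame(
            ["sertraline"] * 40, np.full(40, np.nan), np.full(40, 8.0),
            small_dataset.subject_ids,
        )
        with pytest.raises(ValueError, match="baseline"):
            stratify_patients(small_dataset, frame, params, params)

    def test_responder_rule_strictly_greater_than_half(self):
        from neurofuse.io import read_subjects
        import io as _io  # noqa: F401
        # covered in io tests; here check the stratification's own flag
        c = gen_connectivity_cohort(fast_config(seed=33, n_subjects=40))
        ds = FusionDataset.from_cohort(c)
        params = train_model(ds, fast_model_config(20, epochs=2), seed=0)
        baseline = np.full(40, 20.0)
        week8 = np.full(40, 10.0)   # exactly 50% reduction: not a responder
        week8[0] = 9.0              # > 50%: responder
        frame = self._frame(["sertraline"] * 20 + ["placebo"] * 20, baseline, week8,
                            ds.subject_ids)
        res = stratify_patients(ds, frame, params, params)
        assert res.responder[0]
        assert not res.responder[1:].any()
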