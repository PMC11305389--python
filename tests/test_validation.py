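import numpy as np
import pandas as pd
import pytest

from spinemem.validation import (ModelSpec, SingularModelError,
                                 _loocv_errors, bootstrap_mse_ci,
                                 compare_models, default_model_specs,
                                 loocv_evaluate, reports_frame)


def toy_table(rng, n=30, noise=0.5, beta_hd=1.0):
    hd = rng.normal(0.4, 0.05, n)
    np_score = rng.gamma(2.0, 0.5, n)
    nft = rng.gamma(2.0, 0.5, n)
    sex = rng.integers(0, 2, n)
    age = rng.normal(90, 6, n)
    y = (beta_hd * hd - 0.4 * np_score - 0.3 * nft + 0.2 * sex
         + noise * rng.normal(size=n))
    return pd.DataFrame(dict(
        age=age, sex=sex, np_score=np_score, nft_burden=nft,
        mean_density=rng.normal(5, 1, n), mean_length=rng.normal(1.5, .2, n),
        mean_head_diameter=hd, mean_volume=rng.normal(.05, .01, n),
        episodic_memory=y))


SPEC_HD = ModelSpec("ps_hd", ("np_score", "nft_burden", "sex", "head_diameter"))
SPEC_PS = ModelSpec("ps", ("np_score", "nft_burden", "sex"))


class TestLoocv:
    def test_hat_matrix_equals_explicit_refits(self, rng):
        # brute-force oracle: n separate least-squares refits
        for n in (10, 20):
            table = toy_table(rng, n=n)
            rep = loocv_evaluate(table, SPEC_PS)
            cols = SPEC_PS.columns()
            X = np.column_stack([np.ones(n), table[cols].to_numpy()])
            y = table.episodic_memory.to_numpy()
            errs = []
            for i in range(n):
                keep = np.arange(n) != i
                beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
                errs.append(y[i] - X[i] @ beta)
            assert rep.loocv_mse == pytest.approx(np.mean(np.square(errs)),
                                                  abs=1e-10)
            np.testing.assert_allclose(rep.predictions, y - np.array(errs),
                                       atol=1e-10)

    def test_intercept_only_closed_form(self, rng):
        # leave-one-out mean oracle: error_i = y_i - mean(y_-i)
        y = rng.normal(size=12)
        e = _loocv_errors(np.ones((12, 1)), y)
        n = len(y)
        expected = y - (y.sum() - y) / (n - 1)
        np.testing.assert_allclose(e, expected, atol=1e-12)

    def test_noiseless_linear_model_recovered(self, rng):
        table = toy_table(rng, n=40, noise=0.0)
        rep = loocv_evaluate(table, SPEC_HD)
        assert rep.loocv_mse == pytest.approx(0.0, abs=1e-16)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)
        assert rep.pearson_observed_vs_predicted == pytest.approx(1.0, abs=1e-8)

    def test_missing_rows_dropped(self, rng):
        table = toy_table(rng, n=25)
        table.loc[3, "np_score"] = np.nan
        rep = loocv_evaluate(table, SPEC_PS)
        assert rep.n_used == 24

    def test_singular_design_reported(self, rng):
        table = toy_table(rng, n=20)
        table["nft_burden"] = 2.0 * table["np_score"]
        with pytest.raises(SingularModelError):
            loocv_evaluate(table, SPEC_PS)

    def test_report_invariant_to_row_order(self, rng):
        table = toy_table(rng, n=25)
        a = loocv_evaluate(table, SPEC_HD)
        b = loocv_evaluate(table.sample(frac=1.0, random_state=3), SPEC_HD)
        assert a.loocv_mse == pytest.approx(b.loocv_mse, abs=1e-12)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)


class TestCompareModels:
    def test_sorted_ascending_by_mse(self, rng):
        table = toy_table(rng, n=50)
        reports = compare_models(table, default_model_specs())
        mses = [r.loocv_mse for r in reports]
        assert mses == sorted(mses)

    def test_duplicate_spec_identical_reports_stable_order(self, rng):
        table = toy_table(rng, n=40)
        reports = compare_models(table, [SPEC_HD, SPEC_HD])
        assert reports[0].loocv_mse == reports[1].loocv_mse
        assert reports[0].spec.name == reports[1].spec.name

    def test_singular_model_skipped_not_fatal(self, rng):
        table = toy_table(rng, n=40)
        table["mean_volume"] = table["mean_head_diameter"]
        bad = ModelSpec("collinear", ("head_diameter", "volume", "sex"))
        reports = compare_models(table, [bad, SPEC_PS])
        assert [r.spec.name for r in reports] == ["ps"]

    def test_frame_output_columns(self, rng):
        table = toy_table(rng, n=40)
        df = reports_frame(compare_models(table, [SPEC_HD, SPEC_PS]))
        assert {"model", "loocv_mse", "r_squared", "pearson", "n"} <= set(df.columns)

    def test_insample_sse_monotone_but_loocv_can_worsen(self, rng):
        # sanity on the fitter: nesting never hurts in-sample; with junk
        # predictors at small n the LOOCV MSE does get worse
        n = 12
        table = toy_table(rng, n=n)
        small = ModelSpec("small", ("np_score",))
        big = ModelSpec("big", ("np_score", "nft_burden", "sex", "age",
                                "density", "length", "head_diameter",
                                "volume"))
        def sse(spec):
            X = np.column_stack([np.ones(n), table[spec.columns()]])
            y = table.episodic_memory.to_numpy()
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            return np.sum((y - X @ beta) ** 2)
        assert sse(big) <= sse(small) + 1e-10
        assert (loocv_evaluate(table, big).loocv_mse
                > loocv_evaluate(table, small).loocv_mse)


class TestBootstrap:
    def test_deterministic_for_seed(self, rng):
        table = toy_table(rng, n=30)
        a = bootstrap_mse_ci(table, SPEC_PS, B=150, seed=4)
        b = bootstrap_mse_ci(table, SPEC_PS, B=150, seed=4)
        assert a == b

    def test_level_zero_degenerates_to_median(self, rng):
        table = toy_table(rng, n=30)
        lo, hi = bootstrap_mse_ci(table, SPEC_PS, B=151, level=0.0, seed=1)
        assert lo == pytest.approx(hi)

    def test_interval_brackets_point_estimate_and_orders(self, rng):
        table = toy_table(rng, n=40)
        lo, hi = bootstrap_mse_ci(table, SPEC_HD, B=300, level=0.9, seed=2)
        assert lo <= hi
        assert lo > 0

    def test_monte_carlo_stability_when_B_doubles(self, rng):
        table = toy_table(rng, n=40)
        a = bootstrap_mse_ci(table, SPEC_PS, B=400, level=0.8, seed=7)
        b = bootstrap_mse_ci(table, SPEC_PS, B=800, level=0.8, seed=7)
        width = a[1] - a[0]
        assert abs(a[0] - b[0]) < 0.5 * width
        assert abs(a[1] - b[1]) < 0.5 * width

    def test_small_B_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_mse_ci(toy_table(rng), SPEC_PS, B=50)

    def test_coverage_near_nominal(self):
        """Empirical coverage of the expected LOOCV MSE at nominal 90%."""
        def sample(r, n=62):
            return toy_table(r, n=n, noise=0.5)
        truth_rng = np.random.default_rng(900)
        true_mse = np.mean([
            loocv_evaluate(sample(truth_rng), SPEC_PS).loocv_mse
            for _ in range(2000)])
        cover = 0
        outer = 200
        out_rng = np.random.default_rng(901)
        for i in range(outer):
            table = sample(out_rng)
            lo, hi = bootstrap_mse_ci(table, SPEC_PS, B=200, level=0.9,
                                      seed=i)
            cover += lo <= true_mse <= hi
        assert abs(cover / outer - 0.90) <= 0.05
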