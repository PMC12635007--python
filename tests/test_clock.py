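"""Clock math: dCt expression, gene screening, AR/GamC algebra."""

import numpy as np
import pandas as pd
import pytest

from gamclock import (
    DegenerateGeneError,
    ExpressionMatrix,
    GeneFit,
    MissingReferenceGeneError,
    apply_clock,
    delta_ct_expression,
    fit_clock,
    select_age_genes,
    simulate_cohort,
)
from gamclock.simulate import CohortSimSpec


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "gene", "ct"])


class TestDeltaCt:
    def test_definitional_arithmetic(self):
        ct = _ct_table([("s1", "UBE2D2", 20.0), ("s1", "GUSB2", 22.0),
                        ("s1", "TGT", 25.0)])
        expr = delta_ct_expression(ct)
        # dCt = 25 - mean(20, 22) = 4 -> 2**-4
        assert expr.loc["s1", "TGT"] == pytest.approx(0.0625)

    def test_gene_at_reference_level_gives_unity(self):
        ct = _ct_table([("s1", "UBE2D2", 20.0), ("s1", "GUSB2", 22.0),
                        ("s1", "TGT", 21.0)])
        assert delta_ct_expression(ct).loc["s1", "TGT"] == pytest.approx(1.0)

    def test_missing_target_kept_as_missing(self):
        ct = _ct_table([("s1", "UBE2D2", 20.0), ("s1", "GUSB2", 22.0),
                        ("s1", "A", 25.0),
                        ("s2", "UBE2D2", 20.0), ("s2", "GUSB2", 22.0),
                        ("s2", "A", 24.0), ("s2", "B", 26.0)])
        expr = delta_ct_expression(ct)
        assert np.isnan(expr.loc["s1", "B"])
        assert expr.loc["s1", "A"] == pytest.approx(0.0625)

    def test_missing_reference_rejects_subject(self):
        ct = _ct_table([("s1", "UBE2D2", 20.0), ("s1", "A", 25.0)])
        with pytest.raises(MissingReferenceGeneError):
            delta_ct_expression(ct)

    def test_reference_genes_configurable(self):
        ct = _ct_table([("s1", "ACTB", 18.0), ("s1", "TGT", 18.0)])
        expr = delta_ct_expression(ct, reference_genes=("ACTB",))
        assert expr.loc["s1", "TGT"] == pytest.approx(1.0)


class TestGeneSelection:
    def test_weakly_correlated_gene_excluded(self, rng):
        # a NELL2-like gene: independent of age, should not pass P <= 0.05
        n = 85
        ca = pd.Series(rng.uniform(20, 100, n),
                       index=[f"s{i}" for i in range(n)])
        values = pd.DataFrame({
            "LINEAR": 2.0 - 0.01 * ca,
            "NULL": rng.normal(1.0, 0.1, n),
        }, index=ca.index)
        expr = ExpressionMatrix(values=values, ca=ca)
        selected, report = select_age_genes(expr)
        assert "LINEAR" in selected
        assert "NULL" not in selected
        assert report.loc["NULL", "p"] > 0.05

    def test_null_gene_excluded_in_most_replicates(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            ca = pd.Series(r.uniform(20, 100, 50))
            values = pd.DataFrame({"G": r.normal(1.0, 0.1, 50)},
                                  index=ca.index)
            sel, _ = select_age_genes(ExpressionMatrix(values=values, ca=ca))
            if not sel:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_zero_variance_gene_excluded_not_fatal(self, rng):
        ca = pd.Series(rng.uniform(20, 100, 20))
        values = pd.DataFrame({"FLAT": np.ones(20)}, index=ca.index)
        sel, report = select_age_genes(ExpressionMatrix(values=values, ca=ca))
        assert sel == []
        assert np.isnan(report.loc["FLAT", "r"])


def _fit_from_line(slope, intercept, residuals, ca):
    """GeneFit for a stored line; used to exercise the scoring arithmetic."""
    return GeneFit(gene_name="g", slope=slope, intercept=intercept, r=0.0,
                   p=0.0, n=len(ca), sigma=pd.Series(dtype=float))


class TestClockArithmetic:
    def test_single_gene_residual_ratio(self):
        # sigma = -0.05 with slope a = -0.01 -> Delta = 5 years
        ca = pd.Series([50.0], index=["s1"])
        fit = _fit_from_line(-0.01, 2.0, None, ca)
        expr = ExpressionMatrix(
            values=pd.DataFrame({"g": [2.0 - 0.01 * 50.0 - 0.05]},
                                index=ca.index),
            ca=ca)
        res = apply_clock([fit], expr)
        assert res.ar["s1"] == pytest.approx(5.0)
        assert res.gamc["s1"] == pytest.approx(55.0)

    def test_two_genes_average(self):
        ca = pd.Series([50.0], index=["s1"])
        f1 = GeneFit("g1", slope=-0.01, intercept=2.0, r=0, p=0, n=1,
                     sigma=pd.Series(dtype=float))
        f2 = GeneFit("g2", slope=0.02, intercept=1.0, r=0, p=0, n=1,
                     sigma=pd.Series(dtype=float))
        # Delta_g1 = 4, Delta_g2 = 6 -> AR = 5
        expr = ExpressionMatrix(
            values=pd.DataFrame(
                {"g1": [2.0 - 0.01 * 50.0 + (-0.01 * 4.0)],
                 "g2": [1.0 + 0.02 * 50.0 + (0.02 * 6.0)]}, index=ca.index),
            ca=ca)
        res = apply_clock([f1, f2], expr)
        assert res.ar["s1"] == pytest.approx(5.0)

    def test_zero_noise_cohort_perfect_clock(self):
        spec = CohortSimSpec(n_subjects=40, offset_sd=0.0, seed=2,
                             genes=[("G1", 2.0, -0.010, 0.0),
                                    ("G2", 2.5, -0.012, 0.0),
                                    ("G3", 1.8, -0.008, 0.0)])
        expr, _ = simulate_cohort(spec)
        res = fit_clock(expr)
        assert np.allclose(res.ar, 0.0, atol=1e-9)
        assert np.allclose(res.gamc, expr.ca, atol=1e-9)
        assert np.corrcoef(res.gamc, expr.ca)[0, 1] == pytest.approx(1.0)

    def test_offset_recovery_rmse(self, noiseless_cohort):
        expr, offsets = noiseless_cohort
        res = fit_clock(expr)
        rmse = float(np.sqrt(np.mean((res.ar - offsets) ** 2)))
        assert rmse < 0.5

    def test_empty_gene_list_rejected(self, noiseless_cohort):
        with pytest.raises(ValueError):
            fit_clock(noiseless_cohort[0], genes=[])

    def test_flat_gene_rejected_by_slope_guard(self, rng):
        ca = pd.Series(rng.uniform(20, 100, 30))
        values = pd.DataFrame({"FLAT": rng.normal(1.0, 0.1, 30)},
                              index=ca.index)
        # remove the fitted age trend so the OLS slope is exactly zero
        fitted = np.polyval(np.polyfit(ca, values["FLAT"], 1), ca)
        values["FLAT"] = values["FLAT"] - fitted + 1.0
        with pytest.raises(DegenerateGeneError):
            fit_clock(ExpressionMatrix(values=values, ca=ca))


class TestClockInvariants:
    def test_ols_normal_equations(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        res = fit_clock(expr)
        scale = expr.values.abs().mean().mean()
        for f in res.gene_fits:
            assert abs(f.sigma.sum()) < 1e-9 * scale * len(expr.ca)
            assert abs((f.sigma * expr.ca).sum()) < 1e-6 * scale * len(expr.ca)

    def test_ar_orthogonal_to_ca(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        res = fit_clock(expr)
        assert abs(res.ar.mean()) < 1e-8
        assert abs(np.cov(res.ar, expr.ca)[0, 1]) < 1e-6
        slope, intercept = np.polyfit(expr.ca, res.gamc, 1)
        assert slope == pytest.approx(1.0, abs=1e-6)
        assert intercept == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance_of_delta(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        base = fit_clock(expr)
        scaled = ExpressionMatrix(
            values=expr.values.assign(G1=expr.values["G1"] * 37.5),
            ca=expr.ca, source_kind="transcriptomic")
        res = fit_clock(scaled)
        assert np.allclose(res.ar, base.ar, atol=1e-9)

    def test_transcriptomic_source_same_math(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        shifted = ExpressionMatrix(values=expr.values - expr.values.mean(),
                                   ca=expr.ca, source_kind="transcriptomic")
        res = fit_clock(shifted)
        base = fit_clock(expr)
        assert np.allclose(res.ar, base.ar, atol=1e-9)


class TestApplyClock:
    def test_self_consistency(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        fitted = fit_clock(expr)
        reapplied = apply_clock(fitted.gene_fits, expr)
        assert np.allclose(reapplied.ar, fitted.ar, atol=1e-12)

    def test_subject_on_the_line_scores_zero(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        fitted = fit_clock(expr)
        ca_new = pd.Series([42.0], index=["new"])
        values = pd.DataFrame(
            {f.gene_name: [f.intercept + f.slope * 42.0]
             for f in fitted.gene_fits}, index=ca_new.index)
        res = apply_clock(fitted.gene_fits,
                          ExpressionMatrix(values=values, ca=ca_new))
        assert res.ar["new"] == pytest.approx(0.0, abs=1e-12)

    def test_shift_by_ten_slope_units_scores_ten_years(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        fitted = fit_clock(expr)
        ca_new = pd.Series([42.0], index=["new"])
        values = pd.DataFrame(
            {f.gene_name: [f.intercept + f.slope * 42.0 + f.slope * 10.0]
             for f in fitted.gene_fits}, index=ca_new.index)
        res = apply_clock(fitted.gene_fits,
                          ExpressionMatrix(values=values, ca=ca_new))
        assert res.ar["new"] == pytest.approx(10.0)

    def test_missing_model_gene_rejected(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        fitted = fit_clock(expr)
        smaller = ExpressionMatrix(values=expr.values[["G1", "G2"]],
                                   ca=expr.ca)
        with pytest.raises(KeyError):
            apply_clock(fitted.gene_fits, smaller)
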