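"""Normalization, median polish (vs R reference), differential tests, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers_r import HAVE_R

from diaforge.core import SampleAnnotation, ValidationError
from diaforge.quant import (
    PowerSettings,
    bh_adjust,
    calibrate_cv_for_fc,
    differential_test,
    median_polish,
    min_detectable_fc,
    normalize_medians,
    summarize_protein,
)


def _annot(n_per_pop=6, pops=("A", "B", "C", "D"), batches=("PS1",)):
    out = []
    for b in batches:
        for pop in pops:
            for r in range(n_per_pop):
                out.append(SampleAnnotation(f"{b}_{pop}_{r}", pop, b, r + 1))
    return out


class TestNormalization:
    def test_medians_equalized_exactly(self):
        qm = pd.DataFrame({"s1": [8.0, 10.0, 12.0], "s2": [10.0, 12.0, 14.0]})
        out = normalize_medians(qm)
        assert out["s1"].median() == out["s2"].median() == 11.0
        # within-sample differences unchanged
        assert np.allclose(np.diff(out["s1"]), np.diff(qm["s1"]))

    def test_single_sample_unchanged(self):
        qm = pd.DataFrame({"s1": [1.0, 2.0, 3.0]})
        assert normalize_medians(qm).equals(qm)

    def test_equal_medians_identity(self):
        qm = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [0.0, 2.0, 9.0]})
        assert np.allclose(normalize_medians(qm), qm)

    def test_all_missing_column_rejected(self):
        qm = pd.DataFrame({"s1": [1.0, 2.0], "s2": [np.nan, np.nan]})
        with pytest.raises(ValidationError, match="s2"):
            normalize_medians(qm)


class TestMedianPolish:
    def test_two_by_two_hand_example(self):
        rows = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], columns=["s1", "s2"])
        abund = summarize_protein(rows)
        assert abund.tolist() == pytest.approx([2.0, 3.0])

    def test_constant_matrix(self):
        rows = pd.DataFrame(np.full((3, 4), 7.5), columns=list("abcd"))
        assert summarize_protein(rows).tolist() == pytest.approx([7.5] * 4)

    def test_single_row_passthrough(self):
        rows = pd.DataFrame([[1.0, 5.0, 9.0]], columns=list("abc"))
        assert summarize_protein(rows).tolist() == [1.0, 5.0, 9.0]

    def test_missing_values_enter_as_zero(self):
        rows = pd.DataFrame([[np.nan, 4.0]], columns=["s1", "s2"])
        assert summarize_protein(rows).tolist() == [0.0, 4.0]

    @pytest.mark.skipif(not HAVE_R, reason="Rscript not available")
    def test_agrees_with_r_reference_on_random_matrices(self, tmp_path):
        """Cross-check column+overall effects against stats::medpolish on 50 matrices."""
        from helpers_r import max_diff_vs_r_medpolish, random_small_matrices

        mats = random_small_matrices(seed=12, n=50)
        assert max_diff_vs_r_medpolish(mats, tmp_path) < 1e-6


class TestBhAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestDifferentialTest:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(21)
        annot = _annot(n_per_pop=24, batches=("PS1",))
        samples = [a.sample_id for a in annot]
        y = pd.Series(rng.normal(10, 0.2, len(samples)), index=samples)
        y[[a.sample_id for a in annot if a.population == "A"]] += 1.0
        mat = pd.DataFrame([y], index=["prot1"])
        res = differential_test(mat, annot, "A").iloc[0]
        assert abs(res["log2fc"] - 1.0) <= 3 * res["se"]
        assert res["p"] < 0.05

    def test_zero_noise_null(self):
        annot = _annot(n_per_pop=3)
        mat = pd.DataFrame(
            [[5.0] * len(annot)], index=["p"], columns=[a.sample_id for a in annot]
        )
        res = differential_test(mat, annot, "A").iloc[0]
        assert res["log2fc"] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_null_p_uniform(self):
        """Label permutations of a null protein give ~uniform p-values."""
        rng = np.random.default_rng(77)
        annot = _annot(n_per_pop=6)
        samples = [a.sample_id for a in annot]
        y = rng.normal(0, 1, len(samples))
        ps = []
        for _ in range(200):
            perm = rng.permutation(len(samples))
            mat = pd.DataFrame([y[perm]], index=["p"], columns=samples)
            ps.append(differential_test(mat, annot, "A").iloc[0]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_batch_term_in_combined_analysis(self):
        """A pure batch shift must not masquerade as a population effect."""
        annot = _annot(n_per_pop=3, batches=("PS1", "PS2"))
        samples = [a.sample_id for a in annot]
        y = pd.Series(
            [2.0 if a.sampling_batch == "PS2" else 0.0 for a in annot], index=samples
        )
        rng = np.random.default_rng(5)
        y = y + rng.normal(0, 0.05, len(y))
        mat = pd.DataFrame([y], index=["p"])
        res = differential_test(mat, annot, "A", combined=True).iloc[0]
        assert abs(res["log2fc"]) < 0.2

    def test_matches_statsmodels_ols(self):
        """The shared-design solve reproduces a reference OLS fit per protein."""
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        annot = _annot(n_per_pop=4, batches=("PS1", "PS2"))
        samples = [a.sample_id for a in annot]
        mat = pd.DataFrame(
            rng.normal(10, 1, (5, len(samples))),
            index=[f"p{i}" for i in range(5)],
            columns=samples,
        )
        res = differential_test(mat, annot, "B", combined=True).set_index("protein")
        group = np.array([1.0 if a.population == "B" else 0.0 for a in annot])
        batch = np.array([1.0 if a.sampling_batch == "PS2" else 0.0 for a in annot])
        X = sm.add_constant(np.column_stack([group, batch]))
        for prot in mat.index:
            fit = sm.OLS(mat.loc[prot].to_numpy(), X).fit()
            assert res.loc[prot, "log2fc"] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.loc[prot, "se"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert res.loc[prot, "p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_too_few_samples_rejected(self):
        annot = _annot(n_per_pop=1)
        mat = pd.DataFrame(
            [[1.0] * len(annot)], index=["p"], columns=[a.sample_id for a in annot]
        )
        with pytest.raises(ValidationError):
            differential_test(mat, annot, "A")


class TestPower:
    def test_monotone_decreasing_in_n(self):
        s = PowerSettings(cv=0.3)
        fcs = [min_detectable_fc(n, s) for n in (2, 4, 8, 16, 32)]
        assert all(a > b for a, b in zip(fcs, fcs[1:]))

    def test_quadrupling_n_halves_delta(self):
        s = PowerSettings(cv=0.3)
        fc6 = min_detectable_fc(6, s)
        fc24 = min_detectable_fc(24, s)
        assert fc24 == pytest.approx(np.sqrt(fc6), rel=1e-9)

    def test_study_design_anchor(self):
        """CV calibrated for FC=2.0 at n=6 gives ~1.41 at n=24 (within 3% of 1.45)."""
        settings = PowerSettings()
        cv = calibrate_cv_for_fc(2.0, 6, settings)
        settings = PowerSettings(cv=cv)
        assert min_detectable_fc(6, settings) == pytest.approx(2.0, rel=1e-9)
        fc24 = min_detectable_fc(24, settings)
        assert abs(fc24 - 1.45) / 1.45 <= 0.03
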