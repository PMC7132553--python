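"""Female saturated/GLM fits, whitened components and Fisher combinations."""

import numpy as np
import pytest
from scipy import stats

from xci_assoc import (
    GenotypeCounts,
    female_components,
    fisher_left,
    fisher_right,
    fit_female_glm,
    fit_female_saturated,
)
from xci_assoc.female_test import (
    DegenerateFitError,
    FemaleComponentStats,
    female_components_batch,
    fisher_batch,
)
from xci_assoc.simulator import expand_to_records

from conftest import random_counts


def counts_from_cells(case, control):
    return GenotypeCounts(female_case=case, female_control=control,
                          male_case=[1, 1], male_control=[1, 1])


class TestSaturatedFit:
    def test_hand_checked_coefficients(self):
        # cases 10/20/30/40, controls 40/30/20/10 over a/a, a/A, A/a, A/A
        fit = fit_female_saturated(counts_from_cells([10, 20, 30, 40], [40, 30, 20, 10]))
        c = fit.coefficients
        assert c.b1 == pytest.approx(np.log(1.5) - np.log(0.25), abs=1e-12)
        assert c.b1 == pytest.approx(1.7918, abs=5e-5)
        # symmetric table: interaction cancels
        assert c.b3 == pytest.approx(0.0, abs=1e-12)
        assert c.cov[0, 0] == pytest.approx(1 / 10 + 1 / 40 + 1 / 30 + 1 / 20, abs=1e-12)
        assert c.cov[0, 0] == pytest.approx(0.2083, abs=5e-5)

    def test_balanced_table_gives_zero_effects(self):
        fit = fit_female_saturated(counts_from_cells([25, 25, 25, 25], [25, 25, 25, 25]))
        assert np.allclose(fit.coefficients.effects, 0.0)

    def test_zero_cell_triggers_correction(self):
        fit = fit_female_saturated(counts_from_cells([10, 0, 30, 40], [40, 30, 20, 10]))
        assert fit.zero_cell_corrected
        assert np.all(np.isfinite(fit.coefficients.effects))

    def test_zero_cell_error_policy(self):
        with pytest.raises(DegenerateFitError):
            fit_female_saturated(counts_from_cells([10, 0, 30, 40], [40, 30, 20, 10]),
                                 zero_cell="error")

    def test_all_case_stratum_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_female_saturated(counts_from_cells([10, 10, 10, 10], [0, 0, 0, 0]))


class TestGlmOracleEquivalence:
    def test_agrees_with_closed_form_on_example(self):
        counts = counts_from_cells([10, 20, 30, 40], [40, 30, 20, 10])
        sat = fit_female_saturated(counts)
        glm = fit_female_glm(expand_to_records(counts))
        assert glm.coefficients.effects == pytest.approx(
            sat.coefficients.effects, abs=1e-6)
        assert glm.coefficients.cov == pytest.approx(sat.coefficients.cov, abs=1e-6)

    def test_zero_effect_covariate_leaves_estimates(self, rng):
        counts = counts_from_cells([30, 40, 50, 30], [60, 35, 30, 20])
        base = fit_female_glm(expand_to_records(counts))
        records = [
            type(rec)(rec.sex, rec.phenotype, rec.genotype,
                      covariates=(float(rng.integers(0, 2)),))
            for rec in expand_to_records(counts) if rec.sex == "F"
        ]
        with_cov = fit_female_glm(records)
        se = np.sqrt(np.diag(with_cov.coefficients.cov))
        assert np.all(np.abs(with_cov.coefficients.effects
                             - base.coefficients.effects) < 2 * se)

    def test_constant_covariate_raises_named_error(self):
        records = [
            type(rec)(rec.sex, rec.phenotype, rec.genotype, covariates=(1.0,))
            for rec in expand_to_records(
                counts_from_cells([10, 20, 30, 40], [40, 30, 20, 10]))
            if rec.sex == "F"
        ]
        from xci_assoc.female_test import FitConvergenceError

        with pytest.raises(FitConvergenceError, match="c1"):
            fit_female_glm(records)


class TestFemaleComponents:
    def test_zero_effects_give_zero_components(self):
        fit = fit_female_saturated(counts_from_cells([25, 25, 25, 25], [25, 25, 25, 25]))
        comp = female_components(fit)
        assert np.allclose(comp.z, 0.0)
        assert np.allclose(comp.p_right, 0.5)

    def test_whitening_normalizes_quadratic_form(self):
        """||Z||^2 equals the Wald quadratic form of the step contrasts."""
        from xci_assoc.female_test import STEP_CONTRASTS

        fit = fit_female_saturated(counts_from_cells([10, 20, 30, 40], [40, 30, 20, 10]))
        comp = female_components(fit)
        c = STEP_CONTRASTS @ fit.coefficients.effects
        S = STEP_CONTRASTS @ fit.coefficients.cov @ STEP_CONTRASTS.T
        assert comp.z @ comp.z == pytest.approx(c @ np.linalg.solve(S, c), rel=1e-10)

    def test_one_sided_pvalues_are_complementary(self):
        fit = fit_female_saturated(counts_from_cells([12, 25, 31, 44], [40, 33, 21, 13]))
        comp = female_components(fit)
        assert comp.p_right + comp.p_left == pytest.approx(np.ones(3), abs=1e-12)

    def test_batch_matches_single_table_path(self, rng):
        tables = random_counts(rng, 50)
        fc = np.stack([t.female_case for t in tables])
        fs = np.stack([t.female_control for t in tables])
        z_batch, corrected = female_components_batch(fc, fs)
        assert not corrected.any()
        for i, t in enumerate(tables):
            comp = female_components(fit_female_saturated(t))
            assert z_batch[i] == pytest.approx(comp.z, rel=1e-10)


class TestFisherCombination:
    def test_null_point_statistic(self):
        comp = FemaleComponentStats(z=np.zeros(3), p_right=np.full(3, 0.5),
                                    p_left=np.full(3, 0.5))
        right = fisher_right(comp)
        assert right.statistic == pytest.approx(-6 * np.log(0.5), abs=1e-12)
        assert right.statistic == pytest.approx(4.1589, abs=5e-5)
        assert right.p_value == pytest.approx(0.6552, abs=5e-5)

    def test_boundary_pvalues(self):
        comp = FemaleComponentStats(z=np.full(3, -40.0),
                                    p_right=np.array([1.0 - 1e-16] * 3),
                                    p_left=np.array([1e-300] * 3))
        right = fisher_right(comp)
        assert right.statistic == pytest.approx(0.0, abs=1e-9)
        assert right.p_value == pytest.approx(1.0, abs=1e-9)

    def test_right_of_z_equals_left_of_negated_z(self):
        z = np.array([0.7, -1.2, 2.4])
        comp = FemaleComponentStats(z=z, p_right=stats.norm.sf(z),
                                    p_left=stats.norm.cdf(z))
        neg = FemaleComponentStats(z=-z, p_right=stats.norm.sf(-z),
                                   p_left=stats.norm.cdf(-z))
        assert fisher_right(comp).statistic == pytest.approx(
            fisher_left(neg).statistic, rel=1e-12)

    def test_underflow_clamped_with_warning(self):
        comp = FemaleComponentStats(z=np.full(3, 40.0), p_right=np.zeros(3),
                                    p_left=np.ones(3))
        with pytest.warns(RuntimeWarning, match="underflow"):
            right = fisher_right(comp)
        assert np.isfinite(right.statistic)

    def test_transformed_z_monotone_in_pvalue(self):
        zs = np.linspace(-2, 5, 30)
        prev = np.inf
        for z in zs:
            comp = FemaleComponentStats(z=np.full(3, z),
                                        p_right=stats.norm.sf(np.full(3, z)),
                                        p_left=stats.norm.cdf(np.full(3, z)))
            f = fisher_right(comp)
            assert f.p_value <= prev + 1e-15
            prev = f.p_value

    def test_batch_matches_single(self, rng):
        z = rng.normal(size=(40, 3))
        fr, fl = fisher_batch(z)
        for i in range(40):
            comp = FemaleComponentStats(z=z[i], p_right=stats.norm.sf(z[i]),
                                        p_left=stats.norm.cdf(z[i]))
            assert fr[i] == pytest.approx(fisher_right(comp).statistic, rel=1e-12)
            assert fl[i] == pytest.approx(fisher_left(comp).statistic, rel=1e-12)
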