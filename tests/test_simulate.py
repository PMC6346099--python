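"""Generator contracts: determinism, constraints, and statistical structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pcbscan as pk
from pcbscan.simulate import FE_NAMES, SEX_SHIFTED_CONGENERS, cell_index, pcb_index

from oracles import ols_beta


class TestGenerateCohort:
    def test_case_control_split_matches_study_design(self):
        cohort = pk.generate_cohort(512, 217, seed=1)
        assert len(cohort) == 512
        assert int(cohort["future_case"].sum()) == 217
        assert int((~cohort["future_case"]).sum()) == 295

    def test_same_seed_is_byte_identical(self):
        a = pk.generate_cohort(200, 80, seed=7)
        b = pk.generate_cohort(200, 80, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_different_seed_differs(self):
        a = pk.generate_cohort(200, 80, seed=7)
        b = pk.generate_cohort(200, 80, seed=8)
        assert not a.equals(b)

    def test_invariants(self, small_cohort):
        co = small_cohort
        assert (co[list(pk.PCB_COLUMNS)] > 0).all().all()
        sums = co[list(pk.CELL_TYPES)].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        cases = co["future_case"]
        assert co.loc[cases, "time_to_diagnosis"].between(2, 17).all()
        assert co.loc[~cases, "time_to_diagnosis"].isna().all()
        assert (co["batch"].value_counts() >= 2).all()

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            pk.generate_cohort(100, 101)
        with pytest.raises(ValueError):
            pk.generate_cohort(100, 10, config=pk.CohortConfig(age_sd=-1.0))
        with pytest.raises(ValueError):
            pk.CohortConfig(pcb_log_sd=(0.5,) * 5 + (0.0,)).validate()

    def test_zero_sex_shift_gives_uniform_ttest_pvalues(self):
        """With the female shift off, sex-difference p-values are null-uniform
        (KS over 200 replicate cohorts)."""
        cfg = pk.CohortConfig(female_shift_sd=0.0)
        pvals = []
        for seed in range(200):
            co = pk.generate_cohort(150, 60, config=cfg, seed=seed)
            pvals.extend(pk.exposure_sex_ttest(co)["p"].tolist())
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestWBCProportions:
    def test_rows_on_simplex(self, rng):
        w = pk.generate_wbc_proportions(50, np.ones(6), seed=3)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)
        assert (w >= 0).all()

    def test_dirichlet_mean(self):
        w = pk.generate_wbc_proportions(10000, np.full(6, 10.0), seed=4)
        assert np.abs(w.mean(axis=0) - 1 / 6).max() < 0.01

    def test_degenerate_concentration(self):
        conc = np.full(6, 1e-6)
        conc[2] = 1e6
        w = pk.generate_wbc_proportions(100, conc, seed=5)
        assert np.allclose(w[:, 2], 1.0, atol=1e-6)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            pk.generate_wbc_proportions(10, np.array([1, 1, 1, 0, 1, 1.0]), seed=0)


class TestGenerateExpression:
    def test_determinism(self, small_cohort):
        truth = pk.SimulationTruth.null(20)
        a = pk.generate_expression(small_cohort, truth, seed=9)
        b = pk.generate_expression(small_cohort, truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_dimension_mismatch_raises(self, small_cohort):
        bad = pk.SimulationTruth.null(5)
        bad_beta = np.zeros((5, 4))
        with pytest.raises(ValueError):
            pk.SimulationTruth(
                alpha=np.zeros(5), beta_pcb=bad_beta, beta_wbc=bad.beta_wbc,
                beta_inter=bad.beta_inter, beta_fe=bad.beta_fe,
                sigma2_u=0.1, sigma2_e=1.0,
            )

    @pytest.mark.parametrize("effect", [0.0, 0.2, 0.5, 1.0])
    def test_planted_interaction_recovered_unbiased(self, effect):
        """OLS on the correctly specified model recovers the planted
        interaction coefficient without bias (Monte-Carlo over 100 seeds)."""
        co = pk.generate_cohort(300, 120, config=pk.CohortConfig(n_batches=5),
                                seed=42)
        c, k = pcb_index(156), cell_index("B")
        p = np.log(co["PCB156"].to_numpy())
        p = (p - p.mean()) / p.std()
        w = co["B"].to_numpy()
        fe = np.column_stack([np.ones(len(co)), p, w])
        X = np.column_stack([fe, p * w])
        estimates = []
        for seed in range(100):
            truth = pk.SimulationTruth.null(1, sigma2_u=0.0)
            truth.beta_inter[0, c, k] = effect
            y = pk.generate_expression(co, truth, seed=seed).to_numpy()[0]
            estimates.append(ols_beta(X, y)[-1])
        mc_se = np.std(estimates) / 10
        assert abs(np.mean(estimates) - effect) < 4 * mc_se + 1e-12

    def test_planted_coefficient_ci_coverage(self):
        """95% OLS confidence interval covers a planted effect of 0.5 in at
        least 93 of 100 seeds (n=500)."""
        co = pk.generate_cohort(500, 200, config=pk.CohortConfig(n_batches=5),
                                seed=13)
        c, k = pcb_index(156), cell_index("B")
        p = np.log(co["PCB156"].to_numpy())
        p = (p - p.mean()) / p.std()
        w = co["B"].to_numpy()
        X = np.column_stack([np.ones(len(co)), p, w, p * w])
        cover = 0
        tcrit = stats.t.ppf(0.975, len(co) - X.shape[1])
        for seed in range(100):
            truth = pk.SimulationTruth.null(1, sigma2_u=0.0)
            truth.beta_inter[0, c, k] = 0.5
            y = pk.generate_expression(co, truth, seed=seed).to_numpy()[0]
            beta = ols_beta(X, y)
            resid = y - X @ beta
            s2 = resid @ resid / (len(y) - X.shape[1])
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[-1, -1])
            cover += abs(beta[-1] - 0.5) <= tcrit * se
        assert cover >= 93

    def test_sex_mask_restricts_effect_to_one_sex(self, small_cohort):
        truth = pk.SimulationTruth.null(1, sigma2_u=0.0, sigma2_e=1e-12)
        truth.beta_pcb[0, pcb_index(156)] = 10.0
        truth.sex_mask[0] = "F"
        y = pk.generate_expression(small_cohort, truth, seed=1).to_numpy()[0]
        males = (small_cohort["sex"] == "M").to_numpy()
        assert np.std(y[males]) < 1e-5
        assert np.std(y[~males]) > 1.0

    def test_truth_json_roundtrip(self, tmp_path):
        truth = pk.SimulationTruth.null(4, sigma2_u=0.3)
        truth.plant_interactions(118, "NK", 0.7, 0.5, seed=0)
        truth.to_json(tmp_path / "t.json")
        back = pk.SimulationTruth.from_json(tmp_path / "t.json")
        assert np.array_equal(back.beta_inter, truth.beta_inter)
        assert back.sigma2_u == truth.sigma2_u


class TestGenerateMethylation:
    def test_vertex_fraction_returns_reference_column(self):
        ref = pk.generate_reference_signature(50, seed=1)
        fr = np.zeros((1, 6))
        fr[0, 1] = 1.0  # pure B cells
        meth = pk.generate_methylation(fr, ref, noise_sd=0.0, seed=0)
        assert np.allclose(meth.to_numpy()[:, 0], ref["B"].to_numpy())

    def test_mixture_linearity(self):
        ref = pk.generate_reference_signature(50, seed=1)
        fr = np.zeros((1, 6))
        fr[0, 0] = fr[0, 1] = 0.5
        meth = pk.generate_methylation(fr, ref, noise_sd=0.0, seed=0)
        expected = 0.5 * (ref["NK"] + ref["B"]).to_numpy()
        assert np.allclose(meth.to_numpy()[:, 0], expected)

    def test_clipping_and_simplex_validation(self):
        ref = pk.generate_reference_signature(30, seed=2)
        fr = pk.generate_wbc_proportions(20, np.ones(6), seed=3)
        meth = pk.generate_methylation(fr, ref, noise_sd=5.0, seed=4)
        vals = meth.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        with pytest.raises(ValueError):
            pk.generate_methylation(fr * 1.5, ref, noise_sd=0.0, seed=0)


def test_fe_encoding_order_matches_truth_layout(small_cohort):
    from pcbscan.simulate import encode_fixed_effects

    fe = encode_fixed_effects(small_cohort)
    assert fe.shape == (len(small_cohort), len(FE_NAMES))
    # binary columns really are 0/1
    for j in (0, 1, 2, 5, 6):
        assert set(np.unique(fe[:, j])) <= {0.0, 1.0}
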