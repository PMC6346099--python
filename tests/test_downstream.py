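"""Stratified counts, sex comparison, overlaps, ORA, signatures, time-to-diagnosis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pcbscan as pk
from pcbscan.downstream import GeneSet

from oracles import hypergeom_tail_enumeration


class TestStratifiedCounts:
    def test_table_shape_and_overlap_bound(self):
        co = pk.generate_cohort(360, 160, config=pk.CohortConfig(n_batches=6),
                                seed=51)
        truth = pk.SimulationTruth.null(120, sigma2_u=0.1)
        expr = pk.generate_expression(co, truth, seed=52)
        counts = pk.stratified_scan_counts(
            expr, co, congeners=(156, 180), cell_types=("B", "NK"), min_n=30
        )
        assert len(counts) == 2 * 2 * 2  # sex x cell x congener
        assert set(counts["population"]) == {"Females", "Males"}
        ok = counts.dropna()
        assert (ok["overlap"] <= ok[["controls", "future_cases"]].min(axis=1)).all()
        # null configuration: the vast majority of cells hold zero hits
        assert (ok[["controls", "future_cases"]].to_numpy() == 0).mean() > 0.9

    def test_small_stratum_marked_na(self):
        co = pk.generate_cohort(120, 6, config=pk.CohortConfig(n_batches=4),
                                seed=53)
        truth = pk.SimulationTruth.null(40, sigma2_u=0.1)
        expr = pk.generate_expression(co, truth, seed=54)
        counts = pk.stratified_scan_counts(
            expr, co, congeners=(156,), cell_types=("B",), min_n=30
        )
        assert counts["future_cases"].isna().all()  # only ~6 cases per cohort


class TestExposureSexTtest:
    def test_identical_groups_give_t0_p1(self):
        co = pk.generate_cohort(60, 20, seed=55)
        co = co[co["sex"] == "F"].reset_index(drop=True)
        mirrored = pd.concat([co, co.assign(sex="M")], ignore_index=True)
        out = pk.exposure_sex_ttest(mirrored)
        assert np.allclose(out["t"], 0.0, atol=1e-12)
        assert np.allclose(out["p"], 1.0, atol=1e-12)

    def test_shifted_congeners_detected(self):
        detected = np.zeros(6)
        for seed in range(20):
            co = pk.generate_cohort(512, 217, seed=seed + 300)
            detected += (pk.exposure_sex_ttest(co)["p"] < 0.05).to_numpy()
        rates = dict(zip(pk.CONGENERS, detected / 20))
        for c in (118, 156, 170, 180):
            assert rates[c] > 0.6
        for c in (138, 153):
            assert rates[c] < 0.3

    def test_single_sex_rejected(self):
        co = pk.generate_cohort(60, 20, seed=56)
        with pytest.raises(ValueError):
            pk.exposure_sex_ttest(co[co["sex"] == "F"])


class TestGeneListOps:
    def test_overlap_identity_disjoint_and_fraction(self):
        hits = GeneSet("hits", frozenset("abcde"))
        n, frac, novel = pk.gene_list_overlap(hits, hits)
        assert (n, frac, novel) == (5, 1.0, None)
        other = GeneSet("known", frozenset("xyz"))
        n, frac, novel = pk.gene_list_overlap(hits, other)
        assert n == 0 and frac == 0.0 and novel.genes == hits.genes
        partial = GeneSet("known", frozenset("ab"))
        n, frac, novel = pk.gene_list_overlap(hits, partial)
        assert n == 2 and frac == pytest.approx(0.4)
        assert novel.genes == frozenset("cde")

    def test_empty_geneset_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("empty", frozenset())


class TestORA:
    def test_saturated_pathway_has_p_one(self):
        bg = GeneSet("bg", frozenset(f"g{i}" for i in range(30)))
        hits = GeneSet("hits", frozenset(f"g{i}" for i in range(6)))
        out = pk.ora_hypergeometric(hits, [GeneSet("all", bg.genes)], bg)
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["overlap"].iloc[0] == 6

    def test_matches_exhaustive_enumeration(self):
        """|background| = 20: hypergeometric upper tail equals enumeration of
        all C(20, 5) possible hit draws."""
        bg_ids = range(20)
        pathway = set(range(5))
        hits = {0, 1, 2, 3, 10}
        observed = len(pathway & hits)
        bg = GeneSet("bg", frozenset(map(str, bg_ids)))
        out = pk.ora_hypergeometric(
            GeneSet("hits", frozenset(map(str, hits))),
            [GeneSet("pw", frozenset(map(str, pathway)))],
            bg,
        )
        exact = hypergeom_tail_enumeration(20, pathway, hits, observed)
        assert abs(out["p"].iloc[0] - exact) < 1e-12

    def test_q_is_bh_of_p(self):
        rng = np.random.default_rng(0)
        bg = GeneSet("bg", frozenset(f"g{i}" for i in range(100)))
        hits = GeneSet("hits", frozenset(f"g{i}" for i in range(10)))
        pws = [
            GeneSet(f"pw{j}", frozenset(
                f"g{i}" for i in rng.choice(100, size=15, replace=False)))
            for j in range(8)
        ]
        out = pk.ora_hypergeometric(hits, pws, bg)
        q, _ = pk.bh_fdr(out["p"].to_numpy())
        assert np.allclose(out["q"].to_numpy(), q)

    def test_hits_outside_background_rejected(self):
        bg = GeneSet("bg", frozenset("abc"))
        with pytest.raises(ValueError):
            pk.ora_hypergeometric(GeneSet("h", frozenset("az")),
                                  [GeneSet("p", frozenset("ab"))], bg)


class TestDiffExprSignature:
    def test_defaults_and_null(self, rng):
        import inspect

        sig = inspect.signature(pk.diff_expr_signature)
        assert sig.parameters["fc_cut"].default == 1.5
        assert sig.parameters["q_cut"].default == 0.05
        assert sig.parameters["tail_frac"].default == 0.05
        X = pd.DataFrame(rng.normal(size=(50, 20)))
        labels = np.arange(20) < 10
        table, up, down = pk.diff_expr_signature(X, labels)
        assert not table["significant"].any()
        assert up is None and down is None

    def test_welch_statistic_matches_hand_computation(self):
        a = np.array([10.0, 12.0, 11.0, 13.0])
        b = np.array([8.0, 7.5, 8.5])
        X = pd.DataFrame([np.concatenate([a, b]),
                          np.concatenate([b, a[:4]])])
        labels = np.array([True] * 4 + [False] * 3)
        table, *_ = pk.diff_expr_signature(X, labels)
        ma, mb = a.mean(), b.mean()
        se = np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 3)
        assert table["log2_fc"].iloc[0] == pytest.approx(ma - mb)
        assert table["t"].iloc[0] == pytest.approx((ma - mb) / se)
        assert table["fold_change"].iloc[0] == pytest.approx(2 ** (ma - mb))

    def test_signature_sets_disjoint_and_significant(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 40)))
        labels = np.arange(40) < 20
        X.iloc[:10, :20] += 3.0          # up in group
        X.iloc[10:20, :20] -= 3.0        # down in group
        table, up, down = pk.diff_expr_signature(X, labels)
        assert up is not None and down is not None
        assert not (up.genes & down.genes)
        sig_genes = set(table.index[table["significant"]])
        assert up.genes <= sig_genes and down.genes <= sig_genes

    def test_small_group_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            pk.diff_expr_signature(X, [True, False, False, False])


class TestTimeToDiagnosis:
    def test_perfect_linear_relation(self):
        ttd = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        expr = pd.DataFrame([3.0 * ttd + 1.0], index=["g1"],
                            columns=[f"s{i}" for i in range(5)])
        out = pk.ttd_correlation(expr, ttd)
        assert out.loc["g1", "r"] == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        ttd = np.array([2.1, 3.3, 4.0, 8.2, 6.0])
        expr = pd.DataFrame([x], index=["g"], columns=list("abcde"))
        out = pk.ttd_correlation(expr, ttd)
        r_hand = np.sum((x - x.mean()) * (ttd - ttd.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((ttd - ttd.mean()) ** 2)
        )
        assert out.loc["g", "r"] == pytest.approx(r_hand)

    def test_sign_preserved_under_affine_transforms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        ttd = 0.5 * x + rng.normal(size=8) * 0.1
        expr = pd.DataFrame([x, -2.0 * x + 7.0], index=["g+", "g-"],
                            columns=[f"s{i}" for i in range(8)])
        out = pk.ttd_correlation(expr, 3.0 * ttd + 1.0)
        assert out.loc["g+", "r"] > 0 > out.loc["g-", "r"]
        assert out.loc["g+", "r"] == pytest.approx(-out.loc["g-", "r"])

    def test_constant_gene_is_na(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0]], index=["flat"],
                            columns=list("abc"))
        out = pk.ttd_correlation(expr, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(out.loc["flat", "r"])

    def test_batch_correction_shrinks_batch_variance(self, small_cohort):
        truth = pk.SimulationTruth.null(60, sigma2_u=2.0, sigma2_e=0.5)
        expr = pk.generate_expression(small_cohort, truth, seed=71)
        corrected = pk.remove_batch_effects(expr, small_cohort)
        codes, _ = pd.factorize(small_cohort["batch"])

        def batch_var(mat):
            resid = mat.to_numpy() - mat.to_numpy().mean(axis=1, keepdims=True)
            means = np.stack(
                [resid[:, codes == b].mean(axis=1) for b in range(codes.max() + 1)]
            )
            return float(np.mean(means.var(axis=0)))

        assert batch_var(corrected) < 0.35 * batch_var(expr)
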