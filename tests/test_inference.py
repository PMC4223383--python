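"""Factorial NB GLM, contrast LRTs, FDR and classification rules."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from chimera_lse.inference import (
    CONTRASTS,
    L1_RELATED,
    L1_SPECIFIC,
    L2L3_RELATED,
    L2L3_SPECIFIC,
    UNCLASSIFIED,
    ContrastResult,
    ModelConfig,
    _REDUCED,
    adjust_fdr,
    classify_gene,
    classify_genes,
    combine_tissues,
    estimate_common_dispersion,
    fit_factorial_nb,
    fit_nb_glm,
    nb_loglik,
    saturated_loglik,
    test_contrast,
    test_contrasts_batch,
    tissue_support_summary,
)
from chimera_lse.simulate import SimConfig, simulate_counts


def _cr(contrast, q, logfc):
    return ContrastResult("g", "leaf", contrast, logFC=logfc, stat=0.0, p=q, q=q)


class TestSaturatedFit:
    def test_symmetric_table_gives_zero_effects(self):
        fit = fit_factorial_nb(np.array([10.0, 10, 10, 10]))
        assert fit["coefficients"][1:] == pytest.approx([0, 0, 0], abs=1e-12)
        assert fit["fitted"] == pytest.approx([10, 10, 10, 10])

    def test_interaction_equals_log_cross_ratio(self):
        # all-positive counts: beta_int = log((Lw*Pc)/(Lc*Pw))
        fit = fit_factorial_nb(np.array([20.0, 10, 5, 10]))
        assert fit["coefficients"][3] == pytest.approx(np.log(4.0), abs=1e-12)

    def test_zero_cell_uses_continuity_correction(self):
        fit = fit_factorial_nb(np.array([20.0, 10, 0, 10]))
        expected = np.log((20.5 * 10.5) / (0.5 * 10.5))
        assert fit["coefficients"][3] == pytest.approx(expected)

    def test_all_zero_gene_rejected(self):
        with pytest.raises(ValueError):
            fit_factorial_nb(np.zeros(4))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_factorial_nb(np.array([1.0, -2, 3, 4]))


class TestGlmOracles:
    Y = np.array([23.0, 11, 7, 19])

    @pytest.mark.parametrize("contrast", list("abcd"))
    def test_poisson_limit_matches_statsmodels_irls(self, contrast):
        Xr, _ = _REDUCED[contrast]
        beta, ll = fit_nb_glm(self.Y, Xr, phi=0.0)
        oracle = sm.GLM(self.Y, Xr, family=sm.families.Poisson()).fit()
        assert beta[0] == pytest.approx(oracle.params, abs=1e-6)
        assert ll[0] == pytest.approx(oracle.llf, abs=1e-8)

    @pytest.mark.parametrize("contrast", list("abcd"))
    def test_nb_fit_matches_statsmodels_family(self, contrast):
        phi = 0.1
        Xr, _ = _REDUCED[contrast]
        beta, ll = fit_nb_glm(self.Y, Xr, phi=phi)
        fam = sm.families.NegativeBinomial(alpha=phi)
        oracle = sm.GLM(self.Y, Xr, family=fam).fit()
        assert beta[0] == pytest.approx(oracle.params, abs=1e-5)
        # and the likelihood reached is at least statsmodels' optimum
        assert ll[0] >= oracle.llf - 1e-8

    def test_irls_maximum_matches_direct_optimizer(self):
        # independent route: generic optimizer on the NB log-likelihood
        phi = 0.1
        Xr, _ = _REDUCED["c"]
        beta, ll = fit_nb_glm(self.Y, Xr, phi=phi)

        def nll(b):
            mu = np.exp(Xr @ b)
            return -nb_loglik(self.Y, mu, phi).sum()

        opt = minimize(nll, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert ll[0] == pytest.approx(-opt.fun, abs=1e-4)

    def test_chi2_quantile_anchor(self):
        # published chi-square table: a deviance of 3.841 on 1 df is p = 0.05
        from scipy.stats import chi2

        assert chi2.sf(3.841, df=1) == pytest.approx(0.05, abs=1e-4)

    def test_offsets_shift_fitted_means(self):
        off = np.array([0.0, 0.0, np.log(2.0), np.log(2.0)])
        y = np.array([10.0, 10, 20, 20])
        res = test_contrasts_batch(y[None, :], ModelConfig(), off[None, :])
        for k in "abcd":
            assert res[k]["logFC"][0] == pytest.approx(0.0, abs=1e-12)
            assert res[k]["p"][0] == pytest.approx(1.0)


class TestContrastTests:
    def test_no_signal_all_null(self):
        res = test_contrasts_batch(np.array([[50.0, 50, 50, 50]]), ModelConfig())
        for k in "abcd":
            assert res[k]["logFC"][0] == 0.0
            assert res[k]["p"][0] == pytest.approx(1.0)

    def test_collapsed_lyc_chimera_signal(self):
        res = test_contrasts_batch(
            np.array([[100.0, 100, 1, 100]]), ModelConfig(dispersion_value=0.1)
        )
        assert res["a"]["logFC"][0] < -3
        assert res["a"]["p"][0] < 1e-4
        assert res["b"]["p"][0] > 0.5
        assert res["c"]["p"][0] < 1e-3
        assert res["d"]["logFC"][0] > 3 and res["d"]["p"][0] < 1e-4

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError):
            test_contrast(np.array([1.0, 2, 3, 4]), ModelConfig(), "z")

    def test_tissue_fraction_mode_nulls_composition_ratio(self):
        # counts sitting exactly at the 20:80 composition ratio are null for
        # contrast d under tissue_fraction mode but significant under none
        y = np.array([[100.0, 100, 80, 20]])
        none = test_contrasts_batch(y, ModelConfig(contrast_d_offset="none"))
        tf = test_contrasts_batch(
            y, ModelConfig(contrast_d_offset="tissue_fraction", p_l1=0.2)
        )
        assert none["d"]["p"][0] < 0.01 and none["d"]["logFC"][0] < 0
        assert tf["d"]["stat"][0] == pytest.approx(0.0, abs=1e-8)
        assert tf["d"]["logFC"][0] == pytest.approx(0.0, abs=1e-12)

    def test_mirror_symmetry_of_roles(self, rng):
        y = rng.poisson(60, size=(40, 4)).astype(float) + 1
        off = rng.normal(0, 0.3, size=(40, 4))
        swap = [1, 0, 3, 2]  # (Lw,Pw,Lc,Pc) -> (Pw,Lw,Pc,Lc)
        res = test_contrasts_batch(y, ModelConfig(), off)
        res_sw = test_contrasts_batch(y[:, swap], ModelConfig(), off[:, swap])
        np.testing.assert_allclose(res_sw["a"]["stat"], res["b"]["stat"], atol=1e-6)
        np.testing.assert_allclose(res_sw["b"]["stat"], res["a"]["stat"], atol=1e-6)
        np.testing.assert_allclose(res_sw["a"]["logFC"], res["b"]["logFC"], atol=1e-9)
        np.testing.assert_allclose(res_sw["c"]["logFC"], -res["c"]["logFC"], atol=1e-9)
        np.testing.assert_allclose(res_sw["c"]["stat"], res["c"]["stat"], atol=1e-6)
        np.testing.assert_allclose(res_sw["d"]["logFC"], -res["d"]["logFC"], atol=1e-9)
        np.testing.assert_allclose(res_sw["d"]["stat"], res["d"]["stat"], atol=1e-6)


class TestFdr:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.03]) == pytest.approx([0.03])

    def test_bh_step_up_hand_example(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04], "BH")
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_by_inflates_by_harmonic_sum(self):
        bh = adjust_fdr([0.01, 0.02, 0.03, 0.04], "BH")
        by = adjust_fdr([0.01, 0.02, 0.03, 0.04], "BY")
        assert by == pytest.approx(bh * 25 / 12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.1, 1.5])
        with pytest.raises(ValueError):
            adjust_fdr([-0.1])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5], "bonferroni-ish")

    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
        method=st.sampled_from(["BH", "BY"]),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_and_permutation_invariant(self, ps, method):
        p = np.array(ps)
        q = adjust_fdr(p, method)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(adjust_fdr(p[perm], method), q[perm])


class TestClassifyGene:
    def test_all_four_signatures_give_l1_specific(self):
        results = {
            "a": _cr("a", 0.01, -2.0),
            "b": _cr("b", 0.8, 0.1),
            "c": _cr("c", 0.01, 2.0),
            "d": _cr("d", 0.01, 1.5),
        }
        assert classify_gene(results) == L1_SPECIFIC

    def test_no_significance_unclassified(self):
        results = {k: _cr(k, 0.5, 0.2) for k in "abcd"}
        assert classify_gene(results) == UNCLASSIFIED

    def test_penn_collapse_without_d_is_l2l3_related(self):
        results = {
            "a": _cr("a", 0.9, 0.1),
            "b": _cr("b", 0.01, -2.0),
            "c": _cr("c", 0.02, -2.0),
            "d": _cr("d", 0.7, -0.1),
        }
        assert classify_gene(results) == L2L3_RELATED

    def test_significant_up_b_does_not_block_l1(self):
        # an L1-concentrated gene rises in the chimera penn channel
        results = {
            "a": _cr("a", 0.001, -2.0),
            "b": _cr("b", 0.001, 1.2),
            "c": _cr("c", 0.001, 3.0),
            "d": _cr("d", 0.001, 2.0),
        }
        assert classify_gene(results) == L1_SPECIFIC

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError, match="missing contrast"):
            classify_gene({k: _cr(k, 0.5, 0.0) for k in "abc"})


class TestCombineTissues:
    def test_strongest_grade_wins(self):
        out = combine_tissues(
            {"leaf": L1_RELATED, "dehydrated_leaf": L1_SPECIFIC,
             "fruit": UNCLASSIFIED},
            gene_id="g1",
        )
        assert out.label == L1_SPECIFIC
        assert out.supporting_tissues == {"leaf", "dehydrated_leaf"}
        assert not out.conflict

    def test_opposite_layers_conflict(self):
        out = combine_tissues({"leaf": L1_SPECIFIC, "fruit": L2L3_SPECIFIC})
        assert out.label == UNCLASSIFIED and out.conflict

    def test_all_unclassified(self):
        out = combine_tissues({"leaf": UNCLASSIFIED, "fruit": UNCLASSIFIED})
        assert out.label == UNCLASSIFIED and not out.conflict
        assert out.supporting_tissues == frozenset()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_tissues({})


class TestTissueSupport:
    def test_single_tissue_sole_support(self):
        cls = [combine_tissues({"leaf": L1_RELATED}, gene_id=f"g{i}") for i in range(3)]
        df = tissue_support_summary(cls)
        row = df[df["tissue"] == "leaf"].iloc[0]
        assert row.supported_fraction == 1.0 and row.sole_fraction == 1.0

    def test_shared_and_sole_fractions(self):
        c1 = combine_tissues({"T": L1_RELATED}, gene_id="g1")
        c2 = combine_tissues({"T": L1_RELATED, "U": L1_RELATED}, gene_id="g2")
        df = tissue_support_summary([c1, c2]).set_index("tissue")
        assert df.loc["T", "supported_fraction"] == 1.0
        assert df.loc["T", "sole_fraction"] == 0.5
        assert df.loc["U", "supported_fraction"] == 0.5

    def test_no_classified_genes_gives_empty_table(self):
        df = tissue_support_summary(
            [combine_tissues({"leaf": UNCLASSIFIED}, gene_id="g")]
        )
        assert len(df) == 0


class TestDriver:
    def test_mirror_symmetry_of_classification(self):
        cfg = SimConfig(n_genes=200, frac_l1_specific=0.15, frac_l2l3_specific=0.15,
                        frac_l1_related=0.1, frac_l2l3_related=0.1, seed=21)
        counts = simulate_counts(cfg)
        swapped = counts.rename(
            columns={"Lw": "Pw", "Pw": "Lw", "Lc": "Pc", "Pc": "Lc",
                     "off_lw": "off_pw", "off_pw": "off_lw",
                     "off_lc": "off_pc", "off_pc": "off_lc"}
        )
        _, per1, _ = classify_genes(counts, ModelConfig())
        _, per2, _ = classify_genes(swapped, ModelConfig())
        mirror = {
            L1_SPECIFIC: L2L3_SPECIFIC, L1_RELATED: L2L3_RELATED,
            L2L3_SPECIFIC: L1_SPECIFIC, L2L3_RELATED: L1_RELATED,
            UNCLASSIFIED: UNCLASSIFIED,
        }
        m1 = dict(zip(per1["gene_id"], per1["label"]))
        m2 = dict(zip(per2["gene_id"], per2["label"]))
        assert m2 == {g: mirror[l] for g, l in m1.items()}

    def test_all_zero_and_not_expressed_genes_skipped(self):
        counts = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3"],
            "tissue": "leaf",
            "Lw": [100, 0, 100], "Pw": [100, 0, 100],
            "Lc": [80, 0, 80], "Pc": [20, 0, 20],
            "expressed": [True, True, False],
        })
        results, per_tissue, cls = classify_genes(counts, ModelConfig())
        assert set(per_tissue["gene_id"]) == {"g1"}

    def test_common_dispersion_moment_estimate_recovers_phi(self):
        cfg = SimConfig(n_genes=3000, dispersion=0.1, frac_l1_specific=0.0,
                        frac_l1_related=0.0, frac_l2l3_specific=0.0,
                        frac_l2l3_related=0.0, seed=23)
        counts = simulate_counts(cfg)
        y = counts[["Lw", "Pw", "Lc", "Pc"]].to_numpy(float)
        off = counts[["off_lw", "off_pw", "off_lc", "off_pc"]].to_numpy(float)
        phi_hat = estimate_common_dispersion(y, off)
        assert 0.05 < phi_hat < 0.2

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            classify_genes(pd.DataFrame({"gene_id": [], "tissue": []}))
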