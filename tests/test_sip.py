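"""The per-gradient NB differential-abundance caller and its diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from diazosip.sip import (
    DensityWindows,
    GradientFractionTable,
    assign_fraction_classes,
    call_gradient,
    compare_to_control_mode,
    consolidate_calls,
    estimate_dispersions,
    estimate_size_factors,
    filter_sparse_otus,
    fit_nb_two_group,
    hump_shape_diagnostic,
    normalize_copy_profile,
)
from diazosip.sip import test_enrichment as enrichment_test
from diazosip.synthetic import GradientSimParams, simulate_gradient_experiment


def make_table(counts, densities=None, gradient_id="G1", copy_quant=None, **kw):
    counts = pd.DataFrame(counts)
    counts.index = [f"F{i + 1:02d}" for i in range(counts.shape[0])]
    if densities is None:
        densities = np.linspace(1.742, 1.833, counts.shape[0])
    fields = dict(gradient_id=gradient_id, label_status="15N", medium="RNA-CsTFA", timepoint=7.0)
    fields.update(kw)
    return GradientFractionTable(
        densities=pd.Series(densities, index=counts.index),
        counts=counts,
        copy_quant=None if copy_quant is None else pd.Series(copy_quant, index=counts.index),
        **fields,
    )


class TestFractionClasses:
    @pytest.mark.parametrize(
        "density, expected",
        [
            (1.80, "labelled"),  # inside the heavy window
            (1.75, "unlabelled"),  # inside the light window
            (1.90, "excluded"),  # beyond both windows
            (1.785, "labelled"),  # shared boundary belongs to the upper window
            (1.820, "labelled"),  # outermost boundary closed
            (1.740, "unlabelled"),
        ],
    )
    def test_rna_window_classification(self, rna_windows, density, expected):
        assert rna_windows.classify(density) == expected

    def test_dna_orientation_labelled_is_light(self):
        w = DensityWindows.dna_default()
        assert w.classify(1.68) == "labelled"
        assert w.classify(1.72) == "unlabelled"
        assert w.classify(1.60) == "excluded"

    def test_too_few_fractions_in_class_raises(self, rna_windows):
        # all densities in the light window only
        t = make_table(np.ones((6, 3), dtype=int), densities=np.linspace(1.741, 1.78, 6))
        with pytest.raises(ValueError, match="G1"):
            assign_fraction_classes(t, rna_windows)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            DensityWindows(labelled=(1.78, 1.82), unlabelled=(1.74, 1.79))


class TestCopyProfile:
    def test_equal_copies(self):
        t = make_table(np.ones((20, 2), dtype=int), copy_quant=np.ones(20))
        prof = normalize_copy_profile(t)
        assert np.allclose(prof, 0.05)

    def test_simple_proportions(self):
        q = np.zeros(20)
        q[0], q[1] = 3, 1
        t = make_table(np.ones((20, 2), dtype=int), copy_quant=q)
        prof = normalize_copy_profile(t)
        assert prof.iloc[0] == pytest.approx(0.75)
        assert prof.iloc[1] == pytest.approx(0.25)

    def test_simulated_profiles_sum_to_one(self, small_experiment):
        _, tables, _, _ = small_experiment
        for t in tables:
            assert normalize_copy_profile(t).sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_raises(self):
        t = make_table(np.ones((20, 2), dtype=int), copy_quant=np.zeros(20))
        with pytest.raises(ValueError, match="all-zero"):
            normalize_copy_profile(t)


class TestSparseFilter:
    def _tables(self, counts):
        # split 40 samples into two 20-fraction gradients
        return [
            make_table(counts[:20], gradient_id="A"),
            make_table(counts[20:], gradient_id="B"),
        ]

    def test_total_rule(self):
        counts = np.zeros((40, 2), dtype=int)
        counts[:30, 0] = [1] * 9 + [0] * 21  # total 9, present in 9 samples
        counts[:, 1] = 5
        tables, report = filter_sparse_otus(self._tables(counts))
        assert not report.loc[0, "kept"]
        assert report.loc[0, "removal_reason"] == "total"
        assert report.loc[1, "kept"]

    def test_prevalence_rule(self):
        counts = np.zeros((40, 2), dtype=int)
        counts[:7, 0] = [72, 72, 72, 72, 72, 70, 70]  # total 500 in 7/40 samples
        counts[:, 1] = 5
        _, report = filter_sparse_otus(self._tables(counts))
        assert not report.loc[0, "kept"]
        assert report.loc[0, "removal_reason"] == "prevalence"

    def test_both_boundaries_inclusive_pass(self):
        counts = np.zeros((40, 2), dtype=int)
        counts[:8, 0] = [2, 2, 1, 1, 1, 1, 1, 1]  # total 10 in 8/40 = exactly 20%
        counts[:, 1] = 5
        tables, report = filter_sparse_otus(self._tables(counts))
        assert report.loc[0, "kept"]
        assert list(tables[0].counts.columns) == [0, 1]


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame([[10, 5, 3], [10, 5, 3]])
        np.testing.assert_allclose(estimate_size_factors(counts), [1.0, 1.0])

    def test_threefold_sample(self):
        a = np.array([10, 20, 42, 7])
        counts = pd.DataFrame([a, 3 * a])
        f = estimate_size_factors(counts)
        np.testing.assert_allclose(f, [1 / np.sqrt(3), np.sqrt(3)], rtol=1e-12)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(3.0, rel=1e-12)

    def test_permutation_invariance(self, rng):
        counts = pd.DataFrame(rng.poisson(20, size=(5, 30)) + 1)
        f1 = estimate_size_factors(counts)
        perm = rng.permutation(30)
        f2 = estimate_size_factors(counts.iloc[:, perm])
        np.testing.assert_allclose(f1, f2)

    def test_fallback_when_no_shared_otu(self):
        counts = pd.DataFrame([[5, 0, 3], [0, 4, 6], [2, 2, 0]])
        with pytest.warns(UserWarning, match="positive-count"):
            f = estimate_size_factors(counts)
        assert np.isfinite(f).all() and (f > 0).all()


class TestDispersions:
    def test_poisson_counts_land_near_floor(self, rng):
        counts = pd.DataFrame(rng.poisson(200, size=(50, 40)))
        sf = estimate_size_factors(counts)
        d = estimate_dispersions(counts, sf)
        assert (d["final_dispersion"] <= 0.05).mean() >= 0.9

    def test_nb_dispersion_recovery(self, rng):
        alpha = 0.5
        mu = 50.0
        counts = pd.DataFrame(
            rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), size=(100, 40))
        )
        sf = pd.Series(np.ones(100), index=counts.index)
        d = estimate_dispersions(counts, sf)
        assert 0.3 <= d["raw_dispersion"].median() <= 0.7

    def test_constant_counts_hit_floor(self):
        counts = pd.DataFrame(np.full((6, 3), 7))
        sf = pd.Series(np.ones(6))
        d = estimate_dispersions(counts, sf)
        assert (d["raw_dispersion"] == 0).all()
        np.testing.assert_allclose(d["final_dispersion"], 1e-8)

    def test_zero_mean_otu_flagged(self):
        counts = pd.DataFrame({"a": [5, 6, 7], "b": [0, 0, 0]})
        sf = pd.Series(np.ones(3))
        d = estimate_dispersions(counts, sf)
        assert not d.loc["b", "testable"]
        assert np.isnan(d.loc["b", "final_dispersion"])


class TestNBFit:
    def test_matches_statsmodels_glm(self, rng):
        """The vectorized Fisher-scoring fit agrees with an independent GLM."""
        n = 16
        x = np.array([0] * 9 + [1] * 7)
        s = np.exp(rng.normal(0, 0.2, n))
        alpha = 0.15
        for mu0, lfc_nat in ((20, 0.8), (5, 0.0), (100, -0.5)):
            mu = s * mu0 * np.exp(lfc_nat * x)
            k = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
            mine = fit_nb_two_group(k[None, :], s, x, np.array([alpha]))
            glm = sm.GLM(
                k, sm.add_constant(x.astype(float)),
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(s),
            ).fit()
            assert mine["b0"][0] == pytest.approx(glm.params[0], abs=1e-6)
            assert mine["b1"][0] == pytest.approx(glm.params[1], abs=1e-6)
            assert mine["se_b1"][0] == pytest.approx(glm.bse[1], rel=1e-5)

    def test_wald_p_agrees_with_parametric_bootstrap(self, rng):
        """One-sided Wald p within 10% of a 5000-resample bootstrap oracle."""
        n = 16
        x = np.array([0] * 9 + [1] * 7)
        s = np.exp(rng.normal(0, 0.15, n))
        alpha = 0.08
        B = 5000
        for _ in range(10):
            mu0 = rng.uniform(20, 120)
            k = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * s * mu0))
            obs = fit_nb_two_group(k[None, :], s, x, np.array([alpha]))
            mu_null = s * (k / s).mean()
            kb = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu_null), size=(B, n))
            boot = fit_nb_two_group(kb, s, x, np.full(B, alpha))
            p_boot = float((boot["wald_z"] >= obs["wald_z"][0]).mean())
            p_wald = float(obs["wald_p"][0])
            mc_err = 3 * np.sqrt(max(p_boot * (1 - p_boot), 1e-6) / B)
            assert abs(p_wald - p_boot) <= 0.10 * max(p_wald, p_boot) + mc_err

    def test_degenerate_group_does_not_blow_up(self):
        k = np.array([[0, 0, 0, 0, 10, 12, 9, 11]], dtype=float)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        out = fit_nb_two_group(k, np.ones(8), x, np.array([0.1]))
        assert np.isfinite(out["b1"]).all()
        assert out["wald_p"][0] > 0.5  # depletion, not enrichment


class TestEnrichmentCalls:
    def test_null_gradients_yield_no_confirmed_calls(self, rna_windows):
        any_model = 0
        for seed in range(10):
            tables, _, _ = simulate_gradient_experiment(
                GradientSimParams(n_otus=150, seed=seed), include_control=False
            )
            res = call_gradient(tables[0], rna_windows)
            assert int(res["confirmed"].sum()) == 0
            any_model += int(res["model_enriched"].sum() > 0)
        assert any_model <= 3  # consistent with BH at FDR 0.1 under the null

    def test_spiked_otu_called_specifically(self, rna_windows):
        hits = 0
        for seed in range(10):
            tables, _, _ = simulate_gradient_experiment(
                GradientSimParams(
                    n_otus=150,
                    labelled_otu_ids=frozenset({"OTU_0001"}),
                    fixed_abundances={"OTU_0001": 0.02},
                    seed=seed,
                ),
                include_control=False,
            )
            res = call_gradient(tables[0], rna_windows)
            called = set(res.index[res["model_enriched"]])
            if called == {"OTU_0001"}:
                hits += 1
        assert hits >= 9

    def test_results_frame_contract(self, small_experiment, rna_windows):
        _, tables, _, _ = small_experiment
        res = call_gradient(tables[0], rna_windows)
        assert res["wald_p"].between(0, 1).all()
        assert res["padj"].between(0, 1).all()
        assert (res["padj"] >= res["wald_p"] - 1e-12).all()  # BH only increases p
        assert (res["confirmed"] <= res["model_enriched"]).all()
        assert res.loc["OTU_0001", "log2_fold_change"] > 0.25

    def test_classes_required(self, small_experiment):
        _, tables, _, _ = small_experiment
        with pytest.raises(ValueError, match="classes"):
            enrichment_test(tables[0])

    def test_all_zero_class_rejected(self, rna_windows):
        densities = np.linspace(1.742, 1.833, 20)
        counts = np.zeros((20, 3), dtype=int)
        counts[densities < 1.785] = 5  # only light fractions populated
        t = assign_fraction_classes(make_table(counts, densities=densities), rna_windows)
        with pytest.raises(ValueError, match="all zero"):
            enrichment_test(t)


class TestHumpDiagnostic:
    densities = pd.Series(np.linspace(1.742, 1.833, 20))

    def test_gaussian_in_window_passes(self, rna_windows):
        prof = pd.Series(np.exp(-0.5 * ((self.densities - 1.80) / 0.01) ** 2))
        out = hump_shape_diagnostic(prof / prof.sum(), self.densities, rna_windows)
        assert out.passed
        assert 1.785 <= out.peak_density <= 1.82

    def test_peak_in_unlabelled_window_fails(self, rna_windows):
        # prominent hump, but centred in the light window
        prof = pd.Series(np.exp(-0.5 * ((self.densities - 1.76) / 0.01) ** 2))
        out = hump_shape_diagnostic(prof / prof.sum(), self.densities, rna_windows)
        assert not out.passed
        assert out.reason == "peak outside labelled window"

    def test_monotone_decreasing_profile_fails(self, rna_windows):
        prof = pd.Series(np.linspace(1.0, 0.0, 20))
        out = hump_shape_diagnostic(prof / prof.sum(), self.densities, rna_windows)
        assert not out.passed

    def test_flat_profile_fails(self, rna_windows):
        prof = pd.Series(np.full(20, 0.05))
        out = hump_shape_diagnostic(prof, self.densities, rna_windows)
        assert not out.passed
        assert "prominent" in out.reason

    def test_all_zero_fails_with_reason(self, rna_windows):
        out = hump_shape_diagnostic(pd.Series(np.zeros(20)), self.densities, rna_windows)
        assert not out.passed
        assert "all-zero" in out.reason


class TestConsolidation:
    def _frame(self, otu, model, base_mean, hump, gradient="G1"):
        return pd.DataFrame(
            {
                "gradient_id": [gradient],
                "base_mean": [base_mean],
                "log2_fold_change": [1.0],
                "model_enriched": [model],
                "abundance_pass": [base_mean >= 1.25],
                "hump_pass": [hump],
            },
            index=pd.Index([otu], name="otu_id"),
        )

    def test_low_abundance_call_not_confirmed(self):
        out = consolidate_calls([self._frame("OTU_1", True, 0.8, True)])
        assert out["confirmed_otus"] == set()

    def test_full_pass_confirmed(self):
        out = consolidate_calls([self._frame("OTU_1", True, 50.0, True)])
        assert out["confirmed_otus"] == {"OTU_1"}

    def test_empty_call_set_is_valid(self):
        out = consolidate_calls([self._frame("OTU_1", False, 50.0, True)])
        assert out["confirmed_otus"] == set()
        assert out["summary"].loc["OTU_1", "n_gradients_enriched"] == 0

    def test_phylum_summary(self):
        frames = [self._frame("OTU_1", True, 50.0, True), self._frame("OTU_2", False, 5.0, False)]
        tax = pd.Series({"OTU_1": "Firmicutes", "OTU_2": "Actinobacteria"})
        out = consolidate_calls(frames, taxonomy=tax)
        assert set(out["phylum_summary"].index) == {"Firmicutes", "Actinobacteria"}


class TestControlComparisonMode:
    def test_identical_distributions_give_no_calls(self, rna_windows):
        tables, _, _ = simulate_gradient_experiment(
            GradientSimParams(n_otus=100, seed=4), include_control=True
        )
        res = compare_to_control_mode(tables[0], tables[1], rna_windows)
        assert int(res["model_enriched"].sum()) == 0
        assert (res["mode"] == "vs-control").all()

    def test_spiked_otu_recovered(self, rna_windows):
        hits = 0
        for seed in range(10):
            tables, _, _ = simulate_gradient_experiment(
                GradientSimParams(
                    n_otus=100,
                    labelled_otu_ids=frozenset({"OTU_0001"}),
                    fixed_abundances={"OTU_0001": 0.02},
                    seed=seed,
                )
            )
            res = compare_to_control_mode(tables[0], tables[1], rna_windows)
            hits += bool(res.loc["OTU_0001", "model_enriched"])
        assert hits >= 8

    def test_mismatched_otu_universe_rejected(self, rna_windows, small_experiment):
        _, tables, _, _ = small_experiment
        trimmed = tables[1].with_otus(tables[1].otu_ids[:-1])
        with pytest.raises(ValueError, match="universe"):
            compare_to_control_mode(tables[0], trimmed, rna_windows)
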