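import numpy as np
import pandas as pd
import pytest

from casekit import (
    annotation_variance_regression,
    fit_variance_components,
    partition_ase_variance,
    partition_expression_variance,
    rank_variance_genes,
)
from casekit.varcomp import cpm_filter, reml_variance_components


def balanced_oneway_anova(y, n_levels, n_reps):
    """Henderson method-III closed form for a balanced one-way layout."""
    y = np.asarray(y).reshape(n_levels, n_reps)
    level_means = y.mean(axis=1)
    msa = n_reps * np.sum((level_means - y.mean()) ** 2) / (n_levels - 1)
    mse = np.sum((y - level_means[:, None]) ** 2) / (n_levels * (n_reps - 1))
    return max((msa - mse) / n_reps, 0.0), mse


def _oneway_data(rng, n_levels=20, n_reps=50, s2a=1.0, s2e=1.0):
    u = rng.normal(0, np.sqrt(s2a), n_levels)
    y = np.repeat(u, n_reps) + rng.normal(0, np.sqrt(s2e), n_levels * n_reps)
    frame = pd.DataFrame({"ase": y, "treatment": np.repeat(np.arange(n_levels), n_reps).astype(str)})
    return frame


class TestRemlEngine:
    def test_matches_balanced_anova_closed_form(self):
        rng = np.random.default_rng(17)
        frame = _oneway_data(rng)
        res = fit_variance_components(frame, ("treatment",), unit_id="u1")
        s2a_ref, s2e_ref = balanced_oneway_anova(frame["ase"], 20, 50)
        assert res.sigma2["treatment"] == pytest.approx(s2a_ref, abs=1e-6)
        assert res.sigma2_resid == pytest.approx(s2e_ref, abs=1e-6)
        # the realized level variance has ~sqrt(2/19) relative sampling noise,
        # so the estimated fraction scatters around 0.5 accordingly
        assert 0.35 <= res.fractions["treatment"] <= 0.65

    def test_zero_variance_factor_truncated(self):
        rng = np.random.default_rng(18)
        frame = _oneway_data(rng, s2a=0.0)
        res = fit_variance_components(frame, ("treatment",))
        assert res.fractions["treatment"] <= 0.02

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(19)
        frame = _oneway_data(rng, n_levels=8, n_reps=6)
        frame["plate"] = np.tile(["p1", "p2", "p3"], 16)
        res = fit_variance_components(frame, ("treatment", "plate"))
        total = sum(res.fractions.values()) + res.residual_fraction
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_factor_order_invariance(self):
        rng = np.random.default_rng(20)
        frame = _oneway_data(rng, n_levels=8, n_reps=6)
        frame["plate"] = np.tile(["p1", "p2", "p3"], 16)
        a = fit_variance_components(frame, ("treatment", "plate"))
        b = fit_variance_components(frame, ("plate", "treatment"))
        assert a.sigma2_resid == pytest.approx(b.sigma2_resid, rel=1e-6)
        assert a.fractions["treatment"] == pytest.approx(b.fractions["treatment"], rel=1e-5, abs=1e-8)

    def test_single_level_factor_dropped(self):
        rng = np.random.default_rng(21)
        frame = _oneway_data(rng, n_levels=6, n_reps=4)
        frame["cell_type"] = "CM"
        res = fit_variance_components(frame, ("cell_type", "treatment"))
        assert res.dropped_factors == ("cell_type",)
        assert "cell_type" not in res.fractions

    def test_agrees_with_statsmodels_mixedlm(self):
        # independent route: MixedLM with a variance component over one
        # dummy group reproduces the same REML solution
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(22)
        frame = _oneway_data(rng, n_levels=10, n_reps=8)
        frame["g"] = 1
        md = smf.mixedlm("ase ~ 1", frame, groups="g",
                         vc_formula={"treatment": "0 + C(treatment)"})
        fit = md.fit(reml=True, method="lbfgs")
        mine = fit_variance_components(frame, ("treatment",))
        assert mine.sigma2["treatment"] == pytest.approx(float(fit.vcomp[0]), rel=1e-3, abs=1e-6)
        assert mine.sigma2_resid == pytest.approx(float(fit.scale), rel=1e-3)


class TestAsePartition:
    def test_combined_scope_factor_set(self, effect_obs):
        _, obs = effect_obs
        out = partition_ase_variance(obs, scope="combined")
        assert {"frac_vehicle", "frac_cell_type", "frac_treatment",
                "frac_cell_type:treatment"} <= set(out.columns)
        sums = out[[c for c in out.columns if c.startswith("frac_")]].sum(axis=1) \
            + out["residual_fraction"]
        assert np.allclose(sums[out["converged"]], 1.0, atol=1e-6)

    def test_per_celltype_scope_excludes_celltype_factor(self, effect_obs):
        _, obs = effect_obs
        out = partition_ase_variance(obs, scope="per_cell_type")
        assert "frac_cell_type" not in out.columns
        assert {"frac_vehicle", "frac_plate", "frac_treatment"} <= set(out.columns)
        assert set(out["scope"]) == {"CM", "IPSC", "LCL"}

    def test_unit_restriction(self, effect_obs):
        _, obs = effect_obs
        units = {("snp000000", "ind1")}
        out = partition_ase_variance(obs, units=units)
        assert list(out["unit_id"]) == ["snp000000:ind1"]

    def test_null_generator_fractions_small(self, null_obs):
        out = partition_ase_variance(null_obs)
        assert out["frac_cell_type"].median() <= 0.05
        assert out["frac_treatment"].median() <= 0.05


class TestExpressionPartition:
    def _design(self, n_ind=4, n_treat=3, n_plates=2):
        import itertools
        rows = [
            {"individual": f"i{i}", "cell_type": "CM", "treatment": f"t{t}",
             "plate": f"p{p}"}
            for i, t, p in itertools.product(range(n_ind), range(n_treat), range(n_plates))
        ]
        return pd.DataFrame(rows)

    def test_individual_driven_gene(self):
        design = self._design()
        rng = np.random.default_rng(30)
        offsets = {f"i{i}": v for i, v in enumerate(rng.normal(0, 3, 4))}
        expr = design["individual"].map(offsets) + rng.normal(0, 0.2, len(design))
        matrix = pd.DataFrame([expr.to_numpy()], index=["geneA"])
        out = partition_expression_variance(matrix, design)
        assert out.loc[0, "frac_individual"] >= 0.9

    def test_constant_gene_flagged(self):
        design = self._design()
        matrix = pd.DataFrame([np.ones(len(design))], index=["flat"])
        out = partition_expression_variance(matrix, design)
        assert not out.loc[0, "converged"]
        assert np.isnan(out.loc[0, "residual_fraction"])

    def test_mismatched_library_count_rejected(self):
        with pytest.raises(ValueError):
            partition_expression_variance(
                pd.DataFrame([[1.0, 2.0]]), self._design()
            )

    def test_cpm_filter_hand_computed(self):
        # library sizes 100 and 400 -> cpm threshold 1 corresponds to raw
        # counts >= 0.0001 and 0.0004 of the library; gene g2 passes in only
        # 1 of 2 libraries (50%) and g3 in 0
        counts = pd.DataFrame(
            {"lib1": [90, 1, 0, 9], "lib2": [300, 0, 0, 100]},
            index=["g1", "g2", "g3", "g4"],
        )
        kept = cpm_filter(counts, min_cpm=1.0, min_fraction=0.75)
        assert list(kept.index) == ["g1", "g4"]
        kept_half = cpm_filter(counts, min_cpm=1.0, min_fraction=0.5)
        assert list(kept_half.index) == ["g1", "g2", "g4"]


class TestAnnotationRegression:
    def _varcomp(self, response, coverage):
        return pd.DataFrame({
            "unit_id": [f"u{i}" for i in range(len(response))],
            "sigma2_resid": response,
            "coverage_covariate": coverage,
        })

    def test_binary_annotation_exact_coefficient(self):
        vc = self._varcomp([1.0, 1.0, 2.0, 2.0], [2.0] * 4)
        ann = pd.DataFrame({"flag": [0, 0, 1, 1]}, index=[f"u{i}" for i in range(4)])
        out = annotation_variance_regression(vc, ann, "sigma2_resid", min_units=4)
        assert out.loc[0, "coefficient"] == pytest.approx(1.0, abs=1e-10)

    def test_perfect_fit_p_at_floor(self):
        rng = np.random.default_rng(31)
        resp = rng.uniform(1, 2, 20)
        vc = self._varcomp(resp, [2.0] * 20)
        ann = pd.DataFrame({"self": resp}, index=[f"u{i}" for i in range(20)])
        out = annotation_variance_regression(vc, ann, "sigma2_resid")
        assert out.loc[0, "coefficient"] == pytest.approx(1.0, abs=1e-8)
        assert out.loc[0, "p"] < 1e-200

    def test_constant_annotation_skipped(self):
        vc = self._varcomp([1.0, 2.0] * 6, [2.0] * 12)
        ann = pd.DataFrame({"const": [1] * 12}, index=[f"u{i}" for i in range(12)])
        out = annotation_variance_regression(vc, ann, "sigma2_resid")
        assert len(out) == 0

    def test_coverage_covariate_absorbs_depth_trend(self):
        # a null annotation correlated with depth should not show up once the
        # coverage covariate is in the model
        rng = np.random.default_rng(32)
        n_sig = 0
        reps = 200
        for _ in range(reps):
            cov = rng.uniform(1, 3, 300)
            resp = 2.0 - 0.5 * cov + rng.normal(0, 0.1, 300)  # pure depth trend
            ann_vals = cov + rng.normal(0, 0.5, 300)          # depth-correlated null
            vc = self._varcomp(resp, cov)
            ann = pd.DataFrame({"nullann": ann_vals}, index=vc["unit_id"])
            out = annotation_variance_regression(vc, ann, "sigma2_resid")
            n_sig += int(out.loc[0, "p"] < 0.05)
        assert 1 - n_sig / reps >= 0.90


class TestRankVarianceGenes:
    def _varcomp(self, values):
        return pd.DataFrame({
            "unit_id": [f"s{i}:ind1" for i in range(len(values))],
            "sigma2_resid": values,
            "coverage_covariate": 2.0,
        })

    def test_counts(self):
        vc = self._varcomp(np.arange(10, dtype=float))
        mapping = {f"s{i}": f"g{i}" for i in range(10)}
        high, low = rank_variance_genes(vc, mapping, quantile=0.2)
        assert len(high) == 2 and len(low) == 2
        assert set(low) == {"g0", "g1"} and set(high) == {"g8", "g9"}

    def test_ties_resolved_by_stable_gene_order(self):
        vc = self._varcomp([1.0] * 10)
        mapping = {f"s{i}": f"g{i}" for i in range(10)}
        high, low = rank_variance_genes(vc, mapping, quantile=0.2)
        assert low == ["g0", "g1"]
        assert high == ["g8", "g9"]

    def test_empty_mapping(self):
        high, low = rank_variance_genes(self._varcomp([1.0, 2.0]), {}, 0.2)
        assert high == [] and low == []

    def test_gene_aggregation_is_median(self):
        vc = pd.DataFrame({
            "unit_id": ["s1:i1", "s2:i1", "s3:i1"],
            "sigma2_resid": [0.0, 10.0, 3.0],
            "coverage_covariate": 2.0,
        })
        mapping = {"s1": "gA", "s2": "gA", "s3": "gB"}
        high, low = rank_variance_genes(vc, mapping, quantile=0.4)
        assert set(high) == {"gA"} and set(low) == {"gB"}
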