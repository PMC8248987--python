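import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casekit import (
    PairCategory,
    build_observation_table,
    compare_correlation_categories,
    compute_ase,
    filter_sites,
    replicate_correlations,
)
from casekit.ase import classify_pair


class TestComputeAse:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (10, 10, 0.0),
            (0, 0, 0.0),
            (3, 1, math.log(2)),
            (7, 0, math.log(8)),
        ],
    )
    def test_pseudocount_log_ratio(self, ref, alt, expected):
        assert compute_ase(ref, alt) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_ase(-1, 5)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, ref, alt):
        assert compute_ase(ref, alt) == pytest.approx(-compute_ase(alt, ref), abs=1e-12)


class TestFilterSites:
    def _record(self, chrom, ref, alt):
        return pd.DataFrame(
            [{"chrom": chrom, "pos": 100, "ref_allele": "A", "alt_allele": "G",
              "snp_id": "s", "individual": "i", "cell_type": "LCL",
              "treatment": "water", "vehicle": "water", "plate": "p1",
              "ref_count": ref, "alt_count": alt}]
        )

    def test_coverage_cutoff_is_strict(self):
        # coverage exactly 5 is excluded at cutoff 5
        assert len(filter_sites(self._record("chr1", 3, 2), 5)) == 0
        assert len(filter_sites(self._record("chr1", 4, 2), 5)) == 1

    def test_non_autosomes_excluded(self):
        assert len(filter_sites(self._record("chrX", 100, 100), 5)) == 0

    def test_autosome_retained(self):
        assert len(filter_sites(self._record("chr7", 4, 3), 5)) == 1

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_sites(self._record("chr1", 1, 1), -1)


class TestObservationTable:
    def test_one_observation_per_record(self, null_obs):
        # full design for one individual: 3 cell types x 14 conditions x 2 plates
        per_unit = null_obs.groupby(["snp_id", "individual"]).size()
        assert (per_unit == 84).all()

    def test_empty_input(self):
        cols = ["chrom", "pos", "ref_allele", "alt_allele", "snp_id", "individual",
                "cell_type", "treatment", "vehicle", "plate", "ref_count", "alt_count"]
        out = build_observation_table(pd.DataFrame(columns=cols))
        assert len(out) == 0
        assert "ase" in out.columns


def _lib(ind, cell, treat, plate, veh):
    return pd.Series(
        {"individual": ind, "cell_type": cell, "treatment": treat,
         "plate": plate, "vehicle": veh}
    )


class TestPairCategories:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("i1", "CM", "caffeine", "p1", "water"),
             ("i1", "LCL", "caffeine", "p1", "water"), PairCategory.ACROSS_CELL),
            (("i1", "CM", "caffeine", "p1", "water"),
             ("i2", "CM", "caffeine", "p1", "water"), PairCategory.ACROSS_INDIVIDUAL),
            (("i1", "CM", "caffeine", "p1", "water"),
             ("i1", "CM", "caffeine", "p2", "water"), PairCategory.ACROSS_REPLICATE),
            (("i1", "CM", "caffeine", "p1", "water"),
             ("i1", "CM", "zinc", "p1", "water"), PairCategory.ACROSS_TREATMENT),
            (("i1", "CM", "water", "p1", "water"),
             ("i1", "CM", "ethanol", "p1", "ethanol"), PairCategory.CONTROL1_VS_CONTROL2),
            # two controls on different plates are not the control pair
            (("i1", "CM", "water", "p1", "water"),
             ("i1", "CM", "ethanol", "p2", "ethanol"), None),
        ],
    )
    def test_classification_rules(self, a, b, expected):
        got = classify_pair(_lib(a[0], a[1], a[2], a[3], a[4]),
                            _lib(b[0], b[1], b[2], b[3], b[4]))
        assert got == expected

    def test_categories_partition_pairs(self):
        # brute force over a 2x2x2x2 design plus a second vehicle control:
        # no pair can satisfy two category definitions
        libs = [
            _lib(i, c, t, p, "water")
            for i, c, t, p in itertools.product(
                ["i1", "i2"], ["CM", "LCL"], ["water", "zinc"], ["p1", "p2"]
            )
        ] + [
            _lib(i, c, "ethanol", p, "ethanol")
            for i, c, p in itertools.product(["i1", "i2"], ["CM", "LCL"], ["p1", "p2"])
        ]
        for a, b in itertools.combinations(libs, 2):
            matches = []
            for rule, cat in [
                (lambda: a["individual"] == b["individual"] and a["cell_type"] == b["cell_type"]
                 and a["plate"] == b["plate"] and a["treatment"] != b["treatment"]
                 and a["treatment"] == a["vehicle"] and b["treatment"] == b["vehicle"],
                 PairCategory.CONTROL1_VS_CONTROL2),
                (lambda: a["individual"] == b["individual"] and a["treatment"] == b["treatment"]
                 and a["cell_type"] != b["cell_type"], PairCategory.ACROSS_CELL),
                (lambda: a["cell_type"] == b["cell_type"] and a["treatment"] == b["treatment"]
                 and a["plate"] == b["plate"] and a["individual"] != b["individual"],
                 PairCategory.ACROSS_INDIVIDUAL),
                (lambda: a["individual"] == b["individual"] and a["cell_type"] == b["cell_type"]
                 and a["treatment"] == b["treatment"] and a["plate"] != b["plate"],
                 PairCategory.ACROSS_REPLICATE),
                (lambda: a["individual"] == b["individual"] and a["cell_type"] == b["cell_type"]
                 and a["plate"] == b["plate"] and a["treatment"] != b["treatment"]
                 and not (a["treatment"] == a["vehicle"] and b["treatment"] == b["vehicle"]),
                 PairCategory.ACROSS_TREATMENT),
            ]:
                if rule():
                    matches.append(cat)
            assert len(matches) <= 1
            assert classify_pair(a, b) == (matches[0] if matches else None)


class TestReplicateCorrelations:
    def _obs(self, vectors):
        """vectors: {(ind, cell, treat, plate, veh): {snp: ase}}"""
        rows = []
        for (ind, cell, treat, plate, veh), snps in vectors.items():
            for snp, value in snps.items():
                rows.append({"snp_id": snp, "individual": ind, "cell_type": cell,
                             "treatment": treat, "vehicle": veh, "plate": plate,
                             "ase": value, "coverage": 50})
        return pd.DataFrame(rows)

    def test_identical_vectors_give_rho_one(self):
        v = {f"s{i}": float(i) for i in range(5)}
        obs = self._obs({("i1", "CM", "zinc", "p1", "water"): v,
                         ("i1", "CM", "zinc", "p2", "water"): v})
        out = replicate_correlations(obs, set(v))
        assert out.loc[0, "category"] == "across_replicate"
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_rank_reversal_gives_rho_minus_one(self):
        v = {f"s{i}": float(i) for i in range(5)}
        w = {f"s{i}": float(-i) for i in range(5)}
        obs = self._obs({("i1", "CM", "zinc", "p1", "water"): v,
                         ("i1", "CM", "zinc", "p2", "water"): w})
        out = replicate_correlations(obs, set(v))
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_pairs_below_min_shared_are_skipped(self):
        v = {"s1": 1.0, "s2": 2.0}
        obs = self._obs({("i1", "CM", "zinc", "p1", "water"): v,
                         ("i1", "CM", "zinc", "p2", "water"): v})
        assert len(replicate_correlations(obs, {"s1", "s2"}, min_shared=3)) == 0

    def test_empty_significant_set_rejected(self, null_obs):
        with pytest.raises(ValueError):
            replicate_correlations(null_obs, set())


class TestCategoryComparison:
    def _table(self, groups):
        rows = []
        for cat, rhos in groups.items():
            for i, r in enumerate(rhos):
                rows.append({"library_a": f"a{i}", "library_b": f"b{i}",
                             "category": cat, "n_shared": 10, "rho": r})
        return pd.DataFrame(rows)

    def test_identical_distributions(self):
        rhos = list(np.linspace(0, 1, 10))
        out = compare_correlation_categories(self._table({"a": rhos, "b": rhos}))
        assert out.loc[0, "ks_statistic"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_disjoint_supports_force_supremum(self):
        rng = np.random.default_rng(0)
        lo = rng.uniform(0, 0.3, 50)
        hi = rng.uniform(0.7, 1.0, 50)
        out = compare_correlation_categories(self._table({"lo": lo, "hi": hi}))
        assert out.loc[0, "ks_statistic"] == pytest.approx(1.0)

    def test_three_categories_give_three_pairs(self):
        rng = np.random.default_rng(1)
        groups = {c: rng.uniform(0, 1, 8) for c in "abc"}
        assert len(compare_correlation_categories(self._table(groups))) == 3

    def test_undersized_category_skipped(self):
        rng = np.random.default_rng(2)
        out = compare_correlation_categories(
            self._table({"a": rng.uniform(0, 1, 8), "b": rng.uniform(0, 1, 8),
                         "c": [0.5]})
        )
        assert len(out) == 1


def test_null_replicate_and_control_correlations_match():
    """With no true effects the control-pair and replicate-pair correlation
    medians are driven by noise alone and should be close."""
    from casekit import SimParams, simulate_counts, simulate_truth

    params = SimParams(n_snps=60, n_individuals=2, prop_base=0.0,
                       sigma_resid=0.0, depth_mean=300.0, seed=11)
    obs = build_observation_table(filter_sites(simulate_counts(simulate_truth(params))))
    cors = replicate_correlations(obs, set(obs["snp_id"]))
    med = cors.groupby("category")["rho"].median()
    assert abs(med["across_replicate"] - med["control1_vs_control2"]) < 0.15
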