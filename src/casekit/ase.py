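"""ASE observation table and replicate-correlation quality control.

Allelic imbalance at a heterozygous site is summarized as the natural log of
the reference/alternate read-count ratio after adding a pseudocount of 1 to
both alleles: ase = ln((ref + 1) / (alt + 1)).  The pseudocount keeps sites
where one allele is unobserved, and maps ref == alt (including 0/0) to 0.

The correlation QC computes Spearman correlations of ASE between every pair
of libraries over their shared significant SNPs and buckets each pair by what
differs between the libraries (cell type, individual, replicate plate,
treatment, or the two vehicle controls), which separates biological from
technical sources of ASE variation.
"""

from __future__ import annotations

import itertools
import logging
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

AUTOSOMES = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
)


class PairCategory(str, Enum):
    """What differs between two libraries being correlated."""

    ACROSS_CELL = "across_cell"
    ACROSS_INDIVIDUAL = "across_individual"
    ACROSS_REPLICATE = "across_replicate"
    ACROSS_TREATMENT = "across_treatment"
    CONTROL1_VS_CONTROL2 = "control1_vs_control2"


def compute_ase(ref_count, alt_count):
    """ln((ref + 1)/(alt + 1)); antisymmetric in its arguments."""
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    out = np.log((ref + 1.0) / (alt + 1.0))
    return float(out) if out.ndim == 0 else out


def filter_sites(
    counts: pd.DataFrame,
    min_coverage: int = 5,
    autosomes: frozenset[str] = AUTOSOMES,
) -> pd.DataFrame:
    """Keep autosomal records with coverage strictly greater than the cutoff."""
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    cov = counts["ref_count"] + counts["alt_count"]
    keep = (cov > min_coverage) & counts["chrom"].astype(str).isin(autosomes)
    return counts.loc[keep].reset_index(drop=True)


def build_observation_table(counts: pd.DataFrame) -> pd.DataFrame:
    """One ASE observation per (already filtered) count record."""
    cols = ["snp_id", "individual", "cell_type", "treatment", "vehicle", "plate"]
    obs = counts[cols].copy()
    obs["ase"] = compute_ase(
        counts["ref_count"].to_numpy(), counts["alt_count"].to_numpy()
    )
    obs["coverage"] = (counts["ref_count"] + counts["alt_count"]).astype(int)
    return obs.reset_index(drop=True)


_LIB_KEY = ["individual", "cell_type", "treatment", "plate"]


def classify_pair(lib_a: pd.Series, lib_b: pd.Series) -> PairCategory | None:
    """Assign a library pair to its correlation category, or None.

    The categories partition the eligible pairs: a control-vs-control pair on
    one plate is never also counted as an across-treatment pair.
    """
    same = {k: lib_a[k] == lib_b[k] for k in _LIB_KEY + ["vehicle"]}
    both_controls = (
        lib_a["treatment"] == lib_a["vehicle"]
        and lib_b["treatment"] == lib_b["vehicle"]
    )
    if (
        same["individual"] and same["cell_type"] and same["plate"]
        and not same["treatment"] and both_controls
    ):
        return PairCategory.CONTROL1_VS_CONTROL2
    if same["individual"] and same["treatment"] and not same["cell_type"]:
        return PairCategory.ACROSS_CELL
    if (
        same["cell_type"] and same["treatment"] and same["plate"]
        and not same["individual"]
    ):
        return PairCategory.ACROSS_INDIVIDUAL
    if (
        same["individual"] and same["cell_type"] and same["treatment"]
        and not same["plate"]
    ):
        return PairCategory.ACROSS_REPLICATE
    if (
        same["individual"] and same["cell_type"] and same["plate"]
        and not same["treatment"]
    ):
        return PairCategory.ACROSS_TREATMENT
    return None


def replicate_correlations(
    obs: pd.DataFrame,
    significant_snps: set[str],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Spearman rho per library pair over shared ASE-significant SNPs.

    Pairs with fewer than ``min_shared`` shared SNPs are skipped (counted in
    the log).  Ties are handled by average ranks (scipy default).
    """
    if not significant_snps:
        raise ValueError("significant_snps must be nonempty")
    sig = obs[obs["snp_id"].isin(significant_snps)]
    libs = sig.drop_duplicates(subset=_LIB_KEY)[_LIB_KEY + ["vehicle"]]
    vectors = {
        key: grp.set_index("snp_id")["ase"]
        for key, grp in sig.groupby(_LIB_KEY)
    }
    records = []
    n_skipped = 0
    lib_rows = list(libs.itertuples(index=False))
    for a, b in itertools.combinations(lib_rows, 2):
        sa, sb = pd.Series(a._asdict()), pd.Series(b._asdict())
        category = classify_pair(sa, sb)
        if category is None:
            continue
        va = vectors[tuple(sa[k] for k in _LIB_KEY)]
        vb = vectors[tuple(sb[k] for k in _LIB_KEY)]
        shared = va.index.intersection(vb.index)
        if len(shared) < min_shared:
            n_skipped += 1
            continue
        rho = stats.spearmanr(va.loc[shared], vb.loc[shared]).statistic
        records.append(
            {
                "library_a": ":".join(str(sa[k]) for k in _LIB_KEY),
                "library_b": ":".join(str(sb[k]) for k in _LIB_KEY),
                "category": category.value,
                "n_shared": len(shared),
                "rho": rho,
            }
        )
    if n_skipped:
        log.info("skipped %d pairs with < %d shared SNPs", n_skipped, min_shared)
    return pd.DataFrame(
        records, columns=["library_a", "library_b", "category", "n_shared", "rho"]
    )


def compare_correlation_categories(cor_table: pd.DataFrame) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov test for every pair of categories."""
    groups = {
        cat: grp["rho"].dropna().to_numpy()
        for cat, grp in cor_table.groupby("category")
    }
    usable = {c: v for c, v in groups.items() if len(v) >= 2}
    skipped = set(groups) - set(usable)
    if skipped:
        log.warning("categories with < 2 correlations skipped: %s", sorted(skipped))
    if len(usable) < 2:
        raise ValueError("need >= 2 categories with >= 2 correlations each")
    rows = []
    for ca, cb in itertools.combinations(sorted(usable), 2):
        res = stats.ks_2samp(usable[ca], usable[cb], method="auto")
        rows.append(
            {
                "category_a": ca,
                "category_b": cb,
                "ks_statistic": res.statistic,
                "p": res.pvalue,
                "n_a": len(usable[ca]),
                "n_b": len(usable[cb]),
            }
        )
    return pd.DataFrame(rows)
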