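"""Conditional ASE: per-coefficient tests of the fixed-effect model.

A SNP-individual unit that shows ASE overall is refit with the same factor
model (Control + CellType + Treatment + CellType:Treatment, or
Control + Plate + Treatment within one cell type) and every coefficient is
tested with a t statistic on the residual degrees of freedom.  A significant
cell-type, treatment, or interaction coefficient is one *instance* of
conditional ASE (cASE) — a molecular gene-by-environment signal.  Multiple
testing is controlled separately within each term class (all cell-type
coefficients across units form one BH family, all treatment coefficients
another, all interactions a third), mirroring how the three classes are
reported.

Treatment contrasts are anchored at the control condition: the reference
level of the treatment and vehicle factors is the first control label, so a
treatment coefficient is that treatment's ASE shift relative to baseline.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .detection import GROUP_KEY, bh_fdr
from .linmod import COMBINED_SPEC, PER_CELLTYPE_SPEC, ModelSpec, build_model_matrix, ols_fit

log = logging.getLogger(__name__)


class DegenerateGroupError(ValueError):
    """Unit cannot support the per-term fit (no residual degrees of freedom)."""


_LEVEL_RE = re.compile(r"\[T\.([^\]]+)\]")

_FACTOR_CLASS = {
    "vehicle": "control",
    "cell_type": "cell_type",
    "treatment": "treatment",
    "plate": "plate",
}


def classify_coefficient(name: str) -> tuple[str, str] | None:
    """Map a model-matrix column name to (term_class, level); None for intercept."""
    if name == "Intercept":
        return None
    levels = _LEVEL_RE.findall(name)
    factors = re.findall(r"C\((\w+)\)", name)
    if ":" in name:
        return "celltype_x_treatment", ":".join(levels)
    if len(factors) == 1 and factors[0] in _FACTOR_CLASS:
        return _FACTOR_CLASS[factors[0]], levels[0] if levels else name
    return "other", name


def fit_case(
    group: pd.DataFrame,
    spec: ModelSpec = COMBINED_SPEC,
    reference_control: str | None = None,
) -> pd.DataFrame:
    """Per-coefficient estimates and t tests for one SNP-individual unit.

    Aliased (inestimable) coefficients are reported with ``estimable=False``
    and missing estimates rather than dropped silently.
    """
    y = group["ase"].to_numpy(dtype=float)
    X = build_model_matrix(group, spec, reference_control)
    fit = ols_fit(X, y)
    if fit.df_resid < 1:
        raise DegenerateGroupError(
            f"unit has {fit.n} observations for {fit.df_model} parameters"
        )
    rows = []
    for j, name in enumerate(fit.names):
        parsed = classify_coefficient(name)
        if parsed is None:
            continue
        term_class, level = parsed
        rows.append(
            {
                "term_class": term_class,
                "level": level,
                "estimate": fit.beta[j],
                "se": fit.se[j],
                "t": fit.tvalues[j],
                "p": fit.pvalues[j],
                "df_resid": fit.df_resid,
                "estimable": True,
            }
        )
    for name in fit.aliased:
        parsed = classify_coefficient(name)
        if parsed is None:
            continue
        term_class, level = parsed
        rows.append(
            {
                "term_class": term_class,
                "level": level,
                "estimate": np.nan,
                "se": np.nan,
                "t": np.nan,
                "p": np.nan,
                "df_resid": fit.df_resid,
                "estimable": False,
            }
        )
    return pd.DataFrame(rows)


def fit_case_per_celltype(
    group: pd.DataFrame,
    reference_control: str | None = None,
) -> pd.DataFrame:
    """Per-term fit within a single cell type; plate enters as a covariate."""
    if group["cell_type"].nunique() != 1:
        raise ValueError("fit_case_per_celltype expects observations from one cell type")
    return fit_case(group, PER_CELLTYPE_SPEC, reference_control)


def _controls_covered_per_celltype(group: pd.DataFrame) -> bool:
    controls = set(group["vehicle"].astype(str))
    for _, sub in group.groupby("cell_type", observed=True):
        is_ctl = sub["treatment"].astype(str) == sub["vehicle"].astype(str)
        seen = set(sub.loc[is_ctl, "treatment"].astype(str))
        if seen < controls:
            return False
    return True


def case_scan(
    obs: pd.DataFrame,
    ase_results: pd.DataFrame,
    spec: ModelSpec = COMBINED_SPEC,
    fdr_level: float = 0.10,
    reference_control: str | None = None,
) -> pd.DataFrame:
    """Fit the per-term model for every ASE-significant unit.

    Units must additionally have at least one observation of each control in
    each cell type they cover; others are skipped with a log entry.  BH
    correction is applied within each term class across all units.
    """
    sig = ase_results[ase_results["significant"]]
    sig_units = set(zip(sig["snp_id"], sig["individual"]))
    frames = []
    n_skipped = 0
    for key, group in obs.groupby(GROUP_KEY, observed=True, sort=True):
        if key not in sig_units:
            continue
        if not _controls_covered_per_celltype(group):
            n_skipped += 1
            continue
        try:
            terms = fit_case(group, spec, reference_control)
        except DegenerateGroupError as exc:
            log.info("unit %s skipped: %s", key, exc)
            n_skipped += 1
            continue
        terms.insert(0, "snp_id", key[0])
        terms.insert(1, "individual", key[1])
        frames.append(terms)
    if n_skipped:
        log.info("case_scan skipped %d units", n_skipped)
    if not frames:
        return pd.DataFrame(
            columns=["snp_id", "individual", "term_class", "level", "estimate",
                     "se", "t", "p", "df_resid", "estimable", "q", "significant"]
        )
    result = pd.concat(frames, ignore_index=True)
    result["q"] = np.nan
    result["significant"] = False
    for term_class, idx in result.groupby("term_class").groups.items():
        sub = result.loc[idx]
        ok = sub["estimable"] & sub["p"].notna()
        if ok.any():
            q, sig_flags = bh_fdr(sub.loc[ok, "p"].to_numpy(), fdr_level)
            result.loc[sub.index[ok], "q"] = q
            result.loc[sub.index[ok], "significant"] = sig_flags
    return result


def summarize_case(
    results: pd.DataFrame,
    snp_to_gene: dict[str, str] | None = None,
    level: float = 0.10,
    by_level: bool = False,
) -> pd.DataFrame:
    """Count significant instances, unique SNPs, and unique genes per term class.

    An *instance* is one significant coefficient in one SNP-individual
    regression, so instances >= unique SNPs >= unique genes.  SNPs absent
    from the gene map count toward SNP tallies but not gene tallies.
    """
    snp_to_gene = snp_to_gene or {}
    if len(results) == 0:
        return pd.DataFrame(columns=["term_class", "instances", "unique_snps", "unique_genes"])
    sig = results[results["significant"] & results["estimable"]]
    unmapped = set(sig["snp_id"]) - set(snp_to_gene)
    if unmapped and snp_to_gene:
        log.info("%d significant SNPs missing from the gene map", len(unmapped))
    keys = ["term_class", "level"] if by_level else ["term_class"]
    rows = []
    for key, grp in sig.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        genes = {snp_to_gene[s] for s in grp["snp_id"] if s in snp_to_gene}
        rows.append(
            dict(zip(keys, key))
            | {
                "instances": len(grp),
                "unique_snps": grp["snp_id"].nunique(),
                "unique_genes": len(genes),
            }
        )
    out = pd.DataFrame(rows, columns=keys + ["instances", "unique_snps", "unique_genes"])
    # make zero-count classes explicit
    for term_class in ("cell_type", "treatment", "celltype_x_treatment"):
        if not by_level and term_class not in set(out["term_class"]):
            out.loc[len(out)] = {
                "term_class": term_class, "instances": 0,
                "unique_snps": 0, "unique_genes": 0,
            }
    return out.sort_values(keys).reset_index(drop=True)
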