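"""ASE detection: whole-model ANOVA per SNP-individual against the zero model.

For each SNP in each individual, the ASE log-ratios observed across all
conditions are regressed on the design factors (vehicle/Control, cell type,
treatment, their interaction — or Control + plate + treatment when one cell
type is analyzed alone).  The null is the *zero* model: fitted values
identically 0 and no free parameters, i.e. no allelic imbalance anywhere.
Because the reduced model has no intercept, the numerator degrees of freedom
of the F test count every estimable parameter of the full model, intercept
included.

Significance across SNP-individual units is controlled with Benjamini-
Hochberg FDR (default level 10%); the combined-model scan forms one
correction family and each per-cell-type scan its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import COMBINED_SPEC, PER_CELLTYPE_SPEC, ModelSpec, build_model_matrix, ols_fit

log = logging.getLogger(__name__)

GROUP_KEY = ["snp_id", "individual"]

#: smallest representable p-value, used when the full model fits exactly
P_FLOOR = np.nextafter(0.0, 1.0)


def bh_fdr(pvalues, level: float = 0.10):
    """Benjamini-Hochberg step-up q-values and significance flags.

    Returns ``(q, significant)`` where ``significant = q < level``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] / (np.arange(1, m + 1) / m)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < level


@dataclass
class TestabilityThresholds:
    """Unit-eligibility rules for the ANOVA scan."""

    __test__ = False  # not a pytest class, despite the name

    min_conditions_per_celltype: int = 5
    min_resid_df: int = 5
    controls_per_celltype: bool = False  # True for per-cell-type / cASE scans


def _group_testable(
    group: pd.DataFrame,
    spec: ModelSpec,
    thresholds: TestabilityThresholds,
    required_cell_types: list[str] | None,
    reference_control: str | None,
) -> bool:
    controls = sorted(set(group["vehicle"].astype(str)))
    if required_cell_types:
        present = group.groupby("cell_type", observed=True)["treatment"].nunique()
        for ct in required_cell_types:
            if present.get(ct, 0) < thresholds.min_conditions_per_celltype:
                return False
    else:
        if group["treatment"].nunique() < thresholds.min_conditions_per_celltype:
            return False
    # at least one measurement of each control library
    is_control_obs = group["treatment"].astype(str) == group["vehicle"].astype(str)
    ctl_obs = group[is_control_obs]
    scopes = (
        required_cell_types if thresholds.controls_per_celltype and required_cell_types
        else [None]
    )
    for scope_ct in scopes:
        sub = ctl_obs if scope_ct is None else ctl_obs[ctl_obs["cell_type"] == scope_ct]
        if set(sub["treatment"].astype(str)) < set(controls):
            return False
    X = build_model_matrix(group, spec, reference_control)
    fit_rank = len(ols_fit(X, np.zeros(len(group))).names)
    return len(group) - fit_rank >= thresholds.min_resid_df


def select_testable(
    obs: pd.DataFrame,
    spec: ModelSpec = COMBINED_SPEC,
    thresholds: TestabilityThresholds | None = None,
    required_cell_types: list[str] | None = None,
    reference_control: str | None = None,
) -> list[tuple]:
    """Eligible (snp_id, individual) groups for the ANOVA scan.

    A unit qualifies if ASE was measured in at least
    ``min_conditions_per_celltype`` conditions in every required cell type,
    every control label has at least one observation, and the residual
    degrees of freedom after dropping aliased columns meet ``min_resid_df``.
    By default the required cell types are all cell types present in ``obs``
    when the spec models cell type, else none.
    """
    thresholds = thresholds or TestabilityThresholds()
    if required_cell_types is None:
        models_cell = any("cell_type" in t for t in spec.terms)
        required_cell_types = (
            sorted(obs["cell_type"].astype(str).unique()) if models_cell else []
        )
    eligible = []
    for key, group in obs.groupby(GROUP_KEY, observed=True, sort=True):
        if _group_testable(group, spec, thresholds, required_cell_types, reference_control):
            eligible.append(key)
    return eligible


def anova_ase(
    group: pd.DataFrame,
    spec: ModelSpec = COMBINED_SPEC,
    reference_control: str | None = None,
) -> dict:
    """F test of the full factor model against the zero model for one unit."""
    y = group["ase"].to_numpy(dtype=float)
    X = build_model_matrix(group, spec, reference_control)
    fit = ols_fit(X, y)
    rss_reduced = float(y @ y)
    rss_full = fit.rss
    df1, df2 = fit.df_model, fit.df_resid
    flag = ""
    if rss_full <= 1e-300 and rss_reduced <= 1e-300:
        f_stat, p = 0.0, 1.0
        flag = "degenerate"
    elif rss_full <= 1e-300:
        f_stat, p = np.inf, P_FLOOR
        flag = "exact_fit"
    else:
        f_stat = ((rss_reduced - rss_full) / df1) / (rss_full / df2)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df1, df2))
    return {
        "F": f_stat,
        "df1": df1,
        "df2": df2,
        "p": p,
        "rss_full": rss_full,
        "rss_reduced": rss_reduced,
        "flag": flag,
    }


def ase_scan(
    obs: pd.DataFrame,
    spec: ModelSpec = COMBINED_SPEC,
    scope: str = "combined",
    fdr_level: float = 0.10,
    thresholds: TestabilityThresholds | None = None,
    reference_control: str | None = None,
) -> pd.DataFrame:
    """ANOVA over every testable SNP-individual unit, BH-corrected as one family."""
    eligible = set(
        select_testable(obs, spec, thresholds, reference_control=reference_control)
    )
    rows = []
    for key, group in obs.groupby(GROUP_KEY, observed=True, sort=True):
        if key not in eligible:
            continue
        res = anova_ase(group, spec, reference_control)
        rows.append({"snp_id": key[0], "individual": key[1], "scope": scope, **res})
    result = pd.DataFrame(
        rows,
        columns=["snp_id", "individual", "scope", "F", "df1", "df2", "p",
                 "rss_full", "rss_reduced", "flag"],
    )
    if len(result):
        q, sig = bh_fdr(result["p"].to_numpy(), fdr_level)
        result["q"] = q
        result["significant"] = sig
    else:
        result["q"] = []
        result["significant"] = []
    return result


def ase_scan_per_celltype(
    obs: pd.DataFrame,
    fdr_level: float = 0.10,
    thresholds: TestabilityThresholds | None = None,
    reference_control: str | None = None,
) -> pd.DataFrame:
    """Per-cell-type ANOVA scans; each cell type is its own BH family."""
    frames = []
    for ct, sub in obs.groupby("cell_type", observed=True, sort=True):
        frames.append(
            ase_scan(
                sub,
                PER_CELLTYPE_SPEC,
                scope=str(ct),
                fdr_level=fdr_level,
                thresholds=thresholds,
                reference_control=reference_control,
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
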