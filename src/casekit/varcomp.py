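"""Random-effect variance decomposition of ASE and expression.

Each unit (a SNP-individual for ASE, a gene for expression) is modeled as a
random-intercept mixed model: every design factor contributes an independent
Gaussian level effect, and the fraction of total variance attributed to each
factor is sigma_k^2 / (sum_k sigma_k^2 + sigma_e^2).  Components are
estimated by restricted maximum likelihood (REML), profiled over the
variance ratios gamma_k = sigma_k^2 / sigma_e^2 with the residual variance
solved in closed form; negative solutions are truncated at zero by the
box constraint gamma_k >= 0.  On balanced designs the interior REML solution
coincides with the classical ANOVA (Henderson) method-of-moments estimator,
which serves as the test oracle.

Residual ASE variance is partially a function of sequencing depth, so every
unit carries its mean log10 coverage; downstream regressions of variance on
gene annotations include that covariate to absorb the depth trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

#: Eq-style factor sets.  "Control" is the vehicle label; "Batch" the plate.
ASE_COMBINED_FACTORS = ("vehicle", "cell_type", "treatment", "cell_type:treatment")
ASE_PER_CELLTYPE_FACTORS = ("vehicle", "plate", "treatment")
EXPRESSION_COMBINED_FACTORS = ("individual", "cell_type", "plate", "treatment")
EXPRESSION_PER_CELLTYPE_FACTORS = ("individual", "treatment", "plate", "individual:treatment")


@dataclass
class VarCompResult:
    """Variance fractions for one unit; fractions + residual sum to one."""

    unit_id: str
    scope: str
    fractions: dict[str, float]
    residual_fraction: float
    sigma2: dict[str, float]
    sigma2_resid: float
    coverage_covariate: float = np.nan
    converged: bool = True
    dropped_factors: tuple[str, ...] = ()

    @property
    def total_variance(self) -> float:
        return sum(self.sigma2.values()) + self.sigma2_resid


def _factor_levels(frame: pd.DataFrame, factor: str) -> pd.Series:
    if ":" in factor:
        a, b = factor.split(":")
        return frame[a].astype(str) + ":" + frame[b].astype(str)
    return frame[factor].astype(str)


def _indicator(levels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(levels, sort=True)
    return np.eye(codes.max() + 1)[codes]


def reml_variance_components(
    y: np.ndarray,
    Zs: list[np.ndarray],
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    """REML estimates (sigma2_k for each Z, sigma2_resid, converged).

    The REML criterion is profiled over the variance ratios; each evaluation
    costs one q x q Cholesky factorization (q = total random levels), so
    units with dozens of levels fit in milliseconds.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    Z = np.hstack(Zs)
    qs = [z.shape[1] for z in Zs]
    q = Z.shape[1]
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    ZtX = Z.T @ X

    def crit(gam: np.ndarray) -> tuple[float, float]:
        g = np.repeat(np.maximum(gam, 0.0), qs)
        sg = np.sqrt(g)
        M = np.eye(q) + sg[:, None] * ZtZ * sg[None, :]
        cf = np.linalg.cholesky(M)
        logdet_w = 2.0 * np.sum(np.log(np.diag(cf)))

        def winv(ZtA, A):
            t = np.linalg.solve(M, sg[:, None] * ZtA)
            return A - Z @ (sg[:, None] * t)

        wiX = winv(ZtX, X)
        wiy = winv(Zty[:, None], y[:, None])[:, 0]
        xtwix = float((X[:, 0] @ wiX[:, 0]))
        xtwiy = float(X[:, 0] @ wiy)
        beta = xtwiy / xtwix
        r2 = float(y @ wiy) - xtwiy * beta
        s2e = max(r2 / (n - 1), 1e-300)
        return logdet_w + np.log(xtwix) + (n - 1) * np.log(s2e), s2e

    k = len(Zs)
    res = optimize.minimize(
        lambda g: crit(g)[0],
        np.ones(k),
        method="L-BFGS-B",
        bounds=[(0.0, 1e8)] * k,
        options=dict(ftol=1e-14, gtol=1e-12, maxiter=500),
    )
    # polish with a derivative-free pass; the profile surface is smooth but
    # L-BFGS-B's numerical gradient can stall near the boundary
    res2 = optimize.minimize(
        lambda g: crit(np.maximum(g, 0.0))[0],
        res.x,
        method="Nelder-Mead",
        options=dict(xatol=1e-12, fatol=1e-14, maxiter=4000, maxfev=6000),
    )
    gam = np.maximum(res2.x if res2.fun <= res.fun else res.x, 0.0)
    _, s2e = crit(gam)
    sigma2 = gam * s2e
    converged = bool(res.success or res2.success)
    return sigma2, float(s2e), converged


def fit_variance_components(
    unit: pd.DataFrame,
    random_factors: tuple[str, ...],
    response: str = "ase",
    unit_id: str = "",
    scope: str = "combined",
) -> VarCompResult:
    """Variance fractions over named random factors for one unit.

    Factors with a single observed level carry no variance information and
    are dropped (recorded in ``dropped_factors``).
    """
    y = unit[response].to_numpy(dtype=float)
    kept, dropped, Zs = [], [], []
    for factor in random_factors:
        levels = _factor_levels(unit, factor)
        if levels.nunique() < 2:
            dropped.append(factor)
            continue
        kept.append(factor)
        Zs.append(_indicator(levels))
    if dropped:
        log.info("unit %s: dropped single-level factors %s", unit_id, dropped)
    if not kept or np.var(y) == 0:
        return VarCompResult(
            unit_id=unit_id, scope=scope, fractions={}, residual_fraction=np.nan,
            sigma2={}, sigma2_resid=np.nan, converged=False,
            dropped_factors=tuple(dropped),
        )
    sigma2, s2e, converged = reml_variance_components(y, Zs)
    total = sigma2.sum() + s2e
    fractions = {f: float(v / total) for f, v in zip(kept, sigma2)}
    cov = (
        float(np.log10(unit["coverage"].astype(float).mean()))
        if "coverage" in unit.columns
        else np.nan
    )
    return VarCompResult(
        unit_id=unit_id,
        scope=scope,
        fractions=fractions,
        residual_fraction=float(s2e / total),
        sigma2={f: float(v) for f, v in zip(kept, sigma2)},
        sigma2_resid=float(s2e),
        coverage_covariate=cov,
        converged=converged,
        dropped_factors=tuple(dropped),
    )


def _results_frame(results: list[VarCompResult], factors: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"unit_id": r.unit_id, "scope": r.scope}
        for f in factors:
            row[f"frac_{f}"] = r.fractions.get(f, np.nan)
            row[f"sigma2_{f}"] = r.sigma2.get(f, np.nan)
        row["residual_fraction"] = r.residual_fraction
        row["sigma2_resid"] = r.sigma2_resid
        row["total_variance"] = r.total_variance
        row["coverage_covariate"] = r.coverage_covariate
        row["converged"] = r.converged
        rows.append(row)
    return pd.DataFrame(rows)


def partition_ase_variance(
    obs: pd.DataFrame,
    scope: str = "combined",
    factors: tuple[str, ...] | None = None,
    units: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Variance decomposition of ASE for each SNP-individual unit.

    ``units`` restricts the decomposition to ASE-significant groups (pass the
    significant (snp_id, individual) pairs from the ANOVA scan).  Scope
    "combined" uses vehicle/cell type/treatment/interaction; "per_cell_type"
    uses vehicle/plate/treatment within each cell type.
    """
    if factors is None:
        factors = (
            ASE_COMBINED_FACTORS if scope == "combined" else ASE_PER_CELLTYPE_FACTORS
        )
    results = []
    if scope == "combined":
        grouped = obs.groupby(["snp_id", "individual"], observed=True, sort=True)
        for (snp, ind), group in grouped:
            if units is not None and (snp, ind) not in units:
                continue
            results.append(
                fit_variance_components(
                    group, factors, unit_id=f"{snp}:{ind}", scope=scope
                )
            )
    else:
        grouped = obs.groupby(["snp_id", "individual", "cell_type"], observed=True, sort=True)
        for (snp, ind, ct), group in grouped:
            if units is not None and (snp, ind) not in units:
                continue
            results.append(
                fit_variance_components(
                    group, factors, unit_id=f"{snp}:{ind}", scope=str(ct)
                )
            )
    return _results_frame(results, factors)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per library (columns are libraries)."""
    libsize = counts.sum(axis=0)
    return counts * 1e6 / libsize


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 1.0, min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep genes with cpm >= min_cpm in at least min_fraction of libraries."""
    frac = (cpm(counts) >= min_cpm).mean(axis=1)
    return counts.loc[frac >= min_fraction]


def log_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2(cpm + prior) fallback transform for raw count matrices."""
    return np.log2(cpm(counts) + prior)


def partition_expression_variance(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    scope: str = "combined",
    factors: tuple[str, ...] | None = None,
    raw_counts: bool = False,
) -> pd.DataFrame:
    """Variance decomposition of an expression matrix (units x libraries).

    ``matrix`` rows are genes (or introns) and columns align with ``design``
    rows (one per library).  Pass ``raw_counts=True`` to apply the cpm >= 1
    in 50% of libraries filter and the log2(cpm + 0.5) transform; otherwise
    the matrix is assumed already variance-stabilized.
    """
    if matrix.shape[1] != len(design):
        raise ValueError(
            f"matrix has {matrix.shape[1]} libraries but design has {len(design)} rows"
        )
    if factors is None:
        factors = (
            EXPRESSION_COMBINED_FACTORS
            if scope == "combined"
            else EXPRESSION_PER_CELLTYPE_FACTORS
        )
    if raw_counts:
        matrix = log_cpm(cpm_filter(matrix))
    results = []
    frame = design.reset_index(drop=True).copy()
    for gene, row in matrix.iterrows():
        unit = frame.copy()
        unit["expr"] = row.to_numpy(dtype=float)
        results.append(
            fit_variance_components(
                unit, factors, response="expr", unit_id=str(gene), scope=scope
            )
        )
    return _results_frame(results, factors)


def annotation_variance_regression(
    varcomp: pd.DataFrame,
    annotations: pd.DataFrame,
    response: str,
    min_units: int = 10,
) -> pd.DataFrame:
    """Regress a variance response on each annotation, adjusting for coverage.

    ``response`` is a column of ``varcomp`` (e.g. ``sigma2_treatment``,
    ``sigma2_resid``, or a mean-absolute-ASE column merged in); each
    annotation column of ``annotations`` (indexed by unit_id) is fit in the
    model ``response ~ annotation + mean log10 coverage``.  Categorical
    annotations are expanded to indicator contrasts.
    """
    merged = varcomp.set_index("unit_id").join(annotations, how="inner")
    rows = []
    for ann in annotations.columns:
        sub = merged[[response, ann, "coverage_covariate"]].dropna()
        if len(sub) < min_units:
            log.warning("annotation %s defined for %d < %d units; skipped", ann, len(sub), min_units)
            continue
        col = sub[ann]
        if col.nunique() < 2:
            log.warning("annotation %s is constant; skipped", ann)
            continue
        if col.dtype == object or col.dtype.name == "category" or col.dtype == bool:
            x_ann = pd.get_dummies(col, drop_first=True, dtype=float)
        else:
            x_ann = col.to_frame().astype(float)
        X = np.column_stack(
            [np.ones(len(sub)), x_ann.to_numpy(), sub["coverage_covariate"].to_numpy()]
        )
        y = sub[response].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = len(sub) - X.shape[1]
        sigma2 = resid @ resid / df if df > 0 else np.nan
        xtxi = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtxi), 0))
        for j, name in enumerate(x_ann.columns):
            coef, coef_se = beta[1 + j], se[1 + j]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = coef / coef_se if coef_se > 0 else np.inf * np.sign(coef)
            p = 2 * stats.t.sf(abs(t), df) if df > 0 else np.nan
            rows.append(
                {
                    "annotation": str(name) if len(x_ann.columns) > 1 else ann,
                    "response": response,
                    "coefficient": coef,
                    "se": coef_se,
                    "t": t,
                    "p": p,
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows, columns=["annotation", "response", "coefficient", "se", "t", "p", "n"])


def rank_variance_genes(
    varcomp: pd.DataFrame,
    snp_to_gene: dict[str, str],
    quantile: float = 0.20,
    response: str = "sigma2_resid",
) -> tuple[list[str], list[str]]:
    """Top- and bottom-quantile gene sets by median residual variance.

    Gene-level variance is the median over the gene's units; ties at the cut
    are resolved by stable gene-ID order.
    """
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    if not snp_to_gene:
        log.warning("empty SNP-to-gene mapping; returning empty sets")
        return [], []
    snps = varcomp["unit_id"].str.split(":").str[0]
    genes = snps.map(snp_to_gene)
    per_gene = (
        varcomp.assign(gene=genes)
        .dropna(subset=["gene", response])
        .groupby("gene")[response]
        .median()
        .sort_values(kind="mergesort")  # stable: ties keep gene-ID order
    )
    k = max(1, int(round(quantile * len(per_gene)))) if len(per_gene) else 0
    if k == 0:
        return [], []
    low = list(per_gene.index[:k])
    high = list(per_gene.index[-k:])
    return high, low
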