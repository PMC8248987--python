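"""Shared least-squares machinery for the ASE linear models.

All models in this package are ordinary least squares on categorical
predictors.  Designs are frequently rank deficient (the vehicle covariate is
a function of the treatment factor; a treatment may be observed in only one
cell type), so the model matrix is reduced by a sequential left-to-right
sweep that keeps each column only if it is linearly independent of the
columns already kept — the same behaviour as R's pivoting ``lm``, which the
field's ASE scans rely on.  Earlier terms therefore absorb shared degrees of
freedom from later ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats


@dataclass(frozen=True)
class ModelSpec:
    """An ordered categorical model formula for ASE regressions.

    ``terms`` are patsy term strings evaluated against an observation table
    whose factor columns are pandas Categoricals (level order fixes the
    reference level).  The reduced model is always the zero model: fitted
    values identically 0, no parameters.
    """

    name: str
    terms: tuple[str, ...]

    @property
    def formula(self) -> str:
        return "1" if not self.terms else "1 + " + " + ".join(self.terms)


#: all-cell-type model: ASE ~ Control + CellType + Treatment + CellType:Treatment
COMBINED_SPEC = ModelSpec(
    "combined",
    ("C(vehicle)", "C(cell_type)", "C(treatment)", "C(cell_type):C(treatment)"),
)

#: one-cell-type model: ASE ~ Control + Plate + Treatment
PER_CELLTYPE_SPEC = ModelSpec(
    "per_cell_type",
    ("C(vehicle)", "C(plate)", "C(treatment)"),
)


def _with_reference_levels(obs: pd.DataFrame, reference_control: str | None) -> pd.DataFrame:
    """Order factor levels so the reference is the (first) control label."""
    out = obs.copy()
    for col in ("vehicle", "cell_type", "treatment", "plate"):
        if col not in out.columns:
            continue
        levels = sorted(map(str, out[col].unique()))
        if reference_control is not None and col in ("vehicle", "treatment"):
            ctl = [l for l in levels if l == reference_control]
            levels = ctl + [l for l in levels if l != reference_control]
        out[col] = pd.Categorical(out[col].astype(str), categories=levels)
    return out


_FACTOR_COLS = ("vehicle", "cell_type", "treatment", "plate")
_MATRIX_CACHE: dict = {}


def build_model_matrix(
    obs: pd.DataFrame,
    spec: ModelSpec,
    reference_control: str | None = None,
) -> pd.DataFrame:
    """Patsy model matrix (with intercept) before aliasing removal.

    Matrices are memoized on the exact sequence of factor values, which makes
    scans over thousands of units sharing one design cheap.
    """
    cols = [c for c in _FACTOR_COLS if c in obs.columns]
    key = (
        spec.name,
        spec.terms,
        reference_control,
        tuple(map(tuple, obs[cols].astype(str).to_numpy())),
    )
    cached = _MATRIX_CACHE.get(key)
    if cached is not None:
        return cached
    if reference_control is None and "vehicle" in obs.columns:
        # anchor treatment contrasts at the first control label
        reference_control = sorted(set(obs["vehicle"].astype(str)))[0]
    frame = _with_reference_levels(obs, reference_control)
    dm = patsy.dmatrix(self_formula(spec), frame, return_type="dataframe")
    dm.index = pd.RangeIndex(len(dm))
    if len(_MATRIX_CACHE) > 512:
        _MATRIX_CACHE.clear()
    _MATRIX_CACHE[key] = dm
    return dm


def self_formula(spec: ModelSpec) -> str:
    return spec.formula


def sequential_independent_columns(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Indices of a maximal independent subset, scanning left to right.

    Modified Gram-Schmidt: a column is kept iff its residual against the span
    of previously kept columns exceeds ``tol`` relative to its own norm.
    """
    n, m = X.shape
    Q = np.empty((n, min(n, m)))
    k = 0
    keep: list[int] = []
    for j in range(m):
        v = X[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            continue
        for i in range(k):
            v -= (Q[:, i] @ v) * Q[:, i]
        # second pass for numerical safety
        for i in range(k):
            v -= (Q[:, i] @ v) * Q[:, i]
        nv = np.linalg.norm(v)
        if nv > tol * norm0:
            Q[:, k] = v / nv
            k += 1
            keep.append(j)
    return keep


@dataclass
class OlsFit:
    """Least-squares fit with aliased columns dropped."""

    names: list[str]                 # estimable coefficient names, design order
    aliased: list[str]               # dropped (inestimable) coefficient names
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    rss: float
    df_model: int                    # number of estimable parameters
    df_resid: int
    n: int
    sigma2: float = field(default=np.nan)


def ols_fit(X: pd.DataFrame, y: np.ndarray, tol: float = 1e-9) -> OlsFit:
    y = np.asarray(y, dtype=float)
    keep = sequential_independent_columns(X.values, tol=tol)
    names = [X.columns[j] for j in keep]
    aliased = [c for j, c in enumerate(X.columns) if j not in set(keep)]
    Xk = X.values[:, keep]
    n, p = Xk.shape
    XtX = Xk.T @ Xk
    XtXi = np.linalg.pinv(XtX)
    beta = XtXi @ (Xk.T @ y)
    resid = y - Xk @ beta
    rss = float(resid @ resid)
    df_resid = n - p
    if df_resid > 0:
        sigma2 = rss / df_resid
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtXi), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.nan)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    else:
        sigma2 = np.nan
        se = np.full(p, np.nan)
        tvals = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    return OlsFit(
        names=names,
        aliased=aliased,
        beta=beta,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        rss=rss,
        df_model=p,
        df_resid=df_resid,
        n=n,
        sigma2=sigma2,
    )
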