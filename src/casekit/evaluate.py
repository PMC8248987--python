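"""Calibration experiments for the detection and decomposition machinery.

These runners exercise the full pipeline on generator output under known
conditions — no effects (size calibration), a single injected effect
(recovery and power), known variance fractions (decomposition accuracy) —
and summarize how well the statistics behave.  They are what the test suite
and the reproduction script run; they are also useful when adapting the
pipeline to a new design (different replicate counts, depths) to see what
power and calibration to expect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ase import build_observation_table, filter_sites
from .case import case_scan
from .detection import ase_scan
from .simulate import SimParams, inject_treatment_effect, simulate_counts, simulate_truth, simulate_variance_units
from .varcomp import partition_ase_variance


def _null_scan(n_units: int, depth_mean: float, sigma_resid: float, seed: int):
    params = SimParams(
        n_snps=n_units, n_individuals=1, prop_base=0.0,
        sigma_resid=sigma_resid, depth_mean=depth_mean, seed=seed,
    )
    truth = simulate_truth(params)
    counts = simulate_counts(truth)
    obs = build_observation_table(filter_sites(counts))
    return obs, ase_scan(obs)


def anova_type1_error(
    n_units: int = 2000,
    depth_mean: float = 50.0,
    sigma_resid: float = 0.15,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical size of the whole-model ANOVA under the null generator."""
    _, results = _null_scan(n_units, depth_mean, sigma_resid, seed)
    return {
        "size": float((results["p"] < alpha).mean()),
        "n": int(len(results)),
        "alpha": alpha,
    }


def case_type1_error(
    n_units: int = 2000,
    depth_mean: float = 50.0,
    sigma_resid: float = 0.15,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Per-term empirical size of the fixed-effect coefficient tests.

    All units are fit (the ASE pre-filter is bypassed: under the null almost
    no unit would pass it, and the per-term size is a property of the
    coefficient test itself).
    """
    obs, results = _null_scan(n_units, depth_mean, sigma_resid, seed)
    all_sig = results.copy()
    all_sig["significant"] = True
    terms = case_scan(obs, all_sig)
    terms = terms[terms["estimable"] & terms["p"].notna()]
    per_class = {
        str(tc): float((grp["p"] < alpha).mean())
        for tc, grp in terms.groupby("term_class")
        if tc in ("cell_type", "treatment", "celltype_x_treatment")
    }
    pooled = terms[terms["term_class"].isin(
        ["cell_type", "treatment", "celltype_x_treatment"])]
    return {
        "size": float((pooled["p"] < alpha).mean()),
        "per_class": per_class,
        "n_terms": int(len(pooled)),
        "alpha": alpha,
    }


@dataclass
class RecoveryResult:
    mean_estimate: float
    true_effect: float
    detection_rate: float
    n_units_fit: int
    n_units: int


def treatment_effect_recovery(
    n_units: int = 500,
    delta: float = 0.75,
    sigma_resid: float = 0.25,
    depth_mean: float = 100.0,
    fdr_level: float = 0.10,
    treatment: str = "caffeine",
    seed: int = 0,
) -> RecoveryResult:
    """Inject one treatment effect into every unit and run the full pipeline.

    Every unit is fit (the experiment measures the coefficient estimator, so
    the ASE pre-filter — whose power is a property of the ANOVA — is not
    applied).  Detection is scored on the injected treatment's coefficient
    reaching the FDR threshold within the treatment term-class family of the
    scan.
    """
    params = SimParams(
        n_snps=n_units, n_individuals=1, prop_base=0.0,
        sigma_resid=sigma_resid, depth_mean=depth_mean, seed=seed,
    )
    truth = inject_treatment_effect(simulate_truth(params), treatment, delta)
    obs = build_observation_table(filter_sites(simulate_counts(truth)))
    ase_results = ase_scan(obs, fdr_level=fdr_level)
    all_units = ase_results.copy()
    all_units["significant"] = True
    terms = case_scan(obs, all_units, fdr_level=fdr_level)
    hit = terms[(terms["term_class"] == "treatment") & (terms["level"] == treatment)
                & terms["estimable"]]
    detected = int((hit["q"] < fdr_level).sum())
    return RecoveryResult(
        mean_estimate=float(hit["estimate"].mean()) if len(hit) else float("nan"),
        true_effect=delta,
        detection_rate=detected / n_units,
        n_units_fit=int(len(hit)),
        n_units=n_units,
    )


def variance_recovery(
    n_units: int = 200,
    variances: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Median absolute error of REML fractions against realized fractions.

    Units follow the full one-individual design; the default variances are
    cell type 0.4, treatment 0.2, interaction 0.1, residual 0.3 (fractions of
    a unit total of 1).
    """
    if variances is None:
        variances = {
            "cell_type": 0.4, "treatment": 0.2,
            "cell_type:treatment": 0.1, "residual": 0.3,
        }
    obs, truth = simulate_variance_units(n_units, variances, seed=seed)
    factors = tuple(f for f in variances if f != "residual")
    est = partition_ase_variance(obs, scope="combined", factors=factors)
    merged = est.merge(truth, on="unit_id", suffixes=("_est", "_true"))
    rows = []
    for factor in variances:
        est_col = "residual_fraction" if factor == "residual" else f"frac_{factor}_est"
        true_col = f"frac_{factor}_true" if f"frac_{factor}_true" in merged else f"frac_{factor}"
        err = (merged[est_col] - merged[true_col]).abs()
        rows.append({
            "factor": factor,
            "median_abs_error": float(err.median()),
            "median_estimated_fraction": float(merged[est_col].median()),
            "n": int(len(merged)),
        })
    return pd.DataFrame(rows)


def direction_detection_rates(
    n_reps: int = 200,
    n_conditions: int = 36,
    n_shifted: int = 10,
    shift: float = 0.3,
    n_introns: int = 1000,
    fdr_level: float = 0.10,
    seed: int = 0,
) -> dict:
    """Null false-positive and shifted-condition detection rates."""
    from .simulate import simulate_psi_table
    from .splicing import direction_test

    rng = np.random.default_rng(seed)
    clean_null = 0
    for _ in range(n_reps):
        table = simulate_psi_table(n_conditions, n_introns, 0.0,
                                   seed=int(rng.integers(2**31)))
        out = direction_test(table, fdr_level)
        clean_null += int(out["significant"].sum() == 0)
    shifts = np.array([shift] * n_shifted + [0.0] * (n_conditions - n_shifted))
    detected = []
    for _ in range(n_reps):
        table = simulate_psi_table(n_conditions, n_introns, shifts,
                                   seed=int(rng.integers(2**31)))
        out = direction_test(table, fdr_level).set_index("condition")
        shifted = out.loc[[f"cond{i + 1}" for i in range(n_shifted)]]
        hits = shifted["significant"] & (shifted["direction"] > 0)
        detected.append(float(hits.mean()))
    return {
        "null_clean_fraction": clean_null / n_reps,
        "shifted_detection_rate": float(np.mean(detected)),
        "n_reps": n_reps,
    }
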