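"""Synthetic allelic-count, splicing-shift, and gene-set generators.

The generator emulates a multi-condition allelic-imbalance study: a panel of
individuals, each assayed in several cell types under a battery of treatments
plus matched vehicle controls, in replicate.  For every heterozygous site the
allelic imbalance is a logit-scale linear predictor

    logit(p) = beta0 + beta_cell + beta_treat + beta_int + Normal(0, sigma_resid)

and read counts are drawn as reference ~ Binomial(total, p) with total
coverage ~ negative binomial.  The drawn effect sizes are retained
(:class:`SimTruth`) so recovery of effects and variance fractions can be
scored against the realized truth.

Everything is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CELL_TYPES, CONTROL_LABELS, VEHICLE_MAP, default_design


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class SimParams:
    """Generator configuration.

    Defaults mirror the study design this package targets: 6 individuals,
    3 cell types, 12 treatments + 2 vehicle controls, 2 replicate plates,
    negative-binomial site coverage with mean 60 and dispersion 0.3 (typical
    exonic heterozygous-site coverage at bulk RNA-seq depths).
    """

    n_snps: int = 100
    n_individuals: int = 6
    cell_types: tuple[str, ...] = CELL_TYPES
    treatments: tuple[str, ...] = tuple(VEHICLE_MAP)
    n_plates: int = 2
    snps_per_gene: int = 2
    # effect-class proportions
    prop_base: float = 0.2
    prop_cell: float = 0.0
    prop_treat: float = 0.0
    prop_inter: float = 0.0
    # effect-size SDs (logit scale) for each class
    sd_base: float = 0.5
    sd_cell: float = 0.5
    sd_treat: float = 0.5
    sd_inter: float = 0.5
    # per-observation extra-binomial noise SD (logit scale)
    sigma_resid: float = 0.15
    # coverage model
    depth_mean: float = 60.0
    depth_dispersion: float = 0.3
    # "beta_binomial" replaces the additive logit-normal noise with a
    # beta-binomial of matching overdispersion (robustness checks)
    noise_model: str = "logit_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        props = (self.prop_base, self.prop_cell, self.prop_treat, self.prop_inter)
        if any(p < 0 or p > 1 for p in props):
            raise ParameterError("effect-class proportions must lie in [0, 1]")
        for name, value in (
            ("n_snps", self.n_snps),
            ("n_individuals", self.n_individuals),
            ("n_plates", self.n_plates),
        ):
            if value < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.sigma_resid < 0:
            raise ParameterError("sigma_resid must be >= 0")
        if self.depth_mean <= 0:
            raise ParameterError("depth_mean must be > 0")
        if self.noise_model not in ("logit_normal", "beta_binomial"):
            raise ParameterError(f"unknown noise_model {self.noise_model!r}")

    @property
    def control_treatments(self) -> tuple[str, ...]:
        return tuple(t for t in self.treatments if VEHICLE_MAP.get(t, t) == t)


@dataclass
class SimTruth:
    """Realized logit-scale effects and noise parameters, keyed by SNP."""

    params: SimParams
    snp_ids: np.ndarray                 # (n_snps,)
    genes: np.ndarray                   # (n_snps,) gene label per SNP
    beta0: np.ndarray                   # (n_snps,)
    beta_cell: pd.DataFrame             # n_snps x n_cell_types
    beta_treat: pd.DataFrame            # n_snps x n_treatments
    beta_int: pd.DataFrame              # n_snps x (cell_type|treatment) columns
    sigma_resid: np.ndarray             # (n_snps,)
    flags: pd.DataFrame = field(repr=False)  # boolean effect-class indicators

    def predictor(self, snp_index: int, cell_type: str, treatment: str) -> float:
        """Logit-scale mean imbalance for one SNP in one condition."""
        return float(
            self.beta0[snp_index]
            + self.beta_cell.iloc[snp_index][cell_type]
            + self.beta_treat.iloc[snp_index][treatment]
            + self.beta_int.iloc[snp_index][f"{cell_type}|{treatment}"]
        )


def simulate_truth(params: SimParams) -> SimTruth:
    """Draw per-SNP effect assignments under the recorded seed."""
    total = params.prop_base + params.prop_cell + params.prop_treat + params.prop_inter
    if params.prop_cell + params.prop_treat + params.prop_inter > 1 + 1e-12:
        raise ParameterError(f"effect-class proportions sum to {total:.3f} > 1")
    rng = np.random.default_rng(params.seed)
    n = params.n_snps
    cells = list(params.cell_types)
    treats = list(params.treatments)
    controls = set(params.control_treatments)
    int_cols = [f"{c}|{t}" for c in cells for t in treats]

    snp_ids = np.array([f"snp{i:06d}" for i in range(n)])
    genes = np.array([f"gene{i // params.snps_per_gene:05d}" for i in range(n)])

    has_base = rng.random(n) < params.prop_base
    has_cell = rng.random(n) < params.prop_cell
    has_treat = rng.random(n) < params.prop_treat
    has_int = rng.random(n) < params.prop_inter

    beta0 = np.where(has_base, rng.normal(0.0, params.sd_base, n), 0.0)

    beta_cell = pd.DataFrame(0.0, index=snp_ids, columns=cells)
    # offsets relative to the first cell type
    for c in cells[1:]:
        draw = rng.normal(0.0, params.sd_cell, n)
        beta_cell[c] = np.where(has_cell, draw, 0.0)

    beta_treat = pd.DataFrame(0.0, index=snp_ids, columns=treats)
    for t in treats:
        if t in controls:
            continue  # controls define the baseline
        draw = rng.normal(0.0, params.sd_treat, n)
        beta_treat[t] = np.where(has_treat, draw, 0.0)

    beta_int = pd.DataFrame(0.0, index=snp_ids, columns=int_cols)
    for col in int_cols:
        c, t = col.split("|")
        if t in controls or c == cells[0]:
            continue
        draw = rng.normal(0.0, params.sd_inter, n)
        beta_int[col] = np.where(has_int, draw, 0.0)

    flags = pd.DataFrame(
        {
            "base": has_base,
            "cell": has_cell,
            "treat": has_treat,
            "inter": has_int,
        },
        index=snp_ids,
    )
    return SimTruth(
        params=params,
        snp_ids=snp_ids,
        genes=genes,
        beta0=beta0,
        beta_cell=beta_cell,
        beta_treat=beta_treat,
        beta_int=beta_int,
        sigma_resid=np.full(n, params.sigma_resid),
        flags=flags,
    )


def inject_treatment_effect(truth: SimTruth, treatment: str, delta: float) -> SimTruth:
    """Set a fixed treatment effect for every SNP (recovery experiments)."""
    if treatment not in truth.beta_treat.columns:
        raise ParameterError(f"treatment {treatment!r} not in truth")
    bt = truth.beta_treat.copy()
    bt[treatment] = delta
    flags = truth.flags.copy()
    flags["treat"] = flags["treat"] | (delta != 0)
    return replace(truth, beta_treat=bt, flags=flags)


def _draw_totals(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if dispersion <= 0:
        return np.full(size, int(round(mean)))
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size)


def simulate_counts(
    truth: SimTruth,
    design: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Allelic count table for every SNP x library in the design.

    Uses a seed derived from ``truth.params.seed`` unless overridden, so
    (params, seed) fully determine the output.
    """
    params = truth.params
    if design is None:
        design = default_design(
            n_individuals=params.n_individuals,
            cell_types=params.cell_types,
            treatments={t: VEHICLE_MAP.get(t, t) for t in params.treatments},
            n_plates=params.n_plates,
        )
    missing_cells = set(design["cell_type"]) - set(truth.beta_cell.columns)
    missing_treats = set(design["treatment"]) - set(truth.beta_treat.columns)
    if missing_cells or missing_treats:
        raise ParameterError(
            f"design levels missing from truth: cells={sorted(missing_cells)} "
            f"treatments={sorted(missing_treats)}"
        )
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    n_snps = len(truth.snp_ids)
    n_lib = len(design)

    eta_cond = np.empty((n_snps, n_lib))
    cell_arr = design["cell_type"].to_numpy()
    treat_arr = design["treatment"].to_numpy()
    bc = truth.beta_cell.to_numpy()
    bt = truth.beta_treat.to_numpy()
    bi = truth.beta_int.to_numpy()
    cell_idx = {c: j for j, c in enumerate(truth.beta_cell.columns)}
    treat_idx = {t: j for j, t in enumerate(truth.beta_treat.columns)}
    int_idx = {col: j for j, col in enumerate(truth.beta_int.columns)}
    for k in range(n_lib):
        c, t = cell_arr[k], treat_arr[k]
        eta_cond[:, k] = (
            truth.beta0
            + bc[:, cell_idx[c]]
            + bt[:, treat_idx[t]]
            + bi[:, int_idx[f"{c}|{t}"]]
        )

    totals = _draw_totals(rng, params.depth_mean, params.depth_dispersion, n_snps * n_lib)
    totals = totals.reshape(n_snps, n_lib)

    if params.noise_model == "logit_normal":
        eta = eta_cond + rng.normal(0.0, truth.sigma_resid[:, None], (n_snps, n_lib))
        p = 1.0 / (1.0 + np.exp(-eta))
        ref = rng.binomial(totals, p)
    else:
        # beta-binomial with logit-normal-matched overdispersion: the logit-scale
        # noise SD sigma maps to a beta with the same mean and variance
        p = 1.0 / (1.0 + np.exp(-eta_cond))
        sig2 = (truth.sigma_resid[:, None] ** 2) * np.ones((1, n_lib))
        var_p = np.clip(p * (1 - p), 1e-12, None) ** 2 * sig2  # delta method
        rho = np.clip(var_p / np.clip(p * (1 - p), 1e-12, None), 1e-9, 0.99)
        conc = (1 - rho) / rho
        pdraw = rng.beta(np.clip(p * conc, 1e-6, None), np.clip((1 - p) * conc, 1e-6, None))
        ref = rng.binomial(totals, pdraw)

    alt = totals - ref

    n_chrom = 22
    snp_rows = pd.DataFrame(
        {
            "snp_id": truth.snp_ids,
            "chrom": [f"chr{(i % n_chrom) + 1}" for i in range(n_snps)],
            "pos": np.arange(1, n_snps + 1) * 1000,
            "ref_allele": ["A"] * n_snps,
            "alt_allele": ["G"] * n_snps,
        }
    )
    lib = design.reset_index(drop=True)
    out = pd.DataFrame(
        {
            "snp_id": np.repeat(truth.snp_ids, n_lib),
            "individual": np.tile(lib["individual"].to_numpy(), n_snps),
            "cell_type": np.tile(lib["cell_type"].to_numpy(), n_snps),
            "treatment": np.tile(treat_arr, n_snps),
            "vehicle": np.tile(lib["vehicle"].to_numpy(), n_snps),
            "plate": np.tile(lib["plate"].to_numpy(), n_snps),
            "ref_count": ref.ravel(),
            "alt_count": alt.ravel(),
        }
    )
    out = out.merge(snp_rows, on="snp_id", how="left")
    cols = [
        "chrom", "pos", "ref_allele", "alt_allele", "snp_id",
        "individual", "cell_type", "treatment", "vehicle", "plate",
        "ref_count", "alt_count",
    ]
    return out[cols]


def snp_gene_map(truth: SimTruth) -> dict[str, str]:
    return dict(zip(truth.snp_ids, truth.genes))


def simulate_variance_units(
    n_units: int,
    variances: dict[str, float],
    seed: int,
    design: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect-level ASE observations with known variance components.

    For each unit, every factor named in ``variances`` (keys may be design
    columns or "a:b" interactions; "residual" is the noise variance)
    contributes independent Gaussian level effects with the stated variance.
    Returns the observation table and the *realized* per-unit variance
    fractions (ddof-1 sample variance of the drawn effects), the quantity a
    variance-component estimator can recover from a single unit: with few
    levels the realized level spread, not the population variance, is what
    the data carry.
    """
    if "residual" not in variances:
        raise ParameterError("variances must include a 'residual' entry")
    rng = np.random.default_rng(seed)
    if design is None:
        design = default_design(n_individuals=1)
    lib = design.reset_index(drop=True)
    n = len(lib)
    factor_levels = {}
    for factor in variances:
        if factor == "residual":
            continue
        if ":" in factor:
            a, b = factor.split(":")
            levels = (lib[a].astype(str) + ":" + lib[b].astype(str)).to_numpy()
        else:
            levels = lib[factor].astype(str).to_numpy()
        codes, uniques = pd.factorize(levels, sort=True)
        factor_levels[factor] = (codes, len(uniques))
    obs_frames, truth_rows = [], []
    for u in range(n_units):
        y = np.zeros(n)
        realized = {}
        for factor, var in variances.items():
            if factor == "residual":
                eps = rng.normal(0.0, np.sqrt(var), n)
                y += eps
                realized["residual"] = float(np.var(eps, ddof=1)) if n > 1 else var
                continue
            codes, n_levels = factor_levels[factor]
            effects = rng.normal(0.0, np.sqrt(var), n_levels)
            y += effects[codes]
            realized[factor] = float(np.var(effects, ddof=1)) if n_levels > 1 else 0.0
        total = sum(realized.values())
        frame = lib.copy()
        frame["snp_id"] = f"vsnp{u:05d}"
        frame["ase"] = y
        frame["coverage"] = 100
        obs_frames.append(frame)
        truth_rows.append(
            {"unit_id": f"vsnp{u:05d}:{lib['individual'].iloc[0]}"}
            | {f"frac_{k}": v / total for k, v in realized.items()}
        )
    obs = pd.concat(obs_frames, ignore_index=True)
    return obs, pd.DataFrame(truth_rows)


def simulate_psi_table(
    n_conditions: int,
    n_introns: int,
    shift: float | np.ndarray,
    seed: int,
    introns_per_cluster: int = 3,
) -> pd.DataFrame:
    """Per-condition intron excision changes with a controlled sign bias.

    The sign of each intron's delta-PSI is positive with probability
    0.5 + shift (scalar, or one shift per condition); magnitudes are
    Uniform(0.01, 0.3).  Only the sign matters to the direction test.
    """
    if n_introns < 1 or n_conditions < 1:
        raise ParameterError("n_conditions and n_introns must be >= 1")
    shifts = np.broadcast_to(np.asarray(shift, dtype=float), (n_conditions,))
    if np.any(np.abs(shifts) > 0.5):
        raise ParameterError("|shift| must be <= 0.5")
    rng = np.random.default_rng(seed)
    frames = []
    for ci in range(n_conditions):
        signs = np.where(rng.random(n_introns) < 0.5 + shifts[ci], 1.0, -1.0)
        mags = rng.uniform(0.01, 0.3, n_introns)
        frames.append(
            pd.DataFrame(
                {
                    "condition": f"cond{ci + 1}",
                    "cluster_id": [f"clu{i // introns_per_cluster + 1}" for i in range(n_introns)],
                    "intron_id": [f"intron{i + 1}" for i in range(n_introns)],
                    "delta_psi": signs * mags,
                    "cluster_significant": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_overlap_sets(
    n_genes: int,
    set_sizes: tuple[int, int],
    enrichment_or: float,
    seed: int,
) -> tuple[set[str], set[str], list[str]]:
    """Two gene sets over a universe with a target 2x2 odds ratio.

    Per-gene joint membership probabilities are solved from the marginal set
    sizes and the requested odds ratio, so the expected sample odds ratio of
    the cross-tabulation equals ``enrichment_or``.
    """
    size_a, size_b = set_sizes
    if enrichment_or <= 0:
        raise ParameterError("enrichment_or must be > 0")
    if size_a > n_genes or size_b > n_genes or min(size_a, size_b, n_genes) < 1:
        raise ParameterError("set sizes must be in [1, n_genes]")
    pa, pb = size_a / n_genes, size_b / n_genes
    if abs(enrichment_or - 1.0) < 1e-12:
        p11 = pa * pb
    else:
        a = enrichment_or - 1.0
        b = -((enrichment_or - 1.0) * (pa + pb) + 1.0)
        c = enrichment_or * pa * pb
        disc = b * b - 4 * a * c
        p11 = (-b - np.sqrt(disc)) / (2 * a)
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
    if not (lo - 1e-9 <= p11 <= hi + 1e-9):
        raise ParameterError(
            f"requested odds ratio {enrichment_or} infeasible for sizes {set_sizes}"
        )
    p11 = float(np.clip(p11, lo, hi))
    probs = [p11, pa - p11, pb - p11, 1.0 - pa - pb + p11]
    rng = np.random.default_rng(seed)
    universe = [f"gene{i:05d}" for i in range(n_genes)]
    cells = rng.choice(4, size=n_genes, p=probs)
    set_a = {g for g, cell in zip(universe, cells) if cell in (0, 1)}
    set_b = {g for g, cell in zip(universe, cells) if cell in (0, 2)}
    return set_a, set_b, universe
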