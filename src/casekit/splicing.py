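"""Directional shifts in intron excision.

Given per-condition delta-PSI values (change in an intron's percent-spliced-
in between treatment and control), each condition is tested for a concerted
shift of excision in one direction: among introns in differentially spliced
clusters, is the fraction with delta-PSI > 0 different from the cross-
condition average?  The test is an exact two-sided binomial test; the null
proportion p0 is the unweighted mean of the per-condition positive
proportions, so "direction" is judged relative to the global tendency rather
than an absolute 50:50 split.  Conditions are BH-corrected together.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .detection import bh_fdr

log = logging.getLogger(__name__)


def binomial_two_sided_p(k: int, n: int, p0: float, method: str = "minlike") -> float:
    """Exact two-sided binomial p-value.

    ``minlike`` sums the probabilities of all outcomes no more likely than
    the observed one (the convention of R's binom.test); ``double`` doubles
    the smaller one-sided tail, capped at 1.
    """
    if method == "minlike":
        return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    if method == "double":
        lo = stats.binom.cdf(k, n, p0)
        hi = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown method {method!r}")


def direction_test(
    psi: pd.DataFrame,
    fdr_level: float = 0.10,
    method: str = "minlike",
) -> pd.DataFrame:
    """Per-condition two-sided binomial test for a directional splicing shift.

    Only introns in significant clusters enter; introns with delta-PSI
    exactly 0 carry no sign and are excluded from both the numerator and the
    denominator.
    """
    sig = psi[psi["cluster_significant"].astype(bool)]
    sig = sig[sig["delta_psi"] != 0]
    rows = []
    for cond, grp in sig.groupby("condition", sort=True):
        n_tested = len(grp)
        if n_tested == 0:
            continue
        n_pos = int((grp["delta_psi"] > 0).sum())
        rows.append({"condition": cond, "n_pos": n_pos, "n_tested": n_tested})
    excluded = set(psi["condition"].unique()) - {r["condition"] for r in rows}
    if excluded:
        log.warning("conditions with no tested introns excluded: %s", sorted(excluded))
    if not rows:
        raise ValueError("no condition has introns in significant clusters")
    table = pd.DataFrame(rows)
    props = table["n_pos"] / table["n_tested"]
    p0 = float(props.mean())  # unweighted average across conditions
    table["p0"] = p0
    table["p"] = [
        binomial_two_sided_p(k, n, p0, method)
        for k, n in zip(table["n_pos"], table["n_tested"])
    ]
    q, sig_flags = bh_fdr(table["p"].to_numpy(), fdr_level)
    table["q"] = q
    table["significant"] = sig_flags
    table["direction"] = np.sign(props - p0).astype(int)
    return table
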