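"""Gene/SNP-set overlap statistics.

Three flavors of overlap are used when relating ASE and cASE hits to outside
annotation: (1) Fisher's exact test on 2x2 cross-tabulations of flagged vs
reference sets within a shared tested universe (genomic location categories,
eQTL eGene sets); (2) a one-sample proportion Z statistic comparing one
trait-by-treatment overlap proportion to the average along a comparison
axis (TWAS overlap); (3) plain replication percentages rounded half-up, as
printed in study-style summaries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detection import bh_fdr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contingency2x2:
    """Counts: a = flagged & in reference set, b = flagged & outside it,
    c = unflagged & in reference set, d = unflagged & outside it."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_enrichment(table: Contingency2x2 | np.ndarray) -> dict:
    """Sample odds ratio, 95% CI, and exact hypergeometric two-sided p.

    The reported odds ratio is the sample (ad)/(bc) value; when any cell is
    zero the Haldane-Anscombe 0.5 correction is applied and flagged.  The
    p-value is always the exact conditional (hypergeometric) one.
    """
    if not isinstance(table, Contingency2x2):
        (a, b), (c, d) = np.asarray(table)
        table = Contingency2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    haldane = 0 in (a, b, c, d)
    if haldane:
        ah, bh, ch, dh = (x + 0.5 for x in (a, b, c, d))
    else:
        ah, bh, ch, dh = a, b, c, d
    odds_ratio = (ah * dh) / (bh * ch)
    se_log = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(np.log(odds_ratio) - z * se_log)),
          float(np.exp(np.log(odds_ratio) + z * se_log)))
    p = float(stats.fisher_exact(table.table, alternative="two-sided")[1])
    return {
        "odds_ratio": float(odds_ratio),
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p": p,
        "haldane": haldane,
    }


def fisher_enrichment_scan(tables: dict[str, Contingency2x2], fdr_level: float = 0.10) -> pd.DataFrame:
    """Fisher test per category with BH correction across categories."""
    rows = []
    for name, table in tables.items():
        res = fisher_enrichment(table)
        rows.append({"category": name, "a": table.a, "b": table.b, "c": table.c,
                     "d": table.d, **res})
    out = pd.DataFrame(rows)
    if len(out):
        q, sig = bh_fdr(out["p"].to_numpy(), fdr_level)
        out["q"] = q
        out["significant"] = sig
    return out


def twas_overlap_z(O: int, N: int, P0: float, trait: str = "", treatment: str = "") -> dict:
    """One-sample proportion Z for an overlap count against a reference rate.

    P = O/N is the observed overlap proportion, P0 the average proportion
    along the comparison axis; Z = (P - P0) / sqrt(P0 (1 - P0) / N) with a
    two-sided normal p-value.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= O <= N:
        raise ValueError("O must lie in [0, N]")
    if not 0 < P0 < 1:
        return {"trait": trait, "treatment": treatment, "O": O, "N": N,
                "P": O / N, "P0": P0, "Z": np.nan, "p": np.nan, "flag": "degenerate_p0"}
    P = O / N
    Z = (P - P0) / np.sqrt(P0 * (1 - P0) / N)
    p = float(2 * stats.norm.sf(abs(Z)))
    return {"trait": trait, "treatment": treatment, "O": O, "N": N,
            "P": P, "P0": P0, "Z": float(Z), "p": p, "flag": ""}


def twas_overlap_scan(
    overlaps: pd.DataFrame,
    axis: str = "treatment",
) -> pd.DataFrame:
    """Z statistic per (trait, treatment) cell against the axis-average rate.

    ``overlaps`` has columns trait, treatment, O, N.  ``axis`` names the
    comparison axis: "treatment" compares each treatment's P(t,c) to the
    average over treatments within the trait; "trait" compares to the
    average over traits within the treatment.  The axis must be chosen
    explicitly per analysis.
    """
    if axis not in ("treatment", "trait"):
        raise ValueError("axis must be 'treatment' or 'trait'")
    within = "trait" if axis == "treatment" else "treatment"
    rows = []
    for _, grp in overlaps.groupby(within, sort=True):
        P = grp["O"] / grp["N"]
        p0 = float(P.mean())
        for _, row in grp.iterrows():
            rows.append(
                twas_overlap_z(int(row["O"]), int(row["N"]), p0,
                               trait=row["trait"], treatment=row["treatment"])
            )
    return pd.DataFrame(rows)


def overlap_percentage(O: int, N: int) -> int:
    """Percentage of N overlapped by O, rounded half-up to an integer."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= O <= N:
        raise ValueError("O must lie in [0, N]")
    return int(np.floor(100.0 * O / N + 0.5))


def build_overlap_tables(
    flagged_sets: dict[str, set],
    reference_sets: dict[str, set],
    universe: set,
) -> dict[tuple[str, str], Contingency2x2]:
    """2x2 tables for every (flagged, reference) pair within the universe.

    All sets are intersected with the tested universe first; genes untested
    in either study never enter a margin.
    """
    universe = set(universe)
    tables = {}
    for (fname, flagged), (rname, ref) in itertools.product(
        flagged_sets.items(), reference_sets.items()
    ):
        f = flagged & universe
        r = ref & universe
        if not universe:
            raise ValueError(f"empty universe for pair ({fname}, {rname})")
        a = len(f & r)
        b = len(f - r)
        c = len(r - f)
        d = len(universe - f - r)
        log.debug("pair (%s, %s): margins flagged=%d ref=%d universe=%d",
                  fname, rname, len(f), len(r), len(universe))
        tables[(fname, rname)] = Contingency2x2(a, b, c, d)
    return tables
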