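"""Cross-cohort concurrence and platform-aware replication scoring.

Intergenic DEEs and DEE-DEG links are re-called with the identical protocol
in independent RNA-seq cohorts; a feature's concurrence is one plus the
number of cohorts in which it replicates (same-direction significance for a
DEE; DEE + DEG significance plus the link criteria for a pair). Genic
DME-DEG pairs replicated on a methylation-array cohort are classified as
successes, type I failures (the array covers no CpG in the enhancer) or
type II failures (covered but not significant); the raw replication rate is
successes/total and the platform-adjusted rate is
successes/(successes + type II failures), both as percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "CohortResult",
    "dee_concurrence",
    "link_concurrence",
    "classify_replication",
    "replication_rates",
]


@dataclass
class CohortResult:
    """Significance calls from one replication cohort, keyed by the shared
    enhancer catalog / gene identifiers.

    ``dees``/``degs``: DataFrames indexed by feature id with a ``status``
    column (activated/repressed, up/down). ``links``: DataFrame with
    enhancer_id, gene_id, rho, p_adj for tested pairs.
    """

    cohort_id: str
    dees: pd.DataFrame
    degs: pd.DataFrame
    links: pd.DataFrame = field(default_factory=pd.DataFrame)


def dee_concurrence(
    discovery_dees: pd.DataFrame, cohorts: Sequence[CohortResult]
) -> pd.DataFrame:
    """Concurrence of each discovery DEE: 1 + number of cohorts where it is
    significant with the same direction."""
    if "status" not in discovery_dees.columns:
        raise ValueError("discovery DEE table needs a 'status' column")
    rows = []
    for e_id, status in discovery_dees["status"].items():
        n = sum(
            1
            for c in cohorts
            if e_id in c.dees.index and c.dees.loc[e_id, "status"] == status
        )
        rows.append({"feature_id": e_id, "concurrence": 1 + n})
    return pd.DataFrame(rows, columns=["feature_id", "concurrence"]).set_index("feature_id")


def link_concurrence(
    discovery_links: pd.DataFrame,
    discovery_dees: pd.DataFrame,
    discovery_degs: pd.DataFrame,
    cohorts: Sequence[CohortResult],
    rho_threshold: float = 0.7,
    p_adj_threshold: float = 0.01,
) -> pd.DataFrame:
    """Concurrence of each discovery DEE-DEG pair: 1 + number of cohorts in
    which the DEE is significant (same direction), the DEG is significant
    (same direction), and the pair passes the link criteria
    (rho >= 0.7, corrected p < 0.01) in that cohort."""
    rows = []
    for rec in discovery_links.itertuples():
        e_id, g_id = rec.enhancer_id, rec.gene_id
        e_status = discovery_dees.loc[e_id, "status"] if e_id in discovery_dees.index else None
        g_status = discovery_degs.loc[g_id, "status"] if g_id in discovery_degs.index else None
        n = 0
        for c in cohorts:
            if e_id not in c.dees.index or c.dees.loc[e_id, "status"] != e_status:
                continue
            if g_id not in c.degs.index or c.degs.loc[g_id, "status"] != g_status:
                continue
            if not len(c.links):
                continue
            hit = c.links[(c.links["enhancer_id"] == e_id) & (c.links["gene_id"] == g_id)]
            if len(hit) and bool(
                (hit["rho"].iloc[0] >= rho_threshold)
                and (hit["p_adj"].iloc[0] < p_adj_threshold)
            ):
                n += 1
        rows.append({"enhancer_id": e_id, "gene_id": g_id, "concurrence": 1 + n})
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "concurrence"])


def classify_replication(
    pairs: pd.DataFrame,
    dme_intervals: Mapping[str, GenomicInterval],
    platform_cpgs: pd.DataFrame,
    replication_stats: pd.DataFrame,
) -> pd.DataFrame:
    """Classify genic DME-DEG pair replication on an array platform.

    type1: the DME interval contains zero platform-covered CpGs; success:
    covered and differential methylation, differential expression and the
    methylation-expression correlation are all significant in the
    replication cohort; type2: covered but not all three significant.

    ``pairs``: DataFrame with enhancer_id, gene_id (and optionally
    category). ``platform_cpgs``: chrom, pos of array-covered CpGs.
    ``replication_stats``: indexed by (enhancer_id, gene_id) with boolean
    columns meth_sig, expr_sig, corr_sig.
    """
    per_chrom = {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in platform_cpgs.groupby("chrom")
    }

    def covered(iv: GenomicInterval) -> bool:
        pos = per_chrom.get(iv.chrom)
        if pos is None:
            return False
        i = np.searchsorted(pos, iv.start, side="left")
        j = np.searchsorted(pos, iv.end, side="left")
        return j > i

    rows = []
    for rec in pairs.itertuples():
        key = (rec.enhancer_id, rec.gene_id)
        iv = dme_intervals[rec.enhancer_id]
        if not covered(iv):
            status = "type1"
        else:
            st = replication_stats.loc[key]
            status = (
                "success"
                if bool(st["meth_sig"]) and bool(st["expr_sig"]) and bool(st["corr_sig"])
                else "type2"
            )
        row = {"enhancer_id": rec.enhancer_id, "gene_id": rec.gene_id, "status": status}
        if hasattr(rec, "category"):
            row["category"] = rec.category
        rows.append(row)
    return pd.DataFrame(rows)


def replication_rates(
    records: pd.DataFrame, categories: Sequence[str] | None = None
) -> pd.DataFrame:
    """Raw and platform-adjusted replication rates per category and overall.

    raw_rate = 100 * successes / total;
    adjusted_rate = 100 * successes / (successes + type II failures).
    Rates are computed at full precision; round only when rendering. An
    empty category yields NaN rates (logged), never zero.
    """
    if categories is None:
        categories = (
            sorted(records["category"].unique()) if "category" in records.columns else []
        )
    out = []
    groups = [(cat, records[records["category"] == cat]) for cat in categories]
    groups.append(("all", records))
    for cat, grp in groups:
        n_total = len(grp)
        n_success = int((grp["status"] == "success").sum())
        n_type1 = int((grp["status"] == "type1").sum())
        n_type2 = int((grp["status"] == "type2").sum())
        if n_total == 0:
            logger.warning("replication category %r is empty: rates undefined", cat)
            raw = adj = float("nan")
        else:
            raw = 100.0 * n_success / n_total
            denom = n_success + n_type2
            adj = 100.0 * n_success / denom if denom else float("nan")
        out.append(
            {
                "category": cat,
                "n_total": n_total,
                "n_success": n_success,
                "n_type1": n_type1,
                "n_type2": n_type2,
                "raw_rate": raw,
                "adjusted_rate": adj,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "category",
            "n_total",
            "n_success",
            "n_type1",
            "n_type2",
            "raw_rate",
            "adjusted_rate",
        ],
    )
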