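"""Enhancer-to-gene association.

Intergenic differentially expressed enhancers (DEEs) are linked to
differentially expressed genes (DEGs) whose TSS lies within +/- 1 Mb of the
enhancer center, by Spearman correlation of eRNA and gene expression across
all samples (rho >= 0.7, Bonferroni-corrected p < 0.01 over all tested
candidate pairs). Genic differentially methylated enhancers (DMEs) are
candidate enhancers (catalog concurrence >= 2) overlapping a DMR by
>= 200 bp, >= 30% of the enhancer and >= 5 CpGs; they are linked to DEGs
within 1 Mb of the enhancer edge by methylation-expression correlation
(|rho| >= 0.5, BH-FDR <= 0.01), and retained only with at least one linked
DEG. Additional screens flag methylation-associated DEEs, histone-modifier
co-expression, and positionally chained super-enhancer clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import Dmr
from .intervals import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "link_intergenic",
    "link_degree_counts",
    "GenicDme",
    "link_genic_dme",
    "classify_dme_deg",
    "methylation_associated_dees",
    "modifier_coexpression",
    "SuperEnhancerCluster",
    "detect_super_enhancer_clusters",
]

MAX_LINK_DISTANCE = 1_000_000
INTERGENIC_RHO = 0.7
INTERGENIC_P_ADJ = 0.01
GENIC_RHO = 0.5
GENIC_FDR = 0.01
DME_MIN_OVERLAP_BP = 200
DME_MIN_OVERLAP_FRACTION = 0.3
DME_MIN_CPGS = 5
DME_MIN_CONCURRENCE = 2


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p from the
    t-approximation. A constant vector has no rank correlation: returns
    (0, 1) with a log message."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("constant vector in spearman: rho set to 0, p to 1")
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _rank_standardize(mat: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centred and scaled to unit norm (constant rows
    become all-zero, yielding rho = 0)."""
    ranks = stats.rankdata(mat, axis=1, method="average")
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, ranks / norm, 0.0)
    return out


def _spearman_pairs(
    x_mat: np.ndarray, y_mat: np.ndarray, xi: np.ndarray, yi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and t-approximation p for many (row of x_mat, row of
    y_mat) pairs sharing the sample axis."""
    n = x_mat.shape[1]
    rx = _rank_standardize(x_mat)
    ry = _rank_standardize(y_mat)
    rho = np.einsum("ij,ij->i", rx[xi], ry[yi])
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    # rows that were constant carry rho exactly 0 from _rank_standardize; give p=1
    const_x = ~np.any(x_mat != x_mat[:, :1], axis=1)
    const_y = ~np.any(y_mat != y_mat[:, :1], axis=1)
    degenerate = const_x[xi] | const_y[yi]
    p = np.where(degenerate, 1.0, p)
    return rho, p


def _shared_samples(a: pd.DataFrame, b: pd.DataFrame) -> list[str]:
    shared = [c for c in a.columns if c in set(b.columns)]
    if not shared:
        raise ValueError("expression matrices share no samples")
    return shared


def link_intergenic(
    dees: pd.DataFrame,
    degs: pd.DataFrame,
    erna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    genes: Sequence[GeneModel],
    enhancers: pd.DataFrame,
    max_distance: int = MAX_LINK_DISTANCE,
    rho_threshold: float = INTERGENIC_RHO,
    p_adj_threshold: float = INTERGENIC_P_ADJ,
) -> pd.DataFrame:
    """Intergenic DEE -> DEG links.

    Candidates are (DEE, DEG) pairs on the same chromosome with
    |TSS - enhancer center| <= ``max_distance``. Spearman correlation is
    computed between log2 eRNA and log2 gene expression across all shared
    samples; Bonferroni correction uses the number of tested candidate
    pairs as the family. Links require rho >= ``rho_threshold`` (positive
    only, as specified) and corrected p < ``p_adj_threshold``.

    ``enhancers`` is a catalog-style frame (enhancer_id, chrom, start, end).
    """
    enh = enhancers.set_index("enhancer_id") if "enhancer_id" in enhancers.columns else enhancers
    gene_map = {g.gene_id: g for g in genes}
    dee_ids = [i for i in dees.index if i in erna_expr.index and i in enh.index]
    deg_ids = [i for i in degs.index if i in gene_expr.index and i in gene_map]
    cols = _shared_samples(erna_expr, gene_expr)

    candidates: list[tuple[str, str, int]] = []
    for e_id in dee_ids:
        row = enh.loc[e_id]
        center = (int(row["start"]) + int(row["end"])) // 2
        for g_id in deg_ids:
            g = gene_map[g_id]
            if g.chrom != row["chrom"]:
                continue
            dist = g.tss - center
            if abs(dist) <= max_distance:
                candidates.append((e_id, g_id, dist))
    if not candidates:
        return pd.DataFrame(
            columns=["enhancer_id", "gene_id", "rho", "p", "p_adj", "distance", "category"]
        )

    e_index = {e: i for i, e in enumerate(dee_ids)}
    g_index = {g: i for i, g in enumerate(deg_ids)}
    xi = np.array([e_index[e] for e, _, _ in candidates])
    yi = np.array([g_index[g] for _, g, _ in candidates])
    rho, p = _spearman_pairs(
        erna_expr.loc[dee_ids, cols].to_numpy(float),
        gene_expr.loc[deg_ids, cols].to_numpy(float),
        xi,
        yi,
    )
    m = len(candidates)
    p_adj = np.minimum(1.0, m * p)
    out = pd.DataFrame(
        {
            "enhancer_id": [e for e, _, _ in candidates],
            "gene_id": [g for _, g, _ in candidates],
            "rho": rho,
            "p": p,
            "p_adj": p_adj,
            "distance": [d for _, _, d in candidates],
            "category": "intergenic_DEE_DEG",
        }
    )
    keep = (out["rho"] >= rho_threshold) & (out["p_adj"] < p_adj_threshold)
    return out[keep].reset_index(drop=True)


def link_degree_counts(links: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(targets per enhancer, regulators per gene) for a link table."""
    return (
        links["enhancer_id"].value_counts().rename("n_target_genes"),
        links["gene_id"].value_counts().rename("n_regulating_enhancers"),
    )


@dataclass
class GenicDme:
    """A genic differentially methylated enhancer and its gene links."""

    enhancer_id: str
    interval: GenomicInterval
    overlap_bp: int
    overlap_fraction: float
    n_cpgs_in_overlap: int
    dmr_direction: str
    links: pd.DataFrame = field(repr=False, default=None)


def _cpg_count_in(positions: pd.DataFrame, chrom: str, start: int, end: int) -> int:
    sub = positions[positions["chrom"] == chrom]
    return int(((sub["pos"] >= start) & (sub["pos"] < end)).sum())


def enhancer_mean_beta(
    beta: pd.DataFrame, positions: pd.DataFrame, interval: GenomicInterval
) -> pd.Series | None:
    """Mean beta across the CpGs inside an enhancer interval, per sample."""
    sub = positions[
        (positions["chrom"] == interval.chrom)
        & (positions["pos"] >= interval.start)
        & (positions["pos"] < interval.end)
    ]
    if sub.empty:
        return None
    return beta.loc[sub.index].mean(axis=0)


def link_genic_dme(
    catalog: pd.DataFrame,
    dmrs: Sequence[Dmr],
    cpg_positions: pd.DataFrame,
    degs: pd.DataFrame,
    beta: pd.DataFrame,
    gene_expr: pd.DataFrame,
    genes: Sequence[GeneModel],
    max_distance: int = MAX_LINK_DISTANCE,
    rho_threshold: float = GENIC_RHO,
    fdr_threshold: float = GENIC_FDR,
    min_overlap_bp: int = DME_MIN_OVERLAP_BP,
    min_overlap_fraction: float = DME_MIN_OVERLAP_FRACTION,
    min_cpgs: int = DME_MIN_CPGS,
    min_concurrence: int = DME_MIN_CONCURRENCE,
) -> list[GenicDme]:
    """Genic DMEs and their DEG links.

    A genic catalog enhancer with concurrence >= 2 is a DME candidate when
    some DMR overlaps it by >= 200 bp, >= 30% of the enhancer length, with
    >= 5 CpGs inside the overlap. For candidates, DEGs whose TSS is within
    1 Mb of the nearest enhancer edge are tested by Spearman correlation of
    gene expression against the enhancer's mean methylation (mean beta over
    its CpGs, per sample); links require |rho| >= 0.5 and BH-FDR <= 0.01
    (family = all tested candidate pairs). Candidates without links are
    dropped.
    """
    gene_map = {g.gene_id: g for g in genes}
    genic = catalog[(catalog["class"] == "genic") & (catalog["concurrence"] >= min_concurrence)]

    candidates: list[GenicDme] = []
    for row in genic.itertuples():
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        best = None
        for d in dmrs:
            ov = iv.overlap_bp(d.interval)
            if ov < min_overlap_bp:
                continue
            if ov / iv.length < min_overlap_fraction:
                continue
            lo = max(iv.start, d.interval.start)
            hi = min(iv.end, d.interval.end)
            ncpg = _cpg_count_in(cpg_positions, iv.chrom, lo, hi)
            if ncpg < min_cpgs:
                continue
            if best is None or ov > best[0]:
                best = (ov, ncpg, d)
        if best is None:
            continue
        ov, ncpg, d = best
        candidates.append(
            GenicDme(
                enhancer_id=row.enhancer_id,
                interval=iv,
                overlap_bp=ov,
                overlap_fraction=ov / iv.length,
                n_cpgs_in_overlap=ncpg,
                dmr_direction=d.direction,
            )
        )
    if not candidates:
        return []

    deg_ids = [g for g in degs.index if g in gene_expr.index and g in gene_map]
    cols = [c for c in beta.columns if c in set(gene_expr.columns)]
    if not cols:
        raise ValueError("methylation and expression matrices share no samples")

    meth_rows = []
    pair_meta: list[tuple[int, str, int]] = []  # (candidate idx, gene_id, distance)
    for ci, cand in enumerate(candidates):
        mb = enhancer_mean_beta(beta[cols], cpg_positions, cand.interval)
        if mb is None:
            continue
        meth_rows.append(mb.to_numpy(float))
        mi = len(meth_rows) - 1
        for g_id in deg_ids:
            g = gene_map[g_id]
            if g.chrom != cand.interval.chrom:
                continue
            dist = max(0, cand.interval.start - g.tss, g.tss - (cand.interval.end - 1))
            if dist <= max_distance:
                pair_meta.append((ci, g_id, dist))
        # map candidate to its methylation row
        cand._meth_row = mi  # type: ignore[attr-defined]

    pairs = [
        (ci, g_id, dist)
        for ci, g_id, dist in pair_meta
        if hasattr(candidates[ci], "_meth_row")
    ]
    if not pairs:
        return []
    g_index = {g: i for i, g in enumerate(deg_ids)}
    xi = np.array([candidates[ci]._meth_row for ci, _, _ in pairs])  # type: ignore[attr-defined]
    yi = np.array([g_index[g] for _, g, _ in pairs])
    rho, p = _spearman_pairs(
        np.vstack(meth_rows), gene_expr.loc[deg_ids, cols].to_numpy(float), xi, yi
    )
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "enhancer_id": [candidates[ci].enhancer_id for ci, _, _ in pairs],
            "gene_id": [g for _, g, _ in pairs],
            "rho": rho,
            "p": p,
            "p_adj": fdr,
            "distance": [d for _, _, d in pairs],
            "category": "genic_DME_DEG",
        }
    )
    keep = (table["rho"].abs() >= rho_threshold) & (table["p_adj"] <= fdr_threshold)
    table = table[keep]

    out = []
    for cand in candidates:
        links = table[table["enhancer_id"] == cand.enhancer_id].reset_index(drop=True)
        if len(links):
            cand.links = links
            out.append(cand)
    return out


def classify_dme_deg(dmr_direction: str, deg_direction: str) -> str:
    """Cross DMR direction with DEG direction: HyperUp/HyperDown/HypoUp/HypoDown."""
    if dmr_direction not in ("hyper", "hypo"):
        raise ValueError(f"unknown DMR direction {dmr_direction!r}")
    if deg_direction not in ("up", "down"):
        raise ValueError(f"unknown DEG direction {deg_direction!r}")
    return ("Hyper" if dmr_direction == "hyper" else "Hypo") + deg_direction.capitalize()


def methylation_associated_dees(
    dees: pd.DataFrame,
    enhancers: pd.DataFrame,
    dmrs: Sequence[Dmr],
    beta: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    erna_expr: pd.DataFrame,
    links: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag DEEs whose eRNA correlates with their own methylation.

    A DEE is methylation-associated when it overlaps >= 1 DMR and the
    Spearman correlation between its mean enhancer beta and its eRNA
    expression has BH-FDR < 0.05 (family = all DMR-overlapping DEEs
    tested). Returns the flagged table and summary fractions (of DEEs, and
    of DEE-DEG links whose DEE is flagged, when ``links`` is given).
    """
    enh = enhancers.set_index("enhancer_id") if "enhancer_id" in enhancers.columns else enhancers
    cols = [c for c in beta.columns if c in set(erna_expr.columns)]
    if not cols:
        raise ValueError("methylation and eRNA matrices share no samples")

    tested: list[tuple[str, float, float]] = []
    for e_id in dees.index:
        if e_id not in enh.index or e_id not in erna_expr.index:
            continue
        row = enh.loc[e_id]
        iv = GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]))
        if not any(iv.overlaps(d.interval) for d in dmrs):
            continue
        mb = enhancer_mean_beta(beta[cols], cpg_positions, iv)
        if mb is None:
            continue
        rho, p = spearman(mb.to_numpy(float), erna_expr.loc[e_id, cols].to_numpy(float))
        tested.append((e_id, rho, p))

    if tested:
        fdr = multipletests([p for _, _, p in tested], method="fdr_bh")[1]
        flagged = pd.DataFrame(
            {
                "enhancer_id": [e for e, _, _ in tested],
                "rho": [r for _, r, _ in tested],
                "p": [p for _, _, p in tested],
                "fdr": fdr,
            }
        )
        flagged = flagged[flagged["fdr"] < fdr_threshold].reset_index(drop=True)
    else:
        flagged = pd.DataFrame(columns=["enhancer_id", "rho", "p", "fdr"])

    fractions = {"frac_dees": len(flagged) / len(dees) if len(dees) else 0.0}
    if links is not None and len(links):
        flagged_set = set(flagged["enhancer_id"])
        fractions["frac_dee_degs"] = float(
            links["enhancer_id"].isin(flagged_set).mean()
        )
    return flagged, fractions


def modifier_coexpression(
    modifier_ids: Sequence[str],
    dees: pd.DataFrame,
    links: pd.DataFrame,
    erna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    rho_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fraction of DEEs (eRNA) and linked DEGs (mRNA) co-expressed with each
    histone-modifier gene (|rho| > 0.5, BH-FDR < 0.05 per modifier per
    feature class)."""
    cols = _shared_samples(erna_expr, gene_expr)
    dee_ids = [e for e in dees.index if e in erna_expr.index]
    deg_ids = sorted(set(links["gene_id"])) if len(links) else []
    deg_ids = [g for g in deg_ids if g in gene_expr.index]

    rows = []
    for mod in modifier_ids:
        if mod not in gene_expr.index:
            raise ValueError(f"modifier gene {mod!r} absent from expression matrix")
        mvec = gene_expr.loc[[mod], cols].to_numpy(float)

        def _frac(feature_mat: np.ndarray) -> float:
            if feature_mat.shape[0] == 0:
                return 0.0
            k = feature_mat.shape[0]
            rho, p = _spearman_pairs(
                feature_mat, mvec, np.arange(k), np.zeros(k, dtype=int)
            )
            fdr = multipletests(p, method="fdr_bh")[1]
            return float(((np.abs(rho) > rho_threshold) & (fdr < fdr_threshold)).mean())

        rows.append(
            {
                "modifier": mod,
                "frac_dees": _frac(erna_expr.loc[dee_ids, cols].to_numpy(float)),
                "frac_dee_degs": _frac(gene_expr.loc[deg_ids, cols].to_numpy(float)),
            }
        )
    return pd.DataFrame(rows, columns=["modifier", "frac_dees", "frac_dee_degs"])


@dataclass
class SuperEnhancerCluster:
    """A chain of nearby same-direction DEEs sharing target genes."""

    member_ids: tuple[str, ...]
    shared_genes: frozenset[str]
    span: GenomicInterval
    direction: str  # activated | repressed


def detect_super_enhancer_clusters(
    links: pd.DataFrame,
    dees: pd.DataFrame,
    enhancers: pd.DataFrame,
    max_gap: int = 50_000,
    min_members: int = 5,
    min_shared_genes: int = 5,
    strict: bool = False,
) -> list[SuperEnhancerCluster]:
    """Chain linked, same-direction DEEs along each chromosome.

    DEEs with >= 1 link are sorted by position per (chromosome, direction);
    a DEE joins the current chain when the gap to the previous member is
    <= ``max_gap`` bp and it shares >= 1 linked gene with the chain's gene
    set. Chains with >= ``min_members`` DEEs and >= ``min_shared_genes``
    distinct genes are reported. The reported gene set is the union of the
    members' linked genes; with ``strict=True`` it is restricted to genes
    linked to every member (and the size threshold applies to that set).
    """
    if not len(links):
        return []
    enh = enhancers.set_index("enhancer_id") if "enhancer_id" in enhancers.columns else enhancers
    gene_sets = links.groupby("enhancer_id")["gene_id"].agg(set).to_dict()

    records = []
    for e_id, genes_of_e in gene_sets.items():
        if e_id not in dees.index or e_id not in enh.index:
            continue
        row = enh.loc[e_id]
        status = dees.loc[e_id, "status"] if "status" in dees.columns else (
            "activated" if dees.loc[e_id, "effect"] > 0 else "repressed"
        )
        records.append(
            (str(row["chrom"]), int(row["start"]), int(row["end"]), e_id, status, genes_of_e)
        )

    clusters: list[SuperEnhancerCluster] = []

    def close(chain: list[tuple], chrom: str, direction: str) -> None:
        if len(chain) < min_members:
            return
        union: set[str] = set().union(*(g for *_, g in chain))
        shared = union
        if strict:
            shared = set.intersection(*(set(g) for *_, g in chain))
        if len(shared) < min_shared_genes:
            return
        clusters.append(
            SuperEnhancerCluster(
                member_ids=tuple(e for _, _, e, _ in chain),
                shared_genes=frozenset(shared),
                span=GenomicInterval(chrom, chain[0][0], chain[-1][1]),
                direction=direction,
            )
        )

    df = pd.DataFrame(
        records, columns=["chrom", "start", "end", "enhancer_id", "status", "genes"]
    )
    for (chrom, direction), grp in df.groupby(["chrom", "status"], sort=True):
        grp = grp.sort_values("start")
        chain: list[tuple[int, int, str, set[str]]] = []
        chain_genes: set[str] = set()
        for row in grp.itertuples():
            joins = bool(chain) and (row.start - chain[-1][1] <= max_gap) and bool(
                chain_genes & row.genes
            )
            if not joins:
                close(chain, chrom, direction)
                chain = []
                chain_genes = set()
            chain.append((row.start, row.end, row.enhancer_id, row.genes))
            chain_genes |= row.genes
        close(chain, chrom, direction)
    return clusters
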