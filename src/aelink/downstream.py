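"""Topology confirmation, gene-set enrichment and the six-gene risk score.

Enhancer-gene links are confirmed against chromatin topology: a pair is
TAD-confirmed when the enhancer center and the target TSS fall inside the
same topologically associating domain, and loop-confirmed when the enhancer
overlaps one loop anchor and the TSS lies in the other. Aberrant-enhancer
target genes are tested for gene-set overrepresentation with an upper-tail
hypergeometric test and BH-FDR. A fixed six-gene prognostic score
(PLOD2, HOXD9, BOP1, RAB26, KLRK1, RGL4 with published coefficients) is a
linear combination of normalized expression; patients are split into high-
and low-risk groups at the cutoff minimizing the two-group log-rank p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "hic_confirm",
    "hypergeom_enrich",
    "read_gmt",
    "DEFAULT_RISK_COEFFICIENTS",
    "RiskModel",
    "risk_score",
    "logrank_test",
    "optimal_cutoff",
    "RiskScoreModel",
    "RiskStratificationResults",
]

#: published multivariate-Cox coefficients of the six-gene signature
DEFAULT_RISK_COEFFICIENTS: Mapping[str, float] = {
    "PLOD2": 0.424,
    "HOXD9": 0.109,
    "BOP1": 0.184,
    "RAB26": -0.134,
    "KLRK1": -0.185,
    "RGL4": -0.0547,
}


# ---------------------------------------------------------------------------
# Hi-C confirmation


def hic_confirm(
    links: pd.DataFrame,
    tads: pd.DataFrame,
    loops: pd.DataFrame,
    strict_tad: bool = False,
) -> pd.DataFrame:
    """Flag each enhancer-gene link as TAD- and/or loop-confirmed.

    ``links`` needs columns chrom, enh_start, enh_end, tss. TAD-confirmed:
    some TAD contains both the enhancer center and the TSS (``strict_tad``
    requires the whole enhancer interval inside the TAD); overlapping TADs
    count if any single TAD contains both. Loop-confirmed: the enhancer
    overlaps (>= 1 bp) one anchor and the TSS lies inside the other, in
    either orientation. Adds boolean columns tad_confirmed, loop_confirmed,
    confirmed (either).
    """
    tad_by_chrom = {
        chrom: grp[["start", "end"]].to_numpy(int)
        for chrom, grp in tads.groupby("chrom")
    }
    loop_by_chrom = {}
    if len(loops):
        same = loops[loops["chrom1"] == loops["chrom2"]]
        for chrom, grp in same.groupby("chrom1"):
            loop_by_chrom[chrom] = grp[
                ["start1", "end1", "start2", "end2"]
            ].to_numpy(int)

    tad_flags, loop_flags = [], []
    for rec in links.itertuples():
        chrom = rec.chrom
        e_start, e_end, tss = int(rec.enh_start), int(rec.enh_end), int(rec.tss)
        center = (e_start + e_end) // 2
        tad_ok = False
        for s, e in tad_by_chrom.get(chrom, ()):
            if strict_tad:
                enh_in = s <= e_start and e_end <= e
            else:
                enh_in = s <= center < e
            if enh_in and s <= tss < e:
                tad_ok = True
                break
        loop_ok = False
        for s1, e1, s2, e2 in loop_by_chrom.get(chrom, ()):
            a_over = e_start < e1 and s1 < e_end
            b_over = e_start < e2 and s2 < e_end
            a_tss = s1 <= tss < e1
            b_tss = s2 <= tss < e2
            if (a_over and b_tss) or (b_over and a_tss):
                loop_ok = True
                break
        tad_flags.append(tad_ok)
        loop_flags.append(loop_ok)
    out = links.copy()
    out["tad_confirmed"] = tad_flags
    out["loop_confirmed"] = loop_flags
    out["confirmed"] = out["tad_confirmed"] | out["loop_confirmed"]
    return out


def confirmation_summary(confirmed: pd.DataFrame) -> dict[str, float]:
    n = len(confirmed)
    if not n:
        return {"frac_tad": float("nan"), "frac_loop": float("nan"),
                "frac_either": float("nan"), "frac_both": float("nan")}
    return {
        "frac_tad": float(confirmed["tad_confirmed"].mean()),
        "frac_loop": float(confirmed["loop_confirmed"].mean()),
        "frac_either": float(confirmed["confirmed"].mean()),
        "frac_both": float((confirmed["tad_confirmed"] & confirmed["loop_confirmed"]).mean()),
    }


# ---------------------------------------------------------------------------
# Gene-set enrichment


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def hypergeom_enrich(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, set[str]],
    background: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation test per gene set.

    With background size N, set size K (after intersecting with the
    background), query size n and overlap k, p = P(X >= k) for
    X ~ Hypergeom(N, K, n); BH-FDR across sets.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    query = set(query_genes) & bg
    n = len(query)
    rows = []
    for name, members in gene_sets.items():
        K = len(members & bg)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, len(bg), K, n))
        rows.append({"gene_set": name, "N": len(bg), "K": K, "n": n, "k": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["gene_set", "N", "K", "n", "k", "p"])
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df


# ---------------------------------------------------------------------------
# Risk score and survival stratification


@dataclass
class RiskModel:
    """Linear prognostic score over a fixed gene panel."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_COEFFICIENTS)
    )
    cutoff: float | None = None


def risk_score(expression: pd.DataFrame, model: RiskModel | None = None) -> pd.Series:
    """Per-patient risk score: sum of coefficient * normalized expression.

    ``expression``: rows = genes, columns = patients. Raises on any missing
    panel gene, naming it.
    """
    model = model or RiskModel()
    missing = [g for g in model.coefficients if g not in expression.index]
    if missing:
        raise ValueError(f"missing risk-model gene(s): {', '.join(missing)}")
    coef = pd.Series(model.coefficients)
    return expression.loc[coef.index].mul(coef, axis=0).sum(axis=0).rename("risk_score")


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test.

    Sums observed minus expected group-A events over distinct event times,
    with the hypergeometric variance at each time; the statistic is
    (O-E)^2/V ~ chi-square(1).
    """
    time_a = np.asarray(time_a, float)
    time_b = np.asarray(time_b, float)
    event_a = np.asarray(event_a, int)
    event_b = np.asarray(event_b, int)
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(np.concatenate([time_a[event_a == 1], time_b[event_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((time_a >= t).sum())
        n2 = int((time_b >= t).sum())
        d1 = int(((time_a == t) & (event_a == 1)).sum())
        d2 = int(((time_b == t) & (event_b == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        expected1 = d * n1 / n
        o_minus_e += d1 - expected1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def optimal_cutoff(
    scores: pd.Series,
    time: pd.Series,
    event: pd.Series,
    lower_quantile: float = 0.10,
    upper_quantile: float = 0.90,
) -> tuple[float, pd.Series]:
    """Risk-score cutoff minimizing the log-rank p-value.

    Candidate cutoffs are the observed scores between the 10th and 90th
    percentiles; patients with score > cutoff form the high-risk group.
    Candidates leaving a group without events are skipped; ties in p are
    broken toward the cutoff nearest the median score. Returns the cutoff
    and a high/low group label per patient.
    """
    scores = pd.Series(scores).astype(float)
    time = pd.Series(time).reindex(scores.index).astype(float)
    event = pd.Series(event).reindex(scores.index).astype(int)
    lo, hi = scores.quantile([lower_quantile, upper_quantile])
    candidates = sorted(s for s in scores.unique() if lo <= s <= hi)
    median = float(scores.median())

    best = None  # (p, distance to median, cutoff)
    for c in candidates:
        high = scores > c
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        if event[high].sum() == 0 or event[~high].sum() == 0:
            continue
        _, p = logrank_test(
            time[high].to_numpy(),
            event[high].to_numpy(),
            time[~high].to_numpy(),
            event[~high].to_numpy(),
        )
        key = (p, abs(c - median), c)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no candidate cutoff leaves events in both groups")
    cutoff = best[2]
    groups = pd.Series(
        np.where(scores > cutoff, "high", "low"), index=scores.index, name="group"
    )
    return float(cutoff), groups


class RiskStratificationResults:
    """High/low-risk stratification of a survival cohort."""

    def __init__(
        self,
        scores: pd.Series,
        cutoff: float,
        groups: pd.Series,
        chi2: float,
        p: float,
        survival: pd.DataFrame,
    ) -> None:
        self.scores = scores
        self.cutoff = cutoff
        self.groups = groups
        self.chi2 = chi2
        self.p = p
        self.survival = survival

    def summary(self) -> str:
        n_high = int((self.groups == "high").sum())
        n_low = int((self.groups == "low").sum())
        return "\n".join(
            [
                "Risk-score stratification",
                f"  patients        : {len(self.scores)}",
                f"  cutoff          : {self.cutoff:.4f}",
                f"  high / low risk : {n_high} / {n_low}",
                f"  log-rank chi2   : {self.chi2:.3f}",
                f"  log-rank p      : {self.p:.3g}",
            ]
        )

    def plot_km(self, ax=None):
        """Kaplan-Meier curves of the two risk groups (lifelines)."""
        from lifelines import KaplanMeierFitter

        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        for label in ("high", "low"):
            mask = self.groups == label
            if mask.sum() == 0:
                continue
            km = KaplanMeierFitter()
            km.fit(
                self.survival.loc[mask, "time"],
                self.survival.loc[mask, "event"],
                label=f"{label} risk",
            )
            km.plot_survival_function(ax=ax)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        return ax


class RiskScoreModel:
    """Six-gene prognostic model applied to a survival cohort.

    ``fit()`` scores every patient, finds the log-rank-minimizing cutoff
    (unless the model carries a fixed one) and returns
    :class:`RiskStratificationResults`.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        survival: pd.DataFrame,
        model: RiskModel | None = None,
    ) -> None:
        if not {"time", "event"} <= set(survival.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        if (survival["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        self.expression = expression
        self.survival = survival
        self.model = model or RiskModel()

    def fit(self) -> RiskStratificationResults:
        scores = risk_score(self.expression, self.model)
        scores = scores.reindex(self.survival.index)
        if scores.isna().any():
            raise ValueError("expression missing for some survival patients")
        if self.model.cutoff is not None:
            cutoff = float(self.model.cutoff)
            groups = pd.Series(
                np.where(scores > cutoff, "high", "low"), index=scores.index, name="group"
            )
        else:
            cutoff, groups = optimal_cutoff(
                scores, self.survival["time"], self.survival["event"]
            )
        high = groups == "high"
        chi2, p = logrank_test(
            self.survival.loc[high, "time"].to_numpy(),
            self.survival.loc[high, "event"].to_numpy(),
            self.survival.loc[~high, "time"].to_numpy(),
            self.survival.loc[~high, "event"].to_numpy(),
        )
        return RiskStratificationResults(scores, cutoff, groups, chi2, p, self.survival)
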