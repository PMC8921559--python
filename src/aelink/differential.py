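"""Paired tumor/normal differential testing for genes, eRNAs and CpGs.

The study design is paired: each patient contributes one tumor and one
adjacent-normal sample. Expression features (gene counts, per-enhancer eRNA
fragment counts) are normalised to fragments/counts per million, log2(x+1)
transformed, and tested per feature with a paired t-test; methylation betas
are tested on the raw scale. Benjamini-Hochberg FDR is applied across
features. Differential calls use |log2 fold change| > 0.5 and FDR < 0.05
(strict inequalities); differentially methylated loci are aggregated into
regions by a same-direction run scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "PairedMatrix",
    "PairedDifferenceModel",
    "DifferentialResults",
    "Dmr",
    "fpm",
    "log2_fpm",
    "paired_diff_test",
    "call_dee",
    "call_deg",
    "call_dml_dmr",
]

LFC_THRESHOLD = 0.5
FDR_THRESHOLD = 0.05


class PairedMatrix:
    """Feature x sample matrix with a paired tumor/normal design.

    Parameters
    ----------
    values
        DataFrame, rows = features, columns = sample ids.
    patients, conditions
        Per-column patient label and condition ('tumor' or 'normal').
        Every patient must contribute exactly one tumor and one normal column.
    library_sizes
        Optional per-sample totals (required for FPM/CPM normalisation).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        patients: Sequence[str],
        conditions: Sequence[str],
        library_sizes: pd.Series | None = None,
    ) -> None:
        if len(patients) != values.shape[1] or len(conditions) != values.shape[1]:
            raise ValueError("patients/conditions must match the number of columns")
        design = pd.DataFrame(
            {"patient": list(patients), "condition": list(conditions)},
            index=values.columns,
        )
        bad = set(design["condition"]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        counts = design.groupby("patient")["condition"].value_counts().unstack(fill_value=0)
        if (
            "tumor" not in counts
            or "normal" not in counts
            or not ((counts["tumor"] == 1) & (counts["normal"] == 1)).all()
        ):
            raise ValueError(
                "pairing error: every patient needs exactly one tumor and one normal column"
            )
        if library_sizes is not None:
            library_sizes = pd.Series(library_sizes).reindex(values.columns)
            if library_sizes.isna().any() or (library_sizes <= 0).any():
                raise ValueError("library_sizes must be positive for every sample")
        self.values = values
        self.design = design
        self.library_sizes = library_sizes

    @property
    def n_pairs(self) -> int:
        return self.design["patient"].nunique()

    def paired_columns(self) -> tuple[list[str], list[str], list[str]]:
        """(patients, tumor column ids, normal column ids), aligned."""
        pats, tum, nor = [], [], []
        for patient, grp in self.design.groupby("patient", sort=True):
            pats.append(patient)
            tum.append(grp.index[grp["condition"] == "tumor"][0])
            nor.append(grp.index[grp["condition"] == "normal"][0])
        return pats, tum, nor


def fpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Fragments per million: count / library_size * 1e6."""
    lib = pd.Series(library_sizes).reindex(counts.columns)
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("library sizes must be positive for all samples")
    return counts / lib * 1e6


def log2_fpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """log2(FPM + 1); the pseudocount of 1 keeps zero counts at zero."""
    return np.log2(fpm(counts, library_sizes) + 1.0)


def paired_diff_test(
    matrix: PairedMatrix,
    transform: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-feature paired t-test of tumor vs normal.

    effect = mean over patients of (tumor - normal) on the transformed scale;
    p from the paired t statistic with n_pairs - 1 df; BH-FDR across
    features. Degenerate features: all differences zero -> p = 1; zero
    variance with nonzero mean -> p = 0 (both logged).

    Returns a DataFrame indexed by feature with columns
    effect, t, p, fdr, direction.
    """
    if matrix.n_pairs < 3:
        raise ValueError("paired test needs >= 3 patient pairs")
    values = matrix.values
    if matrix.library_sizes is not None and transform is None:
        transform = lambda v: np.log2(fpm(v, matrix.library_sizes) + 1.0)  # noqa: E731
    if transform is not None:
        values = transform(matrix.values)
    _, tum, nor = matrix.paired_columns()
    diffs = values[tum].to_numpy() - values[nor].to_numpy()
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    null_feature = zero_var & (mean == 0)
    degenerate = zero_var & (mean != 0)
    p[null_feature] = 1.0
    t[null_feature] = 0.0
    p[degenerate] = 0.0
    if null_feature.any():
        logger.info("%d features with identical tumor/normal values: p=1", null_feature.sum())
    if degenerate.any():
        logger.warning(
            "%d features with zero-variance nonzero differences: p=0", degenerate.sum()
        )
    fdr = multipletests(p, method="fdr_bh")[1]
    direction = np.where(mean > 0, "up", np.where(mean < 0, "down", "none"))
    return pd.DataFrame(
        {"effect": mean, "t": t, "p": p, "fdr": fdr, "direction": direction},
        index=matrix.values.index.rename("feature"),
    )


class DifferentialResults:
    """Results of a paired differential analysis.

    Carries the per-feature table (effect, t, p, fdr, direction) and exposes
    threshold-based calls and a summary table.
    """

    def __init__(self, table: pd.DataFrame, n_pairs: int, kind: str = "expression"):
        self.table = table
        self.n_pairs = n_pairs
        self.kind = kind

    def significant(
        self,
        effect_threshold: float = LFC_THRESHOLD,
        fdr_threshold: float = FDR_THRESHOLD,
        effect_inclusive: bool = False,
    ) -> pd.DataFrame:
        t = self.table
        if effect_inclusive:
            mask = (t["effect"].abs() >= effect_threshold) & (t["fdr"] < fdr_threshold)
        else:
            mask = (t["effect"].abs() > effect_threshold) & (t["fdr"] < fdr_threshold)
        return t[mask]

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            f"Paired differential analysis ({self.kind})",
            f"  features tested : {len(self.table)}",
            f"  patient pairs   : {self.n_pairs}",
            f"  significant (|effect| > {LFC_THRESHOLD}, FDR < {FDR_THRESHOLD}): {len(sig)}",
            f"    up   : {(sig['direction'] == 'up').sum()}",
            f"    down : {(sig['direction'] == 'down').sum()}",
        ]
        return "\n".join(lines)


class PairedDifferenceModel:
    """Paired tumor/normal differential model over a feature matrix.

    ``fit()`` runs the per-feature paired t-test (with the configured
    normalising transform) and returns :class:`DifferentialResults`.
    """

    def __init__(
        self,
        matrix: PairedMatrix,
        transform: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
        kind: str = "expression",
    ) -> None:
        self.matrix = matrix
        self.transform = transform
        self.kind = kind

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        patients: Sequence[str],
        conditions: Sequence[str],
        library_sizes: pd.Series,
        kind: str = "expression",
    ) -> "PairedDifferenceModel":
        matrix = PairedMatrix(counts, patients, conditions, library_sizes)
        return cls(matrix, transform=None, kind=kind)

    @classmethod
    def from_betas(
        cls,
        betas: pd.DataFrame,
        patients: Sequence[str],
        conditions: Sequence[str],
    ) -> "PairedDifferenceModel":
        matrix = PairedMatrix(betas, patients, conditions)
        return cls(matrix, transform=lambda v: v, kind="methylation")

    def fit(self) -> DifferentialResults:
        table = paired_diff_test(self.matrix, self.transform)
        return DifferentialResults(table, self.matrix.n_pairs, kind=self.kind)


def call_dee(
    results: DifferentialResults | pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Differentially expressed enhancers: |LFC| > 0.5 and FDR < 0.05.

    Adds a ``status`` column: 'activated' (effect > 0) or 'repressed'.
    """
    table = results.table if isinstance(results, DifferentialResults) else results
    sig = table[(table["effect"].abs() > lfc_threshold) & (table["fdr"] < fdr_threshold)].copy()
    sig["status"] = np.where(sig["effect"] > 0, "activated", "repressed")
    return sig


def call_deg(
    results: DifferentialResults | pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Differentially expressed genes, same thresholds as enhancers.

    The stricter histone-modifier screen is the same call with
    ``lfc_threshold=1``. Adds ``status``: 'up'/'down'.
    """
    table = results.table if isinstance(results, DifferentialResults) else results
    sig = table[(table["effect"].abs() > lfc_threshold) & (table["fdr"] < fdr_threshold)].copy()
    sig["status"] = np.where(sig["effect"] > 0, "up", "down")
    return sig


@dataclass
class Dmr:
    """A differentially methylated region: a maximal same-direction run of
    differentially methylated CpGs."""

    interval: GenomicInterval
    n_cpgs: int
    mean_delta: float
    direction: str  # hyper | hypo
    positions: tuple[int, ...]


def call_dml_dmr(
    beta: PairedMatrix,
    positions: pd.DataFrame,
    min_cpgs: int = 5,
    max_gap: int = 500,
    min_delta: float = 0.1,
    fdr_threshold: float = FDR_THRESHOLD,
) -> tuple[pd.DataFrame, list[Dmr]]:
    """Call differentially methylated loci (DML) and regions (DMR).

    DML: CpG with paired-test FDR < ``fdr_threshold`` and
    |mean tumor-normal beta difference| >= ``min_delta``. DMR: maximal run of
    >= ``min_cpgs`` same-direction DMLs with consecutive genomic gaps
    <= ``max_gap`` bp on one chromosome; its interval spans the first to the
    last member CpG and its mean_delta is the mean of member deltas.

    Parameters
    ----------
    beta
        PairedMatrix of beta values, features = CpG ids.
    positions
        DataFrame indexed like ``beta.values`` with columns chrom, pos;
        positions must be sorted (ascending) within each chromosome.
    """
    pos = positions.reindex(beta.values.index)
    if pos[["chrom", "pos"]].isna().any().any():
        raise ValueError("positions missing for some CpGs")
    for chrom, grp in pos.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"CpG positions on {chrom} are not sorted")

    table = paired_diff_test(beta, transform=lambda v: v)
    table = table.join(pos[["chrom", "pos"]])
    is_dml = (table["fdr"] < fdr_threshold) & (table["effect"].abs() >= min_delta)
    dml = table[is_dml].copy()
    dml["direction"] = np.where(dml["effect"] > 0, "hyper", "hypo")

    dmrs: list[Dmr] = []
    for chrom, grp in dml.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        run: list[tuple[int, float, str]] = []

        def flush(run: list[tuple[int, float, str]]) -> None:
            if len(run) >= min_cpgs:
                ps = tuple(p for p, _, _ in run)
                deltas = [d for _, d, _ in run]
                dmrs.append(
                    Dmr(
                        interval=GenomicInterval(chrom, ps[0], ps[-1] + 1),
                        n_cpgs=len(run),
                        mean_delta=float(np.mean(deltas)),
                        direction=run[0][2],
                    positions=ps,
                    )
                )

        for p, d, direc in zip(grp["pos"], grp["effect"], grp["direction"]):
            if run and (p - run[-1][0] > max_gap or direc != run[-1][2]):
                flush(run)
                run = []
            run.append((int(p), float(d), str(direc)))
        flush(run)
    return dml, dmrs


def dmrs_to_frame(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "n_cpgs": d.n_cpgs,
                "mean_delta": d.mean_delta,
                "direction": d.direction,
            }
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "n_cpgs", "mean_delta", "direction"],
    )
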