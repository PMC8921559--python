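"""Merged enhancer catalog construction from per-sample histone-mark calls.

Per-sample enhancers come either from H3K4me1/H3K27ac peak files (a peak is
an *active* enhancer when it overlaps an H3K27ac peak by >= 1 bp, otherwise
*primed*; samples lacking H3K27ac contribute peaks of *unknown* state) or
from chromatin-state segmentations whose enhancer states are mapped onto the
same vocabulary. All sample enhancers are union-merged into a catalog;
merged intervals shorter than 50 bp or overlapping any promoter are dropped;
the survivors are partitioned into genic (overlapping a gene body) and
intergenic enhancers and annotated with their concurrence — the number of
distinct samples contributing at least one overlapping source interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, merge_intervals, read_bed

logger = logging.getLogger(__name__)

__all__ = [
    "SampleEnhancer",
    "CatalogEnhancer",
    "classify_sample_enhancers",
    "ingest_state_bed",
    "merge_catalog",
    "concurrence_histogram",
    "long_enhancer_fraction",
    "catalog_to_frame",
]

MIN_ENHANCER_LENGTH = 50
LONG_ENHANCER_BP = 3000

#: default chromatin-state label vocabulary -> enhancer state
DEFAULT_STATE_LABELS: Mapping[str, str] = {
    "active_enhancer": "active",
    "poised_enhancer": "primed",
    "primed": "primed",
}


@dataclass(frozen=True)
class SampleEnhancer:
    interval: GenomicInterval
    state: str  # active | primed | unknown
    sample_id: str

    def __post_init__(self) -> None:
        if self.state not in ("active", "primed", "unknown"):
            raise ValueError(f"invalid enhancer state {self.state!r}")


@dataclass
class CatalogEnhancer:
    enhancer_id: str
    interval: GenomicInterval
    concurrence: int
    contributing_samples: frozenset[str]
    cls: str  # intergenic | genic


def _bed_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]


def classify_sample_enhancers(
    h3k4me1: pd.DataFrame | str,
    h3k27ac: pd.DataFrame | str | None,
    sample_id: str,
) -> list[SampleEnhancer]:
    """Label each H3K4me1 peak active/primed by H3K27ac overlap.

    A whole H3K4me1 peak is classified by whether it overlaps (>= 1 bp) any
    H3K27ac peak. When the sample has no H3K27ac data every peak is kept
    with state ``unknown`` (primed or active, indistinguishable).
    """
    if isinstance(h3k4me1, (str, bytes)) or hasattr(h3k4me1, "__fspath__"):
        h3k4me1 = read_bed(h3k4me1)
    peaks = _bed_to_intervals(h3k4me1)
    if h3k27ac is None:
        return [SampleEnhancer(iv, "unknown", sample_id) for iv in peaks]
    if isinstance(h3k27ac, (str, bytes)) or hasattr(h3k27ac, "__fspath__"):
        h3k27ac = read_bed(h3k27ac)
    ac = {}
    for iv in _bed_to_intervals(h3k27ac):
        ac.setdefault(iv.chrom, []).append((iv.start, iv.end))
    # sorted start/end arrays per chromosome for overlap queries
    ac_sorted = {
        chrom: (
            np.array(sorted(s for s, _ in ivs)),
            np.array([e for _, e in sorted(ivs)]),
        )
        for chrom, ivs in ac.items()
    }
    out = []
    for iv in peaks:
        state = "primed"
        if iv.chrom in ac_sorted:
            starts, ends = ac_sorted[iv.chrom]
            # any H3K27ac interval with start < iv.end and end > iv.start
            i = np.searchsorted(starts, iv.end, side="left")
            if np.any(ends[:i] > iv.start):
                state = "active"
        out.append(SampleEnhancer(iv, state, sample_id))
    return out


def ingest_state_bed(
    states: pd.DataFrame | str,
    sample_id: str,
    label_map: Mapping[str, str] = DEFAULT_STATE_LABELS,
) -> list[SampleEnhancer]:
    """Map chromatin-state rows to sample enhancers; unrecognised states are
    dropped with a logged warning."""
    if isinstance(states, (str, bytes)) or hasattr(states, "__fspath__"):
        states = read_bed(states, min_fields=4)
    if states.empty:
        return []
    out = []
    dropped: set[str] = set()
    label_col = states.columns[3]
    for c, s, e, label in zip(
        states["chrom"], states["start"], states["end"], states[label_col]
    ):
        state = label_map.get(str(label))
        if state is None:
            dropped.add(str(label))
            continue
        out.append(SampleEnhancer(GenomicInterval(str(c), int(s), int(e)), state, sample_id))
    for label in sorted(dropped):
        logger.warning("sample %s: dropping state label %r", sample_id, label)
    return out


def _any_overlap(iv: GenomicInterval, index: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    if iv.chrom not in index:
        return False
    starts, ends = index[iv.chrom]
    i = np.searchsorted(starts, iv.end, side="left")
    return bool(np.any(ends[:i] > iv.start))


def _build_index(intervals: Iterable[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: (
            np.array([s for s, _ in sorted(ivs)]),
            np.array([e for _, e in sorted(ivs)]),
        )
        for chrom, ivs in per.items()
    }


def merge_catalog(
    per_sample: Sequence[Sequence[SampleEnhancer]],
    genes: Sequence[GeneModel],
    min_length: int = MIN_ENHANCER_LENGTH,
) -> list[CatalogEnhancer]:
    """Union-merge sample enhancers into the catalog.

    Overlapping or book-ended intervals coalesce; merged intervals with
    length < ``min_length`` or overlapping any promoter (>= 1 bp) are
    excluded. Class is intergenic when the merged interval overlaps no gene
    body [tx_start, tx_end), genic otherwise.
    """
    if not per_sample:
        raise ValueError("merge_catalog requires at least one sample")
    all_ivs = [se.interval for sample in per_sample for se in sample]
    if not all_ivs:
        return []
    merged = merge_intervals(all_ivs)

    promoter_index = _build_index(g.promoter for g in genes)
    body_index = _build_index(g.body for g in genes)
    sample_indexes = [
        (sample[0].sample_id if sample else None, _build_index(se.interval for se in sample))
        for sample in per_sample
    ]

    catalog: list[CatalogEnhancer] = []
    k = 0
    for iv in merged:
        if iv.length < min_length:
            continue
        if _any_overlap(iv, promoter_index):
            continue
        contributing = frozenset(
            sid for sid, idx in sample_indexes if sid is not None and _any_overlap(iv, idx)
        )
        cls = "genic" if _any_overlap(iv, body_index) else "intergenic"
        k += 1
        catalog.append(
            CatalogEnhancer(
                enhancer_id=f"enh_{k:05d}",
                interval=iv,
                concurrence=len(contributing),
                contributing_samples=contributing,
                cls=cls,
            )
        )
    return catalog


def concurrence_histogram(
    catalog: Sequence[CatalogEnhancer], n_samples: int
) -> tuple[pd.Series, float]:
    """Histogram of catalog concurrence over 1..n_samples and the fraction of
    enhancers present in at least two samples."""
    counts = pd.Series(0, index=pd.RangeIndex(1, n_samples + 1, name="concurrence"))
    for enh in catalog:
        counts.loc[enh.concurrence] += 1
    total = len(catalog)
    frac_ge2 = float(sum(c for lvl, c in counts.items() if lvl >= 2) / total) if total else 0.0
    return counts, frac_ge2


def long_enhancer_fraction(
    per_sample: Mapping[str, Sequence[SampleEnhancer]],
    threshold: int = LONG_ENHANCER_BP,
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-sample fraction of enhancers longer than ``threshold`` bp (> strict),
    plus per-group means when a sample -> group mapping is given."""
    fracs = {}
    for sid, enhs in per_sample.items():
        n = len(enhs)
        fracs[sid] = (
            sum(1 for se in enhs if se.interval.length > threshold) / n if n else float("nan")
        )
    per_sample_frac = pd.Series(fracs, name="long_fraction")
    if groups:
        grp = pd.Series({sid: groups.get(sid, "ungrouped") for sid in fracs})
        group_means = per_sample_frac.groupby(grp).mean()
    else:
        group_means = pd.Series(dtype=float)
    return per_sample_frac, group_means


def catalog_to_frame(catalog: Sequence[CatalogEnhancer]) -> pd.DataFrame:
    """Catalog as a BED6-style table (chrom, start, end, enhancer_id,
    concurrence, class)."""
    return pd.DataFrame(
        [
            {
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "enhancer_id": e.enhancer_id,
                "concurrence": e.concurrence,
                "class": e.cls,
            }
            for e in catalog
        ],
        columns=["chrom", "start", "end", "enhancer_id", "concurrence", "class"],
    )
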