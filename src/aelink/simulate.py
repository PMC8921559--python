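"""Synthetic paired tumor/normal epigenome-transcriptome data with planted truth.

Emulates the inputs of an integrative enhancer study: per-sample histone-mark
peak and chromatin-state files for an enhancer catalog, paired tumor/normal
RNA-seq counts for genes and enhancer RNAs with planted differential features
and planted enhancer-gene correlations, per-CpG WGBS-style methylation with
planted DMRs, TADs and loops containing a configured fraction of planted
links, and a survival cohort whose hazard is driven by the six-gene risk
score. Every planted feature is recorded in a GroundTruth object sufficient
to score recovery, FDR, linking precision and topology confirmation without
re-reading the configuration.

Count model: negative binomial with shared per-feature dispersion. The
paired design is induced by a per-pair lognormal sequencing-depth factor
folded into the recorded library sizes, so per-million normalisation cancels
it and unplanted features stay uncorrelated. Planted differential features
carry per-patient effect heterogeneity; a planted link shares that tumor
latent factor between the enhancer and its target gene, with the factor's
scale chosen to target the configured link correlation (targeted, not
exact). Methylation betas are clipped normals around group means.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, write_genes

__all__ = ["SimConfig", "GroundTruth", "SimulatedStudy", "simulate_study"]

LN2_SQ = math.log(2) ** 2


@dataclass
class SimConfig:
    """Configuration of a synthetic study.

    Defaults mirror the emulated study design: 11 ChIP-seq samples (one
    without H3K27ac), 33 paired tumor/normal RNA-seq patients, roughly a
    third of enhancers active per sample, and a majority of catalog
    enhancers concurrent in >= 2 samples.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 3_000_000
    n_genes: int = 80
    n_enhancers: int = 160
    n_samples_chip: int = 11
    n_pairs_rnaseq: int = 33
    frac_active: float = 0.32
    planted_dee_frac: float = 0.25
    planted_deg_frac: float = 0.25
    planted_dmr_frac: float = 0.5
    effect_lfc: float = 2.0
    effect_dmeth: float = 0.3
    link_rho_target: float = 0.95
    nb_dispersion: float = 0.1
    tad_size: int = 1_000_000

    # genome layout
    frac_promoter_enhancers: float = 0.05
    frac_short_enhancers: float = 0.05
    frac_genic_enhancers: float = 0.4
    # ChIP design
    samples_without_h3k27ac: tuple[int, ...] = (5,)
    frac_concurrent: float = 0.6
    overlap_all: bool = False
    # expression
    base_fpm: float = 10.0
    base_library_size: float = 2.0e7
    pair_depth_sigma: float = 0.25
    frac_dee_up: float = 0.8
    frac_deg_up: float = 0.5
    # methylation
    beta_noise_sd: float = 0.08
    cpg_spacing_enhancer: int = 60
    cpg_spacing_background: int = 500
    frac_dee_with_dmr: float = 0.4
    meth_link_scale: float = 0.06
    # topology & survival
    frac_links_in_tad: float = 0.7
    frac_links_looped: float = 0.3
    n_survival_patients: int = 200
    hazard_model: str = "proportional"  # or "threshold"
    risk_effect: float = 1.5
    threshold_hazard_ratio: float = 6.0
    risk_threshold_quantile: float = 0.6

    def validate(self) -> None:
        fractions = {
            "frac_active": self.frac_active,
            "planted_dee_frac": self.planted_dee_frac,
            "planted_deg_frac": self.planted_deg_frac,
            "planted_dmr_frac": self.planted_dmr_frac,
            "link_rho_target": self.link_rho_target,
            "frac_promoter_enhancers": self.frac_promoter_enhancers,
            "frac_short_enhancers": self.frac_short_enhancers,
            "frac_genic_enhancers": self.frac_genic_enhancers,
            "frac_concurrent": self.frac_concurrent,
            "frac_dee_up": self.frac_dee_up,
            "frac_deg_up": self.frac_deg_up,
            "frac_dee_with_dmr": self.frac_dee_with_dmr,
            "frac_links_in_tad": self.frac_links_in_tad,
            "frac_links_looped": self.frac_links_looped,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in (
            "n_chroms",
            "chrom_length",
            "n_enhancers",
            "n_samples_chip",
            "n_pairs_rnaseq",
            "tad_size",
            "n_survival_patients",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.hazard_model not in ("proportional", "threshold"):
            raise ValueError("hazard_model must be 'proportional' or 'threshold'")


@dataclass
class GroundTruth:
    """Planted features of a simulated study, keyed by template/gene ids."""

    dee_direction: dict[str, str] = field(default_factory=dict)  # up | down
    deg_direction: dict[str, str] = field(default_factory=dict)
    links: list[dict] = field(default_factory=list)  # enhancer_id, gene_id, direction
    dmrs: list[dict] = field(default_factory=list)  # chrom/start/end/direction/target
    dme_links: list[dict] = field(default_factory=list)
    template_concurrence: dict[str, int] = field(default_factory=dict)
    link_in_tad: dict[str, bool] = field(default_factory=dict)  # "enh|gene" -> contained
    link_looped: dict[str, bool] = field(default_factory=dict)
    risk_threshold: float | None = None

    def validate(self, templates: pd.DataFrame, genes: Sequence[GeneModel]) -> None:
        tmap = templates.set_index("template_id")
        gmap = {g.gene_id: g for g in genes}
        for link in self.links:
            t = tmap.loc[link["enhancer_id"]]
            g = gmap[link["gene_id"]]
            if t["chrom"] != g.chrom:
                raise AssertionError("planted link spans chromosomes")
            center = (int(t["start"]) + int(t["end"])) // 2
            if abs(g.tss - center) > 1_000_000:
                raise AssertionError("planted link exceeds 1 Mb")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class SimulatedStudy:
    """In-memory bundle of everything the generator produced."""

    config: SimConfig
    genes: list[GeneModel]
    templates: pd.DataFrame  # template_id chrom start end placement
    chip_samples: dict  # sample_id -> {"H3K4me1": df, "H3K27ac": df|None, "states": df}
    presence: pd.DataFrame  # template x sample bool
    gene_counts: pd.DataFrame
    erna_counts: pd.DataFrame
    library_sizes: pd.Series
    patients: list[str]
    conditions: list[str]
    cpg_positions: pd.DataFrame  # index cpg id, columns chrom pos
    beta: pd.DataFrame
    tads: pd.DataFrame
    loops: pd.DataFrame
    survival: pd.DataFrame  # index patient; time, event
    risk_expression: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genes(self.genes, out / "genes.tsv")
        self.templates.to_csv(out / "templates.tsv", sep="\t", index=False)
        for sid, marks in self.chip_samples.items():
            marks["H3K4me1"].to_csv(
                out / f"{sid}.H3K4me1.bed", sep="\t", header=False, index=False
            )
            if marks["H3K27ac"] is not None:
                marks["H3K27ac"].to_csv(
                    out / f"{sid}.H3K27ac.bed", sep="\t", header=False, index=False
                )
            marks["states"].to_csv(
                out / f"{sid}.states.bed", sep="\t", header=False, index=False
            )
        self.gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
        self.erna_counts.to_csv(out / "erna_counts.tsv", sep="\t")
        lib = self.library_sizes.rename("library_size").to_frame()
        lib.insert(0, "patient", self.patients)
        lib.insert(1, "condition", self.conditions)
        lib.to_csv(out / "libsizes.tsv", sep="\t")
        beta_out = self.cpg_positions.join(self.beta)
        beta_out.to_csv(out / "cpg_beta.tsv", sep="\t")
        self.tads.to_csv(out / "tads.bed", sep="\t", header=False, index=False)
        self.loops.to_csv(out / "loops.bedpe", sep="\t", header=False, index=False)
        self.survival.to_csv(out / "survival.tsv", sep="\t")
        self.risk_expression.to_csv(out / "risk_expression.tsv", sep="\t")
        (out / "truth.json").write_text(self.truth.to_json())


# ---------------------------------------------------------------------------
# genome layout


def simulate_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place genes and enhancer templates on each chromosome.

    Templates are deliberately heterogeneous: a configured fraction sits
    inside promoters, a fraction is shorter than 50 bp, and the remainder
    splits genic/intergenic — so the catalog's filters are exercised.
    """
    config.validate()
    genes: list[GeneModel] = []
    rows = []
    t_idx = 0
    genes_per_chrom = _split_count(config.n_genes, config.n_chroms)
    enh_per_chrom = _split_count(config.n_enhancers, config.n_chroms)

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n_g = genes_per_chrom[ci]
        n_e = enh_per_chrom[ci]
        chrom_genes: list[GeneModel] = []
        if n_g:
            spacing = config.chrom_length // (n_g + 1)
            if spacing < 16_000:
                raise ValueError(
                    f"{chrom} too short ({config.chrom_length} bp) to host {n_g} genes"
                )
            for gi in range(n_g):
                length = int(rng.integers(2_000, 10_001))
                anchor = (gi + 1) * spacing
                start = anchor + int(rng.integers(-2_000, 2_001))
                strand = "+" if rng.random() < 0.5 else "-"
                g = GeneModel(
                    gene_id=f"gene_{ci + 1:d}_{gi + 1:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=start + length,
                )
                genes.append(g)
                chrom_genes.append(g)

        n_prom = round(config.frac_promoter_enhancers * n_e) if chrom_genes else 0
        n_short = round(config.frac_short_enhancers * n_e)
        remaining = n_e - n_prom - n_short
        n_genic = round(config.frac_genic_enhancers * remaining) if chrom_genes else 0
        n_inter = remaining - n_genic

        # promoter-resident templates: inside the strand-aware promoter window
        for k in range(n_prom):
            g = chrom_genes[k % len(chrom_genes)]
            if g.strand == "+":
                start = g.tss - 1_000
            else:
                start = g.tss + 400
            rows.append((_tid(t_idx), chrom, start, start + 300, "promoter"))
            t_idx += 1

        # genic templates: non-overlapping slots inside gene bodies, clear of
        # the promoter window (which reaches 500 bp into the body)
        if n_genic:
            per_gene_slots: list[list[tuple[int, int]]] = []
            for g in chrom_genes:
                lo, hi = g.tx_start + 600, g.tx_end - 600
                slots = []
                pos = lo
                while pos + 300 <= hi:
                    length = min(600, hi - pos)
                    slots.append((pos, pos + length))
                    pos += length + 400
                per_gene_slots.append(slots)
            # round-robin across genes so templates spread before doubling up
            ordered: list[tuple[int, int]] = []
            depth = 0
            while len(ordered) < n_genic:
                added = False
                for slots in per_gene_slots:
                    if depth < len(slots):
                        ordered.append(slots[depth])
                        added = True
                if not added:
                    raise ValueError(
                        f"{chrom} gene bodies too small to host {n_genic} genic templates"
                    )
                depth += 1
            for start, end in ordered[:n_genic]:
                rows.append((_tid(t_idx), chrom, start, end, "genic"))
                t_idx += 1

        # intergenic + short templates on a grid avoiding genes and promoters
        forbidden = []
        for g in chrom_genes:
            forbidden.append((g.tx_start - 2_100, g.tx_end + 2_100))
        forbidden.sort()
        free = _free_segments(forbidden, 10_000, config.chrom_length - 10_000)
        total_free = sum(e - s for s, e in free)
        n_slots = n_inter + n_short
        if n_slots:
            if total_free < n_slots * 3_000:
                raise ValueError(
                    f"{chrom} too short to host {n_slots} intergenic enhancer templates"
                )
            positions = _grid_positions(free, n_slots)
            for k, pos in enumerate(positions):
                if k < n_inter:
                    length = int(rng.integers(400, 1_501))
                    placement = "intergenic"
                else:
                    length = int(rng.integers(30, 50))
                    placement = "short"
                rows.append((_tid(t_idx), chrom, pos, pos + length, placement))
                t_idx += 1

    templates = pd.DataFrame(
        rows, columns=["template_id", "chrom", "start", "end", "placement"]
    )
    return genes, templates


def _tid(i: int) -> str:
    return f"tmpl_{i + 1:05d}"


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _free_segments(
    forbidden: list[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    segments = []
    cursor = lo
    for s, e in forbidden:
        if s > cursor:
            segments.append((cursor, min(s, hi)))
        cursor = max(cursor, e)
        if cursor >= hi:
            break
    if cursor < hi:
        segments.append((cursor, hi))
    return [(s, e) for s, e in segments if e - s > 4_000]


def _grid_positions(free: list[tuple[int, int]], n: int) -> list[int]:
    """Spread n positions across free segments proportionally to length."""
    total = sum(e - s for s, e in free)
    positions: list[int] = []
    alloc = []
    for s, e in free:
        alloc.append((e - s) / total * n)
    counts = [int(a) for a in alloc]
    # distribute remainder to largest fractional parts, deterministically
    rem = n - sum(counts)
    order = sorted(range(len(free)), key=lambda i: alloc[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    for (s, e), c in zip(free, counts):
        if c == 0:
            continue
        step = (e - s) // (c + 1)
        for j in range(c):
            positions.append(s + (j + 1) * step)
    return sorted(positions)[:n]


# ---------------------------------------------------------------------------
# ChIP samples


def simulate_chip_samples(
    config: SimConfig, templates: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict, pd.DataFrame]:
    """Per-sample jittered peak and state files plus the presence matrix.

    Each template is present in one sample, or (with probability
    ``frac_concurrent``) in a uniform 2..n_samples of them; ``overlap_all``
    forces presence (and activity) everywhere. Samples listed in
    ``samples_without_h3k27ac`` emit no H3K27ac file, so their peaks are
    state-unknown downstream.
    """
    sample_ids = [f"sample_{k + 1:02d}" for k in range(config.n_samples_chip)]
    n = len(sample_ids)
    presence = pd.DataFrame(
        False, index=templates["template_id"], columns=sample_ids
    )
    active = pd.DataFrame(False, index=templates["template_id"], columns=sample_ids)

    for t in templates.itertuples():
        if config.overlap_all:
            chosen = list(range(n))
        else:
            if n > 1 and rng.random() < config.frac_concurrent:
                k = int(rng.integers(2, n + 1))
            else:
                k = 1
            chosen = sorted(rng.choice(n, size=k, replace=False).tolist())
        for si in chosen:
            presence.iloc[presence.index.get_loc(t.template_id), si] = True
            if config.overlap_all or rng.random() < config.frac_active:
                active.iloc[active.index.get_loc(t.template_id), si] = True

    chip_samples: dict = {}
    for si, sid in enumerate(sample_ids):
        k4_rows, k27_rows, state_rows = [], [], []
        has_k27 = si not in set(config.samples_without_h3k27ac)
        for t in templates.itertuples():
            if not presence.loc[t.template_id, sid]:
                continue
            length = t.end - t.start
            if length < 50:
                # sub-50 bp templates stay exact so the catalog length filter
                # sees them at their planted size
                j1 = j2 = 0
            else:
                j1 = int(rng.integers(-20, 21))
                j2 = int(rng.integers(-20, 21))
            start = max(0, t.start + j1)
            end = max(start + max(10, length // 2), t.end + j2)
            k4_rows.append((t.chrom, start, end))
            is_active = bool(active.loc[t.template_id, sid])
            if has_k27 and is_active:
                mid = (start + end) // 2
                k27_rows.append((t.chrom, max(0, mid - length // 3 - 50), mid + length // 3 + 50))
            state_rows.append(
                (t.chrom, start, end, "active_enhancer" if is_active else "poised_enhancer")
            )
        # decoy non-enhancer state rows exercise the ingest filter
        state_rows.append(("chr1", 0, 200, "promoter"))
        state_rows.append(("chr1", 200, 400, "transcription"))
        chip_samples[sid] = {
            "H3K4me1": pd.DataFrame(k4_rows, columns=["chrom", "start", "end"]),
            "H3K27ac": (
                pd.DataFrame(k27_rows, columns=["chrom", "start", "end"]) if has_k27 else None
            ),
            "states": pd.DataFrame(
                sorted(state_rows), columns=["chrom", "start", "end", "state"]
            ),
        }
    return chip_samples, presence


# ---------------------------------------------------------------------------
# expression


def _latent_scale(config: SimConfig) -> float:
    """Scale of the shared tumor latent factor targeting link_rho_target."""
    mu = config.base_fpm * config.base_library_size / 1e6
    sigma2 = (1.0 / mu + config.nb_dispersion) / LN2_SQ  # log2-count noise variance
    rho = min(config.link_rho_target, 0.99)
    if rho <= 0:
        return 0.0
    return math.sqrt(rho / (1.0 - rho) * sigma2)


def plant_expression_truth(
    config: SimConfig,
    genes: Sequence[GeneModel],
    templates: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> None:
    """Choose planted DEEs/DEGs and pair them into enhancer-gene links.

    Links pair each planted DEE with the nearest unused same-direction
    planted DEG within 1 Mb of the enhancer center.
    """
    inter = templates[templates["placement"] == "intergenic"]
    erna_ids = inter["template_id"].tolist()
    gene_ids = [g.gene_id for g in genes]

    n_dee = round(config.planted_dee_frac * len(erna_ids))
    dee_ids = list(rng.choice(erna_ids, size=n_dee, replace=False)) if n_dee else []
    for e in dee_ids:
        truth.dee_direction[str(e)] = "up" if rng.random() < config.frac_dee_up else "down"
    n_deg = round(config.planted_deg_frac * len(gene_ids))
    deg_ids = list(rng.choice(gene_ids, size=n_deg, replace=False)) if n_deg else []
    for g in deg_ids:
        truth.deg_direction[str(g)] = "up" if rng.random() < config.frac_deg_up else "down"

    tmap = inter.set_index("template_id")
    gmap = {g.gene_id: g for g in genes}
    used_genes: set[str] = set()
    for e in sorted(truth.dee_direction):
        row = tmap.loc[e]
        center = (int(row["start"]) + int(row["end"])) // 2
        best = None
        for g_id, g_dir in truth.deg_direction.items():
            if g_id in used_genes or g_dir != truth.dee_direction[e]:
                continue
            g = gmap[g_id]
            if g.chrom != row["chrom"]:
                continue
            dist = abs(g.tss - center)
            if dist <= 1_000_000 and (best is None or dist < best[0]):
                best = (dist, g_id)
        if best is not None:
            used_genes.add(best[1])
            truth.links.append(
                {
                    "enhancer_id": str(e),
                    "gene_id": best[1],
                    "direction": truth.dee_direction[e],
                }
            )


def plant_methylation_truth(
    config: SimConfig,
    genes: Sequence[GeneModel],
    templates: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> None:
    """Choose planted DMRs over genic enhancers (DME candidates with a linked
    planted DEG) and over a fraction of planted intergenic DEEs."""
    genic = templates[templates["placement"] == "genic"]
    # DMEs are defined over reliable (concurrence >= 2) enhancers, so plant
    # them only where the ChIP design put the template in >= 2 samples
    reliable = [
        t for t in genic["template_id"]
        if truth.template_concurrence.get(str(t), 0) >= 2
    ]
    n_dme = min(round(config.planted_dmr_frac * len(genic)), len(reliable))
    dme_templates = (
        list(rng.choice(reliable, size=n_dme, replace=False)) if n_dme else []
    )
    gmap = {g.gene_id: g for g in genes}
    tmap = templates.set_index("template_id")
    used: set[str] = set(l["gene_id"] for l in truth.links)
    for t_id in dme_templates:
        row = tmap.loc[t_id]
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        truth.dmrs.append(
            {
                "chrom": str(row["chrom"]),
                "start": int(row["start"]) - 100,
                "end": int(row["end"]) + 100,
                "direction": direction,
                "target": str(t_id),
                "kind": "genic_enhancer",
            }
        )
        best = None
        for g_id, g_dir in truth.deg_direction.items():
            if g_id in used:
                continue
            g = gmap[g_id]
            if g.chrom != row["chrom"]:
                continue
            dist = max(0, int(row["start"]) - g.tss, g.tss - (int(row["end"]) - 1))
            if dist <= 1_000_000 and (best is None or dist < best[0]):
                best = (dist, g_id, g_dir)
        if best is not None:
            used.add(best[1])
            truth.dme_links.append(
                {
                    "enhancer_id": str(t_id),
                    "gene_id": best[1],
                    "dmr_direction": direction,
                    "deg_direction": best[2],
                }
            )

    # DMRs over a fraction of planted intergenic DEEs (methylation-associated)
    dee_ids = sorted(truth.dee_direction)
    n_meth_dee = round(config.frac_dee_with_dmr * len(dee_ids))
    for t_id in dee_ids[:n_meth_dee]:
        row = tmap.loc[t_id]
        direction = "hypo" if truth.dee_direction[t_id] == "up" else "hyper"
        truth.dmrs.append(
            {
                "chrom": str(row["chrom"]),
                "start": int(row["start"]) - 100,
                "end": int(row["end"]) + 100,
                "direction": direction,
                "target": str(t_id),
                "kind": "intergenic_dee",
            }
        )


def simulate_expression(
    config: SimConfig,
    genes: Sequence[GeneModel],
    templates: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
    latents: dict,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, list[str], list[str]]:
    """Paired NB count matrices for genes and eRNAs, plus library sizes.

    ``latents`` carries the shared per-patient tumor factors: ``link_z``
    keyed by linked enhancer id (shared with the target gene) and
    ``meth_z`` keyed by DME enhancer id (shared between the DME-linked
    gene's expression and the enhancer's methylation).
    """
    n_pairs = config.n_pairs_rnaseq
    patients = [f"pt_{i + 1:03d}" for i in range(n_pairs)]
    columns, col_patients, col_conditions = [], [], []
    for p in patients:
        for cond in ("tumor", "normal"):
            columns.append(f"{p}_{cond}")
            col_patients.append(p)
            col_conditions.append(cond)

    depth = np.empty(len(columns))
    for i, p in enumerate(patients):
        pair_factor = rng.lognormal(0.0, config.pair_depth_sigma)
        for j in range(2):
            depth[2 * i + j] = pair_factor * rng.lognormal(0.0, 0.1)
    library_sizes = pd.Series(
        np.round(config.base_library_size * depth), index=columns, name="library_size"
    )

    inter = templates[templates["placement"] == "intergenic"]
    erna_ids = inter["template_id"].tolist()
    gene_ids = [g.gene_id for g in genes]

    tau = _latent_scale(config)
    link_z = latents["link_z"]
    meth_z = latents["meth_z"]
    linked_genes = {l["gene_id"]: l["enhancer_id"] for l in truth.links}
    dme_linked_genes = {l["gene_id"]: l["enhancer_id"] for l in truth.dme_links}

    def _counts(feature_ids, directions, shared_for) -> pd.DataFrame:
        """NB counts for one feature class."""
        n_feat = len(feature_ids)
        base_fpm = np.exp(rng.normal(math.log(config.base_fpm), 0.8, size=n_feat))
        mat = np.empty((n_feat, len(columns)))
        for fi, fid in enumerate(feature_ids):
            direction = directions.get(fid)
            lfc = 0.0
            if direction is not None:
                lfc = config.effect_lfc if direction == "up" else -config.effect_lfc
            z = shared_for(fid)
            if direction is not None and z is None:
                z = rng.standard_normal(n_pairs)  # independent tumor heterogeneity
            mu_norm = base_fpm[fi] * library_sizes.to_numpy() / 1e6
            log2_shift = np.zeros(len(columns))
            for pi in range(n_pairs):
                t_col = 2 * pi
                log2_shift[t_col] = lfc + (tau * z[pi] if z is not None else 0.0)
            mu = mu_norm * np.power(2.0, log2_shift)
            # NB via gamma-poisson with shape 1/dispersion
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
            mat[fi] = rng.poisson(lam)
        return pd.DataFrame(mat.astype(int), index=list(feature_ids), columns=columns)

    def _gene_shared(fid):
        if fid in linked_genes:
            return link_z[linked_genes[fid]]
        if fid in dme_linked_genes:
            return meth_z[dme_linked_genes[fid]]
        return None

    erna_counts = _counts(
        erna_ids,
        truth.dee_direction,
        lambda fid: link_z.get(fid),
    )
    gene_counts = _counts(gene_ids, truth.deg_direction, _gene_shared)
    return gene_counts, erna_counts, library_sizes, col_patients, col_conditions


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation(
    config: SimConfig,
    genes: Sequence[GeneModel],
    templates: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
    columns: Sequence[str],
    conditions: Sequence[str],
    latents: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG beta matrix with the planted DMRs applied.

    DMR CpGs shift the tumor mean by +/- effect_dmeth; a DME's CpGs
    additionally move with the shared tumor latent factor of its linked
    gene, inducing the methylation-expression correlation. Betas are
    clipped normals.
    """
    cpg_rows: list[tuple[str, int]] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        tsub = templates[templates["chrom"] == chrom]
        positions: set[int] = set()
        for t in tsub.itertuples():
            positions.update(
                range(t.start + 10, t.end, config.cpg_spacing_enhancer)
            )
        positions.update(
            range(10_000, config.chrom_length - 10_000, config.cpg_spacing_background)
        )
        for pos in sorted(positions):
            cpg_rows.append((chrom, pos))
    cpg_positions = pd.DataFrame(cpg_rows, columns=["chrom", "pos"])
    cpg_positions.index = [f"cpg_{i + 1:06d}" for i in range(len(cpg_positions))]
    cpg_positions.index.name = "cpg_id"

    n_pairs = len(columns) // 2
    base = 0.5
    mean = np.full((len(cpg_positions), len(columns)), base)

    dme_link_by_enh = {l["enhancer_id"]: l for l in truth.dme_links}
    meth_z = latents["meth_z"]

    chrom_arr = cpg_positions["chrom"].to_numpy()
    pos_arr = cpg_positions["pos"].to_numpy()
    tumor_cols = np.array([i for i, c in enumerate(conditions) if c == "tumor"])
    for dmr in truth.dmrs:
        mask = (
            (chrom_arr == dmr["chrom"])
            & (pos_arr >= dmr["start"])
            & (pos_arr < dmr["end"])
        )
        if not mask.any():
            continue
        shift = config.effect_dmeth if dmr["direction"] == "hyper" else -config.effect_dmeth
        mean[np.ix_(mask, tumor_cols)] += shift
        link = dme_link_by_enh.get(dmr["target"])
        if link is not None:
            z = meth_z[dmr["target"]]
            # orient the shared latent so the within-tumor coupling carries
            # the same sign as the tumor/normal group separation
            sign = 1.0 if (dmr["direction"] == "hyper") == (
                link["deg_direction"] == "up"
            ) else -1.0
            for pi in range(n_pairs):
                mean[np.ix_(mask, [2 * pi])] += sign * config.meth_link_scale * z[pi]

    beta = mean + rng.normal(0.0, config.beta_noise_sd, size=mean.shape)
    beta = np.clip(beta, 0.0, 1.0)
    beta_df = pd.DataFrame(beta, index=cpg_positions.index, columns=list(columns))
    return cpg_positions, beta_df


# ---------------------------------------------------------------------------
# topology and survival


def simulate_hic_and_survival(
    config: SimConfig,
    genes: Sequence[GeneModel],
    templates: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TAD tiling, loops and a survival cohort driven by the risk score.

    TAD boundaries start on a tad_size grid, then move off any planted link
    chosen for containment; excluded links receive a boundary between
    enhancer center and TSS where the geometry allows. The realised
    containment of every planted link is recorded in the truth.
    """
    gmap = {g.gene_id: g for g in genes}
    tmap = templates.set_index("template_id")

    link_points: dict[str, tuple[str, int, int]] = {}
    for l in truth.links:
        row = tmap.loc[l["enhancer_id"]]
        center = (int(row["start"]) + int(row["end"])) // 2
        tss = gmap[l["gene_id"]].tss
        link_points[f"{l['enhancer_id']}|{l['gene_id']}"] = (
            str(row["chrom"]),
            min(center, tss),
            max(center, tss),
        )

    keys = sorted(link_points)
    contained_keys = set(
        k for k in keys if rng.random() < config.frac_links_in_tad
    )

    tad_rows = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        boundaries = set(range(0, config.chrom_length, config.tad_size))
        boundaries.add(config.chrom_length)
        spans = [
            (lo, hi)
            for k, (c, lo, hi) in link_points.items()
            if c == chrom and k in contained_keys
        ]

        def inside_contained(b: int) -> bool:
            return any(lo < b <= hi for lo, hi in spans)

        # move boundaries off contained link spans
        fixed = {0, config.chrom_length}
        adjusted = set()
        for b in boundaries:
            if b in fixed or not inside_contained(b):
                adjusted.add(b)
                continue
            # push the boundary just past the furthest overlapping span end
            new_b = b
            while inside_contained(new_b) and new_b < config.chrom_length:
                hi = max(h for lo, h in spans if lo < new_b <= h)
                new_b = hi + 1
            if new_b <= config.chrom_length:
                adjusted.add(new_b)
        # give excluded links a boundary inside their span where possible
        for k in keys:
            c, lo, hi = link_points[k]
            if c != chrom or k in contained_keys:
                continue
            if any(lo < b <= hi for b in adjusted):
                continue
            candidate = None
            for b in range(lo + 1, hi + 1, max(1, (hi - lo) // 50 or 1)):
                if not inside_contained(b):
                    candidate = b
                    break
            if candidate is not None:
                adjusted.add(candidate)
        bs = sorted(adjusted)
        for lo, hi in zip(bs[:-1], bs[1:]):
            if hi > lo:
                tad_rows.append((chrom, lo, hi))

    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])

    # realised containment
    for k in keys:
        c, lo, hi = link_points[k]
        sub = tads[tads["chrom"] == c]
        truth.link_in_tad[k] = bool(
            ((sub["start"] <= lo) & (hi < sub["end"])).any()
        )

    loop_rows = []
    for k in keys:
        looped = rng.random() < config.frac_links_looped
        truth.link_looped[k] = looped
        if not looped:
            continue
        c, lo, hi = link_points[k]
        e_id, g_id = k.split("|")
        row = tmap.loc[e_id]
        center = (int(row["start"]) + int(row["end"])) // 2
        tss = gmap[g_id].tss
        loop_rows.append(
            (
                c,
                max(0, center - 5_000),
                center + 5_000,
                c,
                max(0, tss - 5_000),
                tss + 5_000,
            )
        )
    loops = pd.DataFrame(
        loop_rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )

    # survival cohort driven by the six-gene risk score
    from .downstream import DEFAULT_RISK_COEFFICIENTS

    panel = list(DEFAULT_RISK_COEFFICIENTS)
    n_pt = config.n_survival_patients
    pt_ids = [f"surv_{i + 1:03d}" for i in range(n_pt)]
    expr = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(len(panel), n_pt)), index=panel, columns=pt_ids
    )
    coef = np.array([DEFAULT_RISK_COEFFICIENTS[g] for g in panel])
    scores = coef @ expr.to_numpy()
    centered = scores - scores.mean()
    base_hazard = 1.0 / 1_000.0
    if config.hazard_model == "proportional":
        hazard = base_hazard * np.exp(config.risk_effect * centered)
        truth.risk_threshold = None
    else:
        threshold = float(np.quantile(scores, config.risk_threshold_quantile))
        hazard = np.where(
            scores > threshold, base_hazard * config.threshold_hazard_ratio, base_hazard
        )
        truth.risk_threshold = threshold
    times = rng.exponential(1.0 / hazard)
    censor = rng.uniform(500.0, 3_000.0, size=n_pt)
    obs = np.minimum(times, censor)
    event = (times <= censor).astype(int)
    obs = np.maximum(obs, 1.0)
    survival = pd.DataFrame(
        {"time": np.round(obs, 2), "event": event},
        index=pd.Index(pt_ids, name="patient"),
    )
    return tads, loops, survival, expr


# ---------------------------------------------------------------------------
# top-level driver


def simulate_study(config: SimConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate a full synthetic study (deterministic under a fixed seed)."""
    config = config or SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    genes, templates = simulate_genome(config, rng)
    chip_samples, presence = simulate_chip_samples(config, templates, rng)
    truth.template_concurrence = {
        str(t): int(n) for t, n in presence.sum(axis=1).items()
    }
    plant_expression_truth(config, genes, templates, truth, rng)
    plant_methylation_truth(config, genes, templates, truth, rng)
    latents = {
        "link_z": {
            l["enhancer_id"]: rng.standard_normal(config.n_pairs_rnaseq)
            for l in truth.links
        },
        "meth_z": {
            l["enhancer_id"]: rng.standard_normal(config.n_pairs_rnaseq)
            for l in truth.dme_links
        },
    }
    gene_counts, erna_counts, library_sizes, patients, conditions = simulate_expression(
        config, genes, templates, truth, rng, latents
    )
    cpg_positions, beta = simulate_methylation(
        config, genes, templates, truth, rng, gene_counts.columns, conditions, latents
    )
    tads, loops, survival, risk_expr = simulate_hic_and_survival(
        config, genes, templates, truth, rng
    )
    truth.validate(templates, genes)
    return SimulatedStudy(
        config=config,
        genes=genes,
        templates=templates,
        chip_samples=chip_samples,
        presence=presence,
        gene_counts=gene_counts,
        erna_counts=erna_counts,
        library_sizes=library_sizes,
        patients=patients,
        conditions=conditions,
        cpg_positions=cpg_positions,
        beta=beta,
        tads=tads,
        loops=loops,
        survival=survival,
        risk_expression=risk_expr,
        truth=truth,
    )
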