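import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aelink.differential import Dmr
from aelink.intervals import GeneModel, GenomicInterval
from aelink.linking import (
    classify_dme_deg,
    detect_super_enhancer_clusters,
    link_genic_dme,
    link_intergenic,
    link_degree_counts,
    methylation_associated_dees,
    modifier_coexpression,
    spearman,
)


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.arange(1.0, 11.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)

    def test_reversal(self):
        x = np.arange(1.0, 11.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_six_point_tie_matches_rank_formula(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([1.0, 2, 2, 4, 5, 6])
        # hand oracle: Pearson correlation of average ranks
        rx = stats.rankdata(x)
        ry = np.array([1, 2.5, 2.5, 4, 5, 6])
        oracle = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(oracle)

    def test_constant_vector_degenerate(self):
        rho, p = spearman(np.ones(5), np.arange(5.0))
        assert (rho, p) == (0.0, 1.0)


def _expr(rows: dict, samples: int = 20, seed: int = 0):
    rng = np.random.default_rng(seed)
    cols = [f"s{i}" for i in range(samples)]
    data = {}
    for fid, kind in rows.items():
        if isinstance(kind, str) and kind == "noise":
            data[fid] = rng.normal(5, 1, samples)
        else:
            data[fid] = kind  # explicit vector
    return pd.DataFrame(data, index=cols).T


class TestLinkIntergenic:
    def _frames(self, enh_pos, gene_pos, chrom="chr1"):
        enhancers = pd.DataFrame(
            {
                "enhancer_id": [f"e{i}" for i in range(len(enh_pos))],
                "chrom": chrom,
                "start": [p for p in enh_pos],
                "end": [p + 1_000 for p in enh_pos],
                "class": "intergenic",
            }
        )
        genes = [
            GeneModel(f"g{i}", chrom, "+", p, p + 5_000) for i, p in enumerate(gene_pos)
        ]
        return enhancers, genes

    def test_perfectly_correlated_pair_within_window_is_retained(self):
        base = np.arange(20.0)
        erna = _expr({"e0": base})
        gexp = _expr({"g0": base * 2 + 1})
        enhancers, genes = self._frames([100_000], [995_000])  # center 100500, within 1 Mb
        dees = pd.DataFrame({"status": ["activated"]}, index=["e0"])
        degs = pd.DataFrame({"status": ["up"]}, index=["g0"])
        links = link_intergenic(dees, degs, erna, gexp, genes, enhancers)
        assert len(links) == 1
        assert links["rho"].iloc[0] == pytest.approx(1.0)
        assert abs(links["distance"].iloc[0]) <= 1_000_000

    def test_candidate_beyond_one_megabase_never_tested(self):
        base = np.arange(20.0)
        erna = _expr({"e0": base})
        gexp = _expr({"g0": base})
        enhancers, genes = self._frames([100_000], [1_400_000])  # 1.3 Mb away
        dees = pd.DataFrame({"status": ["activated"]}, index=["e0"])
        degs = pd.DataFrame({"status": ["up"]}, index=["g0"])
        links = link_intergenic(dees, degs, erna, gexp, genes, enhancers)
        assert len(links) == 0

    def test_rho_gate_is_strictly_applied(self):
        """A pair whose Spearman rho falls below 0.7 is rejected however
        small its p-value; at or above 0.7 it passes."""
        rng = np.random.default_rng(4)
        base = np.arange(40.0)
        # shuffle a few entries to drag rho below 0.7
        y = base.copy()
        y[:22] = y[:22][::-1]
        rho_low = stats.spearmanr(base, y)[0]
        assert rho_low < 0.7
        erna = _expr({"e0": base}, samples=40)
        gexp = _expr({"g0": y, "g1": base + 1}, samples=40)
        enhancers, genes = self._frames([100_000], [300_000, 500_000])
        dees = pd.DataFrame({"status": ["activated"]}, index=["e0"])
        degs = pd.DataFrame({"status": ["up", "up"]}, index=["g0", "g1"])
        links = link_intergenic(dees, degs, erna, gexp, genes, enhancers)
        assert list(links["gene_id"]) == ["g1"]

    def test_bonferroni_family_is_all_tested_pairs(self):
        """p_adj = min(1, m*p) with m = number of distance-eligible pairs."""
        rng = np.random.default_rng(1)
        n = 12
        base = rng.normal(size=n)
        erna = _expr({"e0": base, "e1": rng.normal(size=n)}, samples=n)
        gexp = _expr(
            {
                "g0": base + rng.normal(0, 0.1, n),
                "g1": rng.normal(size=n),
                "g2": rng.normal(size=n),
            },
            samples=n,
        )
        enhancers, genes = self._frames([100_000, 200_000], [300_000, 400_000, 500_000])
        dees = pd.DataFrame({"status": ["activated", "activated"]}, index=["e0", "e1"])
        degs = pd.DataFrame({"status": ["up"] * 3}, index=["g0", "g1", "g2"])
        links = link_intergenic(
            dees, degs, erna, gexp, genes, enhancers, rho_threshold=-1.0, p_adj_threshold=1.1
        )
        m = 6  # 2 DEEs x 3 DEGs, all within 1 Mb
        for rec in links.itertuples():
            p_hand = stats.spearmanr(
                erna.loc[rec.enhancer_id], gexp.loc[rec.gene_id]
            )[1]
            assert rec.p_adj == pytest.approx(min(1.0, m * p_hand), rel=1e-6)

    def test_links_stay_on_one_chromosome(self):
        base = np.arange(20.0)
        erna = _expr({"e0": base})
        gexp = _expr({"g0": base})
        enhancers = pd.DataFrame(
            {"enhancer_id": ["e0"], "chrom": "chr1", "start": [100_000],
             "end": [101_000], "class": "intergenic"}
        )
        genes = [GeneModel("g0", "chr2", "+", 100_000, 105_000)]
        dees = pd.DataFrame({"status": ["activated"]}, index=["e0"])
        degs = pd.DataFrame({"status": ["up"]}, index=["g0"])
        assert len(link_intergenic(dees, degs, erna, gexp, genes, enhancers)) == 0

    def test_no_shared_samples_is_an_error(self):
        erna = pd.DataFrame(np.ones((1, 4)), index=["e0"], columns=list("abcd"))
        gexp = pd.DataFrame(np.ones((1, 4)), index=["g0"], columns=list("wxyz"))
        enhancers, genes = self._frames([100_000], [300_000])
        dees = pd.DataFrame({"status": ["activated"]}, index=["e0"])
        degs = pd.DataFrame({"status": ["up"]}, index=["g0"])
        with pytest.raises(ValueError, match="share no samples"):
            link_intergenic(dees, degs, erna, gexp, genes, enhancers)

    def test_degree_counts(self):
        links = pd.DataFrame(
            {"enhancer_id": ["e0", "e0", "e1"], "gene_id": ["g0", "g1", "g0"]}
        )
        per_enh, per_gene = link_degree_counts(links)
        assert per_enh["e0"] == 2 and per_gene["g0"] == 2


def _dmr(chrom, start, end, direction="hypo"):
    n = max(5, (end - start) // 60)
    return Dmr(GenomicInterval(chrom, start, end), n, 0.3 if direction == "hyper" else -0.3,
               direction, tuple(range(start, end, 60)))


class TestGenicDme:
    def _setting(self, enh_len=700, dmr_span=(10_200, 10_460), n_cpgs=6, concurrence=3):
        catalog = pd.DataFrame(
            {
                "enhancer_id": ["e0"],
                "chrom": "chr1",
                "start": [10_000],
                "end": [10_000 + enh_len],
                "concurrence": [concurrence],
                "class": ["genic"],
            }
        )
        dmr = _dmr("chr1", *dmr_span)
        step = max(1, (dmr_span[1] - dmr_span[0]) // n_cpgs)
        cpg_positions = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [dmr_span[0] + 5 + i * step for i in range(n_cpgs)],
            },
            index=[f"c{i}" for i in range(n_cpgs)],
        )
        genes = [GeneModel("g0", "chr1", "+", 200_000, 205_000)]
        n = 20
        rng = np.random.default_rng(0)
        grad = np.linspace(0.2, 0.8, n)
        beta = pd.DataFrame(
            np.tile(grad, (n_cpgs, 1)), index=cpg_positions.index,
            columns=[f"s{i}" for i in range(n)],
        )
        gexp = pd.DataFrame(
            {f"s{i}": [-grad[i]] for i in range(n)}, index=["g0"]
        )
        degs = pd.DataFrame({"status": ["up"]}, index=["g0"])
        return catalog, [dmr], cpg_positions, degs, beta, gexp, genes

    def test_candidate_thresholds_pass(self):
        # overlap 260 bp on a 700 bp enhancer: fraction 0.37, 6 CpGs inside
        args = self._setting()
        dmes = link_genic_dme(*args)
        assert len(dmes) == 1
        dme = dmes[0]
        assert dme.overlap_bp == 260
        assert dme.overlap_fraction == pytest.approx(260 / 700)
        assert dme.n_cpgs_in_overlap == 6

    def test_small_overlap_rejected(self):
        args = self._setting(dmr_span=(10_200, 10_350))  # 150 bp overlap
        assert link_genic_dme(*args) == []

    def test_low_overlap_fraction_rejected(self):
        # 210 bp overlap of a 900 bp enhancer -> fraction 0.23 < 0.3
        args = self._setting(enh_len=900, dmr_span=(10_000, 10_210))
        assert link_genic_dme(*args) == []

    def test_too_few_cpgs_rejected(self):
        args = self._setting(n_cpgs=4)
        assert link_genic_dme(*args) == []

    def test_low_concurrence_rejected(self):
        args = self._setting(concurrence=1)
        assert link_genic_dme(*args) == []

    def test_negative_correlation_retained(self):
        """|rho| >= 0.5 is sign-free: a strongly anti-correlated DEG links."""
        args = self._setting()
        dmes = link_genic_dme(*args)
        assert len(dmes) == 1
        assert dmes[0].links["rho"].iloc[0] == pytest.approx(-1.0)

    def test_candidate_without_linked_deg_dropped(self):
        catalog, dmrs, cpg_positions, degs, beta, gexp, genes = self._setting()
        rng = np.random.default_rng(3)
        gexp_noise = pd.DataFrame(
            rng.normal(size=(1, beta.shape[1])), index=["g0"], columns=beta.columns
        )
        assert link_genic_dme(catalog, dmrs, cpg_positions, degs, beta, gexp_noise, genes) == []


class TestClassifyDmeDeg:
    @pytest.mark.parametrize(
        "dmr,deg,expected",
        [
            ("hyper", "up", "HyperUp"),
            ("hyper", "down", "HyperDown"),
            ("hypo", "up", "HypoUp"),
            ("hypo", "down", "HypoDown"),
        ],
    )
    def test_total_over_four_cells(self, dmr, deg, expected):
        assert classify_dme_deg(dmr, deg) == expected

    def test_rejects_unknown_directions(self):
        with pytest.raises(ValueError):
            classify_dme_deg("high", "up")
        with pytest.raises(ValueError):
            classify_dme_deg("hyper", "increased")

    def test_planted_categories_confusion_diagonal(self, default_study, discovery):
        """Planted genic DME links are recovered with the planted category."""
        study, r = default_study, discovery
        recovered = {d.enhancer_id: d for d in r.dmes}
        checked = 0
        for link in study.truth.dme_links:
            dme = recovered.get(link["enhancer_id"])
            if dme is None or link["gene_id"] not in set(dme.links["gene_id"]):
                continue
            deg_dir = study.truth.deg_direction[link["gene_id"]]
            assert classify_dme_deg(dme.dmr_direction, deg_dir) == classify_dme_deg(
                link["dmr_direction"], link["deg_direction"]
            )
            checked += 1
        assert checked >= max(1, len(study.truth.dme_links) // 2)


class TestMethylationAssociatedDees:
    def test_dee_without_dmr_overlap_not_flagged(self):
        dees = pd.DataFrame({"status": ["activated"]}, index=["e0"])
        enhancers = pd.DataFrame(
            {"enhancer_id": ["e0"], "chrom": "chr1", "start": [1_000], "end": [2_000]}
        )
        dmrs = [_dmr("chr1", 50_000, 50_400)]
        beta = pd.DataFrame(np.full((1, 8), 0.5), index=["c0"], columns=[f"s{i}" for i in range(8)])
        cpg_positions = pd.DataFrame({"chrom": ["chr1"], "pos": [1_500]}, index=["c0"])
        erna = pd.DataFrame(np.ones((1, 8)), index=["e0"], columns=beta.columns)
        flagged, fractions = methylation_associated_dees(
            dees, enhancers, dmrs, beta, cpg_positions, erna
        )
        assert len(flagged) == 0
        assert fractions["frac_dees"] == 0.0

    def test_flagged_subset_and_fractions(self, default_study, discovery):
        study, r = default_study, discovery
        flagged, fractions = methylation_associated_dees(
            r.dees, r.catalog, r.dmrs, study.beta, study.cpg_positions,
            r.erna_log, links=r.links,
        )
        assert set(flagged["enhancer_id"]) <= set(r.dees.index)
        for v in fractions.values():
            assert 0.0 <= v <= 1.0
        # planted methylation-associated DEEs carry a DMR by construction
        planted_meth = {
            d["target"] for d in study.truth.dmrs if d["kind"] == "intergenic_dee"
        }
        if planted_meth and len(flagged):
            assert set(flagged["enhancer_id"]) <= set(r.dees.index)


class TestModifierCoexpression:
    def _mats(self):
        rng = np.random.default_rng(0)
        n = 16
        cols = [f"s{i}" for i in range(n)]
        base = np.linspace(0, 1, n)
        erna = pd.DataFrame([base, rng.normal(size=n)], index=["e0", "e1"], columns=cols)
        gexp = pd.DataFrame(
            [base, base * 3 + 2, rng.normal(size=n)],
            index=["mod", "g0", "g1"],
            columns=cols,
        )
        dees = pd.DataFrame({"status": ["activated", "activated"]}, index=["e0", "e1"])
        links = pd.DataFrame({"enhancer_id": ["e0"], "gene_id": ["g0"]})
        return dees, links, erna, gexp

    def test_identical_expression_counted(self):
        dees, links, erna, gexp = self._mats()
        out = modifier_coexpression(["mod"], dees, links, erna, gexp)
        assert out["frac_dee_degs"].iloc[0] == 1.0  # g0 is a monotone copy
        assert out["frac_dees"].iloc[0] >= 0.5  # e0 is a copy; e1 noise

    def test_missing_modifier_errors_by_name(self):
        dees, links, erna, gexp = self._mats()
        with pytest.raises(ValueError, match="EZH2"):
            modifier_coexpression(["EZH2"], dees, links, erna, gexp)

    def test_noise_modifier_flags_nothing(self):
        dees, links, erna, gexp = self._mats()
        rng = np.random.default_rng(9)
        gexp.loc["mod"] = rng.normal(size=gexp.shape[1])
        out = modifier_coexpression(["mod"], dees, links, erna, gexp)
        assert out["frac_dees"].iloc[0] == 0.0

    def test_result_invariant_to_gene_order(self):
        dees, links, erna, gexp = self._mats()
        a = modifier_coexpression(["mod"], dees, links, erna, gexp)
        b = modifier_coexpression(["mod"], dees, links, erna, gexp.iloc[::-1])
        pd.testing.assert_frame_equal(a, b)


def _cluster_inputs(n_dees, span_start, spacing, genes_per, chrom="chr16", status="repressed"):
    enh = pd.DataFrame(
        {
            "enhancer_id": [f"e{i}" for i in range(n_dees)],
            "chrom": chrom,
            "start": [span_start + i * spacing for i in range(n_dees)],
            "end": [span_start + i * spacing + 1_000 for i in range(n_dees)],
        }
    )
    dees = pd.DataFrame({"status": [status] * n_dees}, index=enh["enhancer_id"])
    rows = []
    for e in enh["enhancer_id"]:
        for g in genes_per:
            rows.append({"enhancer_id": e, "gene_id": g})
    return pd.DataFrame(rows), dees, enh


class TestSuperEnhancerClusters:
    def test_table2_geometry_single_cluster(self):
        """35 repressed DEEs across ~344 kb, each linked to the same 12
        genes, chain into exactly one reported cluster."""
        genes = [f"MT1{c}" for c in "ABCDEFGHIJKL"]
        links, dees, enh = _cluster_inputs(35, 56_520_399, 9_900, genes)
        clusters = detect_super_enhancer_clusters(links, dees, enh)
        assert len(clusters) == 1
        c = clusters[0]
        assert len(c.member_ids) == 35
        assert len(c.shared_genes) == 12
        assert c.direction == "repressed"
        assert c.span.chrom == "chr16"
        assert (c.span.end - c.span.start) == pytest.approx(344_000, rel=0.05)
        # strict mode: every member linked to every gene here, so identical
        strict = detect_super_enhancer_clusters(links, dees, enh, strict=True)
        assert len(strict) == 1 and len(strict[0].shared_genes) == 12

    def test_four_members_not_reported(self):
        links, dees, enh = _cluster_inputs(4, 1_000_000, 9_900, [f"g{i}" for i in range(6)])
        assert detect_super_enhancer_clusters(links, dees, enh) == []

    def test_large_gap_splits_chains(self):
        genes = [f"g{i}" for i in range(6)]
        links1, dees1, enh1 = _cluster_inputs(6, 1_000_000, 9_900, genes)
        links2, dees2, enh2 = _cluster_inputs(6, 1_500_000, 9_900, genes)
        enh2["enhancer_id"] = [f"x{i}" for i in range(6)]
        links2["enhancer_id"] = links2["enhancer_id"].str.replace("e", "x")
        dees2.index = enh2["enhancer_id"]
        links = pd.concat([links1, links2], ignore_index=True)
        dees = pd.concat([dees1, dees2])
        enh = pd.concat([enh1, enh2], ignore_index=True)
        clusters = detect_super_enhancer_clusters(links, dees, enh)
        # 200+ kb between the two blocks: two separate clusters
        assert len(clusters) == 2

    def test_shared_gene_requirement(self):
        # below the >= 5 distinct shared genes threshold
        links, dees, enh = _cluster_inputs(6, 1_000_000, 9_900, ["g0", "g1", "g2", "g3"])
        assert detect_super_enhancer_clusters(links, dees, enh) == []

    def test_direction_partition(self):
        genes = [f"g{i}" for i in range(6)]
        links, dees, enh = _cluster_inputs(10, 1_000_000, 9_900, genes)
        dees.iloc[5:, dees.columns.get_loc("status")] = "activated"
        clusters = detect_super_enhancer_clusters(links, dees, enh)
        assert sorted(c.direction for c in clusters) == ["activated", "repressed"]
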