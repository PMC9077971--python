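"""CTCF 3DR, CNE profiles, TAD conservation scores, and co-expression
stratification."""

import numpy as np
import pandas as pd
import pytest

from archcompare import conservation
from archcompare.conservation import (
    cne_profile,
    coexpression_by_distance,
    compute_3dr,
    tad_conservation_scores,
)
from archcompare.tads import TadSet


def motif_df(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def simple_tads(domains, res=20_000):
    bounds = [
        (c1, e1, s2)
        for (c1, _, e1), (c2, s2, _) in zip(domains, domains[1:])
        if c1 == c2
    ]
    return TadSet(resolution=res, domains=list(domains), boundaries=bounds, unorganized=[])


class TestCompute3DR:
    def toy(self):
        return motif_df(
            [
                ("c", 0, 19, "a", 1.0, "+"),
                ("c", 10, 29, "b", 1.0, "-"),
                ("c", 20, 39, "c", 1.0, "+"),
                ("c", 25, 44, "d", 1.0, "-"),
            ]
        )

    def test_brute_force_toy(self):
        """Pairs: (+,-) d=10, (-,+) d=10, (+,-) d=5 -> 3DR = 7.5/10."""
        out = compute_3dr(self.toy(), score_quantile=0.0)
        assert sorted(out.convergent) == [5, 10]
        assert list(out.divergent) == [10]
        assert out.ratio_3dr == pytest.approx(0.75)

    def test_alternating_equal_spacing_is_one(self):
        rows = [("c", 100 * i, 100 * i + 19, f"m{i}", 1.0, "+-"[i % 2]) for i in range(20)]
        out = compute_3dr(motif_df(rows), score_quantile=0.0)
        assert out.ratio_3dr == pytest.approx(1.0)

    def test_translation_and_scaling_invariance(self):
        base = self.toy()
        shifted = base.assign(start=base.start + 10_000, end=base.end + 10_000)
        scaled = base.assign(start=base.start * 7, end=base.end * 7)
        r0 = compute_3dr(base, score_quantile=0.0).ratio_3dr
        assert compute_3dr(shifted, score_quantile=0.0).ratio_3dr == pytest.approx(r0)
        assert compute_3dr(scaled, score_quantile=0.0).ratio_3dr == pytest.approx(r0)

    def test_chromosome_relabeling_invariance(self):
        base = self.toy()
        relabeled = base.assign(chrom="chr9")
        assert compute_3dr(relabeled, score_quantile=0.0).ratio_3dr == pytest.approx(
            compute_3dr(base, score_quantile=0.0).ratio_3dr
        )

    def test_score_quantile_drops_weak_motifs(self):
        rows = [
            ("c", 0, 19, "a", 0.1, "+"),
            ("c", 50, 69, "b", 0.9, "+"),
            ("c", 100, 119, "d", 0.9, "-"),
            ("c", 150, 169, "e", 0.9, "-"),
            ("c", 200, 219, "f", 0.9, "+"),
        ]
        out = compute_3dr(motif_df(rows), score_quantile=0.5)
        # the 0.1-score motif is gone; surviving pairs start at position 50
        assert min(out.convergent.min(), out.divergent.min()) == 50

    def test_missing_orientation_rejected(self):
        rows = [("c", 0, 19, "a", 1.0, "+"), ("c", 10, 29, "b", 1.0, "+")]
        with pytest.raises(ValueError):
            compute_3dr(motif_df(rows), score_quantile=0.0)

    def test_border_mode_exceeds_genome_wide(self, small_world, tracks, called_tads):
        """Planted convergent anchors at TAD borders: restricted 3DR >
        genome-wide 3DR > 1."""
        genome_wide = compute_3dr(tracks.motifs, score_quantile=0.7)
        border = compute_3dr(
            tracks.motifs,
            regions=conservation.tad_border_regions(called_tads),
            score_quantile=0.7,
        )
        assert border.ratio_3dr > genome_wide.ratio_3dr > 1.0


class TestCneProfile:
    def cnes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])

    def test_single_cne_in_exactly_one_interior_bin(self):
        """TAD [0, 2000) with a CNE at [100, 350): its midpoint 225 lands in
        interior bin 2 of 20 (profile index 12), and nowhere else."""
        t = simple_tads([("c", 0, 2000)])
        out = cne_profile(t, self.cnes([("c", 100, 350, 0.99)]), min_len=200)
        assert out.profile.sum() == pytest.approx(1.0)
        assert out.profile[12] == pytest.approx(1.0)

    def test_zero_cnes_all_zero(self):
        t = simple_tads([("c", 0, 2000)])
        out = cne_profile(t, self.cnes([]))
        assert (out.profile == 0).all()

    def test_score_and_length_filters(self):
        t = simple_tads([("c", 0, 2000)])
        rows = [
            ("c", 100, 350, 0.90),  # score too low
            ("c", 100, 290, 0.99),  # length 190 <= 200
            ("c", 500, 800, 0.99),  # kept
        ]
        out = cne_profile(t, self.cnes(rows))
        assert out.profile.sum() == pytest.approx(1.0)

    def test_interior_enriched_when_planted_inside(self):
        rng = np.random.default_rng(0)
        doms = [("c", i * 1_000_000 + 40_000, (i + 1) * 1_000_000 - 40_000) for i in range(5)]
        t = simple_tads(doms)
        rows = []
        for c, s, e in doms:
            for p in rng.integers(s, e - 400, 40):
                rows.append((c, int(p), int(p) + 300, 0.99))
        out = cne_profile(t, self.cnes(rows))
        assert out.interior_mean > out.flank_mean

    def test_count_conservation(self, tracks, called_tads):
        """Binned counts sum to the number of (filtered) CNE placements in
        the enlarged-TAD windows."""
        out = cne_profile(called_tads, tracks.cnes)
        assert out.profile.sum() * out.n_tads == pytest.approx(
            round(out.profile.sum() * out.n_tads)
        )


def ortho_table(entries):
    return pd.DataFrame(
        entries, columns=["group", "species", "gene", "chrom", "start", "end", "strand"]
    )


class TestTadConservationScores:
    def two_species(self, target_positions):
        ref = [
            ("og1", "A", "A_g1", "c", 100, 200, "+"),
            ("og2", "A", "A_g2", "c", 300, 400, "+"),
            ("og3", "A", "A_g3", "c", 1200, 1300, "+"),
        ]
        tgt = [
            ("og1", "B", "B_g1", "c", target_positions[0], target_positions[0] + 100, "+"),
            ("og2", "B", "B_g2", "c", target_positions[1], target_positions[1] + 100, "+"),
            ("og3", "B", "B_g3", "c", target_positions[2], target_positions[2] + 100, "+"),
        ]
        return ortho_table(ref + tgt)

    def test_hand_count_half(self):
        """2 TADs, genes A,B in TAD1 and C in TAD2, pairing preserved in the
        target: intra score 50% (1 of 2 gene-bearing TADs)."""
        ref_tads = simple_tads([("c", 0, 1000), ("c", 1000, 2000)])
        tgt_tads = simple_tads([("c", 0, 1000), ("c", 1000, 2000)])
        out = tad_conservation_scores(
            ref_tads, tgt_tads, self.two_species([100, 300, 1200]), "A", "B"
        )
        assert out.intra_score == pytest.approx(50.0)

    def test_identity_flags_multi_gene_tads(self):
        """With identical orders and TADs every TAD holding >= 2 genes is
        intra-conserved."""
        ref_tads = simple_tads([("c", 0, 1000), ("c", 1000, 2000)])
        out = tad_conservation_scores(
            ref_tads, ref_tads, self.two_species([100, 300, 1200]), "A", "B"
        )
        assert out.per_tad_intra[0]
        assert not out.per_tad_intra[1]  # single-gene TAD cannot hold a pair

    def test_broken_target_pairing_drops_score(self):
        ref_tads = simple_tads([("c", 0, 1000), ("c", 1000, 2000)])
        tgt_tads = simple_tads([("c", 0, 350), ("c", 350, 2000)])
        out = tad_conservation_scores(
            ref_tads, tgt_tads, self.two_species([100, 400, 1200]), "A", "B"
        )
        assert out.intra_score == 0.0

    def test_shuffle_monotonicity_on_world(self, small_world):
        """Progressively shuffling the target TAD frame never increases the
        intra score (directional: intra conservation needs shared domains)."""
        rng = np.random.default_rng(0)
        ref = simple_tads(small_world.planted.tad_intervals["sp1"])
        tgt_true = simple_tads(small_world.planted.tad_intervals["sp2"])
        # shuffled target: permute domain order per chromosome, breaking
        # gene-domain co-residence
        doms = list(tgt_true.domains)
        sizes = [(e - s) for _, s, e in doms]
        rng.shuffle(sizes)
        shuffled = []
        cursor: dict[str, int] = {}
        for (c, _, _), L in zip(doms, sizes):
            start = cursor.get(c, 0)
            shuffled.append((c, start, start + L))
            cursor[c] = start + L + 40_000
        tgt_shuf = simple_tads(shuffled)
        ot = small_world.orthologs.replace({"species": {"sp1": "A", "sp2": "B"}})
        true_score = tad_conservation_scores(ref, tgt_true, ot, "A", "B").intra_score
        shuf_score = tad_conservation_scores(ref, tgt_shuf, ot, "A", "B").intra_score
        assert true_score >= shuf_score

    def test_intra_exceeds_inter_on_conserved_world(self, small_world):
        ref = simple_tads(small_world.planted.tad_intervals["sp1"])
        tgt = simple_tads(small_world.planted.tad_intervals["sp2"])
        ot = small_world.orthologs.replace({"species": {"sp1": "A", "sp2": "B"}})
        out = tad_conservation_scores(ref, tgt, ot, "A", "B")
        assert 0 <= out.inter_score <= 100
        assert 0 <= out.intra_score <= 100


class TestCoexpressionByDistance:
    def make_inputs(self, r=0.95, n_rep=3, seed=0):
        rng = np.random.default_rng(seed)
        n_genes = 60
        genes = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n_genes)],
                "chrom": "c",
                "start": np.arange(n_genes) * 50_000,
                "end": np.arange(n_genes) * 50_000 + 10_000,
                "strand": "+",
            }
        )
        # TADs of 10 genes each
        doms = [("c", i * 500_000, (i + 1) * 500_000) for i in range(6)]
        t = simple_tads(doms)
        factors = rng.normal(0, 1, (6, n_rep))
        vals = np.empty((n_genes, n_rep))
        for i in range(n_genes):
            tad = i // 10
            vals[i] = np.sqrt(r) * factors[tad] + np.sqrt(1 - r) * rng.normal(0, 1, n_rep)
        expr = pd.DataFrame(2.0 ** vals, index=genes.gene)
        return expr, genes, t

    def test_same_tad_fraction_exceeds_background(self):
        expr, genes, t = self.make_inputs()
        out = coexpression_by_distance(expr, genes, t, r_cutoff=0.9, max_d=2)
        for d in out.index:
            assert out.loc[d, "frac_same_tad"] >= out.loc[d, "frac_all"]

    def test_boundary_straddling_pair_not_same_tad(self):
        expr, genes, t = self.make_inputs()
        out = coexpression_by_distance(expr, genes, t, r_cutoff=0.9, max_d=0)
        # 6 TADs x 9 within-TAD adjacent pairs; 5 straddling pairs excluded
        assert out.loc[0, "n_same_tad"] == 54
        assert out.loc[0, "n_all"] == 59

    def test_too_few_replicates_rejected(self):
        expr, genes, t = self.make_inputs(n_rep=2)
        with pytest.raises(ValueError, match="replicate"):
            coexpression_by_distance(expr, genes, t)

    def test_independent_expression_matches_null(self):
        """With independent expression both fractions approach the analytic
        null P(|r| field > 0.9 ...) for n=5 replicates (one-sided)."""
        from scipy.stats import beta

        expr, genes, t = self.make_inputs(r=0.0, n_rep=5, seed=3)
        out = coexpression_by_distance(expr, genes, t, r_cutoff=0.9, max_d=0)
        n = 5
        # density of sample r under independence: Beta-based closed form
        null_p = 1 - beta.cdf((0.9 + 1) / 2, (n - 2) / 2, (n - 2) / 2)
        assert out.loc[0, "frac_all"] == pytest.approx(null_p, abs=0.08)
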