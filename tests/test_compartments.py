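"""A/B compartment calling, AB index, insulation, state grouping, and
cross-species/tissue consistency."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import archcompare as ac
from archcompare import compartments, phylo
from archcompare.compartments import (
    ab_index,
    call_compartments,
    cluster_states,
    cross_tissue_consistency,
    group_summary,
    insulation_score,
    similarity_vs_divergence,
)
from archcompare.matrix import ContactMatrix, make_bin_table


def dense_matrix(x, resolution=100_000, chrom="chrA"):
    bins = make_bin_table({chrom: x.shape[0] * resolution}, resolution)
    return ContactMatrix(resolution=resolution, bins=bins, counts=sp.csr_matrix(x))


class TestCallCompartments:
    def test_planted_checkerboard_recovered(self, small_world, hic100):
        """Gene density is elevated in planted-A; at least 95% of usable
        bins get the planted sign."""
        spn = "sp1"
        gd = {
            c: (small_world.planted.compartment_sign[spn][c] > 0).astype(float)
            for c in small_world.genomes[spn]
        }
        track = call_compartments(hic100, gd)
        agree = []
        for c in small_world.genomes[spn]:
            lab = track.ab_label[c]
            sign = small_world.planted.compartment_sign[spn][c][: len(lab)]
            ok = lab != ""
            agree.append(((lab[ok] == "A") == (sign[ok] > 0)).mean())
        assert np.mean(agree) >= 0.95

    def test_orientation_invariant_to_matrix_sign_structure(self, hic100, small_world):
        """Calling twice is deterministic, and A is always the gene-dense
        orientation regardless of the eigenvector's arbitrary sign."""
        spn = "sp1"
        gd = {
            c: (small_world.planted.compartment_sign[spn][c] > 0).astype(float)
            for c in small_world.genomes[spn]
        }
        t1 = call_compartments(hic100, gd)
        t2 = call_compartments(hic100, gd)
        for c in t1.pc1:
            assert np.array_equal(t1.ab_label[c], t2.ab_label[c])
            m = np.isfinite(t1.pc1[c])
            from scipy.stats import spearmanr

            assert spearmanr(t1.pc1[c][m], gd[c][: len(m)][m]).statistic > 0

    def test_uniform_matrix_low_confidence(self):
        x = np.ones((30, 30))
        track = call_compartments(dense_matrix(x), {"chrA": np.ones(30)})
        assert track.low_confidence

    def test_small_chromosome_skipped(self):
        x = np.ones((5, 5))
        with pytest.raises(ValueError):
            call_compartments(dense_matrix(x), {"chrA": np.ones(5)})


class TestAbIndex:
    def toy(self):
        # 20-kb matrix over a chromosome whose 100-kb labels alternate A,B
        n = 10
        x = np.zeros((n, n))
        labels = {"chrA": np.array(["A"] * 1 + ["B"] * 1, dtype=object)}
        return x, labels

    def test_pure_a_contact_is_plus_one(self):
        x, labels = self.toy()
        x[0, 1] = x[1, 0] = 5.0  # bin 0 contacts only A-labeled fine bins
        m = dense_matrix(x, resolution=20_000)
        vals = ab_index(m, labels)["chrA"]
        assert vals[0] == pytest.approx(1.0)

    def test_balanced_contact_is_zero(self):
        x, labels = self.toy()
        # bin 0 contacts one A bin (1) and one B bin (6) with weights making
        # the class means equal: A mean over 5 bins, B mean over 5 bins
        x[0, 1] = x[1, 0] = 5.0
        x[0, 6] = x[6, 0] = 5.0
        m = dense_matrix(x, resolution=20_000)
        vals = ab_index(m, labels)["chrA"]
        assert vals[0] == pytest.approx(0.0)

    def test_hand_formula(self):
        """4-bin toy: values match (meanA - meanB)/(meanA + meanB)."""
        n = 10
        x = np.zeros((n, n))
        x[0, 2] = x[2, 0] = 3.0  # A side (bins 0-4)
        x[0, 7] = x[7, 0] = 1.0  # B side (bins 5-9)
        m = dense_matrix(x, resolution=20_000)
        vals = ab_index(m, {"chrA": np.array(["A", "B"], dtype=object)})["chrA"]
        mean_a = 3.0 / 5
        mean_b = 1.0 / 5
        assert vals[0] == pytest.approx((mean_a - mean_b) / (mean_a + mean_b))

    def test_bounded_and_antisymmetric(self, hic20, small_world):
        labels = {
            c: np.where(small_world.planted.compartment_sign["sp1"][c] > 0, "A", "B").astype(object)
            for c in small_world.genomes["sp1"]
        }
        swapped = {c: np.where(v == "A", "B", "A").astype(object) for c, v in labels.items()}
        vals = ab_index(hic20, labels)
        flipped = ab_index(hic20, swapped)
        for c in vals:
            v = vals[c]
            ok = np.isfinite(v)
            assert (np.abs(v[ok]) <= 1 + 1e-9).all()
            assert np.allclose(v[ok], -flipped[c][ok])

    def test_no_contact_masked(self):
        x, labels = self.toy()
        m = dense_matrix(x, resolution=20_000)
        vals = ab_index(m, labels)["chrA"]
        assert np.isnan(vals[3])


class TestInsulationScore:
    def test_uniform_matrix_flat(self):
        x = np.ones((60, 60))
        m = dense_matrix(x, resolution=20_000)
        vals = insulation_score(m, window=100_000)["chrA"]
        ok = np.isfinite(vals)
        assert np.allclose(vals[ok], 0.0, atol=1e-9)

    def test_insulated_blocks_dip_at_boundary(self):
        x = np.ones((60, 60)) * 0.2
        x[:30, :30] = 1.0
        x[30:, 30:] = 1.0
        m = dense_matrix(x, resolution=20_000)
        vals = insulation_score(m, window=100_000)["chrA"]
        ok = np.isfinite(vals)
        assert np.nanargmin(vals) in (29, 30)

    def test_correlates_with_ab_on_planted_world(self, hic20, small_world):
        """Compartment A regions carry more local structure in the planted
        world; IS and AB sign co-occur positively."""
        ins = insulation_score(hic20)
        labels = {
            c: np.where(small_world.planted.compartment_sign["sp1"][c] > 0, "A", "B").astype(object)
            for c in small_world.genomes["sp1"]
        }
        abi = ab_index(hic20, labels)
        xs, ys = [], []
        for c in ins:
            v, a = ins[c], abi[c]
            ok = np.isfinite(v) & np.isfinite(a)
            xs.append(v[ok])
            ys.append(a[ok])
        r = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
        assert np.isfinite(r)


class TestClusterStates:
    def test_all_positive_single_group(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.uniform(0.5, 1.0, (200, 4)))
        a = cluster_states(x, k=3, seed=0)
        assert set(a.group_labels.values()) == {"CA"}
        assert a.group_pct["CA"] == pytest.approx(100.0)

    def test_cosine_just_below_threshold_splits(self):
        """Two clusters of vectors whose means have cosine similarity just
        under 0.85 stay in separate groups (strict >=)."""
        theta = np.arccos(0.84)
        m1 = np.array([1.0, 0.0, 0.0])
        m2 = np.array([np.cos(theta), np.sin(theta), 0.0])
        m3 = -m1
        rng = np.random.default_rng(1)
        rows = np.vstack(
            [m + rng.normal(0, 1e-3, (50, 3)) for m in (m1, m2, m3)]
        )
        a = cluster_states(pd.DataFrame(rows), k=3, seed=0, cos_threshold=0.85)
        g1 = a.state_group[a.states[0]]
        g2 = a.state_group[a.states[60]]
        assert g1 != g2

    def test_cosine_above_threshold_merges(self):
        theta = np.arccos(0.95)
        m1 = np.array([1.0, 0.0, 0.0])
        m2 = np.array([np.cos(theta), np.sin(theta), 0.0])
        m3 = -m1
        rng = np.random.default_rng(1)
        rows = np.vstack([m + rng.normal(0, 1e-3, (50, 3)) for m in (m1, m2, m3)])
        a = cluster_states(pd.DataFrame(rows), k=3, seed=0, cos_threshold=0.85)
        assert a.state_group[a.states[0]] == a.state_group[a.states[60]]

    def test_planted_group_percentages_recovered(self):
        """CA/CB/NC shares recovered within 5 points of the planted aligned
        sign pattern."""
        w = ac.make_world(n_species=5, seed=2, conserved_fraction=0.7)
        al = w.planted.aligned_signs
        rng = np.random.default_rng(3)
        x = al.to_numpy(float) * np.abs(rng.normal(0.5, 0.15, al.shape))
        x += rng.normal(0, 0.05, al.shape)
        a = cluster_states(pd.DataFrame(x, columns=al.columns), k=12, seed=0, bin_mb=0.1)
        planted_ca = (al.to_numpy() > 0).all(axis=1).mean() * 100
        planted_cb = (al.to_numpy() < 0).all(axis=1).mean() * 100
        planted_nc = 100 - planted_ca - planted_cb
        assert a.group_pct["CA"] == pytest.approx(planted_ca, abs=5)
        assert a.group_pct["CB"] == pytest.approx(planted_cb, abs=5)
        assert a.group_pct["NC"] == pytest.approx(planted_nc, abs=5)

    def test_deterministic_and_conserves_span(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(0, 1, (300, 4)))
        a = cluster_states(x, k=5, seed=7, bin_mb=0.02)
        b = cluster_states(x, k=5, seed=7, bin_mb=0.02)
        assert np.array_equal(a.states, b.states)
        assert sum(a.group_mb.values()) == pytest.approx(300 * 0.02)

    def test_k_larger_than_distinct_bins_rejected(self):
        x = pd.DataFrame(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            cluster_states(x, k=5, seed=0)


class TestGroupSummary:
    def test_printed_percentages(self):
        """Conserved-compartment shares of the 849.74 Mb aligned span:
        272.99 Mb -> 32.12% (within one rounding step: the printed Mb are
        themselves rounded), 243.73 -> 28.68%, 184.80 -> 21.75%."""
        pct = group_summary({"CA": 272.99, "NC": 243.73, "CHI": 184.80}, 849.74)
        assert pct["CA"] == pytest.approx(32.12, abs=0.015)
        assert pct["NC"] == 28.68
        assert pct["CHI"] == 21.75

    def test_everything_in_one_group(self):
        assert group_summary({"CA": 50.0}, 50.0)["CA"] == 100.00

    def test_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            group_summary({"CA": 60.0}, 50.0)


class TestCrossTissueConsistency:
    def test_identical_track_full_retention(self):
        labels = np.array(["CA"] * 50 + ["CB"] * 50)
        track = np.r_[np.ones(50), -np.ones(50)]
        out = cross_tissue_consistency(labels, [track], n_perm=20, seed=0)
        assert out["observed"][0] == pytest.approx(1.0)

    def test_shuffled_track_matches_base_rate(self):
        rng = np.random.default_rng(5)
        labels = np.array(["CA"] * 200 + ["CB"] * 200 + ["NC"] * 100)
        track = rng.permutation(np.r_[np.ones(250), -np.ones(250)])
        out = cross_tissue_consistency(labels, [track], n_perm=50, seed=0)
        # base rate: half the labeled bins agree by chance
        assert out["observed"][0] == pytest.approx(0.5, abs=0.1)
        assert out["control_mean"] == pytest.approx(0.5, abs=0.05)

    def test_shared_structure_beats_control(self):
        """Tissues sharing 80% of compartment signs retain conserved states
        significantly more often than shuffled controls."""
        rng = np.random.default_rng(6)
        ref = np.where(rng.random(500) < 0.5, 1.0, -1.0)
        labels = np.where(ref > 0, "CA", "CB")
        tracks = []
        for _ in range(20):
            flip = rng.random(500) < 0.2
            tracks.append(np.where(flip, -ref, ref) + rng.normal(0, 0.1, 500))
        out = cross_tissue_consistency(labels, tracks, n_perm=30, seed=1)
        assert np.mean(out["observed"]) > out["control_mean"]
        assert out["p_value"] < 0.05

    def test_low_permutations_warn(self):
        labels = np.array(["CA", "CB"] * 10)
        with pytest.warns(UserWarning):
            cross_tissue_consistency(labels, [np.ones(20)], n_perm=5, seed=0)


class TestSimilarityVsDivergence:
    def tree3(self):
        return phylo.from_newick("((a:10,b:10):90,c:100);")

    def test_identical_tracks_na(self):
        x = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]})
        out = similarity_vs_divergence(x, self.tree3())
        assert np.isnan(out["pearson_r"])

    def test_hand_cosines(self):
        x = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [1.0, 1.0], "c": [0.0, 1.0]}
        )
        out = similarity_vs_divergence(x, self.tree3())
        assert out["similarity"].loc["a", "b"] == pytest.approx(1 / np.sqrt(2))
        assert out["similarity"].loc["a", "c"] == pytest.approx(0.0)
        assert out["similarity"].loc["b", "c"] == pytest.approx(1 / np.sqrt(2))

    def test_planted_drift_gives_negative_correlation(self):
        """Sign test over seeds: similarity of evolved compartment tracks
        falls with divergence time."""
        neg = 0
        for seed in range(5):
            w = ac.make_world(n_species=6, seed=40 + seed, conserved_fraction=0.6)
            rng = np.random.default_rng(seed)
            al = w.planted.aligned_signs
            x = al.to_numpy(float) + rng.normal(0, 0.3, al.shape)
            out = similarity_vs_divergence(
                pd.DataFrame(x, columns=al.columns), w.phylogeny
            )
            neg += out["pearson_r"] < 0
        assert neg >= 4
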