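"""Inter-chromosomal significance testing, BIN networks, randomized
controls, and network statistics."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import archcompare as ac
from archcompare import transnet
from archcompare.matrix import ContactMatrix, make_bin_table


def exact_binomial_tail(k, n, p):
    """Log-space summation oracle for P(X >= k)."""
    if k <= 0:
        return 1.0
    logs = []
    for i in range(k, n + 1):
        logs.append(
            math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
            + i * math.log(p) + (n - i) * math.log1p(-p)
        )
    m = max(logs)
    return math.exp(m) * sum(math.exp(x - m) for x in logs)


class TestBinomialTail:
    def test_zero_observation_gives_one(self):
        assert transnet.binomial_upper_tail(0, 100, 0.01) == 1.0

    def test_worked_example(self):
        assert transnet.binomial_upper_tail(3, 100, 0.01) == pytest.approx(
            0.0794, abs=2e-4
        )

    @pytest.mark.parametrize("n,p,k", [(10, 0.3, 4), (500, 0.01, 9), (1000, 0.002, 5)])
    def test_matches_exact_summation(self, n, p, k):
        assert transnet.binomial_upper_tail(k, n, p) == pytest.approx(
            exact_binomial_tail(k, n, p), abs=1e-12
        )


@pytest.fixture(scope="module")
def trans_tests(small_world):
    m500 = ac.simulate_hic(small_world, "sp1", 500_000, 300_000, seed=41)
    return transnet.trans_significance(m500), m500


class TestTransSignificance:
    def test_qnorm_identity_for_two_longest(self, trans_tests):
        """When the tested pair involves the two longest chromosomes the
        length-normalization factor is exactly 1."""
        tests, m = trans_tests
        sizes = m.chromsizes
        longest = sorted(sizes, key=sizes.get)[-2:]
        sub = tests[tests.chromA.isin(longest) & tests.chromB.isin(longest)]
        assert len(sub) > 0
        assert np.allclose(sub.q_norm, sub.q_value)

    def test_other_pairs_shrink_q(self, trans_tests):
        tests, m = trans_tests
        sizes = m.chromsizes
        shortest = min(sizes, key=sizes.get)
        longest = max(sizes, key=sizes.get)
        if shortest != longest:
            sub = tests[(tests.chromA == shortest) | (tests.chromB == shortest)]
            assert (sub.q_norm <= sub.q_value + 1e-12).all()

    def test_bh_monotone_within_family(self, trans_tests):
        tests, _ = trans_tests
        for _, fam in tests.groupby(["chromA", "chromB"]):
            s = fam.sort_values("p_value")
            assert (np.diff(s.q_value) >= -1e-12).all()

    def test_zero_count_pairs_have_p_one(self, trans_tests):
        tests, _ = trans_tests
        assert (tests.loc[tests.k == 0, "p_value"] == 1.0).all()


class TestBuildBinNetwork:
    def hand_tests(self):
        return pd.DataFrame(
            {
                "chromA": ["c1"] * 5,
                "binA": range(5),
                "chromB": ["c2"] * 5,
                "binB": range(5),
                "k": [5] * 5,
                "n": [100] * 5,
                "m_norm": [0.01] * 5,
                "p_value": [0.1] * 5,
                "q_value": [0.2] * 5,
                "q_norm": [1e-8, 1e-7, 1e-3, 0.2, 0.9],
            }
        )

    def test_zero_cutoff_empty(self):
        g = transnet.build_bin_network(self.hand_tests(), q_cutoff=0.0)
        assert g.number_of_edges() == 0

    def test_hand_table_cutoff(self):
        g = transnet.build_bin_network(self.hand_tests(), q_cutoff=1e-6)
        assert g.number_of_edges() == 2

    def test_unit_cutoff_keeps_everything(self):
        g = transnet.build_bin_network(self.hand_tests(), q_cutoff=1.0)
        assert g.number_of_edges() == 5

    def test_no_intra_chromosomal_edges(self, trans_tests):
        tests, _ = trans_tests
        g = transnet.build_bin_network(tests, q_cutoff=1e-6)
        for (ca, _), (cb, _) in g.edges():
            assert ca != cb


class TestRandomizeNetwork:
    @pytest.fixture(scope="class")
    def base(self):
        return nx.gnm_random_graph(30, 60, seed=3)

    def test_counts_preserved_and_seed_sensitive(self, base):
        r1 = transnet.randomize_network(base, seed=1)
        r2 = transnet.randomize_network(base, seed=2)
        for r in (r1, r2):
            assert r.number_of_nodes() == base.number_of_nodes()
            assert r.number_of_edges() == base.number_of_edges()
        assert set(r1.edges()) != set(r2.edges())

    def test_deterministic_for_fixed_seed(self, base):
        r1 = transnet.randomize_network(base, seed=5)
        r2 = transnet.randomize_network(base, seed=5)
        assert set(map(frozenset, r1.edges())) == set(map(frozenset, r2.edges()))

    def test_switches_never_decrease_transitivity(self, base):
        before = transnet.randomize_network(base, seed=7, switch_factor=0)
        after = transnet.randomize_network(base, seed=7, switch_factor=10)
        assert nx.transitivity(after) >= nx.transitivity(before)

    def test_observed_bin_exceeds_randomized_variance(self, small_world):
        """Planted trans hubs make the observed network variance far larger
        than the randomization's (one-sided empirical p < 0.05)."""
        m500 = ac.simulate_hic(small_world, "sp1", 500_000, 300_000, seed=41)
        tests = transnet.trans_significance(m500)
        net = transnet.build_bin_network(tests, q_cutoff=1e-6)
        assert net.number_of_edges() >= 10
        observed = transnet.network_stats(net).network_variance
        controls = [
            transnet.network_stats(transnet.randomize_network(net, seed=s)).network_variance
            for s in range(20)
        ]
        assert observed > max(controls)


class TestNetworkStats:
    def test_star_network_variance(self):
        """K_{1,4}: degrees {4,1,1,1,1}; sample variance 1.8 over mean 1.6."""
        g = nx.star_graph(4)
        assert transnet.network_stats(g).network_variance == pytest.approx(1.125)

    def test_triangle_clustering_one(self):
        g = nx.complete_graph(3)
        s = transnet.network_stats(g)
        assert s.clustering_coefficient == pytest.approx(1.0)
        assert s.characteristic_path_length == pytest.approx(1.0)

    def test_path_clustering_zero(self):
        g = nx.path_graph(3)
        assert transnet.network_stats(g).clustering_coefficient == 0.0

    def test_zero_degree_rejected(self):
        g = nx.empty_graph(4)
        with pytest.raises(ValueError):
            transnet.network_stats(g)

    def test_density_ladder_lowers_degree_and_clustering(self):
        """Under a fixed sequencing budget, larger genomes dilute per-pair
        trans counts: average degree and clustering both fall across the
        genome-size ladder."""
        ad, cc = [], []
        for lens in [(8_000_000, 12_000_000), (25_000_000, 35_000_000)]:
            ads, ccs = [], []
            for seed in (61, 62, 63):
                w = ac.make_world(n_species=2, seed=19, chrom_count_range=(3, 3),
                                  chrom_len_range=lens)
                m = ac.simulate_hic(w, "sp1", 500_000, 30_000, seed=seed)
                g = transnet.build_bin_network(
                    transnet.trans_significance(m), q_cutoff=1e-6
                )
                s = transnet.network_stats(g)
                ads.append(s.average_degree)
                ccs.append(s.clustering_coefficient)
            ad.append(np.mean(ads))
            cc.append(np.mean(ccs))
        assert ad[1] < ad[0]
        assert cc[1] < cc[0]


class TestGeneNetworkSimilarity:
    def test_identical_networks_similarity_one(self, small_world):
        m500 = ac.simulate_hic(small_world, "sp1", 500_000, 300_000, seed=41)
        tests = transnet.trans_significance(m500)
        net = transnet.build_bin_network(tests, q_cutoff=1e-3)
        # the same network under two species labels, with sp2 genes mapped to
        # the sp1 coordinates, yields perfectly rank-correlated propensities
        ot = small_world.orthologs
        ot1 = ot[ot.species == "sp1"]
        ot2 = ot1.assign(species="sp2")
        both = pd.concat([ot1, ot2])
        sim = transnet.gene_network_similarity({"sp1": net, "sp2": net}, both)
        assert sim.loc["sp1", "sp2"] == pytest.approx(1.0)

    def test_similarity_declines_with_divergence(self):
        w = ac.make_world(n_species=4, seed=1, chrom_count_range=(3, 4),
                          chrom_len_range=(8_000_000, 30_000_000))
        nets = {}
        for k, spn in enumerate(w.species):
            m = ac.simulate_hic(w, spn, 500_000, 400_000, seed=10 + k)
            t = transnet.trans_significance(m)
            nets[spn] = transnet.build_bin_network(t, q_cutoff=1e-6)
        sim = transnet.gene_network_similarity(nets, w.orthologs)
        div = w.divergence_times()
        xs, ys = [], []
        for i, a in enumerate(w.species):
            for b in w.species[i + 1 :]:
                xs.append(sim.loc[a, b])
                ys.append(div[(a, b)])
        assert np.corrcoef(xs, ys)[0, 1] < 0


class TestContactRatioProfile:
    def toy(self):
        bins = make_bin_table({"c1": 2000, "c2": 1000}, 1000)
        x = np.zeros((3, 3))
        x[0, 2] = x[2, 0] = 4  # bin0: only trans
        x[1, 1] = 3  # bin1 diagonal intra
        x[1, 2] = x[2, 1] = 3  # bin1: equal intra(diag) wait: also trans
        return ContactMatrix(resolution=1000, bins=bins, counts=sp.csr_matrix(x))

    def test_boundary_values(self):
        m = self.toy()
        ratio = transnet.contact_ratio_profile(m)
        assert ratio.loc[("c1", 0)] == pytest.approx(1.0)  # only trans
        assert ratio.loc[("c1", 1)] == pytest.approx(0.5)  # 3 intra vs 3 trans

    def test_matches_brute_force_recount(self, small_world, tmp_path):
        m = ac.simulate_hic(small_world, "sp1", 500_000, 100_000, seed=43)
        ratio = transnet.contact_ratio_profile(m)
        m.to_triplets(tmp_path / "t.tsv")
        df = pd.read_csv(tmp_path / "t.tsv", sep="\t")
        intra = {}
        total = {}
        for row in df.itertuples(index=False):
            # a symmetric matrix marginal sees each off-diagonal entry once
            # per endpoint and each diagonal entry once
            for key in {(row.chromA, row.binA), (row.chromB, row.binB)}:
                total[key] = total.get(key, 0) + row.count
                if row.chromA == row.chromB:
                    intra[key] = intra.get(key, 0) + row.count
        for key, tot in total.items():
            expected = (tot - intra.get(key, 0)) / tot
            assert ratio.loc[key] == pytest.approx(expected)
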