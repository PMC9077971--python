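"""Inter-chromosomal interaction significance, networks, and randomization.

Each inter-chromosomal 500-kb bin pair is tested with an upper-tail
binomial probability against a background rate m_norm derived from
fragment-count products; Benjamini-Hochberg FDR is applied separately per
chromosome pair and q-values are normalized against chromosome length.
Significant pairs form bin interaction networks (BINs) whose summary
statistics (network variance, clustering coefficient, average degree,
characteristic path length, degree power-law slope) are compared against
geometry-based randomized controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binom, spearmanr
from statsmodels.stats.multitest import multipletests

from .matrix import ContactMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Significance testing
# ---------------------------------------------------------------------------

def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p); exact, k=0 gives 1."""
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


def trans_significance(
    m: ContactMatrix, fragment_size: int = 10_000
) -> pd.DataFrame:
    """Binomial significance of every inter-chromosomal bin pair.

    Fragment counts are proxied by the number of ``fragment_size`` sub-bins
    per bin (the m_norm ratio only depends on relative fragment numbers).
    Columns: chromA, binA, chromB, binB, k, n, m_norm, p_value, q_value,
    q_norm. BH families are per chromosome pair; q_norm multiplies q by
    len(chrA)*len(chrB) / (len(L1)*len(L2)) with L1, L2 the two longest
    chromosomes.
    """
    bins = m.bins
    chroms = m.chroms()
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes for trans tests")
    sizes = m.chromsizes
    two_longest = sorted(sizes.values())[-2:]
    norm_den = float(two_longest[0]) * float(two_longest[1])

    frags = np.ceil((bins["end"] - bins["start"]) / fragment_size).astype(float).to_numpy()
    counts = m.counts
    rows = []
    for i, ca in enumerate(chroms):
        sa = m.chrom_slice(ca)
        fa_tot = frags[sa].sum()
        for cb in chroms[i + 1 :]:
            sb = m.chrom_slice(cb)
            fb_tot = frags[sb].sum()
            block = np.asarray(counts[sa, sb].todense())
            n_tot = int(block.sum())
            if n_tot == 0:
                logger.info("no contacts between %s and %s; pair skipped", ca, cb)
                continue
            f_outer = np.outer(frags[sa], frags[sb]) / (fa_tot * fb_tot)
            ks = block.ravel().astype(int)
            ms = f_outer.ravel()
            ps = binom.sf(ks - 1, n_tot, ms)
            ps[ks == 0] = 1.0
            qs = multipletests(ps, method="fdr_bh")[1]
            factor = sizes[ca] * sizes[cb] / norm_den
            na, nb = block.shape
            ia, ib = np.divmod(np.arange(na * nb), nb)
            rows.append(
                pd.DataFrame(
                    {
                        "chromA": ca,
                        "binA": ia,
                        "chromB": cb,
                        "binB": ib,
                        "k": ks,
                        "n": n_tot,
                        "m_norm": ms,
                        "p_value": ps,
                        "q_value": qs,
                        "q_norm": qs * factor,
                    }
                )
            )
    if not rows:
        raise ValueError("no chromosome pair had any trans contacts")
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def build_bin_network(tests: pd.DataFrame, q_cutoff: float = 1e-6) -> nx.Graph:
    """BIN graph: nodes are (chrom, bin) tuples, edges where q_norm < cutoff.

    Edge attribute ``k`` carries the observed contact count. The node set is
    every bin that appears in at least one test.
    """
    g = nx.Graph()
    nodes_a = set(zip(tests["chromA"], tests["binA"]))
    nodes_b = set(zip(tests["chromB"], tests["binB"]))
    g.add_nodes_from(nodes_a | nodes_b)
    sig = tests[tests["q_norm"] < q_cutoff]
    for row in sig.itertuples(index=False):
        g.add_edge((row.chromA, row.binA), (row.chromB, row.binB), k=int(row.k))
    return g


def randomize_network(net: nx.Graph, seed: int, switch_factor: int = 10) -> nx.Graph:
    """Geometry-based randomized control with transitivity-increasing switches.

    Nodes are dropped uniformly in the unit cube and the |E| closest pairs
    become edges; then 10*|E| random edge switches are attempted, each
    accepted only if it increases transitivity. Degrees are preserved by a
    switch, so acceptance reduces to an increase in triangle count.
    """
    n_edges = net.number_of_edges()
    if n_edges < 1:
        raise ValueError("network must have at least one edge")
    nodes = list(net.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    iu = np.triu_indices(n, k=1)
    order = np.argsort(d2[iu], kind="stable")[:n_edges]
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    edges = []
    for idx in order:
        a, b = int(iu[0][idx]), int(iu[1][idx])
        adj[a].add(b)
        adj[b].add(a)
        edges.append((a, b))

    for _ in range(switch_factor * n_edges):
        e1, e2 = rng.integers(0, n_edges, 2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if len({a, b, c, d}) < 4:
            continue
        if d in adj[a] or b in adj[c]:
            continue
        t_old = len(adj[a] & adj[b]) + len(adj[c] & adj[d])
        adj[a].discard(b); adj[b].discard(a)
        adj[c].discard(d); adj[d].discard(c)
        t_new = len(adj[a] & adj[d]) + len(adj[c] & adj[b])
        if t_new > t_old:
            adj[a].add(d); adj[d].add(a)
            adj[c].add(b); adj[b].add(c)
            edges[e1] = (a, d)
            edges[e2] = (c, b)
        else:
            adj[a].add(b); adj[b].add(a)
            adj[c].add(d); adj[d].add(c)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((nodes[a], nodes[b]) for a, b in edges)
    return g


@dataclass
class NetworkStats:
    network_variance: float
    clustering_coefficient: float
    average_degree: float
    characteristic_path_length: float
    degree_powerlaw_slope: float


def network_stats(net: nx.Graph) -> NetworkStats:
    """Summary statistics with the printed sample-variance formula.

    network variance = S_d^2 / x_d with the n-1 denominator; the clustering
    coefficient forces C_n = 0 for nodes with fewer than two neighbors;
    characteristic path length is computed on the largest connected
    component; the degree power-law slope is the least-squares slope of
    log10 count vs log10 degree over the nonzero-degree histogram.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    mean_deg = degrees.mean()
    if mean_deg == 0:
        raise ValueError("zero mean degree; network variance undefined")
    nv = float(degrees.var(ddof=1) / mean_deg)
    cc = float(np.mean(list(nx.clustering(net).values())))
    comps = list(nx.connected_components(net))
    largest = max(comps, key=len)
    if len(largest) > 1:
        cpl = float(nx.average_shortest_path_length(net.subgraph(largest)))
    else:
        cpl = float("nan")
    pos = degrees[degrees > 0].astype(int)
    slope = float("nan")
    if pos.size:
        vals, cnts = np.unique(pos, return_counts=True)
        if vals.size >= 2:
            slope = float(np.polyfit(np.log10(vals), np.log10(cnts), 1)[0])
    return NetworkStats(
        network_variance=nv,
        clustering_coefficient=cc,
        average_degree=float(mean_deg),
        characteristic_path_length=cpl,
        degree_powerlaw_slope=slope,
    )


# ---------------------------------------------------------------------------
# Cross-species gene interaction networks
# ---------------------------------------------------------------------------

def gene_trans_propensity(
    net: nx.Graph, orthologs: pd.DataFrame, species: str, resolution: int = 500_000
) -> pd.Series:
    """Per ortholog group, summed significant trans contact frequency of the
    bins overlapping the gene."""
    strength: dict[tuple[str, int], float] = {}
    for u, v, data in net.edges(data=True):
        w = float(data.get("k", 1))
        strength[u] = strength.get(u, 0.0) + w
        strength[v] = strength.get(v, 0.0) + w
    sub = orthologs[orthologs["species"] == species]
    out = {}
    for row in sub.itertuples(index=False):
        b0 = int(row.start // resolution)
        b1 = int((row.end - 1) // resolution)
        out[row.group] = sum(
            strength.get((row.chrom, b), 0.0) for b in range(b0, b1 + 1)
        )
    return pd.Series(out, name=species)


def gene_network_similarity(
    nets: dict[str, nx.Graph],
    orthologs: pd.DataFrame,
    resolution: int = 500_000,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Pairwise Spearman similarity of ortholog trans-contact propensities."""
    if len(nets) < 2:
        raise ValueError("need at least two species")
    props = {
        spc: gene_trans_propensity(net, orthologs, spc, resolution)
        for spc, net in nets.items()
    }
    species = list(nets)
    sim = pd.DataFrame(np.eye(len(species)), index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            shared = props[a].index.intersection(props[b].index)
            if len(shared) < min_shared:
                sim.loc[a, b] = sim.loc[b, a] = np.nan
                logger.warning("pair %s-%s has <%d shared orthologs", a, b, min_shared)
                continue
            rho = spearmanr(props[a][shared], props[b][shared]).statistic
            sim.loc[a, b] = sim.loc[b, a] = rho
    return sim


def contact_ratio_profile(m: ContactMatrix) -> pd.Series:
    """Per-bin trans fraction: inter / (intra + inter) aligned contacts.

    Zero-coverage bins are NaN (masked).
    """
    chrom = m.bins["chrom"].to_numpy()
    total = np.asarray(m.counts.sum(axis=1)).ravel()
    intra = np.zeros_like(total)
    for c in m.chroms():
        sl = m.chrom_slice(c)
        intra[sl] = np.asarray(m.counts[sl, sl].sum(axis=1)).ravel()
    inter = total - intra
    if not (intra.sum() > 0 and inter.sum() > 0):
        raise ValueError("need both intra- and inter-chromosomal contacts")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, inter / total, np.nan)
    return pd.Series(ratio, index=pd.MultiIndex.from_arrays(
        [chrom, m.bins["start"] // m.resolution], names=["chrom", "bin"]
    ))
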