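"""Seeded multi-species synthetic genome world with planted 3D-genome truth.

The generator builds an ancestral genome (chromosomes, compartment blocks,
TAD boundaries, single-copy genes), evolves compartment states and TAD
boundaries along a random ultrametric phylogeny (a structure element flips
on a branch with probability proportional to branch length), and projects
everything into each species' own coordinate system via per-chromosome
scaling. Ortholog gene positions double as liftOver-style anchor tables
for cross-species coordinate mapping.

Hi-C counts are Poisson draws around a multiplicative expectation:
power-law distance decay x compartment checkerboard x intra-TAD enrichment
for cis, and a chromosome-length-difference affinity for trans. Auxiliary
tracks (CTCF motifs, TE families, CNEs, expression, enhancers) are tied to
the same planted truth so that every downstream statistic has a known
expected direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import phylo
from .matrix import ContactMatrix, make_bin_table

ANCHOR_UNIT = 500_000  # species chromosome lengths are multiples of this
COMP_RES = 100_000  # compartment block grid
TAD_RES = 20_000  # TAD boundary grid
BOUNDARY_GAP = 40_000  # planted gap between adjacent TADs


@dataclass
class PlantedTruth:
    """Ground truth planted into the world, per species."""

    ps_exponent: dict[str, float]
    tad_intervals: dict[str, list[tuple[str, int, int]]]
    compartment_sign: dict[str, dict[str, np.ndarray]]  # per 100-kb bin, +/-1
    trans_affinity: dict[str, float]  # {"scale_bp": ..., "hub_strength": ...}
    conserved_fraction: float
    trans_hubs: dict[str, dict[str, np.ndarray]] = field(default=None, repr=False)  # type: ignore[assignment]
    # per species per chrom: bool per 500-kb slot; hub bins attract trans
    # contacts and evolve along the tree like compartment states
    aligned_signs: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]
    # ancestral 100-kb frame x species, +/-1; the alignment frame for
    # cross-species compartment comparisons


@dataclass
class SpeciesWorld:
    species: list[str]
    genomes: dict[str, dict[str, int]]
    phylogeny: object  # Bio.Phylo Tree
    orthologs: pd.DataFrame  # group, species, gene, chrom, start, end, strand
    planted: PlantedTruth
    scales: dict[str, dict[str, float]] = field(default=None, repr=False)  # type: ignore[assignment]

    def divergence_times(self) -> dict[tuple[str, str], float]:
        return phylo.divergence_times(self.phylogeny)

    # -- ortholog-anchored coordinate mapping (liftOver stand-in) ---------
    def anchor_table(self, sp_from: str, sp_to: str, chrom: str) -> pd.DataFrame:
        """Shared ortholog anchor positions on one chromosome, both species."""
        ot = self.orthologs
        a = ot[(ot.species == sp_from) & (ot.chrom == chrom)].set_index("group")
        b = ot[(ot.species == sp_to) & (ot.chrom == chrom)].set_index("group")
        shared = a.index.intersection(b.index)
        df = pd.DataFrame(
            {"pos_from": a.loc[shared, "start"], "pos_to": b.loc[shared, "start"]}
        ).sort_values("pos_from")
        # chromosome ends as terminal anchors
        ends = pd.DataFrame(
            {
                "pos_from": [0, self.genomes[sp_from][chrom]],
                "pos_to": [0, self.genomes[sp_to][chrom]],
            }
        )
        return (
            pd.concat([df, ends]).sort_values("pos_from").drop_duplicates("pos_from")
        )

    def map_position(self, sp_from: str, sp_to: str, chrom: str, pos: float) -> float:
        """Piecewise-linear interpolation between ortholog anchors."""
        t = self.anchor_table(sp_from, sp_to, chrom)
        return float(np.interp(pos, t["pos_from"], t["pos_to"]))

    def boundaries_of(self, species: str) -> list[tuple[str, int, int]]:
        """Planted boundary intervals: gaps between adjacent planted TADs."""
        out = []
        tads = self.planted.tad_intervals[species]
        for (c1, _, e1), (c2, s2, _) in zip(tads, tads[1:]):
            if c1 == c2 and s2 > e1:
                out.append((c1, e1, s2))
        return out


def align_bin_tracks(
    world: SpeciesWorld,
    ref_species: str,
    tracks: dict[str, dict[str, np.ndarray]],
    resolution: int,
) -> pd.DataFrame:
    """Project per-species per-chromosome bin tracks onto the reference
    species' bin frame via ortholog-anchored coordinate mapping.

    Returns a (ref chrom, ref bin) x species DataFrame; unmappable or
    out-of-range bins are NaN.
    """
    ref_genome = world.genomes[ref_species]
    index = []
    data: dict[str, list[float]] = {sp_name: [] for sp_name in tracks}
    for chrom, L in ref_genome.items():
        nb = int(np.ceil(L / resolution))
        anchor = {
            sp_name: world.anchor_table(ref_species, sp_name, chrom)
            for sp_name in tracks
            if sp_name != ref_species
        }
        for i in range(nb):
            mid = (i + 0.5) * resolution
            index.append((chrom, i))
            for sp_name, per_chrom in tracks.items():
                arr = per_chrom.get(chrom)
                if arr is None:
                    data[sp_name].append(np.nan)
                    continue
                if sp_name == ref_species:
                    pos = mid
                else:
                    t = anchor[sp_name]
                    pos = float(np.interp(mid, t["pos_from"], t["pos_to"]))
                j = int(pos // resolution)
                data[sp_name].append(arr[j] if 0 <= j < len(arr) else np.nan)
    return pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(index, names=["chrom", "bin"])
    )


# ---------------------------------------------------------------------------
# World construction
# ---------------------------------------------------------------------------

def _flip_prob(conserved_fraction: float, branch_len: float, depth: float) -> float:
    if depth <= 0:
        return 0.0
    return min(0.5, (1.0 - conserved_fraction) * branch_len / depth)


def make_world(
    n_species: int = 4,
    chrom_count_range: tuple[int, int] = (2, 5),
    chrom_len_range: tuple[int, int] = (5_000_000, 50_000_000),
    seed: int = 0,
    conserved_fraction: float = 0.8,
    tree_depth_mya: float = 300.0,
    genes_per_mb: float = 2.0,
    ps_exponent_range: tuple[float, float] = (-0.45, -0.23),
    trans_scale_bp: float = 20_000_000.0,
) -> SpeciesWorld:
    """Generate a seeded toy multi-species world with planted truth.

    Species share an ancestral chromosome complement; per-species
    chromosome lengths are rescaled so length distributions differ.
    Compartment block states and TAD boundaries evolve along the phylogeny:
    an element flips state on a branch with probability proportional to
    branch length, scaled by ``1 - conserved_fraction``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not (0 < chrom_count_range[0] <= chrom_count_range[1]):
        raise ValueError("invalid chrom_count_range")
    if not (0 < chrom_len_range[0] <= chrom_len_range[1]):
        raise ValueError("invalid chrom_len_range")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]
    tree = phylo.random_ultrametric_tree(species, tree_depth_mya, rng)
    depth = phylo.tree_depth(tree)

    # ancestral genome
    n_chrom = int(rng.integers(chrom_count_range[0], chrom_count_range[1] + 1))
    anc_lens = {}
    for i in range(n_chrom):
        raw = rng.uniform(*chrom_len_range)
        anc_lens[f"chr{i + 1}"] = int(max(ANCHOR_UNIT * 4, round(raw / ANCHOR_UNIT) * ANCHOR_UNIT))

    # per-species scaling of each chromosome (keeps lengths on the 500-kb grid)
    scales: dict[str, dict[str, float]] = {}
    genomes: dict[str, dict[str, int]] = {}
    for sp_name in species:
        scales[sp_name] = {}
        genomes[sp_name] = {}
        for chrom, L in anc_lens.items():
            f = float(rng.uniform(0.75, 1.3))
            newlen = int(max(ANCHOR_UNIT * 4, round(L * f / ANCHOR_UNIT) * ANCHOR_UNIT))
            genomes[sp_name][chrom] = newlen
            scales[sp_name][chrom] = newlen / L

    # ancestral compartment blocks on the 100-kb grid (geometric block sizes)
    anc_blocks: dict[str, np.ndarray] = {}  # per chrom: block id per 100-kb bin
    anc_block_sign: dict[str, np.ndarray] = {}  # root state per block
    for chrom, L in anc_lens.items():
        nb = L // COMP_RES
        block_of = np.empty(nb, dtype=int)
        b = 0
        i = 0
        sign0 = int(rng.integers(0, 2)) * 2 - 1
        signs = []
        while i < nb:
            size = int(rng.integers(3, 26))  # 0.3-2.5 Mb blocks
            block_of[i : i + size] = b
            signs.append(sign0 if b % 2 == 0 else -sign0)
            i += size
            b += 1
        anc_blocks[chrom] = block_of
        anc_block_sign[chrom] = np.array(signs)

    # ancestral trans-contact hubs on the 500-kb grid: a fixed small number
    # of strongly trans-interacting loci per chromosome (their count does
    # not scale with length, so larger genomes dilute the network)
    hubs_per_chrom = 3
    anc_hubs: dict[str, np.ndarray] = {}
    for chrom, L in anc_lens.items():
        n_slots = L // ANCHOR_UNIT
        flags = np.zeros(n_slots, dtype=bool)
        flags[rng.choice(n_slots, size=min(hubs_per_chrom, n_slots), replace=False)] = True
        anc_hubs[chrom] = flags

    # ancestral TAD boundaries on the 20-kb grid
    anc_bounds: dict[str, np.ndarray] = {}
    for chrom, L in anc_lens.items():
        pos = []
        p = 0
        while True:
            step = int(rng.uniform(400_000, 1_200_000) // TAD_RES) * TAD_RES
            p += step
            if p >= L - 400_000:
                break
            pos.append(p)
        anc_bounds[chrom] = np.array(pos, dtype=np.int64)

    # evolve compartment block states and boundary sets along the tree
    node_states: dict[int, dict[str, np.ndarray]] = {}
    node_bounds: dict[int, dict[str, np.ndarray]] = {}
    node_hubs: dict[int, dict[str, np.ndarray]] = {}
    root = tree.root
    node_states[id(root)] = {c: anc_block_sign[c].copy() for c in anc_lens}
    node_bounds[id(root)] = {c: anc_bounds[c].copy() for c in anc_lens}
    node_hubs[id(root)] = {c: anc_hubs[c].copy() for c in anc_lens}
    for parent, child in phylo.iter_branches(tree):
        p = _flip_prob(conserved_fraction, child.branch_length or 0.0, depth)
        st = {}
        bd = {}
        hb = {}
        for chrom in anc_lens:
            s = node_states[id(parent)][chrom].copy()
            flips = rng.random(s.size) < p
            s[flips] *= -1
            st[chrom] = s
            # hubs relocate (count-preserving) rather than flip
            h = node_hubs[id(parent)][chrom].copy()
            for slot in np.flatnonzero(h):
                if rng.random() < p:
                    h[slot] = False
                    free = np.flatnonzero(~h)
                    h[int(rng.choice(free))] = True
            hb[chrom] = h
            bounds = node_bounds[id(parent)][chrom]
            keep = rng.random(bounds.size) >= p / 2
            kept = bounds[keep]
            n_gain = int(rng.binomial(max(bounds.size, 1), p / 2))
            gains = (
                rng.integers(400_000 // TAD_RES, (anc_lens[chrom] - 400_000) // TAD_RES, n_gain)
                * TAD_RES
            )
            merged = np.unique(np.concatenate([kept, gains]))
            # enforce a minimal inter-boundary spacing of 400 kb
            if merged.size:
                sel = [int(merged[0])]
                for q in merged[1:]:
                    if q - sel[-1] >= 400_000:
                        sel.append(int(q))
                merged = np.array(sel, dtype=np.int64)
            bd[chrom] = merged
        node_states[id(child)] = st
        node_bounds[id(child)] = bd
        node_hubs[id(child)] = hb

    leaf_clades = {leaf.name: leaf for leaf in tree.get_terminals()}

    # ancestral single-copy genes, grouped into ancestral-TAD blocks that
    # can translocate as units along branches (breakpoints respect domain
    # integrity, so within-domain gene adjacencies outlive cross-domain ones)
    gene_list = []  # (group, orig_chrom, orig_pos, strand, block_key)
    g = 0
    for chrom, L in anc_lens.items():
        n_genes = max(4, int(genes_per_mb * L / 1e6))
        pos = np.sort(rng.choice(np.arange(TAD_RES, L - TAD_RES, TAD_RES), size=n_genes, replace=False))
        strands = rng.choice(["+", "-"], size=n_genes)
        blocks = np.searchsorted(anc_bounds[chrom], pos)
        for p0, strand, blk in zip(pos, strands, blocks):
            gene_list.append((f"og{g:05d}", chrom, int(p0), strand, (chrom, int(blk))))
            g += 1
    block_span: dict[tuple[str, int], tuple[int, int]] = {}
    for _, chrom, p0, _, key in gene_list:
        lo, hi = block_span.get(key, (p0, p0))
        block_span[key] = (min(lo, p0), max(hi, p0))

    # evolve block locations: a block relocates to a uniform position on a
    # random other chromosome with branch-length-proportional probability
    node_blocks: dict[int, dict[tuple[str, int], tuple[str, int]]] = {
        id(root): {key: (key[0], lo) for key, (lo, hi) in block_span.items()}
    }
    chrom_names = list(anc_lens)
    for parent, child in phylo.iter_branches(tree):
        p = _flip_prob(conserved_fraction, child.branch_length or 0.0, depth)
        loc = dict(node_blocks[id(parent)])
        if len(chrom_names) > 1:
            for key in loc:
                if rng.random() < p:
                    lo, hi = block_span[key]
                    span = hi - lo + TAD_RES
                    dest = chrom_names[int(rng.integers(0, len(chrom_names)))]
                    limit = max(TAD_RES, anc_lens[dest] - span - TAD_RES)
                    base = int(rng.integers(1, max(2, limit // TAD_RES))) * TAD_RES
                    loc[key] = (dest, base)
        node_blocks[id(child)] = loc

    leaf_clades_tmp = {leaf.name: leaf for leaf in tree.get_terminals()}
    gene_rows = []
    for group, orig_chrom, orig_pos, strand, key in gene_list:
        lo, _ = block_span[key]
        for sp_name in species:
            cur_chrom, base = node_blocks[id(leaf_clades_tmp[sp_name])][key]
            anc_pos = base + (orig_pos - lo)
            f = scales[sp_name][cur_chrom]
            start = int(round(anc_pos * f / TAD_RES) * TAD_RES)
            start = int(np.clip(start, 0, genomes[sp_name][cur_chrom] - TAD_RES))
            gene_rows.append(
                (group, sp_name, f"{sp_name}_{group}", cur_chrom, start, start + 10_000, strand)
            )
    orthologs = pd.DataFrame(
        gene_rows, columns=["group", "species", "gene", "chrom", "start", "end", "strand"]
    )

    # decay exponents: species with longer chromosomes decay more steeply
    # (the cross-species pattern of long-range contact loss in larger
    # genomes), with a small jitter; degenerate ranges pin the exponent
    lo, hi = min(ps_exponent_range), max(ps_exponent_range)
    mean_len = {s: float(np.mean(list(genomes[s].values()))) for s in species}
    ranks = {s: r for r, s in enumerate(sorted(species, key=lambda s: mean_len[s]))}
    ps_exp = {}
    for sp_name in species:
        frac = ranks[sp_name] / max(len(species) - 1, 1)
        e = hi - frac * (hi - lo) + rng.normal(0, 0.05) * (hi - lo)
        ps_exp[sp_name] = float(np.clip(e, lo, hi))
    comp_sign: dict[str, dict[str, np.ndarray]] = {}
    tad_intervals: dict[str, list[tuple[str, int, int]]] = {}
    trans_hubs: dict[str, dict[str, np.ndarray]] = {}
    aligned = {}
    for sp_name in species:
        leaf = leaf_clades[sp_name]
        states = node_states[id(leaf)]
        bounds = node_bounds[id(leaf)]
        hubs = node_hubs[id(leaf)]
        comp_sign[sp_name] = {}
        trans_hubs[sp_name] = {}
        tads: list[tuple[str, int, int]] = []
        al = []
        for chrom, L in anc_lens.items():
            f = scales[sp_name][chrom]
            sp_len = genomes[sp_name][chrom]
            nb = int(np.ceil(sp_len / COMP_RES))
            mids = (np.arange(nb) + 0.5) * COMP_RES
            anc_bin = np.minimum((mids / f / COMP_RES).astype(int), anc_blocks[chrom].size - 1)
            comp_sign[sp_name][chrom] = states[chrom][anc_blocks[chrom][anc_bin]]
            al.append(states[chrom][anc_blocks[chrom]])
            n_slot = int(np.ceil(sp_len / ANCHOR_UNIT))
            slot_mids = (np.arange(n_slot) + 0.5) * ANCHOR_UNIT
            anc_slot = np.minimum(
                (slot_mids / f / ANCHOR_UNIT).astype(int), hubs[chrom].size - 1
            )
            trans_hubs[sp_name][chrom] = hubs[chrom][anc_slot]
            # TADs between mapped boundaries, with a fixed planted gap
            bpos = np.round(bounds[chrom] * f / TAD_RES).astype(np.int64) * TAD_RES
            bpos = np.unique(bpos[(bpos > 0) & (bpos < sp_len)])
            edges = np.concatenate([[0], bpos, [sp_len]])
            half = BOUNDARY_GAP // 2
            for s0, e0 in zip(edges[:-1], edges[1:]):
                start = int(s0 + (half if s0 > 0 else 0))
                end = int(e0 - (half if e0 < sp_len else 0))
                if end - start >= 200_000:
                    tads.append((chrom, start, end))
        tad_intervals[sp_name] = tads
        aligned[sp_name] = np.concatenate(al)

    aligned_signs = pd.DataFrame(aligned)

    planted = PlantedTruth(
        ps_exponent=ps_exp,
        tad_intervals=tad_intervals,
        compartment_sign=comp_sign,
        trans_affinity={"scale_bp": float(trans_scale_bp), "hub_strength": 12.0},
        conserved_fraction=float(conserved_fraction),
        trans_hubs=trans_hubs,
        aligned_signs=aligned_signs,
    )
    return SpeciesWorld(
        species=species,
        genomes=genomes,
        phylogeny=tree,
        orthologs=orthologs,
        planted=planted,
        scales=scales,
    )


# ---------------------------------------------------------------------------
# Hi-C simulation
# ---------------------------------------------------------------------------

def expected_cis(
    world: SpeciesWorld,
    species: str,
    chrom: str,
    resolution: int,
    plaid: float = 0.4,
    tad_boost: float = 3.0,
) -> np.ndarray:
    """Unscaled expected intra-chromosomal matrix for one chromosome.

    decay (s/res)^alpha  x  (1 + plaid * sign_i * sign_j)  x  TAD boost for
    same-TAD bin pairs.
    """
    if species not in world.species:
        raise KeyError(f"unknown species {species!r}")
    alpha = world.planted.ps_exponent[species]
    L = world.genomes[species][chrom]
    n = int(np.ceil(L / resolution))
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    d[d == 0] = 0.5
    decay = d ** alpha
    mids = (np.arange(n) + 0.5) * resolution
    comp = world.planted.compartment_sign[species][chrom]
    sign = comp[np.minimum((mids // COMP_RES).astype(int), comp.size - 1)].astype(float)
    mod = 1.0 + plaid * np.outer(sign, sign)
    tad_id = np.full(n, -1)
    for t, (c, s0, e0) in enumerate(world.planted.tad_intervals[species]):
        if c == chrom:
            tad_id[(mids >= s0) & (mids < e0)] = t
    same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    mod[same] *= tad_boost
    # keep the per-diagonal mean of the modulation at 1 so the expected
    # P(s) is exactly the planted power law
    for off in range(n):
        idx = np.arange(n - off)
        mu = mod[idx, idx + off].mean()
        if mu > 0:
            mod[idx, idx + off] /= mu
            if off:
                mod[idx + off, idx] /= mu
    return decay * mod


def trans_affinity_value(world: SpeciesWorld, species: str, chrom_a: str, chrom_b: str) -> float:
    """Per-pair expected trans weight: decreases with chromosome-length difference."""
    la = world.genomes[species][chrom_a]
    lb = world.genomes[species][chrom_b]
    scale = world.planted.trans_affinity["scale_bp"]
    return float(np.exp(-abs(la - lb) / scale))


def simulate_hic(
    world: SpeciesWorld,
    species: str,
    resolution: int,
    depth: int,
    seed: int,
    cis_fraction: float = 0.7,
    plaid: float = 0.4,
    tad_boost: float = 3.0,
) -> ContactMatrix:
    """Poisson-sampled contact matrix for one species at one resolution."""
    if species not in world.species:
        raise KeyError(f"unknown species {species!r}")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    genome = world.genomes[species]
    bins = make_bin_table(genome, resolution)
    n = len(bins)
    offsets = {}
    off = 0
    for chrom, L in genome.items():
        offsets[chrom] = off
        off += int(np.ceil(L / resolution))

    # cis: dense expectation per chromosome, scaled to cis_fraction * depth
    cis_exps = {
        chrom: expected_cis(world, species, chrom, resolution, plaid, tad_boost)
        for chrom in genome
    }
    cis_total = sum(np.triu(e).sum() for e in cis_exps.values())
    m = sp.lil_matrix((n, n))
    for chrom, e in cis_exps.items():
        lam = np.triu(e) * (cis_fraction * depth / cis_total)
        draw = rng.poisson(lam)
        draw = draw + np.triu(draw, k=1).T
        sl = offsets[chrom]
        k = e.shape[0]
        m[sl : sl + k, sl : sl + k] = draw

    # trans: expectation factorizes as affinity(chrA, chrB) * w_i * w_j where
    # w is elevated on planted hub bins; draw the pair total then scatter
    # with per-bin hub weights
    chroms = list(genome)
    hub_strength = world.planted.trans_affinity.get("hub_strength", 1.0)

    def bin_weights(chrom: str) -> np.ndarray:
        nb = int(np.ceil(genome[chrom] / resolution))
        w = np.ones(nb)
        hubs = world.planted.trans_hubs
        if hubs is not None and hub_strength != 1.0:
            flags = hubs[species][chrom]
            mids = (np.arange(nb) + 0.5) * resolution
            slot = np.minimum((mids // ANCHOR_UNIT).astype(int), flags.size - 1)
            w += (hub_strength - 1.0) * flags[slot]
        return w

    wvec = {c: bin_weights(c) for c in chroms}
    weights = {}
    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1 :]:
            weights[(ca, cb)] = (
                trans_affinity_value(world, species, ca, cb)
                * wvec[ca].sum()
                * wvec[cb].sum()
            )
    wtot = sum(weights.values())
    if wtot > 0:
        for (ca, cb), w in weights.items():
            lam = (1 - cis_fraction) * depth * w / wtot
            n_pair = int(rng.poisson(lam))
            if n_pair == 0:
                continue
            pa = wvec[ca] / wvec[ca].sum()
            pb = wvec[cb] / wvec[cb].sum()
            ia = rng.choice(len(pa), size=n_pair, p=pa) + offsets[ca]
            ib = rng.choice(len(pb), size=n_pair, p=pb) + offsets[cb]
            add = sp.coo_matrix((np.ones(n_pair), (ia, ib)), shape=(n, n))
            add = add + add.T
            m = (m.tocsr() + add.tocsr()).tolil()
    return ContactMatrix(resolution=resolution, bins=bins, counts=m.tocsr())


# ---------------------------------------------------------------------------
# Auxiliary tracks
# ---------------------------------------------------------------------------

class Tracks(NamedTuple):
    motifs: pd.DataFrame  # chrom, start, end, name, score, strand
    tes: pd.DataFrame  # chrom, start, end, family
    cnes: pd.DataFrame  # chrom, start, end, score
    expression: pd.DataFrame  # gene x replicate TPM
    enhancers: pd.DataFrame  # chrom, start, end


def simulate_tracks(
    world: SpeciesWorld,
    species: str,
    seed: int,
    convergence_bias: float = 0.8,
    genome_motif_per_mb: float = 10.0,
    sine_effect: float = 0.5,
    cne_interior_rate: float = 1.2,
    cne_boundary_rate: float = 0.3,
    coexpression_r: float = 0.8,
    n_replicates: int = 3,
) -> Tracks:
    """Generate motif/TE/CNE/expression/enhancer tracks tied to planted truth.

    - CTCF motifs: background motifs with random strand plus, with
      probability ``convergence_bias`` per TAD, an inward-facing (+ ... -)
      pair at the TAD edges; adjacent TADs then yield short divergent
      spacings at boundaries and long convergent spacings inside TADs,
      planting 3DR > 1.
    - TE families: per-20-kb-bin coverage; SINE tracks compartment sign with
      effect size ``sine_effect``, LINE anti-tracks it, LTR/DNA are neutral.
    - CNEs: depleted in boundary bins relative to TAD interiors.
    - Expression: genes sharing a planted TAD load on a common latent factor
      with correlation ``coexpression_r``.
    - Enhancers: placed preferentially on A-compartment (SINE-rich) bins.
    """
    if species not in world.species:
        raise KeyError(f"unknown species {species!r}")
    rng = np.random.default_rng(seed)
    genome = world.genomes[species]
    tads = world.planted.tad_intervals[species]
    comp = world.planted.compartment_sign[species]

    # ---- motifs
    motif_rows = []
    k = 0
    for chrom, L in genome.items():
        n_bg = int(genome_motif_per_mb * L / 1e6)
        pos = np.sort(rng.integers(0, L - 19, n_bg))
        strands = rng.choice(["+", "-"], size=n_bg)
        scores = rng.uniform(0.0, 1.0, n_bg)
        for p, s, sc in zip(pos, strands, scores):
            motif_rows.append((chrom, int(p), int(p) + 19, f"m{k}", float(sc), s))
            k += 1
    # CTCF clusters at boundaries: each boundary midpoint carries a few
    # high-scoring motifs on both sides, oriented into the flanking TADs
    # ('-' upstream of the midpoint closing the previous domain, '+'
    # downstream opening the next), as at real loop-anchor clusters
    for chrom, bs, be in world.boundaries_of(species):
        if rng.random() >= convergence_bias:
            continue
        center = (bs + be) // 2
        for side, strand in ((-1, "-"), (+1, "+")):
            n_side = 1 + int(rng.poisson(1.0))
            for _ in range(n_side):
                off = int(np.clip(abs(rng.normal(8_000, 6_000)), 1_000, 18_000))
                p = int(np.clip(center + side * off, 0, genome[chrom] - 19))
                motif_rows.append(
                    (chrom, p, p + 19, f"m{k}", float(rng.uniform(0.8, 1.0)), strand)
                )
                k += 1
    motifs = (
        pd.DataFrame(motif_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )

    # ---- TE coverage realized as one interval per family per 20-kb bin
    te_rows = []
    effects = {"SINE": sine_effect, "LINE": -sine_effect, "LTR": 0.0, "DNA": 0.0}
    for chrom, L in genome.items():
        nb = int(np.ceil(L / TAD_RES))
        mids = (np.arange(nb) + 0.5) * TAD_RES
        signs = comp[chrom][np.minimum((mids // COMP_RES).astype(int), comp[chrom].size - 1)]
        for family, eff in effects.items():
            base = rng.uniform(0.08, 0.12)
            cover = np.clip(base + 0.1 * eff * signs + rng.normal(0, 0.02, nb), 0.0, 0.9)
            widths = np.round(cover * TAD_RES).astype(int)
            for i, w in enumerate(widths):
                if w > 0:
                    s = int(i * TAD_RES)
                    te_rows.append((chrom, s, min(s + int(w), int(L)), family))
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "family"])

    # ---- CNEs: Poisson counts per 20-kb bin, depleted at boundary +/-1 bin
    boundary_bins: dict[str, set[int]] = {c: set() for c in genome}
    for chrom, bs, be in world.boundaries_of(species):
        mid_bin = int(((bs + be) // 2) // TAD_RES)
        boundary_bins[chrom].update({mid_bin - 1, mid_bin, mid_bin + 1})
    interior_bins: dict[str, set[int]] = {c: set() for c in genome}
    for chrom, s0, e0 in tads:
        interior_bins[chrom].update(range(int(s0 // TAD_RES), int(e0 // TAD_RES)))
    cne_rows = []
    for chrom, L in genome.items():
        nb = int(np.ceil(L / TAD_RES))
        for i in range(nb):
            if i in boundary_bins[chrom]:
                rate = cne_boundary_rate
            elif i in interior_bins[chrom]:
                rate = cne_interior_rate
            else:
                rate = (cne_boundary_rate + cne_interior_rate) / 2
            for _ in range(int(rng.poisson(rate))):
                start = int(i * TAD_RES + rng.integers(0, TAD_RES - 600))
                length = int(rng.integers(100, 600))
                score = float(rng.uniform(0.90, 1.0))
                cne_rows.append((chrom, start, start + length, round(score, 4)))
    cnes = pd.DataFrame(cne_rows, columns=["chrom", "start", "end", "score"])

    # ---- expression: TAD-shared latent factor
    genes = world.orthologs[world.orthologs.species == species].reset_index(drop=True)
    tad_of_gene = np.full(len(genes), -1)
    for t, (chrom, s0, e0) in enumerate(tads):
        inside = (genes.chrom == chrom) & (genes.start >= s0) & (genes.start < e0)
        tad_of_gene[inside.to_numpy()] = t
    n_genes = len(genes)
    factors = rng.normal(0, 1, (len(tads), n_replicates))
    noise = rng.normal(0, 1, (n_genes, n_replicates))
    r = float(np.clip(coexpression_r, 0.0, 1.0))
    log_expr = np.empty((n_genes, n_replicates))
    base = rng.normal(3.0, 1.0, n_genes)
    for i in range(n_genes):
        t = tad_of_gene[i]
        shared = factors[t] if t >= 0 else rng.normal(0, 1, n_replicates)
        log_expr[i] = base[i] + np.sqrt(r) * shared + np.sqrt(1 - r) * noise[i]
    tpm = np.exp2(log_expr)
    expression = pd.DataFrame(
        tpm, index=genes.gene, columns=[f"rep{j + 1}" for j in range(n_replicates)]
    )

    # ---- enhancers on A-compartment bins
    enh_rows = []
    for chrom, L in genome.items():
        nb = int(np.ceil(L / TAD_RES))
        mids = (np.arange(nb) + 0.5) * TAD_RES
        signs = comp[chrom][np.minimum((mids // COMP_RES).astype(int), comp[chrom].size - 1)]
        n_enh = max(2, nb // 40)
        probs = np.where(signs > 0, 4.0, 1.0)
        probs = probs / probs.sum()
        chosen = rng.choice(nb, size=min(n_enh, nb), replace=False, p=probs)
        for i in chosen:
            start = int(i * TAD_RES + rng.integers(0, TAD_RES - 5_000))
            enh_rows.append((chrom, start, start + int(rng.integers(1_000, 5_000))))
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)

    return Tracks(motifs, tes, cnes, expression, enhancers)
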