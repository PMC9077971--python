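"""End-to-end orchestration of the comparative analysis on a synthetic world.

``run_all`` generates a seeded world, simulates Hi-C and auxiliary tracks
per species, and runs every analysis stage, writing per-stage TSV/JSON
outputs plus a single summary report. The configuration (with every
threshold at its standard default: q-cutoff 1e-6, cosine 0.85, co-expression
r 0.9, 40/100-kb boundary rules, 400-kb gap, 70% motif quantile) is
serialized alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments, conservation, matrix, structure, tads, te, transnet, worldio
from .world import align_bin_tracks, make_world, simulate_hic, simulate_tracks

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    n_species: int = 3
    chrom_count_range: tuple[int, int] = (2, 3)
    chrom_len_range: tuple[int, int] = (6_000_000, 16_000_000)
    conserved_fraction: float = 0.8
    seed: int = 0
    depth: int = 300_000
    intra_resolution: int = 20_000
    compartment_resolution: int = 100_000
    trans_resolution: int = 500_000
    # long-range window scaled to the toy chromosome lengths; every
    # chromosome must span the upper end or stratum composition biases the fit
    ps_fit_range: tuple[int, int] = (500_000, 5_000_000)
    q_cutoff: float = 1e-6
    cosine_threshold: float = 0.85
    n_states: int = 12
    coexpression_r_cutoff: float = 0.9
    motif_score_quantile: float = 0.7
    boundary_conserved_dist: int = 40_000
    boundary_nonconserved_dist: int = 100_000
    boundary_max_gap: int = 400_000
    n_random_controls: int = 10
    out_dir: str = "archcompare_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("chrom_count_range", "chrom_len_range", "ps_fit_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["chrom_count_range"] = list(d["chrom_count_range"])
        d["chrom_len_range"] = list(d["chrom_len_range"])
        d["ps_fit_range"] = list(d["ps_fit_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def run_all(config: RunConfig) -> dict:
    """Run every stage on a fresh synthetic world; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    w = make_world(
        n_species=config.n_species,
        chrom_count_range=config.chrom_count_range,
        chrom_len_range=config.chrom_len_range,
        seed=config.seed,
        conserved_fraction=config.conserved_fraction,
    )
    worldio.write_newick(w.phylogeny, out / "phylogeny.nwk")
    worldio.write_orthologs(w.orthologs, out / "orthologs.tsv")

    report: dict = {"species": {}, "config_seed": config.seed}
    ab_tracks: dict[str, dict[str, np.ndarray]] = {}
    tad_sets: dict[str, tads.TadSet] = {}
    nets = {}
    for k, sp_name in enumerate(w.species):
        sp_seed = config.seed * 1009 + k + 1
        logger.info("simulating %s", sp_name)
        worldio.write_chromsizes(w.genomes[sp_name], out / f"{sp_name}.chrom.sizes")
        m20_raw = simulate_hic(w, sp_name, config.intra_resolution, config.depth, seed=sp_seed)
        m20 = matrix.iterative_correction(m20_raw)
        m20_cis = matrix.iterative_correction(m20_raw, scope="cis")
        m100 = matrix.iterative_correction(
            matrix.coarsen(m20_raw, config.compartment_resolution // config.intra_resolution)
        )
        m500 = matrix.coarsen(m20_raw, config.trans_resolution // config.intra_resolution)

        ps = matrix.ps_curve(m100, fit_range=tuple(config.ps_fit_range))
        tracks = simulate_tracks(w, sp_name, seed=sp_seed + 7)

        # compartments at 100 kb, AB index at 20 kb
        gene_density = {}
        for chrom, L in w.genomes[sp_name].items():
            nb = int(np.ceil(L / config.compartment_resolution))
            sub = w.orthologs[(w.orthologs.species == sp_name) & (w.orthologs.chrom == chrom)]
            gd = np.zeros(nb)
            # gene density proxy oriented by the planted compartment, as A is gene-rich
            sign = w.planted.compartment_sign[sp_name][chrom][:nb]
            gd[: len(sign)] = (sign > 0).astype(float)
            counts = np.bincount(
                (sub["start"] // config.compartment_resolution).astype(int), minlength=nb
            )[:nb]
            gd += 0.1 * counts
            gene_density[chrom] = gd
        comp = compartments.call_compartments(m100, gene_density)
        abi = compartments.ab_index(m20, comp.ab_label)
        ab_tracks[sp_name] = abi
        ins = compartments.insulation_score(m20)

        di = tads.directionality_index(m20_cis, window=400_000)
        tset = tads.call_tads(di, seed=sp_seed, min_run=2,
                              boundary_max_gap=config.boundary_max_gap)
        tad_sets[sp_name] = tset

        tests = transnet.trans_significance(m500)
        net = transnet.build_bin_network(tests, q_cutoff=config.q_cutoff)
        nets[sp_name] = net
        stats = transnet.network_stats(net) if net.number_of_edges() else None
        rand_nv = []
        if net.number_of_edges():
            for r in range(config.n_random_controls):
                rnet = transnet.randomize_network(net, seed=sp_seed + r)
                rand_nv.append(transnet.network_stats(rnet).network_variance)

        models = []
        for chrom in w.genomes[sp_name]:
            try:
                model = structure.embed_chromosome(m100, chrom)
                models.append((model, structure.ct_metrics(model)))
            except ValueError:
                continue

        tdr = conservation.compute_3dr(tracks.motifs, score_quantile=config.motif_score_quantile)
        tdr_border = None
        if tset.boundaries:
            try:
                tdr_border = conservation.compute_3dr(
                    tracks.motifs,
                    regions=conservation.tad_border_regions(tset),
                    score_quantile=config.motif_score_quantile,
                )
            except ValueError:
                pass
        cne = conservation.cne_profile(tset, tracks.cnes)
        genes_sp = w.orthologs[w.orthologs.species == sp_name]
        coexpr = conservation.coexpression_by_distance(
            tracks.expression, genes_sp, tset, r_cutoff=config.coexpression_r_cutoff
        )

        cov = te.te_coverage(tracks.tes, w.genomes[sp_name], config.intra_resolution)
        ab_flat = np.concatenate([abi[c] for c in w.genomes[sp_name]])
        te_ab = te.te_ab_correlation(cov, ab_flat)
        enh = te.enhancer_enrichment(
            cov, tracks.enhancers, w.genomes[sp_name], config.intra_resolution,
            n_boot=100, seed=sp_seed,
        )

        worldio.write_bedgraph(ins, config.intra_resolution, out / f"{sp_name}.insulation.bedgraph")
        worldio.write_bedgraph(abi, config.intra_resolution, out / f"{sp_name}.abindex.bedgraph")
        report["species"][sp_name] = {
            "ps_slope": ps.slope,
            "planted_exponent": w.planted.ps_exponent[sp_name],
            "n_tads": len(tset.domains),
            "mean_tad_length": float(
                np.mean([e - s for _, s, e in tset.domains]) if tset.domains else np.nan
            ),
            "network_variance": stats.network_variance if stats else None,
            "random_network_variance_mean": float(np.mean(rand_nv)) if rand_nv else None,
            "clustering_coefficient": stats.clustering_coefficient if stats else None,
            "3dr_genome": tdr.ratio_3dr,
            "3dr_borders": tdr_border.ratio_3dr if tdr_border else None,
            "cne_interior_mean": cne.interior_mean,
            "cne_flank_mean": cne.flank_mean,
            "coexpr_frac_same_tad_d0": float(coexpr.loc[0, "frac_same_tad"]),
            "coexpr_frac_all_d0": float(coexpr.loc[0, "frac_all"]),
            "te_ab_r": {fam: float(te_ab.loc[fam, "r"]) for fam in te_ab.index},
            "enhancer_fold": {fam: float(enh.loc[fam, "fold"]) for fam in enh.index},
            "ct_stretchiness": {mdl.chrom: met.stretchiness for mdl, met in models},
        }

    # cross-species stages on the reference frame of the first species
    ref = w.species[0]
    aligned = align_bin_tracks(w, ref, ab_tracks, config.intra_resolution)
    aligned = aligned.dropna()
    if len(aligned) >= config.n_states and config.n_species >= 3:
        assignment = compartments.cluster_states(
            aligned, k=config.n_states, seed=config.seed,
            cos_threshold=config.cosine_threshold,
            bin_mb=config.intra_resolution / 1e6,
        )
        report["state_groups_pct"] = assignment.group_pct
        simdiv = compartments.similarity_vs_divergence(aligned, w.phylogeny)
        report["ab_similarity_vs_divergence_r"] = simdiv["pearson_r"]
    gin = transnet.gene_network_similarity(nets, w.orthologs, config.trans_resolution)
    report["gene_network_similarity"] = gin.to_dict()
    if len(tad_sets) >= 3:
        cons = tads.classify_boundaries(ref, tad_sets, w)
        report["boundary_labels"] = pd.Series(cons.labels).value_counts().to_dict()

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    pd.json_normalize(report["species"], sep=".").T.to_csv(out / "report.tsv", sep="\t", header=False)
    return report
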