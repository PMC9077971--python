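"""Plain-text readers/writers for the formats the world emits.

chrom.sizes TSV, BED6 motifs, BED+family TEs, BED+score CNEs, BED3
enhancers, BED12 genes, gene x replicate TPM TSV, ortholog tables, Newick
phylogenies, and bedGraph tracks. Every writer round-trips through the
matching reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import phylo


def write_chromsizes(genome: dict[str, int], path) -> None:
    pd.Series(genome).rename("length").to_csv(path, sep="\t", header=False)


def read_chromsizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_bed6(motifs: pd.DataFrame, path) -> None:
    motifs[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def write_te_bed(tes: pd.DataFrame, path) -> None:
    tes[["chrom", "start", "end", "family"]].to_csv(path, sep="\t", header=False, index=False)


def read_te_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "family"])


def write_cne_bed(cnes: pd.DataFrame, path) -> None:
    cnes[["chrom", "start", "end", "score"]].to_csv(path, sep="\t", header=False, index=False)


def read_cne_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "score"])


def write_bed3(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed3(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])


def write_genes_bed12(genes: pd.DataFrame, path) -> None:
    """Single-block BED12 per gene."""
    df = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene"],
            "score": 0,
            "strand": genes["strand"],
            "thickStart": genes["start"],
            "thickEnd": genes["end"],
            "rgb": "0,0,0",
            "blockCount": 1,
            "blockSizes": (genes["end"] - genes["start"]).astype(str) + ",",
            "blockStarts": "0,",
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed12(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    out = df[[0, 1, 2, 3, 5]].copy()
    out.columns = ["chrom", "start", "end", "gene", "strand"]
    return out


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("gene").to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_orthologs(orthologs: pd.DataFrame, path) -> None:
    orthologs.to_csv(path, sep="\t", index=False)


def read_orthologs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_newick(tree, path) -> None:
    Path(path).write_text(phylo.to_newick(tree) + "\n")


def read_newick(path):
    return phylo.from_newick(Path(path).read_text())


def write_bedgraph(track: dict[str, np.ndarray], resolution: int, path) -> None:
    rows = []
    for chrom, vals in track.items():
        for i, v in enumerate(vals):
            if np.isfinite(v):
                rows.append((chrom, i * resolution, (i + 1) * resolution, v))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
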