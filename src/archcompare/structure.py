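"""3D chromosome models and chromosome-territory shape metrics.

Contacts are converted to distances by a power law d = c^(-alpha), missing
distances are completed by shortest paths, and classical (Torgerson) metric
MDS embeds each chromosome in 3D. Territory stretchiness and condensation
come from the convex hull: VSR = volume/surface and VpM = volume per Mb,
with stretchiness = 1/VSR and condensation = 1/VpM (a sphere minimizes
surface for a given volume, so a more stretched territory has higher 1/VSR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import spearmanr

from .matrix import ContactMatrix


@dataclass
class ChromosomeModel:
    chrom: str
    coords: np.ndarray  # (n_bins, 3), genomic order, centered at origin
    length_mb: float


@dataclass
class CTMetrics:
    volume: float
    surface: float
    vsr: float
    vpm: float
    stretchiness: float
    condensation: float


def classical_mds(d: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Torgerson classical MDS: eigendecomposition of the double-centered
    squared-distance matrix; deterministic."""
    n = d.shape[0]
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[idx], 0, None)
    x = vecs[:, idx] * np.sqrt(lam)
    return x - x.mean(axis=0)


def embed_chromosome(
    m: ContactMatrix,
    chrom: str,
    alpha: float = 0.25,
    seed: int = 0,
    min_bins: int = 10,
) -> ChromosomeModel:
    """Embed one chromosome in 3D from its balanced contact submatrix.

    Distances are (contact / max contact)^(-alpha) for observed contacts;
    unobserved pairs are completed with graph shortest paths. ``seed`` is
    accepted for interface symmetry; the embedding is deterministic.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive (alpha=0 degenerates all distances)")
    x = m.dense(chrom, balanced=m.balance_weights is not None)
    np.fill_diagonal(x, 0)
    signal = x.sum(axis=1) > 0
    if signal.sum() < min_bins:
        raise ValueError(f"chromosome {chrom} has <{min_bins} bins with signal")
    x = x[np.ix_(signal, signal)]
    cmax = x.max()
    with np.errstate(divide="ignore"):
        d = np.where(x > 0, (x / cmax) ** (-alpha), 0.0)
    g = csr_matrix(d)
    n_comp, labels = connected_components(g, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        iso = int(np.argmin(sizes))
        raise ValueError(
            f"contact graph of {chrom} is disconnected; isolated segment is "
            f"component {iso} with {sizes[iso]} bins"
        )
    full = shortest_path(g, directed=False)
    coords = classical_mds(full, 3)
    length_mb = m.chromsizes[chrom] / 1e6
    return ChromosomeModel(chrom=chrom, coords=coords, length_mb=length_mb)


def ct_metrics(model: ChromosomeModel) -> CTMetrics:
    """Convex-hull volume/surface metrics of a chromosome territory."""
    pts = np.asarray(model.coords, dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need >= 4 points for a 3D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError("degenerate (coplanar) point set; hull undefined") from err
    v = float(hull.volume)
    s = float(hull.area)
    if v <= 0 or s <= 0:
        raise ValueError("degenerate hull with zero volume or surface")
    vsr = v / s
    vpm = v / model.length_mb
    return CTMetrics(
        volume=v,
        surface=s,
        vsr=vsr,
        vpm=vpm,
        stretchiness=1.0 / vsr,
        condensation=1.0 / vpm,
    )


def length_scaling(models: list[tuple[ChromosomeModel, CTMetrics]]) -> dict:
    """Spearman correlation of chromosome length against stretchiness
    (expected negative) and condensation (expected positive)."""
    if len(models) < 3:
        raise ValueError("need >= 3 chromosomes")
    lengths = np.array([m.length_mb for m, _ in models])
    stretch = np.array([c.stretchiness for _, c in models])
    cond = np.array([c.condensation for _, c in models])
    if np.allclose(lengths, lengths[0]):
        return {
            "stretchiness": (float("nan"), float("nan")),
            "condensation": (float("nan"), float("nan")),
        }
    rs = spearmanr(lengths, stretch)
    rc = spearmanr(lengths, cond)
    return {
        "stretchiness": (float(rs.statistic), float(rs.pvalue)),
        "condensation": (float(rc.statistic), float(rc.pvalue)),
    }
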