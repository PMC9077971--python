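"""Contact-matrix data model, balancing, reproducibility, and P(s) decay.

The central object is :class:`ContactMatrix`: binned genome-wide contact
counts M_ij stored as a sparse symmetric matrix over an ordered bin table.
On top of it this module provides ICE-style iterative correction,
distance-stratified quantile normalization across samples, the
stratum-adjusted correlation coefficient (SCC) for replicate
reproducibility, and contact-decay P(s) curves with log-log slope fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import uniform_filter


class NonConvergenceWarning(UserWarning):
    """Balancing stopped at max_iter before reaching tolerance."""


def make_bin_table(chromsizes: Mapping[str, int], resolution: int) -> pd.DataFrame:
    """Tile each chromosome with fixed-width bins (last bin may be short).

    Bins use 0-based half-open coordinates; bin index of position p is
    floor(p / resolution).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rows = []
    for chrom, length in chromsizes.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        starts = np.arange(0, length, resolution, dtype=np.int64)
        ends = np.minimum(starts + resolution, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C contact matrix with optional balancing weights.

    Parameters
    ----------
    resolution : bin width in bp.
    bins : ordered table with columns chrom/start/end tiling each chromosome.
    counts : sparse symmetric nonnegative matrix over the bins.
    balance_weights : per-bin positive multipliers; NaN marks masked bins.
    """

    resolution: int
    bins: pd.DataFrame
    counts: sp.csr_matrix
    balance_weights: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if self.counts.shape[0] != len(self.bins):
            raise ValueError("counts dimension does not match bin table")

    # -- structure ---------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromsizes(self) -> dict[str, int]:
        g = self.bins.groupby("chrom", sort=False)["end"].max()
        return dict(g.items())

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in bin table")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def bin_index(self, chrom: str, pos: int) -> int:
        sl = self.chrom_slice(chrom)
        return sl.start + int(pos // self.resolution)

    # -- values ------------------------------------------------------------
    def marginals(self, balanced: bool = False) -> np.ndarray:
        c = self.balanced() if balanced else self.counts
        return np.asarray(c.sum(axis=1)).ravel()

    def balanced(self) -> sp.csr_matrix:
        """Return w_i * w_j * M_ij with masked bins zeroed."""
        if self.balance_weights is None:
            raise ValueError("matrix has no balance weights; run iterative_correction")
        w = np.nan_to_num(self.balance_weights, nan=0.0)
        d = sp.diags(w)
        return (d @ self.counts @ d).tocsr()

    def dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        sl = self.chrom_slice(chrom)
        c = self.balanced() if balanced else self.counts
        return c[sl, sl].toarray()

    def same_bins(self, other: "ContactMatrix") -> bool:
        return self.resolution == other.resolution and self.bins.reset_index(
            drop=True
        ).equals(other.bins.reset_index(drop=True))

    # -- I/O ---------------------------------------------------------------
    def to_triplets(self, path) -> None:
        """Write sparse upper-triangle triplet TSV: chromA binA chromB binB count."""
        coo = sp.triu(self.counts).tocoo()
        chrom = self.bins["chrom"].to_numpy()
        start = self.bins["start"].to_numpy()
        df = pd.DataFrame(
            {
                "chromA": chrom[coo.row],
                "binA": start[coo.row] // self.resolution,
                "chromB": chrom[coo.col],
                "binB": start[coo.col] // self.resolution,
                "count": coo.data,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_triplets(
        cls, path, chromsizes: Mapping[str, int], resolution: int
    ) -> "ContactMatrix":
        bins = make_bin_table(chromsizes, resolution)
        df = pd.read_csv(path, sep="\t")
        offsets = {}
        off = 0
        for chrom, length in chromsizes.items():
            offsets[chrom] = off
            off += int(np.ceil(length / resolution))
        rows = df["chromA"].map(offsets).to_numpy() + df["binA"].to_numpy()
        cols = df["chromB"].map(offsets).to_numpy() + df["binB"].to_numpy()
        n = len(bins)
        m = sp.coo_matrix((df["count"].to_numpy(float), (rows, cols)), shape=(n, n))
        m = m + sp.triu(m, k=1).T  # symmetrize from the upper triangle
        return cls(resolution=resolution, bins=bins, counts=m.tocsr())


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum contacts into bins ``factor`` times wider."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return m
    new_res = m.resolution * factor
    new_bins = make_bin_table(m.chromsizes, new_res)
    rows = []
    cols = []
    off_new = 0
    for chrom, L in m.chromsizes.items():
        sl = m.chrom_slice(chrom)
        starts = m.bins["start"].to_numpy()[sl]
        for j, s in enumerate(starts):
            rows.append(off_new + int(s // new_res))
            cols.append(sl.start + j)
        off_new += int(np.ceil(L / new_res))
    agg = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(new_bins), m.n_bins)
    ).tocsr()
    counts = agg @ m.counts @ agg.T
    return ContactMatrix(resolution=new_res, bins=new_bins, counts=counts.tocsr())


# ---------------------------------------------------------------------------
# Iterative correction (ICE)
# ---------------------------------------------------------------------------

def iterative_correction(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-4,
    low_coverage_quantile: float = 0.02,
    scope: str = "genome",
) -> ContactMatrix:
    """Matrix balancing: find per-bin weights equalizing retained marginals.

    Bins in the bottom ``low_coverage_quantile`` of nonzero marginals (and
    all zero-coverage bins) are masked; their weights are NaN and they are
    excluded from every downstream statistic. Non-convergence within
    ``max_iter`` emits :class:`NonConvergenceWarning` and returns the last
    iterate flagged ``converged=False``.

    ``scope='cis'`` equalizes intra-chromosomal marginals only (the
    standard choice before cis scores such as DI or insulation, where
    trans-driven coverage differences should not rescale rows); weights
    still apply to the full matrix.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if scope not in ("genome", "cis"):
        raise ValueError("scope must be 'genome' or 'cis'")
    counts = m.counts.astype(float)
    if scope == "cis":
        keep = sp.lil_matrix(counts.shape)
        for chrom in m.chroms():
            sl = m.chrom_slice(chrom)
            keep[sl, sl] = counts[sl, sl]
        counts = keep.tocsr()
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be nonnegative")
    marg = np.asarray(counts.sum(axis=1)).ravel()
    retained = marg > 0
    if low_coverage_quantile > 0 and retained.any():
        thresh = np.quantile(marg[retained], low_coverage_quantile)
        retained &= marg >= thresh
    w = np.ones(m.n_bins)
    w[~retained] = 0.0
    converged = False
    for _ in range(max_iter):
        s = np.asarray((sp.diags(w) @ counts @ sp.diags(w)).sum(axis=1)).ravel()
        s_ret = s[retained]
        mean = s_ret.mean()
        if mean == 0:
            break
        dev = np.abs(s_ret / mean - 1).max()
        if dev < tol:
            converged = True
            break
        adj = np.ones_like(w)
        adj[retained] = s[retained] / mean
        w = w / np.where(adj > 0, adj, 1.0)
    if not converged:
        warnings.warn(
            f"iterative correction did not reach tol={tol} in {max_iter} iterations",
            NonConvergenceWarning,
        )
    weights = w.copy()
    weights[~retained] = np.nan
    return ContactMatrix(
        resolution=m.resolution,
        bins=m.bins,
        counts=m.counts,
        balance_weights=weights,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Quantile normalization across samples
# ---------------------------------------------------------------------------

def _stratum_keys(m: ContactMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle COO rows/cols and the distance stratum of each entry.

    Intra-chromosomal entries get their separation in bins; inter-chromosomal
    entries share the single stratum -1.
    """
    coo = sp.triu(m.counts).tocoo()
    chrom = m.bins["chrom"].to_numpy()
    same = chrom[coo.row] == chrom[coo.col]
    d = np.where(same, coo.col - coo.row, -1)
    return coo, d, same


def quantile_normalize(samples: Sequence[ContactMatrix]) -> list[ContactMatrix]:
    """Rank-match nonzero contact values to the cross-sample mean quantile,
    separately within each genomic-distance stratum.

    Equalizes intensity distributions between samples without disturbing
    the decay of interaction frequency with distance.
    """
    if len(samples) < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    ref = samples[0]
    for s in samples[1:]:
        if not ref.same_bins(s):
            raise ValueError("samples must share an identical bin table")

    parsed = [_stratum_keys(s) for s in samples]
    strata = sorted({int(v) for _, d, _ in parsed for v in np.unique(d)})
    out_data = [coo.data.astype(float).copy() for coo, _, _ in parsed]

    for stratum in strata:
        idxs = [np.flatnonzero(d == stratum) for _, d, _ in parsed]
        vals = [out_data[k][idx] for k, idx in enumerate(idxs)]
        sorted_vals = [np.sort(v) for v in vals if v.size]
        if not sorted_vals:
            continue

        def mean_quantile(p: np.ndarray) -> np.ndarray:
            acc = np.zeros_like(p, dtype=float)
            for v in sorted_vals:
                q = (np.arange(v.size) + 0.5) / v.size
                acc += np.interp(p, q, v)
            return acc / len(sorted_vals)

        for k, idx in enumerate(idxs):
            v = vals[k]
            if v.size == 0:
                continue
            order = np.argsort(v, kind="stable")
            p = (np.arange(v.size) + 0.5) / v.size
            new = np.empty_like(v)
            new[order] = mean_quantile(p)
            out_data[k][idx] = new

    results = []
    for (coo, _, _), data, s in zip(parsed, out_data, samples):
        n = s.n_bins
        upper = sp.coo_matrix((data, (coo.row, coo.col)), shape=(n, n))
        full = upper + sp.triu(upper, k=1).T
        results.append(
            ContactMatrix(
                resolution=s.resolution,
                bins=s.bins,
                counts=full.tocsr(),
                balance_weights=s.balance_weights,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Stratum-adjusted correlation coefficient (SCC)
# ---------------------------------------------------------------------------

@dataclass
class ReproducibilityResult:
    per_chromosome: dict[str, float]
    aggregate: float


def scc(
    a: ContactMatrix,
    b: ContactMatrix,
    h: int = 1,
    max_dist: int = 5_000_000,
) -> ReproducibilityResult:
    """HiCRep-style stratum-adjusted correlation between two contact maps.

    Both maps are mean-filter smoothed (window 2h+1), stratified by genomic
    distance up to ``max_dist``, and per-stratum Pearson correlations are
    combined with stratum-size-and-variance weights. The aggregate is the
    median across chromosomes.
    """
    if not a.same_bins(b):
        raise ValueError("matrices must share bin table and resolution")
    max_d = max_dist // a.resolution
    per_chrom: dict[str, float] = {}
    for chrom in a.chroms():
        x = a.dense(chrom)
        y = b.dense(chrom)
        if x.shape[0] < 2:
            continue
        if h > 0:
            x = uniform_filter(x, size=2 * h + 1, mode="constant")
            y = uniform_filter(y, size=2 * h + 1, mode="constant")
        num = 0.0
        den = 0.0
        for d in range(1, min(max_d, x.shape[0] - 1) + 1):
            xd = np.diagonal(x, d)
            yd = np.diagonal(y, d)
            vx = xd.var()
            vy = yd.var()
            if xd.size < 2 or vx == 0 or vy == 0:
                continue
            r = float(np.corrcoef(xd, yd)[0, 1])
            w = xd.size * np.sqrt(vx * vy)
            num += w * r
            den += w
        if den > 0:
            per_chrom[chrom] = num / den
    if not per_chrom:
        raise ValueError("no usable distance strata; SCC undefined")
    return ReproducibilityResult(
        per_chromosome=per_chrom, aggregate=float(np.median(list(per_chrom.values())))
    )


# ---------------------------------------------------------------------------
# P(s) contact decay
# ---------------------------------------------------------------------------

@dataclass
class PsCurve:
    distances: np.ndarray
    probability: np.ndarray
    fit_range: tuple[float, float]
    slope: float
    intercept: float = 0.0


def ps_curve(
    m: ContactMatrix,
    fit_range: tuple[float, float] = (1_000_000, 10_000_000),
    balanced: bool = False,
    min_strata: int = 5,
) -> PsCurve:
    """Contact probability vs genomic separation, averaged over chromosomes.

    Per chromosome, P at separation s = d * resolution is the mean count per
    bin pair at diagonal offset d, normalized so the strata sum to 1, then
    averaged (unweighted) across chromosomes. The slope is the least-squares
    slope of log10 P against log10 s within ``fit_range``.
    """
    res = m.resolution
    chrom_curves = []
    max_len = 0
    for chrom in m.chroms():
        x = m.dense(chrom, balanced=balanced)
        n = x.shape[0]
        if n < 3:
            continue
        p = np.array([np.diagonal(x, d).mean() for d in range(1, n)])
        tot = p.sum()
        if tot > 0:
            chrom_curves.append(p / tot)
            max_len = max(max_len, p.size)
    if not chrom_curves:
        raise ValueError("no chromosome long enough for a P(s) curve")
    acc = np.full((len(chrom_curves), max_len), np.nan)
    for i, p in enumerate(chrom_curves):
        acc[i, : p.size] = p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prob = np.nanmean(acc, axis=0)
    s = np.arange(1, max_len + 1) * res

    lo, hi = fit_range
    sel = (s >= lo) & (s <= hi) & (prob > 0)
    if sel.sum() < min_strata:
        raise ValueError(
            f"only {int(sel.sum())} strata in fit range {fit_range}; "
            f"need >= {min_strata} for a slope"
        )
    slope, intercept = np.polyfit(np.log10(s[sel]), np.log10(prob[sel]), 1)
    return PsCurve(
        distances=s,
        probability=prob,
        fit_range=(float(lo), float(hi)),
        slope=float(slope),
        intercept=float(intercept),
    )


# ---------------------------------------------------------------------------
# Genome summary
# ---------------------------------------------------------------------------

def genome_summary(genome: Mapping[str, int | float]) -> dict:
    """Per-chromosome lengths, mean length, and pairwise long/short ratios.

    Ratios are longer/shorter, rounded to 2 decimal places (so equal-length
    pairs give exactly 1.00).
    """
    if len(genome) < 1:
        raise ValueError("genome must contain at least one chromosome")
    for chrom, length in genome.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom!r}")
    names = list(genome)
    lengths = np.array([genome[c] for c in names], dtype=float)
    ratios = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = lengths[i], lengths[j]
            ratios[(names[i], names[j])] = round(max(a, b) / min(a, b), 2)
    return {
        "lengths": dict(zip(names, lengths)),
        "mean_length": float(lengths.mean()),
        "pairwise_ratios": ratios,
    }
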