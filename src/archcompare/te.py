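"""Transposable-element coverage versus chromatin state and contacts.

TE records are split into the four major families (SINE, LINE, LTR, DNA),
merged within family, and reduced to per-20-kb-bin coverage fractions.
These coverages are correlated with the AB index, with filtered
intra-chromosomal contact frequencies, and contrasted between enhancer and
non-enhancer sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .matrix import ContactMatrix
from .tads import TadSet

logger = logging.getLogger(__name__)

FAMILIES = ("SINE", "LINE", "LTR", "DNA")


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals per chromosome (half-open coordinates)."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _overlap_per_bin(intervals: pd.DataFrame, genome: dict[str, int], resolution: int) -> dict[str, np.ndarray]:
    out = {c: np.zeros(int(np.ceil(L / resolution))) for c, L in genome.items()}
    for row in intervals.itertuples(index=False):
        if row.chrom not in out:
            continue
        arr = out[row.chrom]
        b0 = int(row.start // resolution)
        b1 = int((row.end - 1) // resolution)
        for b in range(b0, min(b1, len(arr) - 1) + 1):
            lo = max(row.start, b * resolution)
            hi = min(row.end, (b + 1) * resolution)
            arr[b] += max(0, hi - lo)
    return out


def te_coverage(
    tes: pd.DataFrame, genome: dict[str, int], resolution: int = 20_000
) -> pd.DataFrame:
    """Per-bin coverage fraction per TE family; uncertain families dropped.

    Within-family records are merged first so overlapping annotations never
    count the same base twice; coverage is bounded in [0, 1].
    """
    frames = {}
    known = tes[tes["family"].isin(FAMILIES)]
    dropped = len(tes) - len(known)
    if dropped:
        logger.info("discarded %d TE records with uncertain family", dropped)
    for fam in FAMILIES:
        merged = merge_intervals(known[known["family"] == fam])
        per = _overlap_per_bin(merged, genome, resolution) if len(merged) else {
            c: np.zeros(int(np.ceil(L / resolution))) for c, L in genome.items()
        }
        frames[fam] = np.concatenate([per[c] for c in genome])
    widths = np.concatenate(
        [
            np.minimum(
                np.full(int(np.ceil(L / resolution)), resolution),
                L - resolution * np.arange(int(np.ceil(L / resolution))),
            )
            for c, L in genome.items()
        ]
    ).astype(float)
    cov = pd.DataFrame(frames)
    cov = cov.div(widths, axis=0).clip(0, 1)
    chroms = np.concatenate(
        [[c] * int(np.ceil(L / resolution)) for c, L in genome.items()]
    )
    bins = np.concatenate([np.arange(int(np.ceil(L / resolution))) for c, L in genome.items()])
    cov.index = pd.MultiIndex.from_arrays([chroms, bins], names=["chrom", "bin"])
    return cov


def te_ab_correlation(
    cov: pd.DataFrame, ab: np.ndarray, min_bins: int = 30
) -> pd.DataFrame:
    """Pearson correlation of each family's coverage with the AB index."""
    ab = np.asarray(ab, dtype=float)
    ok = np.isfinite(ab)
    if ok.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} usable bins")
    rows = {}
    for fam in cov.columns:
        x = cov[fam].to_numpy(dtype=float)[ok]
        y = ab[ok]
        if x.std() == 0 or y.std() == 0:
            rows[fam] = (np.nan, np.nan)
            continue
        res = pearsonr(x, y)
        rows[fam] = (float(res.statistic), float(res.pvalue))
    return pd.DataFrame(rows, index=["r", "p"]).T


# ---------------------------------------------------------------------------
# Contact-frequency filtering and correlation
# ---------------------------------------------------------------------------

@dataclass
class CiFilterSpec:
    lower: float
    removed_levels: list[int]
    retained: pd.DataFrame  # chrom, binA, binB, freq
    removed_fraction: float


def filter_bin_pairs(
    m: ContactMatrix, tads: TadSet, min_pairs: int = 100
) -> CiFilterSpec:
    """Two-stage filtering of intra-chromosomal contact frequencies.

    First drop bin pairs below the mean inter-domain contact frequency
    (background); then remove integer frequency levels carried by fewer
    than ``min_pairs`` bin pairs (scanning levels from the top downward).
    """
    recs = []
    inter_domain_vals = []
    for chrom in m.chroms():
        x = m.dense(chrom)
        n = x.shape[0]
        tad_id = np.full(n, -1)
        for t, (c, s, e) in enumerate(tads.domains):
            if c == chrom:
                b0, b1 = s // m.resolution, int(np.ceil(e / m.resolution))
                tad_id[b0:b1] = t
        iu = np.triu_indices(n, k=1)
        vals = x[iu]
        ta, tb = tad_id[iu[0]], tad_id[iu[1]]
        inter = (ta >= 0) & (tb >= 0) & (ta != tb)
        inter_domain_vals.append(vals[inter])
        recs.append((chrom, iu[0], iu[1], vals))
    inter_all = np.concatenate(inter_domain_vals) if inter_domain_vals else np.array([])
    if inter_all.size == 0:
        raise ValueError("no inter-domain bin pairs; lower threshold undefined")
    lower = float(inter_all.mean())

    frames = []
    total_pairs = 0
    for chrom, ia, ib, vals in recs:
        total_pairs += vals.size
        keep = vals >= lower
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "binA": ia[keep], "binB": ib[keep], "freq": vals[keep]}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        logger.warning("all bin pairs fall below the lower threshold")
        return CiFilterSpec(lower=lower, removed_levels=[], retained=df, removed_fraction=0.0)

    levels = np.sort(np.unique(np.round(df["freq"]).astype(int)))[::-1]
    removed = []
    for lev in levels:
        cnt = int((np.round(df["freq"]).astype(int) == lev).sum())
        if cnt < min_pairs:
            removed.append(int(lev))
    if removed:
        lev_col = np.round(df["freq"]).astype(int)
        before = len(df)
        df = df[~lev_col.isin(removed)].reset_index(drop=True)
        removed_fraction = (before - len(df)) / total_pairs
    else:
        removed_fraction = 0.0
    return CiFilterSpec(
        lower=lower,
        removed_levels=removed,
        retained=df,
        removed_fraction=float(removed_fraction),
    )


def te_contact_correlation(cov: pd.DataFrame, retained: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of per-pair TE proportion (mean of the two bins' coverage)
    against contact frequency, per family."""
    rows = {}
    for fam in cov.columns:
        track = cov[fam]
        xs, ys = [], []
        for row in retained.itertuples(index=False):
            try:
                a = track.loc[(row.chrom, row.binA)]
                b = track.loc[(row.chrom, row.binB)]
            except KeyError:
                continue
            xs.append((a + b) / 2)
            ys.append(row.freq)
        if len(xs) < 2 or np.std(xs) == 0 or np.std(ys) == 0:
            rows[fam] = (np.nan, np.nan)
            continue
        res = pearsonr(xs, ys)
        rows[fam] = (float(res.statistic), float(res.pvalue))
    return pd.DataFrame(rows, index=["r", "p"]).T


# ---------------------------------------------------------------------------
# Enhancer enrichment
# ---------------------------------------------------------------------------

def enhancer_enrichment(
    cov: pd.DataFrame,
    enhancers: pd.DataFrame,
    genome: dict[str, int],
    resolution: int = 20_000,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold = mean family coverage over enhancer bp / mean over the rest.

    Coverage is bp-weighted by each bin's enhancer overlap. If enhancers
    tile the whole genome the contrast vanishes and folds are 1. Bootstrap
    CIs resample bins.
    """
    if enhancers.empty:
        raise ValueError("empty enhancer set")
    merged = merge_intervals(enhancers)
    enh_bp = _overlap_per_bin(merged, genome, resolution)
    e = np.concatenate([enh_bp[c] for c in genome])
    widths = []
    for c, L in genome.items():
        nb = int(np.ceil(L / resolution))
        w = np.minimum(np.full(nb, resolution), L - resolution * np.arange(nb))
        widths.append(w)
    w = np.concatenate(widths).astype(float)
    non = np.maximum(w - e, 0.0)
    rng = np.random.default_rng(seed)
    rows = {}
    idx = np.arange(len(w))
    for fam in cov.columns:
        c = cov[fam].to_numpy(dtype=float)

        def fold(sel: np.ndarray) -> float:
            ew = e[sel].sum()
            nw = non[sel].sum()
            enh_mean = (e[sel] * c[sel]).sum() / ew if ew > 0 else np.nan
            non_mean = (non[sel] * c[sel]).sum() / nw if nw > 0 else enh_mean
            if not np.isfinite(enh_mean) or non_mean == 0:
                return np.nan
            return enh_mean / non_mean

        est = fold(idx)
        boots = [fold(rng.choice(idx, size=len(idx), replace=True)) for _ in range(n_boot)]
        boots = [b for b in boots if np.isfinite(b)]
        lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
        rows[fam] = (est, float(lo), float(hi))
    return pd.DataFrame(rows, index=["fold", "ci_lo", "ci_hi"]).T


def te_similarity_vs_divergence(
    coverage_by_species: pd.DataFrame, tree
) -> dict:
    """Spearman similarity of per-species TE-coverage vectors vs divergence
    time (Pearson r over species pairs)."""
    from .compartments import similarity_vs_divergence

    return similarity_vs_divergence(coverage_by_species, tree, method="spearman")
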