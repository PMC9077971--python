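"""A/B compartment calling, AB index, insulation, and conserved-state grouping.

Compartments are called per chromosome from the first principal component
of the observed/expected Pearson correlation matrix at 100 kb, oriented so
that PC1 correlates positively with gene density (compartment A). The AB
index refines the call to 20 kb: the normalized difference between a bin's
mean contact with A- versus B-labeled 100-kb bins, bounded in [-1, 1].

Cross-species conservation grouping is a documented stand-in for
phylogenetic HMM state discovery: K-means states over aligned per-bin
cross-species vectors, merged into groups when all pairwise cosine
similarities of state means reach the threshold (default 0.85), then
labeled conserved-A / conserved-B / not-conserved by the sign pattern of
the state means (or high/low/ambiguous against per-species medians for
insulation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, ranksums, spearmanr
from sklearn.cluster import KMeans

from . import phylo
from .matrix import ContactMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PC1 compartment calling
# ---------------------------------------------------------------------------

@dataclass
class CompartmentTrack:
    resolution: int
    pc1: dict[str, np.ndarray]  # per chromosome, NaN on masked bins
    ab_label: dict[str, np.ndarray]  # 'A' / 'B' / '' per bin
    pcs: dict[str, np.ndarray] = field(default_factory=dict)  # first 3 PCs
    low_confidence: bool = False


def _obs_exp(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    oe = np.zeros_like(x, dtype=float)
    for d in range(n):
        diag = np.diagonal(x, d)
        mu = diag.mean()
        if mu > 0:
            idx = np.arange(n - d)
            oe[idx, idx + d] = diag / mu
            oe[idx + d, idx] = diag / mu
    return oe


def call_compartments(
    m: ContactMatrix,
    gene_density: dict[str, np.ndarray],
    min_bins: int = 20,
) -> CompartmentTrack:
    """PC1-based A/B calling on a 100-kb matrix, A oriented by gene density."""
    pc1: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    pcs: dict[str, np.ndarray] = {}
    low_conf = False
    for chrom in m.chroms():
        x = m.dense(chrom, balanced=m.balance_weights is not None)
        n = x.shape[0]
        usable = x.sum(axis=1) > 0
        if usable.sum() < min_bins:
            logger.warning("chromosome %s has <%d usable bins; skipped", chrom, min_bins)
            continue
        sub = x[np.ix_(usable, usable)]
        oe = _obs_exp(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(oe)
        corr = np.nan_to_num(corr)
        vals, vecs = np.linalg.eigh(corr)
        order = np.argsort(vals)[::-1]
        top = vecs[:, order[:3]] * np.sqrt(np.clip(vals[order[:3]], 0, None))
        v1 = top[:, 0]
        gd = np.asarray(gene_density[chrom], dtype=float)[usable]
        if np.ptp(v1) < 1e-10:
            low_conf = True
        else:
            rho = spearmanr(v1, gd).statistic
            if np.isfinite(rho) and rho < 0:
                v1 = -v1
                top = top.copy()
                top[:, 0] = v1
        full = np.full(n, np.nan)
        full[usable] = v1
        pc1[chrom] = full
        lab = np.full(n, "", dtype=object)
        lab[usable] = np.where(v1 > 0, "A", "B")
        labels[chrom] = lab
        full3 = np.full((n, 3), np.nan)
        full3[usable] = top
        pcs[chrom] = full3
    if not pc1:
        raise ValueError("no chromosome had enough usable bins")
    return CompartmentTrack(
        resolution=m.resolution, pc1=pc1, ab_label=labels, pcs=pcs, low_confidence=low_conf
    )


# ---------------------------------------------------------------------------
# AB index at fine resolution
# ---------------------------------------------------------------------------

def ab_index(
    m: ContactMatrix,
    labels100k: dict[str, np.ndarray],
    label_resolution: int = 100_000,
) -> dict[str, np.ndarray]:
    """Per-fine-bin relative affinity for A vs B 100-kb bins, in [-1, 1].

    ab(i) = (mean contact with A bins - mean with B bins) / (sum of means);
    NaN where a bin touches neither class.
    """
    factor = label_resolution // m.resolution
    out: dict[str, np.ndarray] = {}
    for chrom in m.chroms():
        x = m.dense(chrom, balanced=m.balance_weights is not None)
        n = x.shape[0]
        lab = labels100k[chrom]
        fine_label = np.array(
            [lab[min(i // factor, len(lab) - 1)] for i in range(n)], dtype=object
        )
        is_a = fine_label == "A"
        is_b = fine_label == "B"
        vals = np.full(n, np.nan)
        for i in range(n):
            row = x[i]
            a_m = row[is_a].mean() if is_a.any() else 0.0
            b_m = row[is_b].mean() if is_b.any() else 0.0
            tot = a_m + b_m
            if tot > 0:
                vals[i] = (a_m - b_m) / tot
        out[chrom] = vals
    return out


# ---------------------------------------------------------------------------
# Insulation score
# ---------------------------------------------------------------------------

def insulation_score(
    m: ContactMatrix, window: int = 500_000
) -> dict[str, np.ndarray]:
    """Sliding-square insulation: log2 of the mean contact in the
    (window x window) square crossing each bin over the chromosome mean of
    those window means. NaN within a window of the chromosome edge."""
    w = window // m.resolution
    if w < 1:
        raise ValueError("window must cover at least one bin")
    out: dict[str, np.ndarray] = {}
    for chrom in m.chroms():
        x = m.dense(chrom, balanced=m.balance_weights is not None)
        n = x.shape[0]
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            raw[i] = x[i - w : i, i + 1 : i + w + 1].mean()
        valid = np.isfinite(raw) & (raw > 0)
        vals = np.full(n, np.nan)
        if valid.any():
            mu = raw[valid].mean()
            vals[valid] = np.log2(raw[valid] / mu)
        out[chrom] = vals
    return out


# ---------------------------------------------------------------------------
# Cross-species state grouping (K-means + cosine merge)
# ---------------------------------------------------------------------------

@dataclass
class StateAssignment:
    states: np.ndarray  # per aligned bin, 0..K-1
    state_means: np.ndarray  # K x n_species
    state_group: np.ndarray  # per state, group id
    group_labels: dict[int, str]  # group id -> CA/CB/NC or CHI/CLI/AI
    group_mb: dict[str, float]
    group_pct: dict[str, float]
    kind: str  # 'ab' or 'is'


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def cluster_states(
    aligned: pd.DataFrame,
    k: int = 30,
    seed: int = 0,
    cos_threshold: float = 0.85,
    kind: str = "ab",
    bin_mb: float = 0.1,
) -> StateAssignment:
    """K-means state discovery over aligned cross-species bin vectors.

    States whose mean vectors are pairwise cosine-similar (>= threshold,
    against every member, earliest group wins) are merged into one group.
    For ``kind='ab'`` a group is CA if every member state mean is positive
    in every species, CB if all negative, NC otherwise; for ``kind='is'``
    the threshold is the per-species median (CHI / CLI / AI).

    This is the documented stand-in for phylogenetic HMM state discovery;
    outputs are labeled accordingly by the ``kind``/``stand_in`` metadata.
    """
    if aligned.shape[1] < 3:
        raise ValueError("need aligned values for at least 3 species")
    x = aligned.to_numpy(dtype=float)
    if k < 3:
        raise ValueError("K must be >= 3")
    if k > len(np.unique(x, axis=0)):
        raise ValueError("K exceeds the number of distinct aligned bins")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    states = km.fit_predict(x)
    means = km.cluster_centers_

    # greedy cosine grouping, earliest-indexed group wins ties
    group_of = np.full(k, -1)
    groups: list[list[int]] = []
    for s in range(k):
        placed = False
        for gi, members in enumerate(groups):
            if all(_cosine(means[s], means[t]) >= cos_threshold for t in members):
                members.append(s)
                group_of[s] = gi
                placed = True
                break
        if not placed:
            groups.append([s])
            group_of[s] = len(groups) - 1

    if kind == "ab":
        thresh = np.zeros(aligned.shape[1])
        pos_lab, neg_lab, mix_lab = "CA", "CB", "NC"
    elif kind == "is":
        thresh = np.median(x, axis=0)
        pos_lab, neg_lab, mix_lab = "CHI", "CLI", "AI"
    else:
        raise ValueError("kind must be 'ab' or 'is'")
    group_labels: dict[int, str] = {}
    for gi, members in enumerate(groups):
        sub = means[members]  # (n_member, n_species)
        if np.all(sub > thresh):
            group_labels[gi] = pos_lab
        elif np.all(sub < thresh):
            group_labels[gi] = neg_lab
        else:
            group_labels[gi] = mix_lab

    group_mb: dict[str, float] = {}
    for lab in {pos_lab, neg_lab, mix_lab}:
        sel = np.isin(states, [s for s in range(k) if group_labels[group_of[s]] == lab])
        group_mb[lab] = float(sel.sum() * bin_mb)
    total = sum(group_mb.values())
    group_pct = {lab: round(mb / total * 100, 2) if total else 0.0 for lab, mb in group_mb.items()}
    return StateAssignment(
        states=states,
        state_means=means,
        state_group=group_of,
        group_labels=group_labels,
        group_mb=group_mb,
        group_pct=group_pct,
        kind=kind,
    )


def group_summary(group_mb: dict[str, float], total_mb: float) -> dict[str, float]:
    """Percentage of the aligned span per group, 2 decimal places."""
    if sum(group_mb.values()) > total_mb * (1 + 1e-9):
        raise ValueError("group Mb totals exceed the aligned span")
    return {lab: round(mb / total_mb * 100, 2) for lab, mb in group_mb.items()}


# ---------------------------------------------------------------------------
# Cross-tissue consistency
# ---------------------------------------------------------------------------

def cross_tissue_consistency(
    conserved_labels: np.ndarray,
    other_tracks: list[np.ndarray],
    n_perm: int = 100,
    seed: int = 0,
    positive_label: str = "CA",
    negative_label: str = "CB",
    kind: str = "ab",
) -> dict:
    """Fraction of conserved-state bins retaining their state in other
    tissue tracks, against a random-reassignment control.

    ``conserved_labels`` gives the per-aligned-bin group label; a track
    retains a CA (CHI) bin when its value is above zero (its median), and a
    CB (CLI) bin when below. Controls shuffle each track ``n_perm`` times.
    Significance: two-sided Wilcoxon rank-sum of observed vs control
    fractions.
    """
    if n_perm < 10:
        warnings.warn("n_perm < 10: permutation p-value is unstable")
    rng = np.random.default_rng(seed)
    labels = np.asarray(conserved_labels)

    def retention(track: np.ndarray) -> float:
        t = np.asarray(track, dtype=float)
        cut = np.median(t) if kind == "is" else 0.0
        pos = labels == positive_label
        neg = labels == negative_label
        hits = (t[pos] > cut).sum() + (t[neg] < cut).sum()
        denom = pos.sum() + neg.sum()
        return float(hits / denom) if denom else float("nan")

    observed = [retention(t) for t in other_tracks]
    controls = []
    for t in other_tracks:
        t = np.asarray(t, dtype=float)
        for _ in range(n_perm):
            controls.append(retention(rng.permutation(t)))
    stat = ranksums(observed, controls)
    return {
        "observed": observed,
        "control_mean": float(np.mean(controls)),
        "controls": controls,
        "p_value": float(stat.pvalue),
    }


# ---------------------------------------------------------------------------
# Similarity vs divergence time
# ---------------------------------------------------------------------------

def similarity_vs_divergence(
    tracks: pd.DataFrame,
    tree,
    method: str = "cosine",
) -> dict:
    """Pairwise track similarity, average-linkage tree, and the Pearson
    correlation of similarity against divergence time.

    ``tracks`` is aligned-bin x species. Identical tracks everywhere give
    zero-variance similarities and an NA correlation.
    """
    species = list(tracks.columns)
    if len(species) < 3:
        raise ValueError("need >= 3 species")
    x = tracks.to_numpy(dtype=float)
    sim = pd.DataFrame(np.eye(len(species)), index=species, columns=species)
    for i, a in enumerate(species):
        for j in range(i + 1, len(species)):
            b = species[j]
            mask = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
            if method == "cosine":
                s = _cosine(x[mask, i], x[mask, j])
            elif method == "spearman":
                s = float(spearmanr(x[mask, i], x[mask, j]).statistic)
            else:
                raise ValueError("method must be 'cosine' or 'spearman'")
            sim.loc[a, b] = sim.loc[b, a] = s
    div = phylo.divergence_times(tree)
    sims = []
    divs = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            sims.append(sim.loc[a, b])
            divs.append(div[(a, b)])
    if np.std(sims) == 0 or np.std(divs) == 0:
        r, p = float("nan"), float("nan")
    else:
        res = pearsonr(sims, divs)
        r, p = float(res.statistic), float(res.pvalue)
    dist = 1 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return {"similarity": sim, "linkage": z, "pearson_r": r, "p_value": p}
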