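"""Sequence- and expression-level conservation analytics around TADs.

Covers the CTCF motif-orientation ratio 3DR (median convergent spacing
over median divergent spacing among contiguous motif pairs), CNE
distribution profiles across enlarged TADs, intra- vs inter-TAD ortholog
conservation scores, and co-expression of gene pairs stratified by gene
distance and shared-TAD membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tads import Interval, TadSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# 3DR
# ---------------------------------------------------------------------------

@dataclass
class MotifSpacing:
    convergent: np.ndarray  # distances of contiguous + ... - pairs
    divergent: np.ndarray  # distances of contiguous - ... + pairs
    ratio_3dr: float


def compute_3dr(
    motifs: pd.DataFrame,
    regions: list[Interval] | None = None,
    score_quantile: float = 0.7,
) -> MotifSpacing:
    """3DR = median(d_conv) / median(d_div) over contiguous motif pairs.

    Motifs below the ``score_quantile`` of the score distribution are
    dropped first; when ``regions`` are given only motifs inside them
    survive. Every adjacent surviving pair on a chromosome is classified:
    (+,-) convergent, (-,+) divergent; like-strand pairs contribute to
    neither median. Distances are start-to-start.
    """
    df = motifs
    if score_quantile > 0 and len(df):
        cut = df["score"].quantile(score_quantile)
        df = df[df["score"] >= cut]
    if regions is not None:
        keep = np.zeros(len(df), dtype=bool)
        mids = ((df["start"] + df["end"]) // 2).to_numpy()
        chroms = df["chrom"].to_numpy()
        for chrom, s, e in regions:
            keep |= (chroms == chrom) & (mids >= s) & (mids < e)
        df = df[keep]
    conv, div = [], []
    for _, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        strands = sub["strand"].to_numpy()
        for i in range(len(sub) - 1):
            d = float(starts[i + 1] - starts[i])
            if d <= 0:
                continue
            pair = (strands[i], strands[i + 1])
            if pair == ("+", "-"):
                conv.append(d)
            elif pair == ("-", "+"):
                div.append(d)
    if not conv or not div:
        raise ValueError("3DR undefined: need at least one convergent and one divergent pair")
    conv_a = np.array(conv)
    div_a = np.array(div)
    return MotifSpacing(
        convergent=conv_a,
        divergent=div_a,
        ratio_3dr=float(np.median(conv_a) / np.median(div_a)),
    )


def tad_border_regions(tads: TadSet, pad: int = 20_000) -> list[Interval]:
    """Each boundary interval extended by ``pad`` on each side (40 kb of
    added width in total for the default)."""
    return [(c, max(0, s - pad), e + pad) for c, s, e in tads.boundaries]


# ---------------------------------------------------------------------------
# CNE profile across enlarged TADs
# ---------------------------------------------------------------------------

@dataclass
class CneProfile:
    profile: np.ndarray  # 40 bins: 10 left flank, 20 interior, 10 right flank
    n_tads: int
    interior_mean: float
    flank_mean: float


def cne_profile(
    tads: TadSet,
    cnes: pd.DataFrame,
    min_score: float = 0.95,
    min_len: int = 200,
) -> CneProfile:
    """Mean CNE count per relative bin across TADs enlarged 50% per side.

    CNEs are filtered (score >= min_score, length > min_len) and assigned
    to the bin containing their midpoint. Each TAD of length L spans 40
    uniform bins of width L/20 over [start - L/2, end + L/2).
    """
    f = cnes[(cnes["score"] >= min_score) & ((cnes["end"] - cnes["start"]) > min_len)]
    mids = ((f["start"] + f["end"]) // 2).to_numpy()
    chroms = f["chrom"].to_numpy()
    acc = np.zeros(40)
    n_used = 0
    for chrom, s, e in tads.domains:
        L = e - s
        width = L / 20.0
        if width < 1:
            logger.info("TAD %s:%d-%d too short for 20 bins; skipped", chrom, s, e)
            continue
        lo = s - L / 2.0
        sel = (chroms == chrom) & (mids >= lo) & (mids < e + L / 2.0)
        idx = np.floor((mids[sel] - lo) / width).astype(int)
        idx = np.clip(idx, 0, 39)
        np.add.at(acc, idx, 1)
        n_used += 1
    if n_used == 0:
        raise ValueError("no TAD wide enough for the 20-bin profile")
    profile = acc / n_used
    interior = profile[10:30].mean()
    flank = np.concatenate([profile[:10], profile[30:]]).mean()
    return CneProfile(
        profile=profile, n_tads=n_used, interior_mean=float(interior), flank_mean=float(flank)
    )


# ---------------------------------------------------------------------------
# Intra/inter-TAD ortholog conservation
# ---------------------------------------------------------------------------

@dataclass
class TadConservationScore:
    intra_score: float  # % of reference TADs with >=1 intra-conserved pair
    inter_score: float  # % of reference TADs in >=1 inter-conserved pair
    per_tad_intra: np.ndarray
    per_tad_inter: np.ndarray
    n_ref_tads: int
    # pair-level fractions on a common basis: % of intra-TAD pairs conserved
    # and % of inter-TAD pairs still co-chromosomal in the target (the
    # per-TAD participation percentages saturate when a genome has few
    # rearrangements, so cross-class comparisons use these)
    intra_pair_fraction: float = float("nan")
    inter_pair_fraction: float = float("nan")


def _tad_of(tads: list[Interval], chrom: str, pos: int) -> int:
    for t, (c, s, e) in enumerate(tads):
        if c == chrom and s <= pos < e:
            return t
    return -1


def tad_conservation_scores(
    ref_tads: TadSet,
    target_tads: TadSet,
    orthologs: pd.DataFrame,
    ref_species: str,
    target_species: str,
    mode: str = "consecutive",
) -> TadConservationScore:
    """Intra- and inter-TAD conservation of single-copy ortholog pairs.

    A gene pair (consecutive orthologs in reference gene order, or all
    within-TAD pairs for ``mode='all_pairs'``) is intra-conserved when both
    genes share one TAD in the reference AND one TAD in the target; it is
    inter-conserved when the genes sit in different reference TADs but on
    one chromosome in both species. Scores are percentages of reference
    TADs (those containing at least one ortholog) with >=1 qualifying pair.
    """
    ref = orthologs[orthologs["species"] == ref_species]
    tgt = orthologs[orthologs["species"] == target_species].set_index("group")
    shared = ref[ref["group"].isin(tgt.index)]
    if shared.empty:
        raise ValueError("no shared single-copy orthologs")
    rt = ref_tads.domains
    tt = target_tads.domains

    gene_tads = {}  # group -> (ref chrom, ref tad, tgt chrom, tgt tad)
    tads_with_gene = set()
    for row in shared.itertuples(index=False):
        r_tad = _tad_of(rt, row.chrom, row.start)
        t_row = tgt.loc[row.group]
        t_tad = _tad_of(tt, t_row["chrom"], t_row["start"])
        gene_tads[row.group] = (row.chrom, r_tad, t_row["chrom"], t_tad)
        if r_tad >= 0:
            tads_with_gene.add(r_tad)
    if not tads_with_gene:
        raise ValueError("no reference TAD contains an ortholog")

    pairs: list[tuple[str, str]] = []
    for chrom, sub in shared.groupby("chrom", sort=False):
        order = sub.sort_values("start")["group"].tolist()
        if mode == "consecutive":
            pairs.extend(zip(order, order[1:]))
        elif mode == "all_pairs":
            for i in range(len(order)):
                for j in range(i + 1, len(order)):
                    pairs.append((order[i], order[j]))
        else:
            raise ValueError("mode must be 'consecutive' or 'all_pairs'")

    n_ref = len(rt)
    intra = np.zeros(n_ref, dtype=bool)
    inter = np.zeros(n_ref, dtype=bool)
    n_intra_pairs = n_intra_cons = 0
    n_inter_pairs = n_inter_cons = 0
    for ga, gb in pairs:
        rc_a, rt_a, tc_a, tt_a = gene_tads[ga]
        rc_b, rt_b, tc_b, tt_b = gene_tads[gb]
        if rt_a >= 0 and rt_a == rt_b:
            n_intra_pairs += 1
            if tt_a >= 0 and tt_a == tt_b:
                intra[rt_a] = True
                n_intra_cons += 1
        elif rt_a >= 0 and rt_b >= 0 and rt_a != rt_b and rc_a == rc_b:
            n_inter_pairs += 1
            if tc_a == tc_b:
                inter[rt_a] = True
                inter[rt_b] = True
                n_inter_cons += 1
    denom = np.zeros(n_ref, dtype=bool)
    denom[list(tads_with_gene)] = True
    n_den = int(denom.sum())
    return TadConservationScore(
        intra_score=float(intra[denom].sum() / n_den * 100),
        inter_score=float(inter[denom].sum() / n_den * 100),
        per_tad_intra=intra,
        per_tad_inter=inter,
        n_ref_tads=n_den,
        intra_pair_fraction=(
            100 * n_intra_cons / n_intra_pairs if n_intra_pairs else float("nan")
        ),
        inter_pair_fraction=(
            100 * n_inter_cons / n_inter_pairs if n_inter_pairs else float("nan")
        ),
    )


# ---------------------------------------------------------------------------
# Co-expression by gene distance
# ---------------------------------------------------------------------------

def coexpression_by_distance(
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    tads: TadSet,
    r_cutoff: float = 0.9,
    max_d: int = 3,
) -> pd.DataFrame:
    """Fraction of highly correlated gene pairs, same-TAD vs all, per gene
    distance d (number of intervening genes; d=0 means adjacent).

    ``expr`` is gene x replicate TPM (>= 3 replicates); correlations use
    log2(TPM + 1) across replicates. Pairs straddling a TAD border never
    count as same-TAD.
    """
    if expr.shape[1] < 3:
        raise ValueError("co-expression requires at least 3 biological replicates")
    logx = np.log2(expr.to_numpy(dtype=float) + 1.0)
    gene_idx = {g: i for i, g in enumerate(expr.index)}
    rows = []
    for d in range(max_d + 1):
        n_all = n_all_hit = n_same = n_same_hit = 0
        for chrom, sub in genes.groupby("chrom", sort=False):
            order = sub.sort_values("start")
            names = order["gene"].tolist()
            starts = order["start"].tolist()
            for i in range(len(names) - d - 1):
                a, b = names[i], names[i + d + 1]
                if a not in gene_idx or b not in gene_idx:
                    continue
                va, vb = logx[gene_idx[a]], logx[gene_idx[b]]
                if va.std() == 0 or vb.std() == 0:
                    continue
                r = float(np.corrcoef(va, vb)[0, 1])
                hit = r > r_cutoff
                n_all += 1
                n_all_hit += hit
                ta = _tad_of(tads.domains, chrom, starts[i])
                tb = _tad_of(tads.domains, chrom, starts[i + d + 1])
                if ta >= 0 and ta == tb:
                    n_same += 1
                    n_same_hit += hit
        rows.append(
            {
                "d": d,
                "frac_same_tad": n_same_hit / n_same if n_same else np.nan,
                "frac_all": n_all_hit / n_all if n_all else np.nan,
                "n_same_tad": n_same,
                "n_all": n_all,
            }
        )
    return pd.DataFrame(rows).set_index("d")
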