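"""Directionality-index TAD calling and cross-species boundary conservation.

DI contrasts a bin's upstream and downstream contact sums inside a fixed
window (default 2 Mb at 20 kb bins):

    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E),  E = (A + B) / 2

A 3-state Gaussian HMM segments the DI track into downstream-bias / none /
upstream-bias states; a domain runs from the start of a downstream-bias
run to the end of the following upstream-bias run. Inter-domain gaps below
400 kb are boundaries, larger gaps unorganized chromatin. Boundary
conservation across species uses ortholog-anchored coordinate mapping and
the <40 kb (conserved) / >100 kb (non-conserved) distance rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .matrix import ContactMatrix

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


@dataclass
class DITrack:
    resolution: int
    window: int
    di: dict[str, np.ndarray]


@dataclass
class TadSet:
    resolution: int
    domains: list[Interval]
    boundaries: list[Interval]
    unorganized: list[Interval]
    converged: bool = True

    def domains_on(self, chrom: str) -> list[Interval]:
        return [d for d in self.domains if d[0] == chrom]

    def boundary_midpoints(self) -> list[tuple[str, int]]:
        return [(c, (s + e) // 2) for c, s, e in self.boundaries]


# ---------------------------------------------------------------------------
# Directionality index
# ---------------------------------------------------------------------------

def directionality_index(m: ContactMatrix, window: int = 2_000_000) -> DITrack:
    """Per-bin DI over ``window`` bp up- and downstream (diagonal excluded)."""
    if window < 2 * m.resolution:
        raise ValueError("window must span at least two bins")
    w = window // m.resolution
    out: dict[str, np.ndarray] = {}
    for chrom in m.chroms():
        x = m.dense(chrom, balanced=m.balance_weights is not None)
        n = x.shape[0]
        di = np.zeros(n)
        for i in range(n):
            a = x[i, max(0, i - w) : i].sum()
            b = x[i, i + 1 : min(n, i + w + 1)].sum()
            e = (a + b) / 2.0
            if e > 0 and a != b:
                di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
        out[chrom] = di
    return DITrack(resolution=m.resolution, window=window, di=out)


# ---------------------------------------------------------------------------
# HMM TAD calling
# ---------------------------------------------------------------------------

def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(value, start, end_exclusive) for each constant run."""
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((int(states[start]), start, i))
            start = i
    return out


def call_tads(
    di: DITrack,
    seed: int = 0,
    n_restarts: int = 5,
    min_run: int = 3,
    boundary_max_gap: int = 400_000,
) -> TadSet:
    """Segment DI into TADs with a 3-state Gaussian HMM.

    DI is standardized before fitting, making the call invariant to global
    scaling. States are ranked by emission mean: highest = downstream bias
    (domain start), lowest = upstream bias (domain end). A biased run must
    span ``min_run`` bins to open or close a domain (noise guard). Gaps
    between domains below ``boundary_max_gap`` are boundaries; larger gaps
    unorganized.
    """
    res = di.resolution
    chroms = list(di.di)
    seqs = [np.asarray(di.di[c], dtype=float) for c in chroms]
    concat = np.concatenate(seqs)
    if np.allclose(concat, 0):
        return TadSet(resolution=res, domains=[], boundaries=[], unorganized=[])
    # per-chromosome signed normal-scores transform: DI is heavy-tailed
    # (quadratic in count deviations), which starves the Gaussian emissions;
    # rank-normalizing preserves the sign/order structure and is invariant
    # to global scaling of DI
    from scipy.stats import norm, rankdata

    def normal_scores(s: np.ndarray) -> np.ndarray:
        if np.allclose(s, 0):
            return np.zeros_like(s)
        r = rankdata(s) / (len(s) + 1)
        out = norm.ppf(r)
        # keep exact zeros (no information) at zero
        out[s == 0] = 0.0
        return out

    scaled = [normal_scores(s) for s in seqs]
    obs = np.concatenate(scaled).reshape(-1, 1)
    lengths = [len(s) for s in seqs]

    best = None
    best_score = -np.inf
    converged = False
    rng = np.random.default_rng(seed)
    for r in range(n_restarts):
        model = GaussianHMM(
            n_components=3,
            covariance_type="diag",
            n_iter=200,
            random_state=seed + r,
            init_params="stc",
        )
        # biased-down / neutral / biased-up emission means, jittered per restart
        model.means_ = np.array([[-1.0], [0.0], [1.0]]) + rng.normal(0, 0.1 * r, (3, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(obs, lengths)
                score = model.score(obs, lengths)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if score > best_score:
            best_score = score
            best = model
            converged = converged or model.monitor_.converged
    if best is None:
        raise RuntimeError("HMM fitting failed in every restart")
    if not converged:
        logger.warning("HMM EM did not converge; using best restart")
    order = np.argsort(best.means_.ravel())
    rank = np.empty(3, dtype=int)
    rank[order] = [-1, 0, 1]  # lowest mean -> upstream bias (-1), highest -> +1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        decoded = best.predict(obs, lengths)
    decoded = rank[decoded]

    domains: list[Interval] = []
    pos = 0
    di_by_chrom = dict(zip(chroms, seqs))
    for chrom, L in zip(chroms, lengths):
        states = decoded[pos : pos + L]
        pos += L
        runs = [r for r in _runs(states) if r[0] == 0 or (r[2] - r[1]) >= min_run]
        open_start = None
        for val, s, e in runs:
            if val == 1 and open_start is None:
                open_start = s
            elif val == -1 and open_start is not None:
                domains.append((chrom, open_start * res, e * res))
                open_start = None

    # second pass: the EM decode occasionally smooths over a genuine
    # boundary inside a long domain; split where a sustained strongly
    # negative DI stretch flips to a sustained strongly positive one
    scored = dict(zip(chroms, scaled))

    def split_points(chrom: str, lo: int, hi: int, w: int = 3, z: float = 0.6) -> list[int]:
        s = scored[chrom]
        cuts = []
        j = lo + w
        while j <= hi - w:
            left = s[j - w : j].mean()
            right = s[j : j + w].mean()
            if left < -z and right > z and s[j - 1] < 0 <= s[j]:
                cuts.append(j)
                j += w
            else:
                j += 1
        return cuts

    refined_domains: list[Interval] = []
    for chrom, s0, e0 in domains:
        b0, b1 = s0 // res, e0 // res
        cuts = split_points(chrom, b0, b1)
        edges = [b0] + cuts + [b1]
        for a, b in zip(edges[:-1], edges[1:]):
            refined_domains.append((chrom, a * res, b * res))
    domains = refined_domains

    def refine(chrom: str, lo_bin: int, hi_bin: int) -> list[int]:
        """Strong negative-to-positive DI crossings inside the gap.

        A gap between domains can hold more than one boundary when the
        decoder skipped a short domain; every crossing whose contrast is a
        substantial fraction of the sharpest one becomes a boundary.
        """
        track = di_by_chrom[chrom]
        found: list[tuple[int, float]] = []
        for j in range(max(lo_bin, 1), min(hi_bin + 2, len(track))):
            if track[j - 1] < 0 <= track[j]:
                found.append((j, track[j] - track[j - 1]))
        if not found:
            return []
        best = max(c for _, c in found)
        kept: list[int] = []
        for j, c in sorted(found, key=lambda t: -t[1]):
            if c >= 0.3 * best and all(abs(j - k) >= 3 for k in kept):
                kept.append(j)
        return sorted(kept)

    boundaries: list[Interval] = []
    unorganized: list[Interval] = []
    for (c1, _, e1), (c2, s2, _) in zip(domains, domains[1:]):
        if c1 != c2 or s2 < e1:
            continue
        if s2 - e1 < boundary_max_gap:
            js = refine(c1, e1 // res, s2 // res)
            if js:
                boundaries.extend((c1, (j - 1) * res, (j + 1) * res) for j in js)
            else:
                boundaries.append((c1, e1, s2))
        else:
            unorganized.append((c1, e1, s2))
    return TadSet(
        resolution=res,
        domains=domains,
        boundaries=boundaries,
        unorganized=unorganized,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Profiles around boundaries
# ---------------------------------------------------------------------------

def insulation_profile(
    is_track: dict[str, np.ndarray],
    boundary_classes: dict[str, list[Interval]],
    flank: int = 300_000,
    resolution: int = 20_000,
) -> pd.DataFrame:
    """Mean insulation per offset bin in +/-flank around boundary midpoints,
    one column per boundary class (e.g. conserved vs gained)."""
    if flank % resolution:
        raise ValueError("flank must be a multiple of the resolution")
    w = flank // resolution
    offsets = np.arange(-w, w + 1)
    cols = {}
    for cls, bounds in boundary_classes.items():
        if not bounds:
            warnings.warn(f"boundary class {cls!r} is empty; omitted")
            continue
        acc = np.zeros(2 * w + 1)
        cnt = np.zeros(2 * w + 1)
        for chrom, s, e in bounds:
            if chrom not in is_track:
                continue
            track = is_track[chrom]
            mid = ((s + e) // 2) // resolution
            for k, off in enumerate(offsets):
                i = mid + off
                if 0 <= i < len(track) and np.isfinite(track[i]):
                    acc[k] += track[i]
                    cnt[k] += 1
        with np.errstate(invalid="ignore"):
            cols[cls] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(cols, index=offsets * resolution)


def tss_enrichment(
    boundaries: list[Interval],
    tss: list[tuple[str, int]],
    flank: int = 500_000,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """TSS density per offset bin around boundary midpoints."""
    w = flank // bin_size
    offsets = np.arange(-w, w)
    counts = np.zeros(2 * w)
    if not boundaries:
        warnings.warn("empty boundary set; returning empty profile")
        return pd.DataFrame({"density": counts}, index=offsets * bin_size)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, p in tss:
        tss_by_chrom.setdefault(chrom, [])
        tss_by_chrom[chrom].append(p)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    for chrom, s, e in boundaries:
        mid = (s + e) // 2
        pos = tss_by_chrom.get(chrom)
        if pos is None:
            continue
        rel = pos - mid
        sel = rel[(rel >= -flank) & (rel < flank)]
        idx = (sel + flank) // bin_size
        np.add.at(counts, idx.astype(int), 1)
    return pd.DataFrame({"density": counts / len(boundaries)}, index=offsets * bin_size)


# ---------------------------------------------------------------------------
# Cross-species boundary conservation
# ---------------------------------------------------------------------------

@dataclass
class BoundaryConservation:
    query_species: str
    labels: list[str]  # per query boundary: conserved / gained / lost-in-X / unknown
    per_species: pd.DataFrame  # boundary x species pairwise label
    distances: pd.DataFrame  # boundary x species mapped distance (bp)
    boundaries: list[Interval] = field(default_factory=list)


def classify_boundaries(
    query_species: str,
    all_tads: dict[str, TadSet],
    world,
    conserved_dist: int = 40_000,
    nonconserved_dist: int = 100_000,
    most_fraction: float = 0.5,
) -> BoundaryConservation:
    """Label each query boundary conserved / gained / lost / unknown.

    Each query boundary midpoint is mapped to every other species through
    the world's ortholog anchors; the pairwise label follows the distance
    rule (strictly < ``conserved_dist`` conserved, strictly >
    ``nonconserved_dist`` non-conserved, else unknown). Overall: conserved
    when conserved in all mappable species; gained when non-conserved in
    all; lost-in-X when conserved in more than ``most_fraction`` of species
    but non-conserved in X.
    """
    if len(all_tads) < 3:
        raise ValueError("need called TADs for at least 3 species")
    others = [s for s in all_tads if s != query_species]
    q_bounds = all_tads[query_species].boundaries
    rows = []
    dists = []
    labels = []
    for chrom, s, e in q_bounds:
        mid = (s + e) // 2
        per = {}
        dd = {}
        for sp_name in others:
            try:
                mapped = world.map_position(query_species, sp_name, chrom, mid)
            except KeyError:
                per[sp_name] = "unknown"
                dd[sp_name] = np.nan
                continue
            mids = [
                (bs + be) // 2
                for bc, bs, be in all_tads[sp_name].boundaries
                if bc == chrom
            ]
            if not mids:
                per[sp_name] = "unknown"
                dd[sp_name] = np.nan
                continue
            d = float(np.min(np.abs(np.array(mids) - mapped)))
            dd[sp_name] = d
            if d < conserved_dist:
                per[sp_name] = "conserved"
            elif d > nonconserved_dist:
                per[sp_name] = "non-conserved"
            else:
                per[sp_name] = "unknown"
        rows.append(per)
        dists.append(dd)
        judged = [v for v in per.values() if v != "unknown"]
        if not judged:
            labels.append("unknown")
        elif all(v == "conserved" for v in judged) and len(judged) == len(others):
            labels.append("conserved")
        elif all(v == "non-conserved" for v in per.values()):
            labels.append("gained")
        else:
            n_cons = sum(v == "conserved" for v in per.values())
            lost_in = [s for s, v in per.items() if v == "non-conserved"]
            if n_cons > most_fraction * len(others) and lost_in:
                labels.append("lost-in-" + ",".join(sorted(lost_in)))
            else:
                labels.append("unknown")
    return BoundaryConservation(
        query_species=query_species,
        labels=labels,
        per_species=pd.DataFrame(rows),
        distances=pd.DataFrame(dists),
        boundaries=list(q_bounds),
    )
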