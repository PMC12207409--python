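"""Aggregate analyses: loop pileups (APA), extended-loop construction,
orientation-stratified pairing of regions, and rescaled domain pileups.

"Extended loops" are in-silico recombinations of the 5' and 3' anchors of
primary loops at 1.5-3 Mb separation: when cohesin is stabilised on
chromatin these anchor combinations gain contact frequency even though they
were never called as loops in unperturbed cells. Pairing regions of stalled
cohesin (RSCs) by the orientation of the unique CTCF motif they carry
stratifies such putative loops into convergent / tandem / divergent classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import oe_matrix
from .matrix import ContactMatrix

__all__ = [
    "Pileup",
    "make_extended_loops",
    "pair_regions_by_orientation",
    "aggregate_loop_pileup",
    "rescaled_domain_pileup",
]

LOOP_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def validate_loops(loops: pd.DataFrame) -> pd.DataFrame:
    df = loops.copy()
    if (df["chrom1"] != df["chrom2"]).any():
        raise ValueError("loop lists must be intra-chromosomal")
    mid1 = (df["start1"] + df["end1"]) / 2
    mid2 = (df["start2"] + df["end2"]) / 2
    if (mid1 >= mid2).any():
        raise ValueError("anchor1 midpoint must lie upstream of anchor2 midpoint")
    return df


@dataclass
class Pileup:
    """Mean O/E window over loop pixels or rescaled domains."""

    grid: np.ndarray
    n_loops_used: int
    enrichment: float


def make_extended_loops(
    primary: pd.DataFrame,
    min_dist: float = 1.5e6,
    max_dist: float = 3e6,
    dedup_binsize: int = 5000,
) -> pd.DataFrame:
    """All (5' anchor of loop i, 3' anchor of loop j) recombinations on the
    same chromosome with midpoint separation in [min_dist, max_dist],
    deduplicated on (chrom, bin1, bin2) at ``dedup_binsize``.
    """
    primary = validate_loops(primary)
    if min_dist > max_dist:
        warnings.warn("min_dist > max_dist; returning empty loop list")
        return pd.DataFrame(columns=LOOP_COLS)
    out = []
    for chrom, grp in primary.groupby("chrom1"):
        a5 = grp[["start1", "end1"]].to_numpy()
        a3 = grp[["start2", "end2"]].to_numpy()
        m5 = a5.mean(axis=1)
        m3 = a3.mean(axis=1)
        sep = m3[None, :] - m5[:, None]
        ii, jj = np.where((sep >= min_dist) & (sep <= max_dist))
        for i, j in zip(ii, jj):
            out.append((chrom, *a5[i].astype(int), chrom, *a3[j].astype(int)))
    df = pd.DataFrame(out, columns=LOOP_COLS)
    if len(df):
        key1 = ((df["start1"] + df["end1"]) // 2 // dedup_binsize).astype(int)
        key2 = ((df["start2"] + df["end2"]) // 2 // dedup_binsize).astype(int)
        df = df.loc[~pd.DataFrame({"c": df["chrom1"], "b1": key1, "b2": key2}).duplicated()]
        df = df.reset_index(drop=True)
    return df


def pair_regions_by_orientation(
    regions: pd.DataFrame,
    motifs: pd.DataFrame,
    min_dist: float,
    max_dist: float,
) -> dict[str, pd.DataFrame]:
    """Pair regions carrying CTCF motifs of exactly one orientation.

    Regions overlapping motifs of both orientations (or none) are excluded.
    Same-chromosome pairs with midpoint separation in [min_dist, max_dist]
    are classed: (+ upstream, − downstream) convergent; equal strands tandem;
    (− upstream, + downstream) divergent.
    """
    oriented = []
    for _, reg in regions.iterrows():
        hit = motifs[
            (motifs["chrom"] == reg["chrom"])
            & (motifs["end"] > reg["start"])
            & (motifs["start"] < reg["end"])
        ]
        strands = set(hit["strand"])
        if strands in ({"+"}, {"-"}):
            oriented.append((reg["chrom"], reg["start"], reg["end"], strands.pop()))
    odf = pd.DataFrame(oriented, columns=["chrom", "start", "end", "strand"])
    classes: dict[str, list] = {"convergent": [], "tandem": [], "divergent": []}
    for chrom, grp in odf.groupby("chrom"):
        grp = grp.sort_values("start").reset_index(drop=True)
        mids = (grp["start"] + grp["end"]).to_numpy() / 2
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                sep = mids[j] - mids[i]
                if not (min_dist <= sep <= max_dist):
                    continue
                su, sd = grp.loc[i, "strand"], grp.loc[j, "strand"]
                if su == "+" and sd == "-":
                    cls = "convergent"
                elif su == sd:
                    cls = "tandem"
                else:
                    cls = "divergent"
                classes[cls].append(
                    (chrom, int(grp.loc[i, "start"]), int(grp.loc[i, "end"]),
                     chrom, int(grp.loc[j, "start"]), int(grp.loc[j, "end"]))
                )
    return {k: pd.DataFrame(v, columns=LOOP_COLS) for k, v in classes.items()}


def aggregate_loop_pileup(
    cm: ContactMatrix,
    loops: pd.DataFrame,
    pad_bp: int = 200_000,
    ignore_diags: int = 0,
    center_box: int = 3,
) -> Pileup:
    """Mean O/E window of side ``2*pad+1`` bins centered on each loop pixel.

    Anchor midpoints are snapped to their containing bin. Windows crossing a
    matrix edge or reaching into the (diagonal + ignore_diags) region are
    dropped. Enrichment is the mean of the central ``center_box`` square
    (background is 1 by construction after O/E).
    """
    if len(loops) == 0:
        raise ValueError("empty loop list")
    if pad_bp % cm.resolution:
        raise ValueError("pad_bp must be a multiple of the matrix resolution")
    pad = pad_bp // cm.resolution
    oe = oe_matrix(cm)
    side = 2 * pad + 1
    acc = np.zeros((side, side))
    cnt = np.zeros((side, side))
    used = 0
    for _, row in validate_loops(loops).iterrows():
        chrom = row["chrom1"]
        if chrom not in oe.mats:
            continue
        m = oe.matrix(chrom)
        n = m.shape[0]
        b1 = int((row["start1"] + row["end1"]) // 2 // cm.resolution)
        b2 = int((row["start2"] + row["end2"]) // 2 // cm.resolution)
        if b1 > b2:
            b1, b2 = b2, b1
        if b1 - pad < 0 or b2 + pad >= n:
            continue
        if (b2 - pad) - (b1 + pad) <= ignore_diags:
            continue  # window would cross the masked diagonal band
        win = m[b1 - pad : b1 + pad + 1, b2 - pad : b2 + pad + 1]
        good = np.isfinite(win)
        acc[good] += win[good]
        cnt[good] += 1
        used += 1
    if used == 0:
        raise ValueError("all loop windows dropped (edges/diagonal)")
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(cnt > 0, acc / cnt, np.nan)
    h = center_box // 2
    c = side // 2
    enrichment = float(np.nanmean(grid[c - h : c + h + 1, c - h : c + h + 1]))
    return Pileup(grid, used, enrichment)


def _area_resize(m: np.ndarray, out_size: int) -> np.ndarray:
    """Exact area-mean rescaling of a square matrix, NaN-aware."""
    n = m.shape[0]
    w = np.zeros((out_size, n))
    scale = n / out_size
    for o in range(out_size):
        lo, hi = o * scale, (o + 1) * scale
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n)):
            w[o, i] = max(0.0, min(hi, i + 1) - max(lo, i))
    good = np.isfinite(m)
    num = w @ np.where(good, m, 0.0) @ w.T
    den = w @ good.astype(float) @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def rescaled_domain_pileup(
    cm: ContactMatrix,
    domains: pd.DataFrame,
    out_size_bins: int = 99,
) -> Pileup:
    """Average of local O/E windows (domain plus equal flanks) rescaled to a
    common ``out_size_bins`` square by area-mean interpolation.

    Enrichment is the mean over the central third of the grid (the rescaled
    domain body). ``out_size_bins`` must be odd so a center pixel exists.
    """
    if out_size_bins % 2 == 0:
        raise ValueError("out_size_bins must be odd (center pixel required)")
    oe = oe_matrix(cm)
    acc = np.zeros((out_size_bins, out_size_bins))
    cnt = np.zeros((out_size_bins, out_size_bins))
    used = 0
    for _, row in domains.iterrows():
        chrom = row["chrom"]
        if chrom not in oe.mats:
            continue
        m = oe.matrix(chrom)
        n = m.shape[0]
        b0 = int(row["start"] // cm.resolution)
        b1 = int(np.ceil(row["end"] / cm.resolution))
        L = b1 - b0
        if L < 5:
            continue
        lo, hi = b0 - L, b1 + L
        if lo < 0 or hi > n:
            continue
        win = _area_resize(m[lo:hi, lo:hi], out_size_bins)
        good = np.isfinite(win)
        acc[good] += win[good]
        cnt[good] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable domains (too short or out of bounds)")
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(cnt > 0, acc / cnt, np.nan)
    third = out_size_bins // 3
    enrichment = float(np.nanmean(grid[third : 2 * third + 1, third : 2 * third + 1]))
    return Pileup(grid, used, enrichment)
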