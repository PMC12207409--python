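"""Fountain detection: open-chromatin islands, perpendicular snippets,
mask construction, fountain scoring and the full filter chain.

A fountain is a Hi-C pattern of contact enrichment emanating perpendicular
to the main diagonal at a focal base — the signature of bidirectional loop
extrusion from a preferred cohesin loading site. Detection proceeds in two
halves. First, open chromatin islands (OCIs) — short isolated runs of
100-kb bins with high summed ATAC peak score — locate candidate bases whose
averaged O/E snippets define a binary fountain mask. Second, every genomic
bin is scored against that mask, and candidate score-profile peaks are
filtered by: prominence (Li minimum-cross-entropy threshold), distance to
bad bins, positive mask correlation, replicate support within a 60-kb
offset, then fractional cuts on noise score (top 10%) and fountain score
(bottom 30%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from skimage.filters import threshold_li

from .decay import oe_matrix
from .matrix import ContactMatrix

__all__ = [
    "OCI",
    "Snippet",
    "FountainMask",
    "FountainScore",
    "FountainCall",
    "GenomeScan",
    "call_ocis",
    "extract_snippets",
    "build_fountain_mask",
    "score_snippets",
    "scan_genome",
    "call_fountains",
    "fountain_interaction_profile",
]


# ---------------------------------------------------------------------------
# Open chromatin islands
# ---------------------------------------------------------------------------

@dataclass
class OCI:
    chrom: str
    start: int
    end: int
    score: float  # summed binned peak score over the run


def binned_peak_scores(
    peaks: pd.DataFrame, chrom_size: int, binsize: int
) -> np.ndarray:
    """Per-bin score: sum of scores of all peaks overlapping the bin (each
    overlapped bin receives the peak's full score)."""
    n = int(np.ceil(chrom_size / binsize))
    out = np.zeros(n)
    for _, p in peaks.iterrows():
        b0 = int(p["start"] // binsize)
        b1 = int((p["end"] - 1) // binsize)
        out[b0 : min(b1, n - 1) + 1] += p["score"]
    return out


def call_ocis(
    peaks: pd.DataFrame,
    chrom_sizes: dict[str, int],
    binsize: int = 100_000,
    window_flank_bins: int = 2,
    score_threshold: float = 100.0,
    max_run_bins: int = 10,
    exclusion_flank_bp: int = 1_000_000,
) -> list[OCI]:
    """Maximal runs of "high-ATAC" bins, length-capped and isolation-filtered.

    A bin is high iff the centered (2*window_flank_bins + 1)-bin window sum
    of binned peak scores is strictly over ``score_threshold``. A run
    qualifies as an OCI iff its length is at most ``max_run_bins`` and no
    high bin lies within ``exclusion_flank_bp`` on either side.
    """
    if exclusion_flank_bp % binsize:
        raise ValueError("exclusion_flank_bp must be a multiple of binsize")
    excl = exclusion_flank_bp // binsize
    win = 2 * window_flank_bins + 1
    ocis: list[OCI] = []
    for chrom, size in chrom_sizes.items():
        sub = peaks[peaks["chrom"] == chrom]
        score = binned_peak_scores(sub, size, binsize)
        wsum = np.convolve(score, np.ones(win), mode="same")
        high = wsum > score_threshold
        n = len(high)
        b = 0
        while b < n:
            if not high[b]:
                b += 1
                continue
            e = b
            while e + 1 < n and high[e + 1]:
                e += 1
            run_len = e - b + 1
            left = high[max(0, b - excl) : b]
            right = high[e + 1 : e + 1 + excl]
            if run_len <= max_run_bins and not left.any() and not right.any():
                ocis.append(
                    OCI(chrom, b * binsize, min((e + 1) * binsize, size),
                        float(score[b : e + 1].sum()))
                )
            b = e + 1
    return ocis


# ---------------------------------------------------------------------------
# Snippets, mask, scores
# ---------------------------------------------------------------------------

@dataclass
class Snippet:
    """Perpendicular-diagonal O/E window at a center bin.

    ``grid[a-1, b-1] = O/E(c - a, c + b)`` for a, b in 1..W: rows look
    upstream of the center, columns downstream, so fountain signal runs
    along the grid diagonal a == b.
    """

    chrom: str
    center_bin: int
    grid: np.ndarray


def extract_snippets(
    cm: ContactMatrix,
    centers: list[tuple[str, int]],
    window_bp: int = 1_000_000,
    oe: ContactMatrix | None = None,
) -> list[Snippet]:
    """Snippets at ``centers`` ((chrom, position_bp) pairs); centers within
    ``window_bp`` of a chromosome end are dropped with a warning."""
    if oe is None:
        oe = oe_matrix(cm)
    W = window_bp // cm.resolution
    out: list[Snippet] = []
    for chrom, pos in centers:
        c = int(pos // cm.resolution)
        n = oe.matrix(chrom).shape[0]
        if c - W < 0 or c + W >= n:
            warnings.warn(f"center {chrom}:{pos} within {window_bp} bp of chromosome end; dropped")
            continue
        m = oe.matrix(chrom)
        rows = c - np.arange(1, W + 1)
        cols = c + np.arange(1, W + 1)
        out.append(Snippet(chrom, c, m[np.ix_(rows, cols)]))
    return out


@dataclass
class FountainMask:
    mask: np.ndarray  # boolean grid, True = inside the fountain pattern
    mean_grid: np.ndarray
    binarize_quantile: float


def build_fountain_mask(
    snippets: list[Snippet] | list[list[Snippet]],
    binarize_quantile: float = 0.8,
) -> FountainMask:
    """Element-wise mean of snippets (conditions averaged when a list of
    snippet lists is given), binarized at the given quantile of grid values.
    """
    if len(snippets) and isinstance(snippets[0], Snippet):
        conditions = [snippets]
    else:
        conditions = snippets
    flat = [s for cond in conditions for s in cond]
    if len(flat) < 10:
        raise ValueError("need >= 10 snippets to build a stable mask")
    means = []
    for cond in conditions:
        stack = np.stack([s.grid for s in cond])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means.append(np.nanmean(stack, axis=0))
    mean_grid = np.nanmean(np.stack(means), axis=0)
    if not np.any(np.isfinite(mean_grid)):
        raise ValueError("all snippet values masked; cannot build mask")
    thr = np.nanquantile(mean_grid, binarize_quantile)
    mask = np.where(np.isfinite(mean_grid), mean_grid > thr, False)
    return FountainMask(mask, mean_grid, binarize_quantile)


@dataclass
class FountainScore:
    fountain_score: float
    prominence: float
    noise_score: float
    mask_correlation: float


def _score_grid(grid: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """(fountain_score, mask_correlation, noise_score) for one snippet grid."""
    vals = grid.ravel()
    ind = mask.ravel().astype(float)
    finite = np.isfinite(vals)
    if finite.sum() < 4 or np.nanstd(vals[finite]) == 0:
        return 0.0, 0.0, 0.0
    inside = vals[finite & (ind > 0)]
    outside = vals[finite & (ind == 0)]
    fs = float(np.mean(inside) - np.mean(outside)) if len(inside) and len(outside) else 0.0
    rho = stats.spearmanr(vals[finite], ind[finite]).statistic
    rho = 0.0 if not np.isfinite(rho) else float(rho)
    mu = np.mean(outside) if len(outside) else np.nan
    noise = float(np.std(outside) / abs(mu)) if len(outside) and mu else 0.0
    return fs, rho, noise


def score_snippets(
    snippets: list[Snippet], mask: FountainMask | np.ndarray
) -> list[FountainScore]:
    """Score each snippet against the fountain mask.

    fountain_score = mean(O/E inside mask) - mean(outside);
    mask_correlation = Spearman correlation with the mask indicator;
    noise_score = coefficient of variation outside the mask. Topographic
    prominence is a property of the genomic score *profile*, so it is NaN
    here; :func:`scan_genome` + :func:`call_fountains` fill it in.
    """
    m = mask.mask if isinstance(mask, FountainMask) else mask
    out = []
    for s in snippets:
        if s.grid.shape != m.shape:
            raise ValueError("snippet and mask shapes differ")
        fs, rho, noise = _score_grid(s.grid, m)
        out.append(FountainScore(fs, np.nan, noise, rho))
    return out


@dataclass
class GenomeScan:
    """Per-bin fountain-score profiles for a whole contact matrix."""

    fountain_score: dict[str, np.ndarray]
    mask_correlation: dict[str, np.ndarray]
    noise_score: dict[str, np.ndarray]
    resolution: int
    window_bins: int


def scan_genome(
    cm: ContactMatrix,
    mask: FountainMask,
    window_bp: int = 1_000_000,
) -> GenomeScan:
    """Score every eligible bin center of every chromosome against the mask."""
    oe = oe_matrix(cm)
    W = window_bp // cm.resolution
    fs_d, corr_d, noise_d = {}, {}, {}
    m_ind = mask.mask
    for chrom in cm.chromnames:
        m = oe.matrix(chrom)
        n = m.shape[0]
        fs = np.full(n, np.nan)
        rho = np.full(n, np.nan)
        noise = np.full(n, np.nan)
        up = np.arange(1, W + 1)
        for c in range(W, n - W):
            grid = m[np.ix_(c - up, c + up)]
            fs[c], rho[c], noise[c] = _score_grid(grid, m_ind)
        fs_d[chrom], corr_d[chrom], noise_d[chrom] = fs, rho, noise
    return GenomeScan(fs_d, corr_d, noise_d, cm.resolution, W)


# ---------------------------------------------------------------------------
# Filter chain
# ---------------------------------------------------------------------------

@dataclass
class FountainCall:
    chrom: str
    start: int
    end: int
    score: FountainScore
    prominence_pass: bool = False
    bad_bin_pass: bool = False
    correlation_pass: bool = False
    replicate_pass: bool = False
    noise_pass: bool = False
    score_pass: bool = False

    @property
    def called(self) -> bool:
        return (
            self.prominence_pass
            and self.bad_bin_pass
            and self.correlation_pass
            and self.replicate_pass
            and self.noise_pass
            and self.score_pass
        )


def _smooth(x: np.ndarray, w: int = 3) -> np.ndarray:
    out = x.astype(float).copy()
    finite = np.isfinite(out)
    if finite.sum() == 0:
        return out
    filled = np.where(finite, out, 0.0)
    norm = np.convolve(finite.astype(float), np.ones(w), mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.convolve(filled, np.ones(w), mode="same") / norm
    sm[norm == 0] = np.nan
    return sm


def _profile_peaks(profile: np.ndarray, smooth_bins: int = 3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local maxima of the smoothed profile; ties broken leftmost.

    Returns (peak bins, prominences, smoothed profile).
    """
    sm = _smooth(profile, smooth_bins)
    x = np.where(np.isfinite(sm), sm, -np.inf)
    n = len(x)
    peaks = []
    for i in range(1, n - 1):
        if x[i] == -np.inf:
            continue
        if x[i] > x[i - 1] and x[i] >= x[i + 1]:
            peaks.append(i)
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) == 0:
        return peaks, np.array([]), sm
    finite_floor = np.nanmin(np.where(np.isfinite(sm), sm, np.nan))
    xs = np.where(np.isfinite(sm), sm, finite_floor)
    prom = signal.peak_prominences(xs, peaks)[0]
    return peaks, prom, sm


def call_fountains(
    scan_merged: GenomeScan,
    scan_rep1: GenomeScan,
    scan_rep2: GenomeScan,
    bad_bins: dict[str, np.ndarray],
    offset_bp: int = 60_000,
    bad_bin_flank_bp: int = 100_000,
    noise_top_frac: float = 0.10,
    score_bottom_frac: float = 0.30,
    prominence_wlen_bp: int = 2_000_000,
    smooth_bins: int = 3,
    fraction_reference: str = "candidates",
) -> tuple[list[FountainCall], dict]:
    """Apply the fountain filter chain to candidate score-profile peaks.

    Stages, in order: (1) topographic prominence (within ±1 Mb) at or above
    the Li minimum-cross-entropy threshold of the candidate prominence
    distribution; (2) no bad bin within ``bad_bin_flank_bp``; (3) positive
    mask correlation; (4) a candidate peak within ``offset_bp`` in each
    replicate profile; (5) drop candidates in the top ``noise_top_frac`` of
    the noise-score distribution (ties: leftmost-coordinate candidates
    kept); (6) drop candidates in the bottom ``score_bottom_frac`` of the
    fountain-score distribution. With ``fraction_reference="candidates"``
    (default) the stage-5/6 cutoffs are quantiles of the *full* candidate
    distribution — absolute, data-calibrated thresholds, so a candidate set
    that is uniformly strong loses nothing; with ``"survivors"`` the
    fractions are taken of the set entering each stage (exactly
    floor(frac * n) removed). Returns all candidates with their flags plus a
    per-stage count log; fountains are candidates with every flag set.
    """
    res = scan_merged.resolution
    offset_bins = int(round(offset_bp / res))
    bad_flank_bins = int(round(bad_bin_flank_bp / res))
    wlen = max(3, 2 * (prominence_wlen_bp // (2 * res)) + 1)

    candidates: list[FountainCall] = []
    proms: list[float] = []
    rep_peaks = {}
    for rep, scan in (("rep1", scan_rep1), ("rep2", scan_rep2)):
        rep_peaks[rep] = {
            chrom: _profile_peaks(scan.fountain_score[chrom], smooth_bins)[0]
            for chrom in scan.fountain_score
        }
    for chrom, profile in scan_merged.fountain_score.items():
        peaks, prom_arr, _sm = _profile_peaks(profile, smooth_bins)
        if len(peaks) == 0:
            continue
        # recompute prominence with the ±1 Mb window restriction
        sm = _smooth(profile, smooth_bins)
        floor = np.nanmin(np.where(np.isfinite(sm), sm, np.nan))
        xs = np.where(np.isfinite(sm), sm, floor)
        prom_w = signal.peak_prominences(xs, peaks, wlen=min(wlen, len(xs)))[0]
        bad = np.asarray(bad_bins.get(chrom, np.zeros(len(profile), dtype=bool)))
        for p, pr in zip(peaks, prom_w):
            sc = FountainScore(
                fountain_score=float(profile[p]),
                prominence=float(pr),
                noise_score=float(scan_merged.noise_score[chrom][p]),
                mask_correlation=float(scan_merged.mask_correlation[chrom][p]),
            )
            call = FountainCall(chrom, p * res, (p + 1) * res, sc)
            lo, hi = max(0, p - bad_flank_bins), min(len(bad), p + bad_flank_bins + 1)
            call.bad_bin_pass = not bad[lo:hi].any()
            call.correlation_pass = sc.mask_correlation > 0
            ok = True
            for rep in ("rep1", "rep2"):
                rp = rep_peaks[rep].get(chrom, np.array([], dtype=int))
                if len(rp) == 0 or np.min(np.abs(rp - p)) > offset_bins:
                    ok = False
            call.replicate_pass = ok
            candidates.append(call)
            proms.append(pr)

    log = {"candidates": len(candidates)}
    if not candidates:
        return [], log

    proms = np.asarray(proms)
    li = float(threshold_li(proms, tolerance=1e-6)) if len(np.unique(proms)) > 1 else proms.min()
    for call in candidates:
        call.prominence_pass = call.score.prominence >= li
    log["li_threshold"] = li

    stage = [c for c in candidates if c.prominence_pass]
    log["after_prominence"] = len(stage)
    stage = [c for c in stage if c.bad_bin_pass]
    log["after_bad_bins"] = len(stage)
    stage = [c for c in stage if c.correlation_pass]
    log["after_correlation"] = len(stage)
    stage = [c for c in stage if c.replicate_pass]
    log["after_replicates"] = len(stage)

    if fraction_reference not in ("candidates", "survivors"):
        raise ValueError("fraction_reference must be 'candidates' or 'survivors'")

    ref = candidates if fraction_reference == "candidates" else stage
    n_noise_drop = int(np.floor(noise_top_frac * len(ref)))
    order = sorted(
        range(len(ref)),
        key=lambda i: (-ref[i].score.noise_score, ref[i].chrom, ref[i].start),
    )
    noisy = {id(ref[i]) for i in order[:n_noise_drop]}
    for c in stage:
        c.noise_pass = id(c) not in noisy
    stage = [c for c in stage if c.noise_pass]
    log["after_noise"] = len(stage)

    ref = candidates if fraction_reference == "candidates" else stage
    n_score_drop = int(np.floor(score_bottom_frac * len(ref)))
    order = sorted(
        range(len(ref)),
        key=lambda i: (ref[i].score.fountain_score, ref[i].chrom, ref[i].start),
    )
    weak = {id(ref[i]) for i in order[:n_score_drop]}
    for c in stage:
        c.score_pass = id(c) not in weak
    log["after_score"] = len([c for c in stage if c.score_pass])
    return candidates, log


# ---------------------------------------------------------------------------
# Interaction-strength profile
# ---------------------------------------------------------------------------

def fountain_interaction_profile(
    cm: ContactMatrix,
    chrom: str,
    base_bin: int,
    flank_diagonals: int = 3,
    max_sep_bp: int = 2_000_000,
    oe: ContactMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean O/E along the perpendicular diagonal through the fountain base.

    For separation ``2*k*binsize``, profile(k) = mean over
    j in [-flank_diagonals, +flank_diagonals] of O/E(c+j-k, c+j+k), over
    in-bounds, unmasked entries. Returns (separations_bp, profile). A base
    too close to a chromosome end yields a truncated profile with a warning.
    """
    if oe is None:
        oe = oe_matrix(cm)
    m = oe.matrix(chrom)
    n = m.shape[0]
    c = int(base_bin)
    kmax = int(max_sep_bp // (2 * cm.resolution))
    if c - kmax - flank_diagonals < 0 or c + kmax + flank_diagonals >= n:
        warnings.warn(f"base bin {base_bin} close to chromosome end; profile truncated")
    seps = np.arange(kmax + 1) * 2 * cm.resolution
    prof = np.full(kmax + 1, np.nan)
    for k in range(kmax + 1):
        vals = []
        for j in range(-flank_diagonals, flank_diagonals + 1):
            i1, i2 = c + j - k, c + j + k
            if 0 <= i1 < n and 0 <= i2 < n and np.isfinite(m[i1, i2]):
                vals.append(m[i1, i2])
        if vals:
            prof[k] = float(np.mean(vals))
    return seps, prof


def profile_extent(
    seps: np.ndarray, profile: np.ndarray, threshold: float = 1.05
) -> float:
    """Largest separation with profile still above ``threshold`` (bp); 0 if
    the profile never exceeds it."""
    above = np.where(np.isfinite(profile) & (profile > threshold))[0]
    return float(seps[above[-1]]) if len(above) else 0.0
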