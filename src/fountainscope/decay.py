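"""Distance-decay analysis: expected profiles, O/E transforms and relative
contact probability (RCP) curves with the average-extruded-loop-size estimate.

The expected profile is the per-diagonal mean of balanced contacts over
unmasked pixels, computed per chromosome with ``ignore_diags`` leading
diagonals optionally excluded. Dividing by it yields the observed-over-
expected (O/E) matrix in which distance decay is normalised out; every
defined O/E diagonal then has mean 1 by construction.

The RCP curve aggregates contact probability in log-spaced separation bins.
The local maximum of its smoothed log-log derivative estimates the average
extruded loop size: stabilising cohesin on chromatin (loss of its release
factor WAPL) moves this peak to larger separations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .matrix import ContactMatrix

__all__ = [
    "ExpectedProfile",
    "RCPCurve",
    "compute_expected",
    "observed_over_expected",
    "rcp_curve",
    "estimate_average_loop_size",
]


@dataclass
class ExpectedProfile:
    """Per-chromosome per-diagonal mean balanced contact."""

    profiles: dict[str, np.ndarray]
    resolution: int
    ignore_diags: int = 0

    def expected(self, chrom: str) -> np.ndarray:
        return self.profiles[chrom]


def compute_expected(cm: ContactMatrix, ignore_diags: int = 0) -> ExpectedProfile:
    """Per-diagonal mean of unmasked pixels, per chromosome.

    Diagonals with no unmasked pixel are NaN. A chromosome whose bins are all
    bad yields an all-NaN profile with a warning.
    """
    profiles: dict[str, np.ndarray] = {}
    for chrom in cm.chromnames:
        m = cm.matrix(chrom)
        n = m.shape[0]
        prof = np.full(n, np.nan)
        if np.all(np.isnan(m)):
            warnings.warn(f"chromosome {chrom}: all bins masked; expected undefined")
            profiles[chrom] = prof
            continue
        for d in range(ignore_diags, n):
            diag = np.diagonal(m, d)
            if np.any(~np.isnan(diag)):
                prof[d] = np.nanmean(diag)
        profiles[chrom] = prof
    return ExpectedProfile(profiles, cm.resolution, ignore_diags)


def observed_over_expected(cm: ContactMatrix, exp: ExpectedProfile) -> ContactMatrix:
    """Divide each unmasked pixel by the expected value at its diagonal.

    Diagonals whose expected value is 0 or undefined become NaN.
    """
    if exp.resolution != cm.resolution:
        raise ValueError(
            f"expected profile at {exp.resolution} bp does not match matrix at {cm.resolution} bp"
        )
    mats: dict[str, np.ndarray] = {}
    for chrom in cm.chromnames:
        m = cm.matrix(chrom)
        n = m.shape[0]
        prof = exp.profiles[chrom]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        denom = prof[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(denom > 0, m / denom, np.nan)
        mats[chrom] = oe
    return ContactMatrix(mats, cm.resolution, dict(cm.chrom_sizes))


def oe_matrix(cm: ContactMatrix, ignore_diags: int = 0) -> ContactMatrix:
    """Convenience: O/E of ``cm`` against its own expected profile."""
    return observed_over_expected(cm, compute_expected(cm, ignore_diags))


@dataclass
class RCPCurve:
    """Relative contact probability vs genomic separation (log-spaced)."""

    distances: np.ndarray  # bin centers, bp, strictly increasing
    probability: np.ndarray  # normalised to sum 1 over evaluated range
    derivative: np.ndarray  # smoothed d log10 P / d log10 s
    estimated_loop_size: float | None = None

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance_bp": self.distances,
                "P": self.probability,
                "derivative": self.derivative,
            }
        )


def _moving_average(x: np.ndarray, w: int = 3) -> np.ndarray:
    """Centered moving average, NaN-aware, edges shrink the window."""
    n = len(x)
    out = np.full(n, np.nan)
    h = w // 2
    for i in range(n):
        seg = x[max(0, i - h) : min(n, i + h + 1)]
        if np.any(np.isfinite(seg)):
            out[i] = np.nanmean(seg)
    return out


def rcp_curve(
    cm: ContactMatrix,
    bins_per_decade: int = 8,
    smooth_window: int = 3,
    search_range: tuple[float, float] = (30_000, 5_000_000),
    prominence_floor: float = 0.05,
) -> RCPCurve:
    """Relative contact probability in log-spaced separation bins.

    Per-separation mean contact is pooled over chromosomes, aggregated into
    log10-spaced bins (``bins_per_decade``), normalised to sum 1, and the
    log-log derivative is taken after a centered moving-average smoothing
    over ``smooth_window`` log-bins. The smoothed derivative's local maximum
    in ``search_range`` (if sufficiently prominent) is stored as the average
    extruded loop size. The curve is invariant to uniform count scaling.
    """
    res = cm.resolution
    max_d = max(cm.n_bins(c) for c in cm.chromnames)
    # pooled per-diagonal sums and pixel counts
    sums = np.zeros(max_d)
    counts = np.zeros(max_d)
    for chrom in cm.chromnames:
        m = cm.matrix(chrom)
        n = m.shape[0]
        for d in range(1, n):
            diag = np.diagonal(m, d)
            good = ~np.isnan(diag)
            sums[d] += diag[good].sum()
            counts[d] += good.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        p_per_d = np.where(counts > 0, sums / counts, np.nan)

    dist = np.arange(max_d) * res  # bin-center to bin-center separation
    lo = np.log10(res)
    hi = np.log10(dist[-1]) if max_d > 1 else lo + 1
    n_edges = int(np.ceil((hi - lo) * bins_per_decade)) + 1
    edges = np.logspace(lo, hi, n_edges)
    idx = np.digitize(dist[1:], edges) - 1
    nb = len(edges) - 1
    p_bin = np.full(nb, np.nan)
    centers = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        vals = p_per_d[1:][sel]
        good = np.isfinite(vals)
        if np.any(good):
            p_bin[b] = np.mean(vals[good])
            # the mean separation of contributing diagonals, not the nominal
            # bin center: avoids discretization wiggle where a log bin holds
            # only one or two diagonals
            centers[b] = np.mean(dist[1:][sel][good])
    keep = np.isfinite(p_bin) & (p_bin > 0)
    centers, p_bin = centers[keep], p_bin[keep]
    if len(p_bin) < 3:
        raise ValueError("fewer than 3 usable distance bins; matrix too small/sparse")
    p_norm = p_bin / p_bin.sum()

    logs = np.log10(centers)
    logp = np.log10(p_norm)
    logp_s = _moving_average(logp, smooth_window)
    deriv = np.gradient(logp_s, logs)
    deriv = _moving_average(deriv, smooth_window)

    curve = RCPCurve(centers, p_norm, deriv)
    curve.estimated_loop_size = estimate_average_loop_size(
        curve, search_range=search_range, prominence_floor=prominence_floor
    )
    return curve


def estimate_average_loop_size(
    curve: RCPCurve,
    search_range: tuple[float, float] = (30_000, 5_000_000),
    prominence_floor: float = 0.05,
) -> float | None:
    """Genomic separation of the most prominent local maximum of the
    smoothed RCP derivative within ``search_range``.

    Returns None when no local maximum exceeds its flanking minima by
    ``prominence_floor`` (e.g. a pure power law, whose derivative is flat).
    Below ~30 kb ligation artifacts dominate, above ~5 Mb compartments do,
    hence the default window.
    """
    d = curve.derivative
    sel = (curve.distances >= search_range[0]) & (curve.distances <= search_range[1])
    if sel.sum() < 3:
        return None
    dd = d[sel]
    dist = curve.distances[sel]
    finite = np.isfinite(dd)
    if finite.sum() < 3:
        return None
    peaks, props = signal.find_peaks(dd, prominence=prominence_floor)
    if len(peaks) == 0:
        return None
    best = peaks[np.argmax(props["prominences"])]
    return float(dist[best])
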