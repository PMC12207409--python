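"""A/B compartment scores, saddle plots and compartment strength.

The compartment score is the leading eigenvector of the per-chromosome
Pearson correlation matrix of the O/E map (computed over unmasked bins),
oriented per chromosome so that positive values mark active (A) chromatin:
the sign is chosen to maximise correlation with an orientation reference
track (e.g. H3K4me1 coverage, or a previously oriented score).

The saddle plot ranks bins by score into equal-count quantile groups and
averages O/E genome-wide per group pair. Compartment strength is
(AA * BB) / AB**2 over the extreme ``top_fraction`` of quantile groups at
each end — the product of the strongest within-compartment interactions over
the squared strongest between-compartment interactions. Loop extrusion
antagonises compartmentalisation, so stabilising cohesin (WAPL loss)
lowers this statistic while removing cohesin raises it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decay import compute_expected, observed_over_expected
from .matrix import ContactMatrix

__all__ = [
    "CompartmentTrack",
    "SaddleResult",
    "compartment_score",
    "saddle",
    "compartment_strength",
]


@dataclass
class CompartmentTrack:
    """Per-bin signed compartment score (positive = A), NaN at bad bins."""

    scores: dict[str, np.ndarray]
    resolution: int
    orientation_reference: str = ""

    def values(self, chrom: str) -> np.ndarray:
        return self.scores[chrom]


@dataclass
class SaddleResult:
    """Quantile-by-quantile grid of mean O/E, ordered B -> A (ascending score)."""

    grid: np.ndarray
    quantile_edges: np.ndarray
    n_quantiles: int
    strength_A: float = np.nan
    strength_B: float = np.nan
    strength: float = np.nan


def compartment_score(
    cm: ContactMatrix,
    orientation_track: dict[str, np.ndarray],
    min_bins: int = 20,
) -> CompartmentTrack:
    """Leading-eigenvector compartment score on the O/E correlation matrix.

    Per chromosome: O/E over unmasked bins -> Pearson correlation matrix ->
    eigenvector of the largest eigenvalue -> sign flipped if its correlation
    with ``orientation_track`` is negative. Chromosomes with fewer than
    ``min_bins`` usable bins are skipped with a warning (all-NaN track).
    """
    oe = observed_over_expected(cm, compute_expected(cm))
    scores: dict[str, np.ndarray] = {}
    for chrom in cm.chromnames:
        m = oe.matrix(chrom)
        n = m.shape[0]
        out = np.full(n, np.nan)
        good = ~np.all(np.isnan(m), axis=1)
        if good.sum() < min_bins:
            warnings.warn(f"chromosome {chrom}: <{min_bins} usable bins; skipped")
            scores[chrom] = out
            continue
        sub = m[np.ix_(good, good)]
        # rows may still contain NaN on zero-expected diagonals; drop to means
        col_means = np.nanmean(sub, axis=0)
        inds = np.where(np.isnan(sub))
        sub[inds] = np.take(col_means, inds[1])
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr[np.isnan(corr)] = 0.0
        w, v = np.linalg.eigh(corr)
        e1 = v[:, np.argmax(w)]
        ref = np.asarray(orientation_track[chrom], dtype=float)[good]
        finite = np.isfinite(ref)
        if finite.sum() >= 2 and np.nanstd(ref[finite]) > 0:
            r = np.corrcoef(e1[finite], ref[finite])[0, 1]
            if r < 0:
                e1 = -e1
        out[good] = e1
        scores[chrom] = out
    return CompartmentTrack(scores, cm.resolution, orientation_reference="user-track")


def saddle(
    cm: ContactMatrix,
    score: CompartmentTrack,
    n_quantiles: int = 50,
    exclude_diags: int = 1,
) -> SaddleResult:
    """Mean O/E per pair of compartment-score quantile groups, pooled
    genome-wide. Group 0 is the strongest-B end, group n-1 the strongest-A
    end. The first ``exclude_diags`` diagonals are excluded (self-interaction
    dominates the main diagonal).
    """
    if n_quantiles < 4:
        raise ValueError("n_quantiles must be >= 4")
    oe = observed_over_expected(cm, compute_expected(cm))
    all_scores = np.concatenate([score.values(c) for c in cm.chromnames])
    finite = np.isfinite(all_scores)
    if finite.sum() < n_quantiles:
        raise ValueError("not enough scored bins for the requested quantiles")
    edges = np.nanquantile(all_scores[finite], np.linspace(0, 1, n_quantiles + 1))
    edges[0], edges[-1] = -np.inf, np.inf

    sums = np.zeros((n_quantiles, n_quantiles))
    counts = np.zeros((n_quantiles, n_quantiles))
    for chrom in cm.chromnames:
        m = oe.matrix(chrom)
        s = score.values(chrom)
        n = m.shape[0]
        grp = np.digitize(s, edges) - 1
        grp = np.clip(grp, 0, n_quantiles - 1)
        grp[~np.isfinite(s)] = -1
        ii, jj = np.triu_indices(n, k=exclude_diags)
        gi, gj = grp[ii], grp[jj]
        vals = m[ii, jj]
        ok = (gi >= 0) & (gj >= 0) & np.isfinite(vals)
        np.add.at(sums, (gi[ok], gj[ok]), vals[ok])
        np.add.at(counts, (gi[ok], gj[ok]), 1)
    sums = sums + sums.T
    counts = counts + counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(counts > 0, sums / counts, np.nan)
    result = SaddleResult(grid, edges, n_quantiles)
    try:
        k = _corner_size(n_quantiles, 0.25)
        aa, bb, ab = _corner_means(grid, k)
        result.strength_A = aa / ab
        result.strength_B = bb / ab
        result.strength = aa * bb / ab**2
    except ValueError:
        pass
    return result


def _corner_size(n_quantiles: int, top_fraction: float) -> int:
    # "25% of the strongest" -> outermost floor(f*n) groups, tie-broken
    # toward fewer groups, never fewer than 1
    return max(1, int(np.floor(top_fraction * n_quantiles)))


def _corner_means(grid: np.ndarray, k: int) -> tuple[float, float, float]:
    aa = np.nanmean(grid[-k:, -k:])
    bb = np.nanmean(grid[:k, :k])
    ab = np.nanmean(np.concatenate([grid[:k, -k:].ravel(), grid[-k:, :k].ravel()]))
    if not (aa > 0 and bb > 0 and ab > 0):
        raise ValueError("saddle corner mean <= 0 or undefined; strength not computable")
    return float(aa), float(bb), float(ab)


def compartment_strength(s: SaddleResult, top_fraction: float = 0.25) -> float:
    """(AA * BB) / AB**2 over the extreme ``top_fraction`` quantile corners.

    Invariant under global sign flip of the compartment score (A/B
    relabeling swaps AA and BB). Raises if any corner mean is <= 0.
    """
    k = _corner_size(s.n_quantiles, top_fraction)
    aa, bb, ab = _corner_means(s.grid, k)
    return aa * bb / ab**2
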