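"""Reusable study scenarios: parameterised synthetic genomes that exercise
the full analysis chain with known ground truth.

The fountain benchmark emulates the merged-plus-replicates design of a
degron Hi-C experiment: two replicate maps are independent Poisson draws
from one expected model (20-kb bins, power-law decay, a 2-Mb A/B
checkerboard, loop dots, and injected fountains), the merged map pools
their counts, the mask is trained on snippets at a subset of bases (the
open-chromatin-island proxy), and calls are evaluated against all injected
bases with a ±60 kb matching tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fountains import (
    FountainCall,
    build_fountain_mask,
    call_fountains,
    extract_snippets,
    scan_genome,
)
from .matrix import ContactMatrix
from .synthetic import SyntheticSpec, block_labels, synthesize_contact_matrix

__all__ = ["FountainBenchmark", "build_fountain_benchmark", "run_fountain_benchmark"]


@dataclass
class FountainBenchmark:
    merged: ContactMatrix
    rep1: ContactMatrix
    rep2: ContactMatrix
    truth_bp: np.ndarray  # injected fountain base positions
    mask_training_bp: np.ndarray
    chrom: str
    binsize: int
    loop_list: list
    calls: list[FountainCall] | None = None
    filter_log: dict | None = None

    @property
    def called(self) -> list[FountainCall]:
        return [c for c in (self.calls or []) if c.called]

    def precision_recall(self, tolerance_bp: int = 60_000) -> tuple[float, float]:
        called = self.called
        if not called:
            return 0.0, 0.0
        mids = np.array([(c.start + c.end) / 2 for c in called])
        tp = sum(np.min(np.abs(self.truth_bp - m)) <= tolerance_bp for m in mids)
        matched = sum(np.min(np.abs(mids - t)) <= tolerance_bp for t in self.truth_bp)
        return tp / len(called), matched / len(self.truth_bp)


def build_fountain_benchmark(
    seed: int = 101,
    n_bins: int = 2000,
    binsize: int = 20_000,
    n_fountains: int = 20,
    fountain_amplitude: float = 3.0,
    fountain_extent_bp: int = 600_000,
    n_mask_training: int = 10,
    n_loops: int = 50,
    loop_fold: float = 3.0,
    compartment_block_bins: int = 100,
    compartment_amplitude: float = 1.15,
    depth_per_replicate: float = 5e6,
    chrom: str = "chr1",
) -> FountainBenchmark:
    """Two replicate maps plus their pooled merge, with known fountains.

    Fountain bases sit on the bin grid, evenly spaced and clear of
    chromosome ends; the confounding loop dots are placed uniformly at
    0.2-2 Mb separations; compartment blocks default to 2 Mb (a realistic
    compartment-domain scale at 20 kb resolution).
    """
    size = n_bins * binsize
    rng = np.random.default_rng(seed)
    bases_bp = np.linspace(60, n_bins - 60, n_fountains).astype(int) * binsize
    fountains = [(chrom, int(p), fountain_extent_bp, fountain_amplitude) for p in bases_bp]
    loops = []
    for _ in range(n_loops):
        p1 = int(rng.integers(int(2e6), size - int(4e6)))
        p2 = p1 + int(rng.integers(int(2e5), int(2e6)))
        loops.append((chrom, p1, p2, loop_fold))
    labels = block_labels(n_bins, compartment_block_bins)

    def make(s: int) -> ContactMatrix:
        return synthesize_contact_matrix(
            SyntheticSpec(
                chrom_sizes={chrom: size},
                binsize=binsize,
                compartment_labels={chrom: labels},
                compartment_amplitude=compartment_amplitude,
                loop_list=loops,
                fountain_bases=fountains,
                total_counts=depth_per_replicate,
                seed=s,
            )
        ).matrix

    rep1 = make(seed)
    rep2 = make(seed + 1)
    merged = ContactMatrix(
        {chrom: rep1.matrix(chrom) + rep2.matrix(chrom)}, binsize, dict(rep1.chrom_sizes)
    )
    return FountainBenchmark(
        merged, rep1, rep2, bases_bp,
        bases_bp[:n_mask_training], chrom, binsize, loops,
    )


def run_fountain_benchmark(bench: FountainBenchmark, **call_kwargs) -> FountainBenchmark:
    """Train the mask on the designated bases, scan all maps, call fountains."""
    centers = [(bench.chrom, int(p)) for p in bench.mask_training_bp]
    mask = build_fountain_mask(extract_snippets(bench.merged, centers))
    scan_m = scan_genome(bench.merged, mask)
    scan_1 = scan_genome(bench.rep1, mask)
    scan_2 = scan_genome(bench.rep2, mask)
    bad = {c: bench.merged.bad_bins(c) for c in bench.merged.chromnames}
    bench.calls, bench.filter_log = call_fountains(scan_m, scan_1, scan_2, bad, **call_kwargs)
    return bench
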