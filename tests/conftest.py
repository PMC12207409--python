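"""Shared fixtures: synthetic maps and simulator runs reused across tests."""

import numpy as np
import pytest

import fountainscope as fs


@pytest.fixture(scope="session")
def checkerboard_map():
    """2000-bin 100-kb matrix with a 1-Mb checkerboard at generative
    compartment strength 3, Poisson-sampled to 5e6 counts."""
    labels = fs.block_labels(2000, 10)
    spec = fs.SyntheticSpec(
        chrom_sizes={"chr1": 2000 * 100_000},
        binsize=100_000,
        compartment_labels={"chr1": labels},
        compartment_amplitude=fs.amplitude_for_strength(3.0),
        total_counts=5e6,
        seed=7,
    )
    return fs.synthesize_contact_matrix(spec), labels


@pytest.fixture(scope="session")
def fountain_benchmark():
    """Fountain-calling benchmark: 20 injected fountains (amplitude 3x,
    600 kb extent) on a 2000-bin 20-kb chromosome with compartments and
    loop dots, two Poisson replicates plus their pooled merge."""
    bench = fs.build_fountain_benchmark(seed=101)
    return fs.run_fountain_benchmark(bench)


@pytest.fixture(scope="session")
def preset_maps():
    """One pooled-ensemble map per depletion preset (shared across tests)."""
    out = {}
    for name in ("untreated", "wapl_off", "wapl_ctcf_off", "rad21_off"):
        params = fs.preset_params(name, seed=3, n_ensembles=6)
        out[name] = (params, fs.simulate_extrusion_map(params))
    return out


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def brute_force_expected(mat: np.ndarray) -> np.ndarray:
    """Per-diagonal mean by explicit pixel loop."""
    n = mat.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        vals = []
        for i in range(n - d):
            v = mat[i, i + d]
            if np.isfinite(v):
                vals.append(v)
        if vals:
            out[d] = sum(vals) / len(vals)
    return out


def brute_force_ocis(bin_scores, binsize, threshold=100.0, flank=2, max_run=10, excl=10):
    """All-bins scan for open chromatin islands, independent of the caller."""
    n = len(bin_scores)
    high = []
    for b in range(n):
        w = sum(bin_scores[max(0, b - flank): b + flank + 1])
        high.append(w > threshold)
    runs = []
    b = 0
    while b < n:
        if high[b]:
            e = b
            while e + 1 < n and high[e + 1]:
                e += 1
            runs.append((b, e))
            b = e + 1
        else:
            b += 1
    ocis = []
    for b, e in runs:
        if e - b + 1 > max_run:
            continue
        if any(high[max(0, b - excl): b]) or any(high[e + 1: e + 1 + excl]):
            continue
        ocis.append((b, e))
    return ocis


def brute_force_profile(mat, c, kmax, flank=3):
    """Perpendicular-diagonal average by explicit double loop."""
    n = mat.shape[0]
    prof = np.full(kmax + 1, np.nan)
    for k in range(kmax + 1):
        vals = []
        for j in range(-flank, flank + 1):
            i1, i2 = c + j - k, c + j + k
            if 0 <= i1 < n and 0 <= i2 < n and np.isfinite(mat[i1, i2]):
                vals.append(mat[i1, i2])
        if vals:
            prof[k] = np.mean(vals)
    return prof


def brute_force_extended(primary_rows, min_dist, max_dist):
    """O(n^2) anchor recombination; returns set of (chrom, mid5, mid3)."""
    pairs = set()
    rows = primary_rows
    for i in range(len(rows)):
        for j in range(len(rows)):
            ci = rows[i]
            cj = rows[j]
            if ci["chrom1"] != cj["chrom1"]:
                continue
            m5 = (ci["start1"] + ci["end1"]) / 2
            m3 = (cj["start2"] + cj["end2"]) / 2
            if min_dist <= m3 - m5 <= max_dist:
                pairs.add((ci["chrom1"], m5, m3))
    return pairs
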