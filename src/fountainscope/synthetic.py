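"""Synthetic Hi-C maps and companion tables with known ground truth.

The generative model multiplies a power-law distance decay by independent
structural factors — an A/B checkerboard compartment factor, CTCF-anchored
loop dots, and fountain patterns emanating perpendicular to the diagonal at
designated bases — then Poisson-samples counts to a target sequencing depth.
Peak tables (narrowPeak schema), gene tables with differential-expression
labels, and chromatin-state annotations matching the same coordinates are
generated alongside, so the whole analysis chain runs without external data.

With compartment factor f applied multiplicatively (same-label pixels × f,
opposite-label pixels / f), the generative saddle has corner means
AA = BB = f and AB = 1/f, hence a closed-form compartment strength of f**4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ContactMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticMap",
    "synthesize_contact_matrix",
    "synthesize_peak_table",
    "synthesize_gene_table",
    "block_labels",
    "amplitude_for_strength",
]


def block_labels(n_bins: int, block: int) -> np.ndarray:
    """Alternating ±1 compartment labels in blocks of ``block`` bins."""
    return np.where((np.arange(n_bins) // block) % 2 == 0, 1.0, -1.0)


def amplitude_for_strength(target_strength: float) -> float:
    """Compartment factor f whose generative saddle strength f**4 hits the
    target: f = strength ** (1/4)."""
    return float(target_strength) ** 0.25


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic genome of contact matrices.

    fountain_bases entries are (chrom, position_bp, extent_bp, amplitude);
    loop_list entries are (chrom, pos1_bp, pos2_bp, fold_enrichment).
    """

    chrom_sizes: dict[str, int]
    binsize: int
    decay_exponent: float = -1.0
    loop_bump_size_bp: float | None = None
    loop_bump_amplitude: float = 0.3
    compartment_labels: dict[str, np.ndarray] = field(default_factory=dict)
    compartment_amplitude: float = 1.0
    loop_list: list[tuple] = field(default_factory=list)
    loop_width_bins: int = 1
    fountain_bases: list[tuple] = field(default_factory=list)
    fountain_width_bins: int = 3
    bad_bins: dict[str, np.ndarray] = field(default_factory=dict)
    total_counts: float = 5e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be negative")
        if self.compartment_amplitude < 0:
            raise ValueError("compartment_amplitude must be >= 0")
        for chrom, _pos, extent, amp in self.fountain_bases:
            if amp < 0:
                raise ValueError("fountain amplitude must be >= 0")
            if extent > self.chrom_sizes[chrom]:
                raise ValueError("fountain extent exceeds chromosome length")
        bases = sorted(self.fountain_bases, key=lambda t: (t[0], t[1]))
        for a, b in zip(bases, bases[1:]):
            if a[0] == b[0] and (b[1] - a[1]) < max(a[2], b[2]):
                warnings.warn(
                    f"fountain bases at {a[0]}:{a[1]} and {b[1]} are closer "
                    "than their extents; patterns will overlap"
                )


@dataclass
class SyntheticMap:
    """Synthetic contact matrix plus the ground truth that generated it."""

    matrix: ContactMatrix
    expected_counts: dict[str, np.ndarray]
    spec: SyntheticSpec

    @property
    def fountain_bases(self):
        return self.spec.fountain_bases

    @property
    def loop_list(self):
        return self.spec.loop_list

    @property
    def compartment_labels(self):
        return self.spec.compartment_labels


def _expected_counts(spec: SyntheticSpec, chrom: str) -> np.ndarray:
    size = spec.chrom_sizes[chrom]
    n = int(np.ceil(size / spec.binsize))
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    e = (1.0 + d).astype(float) ** spec.decay_exponent
    if spec.loop_bump_size_bp:
        # Gaussian enhancement of decay in log-separation space, emulating
        # the extruded-loop "bump" of P(s)
        sep = np.maximum(d, 1) * spec.binsize
        mu = np.log10(spec.loop_bump_size_bp)
        e *= np.exp(
            spec.loop_bump_amplitude
            * np.exp(-((np.log10(sep) - mu) ** 2) / (2 * 0.25**2))
        )
    if spec.compartment_amplitude != 1.0 and chrom in spec.compartment_labels:
        lab = np.asarray(spec.compartment_labels[chrom], dtype=float)
        f = spec.compartment_amplitude
        same = np.outer(lab, lab) > 0
        e = np.where(same, e * f, e / f)
    w = spec.loop_width_bins
    for c, p1, p2, fold in spec.loop_list:
        if c != chrom:
            continue
        b1, b2 = int(p1 // spec.binsize), int(p2 // spec.binsize)
        lo1, hi1 = max(0, b1 - w), min(n, b1 + w + 1)
        lo2, hi2 = max(0, b2 - w), min(n, b2 + w + 1)
        e[lo1:hi1, lo2:hi2] *= fold
        e[lo2:hi2, lo1:hi1] *= fold
    fw = spec.fountain_width_bins
    for c, pos, extent, amp in spec.fountain_bases:
        if c != chrom or amp == 0:
            continue
        cbin = int(pos // spec.binsize)
        ext_bins = int(extent // spec.binsize)
        # pixels on the perpendicular diagonal through cbin: i+j ~ 2*cbin,
        # within |j-i| <= extent
        anti = np.abs((idx[:, None] + idx[None, :]) - 2 * cbin) <= fw
        within = d <= ext_bins
        sel = anti & within
        e = np.where(sel, e * amp, e)
    return e


def synthesize_contact_matrix(spec: SyntheticSpec) -> SyntheticMap:
    """Build expected counts and Poisson-sample them to ``total_counts``.

    The upper triangle (including diagonal) is sampled and mirrored, so the
    matrix is exactly symmetric; a fixed seed gives a bit-identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    expected = {c: _expected_counts(spec, c) for c in spec.chrom_sizes}
    total_mass = sum(np.triu(e).sum() for e in expected.values())
    scale = spec.total_counts / total_mass
    mats = {}
    for chrom, e in expected.items():
        lam = np.triu(e) * scale
        counts = rng.poisson(lam).astype(float)
        counts = counts + np.triu(counts, 1).T
        if chrom in spec.bad_bins:
            bad = np.asarray(spec.bad_bins[chrom])
            counts[bad, :] = np.nan
            counts[:, bad] = np.nan
        mats[chrom] = counts
        expected[chrom] = e * scale
    cm = ContactMatrix(mats, spec.binsize, dict(spec.chrom_sizes))
    return SyntheticMap(cm, expected, spec)


NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def synthesize_peak_table(
    oci_positions: list[tuple[str, int]],
    chrom_sizes: dict[str, int],
    oci_score: float = 150.0,
    background_peaks_per_mb: float = 2.0,
    background_score: float = 5.0,
    peak_width: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """ATAC-like narrowPeak table whose binned scores exceed the open-
    chromatin-island threshold exactly at the designated positions.

    Each designated position receives one peak of score ``oci_score`` (above
    the 5-bin window threshold of 100 on its own); background peaks are
    scattered uniformly at low score so no other window crosses it.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for chrom, size in chrom_sizes.items():
        n_bg = rng.poisson(background_peaks_per_mb * size / 1e6)
        for s in np.sort(rng.integers(0, max(1, size - peak_width), n_bg)):
            rows.append((chrom, int(s), int(s + peak_width), f"bg_{k}",
                         background_score, ".", background_score, -1.0, -1.0,
                         peak_width // 2))
            k += 1
    for chrom, pos in oci_positions:
        s = int(max(0, min(pos, chrom_sizes[chrom] - peak_width)))
        rows.append((chrom, s, s + peak_width, f"oci_{k}", oci_score, ".",
                     oci_score, -1.0, -1.0, peak_width // 2))
        k += 1
    df = pd.DataFrame(rows, columns=NARROWPEAK_COLS)
    return df.sort_values(["chrom", "start"], ignore_index=True)


GENE_LABELS = ("up-regulated", "down-regulated", "stable")


def synthesize_gene_table(
    n_genes: int,
    fountain_bases: list[tuple[str, int]],
    chrom_sizes: dict[str, int],
    scenario: str = "null",
    odds: float = 5.0,
    label_fractions: tuple[float, float, float] = (0.1, 0.1, 0.8),
    flank_bp: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene table with TSS coordinates and expression labels.

    Scenarios: "null" draws labels independently of position;
    "down_in_flanks" multiplies the down-regulated odds by ``odds`` for
    genes whose TSS falls within ``flank_bp`` of a fountain base;
    "all_stable" labels every gene stable.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_genes, p=sizes / sizes.sum())
    tss = np.array(
        [rng.integers(0, chrom_sizes[chroms[i]]) for i in chrom_idx], dtype=np.int64
    )
    chrom = np.array([chroms[i] for i in chrom_idx])
    strand = rng.choice(["+", "-"], size=n_genes)

    in_flank = np.zeros(n_genes, dtype=bool)
    for bc, bp in fountain_bases:
        in_flank |= (chrom == bc) & (np.abs(tss - bp) <= flank_bp)

    p_up, p_down, p_stable = label_fractions
    labels = np.empty(n_genes, dtype=object)
    if scenario == "all_stable":
        labels[:] = "stable"
    else:
        base = np.array([p_up, p_down, p_stable])
        boosted = base.copy()
        if scenario == "down_in_flanks":
            boosted[1] *= odds
            boosted /= boosted.sum()
        elif scenario != "null":
            raise ValueError(f"unknown scenario {scenario!r}")
        for i in range(n_genes):
            p = boosted if (scenario == "down_in_flanks" and in_flank[i]) else base
            labels[i] = GENE_LABELS[rng.choice(3, p=p)]
    return pd.DataFrame(
        {
            "gene_id": [f"gene_{i}" for i in range(n_genes)],
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "label": labels,
        }
    )
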