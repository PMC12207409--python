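"""Balanced, binned Hi-C contact matrices and minimal cooler-format I/O.

The in-memory model is deliberately simple: one dense, symmetric, float64
matrix per chromosome holding *balanced* contact values, with NaN at masked
("bad") bins, i.e. bins that received no balancing weight. All downstream
operations (expected profiles, O/E, pileups, snippets) are intra-chromosomal,
so no global pixel table is kept. Dense storage is adequate at the matrix
sizes this package targets (a few thousand bins per chromosome).

On disk the standard single-resolution cooler layout (HDF5 groups ``chroms``,
``bins``, ``pixels``, ``indexes``) is used, so files written here are plain
.cool files; multi-resolution files with a ``resolutions/<res>`` group are
also understood on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["ContactMatrix", "load_matrix", "write_cool"]


@dataclass
class ContactMatrix:
    """Balanced intra-chromosomal contact matrices on a fixed bin grid.

    Parameters
    ----------
    mats :
        Mapping chromosome name -> dense symmetric (n, n) array of balanced
        contact values. Rows/columns of bad bins are NaN.
    resolution :
        Bin size in bp.
    chrom_sizes :
        Mapping chromosome name -> length in bp. Defaults to
        ``n_bins * resolution`` per chromosome.
    """

    mats: dict[str, np.ndarray]
    resolution: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, m in self.mats.items():
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"matrix for {chrom} is not square")
            self.mats[chrom] = m
            if chrom not in self.chrom_sizes:
                self.chrom_sizes[chrom] = m.shape[0] * self.resolution

    @property
    def chromnames(self) -> list[str]:
        return list(self.mats)

    def n_bins(self, chrom: str) -> int:
        return self.mats[chrom].shape[0]

    def matrix(self, chrom: str) -> np.ndarray:
        """Dense balanced matrix for one chromosome (NaN at bad bins)."""
        return self.mats[chrom]

    def bad_bins(self, chrom: str) -> np.ndarray:
        """Boolean mask of bins with no usable data (entire row NaN)."""
        m = self.mats[chrom]
        return np.all(np.isnan(m), axis=1)

    def mask_bins(self, chrom: str, bins: np.ndarray) -> None:
        """Mark ``bins`` (indices or boolean mask) of ``chrom`` as bad."""
        idx = np.asarray(bins)
        self.mats[chrom][idx, :] = np.nan
        self.mats[chrom][:, idx] = np.nan

    def bin_table(self) -> pd.DataFrame:
        """Genome-wide bin table (chrom, start, end), 0-based half-open."""
        frames = []
        for chrom in self.chromnames:
            n = self.n_bins(chrom)
            start = np.arange(n) * self.resolution
            end = np.minimum(start + self.resolution, self.chrom_sizes[chrom])
            frames.append(pd.DataFrame({"chrom": chrom, "start": start, "end": end}))
        return pd.concat(frames, ignore_index=True)

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            {c: m.copy() for c, m in self.mats.items()},
            self.resolution,
            dict(self.chrom_sizes),
        )

    # -- validation helpers -------------------------------------------------

    def check_symmetry(self, atol: float = 1e-8) -> bool:
        for m in self.mats.values():
            a, b = m, m.T
            ok = np.isnan(a) == np.isnan(b)
            if not ok.all():
                return False
            good = ~np.isnan(a)
            if not np.allclose(a[good], b[good], atol=atol):
                return False
        return True


def write_cool(cm: ContactMatrix, path: str) -> None:
    """Write a ContactMatrix as a single-resolution cooler (.cool) file.

    Balanced values are stored in the ``count`` column (float) with unit
    weights for good bins and NaN weights for bad bins, so the round trip
    through :func:`load_matrix` reproduces the matrix exactly.
    """
    chroms = cm.chromnames
    bins = cm.bin_table()
    n_bins_total = len(bins)
    chrom_offsets = np.cumsum([0] + [cm.n_bins(c) for c in chroms])

    bin1, bin2, count = [], [], []
    weights = np.ones(n_bins_total)
    for ci, chrom in enumerate(chroms):
        off = chrom_offsets[ci]
        m = cm.mats[chrom]
        bad = cm.bad_bins(chrom)
        weights[off : off + len(bad)][bad] = np.nan
        iu, ju = np.triu_indices_from(m)
        vals = m[iu, ju]
        keep = ~np.isnan(vals) & (vals != 0)
        bin1.append(iu[keep] + off)
        bin2.append(ju[keep] + off)
        count.append(vals[keep])
    bin1 = np.concatenate(bin1) if bin1 else np.array([], dtype=np.int64)
    bin2 = np.concatenate(bin2) if bin2 else np.array([], dtype=np.int64)
    count = np.concatenate(count) if count else np.array([], dtype=float)
    order = np.lexsort((bin2, bin1))
    bin1, bin2, count = bin1[order], bin2[order], count[order]

    bin1_offset = np.searchsorted(bin1, np.arange(n_bins_total + 1))

    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "HDF5::Cooler"
        h5.attrs["format-version"] = 3
        h5.attrs["bin-type"] = "fixed"
        h5.attrs["bin-size"] = cm.resolution
        h5.attrs["nbins"] = n_bins_total
        h5.attrs["nchroms"] = len(chroms)
        h5.attrs["nnz"] = len(count)
        grp = h5.create_group("chroms")
        grp.create_dataset("name", data=np.array(chroms, dtype="S64"))
        grp.create_dataset(
            "length", data=np.array([cm.chrom_sizes[c] for c in chroms], dtype=np.int64)
        )
        grp = h5.create_group("bins")
        grp.create_dataset(
            "chrom", data=bins["chrom"].map({c: i for i, c in enumerate(chroms)}).to_numpy(np.int32)
        )
        grp.create_dataset("start", data=bins["start"].to_numpy(np.int64))
        grp.create_dataset("end", data=bins["end"].to_numpy(np.int64))
        grp.create_dataset("weight", data=weights)
        grp = h5.create_group("pixels")
        grp.create_dataset("bin1_id", data=bin1.astype(np.int64))
        grp.create_dataset("bin2_id", data=bin2.astype(np.int64))
        grp.create_dataset("count", data=count)
        grp = h5.create_group("indexes")
        grp.create_dataset("chrom_offset", data=chrom_offsets.astype(np.int64))
        grp.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))


def _resolve_group(h5: h5py.File, resolution: int) -> h5py.Group:
    if "resolutions" in h5:
        key = str(resolution)
        if key not in h5["resolutions"]:
            avail = sorted(h5["resolutions"].keys(), key=int)
            raise ValueError(
                f"resolution {resolution} not present; available: {avail}"
            )
        return h5["resolutions"][key]
    binsize = int(h5.attrs.get("bin-size", -1))
    if binsize != resolution:
        raise ValueError(
            f"requested resolution {resolution} but file stores bin-size {binsize}"
        )
    return h5


def load_matrix(path: str, resolution: int) -> ContactMatrix:
    """Load a balanced contact matrix from a cooler file at ``resolution``.

    Raises ``ValueError`` naming the deficiency if the resolution is absent
    or the file carries no balancing weights.
    """
    with h5py.File(path, "r") as h5:
        grp = _resolve_group(h5, resolution)
        names = [n.decode() if isinstance(n, bytes) else n for n in grp["chroms/name"][:]]
        lengths = grp["chroms/length"][:]
        if "weight" not in grp["bins"]:
            raise ValueError(f"{path} has no balancing weights ('bins/weight' missing)")
        weight = grp["bins/weight"][:]
        chrom_ids = grp["bins/chrom"][:]
        bin1 = grp["pixels/bin1_id"][:]
        bin2 = grp["pixels/bin2_id"][:]
        count = grp["pixels/count"][:].astype(float)
        chrom_offset = grp["indexes/chrom_offset"][:]

    mats: dict[str, np.ndarray] = {}
    chrom_sizes: dict[str, int] = {}
    balanced = count * weight[bin1] * weight[bin2]
    for ci, chrom in enumerate(names):
        lo, hi = int(chrom_offset[ci]), int(chrom_offset[ci + 1])
        n = hi - lo
        m = np.zeros((n, n))
        sel = (bin1 >= lo) & (bin1 < hi) & (bin2 >= lo) & (bin2 < hi)
        i = bin1[sel] - lo
        j = bin2[sel] - lo
        m[i, j] = balanced[sel]
        m[j, i] = balanced[sel]
        bad = np.isnan(weight[lo:hi])
        m[bad, :] = np.nan
        m[:, bad] = np.nan
        if np.any((chrom_ids[lo:hi] != ci)):
            warnings.warn(f"bin table of {chrom} not contiguous; trusting chrom_offset")
        mats[chrom] = m
        chrom_sizes[chrom] = int(lengths[ci])
    return ContactMatrix(mats, resolution, chrom_sizes)
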