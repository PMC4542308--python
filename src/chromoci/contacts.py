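"""Sparse binned Hi-C contact maps: representation, text I/O, normalization.

A :class:`ContactMap` stores the upper triangle (including the diagonal) of
a symmetric binned contact matrix as COO records (bin_i <= bin_j, count).
Raw maps carry integer counts so that exact tests (Fisher) always see true
counts; depth-normalized views are a separate, clearly marked
representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinTable, GenomeAssembly, _open_text

__all__ = [
    "ContactMap",
    "read_pairs",
    "write_pairs",
    "read_coo",
    "write_coo",
    "split_cis_trans",
    "depth_normalize",
    "decay_profile",
]


class ContactMap:
    """Binned symmetric contact counts stored as upper-triangle COO records."""

    def __init__(
        self,
        bins: BinTable,
        bin1: np.ndarray,
        bin2: np.ndarray,
        count: np.ndarray,
        *,
        normalized: bool = False,
    ):
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        count = np.asarray(count, dtype=float if normalized else np.int64)
        if not (bin1.shape == bin2.shape == count.shape):
            raise ValueError("bin1/bin2/count must have equal length")
        if bin1.size and (bin1.min() < 0 or bin2.min() < 0):
            raise ValueError("negative bin index")
        if bin1.size and max(bin1.max(), bin2.max()) >= bins.n_bins:
            raise ValueError("bin index outside bin table")
        if (count <= 0).any():
            raise ValueError("counts must be positive")

        # canonicalize: i <= j, then aggregate duplicates
        swap = bin1 > bin2
        b1 = np.where(swap, bin2, bin1)
        b2 = np.where(swap, bin1, bin2)
        key = b1 * bins.n_bins + b2
        uniq, inv = np.unique(key, return_inverse=True)
        agg = np.bincount(inv, weights=count, minlength=uniq.size)
        self.bins = bins
        self.bin1 = (uniq // bins.n_bins).astype(np.int64)
        self.bin2 = (uniq % bins.n_bins).astype(np.int64)
        self.count = agg if normalized else agg.astype(np.int64)
        self.normalized = normalized

    # ---- totals -----------------------------------------------------------

    @property
    def n_records(self) -> int:
        return self.bin1.size

    @property
    def total(self) -> float:
        return float(self.count.sum())

    @property
    def cis_mask(self) -> np.ndarray:
        code = self.bins.chrom_code
        return code[self.bin1] == code[self.bin2]

    @property
    def cis_total(self) -> float:
        return float(self.count[self.cis_mask].sum())

    @property
    def trans_total(self) -> float:
        return float(self.count[~self.cis_mask].sum())

    @property
    def separation_bp(self) -> np.ndarray:
        """Midpoint separation of each record's bins; NaN for trans records."""
        mid = self.bins.midpoint
        sep = np.abs(mid[self.bin2] - mid[self.bin1])
        return np.where(self.cis_mask, sep, np.nan)

    def dense(self) -> np.ndarray:
        """Full symmetric dense matrix (small maps / tests only)."""
        n = self.bins.n_bins
        m = np.zeros((n, n))
        m[self.bin1, self.bin2] = self.count
        m[self.bin2, self.bin1] = self.count
        return m

    def __repr__(self) -> str:  # pragma: no cover
        kind = "normalized" if self.normalized else "raw"
        return f"ContactMap({self.n_records} records, total={self.total:g}, {kind})"


def read_pairs(path, bins: BinTable) -> ContactMap:
    """Read whitespace-separated contact pairs: chrom1 pos1 chrom2 pos2 [count].

    Positions are binned by integer division; duplicate bin pairs are
    aggregated; records are canonicalized to bin_i <= bin_j.
    """
    c1, p1, c2, p2, cnt = [], [], [], [], []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (4, 5):
                raise ValueError(f"{path}:{ln}: expected 4 or 5 columns")
            c1.append(parts[0])
            c2.append(parts[2])
            try:
                p1.append(int(parts[1]))
                p2.append(int(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed position") from exc
            cnt.append(int(parts[4]) if len(parts) == 5 else 1)
    if not c1:
        return ContactMap(bins, np.empty(0, int), np.empty(0, int), np.empty(0, int))
    b1 = bins.bin_of(np.asarray(c1, dtype=object), np.asarray(p1))
    b2 = bins.bin_of(np.asarray(c2, dtype=object), np.asarray(p2))
    return ContactMap(bins, b1, b2, np.asarray(cnt))


def write_pairs(cmap: ContactMap, path) -> None:
    """Serialize a raw map as pairs lines anchored at bin starts."""
    if cmap.normalized:
        raise ValueError("pairs serialization is defined for raw counts only")
    bins = cmap.bins
    with _open_text(path, "wt") as fh:
        for i, j, c in zip(cmap.bin1, cmap.bin2, cmap.count):
            fh.write(
                f"{bins.chrom[i]}\t{bins.start[i]}\t"
                f"{bins.chrom[j]}\t{bins.start[j]}\t{c}\n"
            )


def read_coo(matrix_path, bins_path) -> ContactMap:
    """Read COO triples 'bin_i bin_j count' with a sidecar bin table.

    The sidecar has lines 'chrom start end index'; the bin size is inferred
    and the assembly reconstructed from per-chromosome maxima.
    """
    side = pd.read_csv(
        bins_path, sep=r"\s+", header=None,
        names=["chrom", "start", "end", "index"], comment="#",
    )
    side = side.sort_values("index").reset_index(drop=True)
    if not (side["index"].to_numpy() == np.arange(len(side))).all():
        raise ValueError("sidecar bin indices are not consecutive from 0")
    bin_size = int((side["end"] - side["start"]).max())
    assembly = GenomeAssembly(
        tuple(
            (chrom, int(grp["end"].max()))
            for chrom, grp in side.groupby("chrom", sort=False)
        )
    )
    bins = BinTable(assembly, bin_size)
    if bins.n_bins != len(side):
        raise ValueError("sidecar bin table is not a valid fixed-size tiling")

    tri = pd.read_csv(
        matrix_path, sep=r"\s+", header=None,
        names=["bin1", "bin2", "count"], comment="#",
    )
    if len(tri) == 0:
        return ContactMap(bins, np.empty(0, int), np.empty(0, int), np.empty(0, int))
    if (tri["bin1"].max() >= bins.n_bins) or (tri["bin2"].max() >= bins.n_bins):
        raise ValueError("bin index outside the sidecar bin table")
    return ContactMap(
        bins,
        tri["bin1"].to_numpy(),
        tri["bin2"].to_numpy(),
        tri["count"].to_numpy(),
    )


def write_coo(cmap: ContactMap, matrix_path, bins_path) -> None:
    bins = cmap.bins
    with _open_text(bins_path, "wt") as fh:
        for idx in range(bins.n_bins):
            fh.write(
                f"{bins.chrom[idx]}\t{bins.start[idx]}\t{bins.end[idx]}\t{idx}\n"
            )
    with _open_text(matrix_path, "wt") as fh:
        for i, j, c in zip(cmap.bin1, cmap.bin2, cmap.count):
            fh.write(f"{i}\t{j}\t{c:g}\n" if cmap.normalized else f"{i}\t{j}\t{c}\n")


def split_cis_trans(cmap: ContactMap) -> tuple[float, float, np.ndarray]:
    """(cis total, trans total, per-record cis mask); totals partition total."""
    m = cmap.cis_mask
    return float(cmap.count[m].sum()), float(cmap.count[~m].sum()), m


def depth_normalize(cmap: ContactMap) -> ContactMap:
    """Counts per million total pairs; idempotent in value."""
    if cmap.total <= 0:
        raise ValueError("cannot normalize an empty map")
    scale = 1e6 / cmap.total
    return ContactMap(
        cmap.bins, cmap.bin1, cmap.bin2, cmap.count * scale, normalized=True
    )


def decay_profile(cmap: ContactMap) -> pd.DataFrame:
    """Mean contact count per cis separation stratum (in bins).

    The denominator counts *all possible* cis bin pairs at each separation,
    including zero-count pairs, so the profile estimates the expected count
    per pair. Used as a simulation diagnostic (log-log slope ~ -alpha).
    """
    bins = cmap.bins
    max_n = max(bins.nbins_per_chrom.values())
    npairs = np.zeros(max_n, dtype=np.int64)
    for n in bins.nbins_per_chrom.values():
        s = np.arange(n)
        npairs[:n] += n - s
    total = np.zeros(max_n)
    m = cmap.cis_mask
    sep = (cmap.bin2 - cmap.bin1)[m]
    np.add.at(total, sep, cmap.count[m])
    return pd.DataFrame(
        {
            "separation_bins": np.arange(max_n),
            "total_count": total,
            "n_pairs": npairs,
            "mean_count": total / npairs,
        }
    )
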