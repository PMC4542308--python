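"""The Open Chromatin Index (OCI): local vs distal contact balance per window.

For each genomic window the OCI contrasts *local* contacts (both Hi-C
anchors inside the window) with a *control* count — either
interchromosomal contacts anchored in the window (trans mode, the default)
or cis contacts spanning more than a distance threshold (cis-distal mode,
default 20 Mb). The raw statistic is

    raw = log2((control + psi) / (local + psi)),

centered by subtracting the per-chromosome median over informative
windows and smoothed with a centered rolling mean spanning 20 Mb. High
OCI means a region has lost local connectivity relative to its distal
reach ("open"); a region that loses within-TAD contacts between two
conditions rises in OCI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .genome import BinTable, FeatureClassing, IntervalSet, ScalarTrack, bin_genome

__all__ = [
    "OCIParams",
    "OCITrack",
    "window_table",
    "count_local",
    "count_control",
    "compute_oci",
    "delta_oci",
    "stratify_oci",
    "meta_profile",
]


@dataclass(frozen=True)
class OCIParams:
    """Tunable parameters of the OCI computation."""

    window_bp: int = 200_000
    smoothing_span_bp: int = 20_000_000
    pseudocount: float = 1.0
    control_mode: str = "trans"           # "trans" | "cis-distal"
    cis_threshold_bp: int = 20_000_000
    min_informative: int = 10

    def __post_init__(self) -> None:
        if self.control_mode not in ("trans", "cis-distal"):
            raise ValueError("control_mode must be 'trans' or 'cis-distal'")
        if self.smoothing_span_bp < self.window_bp:
            raise ValueError("smoothing span must be >= window size")


def window_table(bins: BinTable, window_bp: int) -> tuple[BinTable, np.ndarray]:
    """Aggregate bins into windows of ``window_bp``; windows are themselves
    a BinTable, so all per-bin machinery (classing, tracks) applies to them.

    Returns (window table, per-bin window index). ``window_bp`` must be a
    multiple of the bin size.
    """
    if window_bp % bins.bin_size != 0:
        raise ValueError("window size must be a multiple of the bin size")
    windows = bin_genome(bins.assembly, window_bp)
    win_of_bin = windows.bin_of(bins.chrom, bins.start)
    return windows, win_of_bin


def count_local(cmap: ContactMap, win_of_bin: np.ndarray, n_windows: int) -> np.ndarray:
    """Counts with both anchors inside the same window (diagonal included)."""
    w1 = win_of_bin[cmap.bin1]
    w2 = win_of_bin[cmap.bin2]
    inside = w1 == w2
    out = np.zeros(n_windows)
    np.add.at(out, w1[inside], cmap.count[inside])
    return out


def count_control(
    cmap: ContactMap,
    win_of_bin: np.ndarray,
    n_windows: int,
    params: OCIParams,
) -> np.ndarray:
    """Control counts per window.

    trans mode: records whose anchors sit on different chromosomes credit
    the window of *each* anchor (double anchoring keeps genome totals
    conserved). cis-distal mode: same-chromosome records with bin-midpoint
    separation beyond the threshold, likewise credited to both anchor
    windows (once if both anchors share a window, which cannot happen when
    the threshold exceeds the window size).
    """
    w1 = win_of_bin[cmap.bin1]
    w2 = win_of_bin[cmap.bin2]
    if params.control_mode == "trans":
        eligible = ~cmap.cis_mask
    else:
        sep = cmap.separation_bp
        eligible = cmap.cis_mask & (sep > params.cis_threshold_bp)
    out = np.zeros(n_windows)
    np.add.at(out, w1[eligible], cmap.count[eligible])
    second = eligible & (w1 != w2)
    np.add.at(out, w2[second], cmap.count[second])
    return out


@dataclass
class OCITrack:
    """Per-window OCI values (raw, chromosome-median-centered, smoothed)."""

    windows: BinTable
    local: np.ndarray
    control: np.ndarray
    raw: np.ndarray
    centered: np.ndarray
    smoothed: np.ndarray
    mask: np.ndarray          # True = uninformative window
    params: OCIParams

    @property
    def n_windows(self) -> int:
        return self.windows.n_bins

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.windows.chrom,
                "start": self.windows.start,
                "end": self.windows.end,
                "local": self.local,
                "control": self.control,
                "raw": self.raw,
                "centered": self.centered,
                "smoothed": self.smoothed,
                "masked": self.mask.astype(int),
            }
        )

    def as_scalar_track(self, which: str = "smoothed") -> ScalarTrack:
        return ScalarTrack(self.windows, getattr(self, which), name=f"oci_{which}")


def _rolling_mean(values: np.ndarray, width: int) -> np.ndarray:
    """Centered rolling NaN-mean; chromosome ends use the partial span."""
    s = pd.Series(values)
    return s.rolling(width, center=True, min_periods=1).mean().to_numpy()


def compute_oci(cmap: ContactMap, params: OCIParams = OCIParams()) -> OCITrack:
    """Compute the OCI track of a contact map.

    Windows with fewer than ``min_informative`` total (local + control)
    counts are masked before the per-chromosome median is taken; the
    rolling mean skips masked windows and keeps them missing in the
    smoothed output.
    """
    if cmap.n_records == 0:
        raise ValueError("cannot compute OCI on an empty map")
    windows, win_of_bin = window_table(cmap.bins, params.window_bp)
    n = windows.n_bins
    local = count_local(cmap, win_of_bin, n)
    control = count_control(cmap, win_of_bin, n, params)

    psi = params.pseudocount
    raw = np.log2((control + psi) / (local + psi))
    mask = (local + control) < params.min_informative

    centered = np.full(n, np.nan)
    smoothed = np.full(n, np.nan)
    width = 2 * (params.smoothing_span_bp // (2 * params.window_bp)) + 1
    for chrom, sl in windows.chrom_slices().items():
        cmask = mask[sl]
        if cmask.all():
            raise ValueError(f"all windows masked on chromosome {chrom!r}")
        craw = np.where(cmask, np.nan, raw[sl])
        med = np.nanmedian(craw)
        ccen = craw - med
        centered[sl] = ccen
        csm = _rolling_mean(ccen, width)
        csm[cmask] = np.nan
        smoothed[sl] = csm
    return OCITrack(windows, local, control, raw, centered, smoothed, mask, params)


def delta_oci(track_a: OCITrack, track_b: OCITrack, which: str = "smoothed") -> ScalarTrack:
    """Per-window OCI difference b - a; missing where either is masked."""
    if track_a.windows != track_b.windows:
        raise ValueError("tracks are on different windowings")
    va = getattr(track_a, which)
    vb = getattr(track_b, which)
    d = vb - va
    d[track_a.mask | track_b.mask] = np.nan
    return ScalarTrack(track_a.windows, d, name=f"delta_oci_{which}")


def stratify_oci(values: ScalarTrack, classing: FeatureClassing) -> pd.DataFrame:
    """Distribution summary (n, mean, median, quartiles) per feature class."""
    if values.bins != classing.bins:
        raise ValueError("classing is on different windows than the track")
    rows = []
    labels = classing.labels.astype(str)
    for cls in sorted(set(labels)):
        v = values.values[(labels == cls) & ~values.missing]
        if v.size == 0:
            rows.append({"class": cls, "n": 0, "mean": np.nan, "median": np.nan,
                         "q25": np.nan, "q75": np.nan})
        else:
            rows.append({
                "class": cls, "n": int(v.size), "mean": float(v.mean()),
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
            })
    return pd.DataFrame(rows)


def meta_profile(
    values: ScalarTrack,
    intervals: IntervalSet,
    flank_fraction: float = 0.5,
    body_points: int = 50,
    flank_points: int = 25,
) -> pd.DataFrame:
    """Length-normalized average profile of a window track across intervals.

    Each interval is rescaled to [0, 1] with flanks of
    ``flank_fraction * length`` on each side; track values are linearly
    interpolated from window midpoints onto a fixed grid and averaged
    across intervals. Intervals shorter than one window are skipped (the
    count of skipped intervals is reported in ``attrs``).
    """
    windows = values.bins
    grid = np.concatenate([
        -flank_fraction + (np.arange(flank_points) + 0.5) * flank_fraction / flank_points,
        (np.arange(body_points) + 0.5) / body_points,
        1.0 + (np.arange(flank_points) + 0.5) * flank_fraction / flank_points,
    ])
    profiles = []
    skipped = 0
    for row in intervals.frame.itertuples(index=False):
        length = row.end - row.start
        if length < windows.bin_size or row.chrom not in windows.offsets:
            skipped += 1
            continue
        sl = windows.chrom_slices()[row.chrom]
        mids = windows.midpoint[sl]
        vals = values.values[sl]
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            skipped += 1
            continue
        pos = row.start + grid * length
        profiles.append(np.interp(pos, mids[ok], vals[ok]))
    if not profiles:
        out = pd.DataFrame({"x": grid, "mean": np.nan, "n": 0})
    else:
        arr = np.vstack(profiles)
        out = pd.DataFrame({"x": grid, "mean": arr.mean(axis=0), "n": len(profiles)})
    out.attrs["skipped"] = skipped
    return out
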