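"""Genome coordinates, binning, interval annotations and GC/isochore machinery.

Everything downstream (contact maps, OCI tracks, TAD calls, class matrices)
is expressed on top of three containers defined here:

* :class:`GenomeAssembly` — ordered chromosome names and lengths.
* :class:`BinTable` — a fixed-size tiling of the assembly into bins
  (0-based, half-open; the last bin of a chromosome may be short).
* :class:`IntervalSet` — strandless labeled intervals (LADs, isochores,
  TADs, histone-mark domains ...), read and written as BED3/BED4.

Coordinates are 0-based half-open throughout, matching BED natively.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAssembly",
    "BinTable",
    "IntervalSet",
    "ScalarTrack",
    "FeatureClassing",
    "OverlapEnrichment",
    "ISOCHORE_BOUNDS",
    "bin_genome",
    "read_bed",
    "write_bed",
    "gc_track",
    "classify_gc",
    "classify_isochores",
    "assign_bin_class",
    "overlap_enrichment",
]


# --------------------------------------------------------------------------
# assembly and bins
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered list of (chromosome name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for name, length in self.chromosomes:
            if int(length) <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")
        _check_naming(names)

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeAssembly":
        return cls(tuple((str(k), int(v)) for k, v in sizes.items()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(l for _, l in self.chromosomes)

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths))

    def __contains__(self, name: str) -> bool:
        return name in self.sizes


def _check_naming(names: Iterable[str]) -> None:
    """Reject a mixture of 'chr1'-style and bare '1'-style names."""
    names = list(names)
    prefixed = [n.startswith("chr") for n in names]
    if any(prefixed) and not all(prefixed):
        raise ValueError(
            "mixed chromosome naming ('chrN' and bare 'N') within one run"
        )


class BinTable:
    """A gapless fixed-size partition of an assembly into genomic bins.

    Bins are indexed consecutively across chromosomes in assembly order;
    each bin has length ``bin_size`` except possibly the last bin of each
    chromosome.
    """

    def __init__(self, assembly: GenomeAssembly, bin_size: int):
        if bin_size < 1:
            raise ValueError("bin size must be a positive integer")
        self.assembly = assembly
        self.bin_size = int(bin_size)

        chroms: list[str] = []
        codes: list[np.ndarray] = []
        starts: list[np.ndarray] = []
        ends: list[np.ndarray] = []
        offsets: dict[str, int] = {}
        nbins: dict[str, int] = {}
        pos = 0
        for ci, (name, length) in enumerate(assembly.chromosomes):
            n = math.ceil(length / bin_size)
            s = np.arange(n, dtype=np.int64) * bin_size
            e = np.minimum(s + bin_size, length)
            chroms.extend([name] * n)
            codes.append(np.full(n, ci, dtype=np.int32))
            starts.append(s)
            ends.append(e)
            offsets[name] = pos
            nbins[name] = n
            pos += n
        self.chrom = np.asarray(chroms, dtype=object)
        self.chrom_code = np.concatenate(codes) if codes else np.empty(0, np.int32)
        self.start = np.concatenate(starts) if starts else np.empty(0, np.int64)
        self.end = np.concatenate(ends) if ends else np.empty(0, np.int64)
        self.offsets = offsets
        self.nbins_per_chrom = nbins

    @property
    def n_bins(self) -> int:
        return self.start.size

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end}
        )

    def bin_of(self, chrom: np.ndarray | Sequence[str], pos: np.ndarray) -> np.ndarray:
        """Global bin index for genomic positions (vectorized)."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.empty(pos.size, dtype=np.int64)
        sizes = self.assembly.sizes
        for name in np.unique(chrom):
            if name not in sizes:
                raise ValueError(f"unknown chromosome {name!r}")
            m = chrom == name
            p = pos[m]
            if (p < 0).any() or (p >= sizes[name]).any():
                raise ValueError(f"position outside chromosome {name!r}")
            out[m] = self.offsets[name] + p // self.bin_size
        return out

    def chrom_slices(self) -> dict[str, slice]:
        return {
            name: slice(off, off + self.nbins_per_chrom[name])
            for name, off in self.offsets.items()
        }

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinTable)
            and self.bin_size == other.bin_size
            and self.assembly == other.assembly
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BinTable({len(self.assembly.names)} chromosomes, "
            f"{self.n_bins} bins of {self.bin_size} bp)"
        )


def bin_genome(assembly: GenomeAssembly, bin_size: int) -> BinTable:
    """Tile the assembly into consecutive fixed-size bins."""
    return BinTable(assembly, bin_size)


# --------------------------------------------------------------------------
# interval sets and BED I/O
# --------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Named collection of strandless labeled intervals (0-based half-open)."""

    name: str
    frame: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        f = self.frame
        if "label" not in f.columns:
            f = f.assign(label="")
        f = f[["chrom", "start", "end", "label"]].reset_index(drop=True)
        f["start"] = f["start"].astype(np.int64)
        f["end"] = f["end"].astype(np.int64)
        f["label"] = f["label"].astype(str)
        if (f["start"] < 0).any():
            raise ValueError("negative interval start")
        if (f["start"] >= f["end"]).any():
            raise ValueError("interval with start >= end")
        _check_naming(f["chrom"].unique())
        self.frame = f

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        name: str = "",
    ) -> "IntervalSet":
        rows = list(records)
        if not rows:
            return cls(name, pd.DataFrame(columns=["chrom", "start", "end", "label"]))
        ncol = len(rows[0])
        cols = ["chrom", "start", "end", "label"][:ncol]
        return cls(name, pd.DataFrame(rows, columns=cols))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["label"].unique()))

    def subset(self, label: str) -> "IntervalSet":
        return IntervalSet(
            f"{self.name}:{label}",
            self.frame[self.frame["label"] == label].reset_index(drop=True),
        )

    def validate_against(self, assembly: GenomeAssembly) -> None:
        sizes = assembly.sizes
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            if chrom not in sizes:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if (grp["end"] > sizes[chrom]).any():
                raise ValueError(f"interval beyond end of chromosome {chrom!r}")

    def merged(self) -> "IntervalSet":
        """Union of all intervals (labels discarded), merged and sorted."""
        rows = []
        for chrom, grp in self.frame.groupby("chrom", sort=True):
            s, e = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
            rows.extend((chrom, a, b, "") for a, b in zip(s, e))
        return IntervalSet.from_records(rows, name=self.name)

    def total_bp(self) -> int:
        m = self.merged().frame
        return int((m["end"] - m["start"]).sum())

    def is_disjoint(self) -> bool:
        for _, grp in self.frame.groupby("chrom", sort=False):
            srt = grp.sort_values("start")
            if (srt["start"].to_numpy()[1:] < srt["end"].to_numpy()[:-1]).any():
                return False
        return True


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent-in-overlap intervals on one chromosome."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def intersect_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Total base pairs in the intersection of two interval sets (as unions)."""
    total = 0
    fa = a.merged().frame
    fb = b.merged().frame
    for chrom in set(fa["chrom"]) & set(fb["chrom"]):
        sa = fa[fa["chrom"] == chrom]
        sb = fb[fb["chrom"] == chrom]
        s1 = sa["start"].to_numpy()[:, None]
        e1 = sa["end"].to_numpy()[:, None]
        s2 = sb["start"].to_numpy()[None, :]
        e2 = sb["end"].to_numpy()[None, :]
        ov = np.minimum(e1, e2) - np.maximum(s1, s2)
        total += int(np.clip(ov, 0, None).sum())
    return total


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path, assembly: GenomeAssembly | None = None, name: str | None = None) -> IntervalSet:
    """Read a BED3/BED4 file; column 4, when present, is the class label."""
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 tab-separated columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed coordinates") from exc
            label = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start, end, label))
    out = IntervalSet.from_records(rows, name=name or Path(path).stem)
    if assembly is not None:
        out.validate_against(assembly)
    return out


def write_bed(intervals: IntervalSet, path) -> None:
    """Write BED3 (all labels empty) or BED4; round-trips exactly."""
    has_labels = (intervals.frame["label"] != "").any() if len(intervals) else False
    with _open_text(path, "wt") as fh:
        for row in intervals.frame.itertuples(index=False):
            if has_labels:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


# --------------------------------------------------------------------------
# per-bin tracks
# --------------------------------------------------------------------------

@dataclass
class ScalarTrack:
    """One numeric value per bin; NaN marks missing (distinct from zero)."""

    bins: BinTable
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bins.n_bins,):
            raise ValueError("track length does not match bin table")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_bedgraph(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for chrom, s, e, v in zip(
                self.bins.chrom, self.bins.start, self.bins.end, self.values
            ):
                if not np.isnan(v):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path, bins: BinTable, name: str = "") -> "ScalarTrack":
        values = np.full(bins.n_bins, np.nan)
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                idx = bins.bin_of([chrom], np.asarray([int(s)]))[0]
                values[idx] = float(v)
        return cls(bins, values, name=name)


# --------------------------------------------------------------------------
# GC content and isochores
# --------------------------------------------------------------------------

def gc_track(fasta_path, bins: BinTable) -> ScalarTrack:
    """GC fraction per bin from a FASTA file, Ns excluded from the denominator.

    Bins containing no A/C/G/T at all are missing (NaN).
    """
    from pyfaidx import Fasta  # optional dependency, imported lazily

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    values = np.full(bins.n_bins, np.nan)
    for name, sl in bins.chrom_slices().items():
        if name not in fa:
            raise ValueError(f"chromosome {name!r} absent from FASTA")
        seq = str(fa[name][:])
        for i in range(sl.start, sl.stop):
            sub = seq[bins.start[i]: bins.end[i]]
            gc = sub.count("G") + sub.count("C")
            at = sub.count("A") + sub.count("T")
            if gc + at > 0:
                values[i] = gc / (gc + at)
    return ScalarTrack(bins, values, name="gc")


#: Isochore class upper bounds in GC%, half-open on the upper side:
#: [0,37) L1, [37,41) L2, [41,46) H1, [46,53) H2, [53,100] H3.
ISOCHORE_BOUNDS: tuple[tuple[str, float], ...] = (
    ("L1", 37.0),
    ("L2", 41.0),
    ("H1", 46.0),
    ("H2", 53.0),
    ("H3", math.inf),
)


def classify_gc(values: np.ndarray) -> np.ndarray:
    """Map GC values to isochore class labels (L1/L2/H1/H2/H3).

    Accepts GC as a fraction in [0,1] or a percentage in [0,100]; the scale
    is auto-detected from the maximum value. Missing (NaN) maps to "".
    Boundary values (37, 41, 46, 53 %) are assigned to the higher class.
    """
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if finite.size and np.nanmax(finite) <= 1.0:
        v = v * 100.0
    out = np.full(v.shape, "", dtype=object)
    lower = -math.inf
    for label, upper in ISOCHORE_BOUNDS:
        sel = (~np.isnan(v)) & (v >= lower) & (v < upper)
        out[sel] = label
        lower = upper
    # inf upper bound leaves nothing behind; v == +inf is not meaningful GC
    return out


def classify_isochores(gc: ScalarTrack | IntervalSet) -> IntervalSet:
    """Label bins (or intervals carrying GC) by isochore class and merge runs.

    Adjacent same-class bins are merged into maximal intervals; missing GC
    leaves the corresponding bins unlabeled (omitted from the output).
    """
    if isinstance(gc, IntervalSet):
        if "gc" not in gc.frame.columns:
            raise ValueError("IntervalSet input must carry a 'gc' column")
        labels = classify_gc(gc.frame["gc"].to_numpy())
        f = gc.frame.assign(label=labels)
        return IntervalSet("isochores", f[f["label"] != ""])

    labels = classify_gc(gc.values)
    rows = []
    bins = gc.bins
    for chrom, sl in bins.chrom_slices().items():
        cur = None  # (label, start, end)
        for i in range(sl.start, sl.stop):
            lab = labels[i]
            if lab == "":
                if cur:
                    rows.append((chrom, cur[1], cur[2], cur[0]))
                    cur = None
                continue
            if cur and cur[0] == lab:
                cur = (lab, cur[1], bins.end[i])
            else:
                if cur:
                    rows.append((chrom, cur[1], cur[2], cur[0]))
                cur = (lab, bins.start[i], bins.end[i])
        if cur:
            rows.append((chrom, cur[1], cur[2], cur[0]))
    return IntervalSet.from_records(rows, name="isochores")


# --------------------------------------------------------------------------
# bin classification and overlap enrichment
# --------------------------------------------------------------------------

@dataclass
class FeatureClassing:
    """Per-bin class labels; bins not overlapping any feature are 'none'."""

    bins: BinTable
    labels: np.ndarray  # object array of str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.bins.n_bins,):
            raise ValueError("classing length does not match bin table")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels) - {"none"}))

    def counts(self) -> dict[str, int]:
        uniq, cnt = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))


def assign_bin_class(bins: BinTable, features: IntervalSet) -> FeatureClassing:
    """Label each bin by the feature class with the largest bp overlap.

    Ties break by lexicographic class name; bins overlapping nothing get
    "none".
    """
    classes = sorted(set(features.frame["label"]))
    overlap = {c: np.zeros(bins.n_bins) for c in classes}
    for row in features.frame.itertuples(index=False):
        if row.chrom not in bins.offsets:
            continue
        sl = bins.chrom_slices()[row.chrom]
        cs = bins.start[sl]
        ce = bins.end[sl]
        lo = int(np.searchsorted(ce, row.start, side="right"))
        hi = int(np.searchsorted(cs, row.end, side="left"))
        if hi <= lo:
            continue
        ov = np.minimum(ce[lo:hi], row.end) - np.maximum(cs[lo:hi], row.start)
        overlap[row.label][sl.start + lo: sl.start + hi] += np.clip(ov, 0, None)

    labels = np.full(bins.n_bins, "none", dtype=object)
    if classes:
        stack = np.stack([overlap[c] for c in classes])  # classes sorted -> ties lexicographic
        best = np.argmax(stack, axis=0)  # argmax takes first (= lexicographic) on ties
        best_ov = stack[best, np.arange(bins.n_bins)]
        labels[best_ov > 0] = np.asarray(classes, dtype=object)[best[best_ov > 0]]
    return FeatureClassing(bins, labels)


@dataclass(frozen=True)
class OverlapEnrichment:
    """log2 observed/expected overlap of two interval sets."""

    log2_ratio: float
    obs_bp: int
    exp_bp: float
    flagged: bool  # True when query or feature is empty (pseudocount-driven)


def overlap_enrichment(
    query: IntervalSet, feature: IntervalSet, assembly: GenomeAssembly,
    pseudocount_bp: float = 1.0,
) -> OverlapEnrichment:
    """Enrichment of query for overlap with feature, as log2 obs/exp.

    obs is the intersection in bp; exp assumes independence:
    ``exp = query_bp * feature_bp / genome_bp``. A 1 bp pseudocount keeps
    the log finite for disjoint or empty sets (flagged when either set is
    empty).
    """
    query.validate_against(assembly)
    feature.validate_against(assembly)
    qbp = query.total_bp()
    fbp = feature.total_bp()
    obs = intersect_bp(query, feature)
    exp = qbp * fbp / assembly.total_bp
    value = math.log2((obs + pseudocount_bp) / (exp + pseudocount_bp))
    return OverlapEnrichment(value, obs, exp, flagged=(qbp == 0 or fbp == 0))
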