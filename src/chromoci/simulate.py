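"""Synthetic Hi-C generator with planted senescence-like restructuring.

The generator emulates the minimal structure the downstream statistics
need: distance-decaying cis contacts, self-interacting TAD blocks, an
alternating GC-poor / GC-rich (L1 / H2) isochore block layout with LADs
preferentially placed on the GC-poor blocks, and two condition-specific
effects:

* a *local loss* factor ``f`` in (0, 1] that depletes within-TAD contacts
  of TADs lying in the target class (default "L1-LAD") in the
  senescent-like condition — the loss of TAD-internal interactions;
* a *trans gain* factor ``gamma`` >= 1 that boosts interchromosomal
  contacts between pairs of target-class bins — the specific clustering
  of GC-poor lamina-associated regions.

An ESC-like condition applies the inverse compaction ``f_esc = 1/f`` to
the same TADs (extra-strong local structure), giving the inverted
local/distal profile used by the domain-segmentation analyses.

Counts are Poisson-sampled from the expected intensities rescaled to a
target depth. Every stage is deterministic given the config seed; a
machine-readable truth table records the planted per-bin effects.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .genome import (
    BinTable,
    FeatureClassing,
    GenomeAssembly,
    IntervalSet,
    ScalarTrack,
    bin_genome,
)

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "SimulationTruth",
    "plan_genome",
    "expected_matrix",
    "sample_map",
    "emit_truth",
    "simulate_condition",
    "simulate_experiment",
    "CONDITIONS",
]

CONDITIONS = ("growing", "senescent", "esc")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults describe a desk-scale genome: 2 chromosomes x 60 Mb at 200 kb
    bins (600 bins), 2 million read pairs per condition — enough for stable
    OCI and TAD statistics while running in seconds.
    """

    chrom_lengths: tuple[int, ...] = (60_000_000, 60_000_000)
    bin_size: int = 200_000
    #: cis distance-decay exponent: E ~ (s+1)^-alpha, s in bins
    alpha: float = 1.0
    #: background cis intensity (arbitrary units; rescaled to depth)
    cis_intensity: float = 1.0
    #: trans baseline intensity per bin pair
    trans_baseline: float = 0.01
    #: within-TAD contact multiplier tau > 1
    tad_multiplier: float = 3.0
    #: TAD length range in bins (uniform)
    tad_size_bins: tuple[int, int] = (8, 20)
    #: isochore block length range in bins per class (uniform, blocks
    #: alternate L1/H2); GC-poor L1 blocks are kept shorter so that,
    #: as in real genomes, L1-LADs are a clear minority of the genome
    block_size_bins: tuple[tuple[str, tuple[int, int]], ...] = (
        ("L1", (8, 16)), ("H2", (22, 40)),
    )
    #: target mean GC per isochore class, in percent
    gc_means: tuple[tuple[str, float], ...] = (("L1", 35.0), ("H2", 49.0))
    #: per-bin Gaussian GC noise (percentage points)
    gc_noise_sd: float = 0.6
    #: probability that a block of each class is lamina-associated
    lad_prob: tuple[tuple[str, float], ...] = (("L1", 0.9), ("H2", 0.1))
    #: senescent local-loss factor f in (0, 1]; 1 = null
    local_loss: float = 1.0
    #: senescent trans-gain factor gamma >= 1; 1 = null
    trans_gain: float = 1.0
    #: ESC compaction factor applied to target TADs; None -> 1/local_loss
    esc_compaction: float | None = None
    #: bin class receiving the planted effects
    target_class: str = "L1-LAD"
    #: total read pairs per condition
    depth: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.local_loss <= 1):
            raise ValueError("local_loss must be in (0, 1]")
        if self.trans_gain < 1:
            raise ValueError("trans_gain must be >= 1")
        if self.tad_multiplier <= 0 or self.cis_intensity <= 0 or self.trans_baseline <= 0:
            raise ValueError("intensities must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def esc_factor(self) -> float:
        return self.esc_compaction if self.esc_compaction is not None else 1.0 / self.local_loss

    def rng(self, stream: int) -> np.random.Generator:
        """Named substream: layout=0, conditions use 1 + condition index."""
        return np.random.default_rng([self.seed, stream])

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedGenome:
    """Planned annotations shared by all conditions of one simulation."""

    config: SimulationConfig
    assembly: GenomeAssembly
    bins: BinTable
    gc: ScalarTrack                 # percent scale
    isochores: IntervalSet          # planted block labels (L1/H2)
    lads: IntervalSet
    tads: IntervalSet
    histone_domains: IntervalSet    # labeled marks: H3K9me3 (= LADs by
                                    # default) and H3K36me3 (active, non-LAD)
    bin_class: FeatureClassing      # "<isochore>-LAD" / "<isochore>-iLAD"
    tad_id: np.ndarray              # per bin, -1 outside any TAD (never here)
    tad_is_target: np.ndarray       # per TAD (bool)

    @property
    def target_bins(self) -> np.ndarray:
        """Bins lying in a target-class TAD (where local effects act)."""
        return np.isin(self.tad_id, np.flatnonzero(self.tad_is_target))

    @property
    def target_class_bins(self) -> np.ndarray:
        """Bins whose own class is the target class (where trans gain acts)."""
        return self.bin_class.labels == self.config.target_class


def _draw_blocks(
    rng: np.random.Generator, n_bins: int, lo: int, hi: int
) -> list[int]:
    """Partition n_bins into consecutive block lengths uniform in [lo, hi]."""
    sizes: list[int] = []
    left = n_bins
    while left > 0:
        k = int(rng.integers(lo, hi + 1))
        if left - k < lo:  # absorb the remainder into the final block
            k = left
        sizes.append(k)
        left -= k
    return sizes


def _draw_alternating_blocks(
    rng: np.random.Generator,
    n_bins: int,
    ranges: dict[str, tuple[int, int]],
    classes: list[str],
) -> list[tuple[str, int]]:
    """Alternate classes along a chromosome, each with its own size range."""
    out: list[tuple[str, int]] = []
    left = n_bins
    bi = 0
    while left > 0:
        cls = classes[bi % len(classes)]
        lo, hi = ranges[cls]
        k = int(rng.integers(lo, hi + 1))
        if left - k < min(r[0] for r in ranges.values()):
            k = left
        out.append((cls, k))
        left -= k
        bi += 1
    return out


def plan_genome(config: SimulationConfig) -> SimulatedGenome:
    """Lay out isochore blocks, LADs and TADs; deterministic given the seed."""
    assembly = GenomeAssembly(
        tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(config.chrom_lengths))
    )
    bins = bin_genome(assembly, config.bin_size)
    rng = config.rng(0)
    gc_means = dict(config.gc_means)
    lad_prob = dict(config.lad_prob)
    iso_classes = list(gc_means)

    gc = np.full(bins.n_bins, np.nan)
    iso_rows, lad_rows, ilad_rows, tad_rows = [], [], [], []
    tad_id = np.full(bins.n_bins, -1, dtype=np.int64)
    iso_label = np.full(bins.n_bins, "", dtype=object)
    lad_flag = np.zeros(bins.n_bins, dtype=bool)

    for chrom, sl in bins.chrom_slices().items():
        n = sl.stop - sl.start
        starts = bins.start[sl]
        ends = bins.end[sl]
        # alternating isochore blocks, optionally lamina-associated
        pos = 0
        for cls, size in _draw_alternating_blocks(
            rng, n, dict(config.block_size_bins), iso_classes
        ):
            a, b = pos, pos + size
            iso_rows.append((chrom, int(starts[a]), int(ends[b - 1]), cls))
            iso_label[sl.start + a: sl.start + b] = cls
            gc[sl.start + a: sl.start + b] = rng.normal(
                gc_means[cls], config.gc_noise_sd, size
            )
            if rng.random() < lad_prob.get(cls, 0.0):
                lad_rows.append((chrom, int(starts[a]), int(ends[b - 1]), "LAD"))
                lad_flag[sl.start + a: sl.start + b] = True
            else:
                ilad_rows.append((chrom, int(starts[a]), int(ends[b - 1]), "iLAD"))
            pos = b
        # TADs tile the chromosome independently of the block layout
        pos = 0
        for size in _draw_blocks(rng, n, *config.tad_size_bins):
            a, b = pos, pos + size
            tad_rows.append((chrom, int(starts[a]), int(ends[b - 1]), ""))
            tad_id[sl.start + a: sl.start + b] = len(tad_rows) - 1
            pos = b

    gc = np.clip(gc, 0.0, 100.0)
    labels = np.asarray(
        [f"{iso}-{'LAD' if lad else 'iLAD'}" for iso, lad in zip(iso_label, lad_flag)],
        dtype=object,
    )
    classing = FeatureClassing(bins, labels)
    target = labels == config.target_class
    n_tads = len(tad_rows)
    tad_is_target = np.zeros(n_tads, dtype=bool)
    for t in range(n_tads):
        members = tad_id == t
        tad_is_target[t] = target[members].mean() > 0.5

    lads = IntervalSet.from_records(lad_rows, name="LADs")
    marks = IntervalSet.from_records(
        [(c, s_, e, "H3K9me3") for c, s_, e, _ in lad_rows]
        + [(c, s_, e, "H3K36me3") for c, s_, e, _ in ilad_rows],
        name="histone_marks",
    )
    return SimulatedGenome(
        config=config,
        assembly=assembly,
        bins=bins,
        gc=ScalarTrack(bins, gc, name="gc_percent"),
        isochores=IntervalSet.from_records(iso_rows, name="isochores"),
        lads=lads,
        tads=IntervalSet.from_records(tad_rows, name="TADs"),
        histone_domains=marks,
        bin_class=classing,
        tad_id=tad_id,
        tad_is_target=tad_is_target,
    )


def expected_matrix(genome: SimulatedGenome, condition: str) -> np.ndarray:
    """Dense expected contact intensity per bin pair for one condition.

    cis pair at separation s bins:
        E = C * (s+1)^-alpha * tau^[same TAD] * f_cond^[same target TAD]
    trans pair:
        E = beta * gamma^[both bins target-class and condition senescent]
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cfg = genome.config
    bins = genome.bins
    n = bins.n_bins
    code = bins.chrom_code
    cis = code[:, None] == code[None, :]
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])

    same_tad = (genome.tad_id[:, None] == genome.tad_id[None, :]) & (
        genome.tad_id[:, None] >= 0
    )
    target_tad = same_tad & np.isin(
        genome.tad_id, np.flatnonzero(genome.tad_is_target)
    )[:, None]

    local_factor = {"growing": 1.0, "senescent": cfg.local_loss, "esc": cfg.esc_factor}[condition]
    e_cis = cfg.cis_intensity * (sep + 1.0) ** (-cfg.alpha)
    e_cis = e_cis * np.where(same_tad, cfg.tad_multiplier, 1.0)
    e_cis = e_cis * np.where(target_tad, local_factor, 1.0)

    tc = genome.target_class_bins
    both_target = tc[:, None] & tc[None, :]
    gain = cfg.trans_gain if condition == "senescent" else 1.0
    e_trans = cfg.trans_baseline * np.where(both_target, gain, 1.0)

    return np.where(cis, e_cis, e_trans)


def sample_map(
    expected: np.ndarray,
    bins: BinTable,
    depth: int,
    rng: np.random.Generator,
) -> ContactMap:
    """Poisson-sample a contact map whose expected total equals ``depth``."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    n = bins.n_bins
    iu, ju = np.triu_indices(n)
    mu = expected[iu, ju].astype(float)
    mu *= depth / mu.sum()
    counts = rng.poisson(mu)
    nz = counts > 0
    return ContactMap(bins, iu[nz], ju[nz], counts[nz])


@dataclass
class SimulationTruth:
    """Planted ground truth emitted alongside the synthetic maps."""

    per_bin: pd.DataFrame   # bin, chrom, start, end, class, delta_oci_dir, esc_state
    per_tad: pd.DataFrame   # tad, chrom, start, end, opening
    config: SimulationConfig


def emit_truth(genome: SimulatedGenome) -> SimulationTruth:
    """Tabulate the planted effects for downstream benchmarking.

    A bin's OCI is planted to rise ("+") exactly when it lies in a
    target-class TAD and the local-loss factor is < 1. A TAD is planted as
    opening when it is target-class. The ESC-condition domain state is
    "local" for bins in target TADs (extra compaction) and "distal"
    elsewhere.
    """
    cfg = genome.config
    bins = genome.bins
    in_target_tad = genome.target_bins
    effect = cfg.local_loss < 1.0
    per_bin = pd.DataFrame(
        {
            "bin": np.arange(bins.n_bins),
            "chrom": bins.chrom,
            "start": bins.start,
            "end": bins.end,
            "class": genome.bin_class.labels.astype(str),
            "delta_oci_dir": np.where(in_target_tad & effect, "+", "0"),
            "esc_state": np.where(in_target_tad, "local", "distal"),
        }
    )
    per_tad = genome.tads.frame[["chrom", "start", "end"]].copy()
    per_tad.insert(0, "tad", np.arange(len(per_tad)))
    per_tad["opening"] = genome.tad_is_target & effect
    return SimulationTruth(per_bin=per_bin, per_tad=per_tad, config=cfg)


def simulate_condition(genome: SimulatedGenome, condition: str) -> ContactMap:
    """Sample one condition's map from its own named random substream."""
    cfg = genome.config
    stream = 1 + CONDITIONS.index(condition)
    return sample_map(
        expected_matrix(genome, condition), genome.bins, cfg.depth, cfg.rng(stream)
    )


def simulate_experiment(
    config: SimulationConfig, conditions: tuple[str, ...] = ("growing", "senescent")
) -> tuple[SimulatedGenome, dict[str, ContactMap], SimulationTruth]:
    """Plan the genome, sample the requested condition maps, emit the truth."""
    genome = plan_genome(config)
    maps = {c: simulate_condition(genome, c) for c in conditions}
    return genome, maps, emit_truth(genome)
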