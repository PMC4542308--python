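"""Feature-class interaction-change matrices and replication-timing shifts.

The interaction matrices quantify how strongly bins of two annotation
classes contact each other relative to a uniform-mixing expectation,
ignoring short-range cis pairs (default < 2 Mb midpoint separation) so
distance decay does not masquerade as class affinity:

    score(a, b) = (obs(a,b) / total obs) / (npairs(a,b) / total pairs)

with obs summed over eligible records and npairs counting all eligible
bin pairs (zero-count pairs included). The change between two conditions
is log2(score_b / score_a) per class pair. Bins classed "none" are
excluded from both numerator and denominator, so the matrix is closed
over labeled bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .genome import BinTable, FeatureClassing, IntervalSet, ScalarTrack, assign_bin_class

__all__ = [
    "ClassScoreMatrix",
    "class_interaction_score",
    "interaction_change",
    "histone_domain_change",
    "rt_change",
    "rt_scatter",
]


@dataclass
class ClassScoreMatrix:
    """Normalized class-pair interaction scores (symmetric, diagonal defined)."""

    classes: tuple[str, ...]
    score: np.ndarray     # k x k; NaN where no eligible pairs
    obs: np.ndarray       # summed counts per class pair
    npairs: np.ndarray    # eligible bin pairs per class pair
    total_obs: float
    total_pairs: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.score, index=self.classes, columns=self.classes)


def _eligible_upper_pairs(
    bins: BinTable, labeled: np.ndarray, min_sep_bp: float
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) bin pairs eligible for class scoring.

    Excludes cis pairs with midpoint separation < min_sep_bp and pairs
    touching an unlabeled bin. Trans pairs have no separation and are
    always eligible.
    """
    iu, ju = np.triu_indices(bins.n_bins)
    keep = labeled[iu] & labeled[ju]
    iu, ju = iu[keep], ju[keep]
    cis = bins.chrom_code[iu] == bins.chrom_code[ju]
    sep = np.abs(bins.midpoint[ju] - bins.midpoint[iu])
    keep = ~(cis & (sep < min_sep_bp))
    return iu[keep], ju[keep]


def class_interaction_score(
    cmap: ContactMap,
    classing: FeatureClassing,
    min_sep_bp: float = 2_000_000,
) -> ClassScoreMatrix:
    """Observed/expected interaction score per unordered class pair."""
    if classing.bins != cmap.bins:
        raise ValueError("classing is on a different bin table than the map")
    labels = classing.labels.astype(str)
    classes = tuple(sorted(set(labels) - {"none"}))
    k = len(classes)
    cindex = {c: i for i, c in enumerate(classes)}
    code = np.array([cindex.get(l, -1) for l in labels])
    labeled = code >= 0

    # eligible bin pairs (includes zero-count pairs)
    iu, ju = _eligible_upper_pairs(cmap.bins, labeled, min_sep_bp)
    npairs = np.zeros((k, k), dtype=np.int64)
    np.add.at(npairs, (code[iu], code[ju]), 1)
    npairs = npairs + npairs.T - np.diag(np.diag(npairs))

    # observed counts over eligible records
    ri, rj, rc = cmap.bin1, cmap.bin2, cmap.count.astype(float)
    ok = labeled[ri] & labeled[rj]
    cis = cmap.cis_mask
    sep = np.abs(cmap.bins.midpoint[rj] - cmap.bins.midpoint[ri])
    ok &= ~(cis & (sep < min_sep_bp))
    obs = np.zeros((k, k))
    np.add.at(obs, (code[ri[ok]], code[rj[ok]]), rc[ok])
    obs = obs + obs.T - np.diag(np.diag(obs))

    total_obs = float(rc[ok].sum())
    total_pairs = int(iu.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (obs / total_obs) / (npairs / total_pairs)
    score[npairs == 0] = np.nan
    return ClassScoreMatrix(classes, score, obs, npairs, total_obs, total_pairs)


def interaction_change(
    map_a: ContactMap,
    map_b: ContactMap,
    classing: FeatureClassing,
    min_sep_bp: float = 2_000_000,
) -> pd.DataFrame:
    """log2 change of class-pair interaction scores, b over a.

    Entries where either score is undefined (no eligible pairs) or zero
    (no observed counts) are set to 0 and recorded in
    ``attrs['flagged']``.
    """
    sa = class_interaction_score(map_a, classing, min_sep_bp)
    sb = class_interaction_score(map_b, classing, min_sep_bp)
    if sa.classes != sb.classes:
        raise ValueError("conditions yield different class sets")
    bad = (
        ~np.isfinite(sa.score) | ~np.isfinite(sb.score)
        | (sa.score == 0) | (sb.score == 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.log2(sb.score / sa.score)
    change[bad] = 0.0
    out = pd.DataFrame(change, index=sa.classes, columns=sa.classes)
    out.attrs["flagged"] = pd.DataFrame(bad, index=sa.classes, columns=sa.classes)
    return out


def histone_domain_change(
    map_a: ContactMap,
    map_b: ContactMap,
    histone_sets: dict[str, IntervalSet],
    min_sep_bp: float = 2_000_000,
) -> pd.DataFrame:
    """Interaction change between histone-mark domains.

    Bins are classed by majority overlap with the union of the supplied
    mark interval sets (one class per mark), then scored as in
    :func:`interaction_change`.
    """
    frames = [
        s.frame.assign(label=mark) for mark, s in histone_sets.items()
    ]
    union = IntervalSet("histone_marks", pd.concat(frames, ignore_index=True))
    classing = assign_bin_class(map_a.bins, union)
    return interaction_change(map_a, map_b, classing, min_sep_bp)


def rt_change(
    rt_a: ScalarTrack,
    rt_b: ScalarTrack,
    classing: FeatureClassing,
) -> tuple[ScalarTrack, pd.DataFrame]:
    """Change in normalized replication timing between two datasets.

    Each track is z-scored genome-wide over windows where both are
    non-missing; the per-window difference z_b - z_a is summarized per
    class. With the higher-value-equals-earlier convention a positive
    delta means earlier replication in b.
    """
    if rt_a.bins != rt_b.bins or classing.bins != rt_a.bins:
        raise ValueError("tracks and classing must share one window table")
    ok = ~(rt_a.missing | rt_b.missing)

    def zscore(v: np.ndarray) -> np.ndarray:
        m, s = v[ok].mean(), v[ok].std()
        if s == 0:
            raise ValueError("constant replication-timing track")
        out = (v - m) / s
        out[~ok] = np.nan
        return out

    delta = zscore(rt_b.values.copy()) - zscore(rt_a.values.copy())
    dtrack = ScalarTrack(rt_a.bins, delta, name="delta_rt_z")
    rows = []
    labels = classing.labels.astype(str)
    for cls in sorted(set(labels)):
        v = delta[(labels == cls) & ok]
        rows.append({
            "class": cls, "n": int(v.size),
            "mean": float(v.mean()) if v.size else np.nan,
            "median": float(np.median(v)) if v.size else np.nan,
            "q25": float(np.percentile(v, 25)) if v.size else np.nan,
            "q75": float(np.percentile(v, 75)) if v.size else np.nan,
        })
    return dtrack, pd.DataFrame(rows)


def rt_scatter(
    rt_a: ScalarTrack,
    rt_b: ScalarTrack,
    classing: FeatureClassing,
) -> pd.DataFrame:
    """Per-window table for the delta-RT vs reference-RT scatter."""
    dtrack, _ = rt_change(rt_a, rt_b, classing)
    ok = ~(rt_a.missing | rt_b.missing)
    za = (rt_a.values - rt_a.values[ok].mean()) / rt_a.values[ok].std()
    bins = rt_a.bins
    sel = ok & (classing.labels.astype(str) != "none")
    return pd.DataFrame({
        "chrom": bins.chrom[sel],
        "start": bins.start[sel],
        "end": bins.end[sel],
        "rt_a_z": za[sel],
        "delta_z": dtrack.values[sel],
        "class": classing.labels.astype(str)[sel],
    })
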