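"""Two-state segmentation of OCI tracks and multi-condition OCI clustering.

A Gaussian two-state hidden Markov model is fit to the smoothed OCI by
Baum-Welch; the state with the lower emission mean is labeled
"local" (0) — compact, locally connected chromatin — and the higher
"distal" (1). Viterbi decoding yields alternating OCI domains per
chromosome. Conservation of a reference segmentation in another
condition is measured window-wise: each query window is assigned the
reference state with the higher emission likelihood (no path smoothing)
and each reference domain reports its fraction of distal-classed
windows; a histogram of these fractions is bimodal at {0, 1} when the
domain structure is conserved.

Separately, per-window OCI vectors across conditions are grouped by
agglomerative (Ward) clustering into k classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .genome import IntervalSet, ScalarTrack
from .oci import OCITrack

__all__ = [
    "OciHmm",
    "fit_hmm",
    "viterbi_path",
    "decode_domains",
    "domain_conservation",
    "OciClusterResult",
    "cluster_oci",
    "cluster_enrichment",
]

STATE_LABELS = ("local", "distal")


@dataclass
class OciHmm:
    """Fitted two-state Gaussian HMM; state 0 = local (lower OCI mean)."""

    startprob: np.ndarray       # (2,)
    transmat: np.ndarray        # (2, 2), rows sum to 1
    means: np.ndarray           # (2,) emission means, ascending
    sds: np.ndarray             # (2,) emission SDs, > 0
    loglik_history: tuple[float, ...]
    converged: bool
    degenerate: bool            # state collapse: means closer than 0.1 pooled SD

    def emission_loglik(self, values: np.ndarray) -> np.ndarray:
        """(n, 2) per-window Gaussian log-likelihood under each state."""
        v = np.asarray(values, dtype=float)[:, None]
        mu = self.means[None, :]
        sd = self.sds[None, :]
        return -0.5 * np.log(2 * np.pi * sd**2) - (v - mu) ** 2 / (2 * sd**2)

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Window-wise maximum-emission-likelihood state (no path).

        Classification is forced monotone in the OCI value: anything at or
        beyond a state's mean on the far side belongs to that state. With
        unequal state variances the raw likelihood ratio is non-monotone —
        the wider Gaussian's tail would capture values far beyond the
        *other* state's mean, which is nonsensical for query conditions
        whose values exceed the reference range.
        """
        v = np.asarray(values, dtype=float)
        state = np.argmax(self.emission_loglik(v), axis=1)
        state[v <= self.means[0]] = 0
        state[v >= self.means[1]] = 1
        return state


def _unmasked_runs(track: OCITrack) -> list[tuple[int, int]]:
    """Maximal runs of unmasked windows, never crossing a chromosome edge."""
    runs = []
    for _, sl in track.windows.chrom_slices().items():
        ok = ~track.mask[sl]
        k = sl.start
        start = None
        for i, flag in enumerate(ok):
            if flag and start is None:
                start = k + i
            elif not flag and start is not None:
                runs.append((start, k + i))
                start = None
        if start is not None:
            runs.append((start, sl.stop))
    return runs


def fit_hmm(
    track: OCITrack,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> OciHmm:
    """Fit the two-state Gaussian HMM to a track's smoothed OCI.

    Chromosomes (and masked gaps) delimit independent sequences.
    Initialization is a 2-means split of the values; fitting is
    Baum-Welch EM, stopped when the log-likelihood gain drops below
    ``tol`` or after ``max_iter`` iterations. Deterministic given the
    seed.
    """
    from hmmlearn.hmm import GaussianHMM
    from sklearn.cluster import KMeans

    runs = _unmasked_runs(track)
    values = np.concatenate([track.smoothed[a:b] for a, b in runs])
    lengths = [b - a for a, b in runs]
    if values.size < 50:
        raise ValueError("need at least 50 unmasked windows to fit the HMM")

    km = KMeans(n_clusters=2, n_init=1, random_state=seed).fit(values[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    means0 = km.cluster_centers_.ravel()[order]
    sds0 = np.array([
        max(values[km.labels_ == lab].std(), 1e-3) for lab in order
    ])

    model = GaussianHMM(
        n_components=2, covariance_type="diag",
        init_params="", params="stmc",
        n_iter=max_iter, tol=tol, random_state=seed,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    model.means_ = means0[:, None]
    model.covars_ = (sds0**2)[:, None]
    # hmmlearn warns when the last EM step gains < 0 by float rounding;
    # that is the converged case here, not a fitting failure
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
    model.fit(values[:, None], lengths)

    means = model.means_.ravel()
    sds = np.sqrt(np.array([np.ravel(c)[0] for c in model.covars_]))
    order = np.argsort(means)
    means, sds = means[order], sds[order]
    transmat = model.transmat_[np.ix_(order, order)]
    startprob = model.startprob_[order]
    pooled = float(np.sqrt((sds**2).mean()))
    return OciHmm(
        startprob=startprob,
        transmat=transmat,
        means=means,
        sds=sds,
        loglik_history=tuple(float(x) for x in model.monitor_.history),
        converged=bool(model.monitor_.converged),
        degenerate=abs(means[1] - means[0]) < 0.1 * pooled,
    )


def viterbi_path(model: OciHmm, values: np.ndarray) -> np.ndarray:
    """Most probable state path for one observation sequence (log space)."""
    ll = model.emission_loglik(values)
    n = ll.shape[0]
    with np.errstate(divide="ignore"):
        log_start = np.log(model.startprob)
        log_trans = np.log(model.transmat)
    score = log_start + ll[0]
    back = np.zeros((n, 2), dtype=np.int64)
    for t in range(1, n):
        cand = score[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], [0, 1]] + ll[t]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_domains(model: OciHmm, track: OCITrack) -> IntervalSet:
    """Viterbi-decode the track into alternating local/distal domains.

    Masked gaps split domains; each maximal run of one state becomes one
    interval labeled "local" or "distal".
    """
    rows = []
    windows = track.windows
    for a, b in _unmasked_runs(track):
        path = viterbi_path(model, track.smoothed[a:b])
        chrom = windows.chrom[a]
        run_start = a
        for k in range(1, b - a + 1):
            if k == b - a or path[k] != path[k - 1]:
                rows.append((
                    chrom,
                    int(windows.start[run_start]),
                    int(windows.end[a + k - 1]),
                    STATE_LABELS[path[k - 1]],
                ))
                run_start = a + k
    return IntervalSet.from_records(rows, name="oci_domains")


def domain_conservation(
    domains: IntervalSet,
    query_track: OCITrack,
    model: OciHmm,
) -> pd.DataFrame:
    """Per-domain fraction of query windows classed distal by the model.

    The query condition's windows are classified by emission likelihood
    alone. A conserved segmentation yields fractions concentrated at 0
    (local domains) and 1 (distal domains); loss of the domain structure
    pulls fractions toward the interior. Domains whose query windows are
    all masked are dropped (count in ``attrs['dropped']``).
    """
    windows = query_track.windows
    state = model.classify(query_track.smoothed)
    rows = []
    dropped = 0
    mid = windows.midpoint
    for row in domains.frame.itertuples(index=False):
        sel = (
            (windows.chrom == row.chrom)
            & (mid >= row.start) & (mid < row.end)
            & ~query_track.mask
        )
        n = int(sel.sum())
        if n == 0:
            dropped += 1
            continue
        rows.append({
            "chrom": row.chrom, "start": row.start, "end": row.end,
            "ref_state": row.label, "n_windows": n,
            "distal_fraction": float(state[sel].mean()),
        })
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = dropped
    return out


# --------------------------------------------------------------------------
# multi-condition clustering
# --------------------------------------------------------------------------

@dataclass
class OciClusterResult:
    """Ward clustering of per-window OCI vectors across conditions."""

    windows: "BinTable"
    conditions: tuple[str, ...]
    matrix: np.ndarray          # (n complete-case windows, n conditions)
    window_index: np.ndarray    # indices of complete-case windows
    labels: np.ndarray          # 1..k, numbered by descending cluster size
    k: int
    linkage: np.ndarray
    cluster_means: pd.DataFrame
    mean_gc: pd.Series | None


def _aggregate(track: OCITrack, window_bp: int) -> tuple["BinTable", np.ndarray]:
    from .oci import window_table

    coarse, win_of = window_table(track.windows, window_bp)
    sums = np.zeros(coarse.n_bins)
    cnts = np.zeros(coarse.n_bins)
    ok = ~np.isnan(track.smoothed)
    np.add.at(sums, win_of[ok], track.smoothed[ok])
    np.add.at(cnts, win_of[ok], 1)
    with np.errstate(invalid="ignore"):
        out = sums / cnts
    return coarse, out


def cluster_oci(
    tracks: dict[str, OCITrack],
    window_bp: int = 1_000_000,
    k: int = 6,
    gc: ScalarTrack | None = None,
) -> OciClusterResult:
    """Cluster windows by their cross-condition OCI profile.

    Tracks are mean-aggregated to ``window_bp`` windows; complete-case
    windows are clustered with Ward linkage on Euclidean distance and the
    tree cut at ``k``. Clusters are renumbered by descending size. When a
    GC track (on the original windows) is supplied, per-cluster mean GC
    is attached.
    """
    conditions = tuple(tracks)
    coarse = None
    cols = []
    for cond in conditions:
        ctab, vals = _aggregate(tracks[cond], window_bp)
        if coarse is None:
            coarse = ctab
        elif ctab != coarse:
            raise ValueError("tracks disagree on windowing")
        cols.append(vals)
    mat = np.column_stack(cols)
    complete = ~np.isnan(mat).any(axis=1)
    idx = np.flatnonzero(complete)
    if idx.size < k:
        raise ValueError(f"only {idx.size} complete-case windows for k={k}")
    X = mat[complete]
    Z = linkage(X, method="ward")
    raw_labels = fcluster(Z, t=k, criterion="maxclust")
    # renumber by descending size (ties by original id for determinism)
    ids, sizes = np.unique(raw_labels, return_counts=True)
    order = ids[np.lexsort((ids, -sizes))]
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in raw_labels])

    means = pd.DataFrame(
        [
            {"cluster": c, "size": int((labels == c).sum()),
             **{cond: float(X[labels == c, i].mean())
                for i, cond in enumerate(conditions)}}
            for c in range(1, len(ids) + 1)
        ]
    )
    mean_gc = None
    if gc is not None:
        from .oci import window_table

        _, win_of = window_table(gc.bins, window_bp)
        gsum = np.zeros(coarse.n_bins)
        gcnt = np.zeros(coarse.n_bins)
        ok = ~gc.missing
        np.add.at(gsum, win_of[ok], gc.values[ok])
        np.add.at(gcnt, win_of[ok], 1)
        with np.errstate(invalid="ignore"):
            gagg = gsum / gcnt
        mean_gc = pd.Series(
            {c: float(np.nanmean(gagg[idx[labels == c]]))
             for c in range(1, len(ids) + 1)},
            name="mean_gc",
        )
    return OciClusterResult(
        windows=coarse, conditions=conditions, matrix=X, window_index=idx,
        labels=labels, k=int(len(ids)), linkage=Z, cluster_means=means,
        mean_gc=mean_gc,
    )


def cluster_enrichment(
    result: OciClusterResult,
    feature_sets: dict[str, IntervalSet],
    assembly: "GenomeAssembly",
) -> pd.DataFrame:
    """log2 obs/exp overlap enrichment of each cluster for each feature."""
    from .genome import overlap_enrichment

    windows = result.windows
    rows = []
    for c in range(1, result.k + 1):
        sel = result.window_index[result.labels == c]
        query = IntervalSet.from_records(
            [(windows.chrom[i], int(windows.start[i]), int(windows.end[i]), "")
             for i in sel],
            name=f"cluster{c}",
        ).merged()
        for name, feat in feature_sets.items():
            res = overlap_enrichment(query, feat, assembly)
            rows.append({
                "cluster": c, "feature": name,
                "log2_obs_exp": res.log2_ratio, "flagged": res.flagged,
            })
    return pd.DataFrame(rows)
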