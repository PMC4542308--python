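"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over dense
matrices / exhaustive enumerations, sharing no code with the package
implementations it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# OCI by exhaustive enumeration over a dense matrix
# ---------------------------------------------------------------------------

def oci_oracle(dense, bins, params):
    """Recompute the full OCI chain (raw, centered, smoothed, mask) by loops.

    ``dense`` is the symmetric count matrix; windows are groups of
    consecutive bins of ``params.window_bp``.
    """
    n = bins.n_bins
    # window id: consecutive per chromosome by start // window_bp
    win_of = np.zeros(n, dtype=int)
    wid = -1
    prev = None
    for i in range(n):
        key = (bins.chrom[i], bins.start[i] // params.window_bp)
        if key != prev:
            wid += 1
            prev = key
        win_of[i] = wid
    n_win = wid + 1
    win_chrom = [None] * n_win
    win_start = [None] * n_win
    win_end = [0] * n_win
    for i in range(n):
        w = win_of[i]
        if win_chrom[w] is None:
            win_chrom[w] = bins.chrom[i]
            win_start[w] = bins.start[i]
        win_end[w] = bins.end[i]

    mid = (bins.start + bins.end) / 2.0
    local = np.zeros(n_win)
    control = np.zeros(n_win)
    for i in range(n):
        for j in range(i, n):
            c = dense[i, j]
            if c == 0:
                continue
            wi, wj = win_of[i], win_of[j]
            if wi == wj:
                local[wi] += c
            same_chrom = bins.chrom[i] == bins.chrom[j]
            if params.control_mode == "trans":
                eligible = not same_chrom
            else:
                eligible = same_chrom and abs(mid[i] - mid[j]) > params.cis_threshold_bp
            if eligible:
                control[wi] += c
                if wj != wi:
                    control[wj] += c

    psi = params.pseudocount
    raw = np.log2((control + psi) / (local + psi))
    mask = (local + control) < params.min_informative
    centered = np.full(n_win, np.nan)
    smoothed = np.full(n_win, np.nan)
    half = params.smoothing_span_bp // (2 * params.window_bp)
    for chrom in dict.fromkeys(win_chrom):
        idx = [w for w in range(n_win) if win_chrom[w] == chrom]
        vals = [raw[w] for w in idx if not mask[w]]
        if not vals:
            raise ValueError(f"all windows masked on chromosome {chrom!r}")
        med = float(np.median(vals))
        for w in idx:
            if not mask[w]:
                centered[w] = raw[w] - med
        for pos, w in enumerate(idx):
            if mask[w]:
                continue
            lo = max(0, pos - half)
            hi = min(len(idx), pos + half + 1)
            neigh = [centered[idx[q]] for q in range(lo, hi)
                     if not mask[idx[q]]]
            smoothed[w] = float(np.mean(neigh))
    return {
        "local": local, "control": control, "raw": raw,
        "centered": centered, "smoothed": smoothed, "mask": mask,
    }


# ---------------------------------------------------------------------------
# Fisher two-sided p by exact rational hypergeometric enumeration
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=None)
def _comb(n: int, k: int) -> int:
    return math.comb(n, k)


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p via exact rational enumeration of the support.

    Sums the hypergeometric pmf over all tables (with the same margins)
    whose probability does not exceed that of the observed table; ties
    are exact in integer arithmetic.
    """
    n1, n2, n = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or n == 0 or b + d == 0:
        return 1.0
    lo, hi = max(0, n - n2), min(n, n1)
    numers = [_comb(n1, k) * _comb(n2, n - k) for k in range(lo, hi + 1)]
    observed = numers[a - lo]
    total = _comb(n1 + n2, n)
    s = sum(x for x in numers if x <= observed)
    return float(Fraction(s, total))


# ---------------------------------------------------------------------------
# Viterbi by exhaustive path enumeration
# ---------------------------------------------------------------------------

def viterbi_oracle(startprob, transmat, means, sds, values) -> tuple[np.ndarray, float]:
    """Best state path by scoring every one of the 2^n paths in log space."""
    values = np.asarray(values, dtype=float)
    n = values.size
    best_path, best_score = None, -math.inf
    for mask in range(2 ** n):
        path = [(mask >> t) & 1 for t in range(n)]
        score = math.log(startprob[path[0]])
        for t in range(1, n):
            score += math.log(transmat[path[t - 1]][path[t]])
        for t in range(n):
            s = path[t]
            score += (
                -0.5 * math.log(2 * math.pi * sds[s] ** 2)
                - (values[t] - means[s]) ** 2 / (2 * sds[s] ** 2)
            )
        if score > best_score:
            best_score = score
            best_path = path
    return np.asarray(best_path), best_score


# ---------------------------------------------------------------------------
# class-pair interaction score by loops
# ---------------------------------------------------------------------------

def class_score_oracle(dense, bins, labels, min_sep_bp):
    """(score, obs, npairs) per unordered class pair, by explicit loops."""
    n = bins.n_bins
    mid = (bins.start + bins.end) / 2.0
    classes = sorted(set(labels) - {"none"})
    obs: dict[tuple, float] = {}
    npairs: dict[tuple, int] = {}
    total_obs = 0.0
    total_pairs = 0
    for i in range(n):
        for j in range(i, n):
            li, lj = labels[i], labels[j]
            if li == "none" or lj == "none":
                continue
            cis = bins.chrom[i] == bins.chrom[j]
            if cis and abs(mid[i] - mid[j]) < min_sep_bp:
                continue
            key = tuple(sorted((li, lj)))
            npairs[key] = npairs.get(key, 0) + 1
            total_pairs += 1
            cnt = dense[i, j]
            if cnt:
                obs[key] = obs.get(key, 0.0) + cnt
                total_obs += cnt
    score = {}
    for key, npair in npairs.items():
        o = obs.get(key, 0.0)
        score[key] = (o / total_obs) / (npair / total_pairs) if total_obs else math.nan
    return score, obs, npairs, classes


# ---------------------------------------------------------------------------
# Ward agglomeration by direct evaluation of the merge criterion
# ---------------------------------------------------------------------------

def ward_merge_order(points):
    """Sequence of merges minimizing the Ward variance increase.

    Returns a list of (cluster_i, cluster_j, cost) with scipy-style
    cluster numbering (new clusters get ids n, n+1, ...).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []

    def cost(a, b):
        pa = points[clusters[a]]
        pb = points[clusters[b]]
        na, nb = len(pa), len(pb)
        diff = pa.mean(axis=0) - pb.mean(axis=0)
        return math.sqrt(2.0 * na * nb / (na + nb) * float(diff @ diff))

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                c = cost(keys[x], keys[y])
                if best is None or c < best[2]:
                    best = (keys[x], keys[y], c)
        i, j, c = best
        merges.append((i, j, c))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges
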