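"""Independent brute-force reference implementations used to validate the
package's run-length / interval-algebra / scanning code paths.

Everything here works on dense per-base arrays or exhaustive enumeration
and deliberately avoids the package's own algorithms.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------- dense tracks


def dense_track(track, chrom: str, length: int) -> np.ndarray:
    """Expand a run-length track to a dense per-base vector."""
    arr = np.zeros(length)
    for c, s, e, v in track.iter_runs():
        if c == chrom:
            arr[s:e] = v
    return arr


def dense_trimmed_mean(mat: np.ndarray, trim: float) -> np.ndarray:
    """Per-column trimmed mean of a (samples x bases) dense matrix."""
    n = mat.shape[0]
    k = int(trim * n)
    srt = np.sort(mat, axis=0)
    if k:
        srt = srt[k:-k]
    return srt.mean(axis=0)


def positive_quantile_dense(arr: np.ndarray, q: float) -> float:
    pos = arr[arr > 0]
    if pos.size == 0:
        return float("inf")
    return float(np.quantile(pos, q, method="inverted_cdf"))


# ---------------------------------------------------------------- intervals


def dense_subtract_and_merge(intervals, excluded, length: int):
    """Base-occupancy subtraction on a toy chromosome."""
    cov = np.zeros(length, dtype=bool)
    for iv in intervals:
        cov[iv.start : iv.end] = True
    for iv in excluded:
        cov[iv.start : iv.end] = False
    out = []
    start = None
    for i, b in enumerate(cov):
        if b and start is None:
            start = i
        elif not b and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, length))
    return out


# ---------------------------------------------------------------- statistics


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson with average ranks."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------- rG4


def rg4_brute_force(sequence: str, min_tract: int = 2, loop_lo: int = 1, loop_hi: int = 30):
    """Exhaustive enumeration of quadruplex decompositions.

    Walks every start position and every (t1, l1, t2, l2, t3, l3, t4)
    decomposition with maximal tracts (the base before/after each tract is
    not G within the motif) and loops in [loop_lo, loop_hi], and returns
    (start, end, tracts, loops, score) tuples.
    """
    seq = sequence.upper()
    n = len(seq)

    def is_g(i):
        return 0 <= i < n and seq[i] == "G"

    out = []
    for start in range(n):
        if not is_g(start) or is_g(start - 1):
            continue  # tracts are maximal: must begin a G-run
        _extend(seq, n, start, [], [], out, min_tract, loop_lo, loop_hi)
    return out


def _extend(seq, n, pos, tracts, loops, out, min_tract, loop_lo, loop_hi):
    # measure the maximal G-run starting at pos
    run = 0
    while pos + run < n and seq[pos + run] == "G":
        run += 1
    if run < min_tract:
        return
    tracts = tracts + [run]
    end = pos + run
    if len(tracts) == 4:
        score = 20 * (min(tracts) - 1) - sum(max(0, l - 3) for l in loops)
        out.append((end - _motif_len(tracts, loops), end, tuple(tracts), tuple(loops), score))
        return
    for loop in range(loop_lo, loop_hi + 1):
        nxt = end + loop
        # loop must not end with G (next tract must start a maximal run)
        if nxt >= n or seq[nxt] != "G":
            continue
        if seq[nxt - 1] == "G":
            continue
        _extend(seq, n, nxt, tracts, loops + [loop], out, min_tract, loop_lo, loop_hi)


def _motif_len(tracts, loops):
    return sum(tracts) + sum(loops)


def greedy_select(hits, min_score: float):
    """Same greedy rule as the scanner, applied to brute-force candidates."""
    hits = [h for h in hits if h[4] >= min_score]
    hits.sort(key=lambda h: (-h[4], h[0], h[1]))
    chosen = []
    for h in hits:
        if all(h[1] <= c[0] or h[0] >= c[1] for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h[0])
    return chosen


# ---------------------------------------------------------------- five filters


def five_filter_oracle(
    cnes,
    blocklist_intervals,
    transcript_spans,
    cage_tracks,
    sample_tracks,
    chrom_sizes,
    min_length: int = 200,
    noise_quantile: float = 0.05,
    threshold_quantile: float = 0.05,
    detection_fraction: float = 0.05,
    trim_fraction: float = 0.1,
):
    """Per-candidate kept/dropped decision computed on dense arrays.

    Returns {cne_name: {flag: bool, ..., "kept": bool}} for every candidate
    strictly longer than ``min_length`` (others are absent).
    """
    chroms = sorted(chrom_sizes)
    # dense occupancy
    block_cov = {c: np.zeros(chrom_sizes[c], dtype=bool) for c in chroms}
    for iv in blocklist_intervals:
        if iv.chrom in block_cov:
            block_cov[iv.chrom][iv.start : iv.end] = True
    tx_cov = {c: np.zeros(chrom_sizes[c], dtype=bool) for c in chroms}
    for iv in transcript_spans:
        if iv.chrom in tx_cov:
            tx_cov[iv.chrom][iv.start : iv.end] = True
    cage_dense = [
        {c: dense_track(t, c, chrom_sizes[c]) for c in chroms} for t in cage_tracks
    ]
    floors = [
        positive_quantile_dense(np.concatenate([d[c] for c in chroms]), noise_quantile)
        for d in cage_dense
    ]
    sample_dense = [
        {c: dense_track(t, c, chrom_sizes[c]) for c in chroms} for t in sample_tracks
    ]
    agg_dense = {}
    for c in chroms:
        mat = np.stack([d[c] for d in sample_dense])
        agg_dense[c] = dense_trimmed_mean(mat, trim_fraction)

    candidates = [iv for iv in cnes if iv.length > min_length]
    flags = {}
    for iv in candidates:
        f1 = not block_cov[iv.chrom][iv.start : iv.end].any()
        f2 = bool(tx_cov[iv.chrom][iv.start : iv.end].all())
        f3 = any(
            d[iv.chrom][iv.start : iv.end].max() >= floor
            for d, floor in zip(cage_dense, floors)
        )
        flags[iv.name] = {"blocklist": f1, "containment": f2, "independence": f3}

    # threshold population: survivors of filters 1-3
    def elem_mean(iv):
        return float(agg_dense[iv.chrom][iv.start : iv.end].mean())

    survivors = [iv for iv in candidates if all(flags[iv.name].values())]
    vals = np.log2(np.array([elem_mean(iv) for iv in survivors]) + 1.0)
    mu = vals.mean()
    sigma = vals.std(ddof=1)
    tau = mu + sigma * sps.norm.ppf(threshold_quantile)
    n = len(sample_tracks)
    min_det = max(1, math.ceil(detection_fraction * n - 1e-9))
    for iv in candidates:
        f4 = np.log2(elem_mean(iv) + 1.0) >= tau
        detected = sum(
            np.log2(d[iv.chrom][iv.start : iv.end].mean() + 1.0) >= tau
            for d in sample_dense
        )
        f5 = detected >= min_det
        flags[iv.name]["threshold"] = bool(f4)
        flags[iv.name]["recurrence"] = bool(f5)
        flags[iv.name]["kept"] = all(flags[iv.name].values())
    return flags
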