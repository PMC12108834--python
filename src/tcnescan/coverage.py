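"""Per-base read-density tracks and the transcription threshold.

Signal is held run-length encoded: per chromosome, sorted non-overlapping
runs ``(start, end, value)`` with value >= 0; any base not covered by a run
has value 0.  This keeps multi-megabase RNA-seq/CAGE coverage cheap while
remaining exactly equivalent to a dense per-base vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class SignalTrack:
    """Non-negative per-base signal over a genome, run-length encoded."""

    def __init__(self, sample_id: str = "") -> None:
        self.sample_id = sample_id
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_runs(
        cls,
        runs: Iterable[tuple[str, int, int, float]],
        sample_id: str = "",
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if end <= start:
                raise ValueError(f"empty run {chrom}:{start}-{end}")
            if value < 0:
                raise ValueError(f"negative signal {value} at {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        track = cls(sample_id)
        for chrom, items in by_chrom.items():
            items.sort()
            s = np.array([i[0] for i in items], dtype=np.int64)
            e = np.array([i[1] for i in items], dtype=np.int64)
            v = np.array([i[2] for i in items], dtype=float)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            keep = v != 0.0
            track._runs[chrom] = (s[keep], e[keep], v[keep])
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._runs:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), np.empty(0, dtype=float)
        return self._runs[chrom]

    def iter_runs(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            s, e, v = self._runs[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over ``[start, end)`` (zeros where uncovered)."""
        if end <= start:
            raise ValueError("empty window")
        out = np.zeros(end - start, dtype=float)
        s, e, v = self.runs(chrom)
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(int(s[i]), start)
            b = min(int(e[i]), end)
            if b > a:
                out[a - start : b - start] = v[i]
        return out

    def interval_stats(self, iv: GenomicInterval) -> tuple[float, float, float]:
        """(sum, mean, max) of per-base signal over ``iv``, zeros included."""
        s, e, v = self.runs(iv.chrom)
        lo = int(np.searchsorted(e, iv.start, side="right"))
        hi = int(np.searchsorted(s, iv.end, side="left"))
        ss, es, vs = s[lo:hi], e[lo:hi], v[lo:hi]
        widths = np.minimum(es, iv.end) - np.maximum(ss, iv.start)
        good = widths > 0
        total = float((widths[good] * vs[good]).sum())
        covered = int(widths[good].sum())
        mx = float(vs[good].max()) if good.any() else 0.0
        if covered < iv.length:
            mx = max(mx, 0.0)
        return total, total / iv.length, mx

    def positive_values_weighted(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct positive run values and their base counts, pooled
        genome-wide (for quantiles over the positive per-base signal)."""
        vals: list[np.ndarray] = []
        wts: list[np.ndarray] = []
        for chrom in self._runs:
            s, e, v = self._runs[chrom]
            pos = v > 0
            vals.append(v[pos])
            wts.append((e - s)[pos].astype(float))
        if not vals:
            return np.empty(0), np.empty(0)
        return np.concatenate(vals), np.concatenate(wts)

    def positive_quantile(self, q: float) -> float:
        """``q`` quantile of per-base positive signal; +inf when the track
        has no positive bases (disables any >= comparison)."""
        v, w = self.positive_values_weighted()
        if v.size == 0:
            warnings.warn(f"track {self.sample_id!r} has no positive signal")
            return float("inf")
        order = np.argsort(v)
        v, w = v[order], w[order]
        cw = np.cumsum(w)
        target = q * cw[-1]
        idx = int(np.searchsorted(cw, target, side="left"))
        return float(v[min(idx, len(v) - 1)])


@dataclass
class AggregateTrack:
    """Cross-sample trimmed-mean track."""

    track: SignalTrack
    trim_fraction: float
    n_samples: int


def trimmed_mean(values: Sequence[float], trim_fraction: float) -> float:
    """Mean after dropping ``floor(trim_fraction * n)`` values from each tail."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimmed_mean of empty input")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    return float(stats.trim_mean(values, trim_fraction))


def aggregate_tracks(
    tracks: Sequence[SignalTrack], trim_fraction: float = 0.1
) -> AggregateTrack:
    """Per-base trimmed mean across samples (absent bases count as 0)."""
    if not tracks:
        raise ValueError("no tracks to aggregate")
    chroms = sorted({c for t in tracks for c in t.chroms})
    out_runs: list[tuple[str, int, int, float]] = []
    for chrom in chroms:
        cuts: list[np.ndarray] = []
        for t in tracks:
            s, e, _ = t.runs(chrom)
            cuts.append(s)
            cuts.append(e)
        bounds = np.unique(np.concatenate(cuts))
        if len(bounds) < 2:
            continue
        seg_start = bounds[:-1]
        seg_end = bounds[1:]
        # per-track value on each elementary segment
        mat = np.zeros((len(tracks), len(seg_start)), dtype=float)
        for ti, t in enumerate(tracks):
            s, e, v = t.runs(chrom)
            if len(s) == 0:
                continue
            idx = np.searchsorted(s, seg_start, side="right") - 1
            ok = (idx >= 0) & (seg_start < e[np.clip(idx, 0, None)])
            mat[ti, ok] = v[idx[ok]]
        agg = stats.trim_mean(mat, trim_fraction, axis=0)
        # run-length re-encode, dropping zero segments
        for a, b, val in zip(seg_start, seg_end, agg):
            if val != 0.0:
                out_runs.append((chrom, int(a), int(b), float(val)))
    track = SignalTrack.from_runs(out_runs, sample_id="aggregate")
    return AggregateTrack(track=track, trim_fraction=trim_fraction, n_samples=len(tracks))


def interval_signal(track: SignalTrack, iv: GenomicInterval, stat: str = "mean") -> float:
    """Interval statistic over per-base values, zeros included."""
    total, mean, mx = track.interval_stats(iv)
    if stat == "mean":
        return mean
    if stat == "sum":
        return total
    if stat == "max":
        return mx
    raise ValueError(f"unknown stat {stat!r}")


def log2p1(x):
    return np.log2(np.asarray(x, dtype=float) + 1.0)


_TRANSFORMS = {"identity": lambda x: np.asarray(x, dtype=float), "log2p1": log2p1}


@dataclass
class TranscriptionThreshold:
    """Normal fit to (transformed) signal with a lower-quantile cutoff tau."""

    mu: float
    sigma: float
    quantile: float
    tau: float
    transform: str = "log2p1"

    def transform_values(self, x):
        return _TRANSFORMS[self.transform](x)


def fit_transcription_threshold(
    values: Sequence[float],
    quantile: float = 0.05,
    transform: str = "log2p1",
) -> TranscriptionThreshold:
    """Fit a normal to transformed signal values and set the threshold at
    the given lower quantile: ``tau = mu + sigma * Phi^-1(quantile)``.

    ``tau`` is reported on the transformed scale.  The fit is intended for
    the per-candidate-element mean aggregate signal (one value per element).
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    x = _TRANSFORMS[transform](values)
    if x.size < 2:
        raise ValueError("need at least 2 values to fit a threshold")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        logger.warning("degenerate threshold fit: all values equal; tau = mu")
        tau = mu
    else:
        tau = mu + sigma * float(stats.norm.ppf(quantile))
    return TranscriptionThreshold(
        mu=mu, sigma=sigma, quantile=quantile, tau=tau, transform=transform
    )
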