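"""Beat detection and per-beat fiducial localisation.

Beats are detected on the beat-path filtered signal with a multi-scale
peak/trough detector (MSPTD): a point is kept as a peak iff it is a strict
local maximum at every scale ``k = 1..d``, where scale-``k`` maxima are
points larger than both neighbours ``k`` samples away in the linearly
detrended window, and ``d`` is the scale with the most scale-``k`` maxima
(the most informative row of the local-maxima scalogram).  Troughs are
found analogously from the local-minima scalogram.  Long signals are
processed in overlapping windows with de-duplication of near-coincident
detections.

Fiducials per beat: the onset (pulse foot, minimum between successive
detections), the systolic peak (maximum), and the mid-point of the systolic
upslope (first half-amplitude crossing between onset and peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ValidationError

__all__ = [
    "BeatSeries",
    "InsufficientBeatsError",
    "detect_beats_msptd",
    "msptd_window",
    "locate_fiducials",
]

#: Windowing defaults for MSPTD on long records.
DEFAULT_WINDOW_S = 6.0
DEFAULT_OVERLAP = 0.2
DEFAULT_DEDUP_S = 0.25


class InsufficientBeatsError(ValueError):
    """Fewer beats detected than the operation requires."""


@dataclass
class BeatSeries:
    """Per-beat fiducial sample indices for one recording.

    For every beat ``k``: ``onsets[k] < midpoints[k] <= peaks[k]``.
    Boundary beats lacking a flanking detection are dropped, so all three
    arrays have length ``n_beats``.
    """

    peaks: np.ndarray
    onsets: np.ndarray
    midpoints: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=np.intp)
        self.onsets = np.asarray(self.onsets, dtype=np.intp)
        self.midpoints = np.asarray(self.midpoints, dtype=np.intp)
        if not (len(self.peaks) == len(self.onsets) == len(self.midpoints)):
            raise ValidationError("fiducial arrays must have equal length")
        if np.any(np.diff(self.peaks) <= 0):
            raise ValidationError("peaks must be strictly increasing")
        if np.any(self.onsets >= self.midpoints) or np.any(self.midpoints > self.peaks):
            raise ValidationError("need onset < midpoint <= peak for every beat")

    @property
    def n_beats(self) -> int:
        return len(self.peaks)

    def ibis(self) -> np.ndarray:
        """Inter-beat intervals in seconds (successive peak-to-peak)."""
        return np.diff(self.peaks) / self.fs


def msptd_window(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MSPTD on a single window; returns (peak indices, trough indices).

    The window is linearly detrended first.  The scalogram row count runs
    to ``ceil(n/2) - 1`` scales.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    n_scales = int(np.ceil(n / 2)) - 1
    if n < 3 or n_scales < 1:
        return np.array([], dtype=np.intp), np.array([], dtype=np.intp)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite samples in beat-detection input")

    t = np.arange(n)
    coef = np.polyfit(t, x, 1)
    xd = x - np.polyval(coef, t)

    # max_rows[k-1, i] == True iff xd[i] is a strict scale-k local maximum
    max_rows = np.zeros((n_scales, n), dtype=bool)
    min_rows = np.zeros((n_scales, n), dtype=bool)
    for k in range(1, n_scales + 1):
        mid = xd[k : n - k]
        left = xd[: n - 2 * k]
        right = xd[2 * k :]
        max_rows[k - 1, k : n - k] = (mid > left) & (mid > right)
        min_rows[k - 1, k : n - k] = (mid < left) & (mid < right)

    def extrema(rows: np.ndarray) -> np.ndarray:
        counts = rows.sum(axis=1)
        d = int(np.argmax(counts)) + 1  # scale with the most extrema
        return np.flatnonzero(rows[:d].all(axis=0))

    return extrema(max_rows), extrema(min_rows)


def _dedup(idx: np.ndarray, values: np.ndarray, min_gap: int, keep_max: bool) -> np.ndarray:
    """Collapse detections closer than ``min_gap`` samples.

    Within each run of near-coincident detections the most extreme value is
    kept (largest for peaks, smallest for troughs).
    """
    if idx.size == 0:
        return idx
    idx = np.sort(np.unique(idx))
    out = []
    group = [idx[0]]
    for i in idx[1:]:
        if i - group[-1] < min_gap:
            group.append(i)
        else:
            out.append(group)
            group = [i]
    out.append(group)
    pick = np.argmax if keep_max else np.argmin
    return np.array([g[pick(values[g])] for g in out], dtype=np.intp)


def detect_beats_msptd(
    x: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    dedup_s: float = DEFAULT_DEDUP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect candidate beat peaks and troughs over a whole record.

    The signal is processed in overlapping windows (default 6 s with 20%
    overlap); window detections are merged and de-duplicated with a 0.25 s
    radius, keeping the larger-amplitude peak (smaller-amplitude trough).
    A window longer than the signal degenerates to a single whole-signal
    pass, which equals the unwindowed detector exactly.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite samples in beat-detection input")
    n = x.size
    win = int(round(window_s * fs))
    step = max(1, int(round(win * (1.0 - overlap))))
    peaks: list[np.ndarray] = []
    troughs: list[np.ndarray] = []
    if win >= n:
        starts = [0]
    else:
        starts = list(range(0, n - win + 1, step))
        if starts[-1] + win < n:
            starts.append(n - win)
    for s in starts:
        seg = x[s : min(s + win, n)]
        p, tr = msptd_window(seg)
        peaks.append(p + s)
        troughs.append(tr + s)
    min_gap = max(1, int(round(dedup_s * fs)))
    p_all = np.concatenate(peaks) if peaks else np.array([], dtype=np.intp)
    t_all = np.concatenate(troughs) if troughs else np.array([], dtype=np.intp)
    return (
        _dedup(p_all, x, min_gap, keep_max=True),
        _dedup(t_all, x, min_gap, keep_max=False),
    )


def locate_fiducials(
    x_orig: np.ndarray,
    x_filt: np.ndarray,
    peaks: np.ndarray,
    troughs: np.ndarray,
    fs: float,
) -> BeatSeries:
    """Locate onset, peak, and systolic-upslope mid-point for each beat.

    For each interval between successive beat detections the onset is the
    argmin and the peak the subsequent argmax of the filtered signal; the
    mid-point is the first sample on ``[onset, peak]`` whose filtered
    amplitude reaches ``(filt[onset] + filt[peak]) / 2`` (ties broken to the
    earliest index).  Beats whose segment is non-increasing (no upslope)
    are dropped.  ``x_orig`` is unused here but fixes the index frame the
    amplitudes are later read from.
    """
    x_filt = np.asarray(x_filt, dtype=float)
    peaks = np.asarray(peaks, dtype=np.intp)
    if peaks.size < 2:
        raise InsufficientBeatsError(
            f"need >= 2 beat detections to delimit a beat, got {peaks.size}"
        )
    onset_idx, peak_idx, mid_idx = [], [], []
    for lo, hi in zip(peaks[:-1], peaks[1:]):
        seg = x_filt[lo : hi + 1]
        onset = lo + int(np.argmin(seg))
        rise = x_filt[onset : hi + 1]
        peak = onset + int(np.argmax(rise))
        if peak <= onset or x_filt[peak] <= x_filt[onset]:
            continue  # no systolic upslope in this interval
        half = 0.5 * (x_filt[onset] + x_filt[peak])
        cross = onset + int(np.argmax(x_filt[onset : peak + 1] >= half))
        if cross <= onset:
            continue
        onset_idx.append(onset)
        peak_idx.append(peak)
        mid_idx.append(cross)
    if not peak_idx:
        raise InsufficientBeatsError("no complete beats with a systolic upslope")
    return BeatSeries(
        peaks=np.array(peak_idx),
        onsets=np.array(onset_idx),
        midpoints=np.array(mid_idx),
        fs=fs,
    )
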