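"""The three PPG signal-quality metrics: SNR, perfusion index, and TMCC.

* **SNR** — the record is band-pass filtered (Chebyshev II, 0.5–12 Hz) so
  the dominant spectral peak is the cardiac fundamental; a single windowed
  periodogram is partitioned into a DC region, the fundamental peak region,
  harmonic peak regions, and noise; SNR = 10·log10(P_fundamental/P_noise).
* **PI** — per-beat AC amplitude (peak minus onset, read from the original
  signal) and DC amplitude (|signal| at the systolic-upslope mid-point);
  PI (%) = 100 × median(AC) / median(DC).
* **TMCC** — the beat-path filtered signal is segmented into windows of one
  median inter-beat interval centred on the upslope mid-points; the
  template is the pointwise mean of all windows, and the TMCC is the mean
  Pearson correlation between each window and the template.

Higher values indicate higher signal quality for all three metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .beats import BeatSeries, InsufficientBeatsError, detect_beats_msptd, locate_fiducials
from .io_formats import PPGRecording, RunConfig
from .preprocess import FilterSpec, QC_PASS, filter_zero_phase, screen_recording

__all__ = [
    "SpectralDecomposition",
    "PulseAmplitudes",
    "QualityMetrics",
    "compute_snr",
    "compute_pulse_amplitudes",
    "compute_pi",
    "compute_tmcc",
    "compute_all",
]

#: Periodogram window: Kaiser with strong sidelobe suppression, one segment.
KAISER_BETA = 38.0
#: Harmonics of the fundamental excluded from the noise, counted up to this
#: order (and never beyond Nyquist).
N_HARMONICS = 6


class MetricUnavailable(ValueError):
    """A metric's preconditions failed; carries the reason."""


@dataclass
class SpectralDecomposition:
    """Partition of a one-sided power spectrum for the SNR computation.

    ``p_*`` powers are integrated over the respective bin regions; the DC,
    fundamental, harmonic, and noise regions are disjoint and cover the
    whole spectrum, so their powers sum to the total spectral power.
    """

    freqs: np.ndarray
    psd: np.ndarray
    f0: float
    dc_bins: np.ndarray
    fundamental_bins: np.ndarray
    harmonic_bins: list[np.ndarray]
    noise_bins: np.ndarray
    p_dc: float
    p_fundamental: float
    p_harmonics: float
    p_noise: float

    @property
    def p_total(self) -> float:
        df = self.freqs[1] - self.freqs[0]
        return float(np.sum(self.psd) * df)


def _grow_peak_region(psd: np.ndarray, centre: int, free: np.ndarray) -> np.ndarray:
    """Bins of the spectral peak at ``centre``: extend left and right while
    bin powers strictly decrease away from the centre, staying on unclaimed
    bins."""
    n = psd.size
    lo = centre
    while lo - 1 >= 0 and free[lo - 1] and psd[lo - 1] < psd[lo]:
        lo -= 1
    hi = centre
    while hi + 1 < n and free[hi + 1] and psd[hi + 1] < psd[hi]:
        hi += 1
    return np.arange(lo, hi + 1)


def decompose_spectrum(
    x: np.ndarray,
    fs: float,
    n_harmonics: int = N_HARMONICS,
    kaiser_beta: float = KAISER_BETA,
) -> SpectralDecomposition:
    """Windowed periodogram of ``x`` partitioned for the SNR.

    The DC region runs from bin 0 while powers monotonically decrease; the
    fundamental is the global maximum outside the DC region, its region
    grown by the strict monotone-decrease rule; harmonic regions are grown
    the same way around the nearest bin to ``k·f0`` for ``k = 2..n_harmonics``
    (up to Nyquist); everything else is noise.
    """
    x = np.asarray(x, dtype=float)
    # Mean removal before windowing: the band-pass stopband only attenuates
    # (never nulls) the large DC offset of raw PPG, and the leakage of the
    # residual offset can otherwise out-power the cardiac peak.
    freqs, psd = sps.periodogram(
        x, fs=fs, window=("kaiser", kaiser_beta), detrend="constant", scaling="density"
    )
    n = psd.size
    free = np.ones(n, dtype=bool)

    # DC region: bins monotonically decreasing from bin 0.
    dc_hi = 0
    while dc_hi + 1 < n and psd[dc_hi + 1] < psd[dc_hi]:
        dc_hi += 1
    dc_bins = np.arange(0, dc_hi + 1)
    free[dc_bins] = False

    if not np.any(free) or np.max(psd[free]) <= 0.0:
        raise MetricUnavailable("flat spectrum: no spectral peak outside the DC region")

    centre = int(np.flatnonzero(free)[np.argmax(psd[free])])
    fund_bins = _grow_peak_region(psd, centre, free)
    free[fund_bins] = False
    f0 = float(freqs[centre])

    harmonic_bins: list[np.ndarray] = []
    for k in range(2, n_harmonics + 1):
        fk = k * f0
        if fk > freqs[-1]:
            break
        hb = int(np.argmin(np.abs(freqs - fk)))
        if not free[hb]:
            continue
        region = _grow_peak_region(psd, hb, free)
        harmonic_bins.append(region)
        free[region] = False

    noise_bins = np.flatnonzero(free)
    df = float(freqs[1] - freqs[0])
    p = lambda idx: float(np.sum(psd[idx]) * df)
    return SpectralDecomposition(
        freqs=freqs,
        psd=psd,
        f0=f0,
        dc_bins=dc_bins,
        fundamental_bins=fund_bins,
        harmonic_bins=harmonic_bins,
        noise_bins=noise_bins,
        p_dc=p(dc_bins),
        p_fundamental=p(fund_bins),
        p_harmonics=float(sum(p(h) for h in harmonic_bins)),
        p_noise=p(noise_bins),
    )


def compute_snr(
    rec: PPGRecording,
    spec: Optional[FilterSpec] = None,
    n_harmonics: int = N_HARMONICS,
    kaiser_beta: float = KAISER_BETA,
) -> tuple[float, SpectralDecomposition]:
    """SNR in dB of one recording, with the underlying decomposition.

    The record is zero-phase filtered through the SNR path first.  A zero
    noise power is reported as ``+inf``.
    """
    if spec is None:
        spec = FilterSpec("chebyshev2", 4, (0.5, 12.0), rec.fs, 20.0)
    xf = filter_zero_phase(rec.samples, spec)
    dec = decompose_spectrum(xf, rec.fs, n_harmonics=n_harmonics, kaiser_beta=kaiser_beta)
    if dec.p_noise <= 0.0:
        return math.inf, dec
    return 10.0 * math.log10(dec.p_fundamental / dec.p_noise), dec


# ---------------------------------------------------------------------------
# perfusion index


@dataclass
class PulseAmplitudes:
    """Per-beat AC and DC amplitudes (arbitrary units) and their medians."""

    ac: np.ndarray
    dc: np.ndarray

    @property
    def median_ac(self) -> float:
        return float(np.median(self.ac))

    @property
    def median_dc(self) -> float:
        return float(np.median(self.dc))


def compute_pulse_amplitudes(x_orig: np.ndarray, beats: BeatSeries) -> PulseAmplitudes:
    """AC and DC amplitudes read from the original (unfiltered) signal.

    ``AC_k = x[peak_k] - x[onset_k]`` (floored at 0: a pulse amplitude
    cannot be negative; baseline wander in the original signal can
    otherwise push the difference slightly below zero);
    ``DC_k = |x[midpoint_k]|``.
    """
    x_orig = np.asarray(x_orig, dtype=float)
    if beats.n_beats < 1:
        raise MetricUnavailable("no complete beats")
    ac = np.maximum(x_orig[beats.peaks] - x_orig[beats.onsets], 0.0)
    dc = np.abs(x_orig[beats.midpoints])
    return PulseAmplitudes(ac=ac, dc=dc)


def compute_pi(amps: PulseAmplitudes) -> float:
    """Perfusion index in percent: ``100 × median(AC) / median(DC)``."""
    if amps.median_dc == 0.0:
        raise MetricUnavailable("median DC amplitude is zero; PI undefined")
    return 100.0 * amps.median_ac / amps.median_dc


# ---------------------------------------------------------------------------
# template-matching correlation coefficient


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation with (n-1) normalisation; 0 for a zero-variance
    input (flagged by the caller)."""
    du = u - u.mean()
    dv = v - v.mean()
    su = float(np.sqrt(np.sum(du * du)))
    sv = float(np.sqrt(np.sum(dv * dv)))
    if su == 0.0 or sv == 0.0:
        return 0.0
    return float(np.dot(du, dv) / (su * sv))


def compute_tmcc(x: np.ndarray, beats: BeatSeries, fs: float) -> float:
    """Mean correlation between beat-centred windows and their mean template.

    Window length is the median inter-beat interval in samples, forced odd
    so each window is symmetric about its mid-point; windows extending
    beyond the signal bounds are dropped.  The template is computed from
    all windows regardless of their quality.
    """
    x = np.asarray(x, dtype=float)
    if beats.n_beats < 2:
        raise MetricUnavailable("need >= 2 beats for a median inter-beat interval")
    ibi_samples = float(np.median(np.diff(beats.peaks)))
    L = int(round(ibi_samples))
    if L % 2 == 0:
        L -= 1
    if L < 3:
        raise MetricUnavailable("median inter-beat interval too short for a window")
    half = L // 2
    windows = [
        x[m - half : m + half + 1]
        for m in beats.midpoints
        if m - half >= 0 and m + half < x.size
    ]
    if len(windows) < 2:
        raise MetricUnavailable("fewer than 2 windows fully inside the signal")
    W = np.vstack(windows)
    template = W.mean(axis=0)
    corrs = np.array([_pearson(w, template) for w in W])
    return float(np.mean(corrs))


# ---------------------------------------------------------------------------
# all three metrics for one recording


@dataclass
class QualityMetrics:
    """The metric triplet for one recording, with per-metric missingness.

    Missing metrics are NaN with the reason recorded in ``reasons``; the
    QC verdict is ``pass``, ``flat_line`` or ``too_short``.
    """

    subject_id: str
    condition: str
    snr_db: float
    pi_percent: float
    tmcc: float
    median_ac: float
    median_dc: float
    n_beats: int
    qc: str
    reasons: dict[str, str] = field(default_factory=dict)


def compute_all(rec: PPGRecording, cfg: Optional[RunConfig] = None) -> QualityMetrics:
    """Run screening, both filter paths, beat detection, and all three
    metrics for one recording.

    Individual metric failures yield per-metric missing values (NaN with a
    reason); they never abort the recording.
    """
    cfg = cfg or RunConfig()
    nan = float("nan")
    out = dict(snr_db=nan, pi_percent=nan, tmcc=nan, median_ac=nan, median_dc=nan, n_beats=0)
    reasons: dict[str, str] = {}

    qc = screen_recording(rec)
    if qc != QC_PASS:
        for k in ("snr_db", "pi_percent", "tmcc"):
            reasons[k] = f"recording failed screening: {qc}"
        return QualityMetrics(
            subject_id=rec.subject_id, condition=rec.condition.value, qc=qc,
            reasons=reasons, **out,
        )

    snr_spec = FilterSpec(
        cfg.snr_filter.family, cfg.snr_filter.order,
        cfg.snr_filter.band, rec.fs, cfg.snr_filter.stopband_attenuation_db,
    )
    beat_spec = FilterSpec(
        cfg.beat_filter.family, cfg.beat_filter.order,
        cfg.beat_filter.band, rec.fs, cfg.beat_filter.stopband_attenuation_db,
    )

    try:
        out["snr_db"], _ = compute_snr(
            rec, snr_spec, n_harmonics=cfg.n_harmonics, kaiser_beta=cfg.kaiser_beta
        )
    except (MetricUnavailable, ValueError) as err:
        reasons["snr_db"] = str(err)

    beats = None
    try:
        x_beat = filter_zero_phase(rec.samples, beat_spec)
        peaks, troughs = detect_beats_msptd(
            x_beat, rec.fs,
            window_s=cfg.msptd_window_s, overlap=cfg.msptd_overlap,
            dedup_s=cfg.msptd_dedup_s,
        )
        beats = locate_fiducials(rec.samples, x_beat, peaks, troughs, rec.fs)
        out["n_beats"] = beats.n_beats
    except (InsufficientBeatsError, ValueError) as err:
        reasons["pi_percent"] = reasons["tmcc"] = f"beat detection failed: {err}"

    if beats is not None:
        try:
            amps = compute_pulse_amplitudes(rec.samples, beats)
            out["median_ac"] = amps.median_ac
            out["median_dc"] = amps.median_dc
            out["pi_percent"] = compute_pi(amps)
        except MetricUnavailable as err:
            reasons["pi_percent"] = str(err)
        try:
            out["tmcc"] = compute_tmcc(x_beat, beats, rec.fs)
        except MetricUnavailable as err:
            reasons["tmcc"] = str(err)

    return QualityMetrics(
        subject_id=rec.subject_id, condition=rec.condition.value, qc=qc,
        reasons=reasons, **out,
    )
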