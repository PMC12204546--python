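"""Zero-phase band-pass filtering and recording/cohort screening.

Two filtering paths feed the quality metrics:

* the SNR path — a zero-phase Chebyshev type-II band-pass, designed order 4,
  0.5–12 Hz, which removes sub-cardiac baseline variation so that the
  largest spectral peak is the cardiac fundamental;
* the beat path — a zero-phase Butterworth band-pass, designed order 4,
  0.5–8 Hz, used for beat detection and fiducial localisation.

"Order" is the designed order passed to the filter design routine before
forward–backward application; the zero-phase pass doubles the effective
order and squares the magnitude response.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from .io_formats import Condition, PPGRecording, ValidationError

__all__ = [
    "FilterSpec",
    "design_bandpass",
    "filter_zero_phase",
    "screen_recording",
    "screen_cohort",
    "QCVerdict",
]


@dataclass(frozen=True)
class FilterSpec:
    """A band-pass filter design.

    Parameters
    ----------
    family : {"chebyshev2", "butterworth"}
    order : int
        Designed order (even, >= 2) before forward-backward application.
    band : (f_hp, f_lp)
        High-pass and low-pass cut-off frequencies in Hz.
    fs : float
        Sampling frequency in Hz.
    stopband_attenuation_db : float
        Chebyshev-II stopband attenuation (single pass), ignored for
        Butterworth.
    """

    family: str
    order: int
    band: tuple[float, float]
    fs: float
    stopband_attenuation_db: float = 20.0

    def __post_init__(self) -> None:
        if self.family not in ("chebyshev2", "butterworth"):
            raise ValidationError(f"unknown filter family {self.family!r}")
        if self.order < 2 or self.order % 2:
            raise ValidationError(f"order must be even and >= 2, got {self.order}")
        f_hp, f_lp = self.band
        if not 0 < f_hp < f_lp < self.fs / 2:
            raise ValidationError(
                f"band must satisfy 0 < f_hp < f_lp < fs/2; got {self.band} at fs={self.fs}"
            )


def design_bandpass(spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Design the digital IIR band-pass filter and return ``(b, a)``.

    Raises ``ValidationError`` if the realised filter is unstable (poles on
    or outside the unit circle).
    """
    wn = (spec.band[0], spec.band[1])
    if spec.family == "chebyshev2":
        b, a = signal.cheby2(
            spec.order, spec.stopband_attenuation_db, wn, btype="bandpass", fs=spec.fs
        )
    else:
        b, a = signal.butter(spec.order, wn, btype="bandpass", fs=spec.fs)
    poles = np.roots(a)
    if np.any(np.abs(poles) >= 1.0):
        raise ValidationError(
            f"designed filter is unstable (max |pole| = {np.abs(poles).max():.6f})"
        )
    return b, a


def frequency_response(spec: FilterSpec, freqs: Sequence[float]) -> np.ndarray:
    """Single-pass complex frequency response at the given frequencies (Hz)."""
    b, a = design_bandpass(spec)
    _, h = signal.freqz(b, a, worN=np.asarray(freqs, dtype=float), fs=spec.fs)
    return h


def filter_zero_phase(x: Sequence[float], spec: FilterSpec) -> np.ndarray:
    """Apply the filter forward and backward (zero net phase).

    Start-up transients are suppressed by odd-symmetric reflection padding
    of length ``3 * (order_ba + 1)`` where ``order_ba`` is the order of the
    realised transfer function (2x the designed order for a band-pass).
    The forward-backward pass is symmetrised (averaged with its
    time-reversed application), so filtering commutes exactly with time
    reversal and residual edge transients are halved.  Output length equals
    input length.
    """
    x = np.asarray(x, dtype=float)
    b, a = design_bandpass(spec)
    padlen = 3 * max(len(a), len(b))
    if x.size <= padlen:
        raise ValidationError(
            f"input too short for zero-phase filtering: need > {padlen} samples, got {x.size}"
        )
    fwd = signal.filtfilt(b, a, x, padtype="odd", padlen=padlen)
    rev = signal.filtfilt(b, a, x[::-1], padtype="odd", padlen=padlen)[::-1]
    return 0.5 * (fwd + rev)


# ---------------------------------------------------------------------------
# screening

#: QC verdict literals.
QCVerdict = str
QC_PASS = "pass"
QC_FLAT_LINE = "flat_line"
QC_TOO_SHORT = "too_short"

#: Minimum usable record duration in seconds.
MIN_DURATION_S = 10.0
#: Relative flat-line tolerance on |x - median| and its absolute floor.
FLAT_RTOL = 1e-6
FLAT_ATOL = 1e-12


def screen_recording(rec: PPGRecording) -> QCVerdict:
    """Quality-control verdict for one recording.

    ``flat_line`` when the maximum absolute deviation from the record
    median is below tolerance (a missing-signal appearance), or when more
    than 95% of successive differences are exactly zero; ``too_short`` when
    the duration is under 10 s; otherwise ``pass``.
    """
    x = rec.samples
    med = float(np.median(x))
    tol = max(FLAT_RTOL * abs(med), FLAT_ATOL)
    if np.max(np.abs(x - med)) < tol:
        return QC_FLAT_LINE
    diffs = np.diff(x)
    if diffs.size and np.mean(diffs == 0.0) > 0.95:
        return QC_FLAT_LINE
    if rec.duration < MIN_DURATION_S:
        return QC_TOO_SHORT
    return QC_PASS


def screen_cohort(
    recordings: Iterable[PPGRecording],
    expected: Sequence[Condition] | None = None,
) -> tuple[set[str], dict[str, str]]:
    """Complete-case screening over a cohort of recordings.

    A subject is included iff every recording of the expected per-subject
    condition multiset exists and passes :func:`screen_recording`.

    Parameters
    ----------
    recordings : iterable of PPGRecording
    expected : sequence of Condition, optional
        The per-subject condition multiset; defaults to the
        oscillometric-style protocol (2 supine + 5 other conditions).

    Returns
    -------
    included : set of subject ids
    reasons : dict
        Exclusion reason per excluded subject.
    """
    from .io_formats import PROTOCOL_CONDITIONS

    expected_counts = Counter(Condition(c) for c in (expected or PROTOCOL_CONDITIONS))
    by_subject: dict[str, list[PPGRecording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)

    included: set[str] = set()
    reasons: dict[str, str] = {}
    for subject, recs in sorted(by_subject.items()):
        verdicts = [(r, screen_recording(r)) for r in recs]
        bad = [(r, v) for r, v in verdicts if v != QC_PASS]
        counts = Counter(r.condition for r, v in verdicts if v == QC_PASS)
        missing = expected_counts - counts
        if bad:
            r, v = bad[0]
            reasons[subject] = f"{v} recording in condition {r.condition.value}"
        elif missing:
            reasons[subject] = "missing recordings: " + ", ".join(
                f"{c.value} x{k}" for c, k in sorted(missing.items(), key=lambda kv: kv[0].value)
            )
        else:
            included.add(subject)
    return included, reasons
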