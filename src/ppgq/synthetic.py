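"""Synthetic data generators for the two levels of the analysis.

Waveform level
    :func:`generate_recording` builds a PPG-like signal as
    ``dc_level + baseline wander + pulse train + white noise + artifact
    bursts``, where each pulse is a two-Gaussian kernel (systolic wave plus
    an optional diastolic bump) scaled to the beat's inter-beat interval.
    Ground-truth beat onset times and component powers are returned so beat
    detection and the SNR can be checked against known answers.

Metric level
    :func:`simulate_metric_cohort` generates a long-format cohort table with
    the repeated-measures mixed-effects structure the statistical analysis
    assumes: ``y = intercept + Σ β·x + b_subject + ε`` with
    ``b ~ N(0, σ_subject²)`` and ``ε ~ N(0, σ_resid²)``.  Covariates are
    drawn from marginal distributions matching the source cohorts
    (auscultatory-style: 643 subjects, supine only; oscillometric-style:
    499 subjects, six posture/height conditions).

Neither generator is a physiological cardiovascular model; posture and
sensor-height effects enter only through configured amplitude/noise or
fixed-effect parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    Condition,
    PPGRecording,
    PROTOCOL_CONDITIONS,
    SubjectRecord,
    ValidationError,
    condition_dummies,
)

__all__ = [
    "PulseShape",
    "WaveformConfig",
    "GroundTruth",
    "CovariateGenerator",
    "auscultatory_covariates",
    "oscillometric_covariates",
    "CohortDesign",
    "generate_recording",
    "generate_waveform_cohort",
    "simulate_metric_cohort",
    "default_condition_configs",
]


@dataclass(frozen=True)
class PulseShape:
    """Two-Gaussian beat kernel, parametrised as fractions of one IBI.

    The systolic wave peaks at ``sys_pos`` with width ``sys_width``; the
    diastolic bump (relative amplitude ``dia_amp``) at ``dia_pos`` with
    width ``dia_width``.  The kernel must decay inside one beat so that
    successive kernels do not overlap.
    """

    sys_pos: float = 0.22
    sys_width: float = 0.07
    dia_pos: float = 0.55
    dia_width: float = 0.12
    dia_amp: float = 0.30

    def __post_init__(self) -> None:
        for pos, width, name in (
            (self.sys_pos, self.sys_width, "systolic"),
            (self.dia_pos, self.dia_width, "diastolic"),
        ):
            if not 0 < pos < 1 or width <= 0:
                raise ValidationError(f"{name} kernel position/width out of range")
            if pos + 3 * width > 1 or pos - 3 * width < -0.5:
                raise ValidationError(
                    f"{name} kernel wider than one inter-beat interval "
                    f"(pos={pos}, width={width}); kernels would overlap"
                )
        if self.dia_amp < 0:
            raise ValidationError("diastolic relative amplitude must be >= 0")

    def __call__(self, u: np.ndarray) -> np.ndarray:
        """Kernel value at phase ``u`` in [0, 1)."""
        out = np.exp(-0.5 * ((u - self.sys_pos) / self.sys_width) ** 2)
        if self.dia_amp > 0:
            out = out + self.dia_amp * np.exp(
                -0.5 * ((u - self.dia_pos) / self.dia_width) ** 2
            )
        return out


@dataclass
class WaveformConfig:
    """Parameters of one synthetic PPG recording.

    Amplitudes are in arbitrary units, matching the sensor's uncalibrated
    output.  Defaults give a clean supine-like 30 s record at 100 Hz with a
    perfusion index of about 0.5%.
    """

    fs: float = 100.0
    duration: float = 30.0
    mean_hr: float = 70.0
    hr_sd: float = 1.0
    ac_amp: float = 0.5
    dc_level: float = 100.0
    pulse_shape: PulseShape = field(default_factory=PulseShape)
    wander_amp: float = 0.1
    wander_freq: float = 0.2
    noise_sd: float = 0.03
    artifact_rate: float = 0.0
    artifact_amp: float = 0.0
    seed: int = 0
    subject_id: str = "sim"
    condition: Condition = Condition.SUPINE

    def __post_init__(self) -> None:
        if self.dc_level <= 0:
            raise ValidationError("dc_level must be positive")
        if not 30 <= self.mean_hr <= 200:
            raise ValidationError("mean_hr must be in [30, 200] bpm")
        if self.wander_freq >= 0.5:
            raise ValidationError("wander_freq must be below 0.5 Hz")
        for name in ("ac_amp", "hr_sd", "wander_amp", "noise_sd", "artifact_rate", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.fs <= 0 or self.duration <= 0:
            raise ValidationError("fs and duration must be positive")
        self.condition = Condition(self.condition)


@dataclass
class GroundTruth:
    """What the generator injected into one recording.

    ``beat_times`` are pulse onset times in seconds (strictly increasing);
    ``ac_amplitudes`` the per-beat peak-minus-minimum amplitude of the
    noiseless pulse component; the ``*_power`` fields are the variances of
    the individual additive components, so that when components are
    spectrally disjoint their sum matches the total signal variance.
    """

    beat_times: np.ndarray
    ac_amplitudes: np.ndarray
    pulse_power: float
    wander_power: float
    noise_power: float
    artifact_power: float


#: Maximum IBI deviation as a fraction of the mean IBI (prevents kernel
#: overlap between successive beats).
IBI_TRUNC_FRAC = 0.3


def generate_recording(cfg: WaveformConfig) -> tuple[PPGRecording, GroundTruth]:
    """Generate one synthetic recording and its ground truth.

    The same config (including ``seed``) always produces a bit-identical
    sample vector.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    mean_ibi = 60.0 / cfg.mean_hr
    sd_ibi = cfg.hr_sd * 60.0 / cfg.mean_hr**2  # bpm jitter mapped to seconds
    max_dev = IBI_TRUNC_FRAC * mean_ibi

    # Beat onset times: first onset shortly after t=0, IBIs drawn until the
    # record end, deviations truncated to keep kernels inside one beat.
    onsets = [float(rng.uniform(0.0, mean_ibi / 2))]
    ibis = []
    while True:
        dev = float(np.clip(rng.normal(0.0, sd_ibi) if sd_ibi > 0 else 0.0, -max_dev, max_dev))
        ibi = mean_ibi + dev
        if onsets[-1] + ibi > cfg.duration:
            break
        ibis.append(ibi)
        onsets.append(onsets[-1] + ibi)
    if ibis:
        beat_times = np.array(onsets[:-1])
        beat_ibis = np.array(ibis)
    else:  # record shorter than one beat: keep the lone onset
        beat_times = np.array(onsets)
        beat_ibis = np.array([mean_ibi])

    pulses = np.zeros(n)
    ac_truth = []
    for t0, ibi in zip(beat_times, beat_ibis):
        i0 = int(np.ceil(t0 * cfg.fs))
        i1 = min(n, int(np.ceil((t0 + ibi) * cfg.fs)))
        if i1 <= i0:
            continue
        u = (t[i0:i1] - t0) / ibi
        k = cfg.pulse_shape(u)
        pulses[i0:i1] += cfg.ac_amp * k
        ac_truth.append(cfg.ac_amp * (float(k.max()) - float(k.min())) if k.size else 0.0)

    wander = cfg.wander_amp * np.sin(
        2 * np.pi * cfg.wander_freq * t + rng.uniform(0, 2 * np.pi)
    )
    noise = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else np.zeros(n)

    artifact = np.zeros(n)
    if cfg.artifact_rate > 0 and cfg.artifact_amp > 0:
        n_bursts = rng.poisson(cfg.artifact_rate * cfg.duration)
        for _ in range(n_bursts):
            dur = rng.uniform(0.5, 2.0)
            start = rng.uniform(0.0, max(cfg.duration - dur, 0.0))
            i0, i1 = int(start * cfg.fs), min(n, int((start + dur) * cfg.fs))
            if i1 <= i0:
                continue
            # coloured (low-pass, brownian-like) burst noise
            w = np.cumsum(rng.normal(0.0, 1.0, i1 - i0))
            w -= w.mean()
            scale = np.std(w)
            if scale > 0:
                artifact[i0:i1] += cfg.artifact_amp * w / scale

    x = cfg.dc_level + wander + pulses + noise + artifact
    rec = PPGRecording(
        subject_id=cfg.subject_id, condition=cfg.condition, fs=cfg.fs, samples=x
    )
    gt = GroundTruth(
        beat_times=beat_times,
        ac_amplitudes=np.array(ac_truth),
        pulse_power=float(np.var(pulses)),
        wander_power=float(np.var(wander)),
        noise_power=float(np.var(noise)),
        artifact_power=float(np.var(artifact)),
    )
    return rec, gt


# ---------------------------------------------------------------------------
# covariate distributions


@dataclass
class CovariateGenerator:
    """Marginal distributions for the per-subject covariates.

    ``skin_probs`` are the probabilities of Fitzpatrick types 1..6 among
    subjects with known skin tone; ``p_skin_unknown`` is the probability of
    a missing skin tone.  ``dc_bins``/``dc_probs`` define a mixture of
    uniforms over DC-amplitude ranges (arbitrary units), mirroring the
    banded LED-intensity settings seen in wrist-sensor data.
    """

    age_mean: float = 45.0
    age_sd: float = 13.0
    p_female: float = 0.493
    bmi_mean: float = 28.7
    bmi_sd: float = 6.6
    sbp_mean: float = 129.0
    sbp_sd: float = 19.0
    dbp_mean: float = 78.0
    dbp_sd: float = 13.0
    p_diabetes: float = 0.084
    skin_probs: tuple[float, ...] = (0.453, 0.341, 0.128, 0.042, 0.033, 0.005)
    p_skin_unknown: float = 0.0
    dc_bins: tuple[tuple[float, float], ...] = (
        (3e3, 50e3),
        (295e3, 330e3),
        (570e3, 605e3),
        (850e3, 900e3),
    )
    dc_probs: tuple[float, ...] = (0.230, 0.411, 0.314, 0.045)

    def draw(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        """Draw ``n`` subjects' covariates (long-format ready)."""
        age = np.clip(rng.normal(self.age_mean, self.age_sd, n), 18.0, 90.0)
        gender = np.where(rng.random(n) < self.p_female, 1, 2)
        bmi = np.clip(rng.normal(self.bmi_mean, self.bmi_sd, n), 15.0, 60.0)
        sbp = rng.normal(self.sbp_mean, self.sbp_sd, n)
        dbp = rng.normal(self.dbp_mean, self.dbp_sd, n)
        pp = np.clip(sbp - dbp, 5.0, None)
        diabetes = (rng.random(n) < self.p_diabetes).astype(int)
        probs = np.asarray(self.skin_probs, dtype=float)
        probs = probs / probs.sum()
        skin = rng.choice(np.arange(1, 7), size=n, p=probs).astype(float)
        if self.p_skin_unknown > 0:
            skin[rng.random(n) < self.p_skin_unknown] = np.nan
        dc_probs = np.asarray(self.dc_probs, dtype=float)
        dc_probs = dc_probs / dc_probs.sum()
        bin_idx = rng.choice(len(self.dc_bins), size=n, p=dc_probs)
        lo = np.array([self.dc_bins[i][0] for i in bin_idx])
        hi = np.array([self.dc_bins[i][1] for i in bin_idx])
        dc = rng.uniform(lo, hi)
        return pd.DataFrame(
            {
                "age": age,
                "gender": gender,
                "bmi": bmi,
                "diabetes": diabetes,
                "skin": skin,
                "sbp": sbp,
                "pp": pp,
                "dc_amplitude": dc,
            }
        )


def auscultatory_covariates() -> CovariateGenerator:
    """Covariate marginals of the auscultatory-style cohort (skin tone
    known for everyone)."""
    return CovariateGenerator()


def oscillometric_covariates(p_skin_unknown: float = 0.0) -> CovariateGenerator:
    """Covariate marginals of the oscillometric-style cohort.

    In the source data 71.7% of this cohort has unknown skin tone; pass
    ``p_skin_unknown=0.717`` to emulate that missingness (the default keeps
    covariates complete so covariate models retain all subjects).
    """
    return CovariateGenerator(
        age_mean=45.5,
        age_sd=8.9,
        p_female=0.487,
        bmi_mean=30.5,
        bmi_sd=7.1,
        sbp_mean=131.0,
        sbp_sd=17.0,
        dbp_mean=86.0,
        dbp_sd=11.0,
        p_diabetes=0.112,
        skin_probs=(0.057, 0.426, 0.340, 0.113, 0.043, 0.021),
        p_skin_unknown=p_skin_unknown,
        dc_bins=((3e3, 50e3), (295e3, 330e3), (570e3, 605e3), (1135e3, 1140e3)),
        dc_probs=(0.6848, 0.2771, 0.0381, 0.0),
    )


# ---------------------------------------------------------------------------
# waveform-level cohort


def default_condition_configs() -> dict[Condition, WaveformConfig]:
    """Per-condition waveform parameters mimicking the observed quality
    gradient across postures and sensor heights.

    The condition acts on the pulsatile (AC) amplitude — highest supine,
    lowest standing arm-down, values matching typical observed per-condition
    perfusion-index medians — while the additive sensor noise floor is
    condition-independent.  With these settings the simulated per-condition
    median SNRs span roughly 9 dB (standing arm down) to 19 dB (supine).
    """
    ac_amps = {
        Condition.SUPINE: 0.76,
        Condition.STANDING_ARM_UP: 0.49,
        Condition.SITTING_ARM_UP: 0.38,
        Condition.SITTING_ARM_LAP: 0.31,
        Condition.SITTING_ARM_DOWN: 0.20,
        Condition.STANDING_ARM_DOWN: 0.18,
    }
    return {
        cond: WaveformConfig(ac_amp=ac, condition=cond) for cond, ac in ac_amps.items()
    }


def generate_waveform_cohort(
    n_subjects: int,
    condition_configs: Optional[Mapping[Condition, WaveformConfig]] = None,
    seed: int = 0,
    subject_dc_sd: float = 10.0,
    covariates: Optional[CovariateGenerator] = None,
) -> tuple[list[PPGRecording], list[SubjectRecord], dict[tuple[str, str, int], GroundTruth]]:
    """Generate a full repeated-measures waveform cohort.

    Each subject contributes the oscillometric-style protocol multiset: two
    supine recordings plus one of each sitting/standing condition (7
    recordings).  Subjects get a random DC baseline shift (SD
    ``subject_dc_sd``) applied to every recording, plus covariates drawn
    from ``covariates`` (oscillometric-style marginals by default).  The
    cohort table's ``dc_amplitude`` is the subject's realised DC level so
    waveform and covariate data stay consistent.

    Returns recordings, subject records, and ground truth keyed by
    ``(subject_id, condition value, repetition index)``.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    condition_configs = dict(condition_configs or default_condition_configs())
    covariates = covariates or oscillometric_covariates()
    root = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    cov = covariates.draw(cov_rng, n_subjects)

    recordings: list[PPGRecording] = []
    subjects: list[SubjectRecord] = []
    truths: dict[tuple[str, str, int], GroundTruth] = {}
    subj_seeds = root.spawn(n_subjects + 1)[1:]
    for i in range(n_subjects):
        sid = f"S{i:04d}"
        srng = np.random.default_rng(subj_seeds[i])
        dc_shift = float(srng.normal(0.0, subject_dc_sd))
        reps: dict[Condition, int] = {}
        for cond in PROTOCOL_CONDITIONS:
            rep = reps.get(cond, 0)
            reps[cond] = rep + 1
            base = condition_configs[cond]
            cfg = dataclasses.replace(
                base,
                subject_id=sid,
                condition=cond,
                dc_level=max(base.dc_level + dc_shift, 1.0),
                seed=int(srng.integers(0, 2**31 - 1)),
            )
            rec, gt = generate_recording(cfg)
            recordings.append(rec)
            truths[(sid, cond.value, rep)] = gt
        row = cov.iloc[i]
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age=float(row["age"]),
                gender=int(row["gender"]),
                bmi=float(row["bmi"]),
                diabetes=int(row["diabetes"]),
                skin=None if np.isnan(row["skin"]) else int(row["skin"]),
                sbp=float(row["sbp"]),
                pp=float(row["pp"]),
                dc_amplitude=float(
                    max(condition_configs[Condition.SUPINE].dc_level + dc_shift, 1.0)
                ),
            )
        )
    return recordings, subjects, truths


# ---------------------------------------------------------------------------
# metric-level cohort


#: Fixed-effect term names resolvable in a simulated metric cohort.
COVARIATE_TERMS = ("age", "gender", "bmi", "diabetes", "skin", "sbp", "pp", "dc_amplitude")
CONDITION_TERMS = ("posture_sitting", "posture_supine", "height_arm_up", "height_hand_in_lap")


@dataclass
class CohortDesign:
    """Design of a metric-level simulated cohort.

    ``fixed_effects`` maps term names (covariates or treatment-coded
    condition dummies, reference levels standing posture and arm-down
    height) to coefficients in the units of the target metric.
    """

    n_subjects: int
    conditions: Sequence[Condition] = PROTOCOL_CONDITIONS
    intercept: float = 0.0
    fixed_effects: Mapping[str, float] = field(default_factory=dict)
    sigma_subject: float = 4.0
    sigma_resid: float = 4.0
    covariates: CovariateGenerator = field(default_factory=auscultatory_covariates)
    response: str = "value"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.sigma_subject < 0:
            raise ValidationError("sigma_subject must be >= 0")
        if self.sigma_resid < 0:
            raise ValidationError("sigma_resid must be >= 0")
        allowed = set(COVARIATE_TERMS) | set(CONDITION_TERMS)
        unknown = set(self.fixed_effects) - allowed
        if unknown:
            raise ValidationError(
                f"unknown fixed-effect term(s) {sorted(unknown)}; "
                f"known terms: {sorted(allowed)}"
            )


def simulate_metric_cohort(design: CohortDesign) -> pd.DataFrame:
    """Simulate a long-format metric cohort from a mixed-effects design.

    One row per subject x protocol recording; the response column (named
    ``design.response``) is ``intercept + Σ β·x + b_subject + ε``.
    Columns include the condition label, its posture/height dummies, and
    all covariates.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_subjects
    cov = design.covariates.draw(rng, n)
    cov.insert(0, "subject_id", [f"S{i:04d}" for i in range(n)])

    conds = [Condition(c) for c in design.conditions]
    rows = cov.loc[cov.index.repeat(len(conds))].reset_index(drop=True)
    rows["condition"] = [c.value for _ in range(n) for c in conds]
    rows = pd.concat([rows, condition_dummies(rows["condition"])], axis=1)

    y = np.full(len(rows), float(design.intercept))
    for term, beta in design.fixed_effects.items():
        y += beta * rows[term].to_numpy(dtype=float)
    b = rng.normal(0.0, design.sigma_subject, n) if design.sigma_subject > 0 else np.zeros(n)
    y += np.repeat(b, len(conds))
    y += rng.normal(0.0, design.sigma_resid, len(rows))
    rows[design.response] = y
    return rows
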