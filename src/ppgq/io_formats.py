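"""Reading and writing PPG recordings, cohort tables, and run configuration.

Recordings are stored one per file as delimited text with a time column
``t`` (seconds) and an amplitude column ``ppg`` (arbitrary units).  The file
naming convention ``<subject>__<condition>.tsv`` carries the metadata when no
sidecar columns are present.  The per-subject covariate table (``cohort.tsv``)
mirrors the characteristics table of a typical wearable-PPG cohort study:
age, gender, BMI, diabetes, Fitzpatrick skin type, systolic blood pressure,
pulse pressure and the PPG DC amplitude.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ppgq")

__all__ = [
    "Condition",
    "PPGRecording",
    "SubjectRecord",
    "FilterSettings",
    "RunConfig",
    "FormatError",
    "EmptyRecordingError",
    "ValidationError",
    "read_recording",
    "write_recording",
    "read_cohort_table",
    "write_cohort_table",
    "load_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected delimited layout."""


class EmptyRecordingError(ValueError):
    """A recording has fewer than two samples."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, coding, ...)."""


class Condition(str, enum.Enum):
    """Posture x sensor-height measurement condition.

    Six levels: supine (sensor alongside the body, repeated twice per
    subject in the oscillometric-style protocol), three sitting sensor
    heights (arm hanging down, hand in lap, arm up at heart height) and two
    standing heights (arm down, arm up).
    """

    SUPINE = "supine"
    SITTING_ARM_DOWN = "sitting_arm_down"
    SITTING_ARM_LAP = "sitting_arm_lap"
    SITTING_ARM_UP = "sitting_arm_up"
    STANDING_ARM_DOWN = "standing_arm_down"
    STANDING_ARM_UP = "standing_arm_up"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def posture(self) -> str:
        """Posture component: supine, sitting or standing."""
        return self.value.split("_")[0]

    @property
    def height(self) -> str:
        """Sensor-height component: arm_down, hand_in_lap or arm_up.

        Supine measurements are taken with the arm alongside the body and
        are coded as arm_down for the posture/height factorisation.
        """
        if self is Condition.SUPINE:
            return "arm_down"
        if self is Condition.SITTING_ARM_LAP:
            return "hand_in_lap"
        return "arm_up" if self.value.endswith("arm_up") else "arm_down"


#: Per-subject condition multiset of the oscillometric-style protocol:
#: two supine recordings plus one of each other condition (7 recordings).
PROTOCOL_CONDITIONS: tuple[Condition, ...] = (
    Condition.SUPINE,
    Condition.SUPINE,
    Condition.SITTING_ARM_DOWN,
    Condition.SITTING_ARM_LAP,
    Condition.SITTING_ARM_UP,
    Condition.STANDING_ARM_DOWN,
    Condition.STANDING_ARM_UP,
)


@dataclass
class PPGRecording:
    """A single-channel PPG time series with its acquisition metadata.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    condition : Condition
        Posture/sensor-height label.
    fs : float
        Sampling frequency in Hz, finite and positive.
    samples : ndarray
        PPG amplitudes in arbitrary units, at least two samples.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    subject_id: str
    condition: Condition
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise EmptyRecordingError(
                f"recording needs >= 2 samples, got shape {self.samples.shape}"
            )
        if not (math.isfinite(self.fs) and self.fs > 0):
            raise ValidationError(f"fs must be finite and positive, got {self.fs}")
        self.condition = Condition(self.condition)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds, first sample at ``t0``."""
        return self.t0 + np.arange(self.n) / self.fs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPGRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.condition == other.condition
            and np.isclose(self.fs, other.fs, rtol=1e-9)
            and self.samples.size == other.samples.size
            and np.allclose(self.samples, other.samples, rtol=1e-9, atol=0.0)
        )


#: Covariate columns of the cohort table, in file order.
COHORT_COLUMNS = [
    "subject_id",
    "age",
    "gender",
    "bmi",
    "diabetes",
    "skin",
    "sbp",
    "pp",
    "dc_amplitude",
]


@dataclass
class SubjectRecord:
    """Per-subject covariates.

    Codings follow the cohort-table conventions: gender F = 1 / M = 2,
    diabetes present = 1 / absent = 0, skin tone as the Fitzpatrick type
    (integer 1-6, ``None`` when unknown), blood pressures in mmHg, DC
    amplitude in arbitrary units.
    """

    subject_id: str
    age: float
    gender: int
    bmi: float
    diabetes: int
    skin: Optional[int]
    sbp: float
    pp: float
    dc_amplitude: float

    def __post_init__(self) -> None:
        if self.skin is not None and (math.isnan(self.skin) if isinstance(self.skin, float) else False):
            self.skin = None
        if self.skin is not None:
            skin = int(self.skin)
            if not 1 <= skin <= 6:
                raise ValidationError(
                    f"subject {self.subject_id!r}: field 'skin' must be a "
                    f"Fitzpatrick type in 1..6 or missing, got {self.skin}"
                )
            self.skin = skin
        if self.gender not in (1, 2):
            raise ValidationError(
                f"subject {self.subject_id!r}: field 'gender' must be 1 (F) or 2 (M), got {self.gender}"
            )
        if self.diabetes not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id!r}: field 'diabetes' must be 0 or 1, got {self.diabetes}"
            )
        if self.pp < 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: field 'pp' must be >= 0, got {self.pp}"
            )


@dataclass
class FilterSettings:
    """Settings of one band-pass filtering path (see :mod:`ppgq.preprocess`)."""

    family: str = "chebyshev2"
    order: int = 4
    band: tuple[float, float] = (0.5, 12.0)
    stopband_attenuation_db: float = 20.0


@dataclass
class RunConfig:
    """Run configuration for the end-to-end pipeline.

    Defaults reproduce the analysis parameters: Chebyshev-II 0.5-12 Hz SNR
    path, Butterworth 0.5-8 Hz beat path, harmonics counted up to the 6th,
    Kaiser beta 38 periodogram window.
    """

    seed: int = 0
    n_subjects: int = 50
    snr_filter: FilterSettings = field(
        default_factory=lambda: FilterSettings("chebyshev2", 4, (0.5, 12.0), 20.0)
    )
    beat_filter: FilterSettings = field(
        default_factory=lambda: FilterSettings("butterworth", 4, (0.5, 8.0), 0.0)
    )
    n_harmonics: int = 6
    kaiser_beta: float = 38.0
    msptd_window_s: float = 6.0
    msptd_overlap: float = 0.2
    msptd_dedup_s: float = 0.25
    out_dir: str = "ppgq_out"
    simulator: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.n_harmonics < 1:
            raise ValidationError("n_harmonics must be >= 1")
        if not 0 <= self.msptd_overlap < 1:
            raise ValidationError("msptd_overlap must be in [0, 1)")
        for name in ("msptd_window_s", "msptd_dedup_s", "kaiser_beta"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def load_config(path: Union[str, Path, None] = None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file, with keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    for key in ("snr_filter", "beat_filter"):
        if key in data and isinstance(data[key], dict):
            sub = data[key]
            if "band" in sub:
                sub["band"] = tuple(float(v) for v in sub["band"])
            data[key] = FilterSettings(**sub)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# recordings


def _infer_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def recording_filename(subject_id: str, condition: Condition, rep: int = 0) -> str:
    """Canonical file name ``<subject>__<condition>[__rep<k>].tsv``."""
    stem = f"{subject_id}__{Condition(condition).value}"
    if rep:
        stem += f"__rep{rep}"
    return stem + ".tsv"


def _parse_filename(path: Path) -> tuple[str, Optional[Condition]]:
    parts = path.stem.split("__")
    subject = parts[0]
    cond = None
    if len(parts) >= 2:
        try:
            cond = Condition(parts[1])
        except ValueError:
            cond = None
    return subject, cond


def read_recording(
    path: Union[str, Path],
    fs: Optional[float] = None,
    subject_id: Optional[str] = None,
    condition: Optional[Condition] = None,
) -> PPGRecording:
    """Read a recording from a ``t``/``ppg`` delimited file.

    The sampling frequency is inferred as ``1 / median(diff(t))`` when not
    supplied; a warning is logged if the time steps vary by more than 1%.
    Subject and condition default to the ``<subject>__<condition>.tsv``
    filename convention unless sidecar ``subject_id``/``condition`` columns
    are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_infer_delimiter(path))
    if "ppg" not in df.columns:
        raise FormatError(f"{path}: missing 'ppg' column (found {list(df.columns)})")
    if "t" not in df.columns:
        raise FormatError(f"{path}: missing 't' column")
    if len(df) < 2:
        raise EmptyRecordingError(f"{path}: fewer than 2 rows")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    if fs is None:
        med = float(np.median(dt))
        fs = 1.0 / med
        if np.max(np.abs(dt - med)) > 0.01 * med:
            logger.warning(
                "%s: time steps vary by >1%%; fs inferred as 1/median(dt) = %.6g Hz",
                path,
                fs,
            )
    file_subject, file_cond = _parse_filename(path)
    if subject_id is None:
        subject_id = (
            str(df["subject_id"].iloc[0]) if "subject_id" in df.columns else file_subject
        )
    if condition is None:
        if "condition" in df.columns:
            condition = Condition(str(df["condition"].iloc[0]))
        elif file_cond is not None:
            condition = file_cond
        else:
            raise FormatError(
                f"{path}: condition not in filename and no 'condition' column"
            )
    return PPGRecording(
        subject_id=subject_id,
        condition=condition,
        fs=float(fs),
        samples=df["ppg"].to_numpy(dtype=float),
        t0=float(t[0]),
    )


def write_recording(rec: PPGRecording, path: Union[str, Path]) -> Path:
    """Write a recording as a two-column TSV (``t`` in s, ``ppg`` in a.u.).

    Floating-point values are written with 12 significant digits so a
    read-back round trip reproduces the recording to better than 1e-9
    relative.
    """
    path = Path(path)
    df = pd.DataFrame({"t": rec.t, "ppg": rec.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# cohort table


def read_cohort_table(path: Union[str, Path]) -> list[SubjectRecord]:
    """Read the per-subject covariate table.

    Empty cells in the ``skin`` column are kept as missing (unknown skin
    tone); such subjects are excluded later from covariate models that use
    skin tone. An out-of-range Fitzpatrick value raises a
    :class:`ValidationError` naming the row and field.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_delimiter(path))
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        skin = row["skin"]
        skin = None if pd.isna(skin) else int(skin)
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    age=float(row["age"]),
                    gender=int(row["gender"]),
                    bmi=float(row["bmi"]),
                    diabetes=int(row["diabetes"]),
                    skin=skin,
                    sbp=float(row["sbp"]),
                    pp=float(row["pp"]),
                    dc_amplitude=float(row["dc_amplitude"]),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i}: {err}") from err
    return records


def write_cohort_table(records: list[SubjectRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=COHORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Covariate records as a DataFrame (skin missing -> NaN)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=COHORT_COLUMNS)


def condition_dummies(conditions: "pd.Series | list") -> pd.DataFrame:
    """Treatment-coded posture/height dummies for a sequence of conditions.

    Reference levels are the standing posture and the arm-down sensor
    height, so the columns are ``posture_sitting``, ``posture_supine``,
    ``height_arm_up`` and ``height_hand_in_lap``.
    """
    conds = [Condition(c) for c in conditions]
    postures = [c.posture for c in conds]
    heights = [c.height for c in conds]
    return pd.DataFrame(
        {
            "posture_sitting": [1.0 if p == "sitting" else 0.0 for p in postures],
            "posture_supine": [1.0 if p == "supine" else 0.0 for p in postures],
            "height_arm_up": [1.0 if h == "arm_up" else 0.0 for h in heights],
            "height_hand_in_lap": [1.0 if h == "hand_in_lap" else 0.0 for h in heights],
        },
        index=conditions.index if isinstance(conditions, pd.Series) else None,
    )
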