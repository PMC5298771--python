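"""Trial-file I/O for waist-worn inertial recordings.

A trial file holds one 200 Hz sample per line as nine comma-separated signed
ADC counts: accelerometer-1 (x, y, z), gyroscope (x, y, z), accelerometer-2
(x, y, z). Trial identity is encoded in the file name as
``ACTIVITY_SUBJECT_Rnn.txt`` (e.g. ``F05_SA03_R02.txt``). Counts convert to
physical units through the two's-complement full-scale mapping
``units = counts * (2 * range) / 2**bits``.

Only accelerometer-1 (the wide ±16 g device) feeds the analysis; the
gyroscope and the second accelerometer are parsed and preserved untouched.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import protocol

logger = logging.getLogger(__name__)

__all__ = [
    "SensorSpec",
    "TrialRecord",
    "AccelTrace",
    "Dialect",
    "DEFAULT_SENSORS",
    "raw_to_units",
    "read_trial",
    "write_trial",
    "accel_trace",
    "scan_dataset",
    "TrialFormatError",
]


class TrialFormatError(ValueError):
    """A trial file or record violates the expected dialect."""


@dataclass(frozen=True)
class SensorSpec:
    """Full-scale range and ADC resolution of one sensor.

    ``scale`` is the units-per-count factor ``(2 * range) / 2**adc_bits``,
    i.e. the LSB weight of a two's-complement reading spanning the full
    symmetric range.
    """

    name: str
    kind: str  # "accelerometer" | "gyroscope"
    range: float  # full-scale magnitude (g or deg/s)
    adc_bits: int

    def __post_init__(self) -> None:
        if self.kind not in ("accelerometer", "gyroscope"):
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        if not self.range > 0:
            raise ValueError("sensor range must be positive")
        if not 8 <= self.adc_bits <= 16:
            raise ValueError("adc_bits must be in [8, 16]")

    @property
    def scale(self) -> float:
        return 2.0 * self.range / 2**self.adc_bits

    @property
    def count_min(self) -> int:
        return -(2 ** (self.adc_bits - 1))

    @property
    def count_max(self) -> int:
        return 2 ** (self.adc_bits - 1) - 1


#: device sensors in file-column order: accelerometer-1, gyroscope, accelerometer-2
ACC1 = SensorSpec("acc1", "accelerometer", 16.0, 13)
GYRO = SensorSpec("gyro", "gyroscope", 2000.0, 16)
ACC2 = SensorSpec("acc2", "accelerometer", 8.0, 14)
DEFAULT_SENSORS: tuple[SensorSpec, SensorSpec, SensorSpec] = (ACC1, GYRO, ACC2)


@dataclass(frozen=True)
class Dialect:
    """Textual layout of a trial file."""

    delimiter: str = ","
    #: sensor name per 3-column group, in file order
    column_order: tuple[str, str, str] = ("acc1", "gyro", "acc2")
    suffix: str = ".txt"


DEFAULT_DIALECT = Dialect()

_NAME_RE = re.compile(r"^([DF]\d{2})_([A-Z]{2}\d{2})_R(\d+)$")


@dataclass
class TrialRecord:
    """One recorded trial: raw integer samples plus identity metadata."""

    subject_code: str
    activity_code: str
    trial_index: int
    channels: np.ndarray  # (n, 9) integer ADC counts
    fs: float = protocol.DEFAULT_FS
    sensors: tuple[SensorSpec, SensorSpec, SensorSpec] = DEFAULT_SENSORS

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if not np.issubdtype(self.channels.dtype, np.integer):
            raise TrialFormatError("channels must be integer ADC counts")
        if self.channels.ndim != 2 or self.channels.shape[1] != 9:
            raise TrialFormatError("channels must be an (n, 9) array")
        if self.channels.shape[0] < 1:
            raise TrialFormatError("trial must contain at least one sample")
        if self.activity_code not in protocol.ACTIVITIES:
            raise ValueError(f"unknown activity code {self.activity_code!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be positive")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def is_fall(self) -> bool:
        return protocol.is_fall(self.activity_code)

    @property
    def label(self) -> str:
        return protocol.label_of(self.activity_code)

    @property
    def trial_id(self) -> str:
        return f"{self.activity_code}_{self.subject_code}_R{self.trial_index:02d}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialRecord):
            return NotImplemented
        return (
            self.subject_code == other.subject_code
            and self.activity_code == other.activity_code
            and self.trial_index == other.trial_index
            and self.fs == other.fs
            and self.sensors == other.sensors
            and np.array_equal(self.channels, other.channels)
        )


@dataclass
class AccelTrace:
    """Three-axis acceleration in g at a fixed sampling rate.

    Axis convention (device on the waist): +z forward, +y along gravity,
    +x to the subject's right. A subject standing still reads (0, +1, 0) g.
    """

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axis sequences must have equal length")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        for arr in (self.ax, self.ay, self.az):
            if not np.all(np.isfinite(arr)):
                raise ValueError("acceleration values must be finite")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)

    def stacked(self) -> np.ndarray:
        """(n, 3) view-copy of the three axes."""
        return np.column_stack([self.ax, self.ay, self.az])

    def replace(self, **kw) -> "AccelTrace":
        return replace(self, **kw)


def raw_to_units(raw: Sequence[int] | np.ndarray, spec: SensorSpec) -> np.ndarray:
    """Convert raw ADC counts to physical units via the sensor's LSB scale."""
    arr = np.asarray(raw)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        raise TrialFormatError("raw counts must be integers")
    return arr.astype(float) * spec.scale


def parse_trial_name(name: str) -> tuple[str, str, int]:
    """Parse ``ACTIVITY_SUBJECT_Rnn`` from a file stem."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"file name {name!r} does not match ACTIVITY_SUBJECT_Rnn")
    return m.group(1), m.group(2), int(m.group(3))


def _sensor_triplet(dialect: Dialect) -> tuple[SensorSpec, SensorSpec, SensorSpec]:
    by_name = {s.name: s for s in DEFAULT_SENSORS}
    return tuple(by_name[n] for n in dialect.column_order)  # type: ignore[return-value]


def read_trial(
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    *,
    subject_code: str | None = None,
    activity_code: str | None = None,
    trial_index: int | None = None,
    fs: float = protocol.DEFAULT_FS,
) -> TrialRecord:
    """Read one trial file.

    Identity metadata is parsed from the file name unless supplied
    explicitly. Malformed data lines raise :class:`TrialFormatError` naming
    the offending line number.
    """
    path = Path(path)
    if None in (subject_code, activity_code, trial_index):
        act, subj, idx = parse_trial_name(path.stem)
        activity_code = activity_code or act
        subject_code = subject_code or subj
        trial_index = trial_index or idx

    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().rstrip(";").strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(dialect.delimiter)]
            if len(fields) != 9:
                raise TrialFormatError(
                    f"{path.name}:{lineno}: expected 9 fields, got {len(fields)}"
                )
            try:
                rows.append([int(f) for f in fields])
            except ValueError as exc:
                raise TrialFormatError(f"{path.name}:{lineno}: {exc}") from None
    if not rows:
        raise TrialFormatError(f"{path.name}: no data lines")
    return TrialRecord(
        subject_code=subject_code,
        activity_code=activity_code,
        trial_index=trial_index,
        channels=np.asarray(rows, dtype=np.int32),
        fs=fs,
        sensors=_sensor_triplet(dialect),
    )


def write_trial(
    record: TrialRecord, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> Path:
    """Write a trial in the same dialect ``read_trial`` accepts (lossless)."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in record.channels:
            fh.write(dialect.delimiter.join(str(int(v)) for v in row))
            fh.write(";\n")
    return path


def trial_filename(record: TrialRecord, dialect: Dialect = DEFAULT_DIALECT) -> str:
    return (
        f"{record.activity_code}_{record.subject_code}_R{record.trial_index:02d}"
        f"{dialect.suffix}"
    )


def accel_trace(record: TrialRecord, sensor: str = "acc1") -> AccelTrace:
    """Extract one accelerometer's three channels as an :class:`AccelTrace` in g.

    The default is accelerometer-1, the energy-efficient ±16 g device whose
    data the analysis uses exclusively.
    """
    names = [s.name for s in record.sensors]
    if sensor not in names:
        raise ValueError(f"unknown sensor {sensor!r}; available: {names}")
    group = names.index(sensor)
    spec = record.sensors[group]
    if spec.kind != "accelerometer":
        raise ValueError(f"sensor {sensor!r} is a {spec.kind}, not an accelerometer")
    cols = record.channels[:, 3 * group : 3 * group + 3]
    x, y, z = (raw_to_units(cols[:, i], spec) for i in range(3))
    return AccelTrace(fs=record.fs, ax=x, ay=y, az=z)


MANIFEST_COLUMNS = ["subject", "cohort", "activity", "label", "trial", "path", "duration_s"]


def _count_data_lines(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.strip():
                n += 1
    return n


def scan_dataset(
    root: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    fs: float = protocol.DEFAULT_FS,
) -> pd.DataFrame:
    """Build a manifest of all trial files under ``root``.

    One row per file with subject, cohort (``SA`` young / ``SE`` elderly),
    activity, fall/adl label, trial index, path, and duration in seconds.
    Duplicate (subject, activity, trial) triples raise an error naming both
    paths.
    """
    root = Path(root)
    rows = []
    seen: dict[tuple[str, str, int], Path] = {}
    for path in sorted(root.rglob(f"*{dialect.suffix}")):
        try:
            activity, subject, trial = parse_trial_name(path.stem)
        except ValueError:
            logger.warning("skipping non-trial file %s", path)
            continue
        key = (subject, activity, trial)
        if key in seen:
            raise ValueError(f"duplicate trial {key}: {seen[key]} and {path}")
        seen[key] = path
        cohort = protocol.PREFIX_COHORT.get(subject[:2], "unknown")
        rows.append(
            {
                "subject": subject,
                "cohort": cohort,
                "activity": activity,
                "label": protocol.label_of(activity),
                "trial": trial,
                "path": str(path),
                "duration_s": _count_data_lines(path) / fs,
            }
        )
    if not rows:
        logger.warning("no trial files found under %s", root)
        return pd.DataFrame(columns=MANIFEST_COLUMNS)
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
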