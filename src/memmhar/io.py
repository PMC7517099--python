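"""Reading and writing inertial recordings and derived artifacts.

On-disk layout for a recording: one CSV file per recording, a leading
metadata comment line ``# sampling_rate_hz=<value>`` followed by a header
``subject,label,<channel...>`` and one row per time step.  Numeric cells
are written with 17 significant digits so float round-trips are exact.
A dataset is a directory of such files plus a JSON manifest listing
``{"path", "subject_id", "activity"}`` per recording.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError, SchemaError

#: Default channel schema: tri-axial accelerometer + tri-axial gyroscope.
DEFAULT_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

_META_RE = re.compile(r"#\s*sampling_rate_hz\s*=\s*([0-9eE+\-.]+)")


@dataclass
class InertialRecording:
    """One subject's multi-channel inertial time series.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject who produced the recording.
    sampling_rate_hz : float
        Sampling rate of every channel, in Hz. Must be positive.
    channels : list of str
        Ordered channel names, one per sample column.
    samples : ndarray of shape (n_samples, n_channels)
        Raw sensor values, one row per time step.
    labels : ndarray of str, shape (n_samples,)
        Per-sample activity labels. A scalar or length-1 sequence is
        broadcast to all time steps.
    """

    subject_id: str
    sampling_rate_hz: float
    channels: list[str]
    samples: np.ndarray
    labels: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise SchemaError("samples must be a 2-D (time x channel) matrix")
        self.channels = list(self.channels)
        if len(self.channels) == 0:
            raise SchemaError("a recording needs at least one channel")
        if self.samples.shape[1] != len(self.channels):
            raise SchemaError(
                f"samples have {self.samples.shape[1]} columns but "
                f"{len(self.channels)} channel names were given"
            )
        if not self.sampling_rate_hz > 0:
            raise SchemaError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ParseError("samples contain NaN or infinite values")
        labels = self.labels
        if labels is None:
            raise SchemaError("labels are required")
        labels = np.atleast_1d(np.asarray(labels, dtype=str))
        if labels.size == 1 and self.n_samples != 1:
            labels = np.repeat(labels, self.n_samples)
        if labels.size != self.n_samples:
            raise SchemaError(
                f"{labels.size} labels for {self.n_samples} sample rows"
            )
        self.labels = labels

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def read_recording_csv(path, schema=None, sampling_rate_hz=None) -> InertialRecording:
    """Read one recording from the documented CSV layout.

    ``schema`` lists the channel columns that must be present (defaults to
    the six accelerometer/gyroscope channels).  The sampling rate is taken
    from the ``# sampling_rate_hz=`` metadata line, or from the
    ``sampling_rate_hz`` argument when the file has no metadata line.
    """
    path = Path(path)
    schema = list(schema) if schema is not None else list(DEFAULT_CHANNELS)
    with open(path, "r") as fh:
        first = fh.readline()
    skiprows = 0
    if first.startswith("#"):
        skiprows = 1
        m = _META_RE.match(first)
        if m:
            sampling_rate_hz = float(m.group(1))
    if sampling_rate_hz is None:
        raise SchemaError(
            f"{path}: no '# sampling_rate_hz=' metadata line and no "
            "sampling_rate_hz argument given"
        )
    try:
        df = pd.read_csv(path, skiprows=skiprows, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file has no data") from exc
    for col in ["subject", "label", *schema]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: header present but no data rows")
    subjects = df["subject"].unique()
    if len(subjects) != 1:
        raise SchemaError(f"{path}: mixed subject ids {sorted(subjects)}")
    values = np.empty((len(df), len(schema)), dtype=float)
    for j, col in enumerate(schema):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"'{col}' at data row {row + 1}"
            )
        if converted.isna().any():
            raise ParseError(f"{path}: missing value in column '{col}'")
        # numpy's string parser is correctly rounded; pandas' fast parser
        # can be one ulp off, which would break exact round-trips
        values[:, j] = df[col].to_numpy(dtype=float)
    return InertialRecording(
        subject_id=str(subjects[0]),
        sampling_rate_hz=float(sampling_rate_hz),
        channels=schema,
        samples=values,
        labels=df["label"].to_numpy(dtype=str),
    )


def write_recording_csv(recording: InertialRecording, path) -> Path:
    """Write a recording; inverse of :func:`read_recording_csv`."""
    path = Path(path)
    df = pd.DataFrame(recording.samples, columns=recording.channels)
    df.insert(0, "label", recording.labels)
    df.insert(0, "subject", recording.subject_id)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={recording.sampling_rate_hz!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def write_manifest(entries: list[dict], path) -> Path:
    """Write a dataset manifest (list of recording descriptors) as JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"recordings": entries}, fh, indent=2)
        fh.write("\n")
    return path


def read_manifest(path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    return doc["recordings"]


def write_dataset(recordings, out_dir) -> Path:
    """Write each recording as CSV under ``out_dir`` plus a manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        activity = str(rec.labels[0])
        name = f"{rec.subject_id}_{activity}.csv"
        write_recording_csv(rec, out_dir / name)
        entries.append(
            {"path": name, "subject_id": rec.subject_id, "activity": activity}
        )
    return write_manifest(entries, out_dir / "manifest.json")


def read_dataset(manifest_path, schema=None) -> list[InertialRecording]:
    """Read every recording listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    return [
        read_recording_csv(base / entry["path"], schema=schema)
        for entry in read_manifest(manifest_path)
    ]


def write_features_csv(path, features, layout, labels, subject_id) -> Path:
    """Write a per-window feature matrix with its named slot layout.

    The layout (``feature, channel, length`` triples) is stored in a
    metadata comment line so the file is self-describing.
    """
    path = Path(path)
    features = np.asarray(features, dtype=float)
    layout_str = ";".join(f"{name}:{chan}:{length}" for name, chan, length in layout)
    cols = [f"f{i}" for i in range(features.shape[1])]
    df = pd.DataFrame(features, columns=cols)
    df.insert(0, "label", list(labels))
    df.insert(0, "subject", subject_id)
    with open(path, "w") as fh:
        fh.write(f"# layout={layout_str}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_features_csv(path):
    """Read a feature matrix written by :func:`write_features_csv`.

    Returns ``(features, layout, labels, subject_id)``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# layout="):
        raise SchemaError(f"{path}: missing '# layout=' metadata line")
    layout = []
    spec = first[len("# layout="):].strip()
    if spec:
        for part in spec.split(";"):
            name, chan, length = part.split(":")
            layout.append((name, chan, int(length)))
    df = pd.read_csv(path, skiprows=1, float_precision="round_trip")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no feature rows")
    subjects = df["subject"].unique()
    if len(subjects) != 1:
        raise SchemaError(f"{path}: mixed subject ids")
    labels = df["label"].to_numpy(dtype=str)
    features = df.drop(columns=["subject", "label"]).to_numpy(dtype=float)
    return features, layout, labels, str(subjects[0])
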