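"""Readers and writers for the raw-signal and feature-table formats.

Three kinds of artefacts move through the pipeline:

* plain-text 3-axis accelerometer recordings (one ``x y z`` sample per line,
  m/s^2, nominally 100 Hz),
* PCM WAV sustained-vowel phonations (nominally 44.1 kHz),
* CSV feature tables in the classic dysphonia layout — a ``name`` column,
  the 22 canonical voice-feature columns and a binary ``status`` column
  (1 = Parkinson's, 0 = healthy), optionally extended with ``gender`` and
  ``updrs`` sidecar columns.

All indices are 0-based; time of sample ``i`` is ``i / fs``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import EmptyInputError, FormatError, ParameterError, SchemaError

#: Canonical order of the 22 dysphonia features. The names match the classic
#: public dysphonia table; readers reorder any permutation of these columns
#: into this order.
VOICE_FEATURE_NAMES: tuple[str, ...] = (
    "MDVP:Fo(Hz)",
    "MDVP:Fhi(Hz)",
    "MDVP:Flo(Hz)",
    "MDVP:Jitter(%)",
    "MDVP:Jitter(Abs)",
    "MDVP:RAP",
    "MDVP:PPQ",
    "Jitter:DDP",
    "MDVP:Shimmer",
    "MDVP:Shimmer(dB)",
    "Shimmer:APQ3",
    "Shimmer:APQ5",
    "MDVP:APQ",
    "Shimmer:DDA",
    "NHR",
    "HNR",
    "RPDE",
    "D2",
    "DFA",
    "spread1",
    "spread2",
    "PPE",
)

_STATUS_PD = "PD"
_STATUS_HEALTHY = "healthy"


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} contains non-finite values")


@dataclass
class AccelRecording:
    """Time-ordered 3-axis acceleration samples with a sampling rate.

    Channels are in m/s^2 and must have identical length; ``fs`` is in Hz.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float = 100.0
    subject_id: str = ""
    hand: str = "unknown"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.x)
        if n < 1 or len(self.y) != n or len(self.z) != n:
            raise ParameterError("x, y, z must have identical length >= 1")
        if self.hand not in ("left", "right", "unknown"):
            raise ParameterError(f"hand must be left/right/unknown, got {self.hand!r}")
        for name, ch in (("x", self.x), ("y", self.y), ("z", self.z)):
            _check_finite(name, ch)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        return len(self.x) / self.fs

    @property
    def channels(self) -> np.ndarray:
        """(3, n) array stacked in x, y, z order."""
        return np.vstack([self.x, self.y, self.z])

    def replace_channels(self, channels: np.ndarray) -> "AccelRecording":
        return AccelRecording(
            channels[0], channels[1], channels[2],
            fs=self.fs, subject_id=self.subject_id, hand=self.hand,
        )


@dataclass
class VoiceRecording:
    """Mono waveform (dimensionless amplitude) with a sampling rate in Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise ParameterError("samples must be a non-empty 1-D array")
        _check_finite("samples", self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class LabeledFeatureTable:
    """Rows of named feature values plus status / gender / UPDRS metadata.

    ``features`` is a DataFrame indexed by sample id whose columns are the
    (ordered) feature names. ``status`` holds "PD"/"healthy" strings aligned
    with the rows; ``gender`` holds "male"/"female"/"unknown"; ``updrs`` is
    an optional integer severity 0-4 (NaN when absent).
    """

    features: pd.DataFrame
    status: pd.Series
    gender: pd.Series = field(default=None)  # type: ignore[assignment]
    updrs: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.features)
        if self.gender is None:
            self.gender = pd.Series(["unknown"] * n, index=self.features.index)
        if self.updrs is None:
            self.updrs = pd.Series([np.nan] * n, index=self.features.index)
        if len(self.status) != n:
            raise SchemaError("status length does not match feature rows")
        bad = set(self.status.unique()) - {_STATUS_PD, _STATUS_HEALTHY}
        if bad:
            raise SchemaError(f"unknown status values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, mask: np.ndarray) -> "LabeledFeatureTable":
        return LabeledFeatureTable(
            self.features[mask], self.status[mask],
            self.gender[mask], self.updrs[mask],
        )


# ---------------------------------------------------------------------------
# plain-text accelerometer files
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_accel_txt(path: str | Path, fs: float = 100.0, *,
                   subject_id: str = "", hand: str = "unknown") -> AccelRecording:
    """Read a 3-column plain-text accelerometer file.

    Lines are whitespace- or comma-delimited ``x y z`` samples; lines whose
    first token is not numeric (headers, ``#`` comments) are skipped. A line
    that parses numerically but does not yield exactly 3 columns raises
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    cols: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in re.split(r"[,\s]+", line) if t]
            if not _NUM_RE.match(tokens[0]):
                continue  # header line
            if len(tokens) != 3 or not all(_NUM_RE.match(t) for t in tokens):
                raise FormatError(
                    f"{path.name}:{lineno}: expected 3 numeric columns, got {line!r}"
                )
            cols.append((float(tokens[0]), float(tokens[1]), float(tokens[2])))
    if not cols:
        raise EmptyInputError(f"{path}: no data lines found")
    arr = np.asarray(cols, dtype=float)
    return AccelRecording(arr[:, 0], arr[:, 1], arr[:, 2], fs=fs,
                          subject_id=subject_id, hand=hand)


def write_accel_txt(path: str | Path, rec: AccelRecording, *,
                    header: str | None = None) -> None:
    """Write a recording in the 3-column text dialect read_accel_txt expects."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for xi, yi, zi in zip(rec.x, rec.y, rec.z):
            fh.write(f"{xi:.10e} {yi:.10e} {zi:.10e}\n")


# ---------------------------------------------------------------------------
# WAV phonations
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> VoiceRecording:
    """Read a PCM WAV file; multi-channel audio is averaged down to mono."""
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        data = (data.astype(float) - 128.0) / 128.0
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return VoiceRecording(data, float(fs))


def write_wav(path: str | Path, rec: VoiceRecording) -> None:
    """Write 16-bit PCM; samples are clipped to [-1, 1] before quantization."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(rec.fs), pcm)


# ---------------------------------------------------------------------------
# feature-table CSV
# ---------------------------------------------------------------------------

def read_voice_feature_csv(path: str | Path) -> LabeledFeatureTable:
    """Read a dysphonia feature CSV in the 22-feature layout.

    Requires a ``name`` column, exactly the 22 canonical feature columns (in
    any order) and a ``status`` column in {0, 1}; optional ``gender`` and
    ``updrs`` columns are carried through. Column sets that differ from the
    canonical 22 raise :class:`SchemaError` listing the difference.
    """
    df = pd.read_csv(path, comment="#")
    required = {"name", "status"}
    missing_meta = required - set(df.columns)
    if missing_meta:
        raise SchemaError(f"missing required columns: {sorted(missing_meta)}")
    optional = {"gender", "updrs"}
    present = [c for c in df.columns if c not in required | optional]
    missing = sorted(set(VOICE_FEATURE_NAMES) - set(present))
    extra = sorted(set(present) - set(VOICE_FEATURE_NAMES))
    if missing or extra:
        raise SchemaError(
            f"feature columns differ from the canonical 22: "
            f"missing={missing} extra={extra}"
        )
    feats = df[list(VOICE_FEATURE_NAMES)].astype(float)
    feats.index = df["name"].astype(str)
    status = pd.Series(
        np.where(df["status"].astype(int).to_numpy() == 1, _STATUS_PD, _STATUS_HEALTHY),
        index=feats.index,
    )
    gender = (df["gender"].astype(str).reindex(df.index).set_axis(feats.index)
              if "gender" in df.columns else None)
    updrs = (df["updrs"].astype(float).set_axis(feats.index)
             if "updrs" in df.columns else None)
    return LabeledFeatureTable(feats, status, gender, updrs)


def write_feature_csv(path: str | Path, table: LabeledFeatureTable, *,
                      header: str | None = None) -> None:
    """Write a labelled table back to the CSV layout read_voice_feature_csv reads."""
    df = table.features.copy()
    df.insert(0, "name", table.features.index)
    df["status"] = (table.status == _STATUS_PD).astype(int).to_numpy()
    df["gender"] = table.gender.to_numpy()
    df["updrs"] = table.updrs.to_numpy()
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_feature_csv(path: str | Path) -> LabeledFeatureTable:
    """Read a labelled feature CSV with arbitrary feature columns.

    Same layout as :func:`read_voice_feature_csv` but without enforcing the
    22-name schema — used for tremor feature tables.
    """
    df = pd.read_csv(path, comment="#")
    if "name" not in df.columns or "status" not in df.columns:
        raise SchemaError("feature CSV needs 'name' and 'status' columns")
    meta = {"name", "status", "gender", "updrs"}
    feat_cols = [c for c in df.columns if c not in meta]
    if not feat_cols:
        raise SchemaError("feature CSV holds no feature columns")
    feats = df[feat_cols].astype(float)
    feats.index = df["name"].astype(str)
    status_raw = df["status"]
    if status_raw.dtype.kind in "if":
        status = pd.Series(
            np.where(status_raw.astype(int) == 1, _STATUS_PD, _STATUS_HEALTHY),
            index=feats.index)
    else:
        status = status_raw.astype(str).set_axis(feats.index)
    gender = (df["gender"].astype(str).set_axis(feats.index)
              if "gender" in df.columns else None)
    updrs = (df["updrs"].astype(float).set_axis(feats.index)
             if "updrs" in df.columns else None)
    return LabeledFeatureTable(feats, status, gender, updrs)
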