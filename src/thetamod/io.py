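"""Readers and writers for every on-disk format the pipeline touches.

Signals travel as EDF (16-bit integer samples with per-channel physical
scaling, the de-facto interchange format for clinical EEG); a delimited
matrix + JSON sidecar fallback is supported for hand-built fixtures.
Annotations are plain TSV/CSV and a small YAML montage document.

Conventions, fixed package-wide:

* time is in seconds, 0-based, and every interval is half-open
  ``[onset, onset + duration)`` — this makes 1-s epoching unambiguous;
* all readers validate and raise rather than silently coercing, naming
  the offending field or rows in the exception message.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("thetamod")

__all__ = [
    "FormatError",
    "Recording",
    "Montage",
    "read_recording",
    "write_recording",
    "read_edf",
    "write_edf",
    "read_events",
    "write_events",
    "read_attention",
    "write_attention",
    "normalize_intervals",
    "read_montage",
    "write_montage",
    "read_phenotypes",
    "write_phenotypes",
]


class FormatError(ValueError):
    """A file failed validation; the message names the field/rows at fault."""


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG for one subject.

    ``data`` is channels x samples in microvolts. Channel labels must be
    unique; all channels share one sampling rate and length.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("Recording.data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise FormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError(
                f"channel_labels has {len(self.channel_labels)} entries for "
                f"{self.data.shape[0]} signal rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            dupes = sorted({c for c in self.channel_labels if self.channel_labels.count(c) > 1})
            raise FormatError(f"duplicate channel labels: {dupes}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# EDF (16-bit)
# ---------------------------------------------------------------------------

_EDF_HEADER_FIXED = 256
_EDF_HEADER_PER_SIGNAL = 256


def _pad(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii", errors="replace")
    return b + b" " * (width - len(b))


def _fmt_float(x: float, width: int = 8) -> str:
    """Format a physical min/max into EDF's fixed-width ASCII field."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % x
        if len(s) <= width:
            return s
    return ("%.1g" % x)[:width]


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as EDF with 1-s data records and int16 samples.

    The sampling rate must be an integer and the recording is truncated to
    a whole number of seconds (EDF records are fixed-duration). Physical
    min/max are taken per channel from the data, so quantization error is
    at most one step of (phys range)/65535.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise FormatError("recording shorter than one EDF record (1 s)")
    nchan = rec.n_channels
    data = rec.data[:, : n_records * fs]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    offset = pmin - dmin * scale
    digital = np.round((data - offset[:, None]) / scale[:, None])
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header_bytes = _EDF_HEADER_FIXED + _EDF_HEADER_PER_SIGNAL * nchan
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(rec.subject_id, 80))
        fh.write(_pad("thetamod synthetic EEG", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(nchan), 4))
        for lab in rec.channel_labels:
            fh.write(_pad(lab, 16))
        for _ in range(nchan):
            fh.write(_pad("synthetic", 80))
        for _ in range(nchan):
            fh.write(_pad("uV", 8))
        for v in pmin:
            fh.write(_pad(_fmt_float(v), 8))
        for v in pmax:
            fh.write(_pad(_fmt_float(v), 8))
        for _ in range(nchan):
            fh.write(_pad(str(dmin), 8))
        for _ in range(nchan):
            fh.write(_pad(str(dmax), 8))
        for _ in range(nchan):
            fh.write(_pad("", 80))
        for _ in range(nchan):
            fh.write(_pad(str(fs), 8))
        for _ in range(nchan):
            fh.write(_pad("", 32))
        # data records: record-major, signal-major within record
        rec_view = digital.reshape(nchan, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec_view).tobytes())
    logger.info("wrote EDF %s (%d ch, %d s @ %d Hz)", path, nchan, n_records, fs)


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (microvolts).

    Rejects empty/truncated files, non-uniform per-signal sampling rates,
    and duplicate channel labels.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _EDF_HEADER_FIXED:
        raise FormatError(f"{path}: file too short for an EDF header ({len(raw)} bytes)")

    def f(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    subject_id = f(8, 88) or "unknown"
    try:
        header_bytes = int(f(184, 192))
        n_records = int(f(236, 244))
        record_dur = float(f(244, 252))
        nchan = int(f(252, 256))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header numeric field ({exc})") from exc
    if nchan <= 0 or n_records <= 0 or record_dur <= 0:
        raise FormatError(f"{path}: non-positive n_signals/n_records/record duration")
    need = _EDF_HEADER_FIXED + _EDF_HEADER_PER_SIGNAL * nchan
    if header_bytes != need or len(raw) < need:
        raise FormatError(f"{path}: header size field {header_bytes} != expected {need}")

    def sig_field(offset: int, width: int, i: int, base: int) -> str:
        lo = base + i * width
        return raw[lo + offset : lo + offset + width].decode("ascii", errors="replace").strip()

    base = _EDF_HEADER_FIXED
    labels = [sig_field(0, 16, i, base) for i in range(nchan)]
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise FormatError(f"{path}: duplicate channel labels {dupes}")
    base += 16 * nchan + 80 * nchan + 8 * nchan  # skip transducer, phys dim
    pmin = np.array([float(sig_field(0, 8, i, base)) for i in range(nchan)])
    base += 8 * nchan
    pmax = np.array([float(sig_field(0, 8, i, base)) for i in range(nchan)])
    base += 8 * nchan
    dmin = np.array([float(sig_field(0, 8, i, base)) for i in range(nchan)])
    base += 8 * nchan
    dmax = np.array([float(sig_field(0, 8, i, base)) for i in range(nchan)])
    base += 8 * nchan + 80 * nchan
    spr = [int(sig_field(0, 8, i, base)) for i in range(nchan)]
    if len(set(spr)) != 1:
        raise FormatError(f"{path}: signals have differing samples-per-record {sorted(set(spr))}")
    fs = spr[0] / record_dur

    body = raw[need:]
    rec_len = sum(spr)
    expect = n_records * rec_len * 2
    if len(body) < expect:
        raise FormatError(
            f"{path}: data section has {len(body)} bytes, header promises {expect}"
        )
    digital = np.frombuffer(body[:expect], dtype="<i2").reshape(n_records, nchan, spr[0])
    digital = digital.transpose(1, 0, 2).reshape(nchan, n_records * spr[0]).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    offset = pmin - dmin * scale
    data = digital * scale[:, None] + offset[:, None]
    return Recording(data=data, sampling_rate=fs, channel_labels=labels, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Matrix + sidecar fallback
# ---------------------------------------------------------------------------

def _write_matrix(rec: Recording, path: Path) -> None:
    np.savetxt(path, rec.data.T, fmt="%.4f", delimiter="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "sampling_rate": rec.sampling_rate,
                "channel_labels": rec.channel_labels,
                "subject_id": rec.subject_id,
            }
        )
    )


def _read_matrix(path: Path) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: sidecar header {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    for key in ("sampling_rate", "channel_labels"):
        if key not in meta:
            raise FormatError(f"{sidecar}: missing required field '{key}'")
    data = np.loadtxt(path, delimiter="\t", ndmin=2).T
    return Recording(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=list(meta["channel_labels"]),
        subject_id=str(meta.get("subject_id", "unknown")),
    )


def read_recording(path: str | Path) -> Recording:
    """Read a Recording from EDF (``.edf``) or TSV matrix + JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    return _read_matrix(path)


def write_recording(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(rec, path)
    else:
        _write_matrix(rec, path)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

_EVENT_COLS = ["onset_s", "duration_s", "video_id", "condition", "repetition"]
CONDITIONS = ("social", "nonsocial")


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"events table missing columns {missing}")
    df = df[_EVENT_COLS].copy()
    df["onset_s"] = df["onset_s"].astype(float)
    df["duration_s"] = df["duration_s"].astype(float)
    df["repetition"] = df["repetition"].astype(int)
    if (df["onset_s"] < 0).any():
        bad = df.index[df["onset_s"] < 0].tolist()
        raise FormatError(f"events rows {bad}: negative onset")
    if (df["duration_s"] <= 0).any():
        bad = df.index[df["duration_s"] <= 0].tolist()
        raise FormatError(f"events rows {bad}: non-positive duration")
    unknown = set(df["condition"]) - set(CONDITIONS)
    if unknown:
        raise FormatError(f"events: unknown condition values {sorted(unknown)}")
    keys = list(zip(df["video_id"], df["repetition"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise FormatError(f"events: duplicate (video_id, repetition) {dupes}")
    srt = df.sort_values("onset_s").reset_index()
    ends = srt["onset_s"] + srt["duration_s"]
    for i in range(1, len(srt)):
        if srt.loc[i, "onset_s"] < ends[i - 1] - 1e-9:
            a, b = srt.loc[i - 1, "index"], srt.loc[i, "index"]
            raise FormatError(
                f"events rows {a} and {b} overlap: "
                f"[{srt.loc[i-1,'onset_s']}, {ends[i-1]}) vs onset {srt.loc[i,'onset_s']}"
            )
    return df.reset_index(drop=True)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_events(df)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    validate_events(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Attention mask
# ---------------------------------------------------------------------------

def normalize_intervals(intervals: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Sort and merge overlapping/adjacent [onset, onset+duration) intervals.

    Returns an (n, 2) array of (onset, end). [0, 5) and [4, 8) merge to [0, 8).
    """
    if isinstance(intervals, pd.DataFrame):
        arr = np.column_stack(
            [intervals["onset_s"].to_numpy(float),
             intervals["onset_s"].to_numpy(float) + intervals["duration_s"].to_numpy(float)]
        )
    else:
        arr = np.asarray(intervals, dtype=float)
        if arr.size and arr.ndim == 2 and arr.shape[1] == 2:
            arr = np.column_stack([arr[:, 0], arr[:, 0] + arr[:, 1]])
    if arr.size == 0:
        return np.empty((0, 2))
    if (arr[:, 1] <= arr[:, 0]).any():
        raise FormatError("attention intervals must have positive duration")
    if (arr[:, 0] < 0).any():
        raise FormatError("attention intervals must have non-negative onset")
    arr = arr[np.argsort(arr[:, 0])]
    merged = [arr[0].copy()]
    for on, end in arr[1:]:
        if on <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append(np.array([on, end]))
    return np.array(merged)


def read_attention(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "duration_s"):
        if col not in df.columns:
            raise FormatError(f"attention table missing column '{col}'")
    return normalize_intervals(df)


def write_attention(intervals: np.ndarray, path: str | Path) -> None:
    arr = normalize_intervals(np.column_stack([intervals[:, 0], intervals[:, 1] - intervals[:, 0]])
                              if intervals.size else intervals)
    pd.DataFrame(
        {"onset_s": arr[:, 0], "duration_s": arr[:, 1] - arr[:, 0]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

REGIONS = ("frontal_left", "frontal_right", "posterior")


@dataclass
class Montage:
    """Named channel groups and a symmetric neighbor relation.

    Regions are the analysis groups (frontal left/right for the biomarker,
    posterior for the spatial-specificity control); channels outside any
    region still participate in referencing and interpolation.
    """

    regions: dict[str, list[str]]
    neighbors: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for reg, chans in self.regions.items():
            for ch in chans:
                if ch in seen:
                    raise FormatError(
                        f"montage: channel '{ch}' in both '{seen[ch]}' and '{reg}'"
                    )
                seen[ch] = reg
        for ch, nbrs in self.neighbors.items():
            for nb in nbrs:
                if nb == ch:
                    raise FormatError(f"montage: channel '{ch}' lists itself as neighbor")
                if ch not in self.neighbors.get(nb, []):
                    raise FormatError(
                        f"montage: neighbor relation not symmetric ({ch} -> {nb})"
                    )

    def validate_against(self, channel_labels: list[str]) -> None:
        known = set(channel_labels)
        for reg, chans in self.regions.items():
            unknown = [c for c in chans if c not in known]
            if unknown:
                raise FormatError(f"montage region '{reg}': unknown channels {unknown}")
        unknown = [c for c in self.neighbors if c not in known]
        if unknown:
            raise FormatError(f"montage neighbors: unknown channels {unknown}")


def read_montage(path: str | Path) -> Montage:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "regions" not in doc:
        raise FormatError(f"{path}: montage file must contain a 'regions' mapping")
    return Montage(regions={k: list(v) for k, v in doc["regions"].items()},
                   neighbors={k: list(v) for k, v in doc.get("neighbors", {}).items()})


def write_montage(montage: Montage, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"regions": montage.regions, "neighbors": montage.neighbors},
                       sort_keys=True)
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

T_SCORE_BOUNDS = (20.0, 80.0)
IQ_BOUNDS = (40.0, 160.0)


def read_phenotypes(path: str | Path,
                    t_bounds: tuple[float, float] = T_SCORE_BOUNDS,
                    iq_bounds: tuple[float, float] = IQ_BOUNDS) -> pd.DataFrame:
    """Read the per-subject phenotype CSV.

    Required columns: subject_id, group. Score columns are any of the
    ``*_t_*`` t-score columns and ``iq_7y``; missing values are allowed,
    out-of-range values are not.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise FormatError(f"phenotype table missing column '{col}'")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"phenotype table: duplicated subject_id {dupes}")
    for col in df.columns:
        if col in ("subject_id", "group"):
            continue
        lo, hi = iq_bounds if col.startswith("iq") else t_bounds
        vals = df[col].dropna()
        bad = vals[(vals < lo) | (vals > hi)]
        if len(bad):
            raise FormatError(
                f"phenotype column '{col}': values outside [{lo}, {hi}] at rows "
                f"{bad.index.tolist()}"
            )
    return df.set_index("subject_id", drop=False)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
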