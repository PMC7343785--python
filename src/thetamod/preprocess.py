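"""Continuous EEG -> clean, attention-gated 1-s epochs.

The stage order is fixed and logged: segment -> gate_attention ->
detect_artifacts -> interpolate_bad -> rereference_average -> qc_counts.
Detection precedes interpolation, so a repaired channel no longer blocks
an epoch from counting as clean.

The acquisition band-pass (0.1-100 Hz) is treated as a property of the
recording hardware and is not re-applied here; `highpass` offers an
optional first-difference-free Butterworth high-pass for matrix-fallback
inputs that were never hardware-filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import FormatError, Montage, Recording

logger = logging.getLogger("thetamod")

__all__ = [
    "ArtifactParams",
    "EpochSet",
    "segment",
    "gate_attention",
    "detect_artifacts",
    "interpolate_bad",
    "rereference_average",
    "qc_counts",
    "run_preprocess",
    "highpass",
]


@dataclass(frozen=True)
class ArtifactParams:
    """Thresholds for the per-epoch, per-channel artifact rules.

    amp_threshold      absolute amplitude bound, uV
    gradient_threshold max sample-to-sample step, uV
    flat_threshold     minimum peak-to-peak range, uV (flatline rule)
    bad_channel_fraction  a channel bad in more than this fraction of
                          epochs is declared globally bad
    min_epochs_per_half   clean+attended epochs required per half for a
                          (video, presentation) to enter analysis
    """

    amp_threshold: float = 200.0
    gradient_threshold: float = 100.0
    flat_threshold: float = 0.5
    bad_channel_fraction: float = 0.3
    min_epochs_per_half: int = 5

    def __post_init__(self) -> None:
        if min(self.amp_threshold, self.gradient_threshold, self.flat_threshold) <= 0:
            raise ValueError("artifact thresholds must be > 0")
        if not 0 < self.bad_channel_fraction < 1:
            raise ValueError("bad_channel_fraction must be in (0, 1)")
        if self.min_epochs_per_half < 1:
            raise ValueError("min_epochs_per_half must be >= 1")


@dataclass
class EpochSet:
    """1-s epochs with their annotation state.

    data    epochs x channels x samples (uV)
    info    one row per epoch: video_id, condition, repetition, half,
            onset_s, attended, clean
    bad     epochs x channels boolean, artifact flags from detection
    unrepaired  like ``bad`` but only the channels interpolation could
            not fix (all-bad neighborhoods); equals ``bad`` before
            interpolation has run
    """

    data: np.ndarray
    info: pd.DataFrame
    bad: np.ndarray
    unrepaired: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    subject_id: str = "unknown"

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            info=self.info.copy(),
            bad=self.bad.copy(),
            unrepaired=self.unrepaired.copy(),
            channel_labels=list(self.channel_labels),
            sampling_rate=self.sampling_rate,
            subject_id=self.subject_id,
        )


def segment(rec: Recording, events: pd.DataFrame) -> EpochSet:
    """Cut consecutive, non-overlapping 1-s epochs out of each video.

    Epochs start at the video onset; a trailing partial second is dropped.
    ``half`` is 1 when the epoch onset (relative to the video) precedes
    the video midpoint, else 2 — for a 59.5-s video the midpoint is
    29.75 s, giving 30 half-1 and 29 half-2 epochs.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("segmentation requires an integer sampling rate")
    fs = int(round(fs))
    rows, chunks = [], []
    for _, ev in events.iterrows():
        n_ep = int(np.floor(ev.duration_s + 1e-9))
        end_sample = int(round(ev.onset_s * fs)) + n_ep * fs
        if end_sample > rec.n_samples:
            raise FormatError(
                f"video '{ev.video_id}' rep {ev.repetition} extends past the end of "
                f"the recording ({end_sample / fs:.1f} s > {rec.duration:.1f} s)"
            )
        mid = ev.duration_s / 2.0
        start = int(round(ev.onset_s * fs))
        for i in range(n_ep):
            chunks.append(rec.data[:, start + i * fs : start + (i + 1) * fs])
            rows.append(
                {
                    "video_id": ev.video_id,
                    "condition": ev.condition,
                    "repetition": int(ev.repetition),
                    "half": 1 if i < mid - 1e-9 else 2,
                    "onset_s": ev.onset_s + i,
                    "attended": False,
                    "clean": True,
                }
            )
    if not rows:
        raise FormatError("events table produced no epochs")
    data = np.stack(chunks)
    info = pd.DataFrame(rows)
    n, c = data.shape[0], data.shape[1]
    logger.info("segmented %d epochs of 1 s from %d events", n, len(events))
    return EpochSet(
        data=data,
        info=info,
        bad=np.zeros((n, c), dtype=bool),
        unrepaired=np.zeros((n, c), dtype=bool),
        channel_labels=list(rec.channel_labels),
        sampling_rate=float(fs),
        subject_id=rec.subject_id,
    )


def gate_attention(epochs: EpochSet, mask: np.ndarray) -> EpochSet:
    """Flag an epoch attended iff it lies fully inside an attention interval.

    ``mask`` is the normalized (n, 2) array of (onset, end) produced by
    io.normalize_intervals. Full containment is the strict reading of
    attention gating; partial looks do not count.
    """
    out = epochs.copy()
    on = out.info["onset_s"].to_numpy(float)
    attended = np.zeros(len(on), dtype=bool)
    for lo, hi in np.asarray(mask).reshape(-1, 2):
        attended |= (on >= lo - 1e-9) & (on + 1.0 <= hi + 1e-9)
    out.info["attended"] = attended
    logger.info("attention gate: %d/%d epochs attended", attended.sum(), len(on))
    return out


def detect_artifacts(epochs: EpochSet, params: ArtifactParams) -> EpochSet:
    """Per epoch x channel artifact flags.

    A channel is bad within an epoch when |amplitude| exceeds
    amp_threshold, any sample-to-sample step exceeds gradient_threshold,
    or its peak-to-peak range falls below flat_threshold. A channel bad
    in more than bad_channel_fraction of epochs is globally bad. The
    amplitude and gradient rules are even in the signal, so flags are
    invariant under sign flip.
    """
    out = epochs.copy()
    d = out.data
    amp = np.abs(d).max(axis=2) > params.amp_threshold
    grad = np.abs(np.diff(d, axis=2)).max(axis=2) > params.gradient_threshold
    flat = d.max(axis=2) - d.min(axis=2) < params.flat_threshold
    bad = amp | grad | flat
    global_bad = bad.mean(axis=0) > params.bad_channel_fraction
    bad[:, global_bad] = True
    out.bad = bad
    out.unrepaired = bad.copy()
    out.info["clean"] = ~bad.any(axis=1)
    logger.info(
        "artifact detection: %d/%d epochs clean, %d globally bad channels",
        int(out.info["clean"].sum()), out.n_epochs, int(global_bad.sum()),
    )
    return out


def interpolate_bad(epochs: EpochSet, montage: Montage) -> EpochSet:
    """Replace each bad channel, per epoch, by the mean of its good neighbors.

    Neighbor values are taken from the pre-interpolation signal. A bad
    channel with no good neighbor stays unrepaired and keeps its epoch
    unclean.
    """
    missing = [c for c in epochs.channel_labels if c not in montage.neighbors]
    if missing:
        raise FormatError(f"montage neighbor map missing channels {missing}")
    out = epochs.copy()
    idx = {c: i for i, c in enumerate(out.channel_labels)}
    nbr_idx = [
        np.array([idx[n] for n in montage.neighbors[c] if n in idx], dtype=int)
        for c in out.channel_labels
    ]
    unrepaired = out.bad.copy()
    for e in np.nonzero(out.bad.any(axis=1))[0]:
        original = out.data[e].copy()
        for ch in np.nonzero(out.bad[e])[0]:
            good = nbr_idx[ch][~out.bad[e][nbr_idx[ch]]]
            if good.size == 0:
                continue
            out.data[e, ch] = original[good].mean(axis=0)
            unrepaired[e, ch] = False
    out.unrepaired = unrepaired
    out.info["clean"] = ~unrepaired.any(axis=1)
    logger.info("interpolation: %d/%d epochs clean", int(out.info["clean"].sum()),
                out.n_epochs)
    return out


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over channels from every sample.

    Idempotent; preserves all pairwise channel differences. A
    single-channel set degenerates to all-zero signals.
    """
    out = epochs.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    return out


def qc_counts(epochs: EpochSet, params: ArtifactParams) -> pd.DataFrame:
    """Clean+attended epoch counts per (video, presentation, half).

    ``include`` is true for a (video, presentation) only when every half
    reaches min_epochs_per_half usable epochs.
    """
    info = epochs.info
    usable = info["attended"] & info["clean"]
    grp = (
        info.assign(usable=usable)
        .groupby(["video_id", "condition", "repetition", "half"], sort=True)["usable"]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"usable": "n_clean_attended"})
    )
    ok = grp.groupby(["video_id", "repetition"])["n_clean_attended"].transform(
        lambda s: (s >= params.min_epochs_per_half).all()
    )
    grp["include"] = ok.astype(bool)
    grp["subject_id"] = epochs.subject_id
    return grp


def highpass(rec: Recording, cutoff: float = 0.1, order: int = 2) -> Recording:
    """Optional zero-phase Butterworth high-pass for unfiltered matrix input."""
    sos = sps.butter(order, cutoff, btype="highpass", fs=rec.sampling_rate, output="sos")
    return Recording(
        data=sps.sosfiltfilt(sos, rec.data, axis=1),
        sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
    )


def run_preprocess(
    rec: Recording,
    events: pd.DataFrame,
    attention: np.ndarray,
    montage: Montage,
    params: ArtifactParams | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """The fixed stage order; returns the final EpochSet and the QC table."""
    params = params or ArtifactParams()
    montage.validate_against(rec.channel_labels)
    es = segment(rec, events)
    es = gate_attention(es, attention)
    es = detect_artifacts(es, params)
    es = interpolate_bad(es, montage)
    es = rereference_average(es)
    qc = qc_counts(es, params)
    return es, qc
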