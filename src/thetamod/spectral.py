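"""FFT band power on 1-s epochs and aggregation to regional ln power.

With 1-s epochs the discrete spectrum lands on integer-Hz bins, so the
theta band (3-6 Hz) is exactly bins {3,4,5,6} and the upper alpha
control band (8-9 Hz) bins {8,9}; band edges are inclusive.

Normalization: the one-sided power spectrum sums (over all bins,
including DC) to the mean square of the signal, i.e. variance + DC
power — Parseval's identity at 1 Hz resolution. The Hann taper is
power-corrected by its mean square, which keeps broadband power
unbiased; ``taper="none"`` is exact and is what oracle tests use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Montage
from .preprocess import EpochSet

logger = logging.getLogger("thetamod")

__all__ = [
    "BandDef",
    "THETA",
    "UPPER_ALPHA",
    "epoch_spectrum",
    "all_epoch_spectra",
    "band_region_power",
    "frontal_power",
]


@dataclass(frozen=True)
class BandDef:
    """A named frequency band with inclusive integer-Hz edges."""

    name: str
    lo: float
    hi: float

    def validate(self, fs: float) -> None:
        if not 0 < self.lo <= self.hi < fs / 2:
            raise ValueError(
                f"band '{self.name}': need 0 < lo <= hi < Nyquist "
                f"({self.lo}, {self.hi}, fs={fs})"
            )

    def bins(self) -> np.ndarray:
        return np.arange(int(np.ceil(self.lo)), int(np.floor(self.hi)) + 1)


THETA = BandDef("theta", 3.0, 6.0)
UPPER_ALPHA = BandDef("upper_alpha", 8.0, 9.0)


def _taper(n: int, taper: str) -> np.ndarray:
    if taper == "none":
        return np.ones(n)
    if taper == "hann":
        w = np.hanning(n)
        return w / np.sqrt(np.mean(w**2))  # power normalization
    raise ValueError(f"unknown taper '{taper}' (use 'hann' or 'none')")


def epoch_spectrum(epoch_channel: np.ndarray, fs: float, taper: str = "hann") -> np.ndarray:
    """One-sided power spectrum (uV^2) of one channel of one 1-s epoch.

    Requires exactly ``fs`` samples; returns power at integer-Hz bins
    0..fs/2. Sum over bins equals mean(x^2) (taper-corrected).
    """
    x = np.asarray(epoch_channel, dtype=float)
    n = int(round(fs))
    if x.ndim != 1 or x.size != n:
        raise ValueError(f"epoch must be 1-D with exactly {n} samples, got shape {x.shape}")
    return all_epoch_spectra(x[None, None, :], fs, taper)[0, 0]


def all_epoch_spectra(data: np.ndarray, fs: float, taper: str = "hann") -> np.ndarray:
    """Vectorized spectra for an (epochs x channels x samples) block."""
    n = data.shape[-1]
    if n != int(round(fs)):
        raise ValueError(f"epochs must have exactly {int(round(fs))} samples, got {n}")
    w = _taper(n, taper)
    X = np.fft.rfft(data * w, axis=-1)
    p = (np.abs(X) ** 2) / (n * n)
    p[..., 1:] *= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0  # Nyquist bin is not duplicated
    return p


def band_region_power(
    epochs: EpochSet,
    montage: Montage,
    bands: list[BandDef] | None = None,
    regions: list[str] | None = None,
    taper: str = "hann",
) -> pd.DataFrame:
    """Aggregate clean+attended epoch spectra to regional band power.

    Aggregation order: mean linear power over band bins, then channels in
    the region, then epochs within (video, presentation, half); the
    natural log is taken once at the end (``ln_power``). The linear mean
    (``power``, uV^2) is kept alongside for the linear-power metric mode.
    Cells with zero usable epochs are omitted (reason logged).
    """
    bands = bands if bands is not None else [THETA, UPPER_ALPHA]
    regions = regions if regions is not None else list(montage.regions)
    fs = epochs.sampling_rate
    for b in bands:
        b.validate(fs)
    idx = {c: i for i, c in enumerate(epochs.channel_labels)}
    spectra = all_epoch_spectra(epochs.data, fs, taper)

    usable = (epochs.info["attended"] & epochs.info["clean"]).to_numpy()
    rows = []
    keys = ["video_id", "condition", "repetition", "half"]
    for key, sub in epochs.info.groupby(keys, sort=True):
        sel = np.nonzero(usable & epochs.info.index.isin(sub.index))[0]
        if sel.size == 0:
            logger.warning("no usable epochs for %s=%s; row omitted",
                           keys, key)
            continue
        for region in regions:
            chans = np.array([idx[c] for c in montage.regions[region]], dtype=int)
            for band in bands:
                bp = spectra[np.ix_(sel, chans, band.bins())].mean(axis=(1, 2))
                mean_power = float(bp.mean())
                rows.append(
                    dict(
                        subject=epochs.subject_id,
                        video_id=key[0],
                        condition=key[1],
                        repetition=key[2],
                        half=key[3],
                        region=region,
                        band=band.name,
                        power=mean_power,
                        ln_power=float(np.log(mean_power)),
                        n_epochs=int(sel.size),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "video_id", "condition", "repetition", "half",
                 "region", "band", "power", "ln_power", "n_epochs"],
    )


def frontal_power(power: pd.DataFrame, band: str = "theta") -> pd.DataFrame:
    """Collapse frontal_left/right into one frontal value per cell.

    Unweighted mean of the two regions' ln_power (and, consistently, of
    their linear power). Falls back to the single available frontal
    region with a warning.
    """
    sub = power[(power["band"] == band) & power["region"].isin(["frontal_left", "frontal_right"])]
    out = []
    keys = ["subject", "video_id", "condition", "repetition", "half"]
    for key, grp in sub.groupby(keys, sort=True):
        if len(grp) == 1:
            warnings.warn(
                f"only region '{grp['region'].iloc[0]}' available for {dict(zip(keys, key))}; "
                "using it as frontal power", stacklevel=2,
            )
        out.append(
            dict(
                zip(keys, key),
                band=band,
                ln_power=float(grp["ln_power"].mean()),
                power=float(grp["power"].mean()),
                n_epochs=int(grp["n_epochs"].iloc[0]),
            )
        )
    return pd.DataFrame(
        out,
        columns=[*keys, "band", "ln_power", "power", "n_epochs"],
    )
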