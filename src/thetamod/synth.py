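"""Synthetic infant-EEG cohorts with recorded ground truth.

Each subject is a multichannel recording built from three parts:

* 1/f ("pink") background noise, synthesized by spectral shaping of
  white Gaussian noise with an FFT filter 1/f^(beta/2) — exact spectral
  control and fully seedable;
* a theta oscillator (default 4.5 Hz) whose amplitude, during the first
  presentation of each video, ramps linearly so that the mean amplitude
  of the second half is (1 + g) times the mean of the first half. g is
  the subject's latent theta growth, drawn per condition; social videos
  scale theta by ``condition_gain`` and left-hemisphere channels by
  ``left_gain``. The second presentation plays at a constant amplitude
  multiplied by the repetition effect 1 + kappa*g + noise;
* a posterior-weighted alpha oscillator (default 9 Hz, constant
  amplitude) serving the band-specificity control.

Artifacts are square-pulse excursions of (3-10)x the amplitude
threshold lasting 0.2-1.0 s plus occasional whole-channel flatline
spans, exercising both artifact rules downstream. Attention is an
integer-second on/off chunk process covering on average
``attention_fraction`` of each video.

Cognitive t-scores couple to the subject-level growth (the mean of the
two condition growths) through score = mean + lambda*(g - E[g]) + eps
with lambda and sd(eps) derived from the programmed correlation
``target_r`` (see derive_coupling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Montage,
    Recording,
    normalize_intervals,
    validate_events,
    write_attention,
    write_edf,
    write_events,
    write_montage,
    write_phenotypes,
)

logger = logging.getLogger("thetamod")

__all__ = [
    "SynthParams",
    "GroundTruth",
    "SubjectBundle",
    "build_montage",
    "derive_coupling",
    "synth_subject",
    "cohort_plan",
    "iter_cohort",
    "synth_cohort",
    "synth_features_cohort",
]

_DEFAULT_SCHEDULE = (
    ("vidA", "social", 1),
    ("vidB", "nonsocial", 1),
    ("vidA", "social", 2),
    ("vidB", "nonsocial", 2),
)


@dataclass(frozen=True)
class SynthParams:
    """Data-generating constants for one cohort.

    Defaults mirror the acquisition protocol being emulated (500 Hz
    digitization, two 1-min videos each repeated twice) at a 32-channel
    scale; amplitudes are in microvolts. ``target_r`` is the programmed
    correlation between subject-level theta growth and the nonverbal
    t-score; ``verbal_r`` the (weaker) verbal coupling.
    """

    sampling_rate: float = 500.0
    n_channels: int = 32
    video_duration: float = 60.0
    schedule: tuple = _DEFAULT_SCHEDULE
    counterbalance: bool = False
    lead_in: float = 5.0
    inter_video_gap: float = 4.0
    pink_exponent: float = 1.0
    noise_sd: float = 15.0
    theta_freq: float = 4.5
    alpha_freq: float = 9.0
    theta_base_amp: float = 10.0
    alpha_amp: float = 6.0
    alpha_frontal_frac: float = 0.3
    posterior_theta_frac: float = 0.6
    central_theta_frac: float = 0.5
    condition_gain: float = 1.2
    left_gain: float = 1.15
    artifact_rate: float = 2.0
    artifact_amp_ref: float = 200.0
    flatline_prob: float = 0.25
    attention_fraction: float = 0.8
    g_mean: float = 0.25
    g_sd: float = 0.15
    g_min: float = -0.5
    kappa: float = 0.5
    rep_noise_sd: float = 0.1
    cognitive_mean: float = 50.0
    cognitive_sd: float = 10.0
    target_r: float = 0.4
    verbal_r: float = 0.2
    group_target_r: tuple = ()  # ((group, r), ...) overrides per group
    feature_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * self.alpha_freq:
            raise ValueError("sampling_rate must exceed twice the alpha frequency")
        if self.video_duration < 2:
            raise ValueError("video_duration must be >= 2 s")
        if not 0 < self.attention_fraction <= 1:
            raise ValueError("attention_fraction must be in (0, 1]")
        for name in ("target_r", "verbal_r"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if self.condition_gain <= 0 or self.left_gain <= 0:
            raise ValueError("gains must be positive")
        if self.n_channels < 8:
            raise ValueError("need at least 8 channels for the region layout")
        if self.g_min <= -1:
            raise ValueError("g_min must be > -1 to keep amplitudes positive")

    def resolved_schedule(self) -> list[tuple[str, str, int]]:
        sched = list(self.schedule)
        if self.counterbalance:
            order = {1: [], 2: []}
            for item in sched:
                order[item[2]].append(item)
            sched = [it for rep in (1, 2) for it in reversed(order[rep])]
        return sched


@dataclass
class GroundTruth:
    """Exactly the latent values used to synthesize one subject."""

    subject_id: str
    theta_growth: dict[str, float]          # per condition g
    repetition_effect: dict[str, float]     # per condition amplitude factor
    cognitive_scores: dict[str, float]
    group: str = "low_risk"

    @property
    def g_subject(self) -> float:
        return float(np.mean(list(self.theta_growth.values())))


@dataclass
class SubjectBundle:
    recording: Recording
    events: pd.DataFrame
    attention: np.ndarray
    truth: GroundTruth
    artifact_log: pd.DataFrame


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def build_montage(n_channels: int = 32) -> Montage:
    """Named channels with explicit region membership and chain neighbors.

    Layout: ~3/16 of channels per frontal hemisphere, 1/4 posterior, the
    remainder central (referencing/interpolation only). Neighbors are
    the chain within each region — symmetric by construction.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    nfl = nfr = max(2, round(3 * n_channels / 16))
    npost = max(2, round(n_channels / 4))
    ncent = n_channels - nfl - nfr - npost
    labels = (
        [f"FL{i+1}" for i in range(nfl)]
        + [f"FR{i+1}" for i in range(nfr)]
        + [f"P{i+1}" for i in range(npost)]
        + [f"C{i+1}" for i in range(ncent)]
    )
    regions = {
        "frontal_left": labels[:nfl],
        "frontal_right": labels[nfl : nfl + nfr],
        "posterior": labels[nfl + nfr : nfl + nfr + npost],
    }
    neighbors: dict[str, list[str]] = {c: [] for c in labels}
    for group in (regions["frontal_left"], regions["frontal_right"],
                  regions["posterior"], labels[nfl + nfr + npost :]):
        for a, b in zip(group, group[1:]):
            neighbors[a].append(b)
            neighbors[b].append(a)
    return Montage(regions=regions, neighbors=neighbors)


# ---------------------------------------------------------------------------
# Coupling
# ---------------------------------------------------------------------------

def derive_coupling(target_r: float, g_sd: float, cognitive_sd: float) -> tuple[float, float]:
    """Slope and noise sd giving corr(score, g) = target_r, sd(score) = cognitive_sd.

    With score = mean + lambda*g + eps, corr = lambda*g_sd/cognitive_sd
    and var(score) = lambda^2 g_sd^2 + noise_sd^2, so
    lambda = target_r*cognitive_sd/g_sd and
    noise_sd = cognitive_sd*sqrt(1 - target_r^2).
    """
    if not abs(target_r) < 1:
        raise ValueError(f"|target_r| must be < 1, got {target_r}")
    if g_sd <= 0 or cognitive_sd <= 0:
        raise ValueError("g_sd and cognitive_sd must be > 0")
    lam = target_r * cognitive_sd / g_sd
    noise_sd = cognitive_sd * np.sqrt(1.0 - target_r**2)
    return float(lam), float(noise_sd)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, beta: float, sd: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x_sd = x.std(axis=1, keepdims=True)
    return x / x_sd * sd


def _channel_theta_gain(params: SynthParams, montage: Montage,
                        labels: list[str]) -> np.ndarray:
    gain = np.full(len(labels), params.central_theta_frac)
    for i, c in enumerate(labels):
        if c in montage.regions["frontal_left"]:
            gain[i] = params.left_gain
        elif c in montage.regions["frontal_right"]:
            gain[i] = 1.0
        elif c in montage.regions["posterior"]:
            gain[i] = params.posterior_theta_frac
    return gain


def _ramp_profile(n: int, g: float) -> np.ndarray:
    """Linear amplitude envelope with mean(half2) = (1+g)*mean(half1).

    a(t) = 1 + d*t/T with d = 4g/(2-g); half means are 1 + d/4 and
    1 + 3d/4, whose ratio is exactly 1+g.
    """
    d = 4.0 * g / (2.0 - g)
    return 1.0 + d * np.arange(n) / n


def synth_subject(params: SynthParams, truth: GroundTruth,
                  seed: int) -> SubjectBundle:
    """Synthesize one subject's recording, events, attention and artifact log.

    Fully reproducible: all randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    fs = int(round(params.sampling_rate))
    sched = params.resolved_schedule()
    onsets = []
    t = params.lead_in
    for _ in sched:
        onsets.append(t)
        t += params.video_duration + params.inter_video_gap
    total = int(np.ceil(t + 1.0))
    n_samp = total * fs

    montage = build_montage(params.n_channels)
    labels = list(montage.neighbors)  # insertion order: FL, FR, P, C

    data = _pink_noise(rng, params.n_channels, n_samp, fs, params.pink_exponent,
                       params.noise_sd)

    # alpha oscillator, constant amplitude, posterior-weighted
    alpha_gain = np.full(params.n_channels, params.alpha_frontal_frac)
    for i, c in enumerate(labels):
        if c in montage.regions["posterior"]:
            alpha_gain[i] = 1.0
    tt = np.arange(n_samp) / fs
    phases = rng.uniform(0, 2 * np.pi, params.n_channels)
    data += (params.alpha_amp * alpha_gain)[:, None] * np.sin(
        2 * np.pi * params.alpha_freq * tt[None, :] + phases[:, None]
    )

    theta_gain = _channel_theta_gain(params, montage, labels)
    ev_rows = []
    for (video_id, condition, repetition), onset in zip(sched, onsets):
        n_vid = int(round(params.video_duration * fs))
        lo = int(round(onset * fs))
        g = truth.theta_growth[condition]
        amp = params.theta_base_amp
        if condition == "social":
            amp *= params.condition_gain
        if repetition == 1:
            envelope = amp * _ramp_profile(n_vid, g)
        else:
            # second showing plays at the first showing's mean amplitude
            # scaled by the programmed repetition effect, so the
            # between-repetition power change tracks 1 + kappa*g + noise
            # rather than the within-video ramp
            m1 = 1.0 + 2.0 * g / (2.0 - g)
            envelope = np.full(n_vid, amp * m1 * truth.repetition_effect[condition])
        ph = rng.uniform(0, 2 * np.pi, params.n_channels)
        tv = np.arange(n_vid) / fs
        osc = np.sin(2 * np.pi * params.theta_freq * tv[None, :] + ph[:, None])
        data[:, lo : lo + n_vid] += theta_gain[:, None] * envelope[None, :] * osc
        ev_rows.append(dict(onset_s=onset, duration_s=params.video_duration,
                            video_id=video_id, condition=condition,
                            repetition=repetition))
    events = validate_events(pd.DataFrame(ev_rows))

    # artifacts: square pulses + optional whole-channel flatline span
    art_rows = []
    n_art = rng.poisson(params.artifact_rate * total / 60.0)
    for _ in range(n_art):
        ch = int(rng.integers(params.n_channels))
        dur = rng.uniform(0.2, 1.0)
        on = rng.uniform(0.0, total - dur)
        mag = rng.uniform(3.0, 10.0) * params.artifact_amp_ref * rng.choice([-1.0, 1.0])
        lo, hi = int(on * fs), int((on + dur) * fs)
        data[ch, lo:hi] += mag
        art_rows.append(dict(channel=labels[ch], onset_s=on, duration_s=dur,
                             kind="pulse"))
    if params.artifact_rate > 0 and rng.uniform() < params.flatline_prob:
        ch = int(rng.integers(params.n_channels))
        dur = rng.uniform(5.0, 15.0)
        on = rng.uniform(0.0, total - dur)
        lo, hi = int(on * fs), int((on + dur) * fs)
        data[ch, lo:hi] = 0.0
        art_rows.append(dict(channel=labels[ch], onset_s=on, duration_s=dur,
                             kind="flatline"))
    artifact_log = pd.DataFrame(art_rows,
                                columns=["channel", "onset_s", "duration_s", "kind"])

    # attention: integer-second on/off chunks per video
    att = []
    for (video_id, *_), onset in zip(sched, onsets):
        end = onset + params.video_duration
        t0 = onset
        while t0 < end - 1e-9:
            chunk = min(float(rng.integers(3, 9)), end - t0)
            if params.attention_fraction >= 1.0 or rng.uniform() < params.attention_fraction:
                att.append((t0, t0 + chunk))
            t0 += chunk
    attention = normalize_intervals(np.array([(a, b - a) for a, b in att])
                                    if att else np.empty((0, 2)))

    rec = Recording(data=data, sampling_rate=float(fs), channel_labels=labels,
                    subject_id=truth.subject_id)
    return SubjectBundle(recording=rec, events=events, attention=attention,
                         truth=truth, artifact_log=artifact_log)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _draw_g(rng: np.random.Generator, n: int, params: SynthParams) -> np.ndarray:
    """Normal(g_mean, g_sd) truncated below at g_min, by rejection."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(params.g_mean, params.g_sd, size=2 * (n - filled))
        draw = draw[draw >= params.g_min]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _group_assignments(n: int, group_spec: dict[str, int] | None) -> list[str]:
    if group_spec is None:
        return ["low_risk"] * n
    if sum(group_spec.values()) != n:
        raise ValueError(
            f"group_spec totals {sum(group_spec.values())} but n = {n}"
        )
    out = []
    for g, k in group_spec.items():
        out.extend([g] * k)
    return out


def _make_truths(params: SynthParams, n: int, group_spec: dict[str, int] | None,
                 rng: np.random.Generator) -> list[GroundTruth]:
    groups = _group_assignments(n, group_spec)
    g_cond = {c: _draw_g(rng, n, params) for c in ("social", "nonsocial")}
    g_bar = (g_cond["social"] + g_cond["nonsocial"]) / 2.0
    g_bar_sd = params.g_sd / np.sqrt(2.0)  # iid condition growths

    per_group_r = dict(params.group_target_r)
    scores_nv = np.empty(n)
    scores_v = np.empty(n)
    for grp in set(groups):
        sel = np.array([g == grp for g in groups])
        r_nv = per_group_r.get(grp, params.target_r)
        lam, noise_sd = derive_coupling(r_nv, g_bar_sd, params.cognitive_sd)
        scores_nv[sel] = (params.cognitive_mean
                          + lam * (g_bar[sel] - params.g_mean)
                          + rng.normal(0, noise_sd, sel.sum()))
        lam_v, noise_v = derive_coupling(params.verbal_r, g_bar_sd, params.cognitive_sd)
        scores_v[sel] = (params.cognitive_mean
                         + lam_v * (g_bar[sel] - params.g_mean)
                         + rng.normal(0, noise_v, sel.sum()))
    scores_nv = np.clip(scores_nv, 20.0, 80.0)
    scores_v = np.clip(scores_v, 20.0, 80.0)

    truths = []
    for i in range(n):
        rep = {
            c: 1.0 + params.kappa * g_cond[c][i] + rng.normal(0, params.rep_noise_sd)
            for c in ("social", "nonsocial")
        }
        rep = {c: max(v, 0.05) for c, v in rep.items()}  # keep amplitudes positive
        truths.append(
            GroundTruth(
                subject_id=f"S{i+1:03d}",
                theta_growth={c: float(g_cond[c][i]) for c in g_cond},
                repetition_effect=rep,
                cognitive_scores={"nonverbal_t_12m": float(scores_nv[i]),
                                  "verbal_t_12m": float(scores_v[i])},
                group=groups[i],
            )
        )
    return truths


def cohort_plan(
    params: SynthParams,
    n: int,
    group_spec: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[list[GroundTruth], pd.DataFrame, np.ndarray]:
    """Draw the cohort's latent structure without synthesizing signals.

    Returns (ground truths, phenotype table, per-subject signal seeds);
    the phenotype table is indexed by subject_id.
    """
    if n < 2:
        raise ValueError(f"cohort needs n >= 2 subjects, got {n}")
    rng = np.random.default_rng(seed)
    truths = _make_truths(params, n, group_spec, rng)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n)
    phenotypes = pd.DataFrame(
        [
            dict(subject_id=tr.subject_id, group=tr.group, **tr.cognitive_scores)
            for tr in truths
        ]
    ).set_index("subject_id", drop=False)
    return truths, phenotypes, subject_seeds


def iter_cohort(
    params: SynthParams,
    n: int,
    group_spec: dict[str, int] | None = None,
    seed: int = 0,
):
    """Yield SubjectBundles one at a time (constant memory in n).

    Use this for large cohorts: a full-length 32-channel recording is
    tens of MB, so materializing hundreds at once is wasteful.
    """
    truths, _, subject_seeds = cohort_plan(params, n, group_spec, seed)
    for tr, s in zip(truths, subject_seeds):
        yield synth_subject(params, tr, int(s))


def synth_cohort(
    params: SynthParams,
    n: int,
    group_spec: dict[str, int] | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[list[SubjectBundle], pd.DataFrame, list[GroundTruth]]:
    """Synthesize a full-signal cohort; optionally write all standard files.

    Returns (subject bundles, phenotype table, ground truths). With
    ``outdir`` set, writes per-subject EDF + events/attention TSV plus
    cohort-level montage YAML, phenotype CSV and ground-truth CSV.
    Materializes every recording: for cohorts beyond a few dozen
    subjects, prefer ``iter_cohort``.
    """
    truths, phenotypes, subject_seeds = cohort_plan(params, n, group_spec, seed)
    bundles = [synth_subject(params, tr, int(s)) for tr, s in zip(truths, subject_seeds)]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_montage(build_montage(params.n_channels), outdir / "montage.yaml")
        write_phenotypes(phenotypes, outdir / "phenotypes.csv")
        gt_rows = [
            dict(subject_id=tr.subject_id, group=tr.group,
                 g_social=tr.theta_growth["social"],
                 g_nonsocial=tr.theta_growth["nonsocial"],
                 rep_social=tr.repetition_effect["social"],
                 rep_nonsocial=tr.repetition_effect["nonsocial"],
                 **tr.cognitive_scores)
            for tr in truths
        ]
        pd.DataFrame(gt_rows).to_csv(outdir / "ground_truth.csv", index=False)
        for b in bundles:
            sid = b.truth.subject_id
            sdir = outdir / sid
            sdir.mkdir(exist_ok=True)
            write_edf(b.recording, sdir / f"{sid}.edf")
            write_events(b.events, sdir / "events.tsv")
            write_attention(b.attention, sdir / "attention.tsv")
        logger.info("wrote cohort of %d subjects to %s", n, outdir)
    return bundles, phenotypes, truths


def synth_features_cohort(
    params: SynthParams,
    n: int,
    group_spec: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-level cohort: the derived indices drawn directly from the
    latent growths, bypassing signal synthesis.

    The primary index is g_subject plus Gaussian measurement noise
    (``feature_noise_sd``, the scale of the half-power estimation error
    in the full pipeline); posterior theta shares the ramp (slightly
    noisier), alpha change and the attended-proportion change are pure
    noise. Used for replicate-heavy statistical calibration, where only
    the correlation structure matters.
    """
    if n < 2:
        raise ValueError(f"cohort needs n >= 2 subjects, got {n}")
    rng = np.random.default_rng(seed)
    truths = _make_truths(params, n, group_spec, rng)
    ms = params.feature_noise_sd
    rows = []
    for tr in truths:
        rows.append(
            dict(
                subject_id=tr.subject_id,
                group=tr.group,
                pct_theta_frontal=tr.g_subject + rng.normal(0, ms),
                pct_theta_posterior=tr.g_subject + rng.normal(0, 1.2 * ms),
                pct_alpha=rng.normal(0, ms),
                pct_attended=rng.normal(0, 0.4),
                true_g=tr.g_subject,
                **tr.cognitive_scores,
            )
        )
    return pd.DataFrame(rows).set_index("subject_id", drop=False)
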