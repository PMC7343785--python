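"""Segmentation, attention gating, artifact rules, interpolation,
re-referencing and QC counting."""

import numpy as np
import pandas as pd
import pytest

from thetamod.io import FormatError, Montage, Recording, normalize_intervals
from thetamod.preprocess import (
    ArtifactParams,
    detect_artifacts,
    gate_attention,
    interpolate_bad,
    qc_counts,
    rereference_average,
    run_preprocess,
    segment,
)

FS = 100  # mechanics are rate-independent; a low rate keeps fixtures tiny


def make_rec(duration_s: float, n_ch: int = 4, rng=None, amp: float = 10.0):
    n = int(duration_s * FS)
    rng = rng or np.random.default_rng(0)
    data = rng.normal(0, amp, (n_ch, n))
    labels = [f"C{i+1}" for i in range(n_ch)]
    return Recording(data=data, sampling_rate=float(FS), channel_labels=labels)


def make_events(onset=0.0, duration=60.0, video="vidA", cond="social", rep=1):
    return pd.DataFrame(
        [{"onset_s": onset, "duration_s": duration, "video_id": video,
          "condition": cond, "repetition": rep}]
    )


class TestSegment:
    def test_60s_video_gives_30_30(self):
        es = segment(make_rec(60.0), make_events())
        assert es.n_epochs == 60
        assert (es.info["half"] == 1).sum() == 30
        assert (es.info["half"] == 2).sum() == 30

    def test_trailing_partial_second_dropped(self):
        es = segment(make_rec(60.0), make_events(duration=59.5))
        assert es.n_epochs == 59
        # midpoint at 29.75 s: epoch onsets 0..29 fall before it
        assert (es.info["half"] == 1).sum() == 30
        assert (es.info["half"] == 2).sum() == 29

    def test_onset_coordinate(self):
        rec = make_rec(30.0)
        es = segment(rec, make_events(onset=10.0, duration=15.0))
        assert es.info["onset_s"].iloc[0] == 10.0
        np.testing.assert_array_equal(es.data[0], rec.data[:, 10 * FS : 11 * FS])

    def test_video_past_recording_end(self):
        with pytest.raises(FormatError, match="past the end"):
            segment(make_rec(30.0), make_events(onset=0.0, duration=40.0))


class TestGateAttention:
    def test_full_mask_attends_all(self):
        es = segment(make_rec(60.0), make_events())
        es = gate_attention(es, np.array([[0.0, 60.0]]))
        assert es.info["attended"].all()

    def test_partial_containment_not_attended(self):
        es = segment(make_rec(30.0), make_events(duration=30.0))
        es = gate_attention(es, normalize_intervals(np.array([[5.5, 9.0]])))
        by_onset = es.info.set_index("onset_s")["attended"]
        assert not by_onset[5.0]   # [5,6) vs mask [5.5, 14.5)
        assert by_onset[6.0]
        assert not by_onset[14.0]  # [14,15) crosses the mask end
        assert not by_onset[18.0]  # outside the mask entirely

    def test_empty_mask(self):
        es = segment(make_rec(30.0), make_events(duration=30.0))
        es = gate_attention(es, np.empty((0, 2)))
        assert not es.info["attended"].any()


class TestDetectArtifacts:
    def test_amplitude_spike_flags_channel(self):
        rec = make_rec(10.0, amp=5.0)
        rec.data[2, 350] = 500.0
        es = detect_artifacts(segment(rec, make_events(duration=10.0)),
                              ArtifactParams())
        assert es.bad[3, 2]       # epoch [3,4), channel index 2
        assert es.bad.sum() == 1

    def test_flat_channel_flagged_everywhere(self):
        rec = make_rec(10.0, amp=5.0)
        rec.data[1] = 0.0
        es = detect_artifacts(segment(rec, make_events(duration=10.0)),
                              ArtifactParams())
        assert es.bad[:, 1].all()
        assert not es.info["clean"].any()

    def test_gradient_rule(self):
        rec = make_rec(10.0, amp=1.0)
        rec.data[0, 500:550] += 150.0  # step of 150 uV at the edges
        es = detect_artifacts(segment(rec, make_events(duration=10.0)),
                              ArtifactParams(amp_threshold=500.0))
        assert es.bad[5, 0]

    def test_sign_flip_invariance(self, rng):
        rec = make_rec(20.0, rng=rng, amp=80.0)
        ev = make_events(duration=20.0)
        flags = detect_artifacts(segment(rec, ev), ArtifactParams()).bad
        rec2 = Recording(-rec.data, rec.sampling_rate, rec.channel_labels)
        flags2 = detect_artifacts(segment(rec2, ev), ArtifactParams()).bad
        np.testing.assert_array_equal(flags, flags2)

    def test_generator_clean_epochs_unflagged(self, clean_subject):
        es = detect_artifacts(
            segment(clean_subject.recording, clean_subject.events), ArtifactParams()
        )
        assert es.bad.sum() == 0


def chain_montage(labels):
    nb = {c: [] for c in labels}
    for a, b in zip(labels, labels[1:]):
        nb[a].append(b)
        nb[b].append(a)
    return Montage(regions={}, neighbors=nb)


class TestInterpolate:
    def test_neighbor_mean(self):
        rec = make_rec(2.0, n_ch=3, amp=0.0)
        rec.data[0] = 3.0 + np.sin(np.arange(rec.n_samples))  # keep non-flat
        rec.data[1] = 0.0  # flat -> bad
        rec.data[2] = 5.0 + np.sin(np.arange(rec.n_samples))
        es = detect_artifacts(segment(rec, make_events(duration=2.0)),
                              ArtifactParams())
        assert es.bad[:, 1].all()
        fixed = interpolate_bad(es, chain_montage(rec.channel_labels))
        expected = (rec.data[0, :100] + rec.data[2, :100]) / 2
        np.testing.assert_allclose(fixed.data[0, 1], expected)
        assert fixed.info["clean"].all()

    def test_no_good_neighbor_leaves_unclean(self):
        rec = make_rec(2.0, n_ch=3, amp=0.0)
        rec.data[0] = 0.0
        rec.data[1] = 0.0
        rec.data[2] = 0.0
        es = detect_artifacts(segment(rec, make_events(duration=2.0)),
                              ArtifactParams())
        fixed = interpolate_bad(es, chain_montage(rec.channel_labels))
        assert not fixed.info["clean"].any()
        assert fixed.unrepaired.all()

    def test_good_channels_untouched(self, rng):
        rec = make_rec(4.0, n_ch=4, rng=rng, amp=20.0)
        rec.data[3] = 0.0
        es = detect_artifacts(segment(rec, make_events(duration=4.0)),
                              ArtifactParams())
        fixed = interpolate_bad(es, chain_montage(rec.channel_labels))
        for e in range(4):
            np.testing.assert_array_equal(fixed.data[e, :3],
                                          rec.data[:3, e * FS:(e + 1) * FS])

    def test_missing_neighbor_entry_errors(self, rng):
        rec = make_rec(2.0, n_ch=3, rng=rng)
        es = detect_artifacts(segment(rec, make_events(duration=2.0)),
                              ArtifactParams())
        with pytest.raises(FormatError, match="missing channels"):
            interpolate_bad(es, Montage(regions={}, neighbors={"C1": ["C2"],
                                                               "C2": ["C1"]}))


class TestRereference:
    def test_channel_mean_zero(self, rng):
        es = segment(make_rec(5.0, n_ch=6, rng=rng), make_events(duration=5.0))
        out = rereference_average(es)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-9

    def test_idempotent(self, rng):
        es = segment(make_rec(5.0, n_ch=6, rng=rng), make_events(duration=5.0))
        once = rereference_average(es)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_pairwise_differences_preserved(self, rng):
        es = segment(make_rec(5.0, n_ch=4, rng=rng), make_events(duration=5.0))
        out = rereference_average(es)
        np.testing.assert_allclose(
            es.data[:, 0] - es.data[:, 2], out.data[:, 0] - out.data[:, 2],
            atol=1e-12,
        )

    def test_single_channel_zeros(self, rng):
        es = segment(make_rec(3.0, n_ch=1, rng=rng), make_events(duration=3.0))
        out = rereference_average(es)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


class TestQcCounts:
    def _full_es(self, rng):
        rec = make_rec(60.0, rng=rng, amp=10.0)
        es = segment(rec, make_events())
        es = gate_attention(es, np.array([[0.0, 60.0]]))
        return detect_artifacts(es, ArtifactParams())

    def test_all_clean_counts(self, rng):
        qc = qc_counts(self._full_es(rng), ArtifactParams())
        assert qc["n_clean_attended"].tolist() == [30, 30]
        assert qc["include"].all()

    def test_low_half_triggers_exclusion(self, rng):
        es = self._full_es(rng)
        sel = es.info.index[(es.info["half"] == 2)][:26]
        es.info.loc[sel, "attended"] = False  # leave 4 in half 2
        qc = qc_counts(es, ArtifactParams())
        assert qc.loc[qc["half"] == 2, "n_clean_attended"].iloc[0] == 4
        assert not qc["include"].any()

    def test_channel_permutation_invariant(self, rng):
        rec = make_rec(20.0, rng=rng, amp=10.0)
        perm = [2, 0, 3, 1]
        rec2 = Recording(rec.data[perm], rec.sampling_rate,
                         [rec.channel_labels[i] for i in perm])
        ev = make_events(duration=20.0)
        for r in (rec, rec2):
            es = gate_attention(segment(r, ev), np.array([[0.0, 20.0]]))
            es = detect_artifacts(es, ArtifactParams())
            qc = qc_counts(es, ArtifactParams())
            assert qc["n_clean_attended"].tolist() == [10, 10]


def test_pipeline_order_runs_end_to_end(clean_subject, montage32):
    es, qc = run_preprocess(
        clean_subject.recording,
        clean_subject.events,
        clean_subject.attention,
        montage32,
    )
    assert es.info["clean"].all()
    assert es.info["attended"].all()
    assert qc["include"].all()
    assert np.abs(es.data.mean(axis=1)).max() < 1e-9
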