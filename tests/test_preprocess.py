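"""Filtering, EOG removal, baseline stripping and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from emoeeg.layout import standard_layout
from emoeeg.preprocess import (
    AnnotationError,
    ParameterError,
    bandpass,
    n_segments,
    remove_eog,
    segment,
    strip_baseline,
)
from emoeeg.recording import RawRecording, TrialAnnotation
from emoeeg.simulate import SimConfig, generate_subject
from tests.conftest import TINY_KW

FS = 512.0


def single_channel(x: np.ndarray) -> RawRecording:
    return RawRecording(data=x[None, :], fs=FS, layout=standard_layout(1))


class TestBandpass:
    def test_dc_offset_removed(self):
        rec = single_channel(np.full(int(10 * FS), 25.0))
        out = bandpass(rec, 0.1, 80.0)
        assert np.abs(out.data).mean() < 0.01 * 25.0

    @pytest.mark.parametrize("freq,check", [(10.0, "pass"), (100.0, "stop")])
    def test_response_matches_filter_oracle(self, freq, check):
        """The gain at a probe frequency tracks |H(f)|^2 of the designed
        Butterworth run forward-backward (oracle: sosfreqz).  Measured by
        lock-in projection on an interior window, which rejects the slow
        edge transient the 0.1 Hz corner produces."""
        t = np.arange(int(20 * FS)) / FS
        rec = single_channel(np.sin(2 * np.pi * freq * t))
        out = bandpass(rec, 0.1, 80.0)
        sos = sps.butter(4, [0.1, 80.0], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
        expected_gain = np.abs(h[0]) ** 2  # filtfilt squares the magnitude
        core = slice(int(6 * FS), int(14 * FS))
        y, tc = out.data[0, core], t[core]
        a = 2 * np.mean(y * np.sin(2 * np.pi * freq * tc))
        b = 2 * np.mean(y * np.cos(2 * np.pi * freq * tc))
        measured = np.hypot(a, b)
        assert measured == pytest.approx(expected_gain, rel=0.05)
        if check == "pass":
            assert measured > 0.95
        else:
            assert measured < 0.15

    def test_invalid_edges(self):
        rec = single_channel(np.zeros(1024))
        with pytest.raises(ParameterError):
            bandpass(rec, 80.0, 0.1)
        with pytest.raises(ParameterError):
            bandpass(rec, 0.1, 400.0)


@pytest.fixture(scope="module")
def blink_recording():
    cfg = SimConfig(**{**TINY_KW, "blink_rate": 12.0, "seed": 13})
    return generate_subject(cfg, 1)


def blink_regressor(rec) -> np.ndarray:
    """The known injected blink time course, rebuilt from event times."""
    reg = np.zeros(rec.n_samples)
    tpl_t = np.arange(-0.3, 0.3, 1 / rec.fs)
    template = np.exp(-0.5 * (tpl_t / 0.15) ** 2)
    for t0 in rec.meta["blink_times_s"]:
        start = int(round((t0 - 0.3) * rec.fs))
        reg[start : start + len(template)] += template
    return reg


class TestRemoveEog:
    def test_component_count_matches_channels(self):
        rng = np.random.default_rng(0)
        layout = standard_layout(61)
        rec = RawRecording(data=rng.standard_normal((61, 8000)), fs=FS, layout=layout)
        _, report = remove_eog(rec, max_iter=30, seed=0)
        assert report.n_components == 61
        assert len(report.scores) == 61

    def test_blink_component_is_removed(self, blink_recording):
        rec, _ = blink_recording
        reg = blink_regressor(rec)
        fp1 = rec.layout.index("Fp1")
        before = np.corrcoef(rec.data[fp1], reg)[0, 1]
        cleaned, report = remove_eog(rec, seed=1)
        after = np.corrcoef(cleaned.data[fp1], reg)[0, 1]
        assert before > 0.7
        assert abs(after) < 0.3
        assert len(report.flagged) >= 1

    def test_artifact_free_recording_preserved(self, tiny_recording):
        rec, _ = tiny_recording
        cleaned, report = remove_eog(rec, seed=2)
        assert report.flagged == []
        for ch in range(rec.n_channels):
            r = np.corrcoef(rec.data[ch], cleaned.data[ch])[0, 1]
            assert r > 0.95

    def test_rerun_flags_nothing_new(self, blink_recording):
        rec, _ = blink_recording
        cleaned, _ = remove_eog(rec, seed=1)
        _, report2 = remove_eog(cleaned, seed=1)
        assert report2.flagged == []

    def test_rank_deficient_raises_with_channel_names(self):
        layout = standard_layout(4)
        data = np.random.default_rng(0).standard_normal((4, 2000))
        data[2] = 0.0
        rec = RawRecording(data=data, fs=FS, layout=layout)
        with pytest.raises(Exception, match=layout.names[2]):
            remove_eog(rec)


def _annotated(durations, pre=5.0, fs=FS, n_channels=2):
    anns = []
    t = pre
    for i, d in enumerate(durations):
        anns.append(TrialAnnotation(i, "movie", (i % 18) + 1, "joy", t, d))
        t += d + pre
    n = int(round(t * fs))
    rng = np.random.default_rng(0)
    return RawRecording(
        data=rng.standard_normal((n_channels, n)),
        fs=fs,
        layout=standard_layout(n_channels),
        annotations=anns,
    )


class TestStripBaseline:
    def test_keeps_last_analysis_span(self):
        rec = _annotated([60.0])
        out = strip_baseline(rec, 5.0, 50.0)
        assert out.annotations[0].duration_s == 50.0
        assert out.n_samples == int(50 * FS)
        # the retained block is the *last* 50 s of the trial
        src = rec.trial_slice(rec.annotations[0])
        np.testing.assert_array_equal(out.data, rec.data[:, src.stop - int(50 * FS) : src.stop])

    def test_zero_pre_trial_full_span_is_identity_on_trials(self):
        rec = _annotated([20.0, 20.0], pre=0.0)
        out = strip_baseline(rec, 0.0, None)
        assert [a.duration_s for a in out.annotations] == [20.0, 20.0]
        np.testing.assert_array_equal(
            out.data[:, : int(20 * FS)], rec.data[:, rec.trial_slice(rec.annotations[0])]
        )

    def test_short_trial_error_names_trial(self):
        rec = _annotated([30.0])
        with pytest.raises(AnnotationError, match="trial 0"):
            strip_baseline(rec, 5.0, 50.0)

    def test_insufficient_pre_trial_span(self):
        rec = _annotated([20.0], pre=2.0)
        with pytest.raises(AnnotationError, match="precede"):
            strip_baseline(rec, 5.0, 10.0)


class TestSegment:
    def test_study_epoch_counts(self):
        rec = _annotated([50.0] * 18, pre=0.0)
        epochs = segment(rec, 2.0, 0.5)
        assert len(epochs) == 882
        assert epochs.window_samples == 1024
        counts = epochs.info.groupby("trial_index").size()
        assert (counts == 49).all()

    def test_trial_equal_to_window_yields_one_epoch(self):
        rec = _annotated([2.0], pre=0.0)
        assert len(segment(rec, 2.0, 0.5)) == 1

    def test_no_overlap(self):
        rec = _annotated([50.0], pre=0.0)
        assert len(segment(rec, 2.0, 0.0)) == 25

    def test_window_longer_than_trial(self):
        rec = _annotated([1.0], pre=0.0)
        with pytest.raises(ParameterError):
            segment(rec, 2.0, 0.5)

    @given(
        trial_s=st.integers(2, 60),
        window_s=st.integers(1, 4),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    @settings(max_examples=40, deadline=None)
    def test_count_matches_sliding_window_enumeration(self, trial_s, window_s, overlap):
        if window_s > trial_s:
            return
        fs = 64
        L, W = trial_s * fs, window_s * fs
        hop = int(round(W * (1 - overlap)))
        brute = sum(1 for start in range(0, L + 1) if start % hop == 0 and start + W <= L)
        assert n_segments(L, W, overlap) == brute

    def test_epochs_inherit_labels_and_never_cross_trials(self, tiny_epochs):
        info = tiny_epochs.info
        for (_, trial), grp in info.groupby(["paradigm", "trial_index"]):
            assert grp["emotion"].nunique() == 1
            assert grp["onset_s"].max() + 2.0 <= grp["onset_s"].min() + 8.0 + 1e-9
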