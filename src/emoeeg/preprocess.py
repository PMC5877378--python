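"""Preprocessing: band-pass filtering, ICA-based EOG removal, baseline
stripping and overlapping segmentation.

The pipeline order follows standard emotional-EEG practice: a 0.1-80 Hz
zero-phase band-pass, FastICA decomposition into as many sources as
channels with automatic flagging of ocular components, trimming each
trial to its final analysis span, then 2 s epochs with 50 % overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .recording import EpochSet, RawRecording, TrialAnnotation


class ParameterError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


class DecompositionError(RuntimeError):
    pass


def _butter_sos(low: float, high: float, fs: float, order: int = 4):
    if not 0 < low < high < fs / 2:
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < fs/2; got ({low}, {high}) at fs={fs}"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    recording: RawRecording, low: float = 0.1, high: float = 80.0, order: int = 4
) -> RawRecording:
    """Zero-phase Butterworth band-pass (forward-backward, so the effective
    attenuation is that of a squared 4th-order response)."""
    sos = _butter_sos(low, high, recording.fs, order)
    out = recording.copy_with(data=sps.sosfiltfilt(sos, recording.data, axis=1))
    return out


@dataclass
class EogReport:
    n_components: int
    flagged: list[int]
    scores: np.ndarray  # |correlation| of each source with the EOG surrogate

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "flagged": list(map(int, self.flagged)),
            "scores": [float(s) for s in self.scores],
        }


def eog_surrogate(recording: RawRecording) -> np.ndarray:
    """Band-limited (0.5-4 Hz) mean of the most frontal channel pair.

    Uses Fp1/Fp2 when present, otherwise the two most anterior channels.
    A reproducible stand-in for visual selection of ocular components.
    """
    names = recording.layout.names
    if "Fp1" in names and "Fp2" in names:
        idx = [names.index("Fp1"), names.index("Fp2")]
    else:
        idx = list(np.argsort(recording.layout.positions[:, 1])[-2:])
    frontal = recording.data[idx].mean(axis=0)
    sos = sps.butter(2, [0.5, 4.0], btype="bandpass", fs=recording.fs, output="sos")
    return sps.sosfiltfilt(sos, frontal)


def remove_eog(
    recording: RawRecording,
    n_components: int | None = None,
    threshold: float = 0.7,
    fit_stride: int | None = None,
    max_fit_samples: int = 50_000,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[RawRecording, EogReport]:
    """FastICA decomposition with automatic zeroing of ocular components.

    Components whose time course correlates (|r| > ``threshold``) with the
    frontal EOG surrogate are zeroed before reconstruction.  The unmixing
    is fitted on every k-th sample (``fit_stride``, chosen automatically to
    keep at most ``max_fit_samples``) while the full data is transformed
    and reconstructed — a standard economy for long recordings.  FastICA's
    convergence warning is suppressed: on near-Gaussian background activity
    the fixed-point iteration rarely meets its tolerance, yet the rotation
    it reaches isolates the sparse, strongly non-Gaussian ocular sources
    that matter here.
    """
    X = recording.data.T  # samples x channels
    n_ch = recording.n_channels
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ParameterError(f"n_components={n_components} exceeds {n_ch} channels")
    if X.shape[0] < 2 * n_ch:
        raise DecompositionError("too few samples for a stable decomposition")

    if fit_stride is None:
        fit_stride = max(1, int(np.ceil(X.shape[0] / max_fit_samples)))
    sub = X[::fit_stride] if fit_stride > 1 else X
    sd = sub.std(axis=0)
    if np.any(sd < 1e-12):
        dead = [recording.layout.names[i] for i in np.where(sd < 1e-12)[0]]
        raise DecompositionError(f"rank-deficient data; flat channels: {dead}")

    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=1e-3,
        random_state=seed,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ica.fit(sub)
    sources = ica.transform(X)  # samples x components

    surrogate = eog_surrogate(recording)
    s_center = surrogate - surrogate.mean()
    denom_s = np.linalg.norm(s_center)
    sc = sources - sources.mean(axis=0)
    denom_c = np.linalg.norm(sc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.abs(sc.T @ s_center) / (denom_c * denom_s)
    scores = np.nan_to_num(scores)

    flagged = list(np.where(scores > threshold)[0])
    sources[:, flagged] = 0.0
    cleaned = ica.inverse_transform(sources).T

    out = recording.copy_with(data=cleaned)
    return out, EogReport(n_components=n_components, flagged=flagged, scores=scores)


def strip_baseline(
    recording: RawRecording,
    pre_trial_s: float = 5.0,
    analysis_seconds: float | None = None,
) -> RawRecording:
    """Discard pre-trial baselines and trim each trial to its analysis span.

    Keeps, for every annotated trial, the last ``analysis_seconds`` of its
    span (the whole span when ``analysis_seconds`` is None) and drops all
    other data — resting baselines, the ``pre_trial_s`` spans preceding
    trials, and early-trial padding.  Annotations are rebuilt with onsets in
    the trimmed recording.
    """
    fs = recording.fs
    keep: list[np.ndarray] = []
    new_ann: list[TrialAnnotation] = []
    t = 0.0
    for ann in sorted(recording.annotations, key=lambda a: a.onset_s):
        if ann.onset_s < pre_trial_s - 1e-9:
            raise AnnotationError(
                f"trial {ann.trial_index}: only {ann.onset_s:.2f} s precede it, "
                f"need >= {pre_trial_s} s"
            )
        span = ann.duration_s if analysis_seconds is None else analysis_seconds
        if span > ann.duration_s + 1e-9:
            raise AnnotationError(
                f"trial {ann.trial_index} (clip {ann.clip_id}) lasts "
                f"{ann.duration_s:.2f} s < analysis span {span} s"
            )
        stop = int(round((ann.onset_s + ann.duration_s) * fs))
        start = stop - int(round(span * fs))
        keep.append(recording.data[:, start:stop])
        new_ann.append(
            TrialAnnotation(
                ann.trial_index, ann.paradigm, ann.clip_id, ann.emotion, t, span
            )
        )
        t += span
    if not keep:
        raise AnnotationError("recording has no trial annotations")
    return recording.copy_with(data=np.concatenate(keep, axis=1), annotations=new_ann)


def n_segments(trial_samples: int, window_samples: int, overlap: float) -> int:
    """Number of windows of ``window_samples`` with fractional ``overlap``
    that fit in ``trial_samples`` without crossing the trial end."""
    hop = int(round(window_samples * (1.0 - overlap)))
    if hop < 1:
        raise ParameterError("overlap too close to 1 for this window")
    if trial_samples < window_samples:
        raise ParameterError("window longer than trial")
    return (trial_samples - window_samples) // hop + 1


def segment(recording: RawRecording, window_s: float = 2.0, overlap: float = 0.5) -> EpochSet:
    """Cut each annotated trial into fixed windows with fractional overlap.

    Epochs inherit the trial's labels and never cross trial boundaries.
    A 50 s trial at 2 s / 50 % yields 49 epochs, hence 18 trials give 882
    epochs per subject and paradigm.
    """
    if not 0 <= overlap < 1:
        raise ParameterError(f"overlap must be in [0, 1); got {overlap}")
    fs = recording.fs
    w = int(round(window_s * fs))
    hop = int(round(w * (1.0 - overlap)))
    chunks: list[np.ndarray] = []
    rows: list[dict] = []
    for ann in sorted(recording.annotations, key=lambda a: a.onset_s):
        sl = recording.trial_slice(ann)
        trial = recording.data[:, sl]
        count = n_segments(trial.shape[1], w, overlap)
        for k in range(count):
            start = k * hop
            chunks.append(trial[:, start : start + w])
            rows.append(
                {
                    "subject": recording.subject_id,
                    "paradigm": ann.paradigm,
                    "clip_id": ann.clip_id,
                    "emotion": ann.emotion,
                    "trial_index": ann.trial_index,
                    "onset_s": ann.onset_s + start / fs,
                }
            )
    if not chunks:
        raise AnnotationError("no epochs produced; recording has no annotations")
    return EpochSet(np.stack(chunks), pd.DataFrame(rows), fs, recording.layout)
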