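"""Core in-memory containers: recordings, trial annotations and epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import ChannelLayout

EMOTIONS = ("joy", "neutral", "sad", "disgust", "anger", "fear")
PARADIGMS = ("movie", "recall")


@dataclass(frozen=True)
class TrialAnnotation:
    """One trial block: a labelled contiguous span of the recording."""

    trial_index: int
    paradigm: str  # "movie" | "recall"
    clip_id: int  # 1..18
    emotion: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if self.duration_s <= 0:
            raise ValueError("trial duration must be positive")


@dataclass
class RawRecording:
    """Multichannel EEG: channels x samples in microvolts plus annotations."""

    data: np.ndarray
    fs: float
    layout: ChannelLayout
    annotations: list[TrialAnnotation] = field(default_factory=list)
    subject_id: str = "S00"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.layout):
            raise ValueError(
                f"{self.data.shape[0]} data rows vs {len(self.layout)} layout channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        span = self.data.shape[1] / self.fs
        for ann in self.annotations:
            if ann.onset_s < 0 or ann.onset_s + ann.duration_s > span + 1e-9:
                raise ValueError(
                    f"trial {ann.trial_index} [{ann.onset_s}, "
                    f"{ann.onset_s + ann.duration_s}] s outside recording span {span} s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def trial_slice(self, ann: TrialAnnotation) -> slice:
        start = int(round(ann.onset_s * self.fs))
        stop = start + int(round(ann.duration_s * self.fs))
        return slice(start, stop)

    def copy_with(self, **kw) -> "RawRecording":
        kw.setdefault("data", self.data.copy())
        kw.setdefault("annotations", list(self.annotations))
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Fixed-length labelled segments stacked as (n_epochs, channels, samples).

    ``info`` carries one row per epoch: subject, paradigm, clip_id, emotion,
    trial_index, onset_s.
    """

    data: np.ndarray
    info: pd.DataFrame
    fs: float
    layout: ChannelLayout

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")
        if len(self.info) != self.data.shape[0]:
            raise ValueError("info rows must match epoch count")
        if self.data.shape[1] != len(self.layout):
            raise ValueError("epoch channel count must match layout")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def window_samples(self) -> int:
        return self.data.shape[2]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.data[mask],
            self.info.loc[mask].reset_index(drop=True),
            self.fs,
            self.layout,
        )
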