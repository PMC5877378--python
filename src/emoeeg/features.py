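"""Per-epoch feature extraction: band differential entropies from the STFT
and the log mean absolute first difference of the first IMF.

For a 61-channel epoch the feature vector has 61 x 6 = 366 entries:
five band DEs (delta 1-4, theta 4-8, alpha 8-12, beta 12-30, gamma
30-64 Hz) and one EMD feature per channel.  DE here is the log of the
band-limited spectrogram power,

    DE_band = log( mean over frames of  sum over band bins of |S(m, f_k)|^2 ),

which for Gaussian signals tracks differential entropy up to constants.
The EMD feature is log(D_t) with D_t the mean absolute first difference
of IMF1, an amplitude-weighted measure of the fastest oscillation.

Feature order is fixed: the DE block first (channel-major, bands in the
order delta..gamma), then the EMD block (one per channel).  Names are
``<channel>_DE_<band>`` and ``<channel>_EMD_Dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emd import first_imf
from .layout import ChannelLayout
from .recording import EpochSet

BANDS_TABLE = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 64.0),
}
BAND_ORDER = tuple(BANDS_TABLE)
META_COLUMNS = ("subject", "paradigm", "clip_id", "emotion", "trial_index", "onset_s")

#: floor under band powers / D_t before the log; flagged when it triggers
LOG_EPS = 1e-30


@dataclass(frozen=True)
class SpectralConfig:
    stft_window_samples: int = 128
    stft_overlap: float = 0.5
    taper: str = "hamming"
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS_TABLE))

    def __post_init__(self) -> None:
        if self.stft_window_samples < 2:
            raise ValueError("stft_window_samples must be >= 2")
        if not 0 <= self.stft_overlap < 1:
            raise ValueError("stft_overlap must be in [0, 1)")
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} edges must be increasing")

    @property
    def hop(self) -> int:
        return int(round(self.stft_window_samples * (1.0 - self.stft_overlap)))

    def taper_window(self) -> np.ndarray:
        if self.taper == "hamming":
            return np.hamming(self.stft_window_samples)
        if self.taper in ("boxcar", "rect"):
            return np.ones(self.stft_window_samples)
        raise ValueError(f"unknown taper {self.taper!r}")


@dataclass
class Spectrogram:
    """Time-frequency power |S(m, f_k)|^2: frames x frequency bins."""

    power: np.ndarray
    frame_times: np.ndarray
    freqs: np.ndarray


def stft(signal: np.ndarray, config: SpectralConfig, fs: float) -> Spectrogram:
    """Tapered short-time power spectrogram.

    Frames cover the epoch at the configured overlap; a frame that would
    overrun the end is dropped (no padding).
    """
    x = np.asarray(signal, dtype=float)
    w = config.stft_window_samples
    if x.ndim != 1:
        raise ValueError("stft expects a single-channel 1-D epoch")
    if len(x) < w:
        raise ValueError(f"epoch of {len(x)} samples shorter than STFT window {w}")
    hop = config.hop
    frames = np.lib.stride_tricks.sliding_window_view(x, w)[::hop]
    spec = np.fft.rfft(frames * config.taper_window(), axis=-1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(w, 1.0 / fs)
    times = (np.arange(frames.shape[0]) * hop + w / 2) / fs
    return Spectrogram(power=power, frame_times=times, freqs=freqs)


def band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Bin mask for a band: ``low < f_k <= high``.

    Half-open on the left so that adjacent bands from the band table never
    share a bin (at 512 Hz / 128-sample windows the bin pitch is 4 Hz and
    band edges fall exactly on bins).
    """
    lo, hi = band
    return (freqs > lo) & (freqs <= hi)


def band_de(spec: Spectrogram, band: tuple[float, float], eps: float = LOG_EPS):
    """Band differential entropy: log of frame-averaged band power.

    Returns ``(value, floored)``; ``floored`` marks degenerate zero-power
    input whose log was taken at the ``eps`` floor.
    """
    mask = band_bins(spec.freqs, band)
    p = spec.power[:, mask].sum(axis=1).mean() if mask.any() else 0.0
    floored = p < eps
    return float(np.log(max(p, eps))), bool(floored)


def dt_feature(imf1: np.ndarray, eps: float = LOG_EPS):
    """log(D_t) with D_t the mean absolute first difference of the series."""
    x = np.asarray(imf1, dtype=float)
    if len(x) < 2:
        raise ValueError("dt_feature needs at least two samples")
    dt = np.mean(np.abs(np.diff(x)))
    floored = dt < eps
    return float(np.log(max(dt, eps))), bool(floored)


def feature_names(layout: ChannelLayout, bands=BAND_ORDER) -> list[str]:
    names = [f"{ch}_DE_{b}" for ch in layout.names for b in bands]
    names += [f"{ch}_EMD_Dt" for ch in layout.names]
    return names


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split ``T7_DE_gamma`` into (electrode, family)."""
    electrode, family = name.split("_", 1)
    return electrode, family


def extract(epoch: np.ndarray, layout: ChannelLayout, config: SpectralConfig, fs: float):
    """Feature vector for one channels x samples epoch.

    Returns ``(values, names, n_floored)``; length is 6 per channel.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] != len(layout):
        raise ValueError(
            f"epoch shape {epoch.shape} does not match layout of {len(layout)} channels"
        )
    bands = [config.bands[b] for b in BAND_ORDER if b in config.bands]
    band_names = [b for b in BAND_ORDER if b in config.bands]
    de_vals = np.empty((len(layout), len(bands)))
    n_floored = 0
    for i, ch in enumerate(layout.names):
        try:
            spec = stft(epoch[i], config, fs)
            for j, band in enumerate(bands):
                de_vals[i, j], fl = band_de(spec, band)
                n_floored += fl
        except ValueError as exc:
            raise ValueError(f"channel {ch}: {exc}") from exc
    emd_vals = np.empty(len(layout))
    for i, ch in enumerate(layout.names):
        try:
            emd_vals[i], fl = dt_feature(first_imf(epoch[i]))
            n_floored += fl
        except ValueError as exc:
            raise ValueError(f"channel {ch}: {exc}") from exc
    values = np.concatenate([de_vals.ravel(), emd_vals])
    names = [f"{ch}_DE_{b}" for ch in layout.names for b in band_names]
    names += [f"{ch}_EMD_Dt" for ch in layout.names]
    return values, names, n_floored


def _batch_band_power(data: np.ndarray, config: SpectralConfig, fs: float) -> np.ndarray:
    """Frame-averaged band powers for (epochs, channels, samples) data.

    Vectorized equivalent of per-channel ``stft`` + ``band_de`` (before the
    log); returns (epochs, channels, n_bands).
    """
    w = config.stft_window_samples
    hop = config.hop
    frames = np.lib.stride_tricks.sliding_window_view(data, w, axis=-1)[..., ::hop, :]
    spec = np.fft.rfft(frames * config.taper_window(), axis=-1)
    power = np.abs(spec) ** 2  # (E, C, frames, bins)
    freqs = np.fft.rfftfreq(w, 1.0 / fs)
    bands = [config.bands[b] for b in BAND_ORDER if b in config.bands]
    out = np.empty(power.shape[:2] + (len(bands),))
    for j, band in enumerate(bands):
        mask = band_bins(freqs, band)
        out[..., j] = power[..., mask].sum(axis=-1).mean(axis=-1) if mask.any() else 0.0
    return out


def extract_features(
    epochs: EpochSet, config: SpectralConfig | None = None, chunk: int = 64
) -> pd.DataFrame:
    """Feature matrix for an epoch set: metadata columns then named features.

    The DE block is computed vectorized in chunks of epochs; the EMD block
    sifts IMF1 channel by channel.  Column order and values are identical
    to calling :func:`extract` per epoch.
    """
    config = config or SpectralConfig()
    n_bands = sum(b in config.bands for b in BAND_ORDER)
    E, C, _ = epochs.data.shape
    de = np.empty((E, C, n_bands))
    for start in range(0, E, chunk):
        sl = slice(start, min(start + chunk, E))
        de[sl] = _batch_band_power(epochs.data[sl], config, epochs.fs)
    de = np.log(np.maximum(de, LOG_EPS)).reshape(E, C * n_bands)

    emd_vals = np.empty((E, C))
    for e in range(E):
        for c in range(C):
            emd_vals[e, c] = dt_feature(first_imf(epochs.data[e, c]))[0]

    cols = feature_names(epochs.layout, [b for b in BAND_ORDER if b in config.bands])
    feats = pd.DataFrame(np.hstack([de, emd_vals]), columns=cols)
    meta = epochs.info.reset_index(drop=True)
    return pd.concat([meta, feats], axis=1)


def feature_columns(frame: pd.DataFrame) -> list[str]:
    """The feature (non-metadata) columns of a feature matrix."""
    return [c for c in frame.columns if c not in META_COLUMNS]
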