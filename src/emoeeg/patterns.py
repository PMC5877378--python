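"""Per-class neural-pattern summaries: electrode topographies, feature
distributions, and interpolated scalp grids.

A topography is the class-conditional mean of one feature family (say
DE_gamma) at every electrode, pooled over epochs of the cohort.  Grids
are inverse-distance-weighted interpolations on the unit head disc — a
deliberately overshoot-free method, so grid values always stay inside
the range of the electrode values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import feature_columns, parse_feature_name
from .layout import ChannelLayout


@dataclass
class TopographyMap:
    layout: ChannelLayout
    values: np.ndarray  # one scalar per electrode, layout order
    family: str
    emotion: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"electrode": self.layout.names, "value": self.values})


def _family_columns(frame: pd.DataFrame, family: str, layout: ChannelLayout) -> list[str]:
    cols = []
    for ch in layout.names:
        col = f"{ch}_{family}"
        if col not in frame.columns:
            raise KeyError(f"feature column {col!r} missing from the cohort matrix")
        cols.append(col)
    return cols


def class_topography(
    frame: pd.DataFrame,
    family: str,
    emotion: str,
    layout: ChannelLayout,
    weighting: str = "epoch",
) -> TopographyMap:
    """Mean feature value per electrode over all epochs of one class.

    ``weighting='epoch'`` pools every epoch equally across the cohort;
    ``'subject'`` averages per-subject means so each participant counts
    equally regardless of epoch count.
    """
    sub = frame.loc[frame["emotion"] == emotion]
    if sub.empty:
        raise ValueError(f"cohort contains no epochs of class {emotion!r}")
    cols = _family_columns(frame, family, layout)
    if weighting == "epoch":
        values = sub[cols].mean().to_numpy()
    elif weighting == "subject":
        values = sub.groupby("subject")[cols].mean().mean().to_numpy()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return TopographyMap(layout=layout, values=values, family=family, emotion=emotion)


def feature_distribution(frame: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Five-number summary plus Tukey outlier fences of one feature, per class."""
    if feature not in frame.columns:
        raise KeyError(f"unknown feature {feature!r}")
    rows = []
    for emotion, grp in frame.groupby("emotion"):
        x = grp[feature].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        rows.append(
            {
                "emotion": emotion,
                "min": x.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": x.max(),
                "lower_fence": q1 - 1.5 * iqr,
                "upper_fence": q3 + 1.5 * iqr,
                "n": len(x),
            }
        )
    return pd.DataFrame(rows).set_index("emotion")


def interpolate_scalp(
    topo: TopographyMap, resolution: int = 64, power: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """IDW interpolation of a topography onto a gridded unit head disc.

    Returns ``(grid, mask)``: a (resolution, resolution) array (NaN outside
    the head circle) and the boolean validity mask.  Grid values are convex
    combinations of electrode values, hence bounded by their extremes.
    """
    pos = topo.layout.positions
    if len(pos) < 3:
        raise ValueError("need at least 3 electrodes to interpolate")
    span = np.ptp(pos, axis=0)
    if np.any(span < 1e-12):
        raise ValueError("degenerate electrode positions (collinear or coincident)")
    radius = max(1.0, float(np.max(np.hypot(pos[:, 0], pos[:, 1]))))
    axis = np.linspace(-radius, radius, resolution)
    gx, gy = np.meshgrid(axis, axis)
    mask = gx**2 + gy**2 <= radius**2

    d2 = (gx[..., None] - pos[:, 0]) ** 2 + (gy[..., None] - pos[:, 1]) ** 2
    dist = np.sqrt(d2)
    grid = np.full(gx.shape, np.nan)
    exact = dist < 1e-12
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[exact.any(axis=-1)] = 0.0
    w[exact] = 1.0
    grid[mask] = (w[mask] @ topo.values) / w[mask].sum(axis=-1)
    return grid, mask


def cohort_topographies(
    frame: pd.DataFrame, layout: ChannelLayout, families: list[str] | None = None
) -> pd.DataFrame:
    """Long-format table of class topographies for every feature family."""
    if families is None:
        families = sorted(
            {parse_feature_name(c)[1] for c in feature_columns(frame)}
        )
    rows = []
    for family in families:
        for emotion in sorted(frame["emotion"].unique()):
            topo = class_topography(frame, family, emotion, layout)
            for ch, v in zip(layout.names, topo.values):
                rows.append(
                    {"family": family, "emotion": emotion, "electrode": ch, "value": v}
                )
    return pd.DataFrame(rows)
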