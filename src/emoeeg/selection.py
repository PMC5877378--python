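"""Minimal-redundancy-maximal-relevance (MRMR) feature ranking.

Features are discretized (default: three levels split at mu +/- sigma, the
practice of the original MRMR work), mutual information is estimated by
the plug-in formula on the joint contingency table, and features are
ranked by greedy forward selection maximizing

    I(x_j; y)  -  (1/k) * sum_{x_i in S_k} I(x_j; x_i)

at each step — relevance to the class label minus mean redundancy with
the already-selected set.  Per-subject rankings are aggregated into a
cohort-level top-n list by appearance counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import parse_feature_name


@dataclass
class DiscretizedFeatures:
    codes: np.ndarray  # (n_samples, n_features) int
    edges: list[np.ndarray]  # per-feature bin edges
    n_levels: int
    constant: np.ndarray  # per-feature flag: all codes identical

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]


def discretize(
    features: np.ndarray | pd.DataFrame, n_levels: int = 3, method: str = "mu_sigma"
) -> DiscretizedFeatures:
    """Per-feature binning into integer codes.

    ``mu_sigma`` (3 levels only): below mu - sigma, within, above mu + sigma.
    ``quantile``: equal-frequency bins at the empirical quantiles.
    Constant features yield a single level and are flagged.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (samples x features)")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if method == "mu_sigma" and n_levels != 3:
        raise ValueError("mu_sigma binning is defined for exactly 3 levels")

    n, p = X.shape
    codes = np.zeros((n, p), dtype=np.int64)
    edges: list[np.ndarray] = []
    constant = np.zeros(p, dtype=bool)
    for j in range(p):
        x = X[:, j]
        sd = x.std()
        if sd < 1e-15:
            constant[j] = True
            edges.append(np.array([]))
            continue
        if method == "mu_sigma":
            e = np.array([x.mean() - sd, x.mean() + sd])
        elif method == "quantile":
            qs = np.quantile(x, np.linspace(0, 1, n_levels + 1)[1:-1])
            e = np.asarray(qs)
        else:
            raise ValueError(f"unknown discretization method {method!r}")
        codes[:, j] = np.searchsorted(e, x, side="right")
        edges.append(e)
    return DiscretizedFeatures(codes=codes, edges=edges, n_levels=n_levels, constant=constant)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete series."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = len(x)
    if n == 0:
        raise ValueError("empty series")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def _mi_against_all(codes: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """I(codes[:, j]; ref) for every column j."""
    return np.array([mutual_information(codes[:, j], ref) for j in range(codes.shape[1])])


@dataclass
class FeatureRanking:
    order: np.ndarray  # feature indices, best first
    scores: np.ndarray  # D - R value at the moment of selection
    relevance: np.ndarray  # I(x_j; y) for all features
    names: list[str] | None = None

    def top(self, n: int) -> np.ndarray:
        return self.order[:n]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, j in enumerate(self.order, start=1):
            name = self.names[j] if self.names else str(j)
            electrode, family = parse_feature_name(name) if self.names else ("", "")
            rows.append(
                {
                    "rank": rank,
                    "feature": name,
                    "electrode": electrode,
                    "family": family,
                    "score": self.scores[rank - 1],
                    "relevance": self.relevance[j],
                }
            )
        return pd.DataFrame(rows)


def mrmr_rank(
    features: DiscretizedFeatures,
    labels: np.ndarray,
    k: int | None = None,
    redundancy_weight: float = 1.0,
    names: list[str] | None = None,
) -> FeatureRanking:
    """Greedy forward MRMR selection of ``k`` features.

    Ties are broken toward the lower feature index (argmax of the criterion
    returns the first maximizer), making the ranking deterministic.
    ``redundancy_weight=0`` reduces to sorting by relevance.
    """
    y = np.asarray(labels)
    codes = features.codes
    n, p = codes.shape
    if len(y) != n:
        raise ValueError("labels length must match feature rows")
    if k is None:
        k = p
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")

    relevance = _mi_against_all(codes, np.unique(y, return_inverse=True)[1])
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    for step in range(k):
        if step == 0:
            crit = relevance.copy()
        else:
            crit = relevance - redundancy_weight * redundancy_sum / step
        crit[~available] = -np.inf
        j = int(np.argmax(crit))
        selected.append(j)
        scores.append(float(crit[j]))
        available[j] = False
        if step < k - 1:
            redundancy_sum += _mi_against_all(codes, codes[:, j])
    return FeatureRanking(
        order=np.array(selected),
        scores=np.array(scores),
        relevance=relevance,
        names=names,
    )


def aggregate_top_electrodes(
    rankings: list[FeatureRanking], top_n: int = 20
) -> pd.DataFrame:
    """Cohort-level top-n features by appearance count in subjects' top-n lists.

    Each subject votes for its own top ``top_n`` features; features are then
    ordered by number of votes (ties by mean within-list rank, then feature
    index) and the leading ``top_n`` returned with electrode/family labels.
    """
    if not rankings:
        raise ValueError("need at least one ranking to aggregate")
    p = len(rankings[0].relevance)
    if not 1 <= top_n <= p:
        raise ValueError(f"top_n must be in [1, {p}]")
    counts = np.zeros(p, dtype=int)
    rank_sums = np.zeros(p, dtype=float)
    for r in rankings:
        for pos, j in enumerate(r.top(top_n), start=1):
            counts[j] += 1
            rank_sums[j] += pos
    with np.errstate(invalid="ignore"):
        mean_rank = np.where(counts > 0, rank_sums / np.maximum(counts, 1), np.inf)
    order = sorted(range(p), key=lambda j: (-counts[j], mean_rank[j], j))[:top_n]
    names = rankings[0].names
    rows = []
    for pos, j in enumerate(order, start=1):
        name = names[j] if names else str(j)
        electrode, family = parse_feature_name(name) if names else ("", "")
        rows.append(
            {
                "rank": pos,
                "feature": name,
                "electrode": electrode,
                "family": family,
                "n_subjects": counts[j],
                "mean_rank": mean_rank[j] if counts[j] else np.nan,
            }
        )
    return pd.DataFrame(rows)
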