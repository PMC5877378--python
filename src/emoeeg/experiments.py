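"""Cohort-level recovery experiments on synthetic data.

These are the package's standard validation experiments: simulate a
cohort with known gamma-band class effects, run the full pipeline, and
ask whether each stage recovers what was injected — the effect channels
in the MRMR top list, above-chance within-paradigm classification,
chance-level behaviour when the effect is switched off, monotone
cross-paradigm transfer in the recall attenuation, and the
feature-count/accuracy trade-off.  Both the test suite and the analysis
scripts drive the same functions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import classify
from .features import feature_columns
from .pipeline import PipelineConfig, rank_subject, subject_features
from .selection import FeatureRanking, aggregate_top_electrodes
from .simulate import SimConfig


def make_protocol_frame(
    rng: np.random.Generator,
    epochs_per_clip: int = 49,
    n_features: int = 20,
    n_clips_per_emotion: int = 3,
    separation: float = 0.0,
    paradigm: str = "movie",
    subject: str = "S01",
) -> pd.DataFrame:
    """A synthetic feature matrix with the study's clip/label structure.

    Features are standard normal; ``separation`` adds the class index to
    the first feature, making labels linearly encodable when > 0.  Used
    for structural protocol checks that need no EEG signal.
    """
    from .recording import EMOTIONS

    rows, feats = [], []
    clip = 0
    for ei, emotion in enumerate(EMOTIONS):
        for _ in range(n_clips_per_emotion):
            clip += 1
            for k in range(epochs_per_clip):
                rows.append(
                    {
                        "subject": subject,
                        "paradigm": paradigm,
                        "clip_id": clip,
                        "emotion": emotion,
                        "trial_index": clip - 1,
                        "onset_s": float(k),
                    }
                )
                x = rng.standard_normal(n_features)
                x[0] += separation * ei
                feats.append(x)
    frame = pd.DataFrame(rows)
    cols = pd.DataFrame(np.array(feats), columns=[f"Ch{j}_F_{j}" for j in range(n_features)])
    return pd.concat([frame, cols], axis=1)


@dataclass(frozen=True)
class RecoveryConfig:
    """Problem sizes for the standard recovery experiments.

    The trial structure (18 + 18 trials, 6 emotions, 61 channels, 512 Hz)
    matches the emulated protocol; the analysis span per trial and the
    cohort size are reduced relative to the full study (50 s, 30 subjects)
    to keep a complete multi-cohort validation run in the minutes range.
    """

    n_subjects: int = 5
    trial_seconds: float = 30.0
    seed: int = 1
    effect_size: float = 1.0
    blink_rate: float = 6.0
    use_ica: bool = True
    top_n: int = 20

    def sim(self, **overrides) -> SimConfig:
        kw = dict(
            n_subjects=self.n_subjects,
            trial_seconds=self.trial_seconds,
            trial_margin_seconds=10.0,
            pre_trial_seconds=5.0,
            rest_seconds=60.0,
            effect_size=self.effect_size,
            blink_rate=self.blink_rate,
            seed=self.seed,
        )
        kw.update(overrides)
        return SimConfig(**kw)

    def pipeline(self, **sim_overrides) -> PipelineConfig:
        return PipelineConfig(
            sim=self.sim(**sim_overrides), use_ica=self.use_ica, seed=self.seed
        )


def cohort_features(pipe: PipelineConfig, subjects: list[int] | None = None) -> list[pd.DataFrame]:
    """Per-subject feature matrices for a simulated cohort."""
    subjects = subjects or list(range(1, pipe.sim.n_subjects + 1))
    return [subject_features(pipe, sid)[0] for sid in subjects]


def effect_channel_recovery(
    frames: list[pd.DataFrame],
    paradigm: str,
    effect_channels: tuple[str, ...],
    effect_band: str = "gamma",
    top_n: int = 20,
) -> dict:
    """Do the injected channels' band-DE features reach the aggregated top list?"""
    rankings: list[FeatureRanking] = []
    for frame in frames:
        sub = frame.loc[frame["paradigm"] == paradigm]
        rankings.append(rank_subject(sub, k=top_n))
    agg = aggregate_top_electrodes(rankings, top_n)
    wanted = {f"{ch}_DE_{effect_band}" for ch in effect_channels}
    found = sorted(wanted & set(agg["feature"]))
    return {
        "aggregated": agg,
        "wanted": sorted(wanted),
        "found": found,
        "n_found": len(found),
    }


def within_binary(frames: list[pd.DataFrame], paradigm: str) -> classify.ClassificationReport:
    results = []
    for frame in frames:
        sub = frame.loc[frame["paradigm"] == paradigm].reset_index(drop=True)
        results.append(classify.binary_leave_one_clip_out(sub))
    return classify.summarize(f"within_{paradigm}", "binary", results)


def clip_level_chance_interval(
    n_folds: int, chance_rate: float, confidence: float = 0.95
) -> tuple[float, float]:
    """Chance band for fold-averaged accuracy, in percent.

    Epochs within a clip are strongly correlated, so the effective unit of
    the chance process is the held-out clip: each fold is right with
    probability ``chance_rate`` under label-independent features.  The
    band is the binomial interval on the fraction of correct folds.
    """
    lo, hi = stats.binom.interval(confidence, n_folds, chance_rate)
    return 100.0 * lo / n_folds, 100.0 * hi / n_folds


def expected_chance_agreement(report: classify.ClassificationReport) -> float:
    """Chance accuracy from the classifier's own prediction marginals.

    A classifier trained on label-independent features is not a pure
    majority-class predictor — it still emits some minority-class guesses.
    The agreement such a classifier achieves by chance is the
    marginal-agreement rate familiar from Cohen's kappa,
    ``p_e = sum_c q_pred(c) * p_true(c)``, computed from the pooled
    confusion matrix.
    """
    M = report.confusion.to_numpy(dtype=float)
    total = M.sum()
    q_pred = M.sum(axis=1) / total
    p_true = M.sum(axis=0) / total
    return float(q_pred @ p_true)


def chance_experiment(base: RecoveryConfig) -> dict:
    """Re-run the binary protocol with the class effect switched off.

    The observed accuracy is compared with the clip-level binomial band
    around the expected chance agreement ``p_e``.  Blinks and ICA are also
    switched off here: they are label-independent and only add runtime to
    a chance-level measurement.
    """
    pipe = dataclasses.replace(base, use_ica=False).pipeline(
        effect_size=0.0, blink_rate=0.0
    )
    frames = cohort_features(pipe)
    report = within_binary(frames, "movie")
    n_folds = len(report.subject_accuracies) * 15
    p_e = expected_chance_agreement(report)
    lo, hi = clip_level_chance_interval(n_folds, p_e)
    return {
        "report": report,
        "accuracy": report.mean_accuracy,
        "expected_chance": 100.0 * p_e,
        "chance_interval": (lo, hi),
        "within_interval": lo <= report.mean_accuracy <= hi,
    }


def attenuation_curve(
    base: RecoveryConfig, attenuations=(0.3, 0.7, 1.0), n_subjects: int = 3
) -> dict[float, float]:
    """Cross-paradigm binary accuracy as a function of recall attenuation.

    The movie-side signal is identical across attenuation levels (same
    seeds); only the recall copy of the class effect changes, so the curve
    isolates the transfer penalty.  Runs without blinks/ICA for the same
    reason as :func:`chance_experiment`.
    """
    curve: dict[float, float] = {}
    for a in attenuations:
        pipe = dataclasses.replace(base, use_ica=False, n_subjects=n_subjects).pipeline(
            recall_attenuation=a, blink_rate=0.0
        )
        frames = cohort_features(pipe)
        results = []
        for frame in frames:
            movie = frame.loc[frame["paradigm"] == "movie"].reset_index(drop=True)
            recall = frame.loc[frame["paradigm"] == "recall"].reset_index(drop=True)
            results.append(classify.cross_paradigm(movie, recall, scheme="binary"))
        curve[a] = classify.summarize("cross_paradigm", "binary", results).mean_accuracy
    return curve


def topk_accuracy_comparison(
    frames: list[pd.DataFrame], paradigm: str, k: int = 10
) -> dict:
    """Binary accuracy with the subject's top-k MRMR features versus all.

    The ranking is computed per subject on that subject's full feature
    matrix (the subject-dependent design of the accuracy-vs-feature-count
    curve), then the leave-one-clip-out protocol runs on the reduced and
    the full feature sets.
    """
    accs_k, accs_all = [], []
    for frame in frames:
        sub = frame.loc[frame["paradigm"] == paradigm].reset_index(drop=True)
        ranking = rank_subject(sub, k=k)
        cols = feature_columns(sub)
        top_cols = [cols[j] for j in ranking.top(k)]
        accs_k.append(classify.binary_leave_one_clip_out(sub, cols=top_cols).accuracy)
        accs_all.append(classify.binary_leave_one_clip_out(sub).accuracy)
    return {
        "topk": float(np.mean(accs_k)),
        "all": float(np.mean(accs_all)),
        "per_subject_topk": accs_k,
        "per_subject_all": accs_all,
        "k": k,
    }
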