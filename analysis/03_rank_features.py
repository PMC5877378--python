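#!/usr/bin/env python
"""MRMR feature ranking per subject; aggregate the cohort top-20 lists.

For each paradigm, features are discretized at mu +/- sigma, ranked per
subject by the greedy relevance-minus-redundancy criterion, and the
per-subject top-20 lists are pooled by appearance count — the analogue of
a subject-independent important-electrode table.  Prints which injected
effect channels (ground truth: T7, T8, TP8, AF7, O1 in the gamma band)
were recovered.
"""

from pathlib import Path

from emoeeg import io
from emoeeg.layout import DEFAULT_EFFECT_CHANNELS
from emoeeg.pipeline import rank_subject
from emoeeg.selection import aggregate_top_electrodes

IN = Path("results/features")
OUT = Path("results/ranking")
TOP_N = 20


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = [io.read_features(p) for p in sorted(IN.glob("S*.csv"))]
    for paradigm in ("movie", "recall"):
        rankings = []
        for frame in frames:
            sub = frame.loc[frame["paradigm"] == paradigm]
            rankings.append(rank_subject(sub, k=TOP_N))
        agg = aggregate_top_electrodes(rankings, TOP_N)
        agg.to_csv(OUT / f"top{TOP_N}_{paradigm}.csv", index=False)
        wanted = {f"{ch}_DE_gamma" for ch in DEFAULT_EFFECT_CHANNELS}
        found = sorted(wanted & set(agg["feature"]))
        print(f"\n{paradigm}: aggregated top {TOP_N}")
        print(agg[["rank", "feature", "n_subjects"]].to_string(index=False))
        print(f"effect-channel gamma DEs recovered: {len(found)}/{len(wanted)} {found}")


if __name__ == "__main__":
    main()
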