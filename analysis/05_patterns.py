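#!/usr/bin/env python
"""Per-class neural-pattern summaries of the recall (self-induced) epochs.

Computes class-mean topographies for the gamma-band DE and the EMD D_t
feature families, five-number distribution summaries for the ten
top-ranked features, and an interpolated scalp grid for the joy / gamma
map.  Writes CSVs under results/patterns/ and prints the class ordering
at the injected effect channels.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from emoeeg import io
from emoeeg.layout import standard_layout
from emoeeg.patterns import class_topography, cohort_topographies, feature_distribution, interpolate_scalp
from emoeeg.recording import EMOTIONS

IN = Path("results/features")
OUT = Path("results/patterns")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = [io.read_features(p) for p in sorted(IN.glob("S*.csv"))]
    cohort = pd.concat(frames, ignore_index=True)
    recall = cohort.loc[cohort["paradigm"] == "recall"]
    layout = standard_layout()

    topo = cohort_topographies(recall, layout, families=["DE_gamma", "EMD_Dt"])
    topo.to_csv(OUT / "topographies_recall.csv", index=False)

    t7 = topo.loc[(topo["family"] == "DE_gamma") & (topo["electrode"] == "T7")]
    order = t7.sort_values("value", ascending=False)
    print("gamma DE at T7, classes high to low:",
          ", ".join(f"{r.emotion} ({r.value:.2f})" for r in order.itertuples()))
    af7 = topo.loc[(topo["family"] == "DE_gamma") & (topo["electrode"] == "AF7")]
    print("gamma DE at AF7, top class:",
          af7.sort_values('value').iloc[-1]["emotion"])

    ranking_csv = Path("results/ranking/top20_recall.csv")
    if ranking_csv.exists():
        top = pd.read_csv(ranking_csv)["feature"].head(10)
        summaries = {f: feature_distribution(recall, f) for f in top}
        pd.concat(summaries, names=["feature"]).to_csv(OUT / "top10_feature_distributions.csv")
        print(f"wrote five-number summaries for {len(summaries)} top features")

    joy_map = class_topography(recall, "DE_gamma", "joy", layout)
    grid, mask = interpolate_scalp(joy_map, resolution=64)
    np.savetxt(OUT / "joy_gamma_grid.csv", np.where(mask, grid, np.nan), delimiter=",", fmt="%.4f")
    print(f"joy/gamma interpolated grid: {mask.sum()} head-disc nodes, "
          f"range [{np.nanmin(grid):.2f}, {np.nanmax(grid):.2f}]")

    neutral_low = all(
        class_topography(recall, "DE_gamma", "neutral", layout).values[layout.index(ch)]
        <= min(
            class_topography(recall, "DE_gamma", e, layout).values[layout.index(ch)]
            for e in EMOTIONS if e != "neutral"
        )
        for ch in ("T7", "T8", "O1")
    )
    print("neutral lowest gamma DE at T7/T8/O1:", neutral_low)


if __name__ == "__main__":
    main()
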