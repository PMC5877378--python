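"""Independent brute-force oracle for the greedy MRMR ranking.

Kept outside the package on purpose: it recomputes the selection
criterion literally at every step, sharing no code path with
``emoeeg.selection.mrmr_rank``.
"""

from __future__ import annotations

import numpy as np

from emoeeg.selection import mutual_information


def brute_force_mrmr(codes: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    p = codes.shape[1]
    selected: list[int] = []
    for _ in range(k):
        best, best_val = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            rel = mutual_information(codes[:, j], y)
            red = (
                np.mean([mutual_information(codes[:, j], codes[:, i]) for i in selected])
                if selected
                else 0.0
            )
            val = rel - red
            if val > best_val + 1e-12:
                best, best_val = j, val
        selected.append(best)
    return selected
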