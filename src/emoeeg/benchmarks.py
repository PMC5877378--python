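"""Published benchmark numbers from the 30-participant study this package
models, used as worked examples for the evaluation metrics.

The study reported three binary tasks — movie-induced recognition,
self-induced (recall) recognition, and prediction of self-induced emotion
by a movie-trained model — as pooled predicted x true confusion matrices
over 30 subjects x 15 clips x 49 epochs = 22 050 test epochs, plus
per-participant six-class accuracies.  The original EEG recordings are
not public; these tables are the study's printed summary statistics and
serve as exact inputs for :func:`emoeeg.classify.metrics_from_confusion`
and for column averaging, not as outputs of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CLASSES = ["positive", "negative"]

#: pooled binary confusion matrices, rows = predicted, columns = true
BINARY_CONFUSIONS = {
    "movie": pd.DataFrame([[2788, 1200], [1622, 16440]], index=CLASSES, columns=CLASSES),
    "self": pd.DataFrame([[2667, 1044], [1743, 16596]], index=CLASSES, columns=CLASSES),
    "cross": pd.DataFrame([[2578, 2902], [1832, 14738]], index=CLASSES, columns=CLASSES),
}

#: per-participant six-class accuracies (%), tasks as columns
SIX_CLASS_ACCURACIES = pd.DataFrame(
    {
        "movie": [
            65.65, 65.87, 56.01, 39.68, 51.93, 55.10, 57.03, 72.45, 41.27, 52.39,
            56.92, 60.32, 39.46, 41.38, 54.42, 43.65, 42.52, 65.99, 49.89, 60.20,
            73.24, 41.27, 60.54, 58.50, 51.70, 81.52, 62.13, 55.22, 59.52, 53.63,
        ],
        "self": [
            63.04, 56.24, 63.72, 57.71, 50.45, 53.74, 40.82, 71.77, 64.29, 39.57,
            52.95, 54.20, 46.15, 58.05, 56.69, 40.82, 60.66, 44.67, 64.29, 55.33,
            70.52, 41.16, 29.59, 58.50, 47.05, 82.54, 64.63, 49.43, 44.78, 52.38,
        ],
        "cross": [
            65.65, 47.28, 50.00, 66.55, 69.05, 42.06, 33.79, 47.51, 40.93, 54.20,
            39.68, 46.94, 40.36, 64.51, 41.27, 41.95, 46.71, 51.25, 56.92, 31.07,
            29.48, 42.74, 48.64, 60.54, 26.76, 85.94, 51.47, 48.30, 69.16, 56.92,
        ],
    },
    index=pd.RangeIndex(1, 31, name="participant"),
)


def six_class_column_mean(task: str) -> float:
    """Average of the 30 per-participant six-class accuracies for a task."""
    return float(np.mean(SIX_CLASS_ACCURACIES[task]))
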