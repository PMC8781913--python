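"""Published reference tables of the white-asparagus LC-MS authentication study.

These are inputs, not results: the out-of-bag confusion matrices for the
two classification levels (geographical origin, 317 samples in 5 classes;
botanical variety, 150 samples in 4 classes), the per-year sample counts,
and the preprocessed feature-table width used to derive forest parameters.
They let the metric computations be exercised against published numbers
without access to the underlying raw data.
"""

from __future__ import annotations

import pandas as pd

from .evaluation import ConfusionMatrix

ORIGIN_CLASSES = ["Germany", "Greece", "Netherlands", "Peru", "Poland"]
VARIETY_CLASSES = ["Backlim", "Cumulus", "Gijnlim", "Grolim"]

#: published feature count after preprocessing (prevalence filter at 80%)
STUDY_N_FEATURES = 718


def origin_confusion() -> ConfusionMatrix:
    """OOB confusion matrix of the 5-class provenance model (rows = true)."""
    counts = [
        [196, 4, 5, 0, 8],
        [0, 23, 0, 0, 2],
        [5, 0, 23, 0, 3],
        [1, 0, 0, 11, 1],
        [7, 2, 3, 0, 23],
    ]
    return ConfusionMatrix(
        pd.DataFrame(counts, index=ORIGIN_CLASSES, columns=ORIGIN_CLASSES)
    )


def variety_confusion() -> ConfusionMatrix:
    """OOB confusion matrix of the 4-class variety model (rows = true).

    Cell values are reconciled with the published row/column totals and
    per-class metrics (every row sums to the class size of the 150-sample
    variety subset).
    """
    counts = [
        [41, 2, 6, 7],
        [3, 14, 3, 3],
        [9, 1, 31, 1],
        [3, 4, 3, 19],
    ]
    return ConfusionMatrix(
        pd.DataFrame(counts, index=VARIETY_CLASSES, columns=VARIETY_CLASSES)
    )


def origin_samples_per_year() -> pd.DataFrame:
    """Sample counts per origin class and harvest year."""
    data = {
        "Germany": [105, 77, 31],
        "Greece": [14, 7, 4],
        "Netherlands": [10, 10, 11],
        "Peru": [7, 4, 2],
        "Poland": [16, 11, 8],
    }
    return pd.DataFrame(data, index=[2016, 2017, 2018]).T


def variety_samples_per_year() -> pd.DataFrame:
    """Sample counts per variety class and harvest year."""
    data = {
        "Backlim": [33, 23],
        "Cumulus": [12, 11],
        "Gijnlim": [22, 20],
        "Grolim": [18, 11],
    }
    return pd.DataFrame(data, index=[2016, 2017]).T
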