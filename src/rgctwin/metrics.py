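"""Model evaluation metrics on repeated test responses."""

from __future__ import annotations

import numpy as np

from .stats import pearson


def correlation_to_mean(prediction: np.ndarray, repeats: np.ndarray) -> float:
    """Pearson correlation between a prediction and the repeat average.

    Unlike the single-trial correlation this can reach 1 for a perfect
    model as the repeat average converges to the true response.  A constant
    prediction is flagged and reported as 0.
    """
    repeats = np.atleast_2d(repeats)
    if repeats.shape[0] < 2:
        raise ValueError("need at least two repeats")
    return pearson(prediction, repeats.mean(axis=0))


def mean_single_trial_correlation(prediction: np.ndarray, repeats: np.ndarray) -> float:
    """Mean over repeats of the per-repeat Pearson correlation."""
    repeats = np.atleast_2d(repeats)
    if repeats.shape[0] < 2:
        raise ValueError("need at least two repeats")
    return float(np.mean([pearson(prediction, r) for r in repeats]))
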