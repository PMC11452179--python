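"""Trace preprocessing, firing-rate inference, and inclusion filtering.

Raw calcium traces are detrended with a third-order Savitzky-Golay filter
(60 s window), made non-negative by clipping at and subtracting the 2.5th
percentile, and normalised by the SD of the pre-stimulus segment.  Firing
rates are recovered either by ground-truth passthrough (for pipeline tests
against the simulator) or by inverting the exponential calcium kernel
(AR(1) deconvolution with a non-negativity clip), then resampled from
7.8125 Hz to 30 Hz by linear interpolation.

Cells enter the analyses through a fixed sequence of quality filters:

1. response reliability: QI_MB > 0.6 or QI_chirp > 0.35,
2./3. classifier confidence >= 0.25,
4. mean single-trial test correlation > 0.3,
5. (MEI-property analyses only) DoG fit cost < 0.11 in both channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .recording import ResponsePack, resample_linear


@dataclass
class DetrendedTrace:
    values: np.ndarray  # SD-normalised, non-negative
    eta_2_5: float  # 2.5th-percentile offset removed
    baseline_sd: float
    t0: int
    sampling_rate: float
    window_s: float = 60.0
    poly_order: int = 3


@dataclass
class InclusionThresholds:
    qi_mb: float = 0.6
    qi_chirp: float = 0.35
    confidence: float = 0.25
    test_corr: float = 0.3
    dog_cost: float = 0.11


@dataclass
class QualityReport:
    """Per-neuron quality metrics and the filter masks derived from them."""

    table: pd.DataFrame  # one row per neuron
    thresholds: InclusionThresholds = field(default_factory=InclusionThresholds)

    METRICS = (
        "qi_chirp",
        "qi_mb",
        "classifier_confidence",
        "test_corr_single_trial",
        "test_corr_to_mean",
        "dog_cost_green",
        "dog_cost_uv",
    )


def detrend_trace(
    raw: np.ndarray,
    sampling_rate: float,
    t0: int,
    window_s: float = 60.0,
    poly_order: int = 3,
) -> DetrendedTrace:
    """Detrend, clip, and SD-normalise one raw trace.

    Raises
    ------
    ValueError
        If the pre-stimulus segment has zero SD (degenerate trace) or the
        trace is shorter than the smoothing window.
    """
    raw = np.asarray(raw, dtype=float)
    window = int(round(window_s * sampling_rate))
    window += 1 - window % 2  # savgol needs an odd window
    if raw.size <= window:
        raise ValueError(f"trace length {raw.size} <= window {window}")
    if t0 <= 0:
        raise ValueError("t0 must be positive (need a pre-stimulus segment)")
    smooth = savgol_filter(raw, window_length=window, polyorder=poly_order)
    detrended = raw - smooth
    eta = float(np.percentile(detrended, 2.5))
    nonneg = np.clip(detrended, eta, None) - eta
    baseline_sd = float(nonneg[:t0].std())
    # tolerance absorbs float residue of filtering an exactly constant trace
    if baseline_sd <= 1e-12 * max(1.0, float(np.abs(raw).max())):
        raise ValueError("degenerate trace: zero pre-stimulus SD")
    return DetrendedTrace(
        values=nonneg / baseline_sd,
        eta_2_5=eta,
        baseline_sd=baseline_sd,
        t0=t0,
        sampling_rate=sampling_rate,
        window_s=window_s,
        poly_order=poly_order,
    )


def deconvolve_exponential(
    trace: np.ndarray, sampling_rate: float, calcium_tau: float
) -> np.ndarray:
    """Invert a unit-sum exponential calcium kernel (AR(1) model).

    For c[t] = (1-phi) * sum_d phi^d r[t-d] with phi = exp(-dt/tau), the
    rate is recovered as (c[t] - phi*c[t-1]) / (1-phi), clipped at zero.
    """
    phi = float(np.exp(-1.0 / (sampling_rate * calcium_tau)))
    r = np.empty_like(trace, dtype=float)
    r[0] = trace[0]
    r[1:] = (trace[1:] - phi * trace[:-1]) / (1.0 - phi)
    return np.clip(r, 0.0, None)


def infer_rates(
    trace: DetrendedTrace | np.ndarray,
    method: str = "nonneg_deconvolution",
    target_rate: float = 30.0,
    calcium_tau: float = 1.0,
    sampling_rate: float | None = None,
    ground_truth: np.ndarray | None = None,
    smooth_sigma_s: float = 0.2,
) -> np.ndarray:
    """Estimate a non-negative firing rate at ``target_rate`` Hz.

    ``ground_truth_passthrough`` returns the simulator's stored rates (for
    pipeline tests); ``nonneg_deconvolution`` inverts the exponential
    calcium kernel, applies a short Gaussian smoother (``smooth_sigma_s``
    seconds) to tame the noise amplification inherent in deconvolution,
    and resamples by linear interpolation.
    """
    if method == "ground_truth_passthrough":
        if ground_truth is None:
            raise ValueError("passthrough requires the ground-truth rates")
        return np.asarray(ground_truth, dtype=float)
    if method != "nonneg_deconvolution":
        raise ValueError(f"unknown rate-inference method: {method!r}")
    if isinstance(trace, DetrendedTrace):
        values, fs = trace.values, trace.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for raw array input")
        values, fs = np.asarray(trace, dtype=float), sampling_rate
    rates = deconvolve_exponential(values, fs, calcium_tau)
    if smooth_sigma_s > 0:
        from scipy.ndimage import gaussian_filter1d

        rates = gaussian_filter1d(rates, smooth_sigma_s * fs)
    return np.clip(resample_linear(rates, fs, target_rate), 0.0, None)


def quality_index(response_matrix: np.ndarray) -> float:
    """Repeat-reliability index in [0, 1].

    ``response_matrix`` is T x I (time samples by repetitions).  QI is the
    temporal variance of the repeat mean divided by the repeat mean of the
    temporal variances; identical repeats give 1, independent noise gives
    about 1/I.
    """
    r = np.asarray(response_matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need a T x I matrix with T >= 2 and I >= 2")
    num = r.mean(axis=1).var()
    den = r.var(axis=0).mean()
    if den == 0:
        warnings.warn("flat responses: QI denominator is zero, returning 0")
        return 0.0
    return float(num / den)


_STEPS = ("step1_quality", "step2_assigned", "step3_confidence", "step4_test_corr",
          "step5_dog_cost")


def apply_inclusion_filters(
    report: QualityReport, thresholds: InclusionThresholds | None = None
) -> pd.DataFrame:
    """Boolean masks per filter step, cumulative so masks are monotone.

    Steps 2 and 3 both stand on the classifier confidence (assignment to a
    group, then the >= 0.25 confidence threshold); with synthetic type
    labels every cell is "assigned", so step 2 passes whenever a confidence
    is present.
    """
    thr = thresholds or report.thresholds
    t = report.table
    for col in ("qi_mb", "qi_chirp", "classifier_confidence",
                "test_corr_single_trial"):
        if col not in t.columns:
            raise ValueError(f"quality report lacks {col!r} needed for filtering")
    masks = pd.DataFrame(index=t.index)
    masks["step1_quality"] = (t.qi_mb > thr.qi_mb) | (t.qi_chirp > thr.qi_chirp)
    masks["step2_assigned"] = masks.step1_quality & t.classifier_confidence.notna()
    masks["step3_confidence"] = masks.step2_assigned & (
        t.classifier_confidence >= thr.confidence
    )
    masks["step4_test_corr"] = masks.step3_confidence & (
        t.test_corr_single_trial > thr.test_corr
    )
    if {"dog_cost_green", "dog_cost_uv"}.issubset(t.columns):
        masks["step5_dog_cost"] = (
            masks.step4_test_corr
            & (t.dog_cost_green < thr.dog_cost)
            & (t.dog_cost_uv < thr.dog_cost)
        )
    return masks


def build_quality_report(
    pack: ResponsePack,
    predictions: np.ndarray | None = None,
    thresholds: InclusionThresholds | None = None,
) -> QualityReport:
    """Quality metrics for a synthetic recording.

    The synthetic recording has no chirp or moving-bar presentations; the
    repeated test sequence stands in for both, so ``qi_chirp`` and ``qi_mb``
    are the same repeat-reliability index.  Synthetic type labels come with
    confidence 1.0 (the external classifier is not part of this package).
    ``predictions`` (model rates on the test sequence, resampled to the
    trace rate) fills the test-correlation columns when given.
    """
    n = pack.n_cells
    qi = np.array([quality_index(pack.test_repeats[i].T) for i in range(n)])
    rows = {
        "cell_id": [c.cell_id for c in pack.cells],
        "family": [c.family for c in pack.cells],
        "qi_chirp": qi,
        "qi_mb": qi,
        "classifier_confidence": np.ones(n),
        "test_corr_single_trial": np.full(n, np.nan),
        "test_corr_to_mean": np.full(n, np.nan),
        "dog_cost_green": np.full(n, np.nan),
        "dog_cost_uv": np.full(n, np.nan),
    }
    table = pd.DataFrame(rows).set_index("cell_id")
    if predictions is not None:
        from .metrics import correlation_to_mean, mean_single_trial_correlation

        for i, cid in enumerate(table.index):
            reps = pack.test_repeats[i]
            pred = predictions[i]
            table.loc[cid, "test_corr_to_mean"] = correlation_to_mean(pred, reps)
            table.loc[cid, "test_corr_single_trial"] = mean_single_trial_correlation(
                pred, reps
            )
    return QualityReport(table=table, thresholds=thresholds or InclusionThresholds())
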