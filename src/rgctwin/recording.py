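"""Calcium-like recordings of the simulated population.

Ground-truth firing rates at the movie frame rate (30 Hz) are convolved with
an exponential calcium kernel, sampled at the two-photon line rate of
7.8125 Hz, and corrupted with slow sinusoidal drift plus white noise.  A
pre-stimulus baseline segment precedes the movie so that downstream trace
normalisation has a stimulus-free window, and the five-clip test sequence is
re-recorded three times with independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import SimulatedCell
from .stimuli import MovieStimulus

TRACE_RATE = 7.8125  # Hz


@dataclass
class RecordingConfig:
    trace_rate: float = TRACE_RATE
    #: exponential calcium decay time constant (s); None -> identity kernel
    calcium_tau: float | None = 1.0
    #: SD of additive white trace noise, in trace units (overrides per-cell
    #: noise_level when not None)
    noise_level: float | None = None
    drift_amplitude: float = 0.2
    drift_period_s: float = 120.0
    pre_stimulus_s: float = 30.0
    n_test_repeats: int = 3


@dataclass
class ResponsePack:
    """Traces, ground-truth rates and test repeats for one recording."""

    traces: np.ndarray  # [N, T_trace] at trace_rate, incl. pre-stimulus
    rates: np.ndarray  # [N, T_frames] ground truth at movie frame rate
    test_repeats: np.ndarray  # [N, n_repeats, T_test_trace]
    t0: int  # stimulus-start index into traces
    trace_rate: float
    frame_rate: float
    recording_id: str
    cells: list[SimulatedCell]
    config: RecordingConfig = field(default_factory=RecordingConfig)
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    def test_rates(self, movie: MovieStimulus) -> np.ndarray:
        """Ground-truth rates on the test clips, [N, T_test_frames]."""
        mask = ~movie.train_frame_mask
        return self.rates[:, mask]


def calcium_kernel(
    tau: float | None, frame_rate: float, length_s: float = 5.0
) -> np.ndarray:
    """Exponential kernel normalised to unit sum; identity if tau is None."""
    if tau is None:
        return np.array([1.0])
    t = np.arange(int(round(length_s * frame_rate))) / frame_rate
    k = np.exp(-t / tau)
    return k / k.sum()


def _convolve_causal(rates: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution along the last axis, same length as input."""
    if len(kernel) == 1:
        return rates * kernel[0]
    out = np.empty_like(rates)
    pad = np.zeros(len(kernel) - 1)
    for i in range(rates.shape[0]):
        out[i] = np.convolve(np.concatenate([pad, rates[i]]), kernel, mode="valid")
    return out


def resample_linear(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Linear-interpolation resampling along the last axis (t=0 aligned)."""
    t_in = np.arange(x.shape[-1]) / rate_in
    n_out = int(np.floor(t_in[-1] * rate_out)) + 1
    t_out = np.arange(n_out) / rate_out
    if x.ndim == 1:
        return np.interp(t_out, t_in, x)
    return np.stack([np.interp(t_out, t_in, row) for row in x])


def simulate_recording(
    cells: list[SimulatedCell],
    movie: MovieStimulus,
    seed: int = 0,
    config: RecordingConfig | None = None,
    recording_id: str = "synthetic-0",
) -> ResponsePack:
    """Record the population's responses to the movie.

    With ``noise_level == 0``, ``drift_amplitude == 0`` and an identity
    calcium kernel the traces are exact linearly-resampled rates.
    """
    config = config or RecordingConfig()
    rng = np.random.default_rng(seed)
    movie_z = movie.zscored()
    fr = movie.frame_rate
    if config.trace_rate > fr:
        raise ValueError("trace sampling rate exceeds the movie frame rate")

    n_pre = int(round(config.pre_stimulus_s * fr))
    kernel = calcium_kernel(config.calcium_tau, fr)

    rates = np.stack([c.rates(movie_z) for c in cells])  # [N, T]
    resting = np.array([c.resting_rate for c in cells])
    full = np.concatenate(
        [np.tile(resting[:, None], (1, n_pre)), rates], axis=1
    )
    clean = _convolve_causal(full, kernel)
    traces = resample_linear(clean, fr, config.trace_rate)
    t0 = int(np.ceil(n_pre / fr * config.trace_rate))

    T_trace = traces.shape[1]
    tt = np.arange(T_trace) / config.trace_rate
    noise_sd = np.array(
        [c.noise_level if config.noise_level is None else config.noise_level
         for c in cells]
    )
    for i in range(len(cells)):
        phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude * np.sin(
            2 * np.pi * tt / config.drift_period_s + phase
        )
        traces[i] = traces[i] + drift + noise_sd[i] * rng.standard_normal(T_trace)

    # test sequence re-recorded with independent noise
    test_mask = ~movie.train_frame_mask
    test_clean = _convolve_causal(rates[:, test_mask], kernel)
    test_trace_clean = resample_linear(test_clean, fr, config.trace_rate)
    reps = np.empty((len(cells), config.n_test_repeats, test_trace_clean.shape[1]))
    for r in range(config.n_test_repeats):
        reps[:, r] = test_trace_clean + noise_sd[:, None] * rng.standard_normal(
            test_trace_clean.shape
        )

    return ResponsePack(
        traces=traces,
        rates=rates,
        test_repeats=reps,
        t0=t0,
        trace_rate=config.trace_rate,
        frame_rate=fr,
        recording_id=recording_id,
        cells=cells,
        config=config,
        seed=seed,
    )
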