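"""Ground-truth simulated retinal ganglion cells.

Each simulated cell is a linear-nonlinear unit: a spatially localised,
chromatically weighted spatiotemporal filter followed by a static output
nonlinearity.  Five functional families are provided:

``ON``
    fast biphasic kernel, positive chromatic weights in both channels.
``OFF``
    the same, with negative chromatic weights.
``ON-OFF``
    full-wave rectified linear drive (responds to increments and decrements).
``slow-ON``
    like ON with a slower temporal kernel.
``opponent-SbC``
    a nonlinearly colour-opponent, suppressed-by-contrast unit: the UV
    drive is gain-modulated by the green drive through a sigmoidal gate
    (``z = w_uv * s_uv * 2 sigmoid(gate_gain * w_g * s_g)`` with
    ``w_g < 0``), the multiplicative motif of presynaptic inhibition.
    Green increments silence the UV pathway, green decrements double its
    gain, and -- because the green contrast enters only through a
    cross-term with the zero-mean UV drive -- a purely linear fit sees no
    first-order green component at movie contrasts.  The preferred
    stimulus is a UV-ON/green-OFF combination.

Filters are unit L2 norm per channel before the chromatic weighting, and
cells operate on the standardised (z-scored) movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import CANVAS, GREEN, UV

FAMILIES = ("ON", "OFF", "ON-OFF", "slow-ON", "opponent-SbC")


def biphasic_kernel(
    length: int = 21,
    frame_rate: float = 30.0,
    tau_fast: float = 0.05,
    tau_slow: float = 0.12,
    rebound: float = 0.85,
) -> np.ndarray:
    """Biphasic temporal kernel, index 0 = most recent frame, unit L2 norm.

    ``rebound`` is the fraction of the fast lobe's area cancelled by the
    slow opposing lobe, so the kernel keeps a net-positive integral (an ON
    step drives the cell positive in steady state) while staying transient.
    """
    t = np.arange(length) / frame_rate
    fast = (t / tau_fast) * np.exp(1 - t / tau_fast)
    slow = (t / tau_slow) * np.exp(1 - t / tau_slow)
    if slow.sum() > 0:
        slow = slow * (fast.sum() / slow.sum())  # match lobe areas on the grid
    k = fast - rebound * slow
    norm = np.linalg.norm(k)
    if norm == 0:
        raise ValueError("degenerate temporal kernel")
    return k / norm


def gaussian_rf(center: tuple[float, float], sigma: float, shape=CANVAS) -> np.ndarray:
    """Unit-L2-norm isotropic Gaussian spatial filter on the pixel canvas."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    g = np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)))
    return g / np.linalg.norm(g)


@dataclass
class SimulatedCell:
    """A ground-truth model neuron with a known response function."""

    cell_id: int
    family: str
    spatial_filter: np.ndarray  # [2, H, W], unit L2 per channel
    temporal_filter: np.ndarray  # [2, L], unit L2 per channel
    chromatic_weights: tuple[float, float]  # (w_green, w_UV), signed
    rf_location: tuple[float, float]  # (row, col) in pixel coordinates
    noise_level: float = 0.3
    gain: float = 1.0
    baseline: float = 0.5
    rate_scale: float = 4.0
    gate_gain: float = 1.5  # opponent-SbC green-gate steepness
    #: fixed normalising constant bringing the per-channel drive to ~unit SD
    #: under the default movie statistics
    drive_scale: float = 6.0

    def linear_drives(self, movie_z: np.ndarray) -> np.ndarray:
        """Per-channel spatiotemporal drive, shape [2, T].

        ``movie_z`` is the standardised movie, [2, T, H, W].  Causal
        convolution: the drive at frame t looks back over the kernel length.
        """
        drives = np.empty((2, movie_z.shape[1]))
        for c in range(2):
            spatial = np.tensordot(
                movie_z[c], self.spatial_filter[c], axes=([1, 2], [0, 1])
            )  # [T]
            k = self.temporal_filter[c]
            padded = np.concatenate([np.zeros(len(k) - 1), spatial])
            # s[t] = sum_d k[d] * spatial[t - d]
            drives[c] = np.convolve(padded, k, mode="valid")
        return drives / self.drive_scale

    def rates_from_drives(self, drives: np.ndarray) -> np.ndarray:
        """Apply chromatic weighting and the output nonlinearity; returns Hz."""
        w_g, w_uv = self.chromatic_weights
        if self.family == "opponent-SbC":
            # multiplicative green gate: w_g < 0, so green decrements raise
            # the gain of the UV pathway and green increments silence it
            gate = 2.0 / (1.0 + np.exp(-self.gate_gain * w_g * drives[GREEN]))
            z = w_uv * drives[UV] * gate
        elif self.family == "ON-OFF":
            z = np.abs(w_g * drives[GREEN] + w_uv * drives[UV])
        else:
            z = w_g * drives[GREEN] + w_uv * drives[UV]
        return self.rate_scale * _softplus(self.gain * z + self.baseline)

    def rates(self, movie_z: np.ndarray) -> np.ndarray:
        """Ground-truth firing rate (Hz) in response to a standardised movie."""
        return self.rates_from_drives(self.linear_drives(movie_z))

    @property
    def resting_rate(self) -> float:
        return float(self.rate_scale * _softplus(self.baseline))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class PopulationConfig:
    """Family counts and parameter ranges for the simulated population."""

    counts: dict = field(
        default_factory=lambda: {
            "ON": 8,
            "OFF": 8,
            "ON-OFF": 8,
            "slow-ON": 8,
            "opponent-SbC": 8,
        }
    )
    rf_sigma_range: tuple[float, float] = (1.6, 2.4)
    #: rf centres are kept this many pixels away from the canvas border so
    #: every RF lies strictly inside the model readout's field of view
    rf_margin: float = 6.0
    weight_jitter: float = 0.15
    noise_level: float = 0.3
    gate_gain: float = 1.5
    temporal_length: int = 21
    frame_rate: float = 30.0


_FAMILY_TAUS = {
    "ON": (0.05, 0.12),
    "OFF": (0.05, 0.12),
    "ON-OFF": (0.05, 0.12),
    "slow-ON": (0.15, 0.3),
    "opponent-SbC": (0.06, 0.14),
}

#: spontaneous-drive offsets; OFF cells keep a maintained discharge that
#: light increments suppress, the others sit at a low resting rate
_FAMILY_BASELINES = {
    "ON": 0.5,
    "OFF": 1.5,
    "ON-OFF": 0.5,
    "slow-ON": 0.5,
    "opponent-SbC": 0.5,
}


def generate_population(
    config: PopulationConfig | None = None, seed: int = 0
) -> list[SimulatedCell]:
    """Generate ground-truth cells; deterministic given ``(config, seed)``.

    Opponent-SbC cells always have ``sign(w_green) = -sign(w_UV)``; all other
    families have same-sign chromatic weights.
    """
    config = config or PopulationConfig()
    if not config.counts or sum(config.counts.values()) == 0:
        raise ValueError("population config lists no cells")
    unknown = set(config.counts) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    H, W = CANVAS
    m = config.rf_margin
    cells: list[SimulatedCell] = []
    cell_id = 0
    for family in FAMILIES:
        for _ in range(config.counts.get(family, 0)):
            loc = (rng.uniform(m, H - 1 - m), rng.uniform(m, W - 1 - m))
            sigma = rng.uniform(*config.rf_sigma_range)
            spatial = np.stack([gaussian_rf(loc, sigma), gaussian_rf(loc, sigma)])
            tau_fast, tau_slow = _FAMILY_TAUS[family]
            k = biphasic_kernel(
                config.temporal_length, config.frame_rate, tau_fast, tau_slow
            )
            temporal = np.stack([k, k])
            jit = 1.0 + config.weight_jitter * rng.standard_normal(2)
            jit = np.clip(jit, 0.5, 1.5)
            if family == "OFF":
                w = (-jit[0], -jit[1])
            elif family == "opponent-SbC":
                w = (-jit[0], jit[1])
            else:
                w = (jit[0], jit[1])
            cells.append(
                SimulatedCell(
                    cell_id=cell_id,
                    family=family,
                    spatial_filter=spatial,
                    temporal_filter=temporal,
                    chromatic_weights=(float(w[0]), float(w[1])),
                    rf_location=loc,
                    noise_level=config.noise_level,
                    baseline=_FAMILY_BASELINES[family],
                    gate_gain=config.gate_gain,
                )
            )
            cell_id += 1
    return cells
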