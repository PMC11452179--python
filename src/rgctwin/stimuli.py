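"""Clip-structured dichromatic movie stimuli.

The stimulus emulated here is a two-channel (green/UV) natural-movie proxy:
113 five-second clips at 30 Hz, spatially downsampled to 18 x 16 pixels.
Each clip carries a chromatic context label -- ``sky`` clips have a higher
mean intensity in the UV channel than in the green channel, ``ground`` clips
the reverse -- so that ground-to-sky clip transitions fall in the
UV-positive / green-negative contrast quadrant.  Within a clip, spatiotemporal
texture is low-pass-filtered Gaussian noise around the clip's per-channel
mean intensity; clip means are drawn uniformly from a stated intensity range.

Channels are indexed 0 = green, 1 = UV throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

GREEN, UV = 0, 1

#: canvas size (rows, columns) after downsampling
CANVAS = (18, 16)


@dataclass
class MovieConfig:
    """Parameters of the synthetic dichromatic movie.

    Defaults reproduce the study conditions: 113 clips of 150 frames at
    30 Hz, five of which form the repeated test sequence, and per-clip mean
    intensities drawn uniformly in [0.04, 0.22] (intensities in [0, 1]).
    """

    n_clips: int = 113
    n_test_clips: int = 5
    clip_length: int = 150
    frame_rate: float = 30.0
    height: int = CANVAS[0]
    width: int = CANVAS[1]
    mean_range: tuple[float, float] = (0.04, 0.22)
    #: SD of the zero-mean texture added around each clip mean
    texture_amplitude: float = 0.04
    #: Gaussian smoothing sigmas (frames, rows, cols) applied to the texture;
    #: mild temporal smoothing keeps the movie broadband in time so model
    #: behaviour is constrained across the frequency range the cells respond to
    texture_sigma: tuple[float, float, float] = (0.8, 2.0, 2.0)
    #: probability that a clip is a "sky" clip
    p_sky: float = 0.5
    #: number of presentations of the test sequence
    n_test_repeats: int = 3
    #: alternate upper/lower visual-field crop locations (off by default)
    alternate_crops: bool = False


@dataclass
class MovieStimulus:
    """A generated movie plus its train/test bookkeeping.

    ``frames`` holds each unique clip exactly once (training clips first,
    then the test clips); the three presentations of the test sequence share
    these frames and differ only in recording noise downstream.
    """

    frames: np.ndarray  # [2, T, H, W]
    frame_rate: float
    clip_length: int
    clip_ids: np.ndarray  # [T] int, per frame
    clip_labels: np.ndarray  # [n_clips] of {"sky", "ground"}
    split: np.ndarray  # [n_clips] of {"train", "test"}
    test_repeat_index: np.ndarray  # [n_test_repeats] presentation indices
    intensity_range: np.ndarray  # [2, 2] per-channel (min, max) over train frames
    config: MovieConfig = field(default_factory=MovieConfig)
    seed: int | None = None

    @property
    def n_clips(self) -> int:
        return len(self.clip_labels)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    def clip_slice(self, clip_index: int) -> slice:
        start = clip_index * self.clip_length
        return slice(start, start + self.clip_length)

    @property
    def train_clip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.split == "train")

    @property
    def test_clip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.split == "test")

    @property
    def train_frame_mask(self) -> np.ndarray:
        return np.isin(self.clip_ids, self.train_clip_indices)

    def train_frames(self) -> np.ndarray:
        return self.frames[:, self.train_frame_mask]

    def test_frames(self) -> np.ndarray:
        return self.frames[:, ~self.train_frame_mask]

    def clip_means(self) -> np.ndarray:
        """Per-clip, per-channel mean intensity, shape [n_clips, 2]."""
        T = self.n_frames
        means = np.empty((self.n_clips, 2))
        for k in range(self.n_clips):
            sl = self.clip_slice(k)
            means[k] = self.frames[:, sl].mean(axis=(1, 2, 3))
        return means

    def zscore_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel mean and SD over the training frames.

        These are the statistics used to standardise the movie before it is
        shown to model neurons, and to map model-space stimuli back to
        display units.
        """
        tr = self.train_frames()
        mean = tr.mean(axis=(1, 2, 3))
        sd = tr.std(axis=(1, 2, 3))
        return mean, sd

    def zscored(self) -> np.ndarray:
        mean, sd = self.zscore_stats()
        return (self.frames - mean[:, None, None, None]) / sd[:, None, None, None]

    def zscored_range(self) -> np.ndarray:
        """Per-channel (min, max) of the standardised training frames."""
        mean, sd = self.zscore_stats()
        lo = (self.intensity_range[:, 0] - mean) / sd
        hi = (self.intensity_range[:, 1] - mean) / sd
        return np.stack([lo, hi], axis=1)


def generate_movie(config: MovieConfig | None = None, seed: int = 0) -> MovieStimulus:
    """Generate a clip-structured dichromatic movie.

    Deterministic given ``(config, seed)``.  Sky clips receive the larger of
    two mean-intensity draws in the UV channel, ground clips in the green
    channel, which fixes the sign of the mean UV-green difference per label.

    Raises
    ------
    ValueError
        If the configuration cannot form a test set (fewer than
        ``n_test_clips + 1`` clips).
    """
    config = config or MovieConfig()
    if config.n_clips <= config.n_test_clips:
        raise ValueError(
            f"need more than {config.n_test_clips} clips to form a "
            f"{config.n_test_clips}-clip test set, got {config.n_clips}"
        )
    rng = np.random.default_rng(seed)
    n, L = config.n_clips, config.clip_length
    H, W = config.height, config.width

    labels = np.where(rng.random(n) < config.p_sky, "sky", "ground")
    lo, hi = config.mean_range
    mid = 0.5 * (lo + hi)
    # the label's dominant channel draws from the upper half of the range,
    # the other channel from the lower half, so chromatic contrast keeps a
    # consistent sign across any ground/sky clip pairing
    dominant = rng.uniform(mid, hi, size=n)
    recessive = rng.uniform(lo, mid, size=n)
    clip_means = np.empty((n, 2))  # [clip, channel]
    for k in range(n):
        if labels[k] == "sky":
            clip_means[k, UV], clip_means[k, GREEN] = dominant[k], recessive[k]
        else:
            clip_means[k, UV], clip_means[k, GREEN] = recessive[k], dominant[k]

    frames = np.empty((2, n * L, H, W), dtype=np.float64)
    for k in range(n):
        texture = rng.standard_normal((2, L, H, W))
        if config.texture_amplitude > 0:
            for c in range(2):
                texture[c] = gaussian_filter(texture[c], sigma=config.texture_sigma)
                sd = texture[c].std()
                if sd > 0:
                    texture[c] /= sd
            # remove the empirical mean so the clip mean is exactly the draw
            texture -= texture.mean(axis=(1, 2, 3), keepdims=True)
            texture *= config.texture_amplitude
        else:
            texture[:] = 0.0
        frames[:, k * L : (k + 1) * L] = clip_means[k][:, None, None, None] + texture

    # training clips first, then the held-out test clips
    split = np.array(["train"] * n, dtype=object)
    split[n - config.n_test_clips :] = "test"
    split = split.astype(str)
    clip_ids = np.repeat(np.arange(n), L)

    train_mask = np.isin(clip_ids, np.flatnonzero(split == "train"))
    tr = frames[:, train_mask]
    intensity_range = np.stack(
        [tr.min(axis=(1, 2, 3)), tr.max(axis=(1, 2, 3))], axis=1
    )

    return MovieStimulus(
        frames=frames,
        frame_rate=config.frame_rate,
        clip_length=L,
        clip_ids=clip_ids,
        clip_labels=labels,
        split=split,
        test_repeat_index=np.arange(config.n_test_repeats),
        intensity_range=intensity_range,
        config=config,
        seed=seed,
    )


def movie_config_to_dict(config: MovieConfig) -> dict:
    return asdict(config)
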