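"""In-silico MEI validation: rank-1 stimuli, the grid experiment, and SI.

MEIs are reconstructed as presentable rank-1 tensors (outer product of the
first singular pair per channel), mapped back from model (z-scored) space
to display units, and presented on a 5 x 5 spatial grid to every cell.
Responses are Gaussian-weighted by each cell's readout, time-averaged in
the optimisation window, and summarised as a selectivity index: the
standardised response to a cell's own MEI minus the mean standardised
response to the other MEIs.

A 2 x 2 chromatic calibration transform (x' = B^-1 A x) maps stimuli
between display setups with different LED/cone cross-activation, followed
by an affine range restoration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mei import MEIDecomposition

SETUP_A = np.array([[1.0, 0.19], [0.0, 1.0]])
SETUP_B = np.array([[1.0, 0.9], [0.035, 1.0]])


@dataclass
class SetupCalibration:
    """Relative M/S-cone activation matrices of two display setups."""

    A: np.ndarray = field(default_factory=lambda: SETUP_A.copy())
    B: np.ndarray = field(default_factory=lambda: SETUP_B.copy())

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.B)) < 1e-12:
            raise ValueError("setup matrix B is singular")


def reconstruct_rank1(
    decomp: MEIDecomposition,
    movie_mean: np.ndarray | None = None,
    movie_sd: np.ndarray | None = None,
    display_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Rank-1 reconstruction S11 * (temporal x spatial) per channel.

    Without movie statistics the reconstruction stays in model (z-scored)
    units; with them it is de-z-scored (scaled by the movie SD, shifted by
    the movie mean, both per channel) and mapped to the display range by
    treating intensity 0..1 as display 0..255, clipping the rare values
    that stray outside.
    """
    C = decomp.spatial.shape[0]
    out = np.stack(
        [
            decomp.singular_values[c]
            * np.einsum("t,ij->tij", decomp.temporal[c], decomp.spatial[c])
            for c in range(C)
        ]
    )
    if movie_mean is None:
        return out
    lo, hi = display_range
    intens = out * np.asarray(movie_sd)[:, None, None, None] + np.asarray(
        movie_mean
    )[:, None, None, None]
    return np.clip(lo + intens * (hi - lo), lo, hi)


def setup_transform(
    x: np.ndarray,
    cal: SetupCalibration | None = None,
    restore_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Chromatic re-calibration x' = B^-1 A x between display setups.

    ``x`` is a 2-vector or any array whose leading axis is the (green, UV)
    channel.  ``restore_range`` optionally applies the affine offset/gain
    that maps the transformed values back into the display range.
    """
    cal = cal or SetupCalibration()
    M = np.linalg.solve(cal.B, cal.A)
    flat = x.reshape(2, -1)
    out = (M @ flat).reshape(x.shape)
    if restore_range is not None:
        lo, hi = restore_range
        omin, omax = out.min(), out.max()
        if omax > omin:
            out = lo + (out - omin) * (hi - lo) / (omax - omin)
    return out


@dataclass
class GridExperiment:
    """Presentation protocol for MEI stimuli on a spatial grid."""

    n_grid: int = 5
    grid_span_um: float = 110.0
    stimulus_frames: int = 50
    grey_frames: int = 10  # inter-stimulus grey appended after each stimulus
    frame_rate: float = 30.0
    order_seed: int = 0

    @property
    def frames_per_presentation(self) -> int:
        return self.stimulus_frames + self.grey_frames

    def total_duration_s(self, n_stimuli: int = 11) -> float:
        """Total duration: n_stimuli x grid positions x presentation length."""
        return (
            n_stimuli
            * self.n_grid**2
            * self.frames_per_presentation
            / self.frame_rate
        )

    def presentation_order(self, n_stimuli: int) -> np.ndarray:
        """Seeded random interleaving of (stimulus, row, col) presentations."""
        combos = np.array(
            [
                (s, i, j)
                for s in range(n_stimuli)
                for i in range(self.n_grid)
                for j in range(self.n_grid)
            ]
        )
        rng = np.random.default_rng(self.order_seed)
        return combos[rng.permutation(len(combos))]

    def grid_offsets_px(self, px_to_um: float = 50.0) -> np.ndarray:
        """Grid node offsets from the canvas centre, in pixels (x or y)."""
        half = self.grid_span_um / 2.0 / px_to_um
        return np.linspace(-half, half, self.n_grid)


def weighted_response(
    responses: np.ndarray,
    mu: tuple[float, float],
    sigma: float,
    grid_offsets: np.ndarray,
    window: tuple[int, int] = (30, 50),
) -> np.ndarray:
    """Gaussian-readout-weighted, time-averaged response per stimulus.

    ``responses`` is [n_stimuli, n_grid, n_grid, T] of z-scored responses.
    Each grid location is weighted by the readout Gaussian density at that
    node (weights deliberately not renormalised -- the common scale cancels
    in the selectivity index), summed over the grid, then averaged over the
    optimisation window.  Returns one scalar per stimulus.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n_grid = responses.shape[1]
    if len(grid_offsets) != n_grid:
        raise ValueError("grid offsets do not match the response grid")
    gx = grid_offsets[None, :] - mu[0]
    gy = grid_offsets[:, None] - mu[1]
    dens = np.exp(-(gx**2 + gy**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    pooled = np.einsum("sijt,ij->st", responses, dens)
    a, b = window
    return pooled[:, a:b].mean(axis=1)


def selectivity_index(rtilde: np.ndarray, own_index: int) -> float:
    """Standardised own-MEI response minus the mean of the others.

    ``rtilde`` holds one scalar response per MEI stimulus.  Responses are
    standardised across stimuli (zero mean, unit SD) first, making the SI
    invariant to affine rescaling of the raw responses; a zero SD across
    stimuli is flagged and gives SI = 0.
    """
    r = np.asarray(rtilde, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two stimuli")
    sd = r.std()
    if sd == 0:
        import warnings

        warnings.warn("constant responses across stimuli; SI = 0")
        return 0.0
    z = (r - r.mean()) / sd
    others = np.delete(z, own_index)
    return float(z[own_index] - others.mean())


def group_selectivity_index(rtilde_per_cell: np.ndarray, own_index: int) -> float:
    """Group SI: the mean SI over the member cells of a group."""
    return float(
        np.mean([selectivity_index(r, own_index) for r in rtilde_per_cell])
    )


def simulate_grid_responses(
    cells,
    stimuli_z: np.ndarray,
    experiment: GridExperiment,
    px_to_um: float = 50.0,
    zscore: bool = True,
) -> np.ndarray:
    """Present each rank-1 stimulus at every grid node to every cell.

    ``stimuli_z`` is [n_stimuli, 2, T, H, W] in model units.  A stimulus at
    grid node (i, j) is the canvas-sized stimulus rolled so its centre
    lands on the node (edges wrap, negligible for localised MEIs).  Returns
    z-scored responses [n_cells, n_stimuli, n_grid, n_grid, T].
    """
    offs = experiment.grid_offsets_px(px_to_um)
    S, _, T, H, W = stimuli_z.shape
    n = experiment.n_grid
    out = np.zeros((len(cells), S, n, n, T))
    for si in range(S):
        for i, oy in enumerate(offs):
            for j, ox in enumerate(offs):
                shifted = np.roll(
                    stimuli_z[si], (int(round(oy)), int(round(ox))), axis=(2, 3)
                )
                for ci, cell in enumerate(cells):
                    out[ci, si, i, j] = cell.rates(shifted)
    if zscore:
        flat = out.reshape(len(cells), -1)
        mean = flat.mean(axis=1)[:, None, None, None, None]
        sd = flat.std(axis=1)[:, None, None, None, None]
        sd[sd == 0] = 1.0
        out = (out - mean) / sd
    return out
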