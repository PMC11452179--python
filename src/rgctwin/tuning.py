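"""Chromatic-contrast tuning maps in the 2-D subspace of an MEI.

The subspace is spanned by two basis stimuli built from the MEI's rank-1
channel components: e1 carries the green component (sign-flipped) in the
green channel and zeros in UV, e2 the UV component in the UV channel and
zeros in green.  Scaling factors equalise the per-channel L2 norms while
preserving the whole-stimulus norm, so the point (-1, 1) reproduces the
contrast-scaled MEI.  The model neuron's response and input gradient are
evaluated on an 11 x 11 grid of coefficients in [-1, 1]^2; the gradient is
projected back onto (e1, e2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mei import MEIDecomposition, MEIRecord, decompose
from .stimuli import GREEN, UV


@dataclass
class ContrastBasis:
    e1: np.ndarray  # [2, T, H, W]; green channel only, sign-flipped
    e2: np.ndarray  # [2, T, H, W]; UV channel only
    s1: float
    s2: float

    def stimulus(self, a: float, b: float) -> np.ndarray:
        """The stimulus at subspace coordinates (a, b)."""
        return a * self.e1 + b * self.e2


@dataclass
class TuningMap:
    grid: np.ndarray  # [n] coefficients, equally spaced in [-1, 1]
    response: np.ndarray  # [n, n] in % of the map maximum
    response_raw: np.ndarray  # [n, n] model activations
    gradient: np.ndarray  # [n, n, 2] projection onto (e1, e2)


def build_basis(mei: MEIRecord | np.ndarray,
                decomp: MEIDecomposition | None = None) -> ContrastBasis:
    """Contrast basis from an MEI's rank-1 channel components.

    The green/UV components are the per-channel rank-1 reconstructions
    (channel-separable by construction).  With channel norms n_g, n_uv and
    whole-MEI norm N, the scalings s1 = N / (sqrt(2) n_g) and
    s2 = N / (sqrt(2) n_uv) give both basis vectors equal norm N/sqrt(2),
    so the stimulus at (-1, 1) has norm N: per-channel contrast equalised,
    whole-stimulus contrast preserved.
    """
    tensor = mei.tensor if isinstance(mei, MEIRecord) else np.asarray(mei)
    if decomp is None:
        decomp = decompose(tensor)
    comps = np.stack(
        [
            decomp.singular_values[c]
            * np.einsum("t,ij->tij", decomp.temporal[c], decomp.spatial[c])
            for c in range(2)
        ]
    )
    n_g = np.linalg.norm(comps[GREEN])
    n_uv = np.linalg.norm(comps[UV])
    if n_g == 0 or n_uv == 0:
        raise ValueError("cannot build a contrast basis from a zero channel")
    N = float(np.sqrt(n_g**2 + n_uv**2))
    s1 = N / (np.sqrt(2.0) * n_g)
    s2 = N / (np.sqrt(2.0) * n_uv)
    e1 = np.zeros_like(comps)
    e2 = np.zeros_like(comps)
    e1[GREEN] = -s1 * comps[GREEN]
    e2[UV] = s2 * comps[UV]
    return ContrastBasis(e1=e1, e2=e2, s1=float(s1), s2=float(s2))


def map_tuning(results, neuron: int, basis: ContrastBasis, n: int = 11,
               centered: bool = True) -> TuningMap:
    """Response and gradient over the 11 x 11 chromatic-contrast grid.

    Normalisation layers stay frozen (eval-mode forward passes).  The
    response map is expressed as % of its maximum; gradients are the
    coefficients of the model gradient with respect to (e1, e2), computed
    by orthogonal projection (e1 and e2 have disjoint channel support).
    """
    grid = np.linspace(-1.0, 1.0, n)
    resp = np.zeros((n, n))
    grad = np.zeros((n, n, 2))
    n1 = float(np.sum(basis.e1**2))
    n2 = float(np.sum(basis.e2**2))
    for i, a in enumerate(grid):
        for j, b in enumerate(grid):
            x = basis.stimulus(a, b)
            act, g = results.activation_and_gradient(x, neuron,
                                                     centered=centered)
            resp[i, j] = act
            grad[i, j, 0] = float(np.sum(g * basis.e1)) / n1
            grad[i, j, 1] = float(np.sum(g * basis.e2)) / n2
    peak = resp.max()
    norm = resp / peak * 100.0 if peak != 0 else resp
    return TuningMap(grid=grid, response=norm, response_raw=resp, gradient=grad)


def argmax_coordinates(tmap: TuningMap) -> tuple[float, float]:
    """(a, b) subspace coordinates of the tuning-map maximum.

    These are raw basis coefficients; the cell's own MEI sits at (-1, 1).
    """
    i, j = np.unravel_index(np.argmax(tmap.response_raw), tmap.response.shape)
    return float(tmap.grid[i]), float(tmap.grid[j])


def physical_contrast_signs(
    coords: tuple[float, float], mei_gamma: dict
) -> tuple[float, float]:
    """Signed physical (green, UV) contrast of a subspace point.

    The stimulus at (a, b) carries -a times the MEI's green component and
    +b times its UV component, so its physical chromatic contrast is
    (-a * gamma_green_MEI, b * gamma_UV_MEI).  This places an opponent
    cell's preferred stimulus in the green-negative / UV-positive quadrant
    and a non-opponent ON cell's on the green-positive side, even though
    both sit at basis coordinates (-1, 1).
    """
    a, b = coords
    return (-a * mei_gamma["green"], b * mei_gamma["uv"])
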