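"""Maximally exciting inputs: synthesis and characterisation.

An MEI is the 50-frame dichromatic stimulus that maximises a model neuron's
time-averaged predicted response under two constraints: a joint L2 norm
budget of b = 30 across both channels, and a per-channel range box given by
the standardised training movie.  Synthesis is plain gradient ascent
(learning rate 10) on the ensemble-mean response with the readout centred
on the canvas, projecting onto the constraint set after every step (norm
rescale first, then range clip).

Characterisation decomposes each channel by SVD into a spatial and a
temporal component, fits a concentric anisotropic difference-of-Gaussians
to the spatial component (robust soft-L1 loss), and derives centre size,
a centre mask, temporal frequency, and the chromatic contrast pair
(gamma_green, gamma_UV) whose signs define colour opponency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt, find_peaks
from scipy.spatial import ConvexHull, QhullError

from .stimuli import CANVAS, GREEN, UV

CHANNEL_NAMES = ("green", "uv")

#: approximate pixel-to-micrometre scale of the stimulus on the retina
#: (a ~30 degree crop across 18 pixels at ~31 um per degree)
DEFAULT_PX_TO_UM = 50.0


@dataclass
class MEIOptions:
    lr: float = 10.0
    norm_budget: float = 30.0
    max_iter: int = 1000
    min_iter: int = 100
    conv_tol: float = 1e-3
    conv_patience: int = 10
    n_frames: int = 50
    init_sd: float = 0.1
    seed: int = 0


@dataclass
class MEIRecord:
    tensor: np.ndarray  # [2, n_frames, H, W]
    activations: np.ndarray  # ensemble activation per iteration
    converged: bool
    n_iter: int
    norm_budget: float
    window: tuple[int, int]  # optimisation window in input frames
    seed: int
    range_box: np.ndarray  # per-channel (lo, hi) in model (z-scored) units
    neuron: int | None = None

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.tensor))


@dataclass
class MEIDecomposition:
    spatial: np.ndarray  # [2, H, W], unit L2 per channel
    temporal: np.ndarray  # [2, n_frames], unit L2 per channel
    singular_values: np.ndarray  # [2]
    rank1_residual: np.ndarray  # [2] Frobenius norm of the remainder
    flags: list = field(default_factory=list)


@dataclass
class DoGParams:
    mu: tuple[float, float]  # (x, y) in centred pixel coordinates
    amplitude_center: float
    amplitude_surround: float
    sigma_center: tuple[float, float]  # (sigma_x, sigma_y) > 0, pixels
    sigma_surround: tuple[float, float]
    theta_center: float
    theta_surround: float
    cost: float  # robust soft-L1 cost of the fit
    success: bool = True


@dataclass
class MEIProperties:
    centre_size_um: dict  # per channel
    temporal_frequency_hz: dict  # per channel
    gamma: dict  # signed chromatic contrast per channel
    opponent: bool
    chromatic_angle: float  # atan2(gamma_uv, gamma_green)
    centre_mask: np.ndarray  # binary [H, W]
    dog: dict  # per-channel DoGParams
    flags: list = field(default_factory=list)


class MEIError(RuntimeError):
    pass


def _project(x: np.ndarray, budget: float, range_box: np.ndarray) -> np.ndarray:
    """Norm rescale (joint over channels) then per-channel range clip."""
    norm = np.linalg.norm(x)
    if norm > 0:
        x = x * (budget / norm)
    for c in range(2):
        x[c] = np.clip(x[c], range_box[c, 0], range_box[c, 1])
    return x


def synthesize_mei(results, neuron: int,
                   options: MEIOptions | None = None) -> MEIRecord:
    """Gradient-ascent synthesis of one neuron's MEI.

    ``results`` is a fitted :class:`~rgctwin.model.RetinaTwinResults`; the
    neuron's readout is moved to the canvas centre and batch-norm statistics
    stay frozen.  Stops after 10 consecutive iterations with an activation
    change below 1e-3 (never before 100 iterations), or at 1000 iterations.
    """
    opts = options or MEIOptions()
    support = results.members[0].config.temporal_support
    window = (support - 1, opts.n_frames)
    range_box = results.model.movie.zscored_range()
    rng = np.random.default_rng(opts.seed)
    H, W = results.members[0].canvas
    x = opts.init_sd * rng.standard_normal((2, opts.n_frames, H, W))
    x = _project(x, opts.norm_budget, range_box)

    acts = []
    stall = 0
    converged = False
    prev = None
    for i in range(opts.max_iter):
        act, grad = results.activation_and_gradient(x, neuron, centered=True)
        if not np.isfinite(act) or not np.all(np.isfinite(grad)):
            raise MEIError(f"non-finite gradient at iteration {i}")
        acts.append(act)
        if prev is not None and abs(act - prev) < opts.conv_tol:
            stall += 1
        else:
            stall = 0
        prev = act
        if i + 1 >= opts.min_iter and stall >= opts.conv_patience:
            converged = True
            break
        x = _project(x + opts.lr * grad, opts.norm_budget, range_box)
    return MEIRecord(
        tensor=np.asarray(x, dtype=float),
        activations=np.array(acts),
        converged=converged,
        n_iter=len(acts),
        norm_budget=opts.norm_budget,
        window=window,
        seed=opts.seed,
        range_box=range_box,
        neuron=neuron,
    )


def decompose(mei: MEIRecord | np.ndarray) -> MEIDecomposition:
    """Per-channel rank-1 SVD factorisation into space and time.

    Each channel [T, H, W] is flattened to [T, H*W] and factorised; the
    first left singular vector is the temporal component, the first right
    singular vector (reshaped) the spatial one.  The sign is fixed so the
    spatial component is positive at the canvas centre (the MEI centre,
    since synthesis places the readout there); temporal follows.
    """
    tensor = mei.tensor if isinstance(mei, MEIRecord) else np.asarray(mei)
    C, T, H, W = tensor.shape
    spatial = np.zeros((C, H, W))
    temporal = np.zeros((C, T))
    svals = np.zeros(C)
    resid = np.zeros(C)
    flags = []
    for c in range(C):
        M = tensor[c].reshape(T, H * W)
        if not np.any(M):
            flags.append(f"channel {CHANNEL_NAMES[c]} all-zero")
            continue
        Umat, S, Vt = np.linalg.svd(M, full_matrices=False)
        u, s, v = Umat[:, 0], S[0], Vt[0]
        sp = v.reshape(H, W)
        sign = _center_sign(sp)
        spatial[c] = sign * sp
        temporal[c] = sign * u
        svals[c] = s
        resid[c] = float(np.sqrt(max((S[1:] ** 2).sum(), 0.0)))
    return MEIDecomposition(
        spatial=spatial, temporal=temporal, singular_values=svals,
        rank1_residual=resid, flags=flags,
    )


def _center_sign(spatial: np.ndarray) -> float:
    H, W = spatial.shape
    v = spatial[H // 2 - 1:H // 2 + 1, W // 2 - 1:W // 2 + 1].sum()
    if abs(v) < 1e-12:
        v = spatial.flat[np.argmax(np.abs(spatial))]
    return 1.0 if v >= 0 else -1.0


# --------------------------------------------------------------------- DoG
def _grid(shape=CANVAS):
    H, W = shape
    y, x = np.mgrid[0:H, 0:W]
    return x - (W - 1) / 2.0, y - (H - 1) / 2.0


def _gauss2d(x, y, mu, A, sx, sy, theta):
    dx, dy = x - mu[0], y - mu[1]
    c, s = np.cos(theta), np.sin(theta)
    f = c**2 / (2 * sx**2) + s**2 / (2 * sy**2)
    g = np.sin(2 * theta) * (1.0 / (4 * sy**2) - 1.0 / (4 * sx**2))
    h = s**2 / (2 * sx**2) + c**2 / (2 * sy**2)
    return A * np.exp(-(f * dx**2 + 2 * g * dx * dy + h * dy**2))


def dog_model(params: np.ndarray, shape=CANVAS) -> np.ndarray:
    """Concentric anisotropic DoG evaluated on the pixel grid."""
    mx, my, Ac, As, sxc, syc, sxs, sys, thc, ths = params
    x, y = _grid(shape)
    return _gauss2d(x, y, (mx, my), Ac, sxc, syc, thc) - _gauss2d(
        x, y, (mx, my), As, sxs, sys, ths
    )


def fit_dog(spatial: np.ndarray, f_scale: float = 1.0) -> DoGParams:
    """Robust DoG fit to one spatial component.

    Initialisation: of the spatial component's minimum and maximum, the one
    closer to the canvas centre seeds the location; a single-Gaussian
    pre-fit then seeds the full DoG.  Optimiser failure is returned as a
    flagged record with infinite cost, never raised.
    """
    spatial = np.asarray(spatial, dtype=float)
    H, W = spatial.shape
    if np.ptp(spatial) == 0:
        return _failed_dog()
    x, y = _grid((H, W))
    imin = np.unravel_index(np.argmin(spatial), spatial.shape)
    imax = np.unravel_index(np.argmax(spatial), spatial.shape)

    def dist(i):
        return np.hypot(x[i], y[i])

    seed_idx = imin if dist(imin) < dist(imax) else imax
    mx0, my0 = float(x[seed_idx]), float(y[seed_idx])
    A0 = float(spatial[seed_idx])

    bx, by = (W - 1) / 2.0, (H - 1) / 2.0
    amp = 10.0 * max(np.abs(spatial).max(), 1e-3)

    try:
        # single-Gaussian pre-fit
        def res_g(p):
            mx, my, A, sx, sy, th = p
            return (_gauss2d(x, y, (mx, my), A, sx, sy, th) - spatial).ravel()

        pre = least_squares(
            res_g,
            x0=[mx0, my0, A0, 2.0, 2.0, 0.0],
            bounds=([-bx, -by, -amp, 0.3, 0.3, -np.pi],
                    [bx, by, amp, 20.0, 20.0, np.pi]),
            loss="soft_l1", f_scale=f_scale,
        )
        mx0, my0, A0, sx0, sy0, th0 = pre.x
        th0 = _wrap_angle(th0)  # Gaussians are pi-periodic; avoid the bound

        def res_dog(p):
            return (dog_model(p, (H, W)) - spatial).ravel()

        bounds = (
            [-bx, -by, -amp, -amp, 0.3, 0.3, 0.3, 0.3, -np.pi, -np.pi],
            [bx, by, amp, amp, 20.0, 20.0, 20.0, 20.0, np.pi, np.pi],
        )
        # a few surround initialisations guard against local minima
        fit = None
        for As0, sscale in ((0.05 * A0, 2.0), (0.3 * A0, 2.0), (0.5 * A0, 3.0)):
            cand = least_squares(
                res_dog,
                x0=[mx0, my0, A0 + As0, As0, sx0, sy0,
                    sscale * sx0, sscale * sy0, th0, th0],
                bounds=bounds, loss="soft_l1", f_scale=f_scale,
            )
            if fit is None or cand.cost < fit.cost:
                fit = cand
    except Exception:
        return _failed_dog()
    p = fit.x
    sxc, syc, thc = _canonical_axes(p[4], p[5], p[8])
    sxs, sys_, ths = _canonical_axes(p[6], p[7], p[9])
    return DoGParams(
        mu=(float(p[0]), float(p[1])),
        amplitude_center=float(p[2]),
        amplitude_surround=float(p[3]),
        sigma_center=(sxc, syc),
        sigma_surround=(sxs, sys_),
        theta_center=thc,
        theta_surround=ths,
        cost=float(fit.cost),
        success=bool(fit.success),
    )


def _wrap_angle(theta: float) -> float:
    """Wrap an orientation into (-pi/2, pi/2] (Gaussians are pi-periodic)."""
    theta = float(theta)
    while theta > np.pi / 2:
        theta -= np.pi
    while theta <= -np.pi / 2:
        theta += np.pi
    return theta


def _canonical_axes(sx: float, sy: float, theta: float):
    """Canonical (sigma_x <= sigma_y, theta in (-pi/2, pi/2]) representation.

    (sx, sy, theta) and (sy, sx, theta + pi/2) describe the same Gaussian.
    """
    sx, sy = float(sx), float(sy)
    if sx > sy:
        sx, sy = sy, sx
        theta = theta + np.pi / 2
    return sx, sy, _wrap_angle(theta)


def _failed_dog() -> DoGParams:
    return DoGParams(
        mu=(0.0, 0.0), amplitude_center=0.0, amplitude_surround=0.0,
        sigma_center=(1.0, 1.0), sigma_surround=(2.0, 2.0),
        theta_center=0.0, theta_surround=0.0, cost=np.inf, success=False,
    )


def centre_size(dog: DoGParams, px_to_um: float = DEFAULT_PX_TO_UM) -> float:
    """Mean of the centre diameters 2*sigma_x and 2*sigma_y, in um.

    Equals (sigma_x + sigma_y) * px_to_um.
    """
    return (dog.sigma_center[0] + dog.sigma_center[1]) * px_to_um


def centre_gaussian(dog: DoGParams, shape=CANVAS) -> np.ndarray:
    x, y = _grid(shape)
    return _gauss2d(x, y, dog.mu, dog.amplitude_center,
                    dog.sigma_center[0], dog.sigma_center[1], dog.theta_center)


def centre_mask(dog: DoGParams, shape=CANVAS) -> np.ndarray:
    """Binary mask of pixels inside the convex hull of the 1-SD contour.

    The contour is the level set of the centre Gaussian at its value at
    (mu_x + sigma_x, mu_y + sigma_y); degenerate fits give a single-pixel
    mask at the fitted centre.
    """
    H, W = shape
    x, y = _grid(shape)
    Gc = centre_gaussian(dog, shape)
    level = _gauss2d(
        np.array(dog.mu[0] + dog.sigma_center[0]),
        np.array(dog.mu[1] + dog.sigma_center[1]),
        dog.mu, dog.amplitude_center,
        dog.sigma_center[0], dog.sigma_center[1], dog.theta_center,
    )
    if dog.amplitude_center >= 0:
        inside = Gc >= level
    else:
        inside = Gc <= level
    pts = np.column_stack([x[inside], y[inside]])
    mask = np.zeros((H, W), dtype=bool)
    if len(pts) < 3:
        i = int(round(np.clip(dog.mu[1] + (H - 1) / 2.0, 0, H - 1)))
        j = int(round(np.clip(dog.mu[0] + (W - 1) / 2.0, 0, W - 1)))
        mask[i, j] = True
        return mask
    try:
        hull = ConvexHull(pts)
        path = MplPath(pts[hull.vertices])
        grid_pts = np.column_stack([x.ravel(), y.ravel()])
        mask = path.contains_points(grid_pts, radius=0.01).reshape(H, W)
    except QhullError:
        mask[inside] = True
    # the pixel nearest mu is always part of the centre
    i = int(round(np.clip(dog.mu[1] + (H - 1) / 2.0, 0, H - 1)))
    j = int(round(np.clip(dog.mu[0] + (W - 1) / 2.0, 0, W - 1)))
    mask[i, j] = True
    return mask


def temporal_frequency(temporal: np.ndarray, frame_rate: float = 30.0,
                       cutoff_hz: float = 10.0, order: int = 5) -> float:
    """Power-weighted mean frequency of a temporal component, in Hz.

    The component is low-pass filtered (Butterworth, 5th order, 10 Hz) to
    attenuate high-frequency noise before the FFT power spectrum is formed.
    """
    temporal = np.asarray(temporal, dtype=float)
    if not np.any(temporal):
        warnings.warn("zero temporal component; frequency reported as 0 Hz")
        return 0.0
    b, a = butter(order, cutoff_hz, fs=frame_rate, btype="low")
    filtered = filtfilt(b, a, temporal)
    power = np.abs(np.fft.rfft(filtered)) ** 2
    freqs = np.fft.rfftfreq(len(filtered), d=1.0 / frame_rate)
    total = power.sum()
    if total == 0:
        return 0.0
    return float((freqs * power).sum() / total)


def mei_contrast(
    mei: MEIRecord | np.ndarray,
    decomposition: MEIDecomposition,
    mask: np.ndarray,
    peak_prominence_frac: float = 0.05,
):
    """Chromatic contrast (gamma_green, gamma_UV) and the opponency flag.

    The last two peaks of the UV temporal component define the times t1 and
    t2; gamma for each channel is the mask-mean of that channel at t2 minus
    at t1 (the same times for both channels).  Fewer than two UV peaks
    raises :class:`MEIError` so the cell can be flagged and excluded.
    """
    tensor = mei.tensor if isinstance(mei, MEIRecord) else np.asarray(mei)
    tuv = decomposition.temporal[UV]
    # peaks of the absolute component: the last two are the final
    # trough/peak pair, so gamma measures the polarity of the final swing
    mag = np.abs(tuv)
    prom = peak_prominence_frac * np.ptp(mag)
    peaks, _ = find_peaks(mag, prominence=prom if prom > 0 else None)
    if len(peaks) < 2:
        raise MEIError(
            f"UV temporal component has {len(peaks)} extremum/a; need 2"
        )
    t1, t2 = int(peaks[-2]), int(peaks[-1])
    mask = mask.astype(bool)
    gamma = {}
    for c, name in enumerate(CHANNEL_NAMES):
        gamma[name] = float(
            tensor[c, t2][mask].mean() - tensor[c, t1][mask].mean()
        )
    opponent = opponency_flag(gamma)
    return gamma, opponent, (t1, t2)


def opponency_flag(gamma: dict, rel_floor: float = 0.1) -> bool:
    """Colour opponency: opposite-sign contrasts in the two channels.

    A small relative floor keeps numerical noise in a near-zero channel
    from flipping the flag: both magnitudes must exceed ``rel_floor`` times
    the larger one.
    """
    g, u = gamma["green"], gamma["uv"]
    if g * u >= 0:
        return False
    big = max(abs(g), abs(u))
    return min(abs(g), abs(u)) >= rel_floor * big


def characterize_mei(
    mei: MEIRecord,
    px_to_um: float = DEFAULT_PX_TO_UM,
    frame_rate: float = 30.0,
) -> MEIProperties:
    """Full characterisation: decomposition, DoG fits, size, frequency, contrast.

    The centre mask for chromatic contrast comes from the UV-channel DoG
    (the UV temporal component also supplies the peak times).
    """
    dec = decompose(mei)
    flags = list(dec.flags)
    dogs = {
        name: fit_dog(dec.spatial[c]) for c, name in enumerate(CHANNEL_NAMES)
    }
    mask = centre_mask(dogs["uv"], shape=dec.spatial[UV].shape)
    sizes = {n: centre_size(d, px_to_um) for n, d in dogs.items()}
    tfs = {
        name: temporal_frequency(dec.temporal[c], frame_rate)
        for c, name in enumerate(CHANNEL_NAMES)
    }
    try:
        gamma, opponent, _ = mei_contrast(mei, dec, mask)
    except MEIError as err:
        flags.append(str(err))
        gamma, opponent = {"green": np.nan, "uv": np.nan}, False
    angle = float(np.arctan2(gamma["uv"], gamma["green"]))
    return MEIProperties(
        centre_size_um=sizes,
        temporal_frequency_hz=tfs,
        gamma=gamma,
        opponent=opponent,
        chromatic_angle=angle,
        centre_mask=mask,
        dog=dogs,
        flags=flags,
    )
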