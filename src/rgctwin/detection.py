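"""Detection of ground-to-sky context changes at movie clip transitions.

Every boundary between adjacent clips is a transition event, classed by the
labels of the two clips (ground-to-sky, sky-to-ground, ground-to-ground,
sky-to-sky) and characterised by its full-field chromatic contrast: the
per-channel mean luminance over the first second of the post-clip minus the
last second of the pre-clip.  A cell's transition response is its
baseline-subtracted mean rate over the second after the boundary, and a
threshold-sweep ROC analysis (40 equally spaced thresholds over the cell's
response range) scores how well the cell separates ground-to-sky
transitions from all others.

A moving-window simulator reproduces the same four transition types by
sliding a 72 x 64 crop over a static scene along a square trajectory
(220-pixel edges spanning 90.6 degrees of visual angle) at four angular
velocities, downsampling each crop to the 18 x 16 model canvas and padding
to 60 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import GREEN, UV, MovieStimulus

TRANSITION_TYPES = (
    "ground-to-sky",
    "sky-to-ground",
    "ground-to-ground",
    "sky-to-sky",
)

#: trajectory geometry: edge length in pixels and in degrees of visual angle
EDGE_PX = 220
EDGE_DEG = 90.6
#: the four simulated angular velocities (deg/s)
VELOCITIES_DPS = (50, 150, 250, 350)
WINDOW_PX = (72, 64)  # (height, width) of the moving crop
N_STIM_FRAMES = 60


@dataclass
class TransitionEvent:
    t0: int  # frame index of the clip boundary (first frame of post-clip)
    type: str
    contrast: tuple[float, float]  # (gamma_green, gamma_UV)
    pre_clip: int
    post_clip: int


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def px_per_frame(velocity_dps: float, frame_rate: float = 30.0) -> int:
    """Pixels the window moves per frame at a given angular velocity."""
    return int(round(velocity_dps / frame_rate * EDGE_PX / EDGE_DEG))


def find_transitions(
    movie: MovieStimulus, window_s: float = 1.0, michelson: bool = False
) -> list[TransitionEvent]:
    """One transition event per adjacent clip pair.

    Contrast per channel is the post-clip minus pre-clip mean full-field
    luminance over 1-second windows flanking the boundary (``michelson``
    switches to (post-pre)/(post+pre)).
    """
    L = movie.clip_length
    w = int(round(window_s * movie.frame_rate))
    w = min(w, L)
    events = []
    n_clips = movie.n_clips
    for k in range(n_clips - 1):
        t0 = (k + 1) * L
        pre = movie.frames[:, t0 - w:t0].mean(axis=(1, 2, 3))
        post = movie.frames[:, t0:t0 + w].mean(axis=(1, 2, 3))
        if michelson:
            contrast = (post - pre) / (post + pre)
        else:
            contrast = post - pre
        pre_lab = movie.clip_labels[k]
        post_lab = movie.clip_labels[k + 1]
        events.append(
            TransitionEvent(
                t0=t0,
                type=f"{pre_lab}-to-{post_lab}",
                contrast=(float(contrast[GREEN]), float(contrast[UV])),
                pre_clip=k,
                post_clip=k + 1,
            )
        )
    return events


def transition_response(rate: np.ndarray, t0: int, window: int = 30) -> float:
    """Baseline-subtracted mean rate over ``window`` frames after t0."""
    rate = np.asarray(rate, dtype=float)
    if t0 + window > len(rate) or t0 < 0:
        raise ValueError("response window exceeds the rate record")
    return float(rate[t0:t0 + window].mean() - rate[t0])


def roc_auc(responses, labels, n_thresholds: int = 40) -> ROCResult:
    """Threshold-sweep ROC for above-threshold = positive classification.

    Thresholds are equally spaced over the full response range (both
    classes); (FPR, TPR) endpoints (0,0) and (1,1) are appended and the
    AUC is the trapezoidal integral of TPR over FPR.
    """
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = labels.sum()
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("both classes must be non-empty")
    thresholds = np.linspace(responses.min(), responses.max(), n_thresholds)
    tpr = np.array(
        [(responses[labels] > th).mean() for th in thresholds]
    )
    fpr = np.array(
        [(responses[~labels] > th).mean() for th in thresholds]
    )
    f = np.concatenate([[1.0], fpr, [0.0]])
    t = np.concatenate([[1.0], tpr, [0.0]])
    order = np.lexsort((t, f))  # staircase order from (0,0) to (1,1)
    auc = float(np.trapezoid(t[order], f[order]))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def detection_table(
    events: list[TransitionEvent],
    rates: np.ndarray,
    target: str = "ground-to-sky",
    window: int = 30,
    families: list | None = None,
) -> pd.DataFrame:
    """Per-cell ROC/AUC over all usable transition events.

    ``rates`` is [n_cells, T] at the movie frame rate.  Events whose
    response window runs off the record are dropped.
    """
    T = rates.shape[1]
    usable = [e for e in events if e.t0 + window <= T]
    labels = np.array([e.type == target for e in usable])
    rows = []
    for i in range(rates.shape[0]):
        resp = np.array(
            [transition_response(rates[i], e.t0, window) for e in usable]
        )
        roc = roc_auc(resp, labels)
        rows.append(
            dict(
                cell=i,
                family=families[i] if families is not None else None,
                auc=roc.auc,
                n_events=len(usable),
                n_target=int(labels.sum()),
            )
        )
    return pd.DataFrame(rows).set_index("cell")


# ------------------------------------------------------- simulated transitions
@dataclass
class TransitionStimulus:
    frames: np.ndarray  # [2, 60, 18, 16]
    velocity_dps: float
    px_per_frame: int
    direction: str  # "clockwise" or "counterclockwise"
    transition_type: str


def make_scene(
    movie: MovieStimulus | None = None,
    shape: tuple[int, int] = (440, 440),
    seed: int = 0,
    sky_means: tuple[float, float] = (0.06, 0.2),
    ground_means: tuple[float, float] = (0.2, 0.06),
    texture_amplitude: float = 0.04,
) -> np.ndarray:
    """A static dichromatic scene with a horizon bisecting it.

    The upper half has sky chromatic statistics (UV > green), the lower
    half ground statistics; texture is smoothed noise as in the movie
    generator.  Shape must fit the trajectory plus window.
    """
    from scipy.ndimage import gaussian_filter

    H, W = shape
    rng = np.random.default_rng(seed)
    scene = np.empty((2, H, W))
    horizon = H // 2
    for c, (sky_m, gnd_m) in enumerate(zip(sky_means, ground_means)):
        tex = gaussian_filter(rng.standard_normal((H, W)), 8.0)
        sd = tex.std()
        if sd > 0:
            tex = tex / sd * texture_amplitude
        scene[c] = tex
        scene[c, :horizon] += sky_m
        scene[c, horizon:] += gnd_m
    return scene


def _downsample(crop: np.ndarray, out_hw=(18, 16)) -> np.ndarray:
    C, h, w = crop.shape
    oh, ow = out_hw
    fh, fw = h // oh, w // ow
    return crop[:, :oh * fh, :ow * fw].reshape(C, oh, fh, ow, fw).mean(axis=(2, 4))


def simulate_transitions(
    scene: np.ndarray,
    velocity_dps: float,
    direction: str = "clockwise",
    seed: int = 0,
    allow_any_velocity: bool = False,
) -> list[TransitionStimulus]:
    """Slide the crop window along the square trajectory over a scene.

    The square's two vertical edges cross the horizon (context changes:
    upward motion = ground-to-sky, downward = sky-to-ground); its two
    horizontal edges stay within one region (sky-to-sky on top,
    ground-to-ground at the bottom).  Each edge yields one 60-frame
    stimulus: the moving frames padded by duplicating the first and last
    frame.  The seed jitters the trajectory's position in the scene.
    """
    if velocity_dps not in VELOCITIES_DPS and not allow_any_velocity:
        raise ValueError(
            f"velocity {velocity_dps} not in {VELOCITIES_DPS} "
            "(pass allow_any_velocity=True to override)"
        )
    if direction not in ("clockwise", "counterclockwise"):
        raise ValueError(f"unknown direction {direction!r}")
    step = px_per_frame(velocity_dps)
    wh, ww = WINDOW_PX
    C, H, W = scene.shape
    margin_r = H - EDGE_PX - wh
    margin_c = W - EDGE_PX - ww
    if margin_r < 0 or margin_c < 0:
        raise ValueError("scene too small for the trajectory")
    rng = np.random.default_rng(seed)
    # centre the square on the horizon so vertical edges cross it
    horizon = H // 2
    r_top = int(np.clip(horizon - EDGE_PX // 2 - wh // 2,
                        0, margin_r))
    c_left = int(rng.integers(0, margin_c + 1))
    r_bot = r_top + EDGE_PX
    c_right = c_left + EDGE_PX

    # corners in (row, col); clockwise = right along top, down, left, up
    edges_cw = [
        ((r_top, c_left), (0, 1), "sky-to-sky"),
        ((r_top, c_right), (1, 0), "sky-to-ground"),
        ((r_bot, c_right), (0, -1), "ground-to-ground"),
        ((r_bot, c_left), (-1, 0), "ground-to-sky"),
    ]
    if direction == "clockwise":
        edges = edges_cw
    else:
        edges = [
            ((r_top, c_right), (0, -1), "sky-to-sky"),
            ((r_top, c_left), (1, 0), "sky-to-ground"),
            ((r_bot, c_left), (0, 1), "ground-to-ground"),
            ((r_bot, c_right), (-1, 0), "ground-to-sky"),
        ]
    stimuli = []
    n_move = EDGE_PX // step
    for (r0, c0), (dr, dc), ttype in edges:
        crops = []
        for s in range(n_move + 1):
            r = r0 + dr * s * step
            c = c0 + dc * s * step
            crops.append(_downsample(scene[:, r:r + wh, c:c + ww]))
        frames = np.stack(crops, axis=1)  # [2, n, 18, 16]
        n = frames.shape[1]
        if n > N_STIM_FRAMES:
            frames = frames[:, :N_STIM_FRAMES]
            n = N_STIM_FRAMES
        pad_front = (N_STIM_FRAMES - n) // 2
        pad_back = N_STIM_FRAMES - n - pad_front
        frames = np.concatenate(
            [
                np.repeat(frames[:, :1], pad_front, axis=1),
                frames,
                np.repeat(frames[:, -1:], pad_back, axis=1),
            ],
            axis=1,
        )
        stimuli.append(
            TransitionStimulus(
                frames=frames,
                velocity_dps=velocity_dps,
                px_per_frame=step,
                direction=direction,
                transition_type=ttype,
            )
        )
    return stimuli


def simulated_transition_table(
    cells_or_results,
    scenes: list[np.ndarray],
    velocities=VELOCITIES_DPS,
    zscore_stats: tuple[np.ndarray, np.ndarray] | None = None,
    response_window: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC per cell and velocity for the moving-window detection task.

    ``cells_or_results`` is either a list of ground-truth cells or a fitted
    results object (anything with ``.predict``).  Each scene contributes
    both trajectory directions at every velocity.  The transition response
    is measured from the motion-onset frame.  ``zscore_stats`` (per-channel
    mean, SD) standardises the stimuli the way the movie was standardised.
    """
    from .model import RetinaTwinResults

    is_model = isinstance(cells_or_results, RetinaTwinResults)
    rows = []
    for v in velocities:
        stims, types = [], []
        for si, scene in enumerate(scenes):
            for direction in ("clockwise", "counterclockwise"):
                for st in simulate_transitions(scene, v, direction,
                                               seed=seed + si):
                    frames = st.frames
                    if zscore_stats is not None:
                        mean, sd = zscore_stats
                        frames = (frames - mean[:, None, None, None]) / sd[
                            :, None, None, None
                        ]
                    stims.append(frames)
                    types.append(st.transition_type)
        labels = np.array([t == "ground-to-sky" for t in types])
        # the window crosses the horizon (or passes mid-edge) halfway along
        # an edge; anchor the response there so all velocities are scored
        # on the second that contains the potential context change
        n_move = EDGE_PX // px_per_frame(v) + 1
        t_mid = (N_STIM_FRAMES - n_move) // 2 + n_move // 2
        window = min(response_window, N_STIM_FRAMES - t_mid)
        if is_model:
            responses = _model_transition_responses(
                cells_or_results, stims, t_mid, window
            )
            families = None
            n_cells = responses.shape[0]
        else:
            cells = cells_or_results
            n_cells = len(cells)
            responses = np.zeros((n_cells, len(stims)))
            for k, frames in enumerate(stims):
                for i, cell in enumerate(cells):
                    r = cell.rates(frames)
                    responses[i, k] = float(
                        r[t_mid:t_mid + window].mean() - r[t_mid]
                    )
            families = [c.family for c in cells]
        for i in range(n_cells):
            roc = roc_auc(responses[i], labels)
            rows.append(
                dict(
                    cell=i,
                    family=families[i] if families else None,
                    velocity=v,
                    auc=roc.auc,
                )
            )
    return pd.DataFrame(rows)


def _model_transition_responses(results, stims, t_mid, window):
    off = results.time_offset
    out = []
    for frames in stims:
        pred = results.predict(frames)  # [N, T-off]
        t0 = max(t_mid - off, 0)
        w = min(window, pred.shape[1] - t0)
        resp = pred[:, t0:t0 + w].mean(axis=1) - pred[:, t0]
        out.append(resp)
    return np.stack(out, axis=1)  # [N, n_stims]


def group_tuning_map(
    events: list[TransitionEvent],
    responses: np.ndarray,
    bins: int = 10,
    box: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean transition response binned in (gamma_green, gamma_UV) space.

    ``responses`` is [n_cells, n_events].  Returns (map, green_edges,
    uv_edges); the map is a masked array ([bins, bins], green x UV) with
    empty bins masked, averaged over cells of per-cell binned maps.
    """
    g = np.array([e.contrast[0] for e in events])
    u = np.array([e.contrast[1] for e in events])
    if box is None:
        box = ((g.min(), g.max()), (u.min(), u.max()))
    (g0, g1), (u0, u1) = box
    g_edges = np.linspace(g0, g1, bins + 1)
    u_edges = np.linspace(u0, u1, bins + 1)
    gi = np.clip(np.digitize(g, g_edges) - 1, 0, bins - 1)
    ui = np.clip(np.digitize(u, u_edges) - 1, 0, bins - 1)
    maps = np.ma.masked_all((responses.shape[0], bins, bins))
    for c in range(responses.shape[0]):
        acc = np.zeros((bins, bins))
        cnt = np.zeros((bins, bins))
        np.add.at(acc, (gi, ui), responses[c])
        np.add.at(cnt, (gi, ui), 1)
        with np.errstate(invalid="ignore"):
            m = np.ma.masked_invalid(acc / np.where(cnt == 0, np.nan, cnt))
        maps[c] = m
    return maps.mean(axis=0), g_edges, u_edges
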