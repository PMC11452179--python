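"""Digital-twin encoding model: data binding, training, and results.

``RetinaTwin`` binds a movie stimulus and per-neuron firing-rate targets to
the core+readout architecture; ``fit`` runs the Adam/early-stopping training
schedule for an ensemble of differently seeded members and returns a
``RetinaTwinResults`` carrying the trained weights, the training log, and
evaluation, prediction and gradient interfaces.  The MEI, chromatic-tuning
and detection analyses all consume the results object.

The training schedule follows the standard neural-system-identification
recipe: Poisson loss, Adam at an initial learning rate of 0.01, batches of
32 chunks of 50 frames, early stopping (patience 5 epochs) on the validation
correlation, and four restore-and-decay cycles with a learning-rate decay
factor of 0.3.  The ensemble prediction is the arithmetic mean of the
member outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import correlation_to_mean, mean_single_trial_correlation
from .nn import Adam, CoreConfig, CoreReadout, poisson_loss
from .recording import ResponsePack, resample_linear
from .stats import pearson
from .stimuli import MovieStimulus


@dataclass
class TrainingSchedule:
    lr: float = 0.01
    lr_decay: float = 0.3
    n_cycles: int = 4
    patience: int = 5
    batch_size: int = 32
    chunk_size: int = 50
    max_epochs_per_cycle: int = 50
    n_members: int = 5
    n_val_clips: int = 15
    min_tau: float = 0.05
    #: strength of the radial weight decay on spatial kernels; pulls each
    #: kernel's energy toward its own centre, resolving the translation
    #: ambiguity between core kernels and readout locations
    spatial_decay: float = 0.02
    #: learning-rate multipliers for position-like readout parameters
    mu_lr_scale: float = 20.0
    sigma_lr_scale: float = 5.0


def reduced_schedule(max_epochs: int = 10, n_members: int = 2,
                     n_cycles: int = 1, n_val_clips: int = 4) -> TrainingSchedule:
    """A desk-scale schedule for tests and worked examples."""
    return TrainingSchedule(
        n_cycles=n_cycles,
        max_epochs_per_cycle=max_epochs,
        n_members=n_members,
        n_val_clips=n_val_clips,
    )


class RetinaTwin:
    """Encoding model of a recorded population, built from data.

    Parameters
    ----------
    movie
        The stimulus the targets were recorded to.
    rates
        Firing-rate targets [n_neurons, n_frames] at the movie frame rate,
        aligned with ``movie.frames``.
    core_config
        Architecture; defaults to the 16/16-feature CNN.  Pass
        ``ln=True`` for the linearised (identity-activation) variant.
    """

    def __init__(
        self,
        movie: MovieStimulus,
        rates: np.ndarray,
        core_config: CoreConfig | None = None,
        ln: bool = False,
        cells=None,
    ) -> None:
        rates = np.asarray(rates, dtype=float)
        if rates.shape[1] != movie.n_frames:
            raise ValueError("rates and movie disagree on the number of frames")
        self.movie = movie
        self.rates = rates
        if core_config is None:
            core_config = CoreConfig()
        if ln:
            core_config = replace(core_config, nonlinearity="identity")
        self.core_config = core_config
        self.cells = cells
        self.n_neurons = rates.shape[0]
        self._movie_z = movie.zscored()

    # ----------------------------------------------------------- constructors
    @classmethod
    def from_recording(
        cls,
        pack: ResponsePack,
        movie: MovieStimulus,
        rate_method: str = "ground_truth_passthrough",
        **kwargs,
    ) -> "RetinaTwin":
        """Build the model from a simulated recording.

        ``ground_truth_passthrough`` trains on the simulator's stored rates;
        ``nonneg_deconvolution`` runs the trace preprocessing first.
        """
        if rate_method == "ground_truth_passthrough":
            rates = pack.rates
        else:
            from .preprocess import detrend_trace, infer_rates

            tau = pack.config.calcium_tau or 1.0
            rows = []
            for i in range(pack.n_cells):
                det = detrend_trace(pack.traces[i], pack.trace_rate, pack.t0)
                r = infer_rates(det, method=rate_method, calcium_tau=tau,
                                target_rate=movie.frame_rate)
                rows.append(r[pack.t0 * 0:])  # full trace; stimulus part below
            # trim the pre-stimulus segment and align to the movie frames;
            # resampling can fall a few frames short at the end -- edge-pad
            n_pre = int(round(pack.t0 / pack.trace_rate * movie.frame_rate))
            aligned = []
            for row in rows:
                seg = row[n_pre:n_pre + movie.n_frames]
                if len(seg) < movie.n_frames:
                    seg = np.pad(seg, (0, movie.n_frames - len(seg)),
                                 mode="edge")
                aligned.append(seg)
            rates = np.stack(aligned)
        return cls(movie, rates, cells=pack.cells, **kwargs)

    # ------------------------------------------------------------------- fit
    def fit(
        self,
        schedule: TrainingSchedule | None = None,
        seed: int = 0,
        verbose: bool = False,
    ) -> "RetinaTwinResults":
        """Train an ensemble and return the results object."""
        schedule = schedule or TrainingSchedule()
        train_clips, val_clips = self._split_clips(schedule, seed)
        chunks = self._make_chunks(train_clips, schedule.chunk_size)
        if not val_clips.size:
            raise ValueError("no validation clips available")
        members: list[CoreReadout] = []
        logs = []
        seeds = np.random.SeedSequence(seed).generate_state(schedule.n_members)
        for m, mseed in enumerate(seeds):
            member, log = self._fit_member(
                int(mseed % (2**31)), schedule, chunks, val_clips, verbose
            )
            log["member"] = m
            members.append(member)
            logs.append(log)
        history = pd.concat(logs, ignore_index=True)
        return RetinaTwinResults(
            model=self,
            members=members,
            history=history,
            schedule=schedule,
            seed=seed,
            val_clips=val_clips,
        )

    # ------------------------------------------------------------- internals
    def _split_clips(self, schedule, seed):
        train = self.movie.train_clip_indices
        n_val = min(schedule.n_val_clips, max(1, len(train) - 1))
        rng = np.random.default_rng(seed)
        val = rng.choice(train, size=n_val, replace=False)
        keep = np.setdiff1d(train, val)
        return keep, np.sort(val)

    def _make_chunks(self, clip_indices, chunk_size):
        starts = []
        L = self.movie.clip_length
        per_clip = L // chunk_size
        for k in clip_indices:
            base = k * L
            for c in range(per_clip):
                starts.append(base + c * chunk_size)
        return np.array(starts)

    def _batch(self, starts, chunk_size):
        offset = self.core_config.temporal_support - 1
        x = np.stack([self._movie_z[:, s:s + chunk_size] for s in starts])
        y = np.stack(
            [self.rates[:, s + offset:s + chunk_size] for s in starts]
        )  # [B, N, chunk - offset]
        return x, y

    def _validation_corr(self, model, val_clips):
        offset = model.time_offset
        preds, targs = [], []
        L = self.movie.clip_length
        for k in val_clips:
            sl = slice(k * L, (k + 1) * L)
            pred = model.forward(self._movie_z[:, sl])
            preds.append(pred)
            targs.append(self.rates[:, sl][:, offset:])
        pred = np.concatenate(preds, axis=1)
        targ = np.concatenate(targs, axis=1)
        corrs = [
            pearson(pred[n], targ[n], flag_constant=False)
            for n in range(self.n_neurons)
        ]
        return float(np.mean(corrs))

    def _fit_member(self, seed, schedule, chunks, val_clips, verbose):
        model = CoreReadout(self.core_config, self.n_neurons, seed=seed)
        rng = np.random.default_rng(seed)
        radial = {}
        for key in ("S1", "S2"):
            K = model.params[key].shape[-1]
            r = np.arange(K) - (K - 1) / 2.0
            radial[key] = (r[:, None] ** 2 + r[None, :] ** 2) / (K / 2.0) ** 2
        lr = schedule.lr
        best_params = {k: v.copy() for k, v in model.params.items()}
        best_buffers = {k: v.copy() for k, v in model.buffers.items()}
        best_corr = -np.inf
        rows = []
        epoch = 0
        for cycle in range(schedule.n_cycles):
            opt = Adam(
                model.params, lr=lr,
                lr_scale={"mu": schedule.mu_lr_scale,
                          "log_sigma": schedule.sigma_lr_scale},
            )
            stale = 0
            for _ in range(schedule.max_epochs_per_cycle):
                order = rng.permutation(len(chunks))
                for b0 in range(0, len(order), schedule.batch_size):
                    sel = chunks[order[b0:b0 + schedule.batch_size]]
                    x, y = self._batch(sel, schedule.chunk_size)
                    pred, cache = model.forward(x, train=True, cache_out=True)
                    _, dpred = poisson_loss(pred, y, average=True)
                    grads, _ = model.backward(dpred, cache)
                    if schedule.spatial_decay > 0:
                        for key in ("S1", "S2"):
                            grads[key] = grads[key] + (
                                2.0 * schedule.spatial_decay
                                * radial[key] * model.params[key]
                            )
                    opt.step(model.params, grads)
                    model.params["tau"] = np.maximum(
                        model.params["tau"], schedule.min_tau
                    )
                corr = self._validation_corr(model, val_clips)
                rows.append(dict(cycle=cycle, epoch=epoch, lr=lr, val_corr=corr))
                if verbose:
                    print(f"cycle {cycle} epoch {epoch} lr {lr:.4g} "
                          f"val corr {corr:.4f}")
                epoch += 1
                if corr > best_corr:
                    best_corr = corr
                    best_params = {k: v.copy() for k, v in model.params.items()}
                    best_buffers = {k: v.copy() for k, v in model.buffers.items()}
                    stale = 0
                else:
                    stale += 1
                    if stale >= schedule.patience:
                        break
            model.params = {k: v.copy() for k, v in best_params.items()}
            model.buffers = {k: v.copy() for k, v in best_buffers.items()}
            lr *= schedule.lr_decay
        return model, pd.DataFrame(rows)


class RetinaTwinResults:
    """Trained ensemble with evaluation and in-silico probing interfaces."""

    def __init__(self, model, members, history, schedule, seed, val_clips):
        self.model = model
        self.members = members
        self.history = history
        self.schedule = schedule
        self.seed = seed
        self.val_clips = val_clips

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def time_offset(self) -> int:
        return self.members[0].time_offset

    # ------------------------------------------------------------ prediction
    def predict(self, frames_z: np.ndarray) -> np.ndarray:
        """Ensemble-mean rate prediction for a standardised stimulus."""
        return np.mean([m.forward(frames_z) for m in self.members], axis=0)

    def predict_movie(self, clips: str = "test") -> np.ndarray:
        movie = self.model.movie
        z = self.model._movie_z
        mask = (~movie.train_frame_mask if clips == "test"
                else movie.train_frame_mask)
        return self.predict(z[:, mask])

    def activation(self, x: np.ndarray, neuron: int,
                   centered: bool = False) -> float:
        """Time-averaged ensemble response of one neuron to a stimulus."""
        members = self._members_for(neuron, centered)
        vals = [m.forward(x)[neuron].mean() for m in members]
        return float(np.mean(vals))

    def activation_and_gradient(self, x: np.ndarray, neuron: int,
                                centered: bool = False):
        """Objective (time-averaged response) and its input gradient.

        The gradient is of the ensemble mean, with batch-norm statistics
        frozen (all forward passes here run in eval mode).
        """
        members = self._members_for(neuron, centered)
        acts, grads = [], []
        for m in members:
            pred, cache = m.forward(x, train=False, cache_out=True)
            T = pred.shape[1]
            acts.append(pred[neuron].mean())
            dpred = np.zeros_like(pred)
            dpred[neuron] = 1.0 / T
            _, dx = m.backward(dpred, cache, compute_dx=True)
            grads.append(dx)
        return float(np.mean(acts)), np.mean(grads, axis=0)

    def _members_for(self, neuron: int, centered: bool):
        if not centered:
            return self.members
        key = ("centered", neuron)
        cache = getattr(self, "_centered_cache", {})
        if key not in cache:
            mems = []
            for m in self.members:
                mc = m.copy()
                mc.params["mu"][neuron] = 0.0
                mems.append(mc)
            cache[key] = mems
            self._centered_cache = cache
        return cache[key]

    # ------------------------------------------------------------ evaluation
    def evaluate(self, test_repeat_rates: np.ndarray) -> pd.DataFrame:
        """Per-neuron correlation to the repeat mean and single-trial mean.

        ``test_repeat_rates`` is [n_neurons, n_repeats, T] at the movie
        frame rate, aligned with the test clips.  The first
        ``time_offset`` frames are dropped to match the prediction length.
        """
        pred = self.predict_movie("test")
        off = self.time_offset
        reps = test_repeat_rates[:, :, off:off + pred.shape[1]]
        rows = []
        for n in range(pred.shape[0]):
            rows.append(
                dict(
                    neuron=n,
                    corr_to_mean=correlation_to_mean(pred[n], reps[n]),
                    mean_single_trial_corr=mean_single_trial_correlation(
                        pred[n], reps[n]
                    ),
                )
            )
        return pd.DataFrame(rows).set_index("neuron")

    def readout_locations(self) -> np.ndarray:
        """Ensemble-mean readout centres in canvas (row, col) pixels."""
        H, W = self.members[0].canvas
        mus = np.mean([m.params["mu"] for m in self.members], axis=0)  # (x, y)
        rows = mus[:, 1] + (H - 1) / 2.0
        cols = mus[:, 0] + (W - 1) / 2.0
        return np.stack([rows, cols], axis=1)

    def summary(self, test_repeat_rates: np.ndarray | None = None) -> str:
        lines = [
            "RetinaTwin ensemble",
            f"  architecture: {self.model.core_config.nonlinearity.upper()} core, "
            f"{self.model.core_config.n_features} features",
            f"  neurons: {self.model.n_neurons}   members: {self.n_members}",
            f"  training epochs (per member): "
            f"{self.history.groupby('member').size().tolist()}",
            f"  best validation correlation: "
            f"{self.history.groupby('member').val_corr.max().round(3).tolist()}",
        ]
        if test_repeat_rates is not None:
            ev = self.evaluate(test_repeat_rates)
            lines.append(
                f"  test correlation to mean: {ev.corr_to_mean.mean():.3f} "
                f"(mean over neurons)"
            )
        return "\n".join(lines)


def test_repeat_rates(pack: ResponsePack, movie: MovieStimulus,
                      method: str = "ground_truth_passthrough") -> np.ndarray:
    """Firing rates per test repeat at the movie frame rate, [N, R, T].

    Passthrough duplicates the noiseless ground-truth test rates across
    repeats plus nothing (for pipeline tests); deconvolution inverts each
    repeat's calcium trace independently.
    """
    if method == "ground_truth_passthrough":
        tr = pack.test_rates(movie)
        return np.repeat(tr[:, None, :], pack.test_repeats.shape[1], axis=1)
    from .preprocess import deconvolve_exponential

    tau = pack.config.calcium_tau or 1.0
    N, R, Tt = pack.test_repeats.shape
    T_frames = int(np.sum(~movie.train_frame_mask))
    out = np.empty((N, R, T_frames))
    for n in range(N):
        for r in range(R):
            rate = deconvolve_exponential(pack.test_repeats[n, r],
                                          pack.trace_rate, tau)
            up = resample_linear(rate, pack.trace_rate, movie.frame_rate)
            if len(up) < T_frames:
                up = np.pad(up, (0, T_frames - len(up)), mode="edge")
            out[n, r] = up[:T_frames]
    return out
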