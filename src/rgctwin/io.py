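"""HDF5 / YAML / table serialisation for pipeline artefacts."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .population import SimulatedCell
from .recording import RecordingConfig, ResponsePack
from .stimuli import MovieConfig, MovieStimulus


def save_movie(path, movie: MovieStimulus) -> None:
    with h5py.File(path, "a") as f:
        if "movie" in f:
            del f["movie"]
        g = f.create_group("movie")
        g.create_dataset("frames", data=movie.frames, compression="gzip")
        g.create_dataset("clip_ids", data=movie.clip_ids)
        g.create_dataset("clip_labels",
                         data=np.array(movie.clip_labels, dtype="S"))
        g.create_dataset("split", data=np.array(movie.split, dtype="S"))
        g.create_dataset("test_repeat_index", data=movie.test_repeat_index)
        g.create_dataset("intensity_range", data=movie.intensity_range)
        g.attrs["frame_rate"] = movie.frame_rate
        g.attrs["clip_length"] = movie.clip_length
        g.attrs["seed"] = -1 if movie.seed is None else movie.seed
        g.attrs["config"] = json.dumps(dataclasses.asdict(movie.config))


def load_movie(path) -> MovieStimulus:
    with h5py.File(path, "r") as f:
        g = f["movie"]
        cfg_d = json.loads(g.attrs["config"])
        for key in ("mean_range", "texture_sigma"):
            cfg_d[key] = tuple(cfg_d[key])
        seed = int(g.attrs["seed"])
        return MovieStimulus(
            frames=g["frames"][:],
            frame_rate=float(g.attrs["frame_rate"]),
            clip_length=int(g.attrs["clip_length"]),
            clip_ids=g["clip_ids"][:],
            clip_labels=g["clip_labels"][:].astype(str),
            split=g["split"][:].astype(str),
            test_repeat_index=g["test_repeat_index"][:],
            intensity_range=g["intensity_range"][:],
            config=MovieConfig(**cfg_d),
            seed=None if seed < 0 else seed,
        )


def save_responses(path, pack: ResponsePack) -> None:
    with h5py.File(path, "a") as f:
        if "responses" in f:
            del f["responses"]
        g = f.create_group("responses")
        g.create_dataset("traces", data=pack.traces, compression="gzip")
        g.create_dataset("rates", data=pack.rates, compression="gzip")
        g.create_dataset("test_repeats", data=pack.test_repeats,
                         compression="gzip")
        g.attrs["t0"] = pack.t0
        g.attrs["trace_rate"] = pack.trace_rate
        g.attrs["frame_rate"] = pack.frame_rate
        g.attrs["recording_id"] = pack.recording_id
        g.attrs["seed"] = -1 if pack.seed is None else pack.seed
        g.attrs["config"] = json.dumps(dataclasses.asdict(pack.config))
        cells = [_cell_to_dict(c) for c in pack.cells]
        g.attrs["cells"] = json.dumps(cells)


def load_responses(path) -> ResponsePack:
    with h5py.File(path, "r") as f:
        g = f["responses"]
        cells = [_cell_from_dict(d) for d in json.loads(g.attrs["cells"])]
        seed = int(g.attrs["seed"])
        return ResponsePack(
            traces=g["traces"][:],
            rates=g["rates"][:],
            test_repeats=g["test_repeats"][:],
            t0=int(g.attrs["t0"]),
            trace_rate=float(g.attrs["trace_rate"]),
            frame_rate=float(g.attrs["frame_rate"]),
            recording_id=str(g.attrs["recording_id"]),
            cells=cells,
            config=RecordingConfig(**json.loads(g.attrs["config"])),
            seed=None if seed < 0 else seed,
        )


def _cell_to_dict(c: SimulatedCell) -> dict:
    d = dataclasses.asdict(c)
    d["spatial_filter"] = c.spatial_filter.tolist()
    d["temporal_filter"] = c.temporal_filter.tolist()
    return d


def _cell_from_dict(d: dict) -> SimulatedCell:
    d = dict(d)
    d["spatial_filter"] = np.array(d["spatial_filter"])
    d["temporal_filter"] = np.array(d["temporal_filter"])
    d["chromatic_weights"] = tuple(d["chromatic_weights"])
    d["rf_location"] = tuple(d["rf_location"])
    return SimulatedCell(**d)


def save_meis(path, records: dict) -> None:
    """Archive MEIRecord objects as /meis/<cell>/{tensor,trace}."""
    with h5py.File(path, "a") as f:
        if "meis" in f:
            del f["meis"]
        g = f.create_group("meis")
        for name, rec in records.items():
            sub = g.create_group(str(name))
            sub.create_dataset("tensor", data=rec.tensor)
            sub.create_dataset("trace", data=rec.activations)
            sub.attrs["converged"] = rec.converged
            sub.attrs["n_iter"] = rec.n_iter
            sub.attrs["norm_budget"] = rec.norm_budget
            sub.attrs["seed"] = rec.seed


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
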