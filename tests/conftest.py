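"""Shared fixtures.

Heavy fixtures (trained models) are session-scoped and sized for a single
CPU: small movies, small populations, short schedules.  Everything is
generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rgctwin import (
    MovieConfig,
    PopulationConfig,
    RecordingConfig,
    RetinaTwin,
    TrainingSchedule,
    generate_movie,
    generate_population,
    simulate_recording,
)


@pytest.fixture(scope="session")
def small_movie():
    return generate_movie(MovieConfig(n_clips=12), seed=0)


@pytest.fixture(scope="session")
def mixed_cells():
    return generate_population(
        PopulationConfig(
            counts={"ON": 2, "OFF": 2, "ON-OFF": 2, "slow-ON": 2,
                    "opponent-SbC": 2}
        ),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_pack(small_movie, mixed_cells):
    return simulate_recording(mixed_cells, small_movie, seed=2)


@pytest.fixture(scope="session")
def clean_pack(small_movie, mixed_cells):
    return simulate_recording(
        mixed_cells,
        small_movie,
        seed=2,
        config=RecordingConfig(noise_level=0.0, drift_amplitude=0.0,
                               calcium_tau=None),
    )


def _desk_schedule(n_members=1, epochs=12):
    return TrainingSchedule(
        n_cycles=2,
        max_epochs_per_cycle=epochs,
        batch_size=16,
        n_members=n_members,
        n_val_clips=5,
        spatial_decay=0.05,
        patience=6,
    )


@pytest.fixture(scope="session")
def recovery_setup():
    """Noiseless LN cells + trained CNN ensemble for parameter recovery."""
    movie = generate_movie(MovieConfig(n_clips=40), seed=0)
    cells = generate_population(
        PopulationConfig(counts={"ON": 5, "slow-ON": 3}, noise_level=0.0),
        seed=1,
    )
    pack = simulate_recording(
        cells, movie, seed=2,
        config=RecordingConfig(noise_level=0.0, drift_amplitude=0.0),
    )
    twin = RetinaTwin.from_recording(pack, movie)
    results = twin.fit(schedule=_desk_schedule(n_members=2), seed=3)
    return movie, cells, pack, results


@pytest.fixture(scope="session")
def opponency_setup():
    """ON + opponent-SbC population with fitted CNN and LN-variant models."""
    movie = generate_movie(MovieConfig(n_clips=40), seed=0)
    cells = generate_population(
        PopulationConfig(counts={"ON": 6, "opponent-SbC": 6}), seed=1
    )
    pack = simulate_recording(cells, movie, seed=2)
    sch = _desk_schedule(n_members=1)
    res_cnn = RetinaTwin.from_recording(pack, movie).fit(schedule=sch, seed=3)
    res_ln = RetinaTwin.from_recording(pack, movie, ln=True).fit(
        schedule=sch, seed=3
    )
    return movie, cells, pack, res_cnn, res_ln


@pytest.fixture(scope="session")
def opponency_meis(opponency_setup):
    """MEIs and their characterisations for both model variants."""
    from rgctwin.mei import MEIOptions, characterize_mei, synthesize_mei

    movie, cells, pack, res_cnn, res_ln = opponency_setup
    out = {}
    for name, res in (("cnn", res_cnn), ("ln", res_ln)):
        recs, props = [], []
        for i in range(len(cells)):
            rec = synthesize_mei(res, i, MEIOptions(seed=7))
            recs.append(rec)
            props.append(characterize_mei(rec))
        out[name] = (recs, props)
    return out


@pytest.fixture(scope="session")
def linear_model_results():
    """An LN-variant model with hand-set weights in the softplus-linear
    regime: the analytically tractable case for MEI synthesis."""
    from rgctwin.model import RetinaTwinResults
    from rgctwin.nn import CoreReadout

    movie = generate_movie(MovieConfig(n_clips=10), seed=0)
    twin = RetinaTwin(movie, np.ones((1, movie.n_frames)), ln=True)
    member = CoreReadout(twin.core_config, 1, seed=5)
    member.params["W"] *= 20.0
    member.params["bias"][:] = 40.0
    # normalise the effective linear filter to unit norm so the fixed
    # ascent step size is well conditioned
    probe = RetinaTwinResults(
        model=twin, members=[member], history=pd.DataFrame(), schedule=None,
        seed=0, val_clips=np.array([]),
    )
    _, F = probe.activation_and_gradient(
        np.zeros((2, 50, 18, 16)), 0, centered=True
    )
    member.params["W"] /= np.linalg.norm(F)
    return RetinaTwinResults(
        model=twin, members=[member], history=pd.DataFrame(),
        schedule=None, seed=0, val_clips=np.array([]),
    )
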