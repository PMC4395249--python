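"""Shared fixtures: synthetic scenes and fitted models reused across tests."""

import numpy as np
import pytest

from netscale import (
    MultiScaleNetworkModel,
    SceneSpec,
    generate_scene,
    truth_adjusted_rand,
)

N_SWEEP_SEEDS = 20


@pytest.fixture(scope="session")
def scene0():
    """Default-spec scene, seed 0."""
    return generate_scene(SceneSpec(seed=0))


@pytest.fixture(scope="session")
def fitted0(scene0):
    """Model and results fitted on the seed-0 scene."""
    model = MultiScaleNetworkModel.from_scene(scene0)
    return model, model.fit(seed=0)


@pytest.fixture(scope="session")
def hierarchy_sweep():
    """Planted-hierarchy recovery sweep over 20 seeds (criteria 4, 5, 6).

    Returns a list of dicts with the scene, fitted results and recovery
    metrics per seed.
    """
    rows = []
    for seed in range(N_SWEEP_SEEDS):
        scene = generate_scene(SceneSpec(seed=seed))
        model = MultiScaleNetworkModel.from_scene(scene)
        results = model.fit(seed=seed)
        first_cut = results.scale_labels(2)  # root is scale 1; first split at 2
        second_cut = results.scale_labels(3)
        rows.append(
            {
                "seed": seed,
                "scene": scene,
                "results": results,
                "first_split_k": len(np.unique(first_cut)),
                "ari_depth1": truth_adjusted_rand(first_cut, scene.truth_at_level(1)),
                "ari_depth2": truth_adjusted_rand(second_cut, scene.truth_at_level(2)),
            }
        )
    return rows


@pytest.fixture(scope="session")
def tiny_scene():
    """A small, fast scene for pipeline and IO round-trip tests."""
    spec = SceneSpec(
        hierarchy=[2, 2],
        landmarks_per_leaf=2,
        n_subjects=2,
        mesh_subdivisions=3,
        seed=5,
    )
    return generate_scene(spec)
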