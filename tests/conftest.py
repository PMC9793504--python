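import numpy as np
import pytest

import caretraj as ct


@pytest.fixture(scope="session")
def specs():
    return ct.default_channel_specs()


@pytest.fixture(scope="session")
def cost_model(specs):
    return ct.build_cost_model(specs)


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort (raw, unfiltered) with latent labels."""
    cfg = ct.default_config(n_raw=400, seed=123)
    return ct.generate_cohort(cfg)


@pytest.fixture(scope="session")
def retained_small(small_cohort):
    cohort, labels = small_cohort
    kept, retained, _ = ct.filter_min_observations(cohort)
    id_to_lab = dict(zip(cohort.ids, labels))
    lab = np.array([id_to_lab[i] for i in kept.ids])
    return kept, lab


def random_valid_states(rng, n, specs, n_waves=11):
    """Random cohort states honouring the overlay invariants."""
    states = np.zeros((n, n_waves, len(specs)), dtype=np.int8)
    for j, spec in enumerate(specs):
        states[:, :, j] = rng.integers(0, spec.k, size=(n, n_waves))
    death = rng.integers(0, 2 * n_waves, size=n)  # > n_waves-1 = never
    for i in range(n):
        if death[i] < n_waves:
            states[i, death[i]:, :] = ct.DEAD
        for w in range(min(death[i], n_waves)):
            r = rng.random()
            if r < 0.06:
                states[i, w, :] = ct.NR
            elif r < 0.08:
                states[i, w, :] = ct.INCAP
    return states
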