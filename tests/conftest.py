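import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from trtequate import (
    SimulationCondition,
    assemble_concurrent_matrix,
    build_form_pair,
    generate_responses,
    replication_rng,
    sample_persons,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_dich_data():
    """One small dichotomous NEAT replication (n=400/group) with truth attached."""
    cond = SimulationCondition(
        data_family="dichotomous", testlet_effect="moderate", testlet_length=5,
        sample_size=400, n_replications=1, seed=42,
    )
    gen = replication_rng(42, 0, 0)
    pair = build_form_pair(cond, gen)
    pb = sample_persons(cond.sample_size, "base", pair.testlets_for("base"), gen)
    pn = sample_persons(cond.sample_size, "new", pair.testlets_for("new"), gen, 0.5)
    matrix = assemble_concurrent_matrix(
        generate_responses(pair.base_items, pb, gen),
        generate_responses(pair.new_items, pn, gen),
        pair,
    )
    return {"condition": cond, "pair": pair, "matrix": matrix, "base": pb, "new": pn}
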