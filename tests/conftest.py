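import numpy as np
import pandas as pd
import pytest

from riskframe.io import load_packaged_games
from riskframe.sampling import SamplerConfig
from riskframe.simulate import (
    GeneratorTruth,
    gen_endowment,
    gen_hormones,
    simulate_study,
    t_change_from_panel,
)


@pytest.fixture(scope="session")
def games():
    return load_packaged_games()


@pytest.fixture(scope="session")
def games_by_key(games):
    return {(g.game_id, g.framing): g for g in games}


@pytest.fixture(scope="session")
def small_truth():
    return GeneratorTruth(n_subjects=12)


@pytest.fixture(scope="session")
def small_study(small_truth, games):
    return simulate_study(small_truth, seed=101, games=games,
                          n_items_per_type=4)


@pytest.fixture(scope="session")
def small_sampler():
    return SamplerConfig(chains=2, draws=300, warmup=300)


@pytest.fixture(scope="session")
def endowment_panel():
    truth = GeneratorTruth(n_subjects=15)
    hormones = gen_hormones(truth, seed=55)
    records = gen_endowment(truth, n_items_per_type=5, seed=56,
                            hormones=hormones)
    tch = t_change_from_panel(hormones)
    return {"truth": truth, "hormones": hormones, "records": records,
            "t_change": tch}
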