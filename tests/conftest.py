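import numpy as np
import pytest

from gelamatch.data_model import AnalysisConfig, FstMatrix, PopulationPanel, PopulationRecord
from gelamatch.synthetic import ScenarioConfig, expected_fst_matrix, generate_panel


def make_record(pop_id, lat, lon, family, language=None, region="R1", ne=5000.0, n=10):
    return PopulationRecord(
        pop_id=pop_id, n_individuals=n, lat=lat, lon=lon,
        language_id=language or f"lang_{pop_id}", family=family,
        macro_region=region, ne=ne, ne_ci_low=ne * 0.8, ne_ci_high=ne * 1.25,
    )


@pytest.fixture
def tiny_panel():
    """Six populations, two families, all within ~600 km of (0, 0)."""
    recs = [
        make_record("a1", 0.0, 0.0, "famA"),
        make_record("a2", 0.0, 1.0, "famA"),
        make_record("a3", 1.0, 0.5, "famA"),
        make_record("b1", 0.5, 2.0, "famB"),
        make_record("b2", 1.5, 2.5, "famB"),
        make_record("b3", 2.0, 2.0, "famB"),
    ]
    return PopulationPanel(recs)


@pytest.fixture
def tiny_fst(tiny_panel):
    """Within-family FST ~0.01, between-family ~0.05, deterministic."""
    ids = tiny_panel.pop_ids
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = tiny_panel.family_of(ids[i]) == tiny_panel.family_of(ids[j])
            base = 0.01 if same else 0.05
            values[i, j] = values[j, i] = base + 0.001 * (i + j)
    return FstMatrix(ids, values)


@pytest.fixture
def config():
    return AnalysisConfig(rng_seed=17, bootstrap_reps=500)


@pytest.fixture(scope="session")
def scenario():
    """Default scenario panel (seed 11) with planted events and its truth."""
    cfg = ScenarioConfig(rng_seed=11)
    panel, truth = generate_panel(cfg)
    fst = expected_fst_matrix(truth, cfg)
    return cfg, panel, truth, fst


@pytest.fixture(scope="session")
def null_scenario():
    """Event-free scenario panel (seed 23)."""
    cfg = ScenarioConfig(rng_seed=23, events={})
    panel, truth = generate_panel(cfg)
    fst = expected_fst_matrix(truth, cfg)
    return cfg, panel, truth, fst
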