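import numpy as np
import pytest

import nacscore as ns

#: Stationary occupancies used by most fixtures: e.e. = 100*(0.30-0.075)/0.375 = 60.
OCCUPANCIES = {"proS_NAC": 0.30, "proR_NAC": 0.075, "nonproductive_1": 0.625}


@pytest.fixture(scope="session")
def basin_model_60():
    """Fast-mixing three-basin model with analytic epimeric excess 60%."""
    return ns.make_basin_model(OCCUPANCIES, hop_rate_per_ps=1.0)


@pytest.fixture(scope="session")
def slow_basin_model_60():
    """Same occupancies but basin dwell times far beyond replica length."""
    return ns.make_basin_model(OCCUPANCIES, hop_rate_per_ps=1e-4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def synthetic_traj(tmp_path_factory, basin_model_60):
    """Three written PDB replicas (11 frames each) plus the truth sidecar."""
    proto = ns.ProtocolSpec(n_replicas=3, warmup_ps=30.0, equilibration_ps=20.0,
                            production_ps=50.0, snapshot_interval_ps=5.0,
                            nac_eval_interval_ps=5.0, name="fixture")
    out = tmp_path_factory.mktemp("traj")
    result = ns.write_synthetic_trajectory(basin_model_60, proto, seed=7,
                                           out_dir=out)
    result["protocol"] = proto
    return result


@pytest.fixture(scope="session")
def synthetic_selection():
    return ns.SelectionSpec.from_dict(ns.reconstruction_selection())
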