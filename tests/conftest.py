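import numpy as np
import pandas as pd
import pytest

from phosdyn.containers import AbundanceMatrix
from phosdyn.pipeline import PipelineConfig, run_pipeline
from phosdyn.synth import SimulationConfig, simulate, write_simulation

SMALL_CONFIG = SimulationConfig(
    n_proteins=80, length_range=(200, 500),
    n_cdk_sites=60, n_control_sites=30,
    n_flat_decoys=300, n_decreasing_decoys=60)


@pytest.fixture(scope="session")
def small_sim():
    """Reduced synthetic scenario shared by module-level tests."""
    return simulate(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def default_sim():
    """The full default synthetic scenario (study conditions)."""
    return simulate(SimulationConfig(), seed=5)


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """Full pipeline run on the default scenario; returns (simdir, rundir)."""
    base = tmp_path_factory.mktemp("default_run")
    simdir, rundir = base / "simdata", base / "run"
    write_simulation(default_sim, simdir)
    run_pipeline(PipelineConfig(indir=str(simdir), outdir=str(rundir),
                                seed=5))
    return simdir, rundir


def toy_matrix(values, times, replicates, dataset="tc", features=None):
    """Small AbundanceMatrix helper for hand-arithmetic tests."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = features or [f"f{i}" for i in range(n_feat)]
    samples = [f"s{i}" for i in range(n_samp)]
    vals = pd.DataFrame(values, index=features, columns=samples)
    meta = pd.DataFrame({"time_min": times, "replicate": replicates,
                         "dataset": dataset}, index=samples)
    return AbundanceMatrix(vals, meta)
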