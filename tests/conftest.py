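import numpy as np
import pandas as pd
import pytest

from mobrec import pipeline, trajectory_sim
from mobrec.io_config import RunConfig

CANONICAL_SEED = 1


@pytest.fixture(scope="session")
def paper_run():
    """One full raw-trace -> feature -> statistics run of the calibrated
    13-patient cohort (the study-scale conditions), shared across tests."""
    cfg = trajectory_sim.paper_cohort_config()
    bundle = trajectory_sim.simulate_cohort(cfg, CANONICAL_SEED)
    results = pipeline.run_pipeline(bundle, RunConfig(), seed=CANONICAL_SEED)
    results["bundle"] = bundle
    results["cohort_config"] = cfg
    return results


@pytest.fixture(scope="session")
def truth_vs_extracted(paper_run):
    """Daily summaries merged with ground truth (per patient-day)."""
    m = paper_run["daily_summaries"].merge(
        paper_run["bundle"].ground_truth, on=["patient_id", "postop_day"],
        suffixes=("_x", "_t"))
    return m


@pytest.fixture()
def rng():
    return np.random.default_rng(20230403)


def make_gps_frame(t, lat, lon):
    return pd.DataFrame({"t": np.asarray(t, float), "lat": np.asarray(lat, float),
                         "lon": np.asarray(lon, float), "accuracy": 5.0})
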