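import numpy as np
import pytest

from peak4d.models import Frame, FrameArchive, MS2Record
from peak4d.simulate import GroundTruthPeak, SimulationConfig, random_truth, simulate_dataset


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def small_truth():
    return random_truth(10, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_truth, sim_config):
    """One simulated DDA run with 10 ground-truth peaks."""
    return simulate_dataset(small_truth, sim_config, run_id="fixture")


@pytest.fixture
def tiny_archive():
    """Hand-built 3-MS1-frame archive with a single known point pattern."""
    grid = (0.40, 1.50, 0.001)
    frames = [
        Frame(index=1, rt=1.0, ms_level=1,
              mz=np.array([100.000, 100.002, 300.0]),
              mobility=np.array([0.800, 0.800, 1.200]),
              intensity=np.array([10.0, 30.0, 5.0])),
        Frame(index=2, rt=2.0, ms_level=1,
              mz=np.array([100.001]), mobility=np.array([0.801]),
              intensity=np.array([20.0])),
        Frame(index=3, rt=3.0, ms_level=1,
              mz=np.empty(0), mobility=np.empty(0), intensity=np.empty(0)),
    ]
    return FrameArchive(
        run_id="tiny",
        frames=frames,
        metadata={"mode": "DDA", "cycle_time": 1.0, "mobility_grid": grid},
    )


def make_record(mz=300.0, rt=30.0, mobility=0.9, frame=1, fragments=None, title="r"):
    if fragments is None:
        fragments = [(100.0, 500.0), (150.0, 1000.0)]
    return MS2Record(
        precursor_mz=mz, precursor_rt=rt, precursor_mobility=mobility,
        precursor_frame=frame, fragments=np.asarray(fragments, float), title=title,
    )


@pytest.fixture
def record_factory():
    return make_record
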