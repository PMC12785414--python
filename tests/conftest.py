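import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fpdyn.model import Atom, Trajectory
from fpdyn.synthetic import TrajectorySpec, WaterPlant, gen_trajectory


@pytest.fixture(scope="session")
def planted_run():
    """A short trajectory with one exit, one resident water, a flip and
    scripted hydrogen bonds — shared by several analysis tests."""
    spec = TrajectorySpec(
        duration_ns=10.0,
        frame_interval_ns=0.01,
        noise_sd_nm=0.01,
        water_plants=(
            WaterPlant("W1", exit_time_ns=4.2, exit_region="Reg 1"),
            WaterPlant("W2", exit_time_ns=7.77, exit_region="Reg 4"),
            WaterPlant("W3"),  # resident
        ),
        flip_times_ns=(6.0,),
        hbond_water_schedule=((0.0, 2), (5.0, 3)),
        hbond_protein_schedule=((0.0, 1),),
        seed=11,
    )
    return gen_trajectory(spec)


def toy_trajectory(coords, times=None, chain="A"):
    """A minimal trajectory of bare carbon atoms for geometry tests."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    topo = [
        Atom(serial=i + 1, name="CA", element="C", res_name="ALA",
             res_id=i + 1, chain=chain)
        for i in range(n_atoms)
    ]
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(topo, coords, np.asarray(times, dtype=float))
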