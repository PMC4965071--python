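import numpy as np
import pytest

from mutscan.synthetic import (SyntheticSpec, make_toy_complex,
                               simulate_trajectory, variant_charge_plans)


@pytest.fixture(scope="session")
def wt_spec():
    return SyntheticSpec(
        n_residues=9,
        charge_plan=variant_charge_plans(9)["wildtype"],
        fluctuation_amplitudes=0.3,
        ligand_amplitude=0.2,
        replica_count=2,
        frames_per_replica=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def wt_system(wt_spec):
    return make_toy_complex(wt_spec)


@pytest.fixture(scope="session")
def wt_trajectory(wt_spec, wt_system):
    traj, truth = simulate_trajectory(wt_system, wt_spec)
    return traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
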