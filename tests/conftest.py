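"""Shared fixtures: the pentamer scaffold, a ground-truth binding field
in a thin slab (so the 1D marginal along the channel axis tracks the
imposed potential), and the Metropolis sample set reused by the
parameter-recovery tests."""

import numpy as np
import pytest
from hypothesis import settings

from ionloop.pmf import pmf_1d
from ionloop.synthgen import (LOOP_SPAN_G312_Y327, SyntheticField, Well,
                              build_scaffold, sample_ion_trajectory)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

#: Ground-truth well depth (kJ/mol) for recovery tests.
WELL_DEPTH = 5.0
WELL_WIDTH = 0.2
RECOVERY_SEED = 7


@pytest.fixture(scope="session")
def pentamer():
    """Default five-chain scaffold over the G312..Y327 span."""
    top, traj = build_scaffold(n_chains=5,
                               residue_spec=LOOP_SPAN_G312_Y327, seed=0)
    return top, traj


@pytest.fixture(scope="session")
def slab_field():
    """Single 5 kJ/mol Gaussian well centred in a thin slab.

    The slab is 0.04 nm across in y and z, so the potential is within
    1 % of its on-axis value everywhere and the x-marginal histogram
    Boltzmann-inverts back to the declared well.
    """
    return SyntheticField(
        wells=[Well([0.0, 0.0, 0.0], WELL_DEPTH, WELL_WIDTH)],
        box=[[-1.0, 1.0], [-0.02, 0.02], [-0.02, 0.02]])


@pytest.fixture(scope="session")
def recovery_samples(slab_field):
    """1e5 Metropolis samples (10 ions x 1e4 frames) from the slab well."""
    traj = sample_ion_trajectory(slab_field, n_ions=10, n_frames=10_000,
                                 temperature=315.0, seed=RECOVERY_SEED)
    return np.abs(traj.coords[..., 0].ravel())


@pytest.fixture(scope="session")
def recovery_profile(recovery_samples):
    """Boltzmann-inverted profile of the recovery samples, anchored in
    the flat bulk at 0.8 nm, with block-bootstrap standard errors."""
    return pmf_1d(recovery_samples, bin_width=0.02, temperature=315.0,
                  r_ref=0.8, compute_se=True,
                  rng=np.random.default_rng(RECOVERY_SEED))
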