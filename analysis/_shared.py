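"""Shared setup for the numbered analysis scripts.

Every script regenerates the synthetic ensembles from fixed seeds via
:func:`build_condition`, so the whole analysis is reproducible from the
repository alone and no multi-megabyte trajectories need to be stored.
Results (small TSV/JSON tables) go under ``results/``.
"""

from pathlib import Path

import numpy as np

from ionloop.structio import resolve_selection
from ionloop.synthgen import (assemble_system, build_scaffold,
                              field_from_scaffold, ion_topology,
                              sample_ion_trajectory)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCAFFOLD_SEED = 1
N_IONS = 10
N_FRAMES = 2000
TEMPERATURE = 315.0
BULK_MARGIN = 1.6  # nm of flat bulk so the 2 nm PMF reference exists

#: The two declared landscapes: well depth = the condition's global
#: ion-loop binding free energy (kJ/mol).
CONDITIONS = {
    "trivalent": {"depths": (16.8, 16.8), "seed": 3},
    "divalent": {"depths": (9.5, 9.5), "seed": 6},
}


def build_condition(name):
    """(system topology, trajectory, field) for one declared condition."""
    cond = CONDITIONS[name]
    top, straj = build_scaffold(n_chains=5, seed=SCAFFOLD_SEED)
    frame0 = straj.coords[0]
    field = field_from_scaffold(top, frame0,
                                depth_e316=cond["depths"][0],
                                depth_e320=cond["depths"][1],
                                margin=BULK_MARGIN)
    itraj = sample_ion_trajectory(field, n_ions=N_IONS,
                                  n_frames=N_FRAMES,
                                  temperature=TEMPERATURE,
                                  seed=cond["seed"])
    sys_top, sys_traj = assemble_system(top, frame0,
                                        ion_topology(N_IONS), itraj)
    return sys_top, sys_traj, field


def glutamate_groups(top):
    e316 = [resolve_selection(top, f"chain:{c} and resid:316")
            for c in "ABCDE"]
    e320 = [resolve_selection(top, f"chain:{c} and resid:320")
            for c in "ABCDE"]
    return e316, e320


def per_ion_min_distances(top, traj, target_group):
    """(n_frames, n_ions) minimum distances from each ion center to the
    heavy atoms of the target group."""
    from scipy.spatial.distance import cdist
    heavy = target_group.indices[top.heavy_mask[target_group.indices]]
    ions = top.roles["ion_center"]
    return np.stack([cdist(traj.coords[f][ions],
                           traj.coords[f][heavy]).min(axis=1)
                     for f in range(traj.n_frames)])


def ensure_results():
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
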