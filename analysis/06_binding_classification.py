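#!/usr/bin/env python
"""Contact-based binding classification of the synthetic ensembles.

Per condition: bound-ion statistics (an ion is bound when at least one
residue has a heavy atom within 0.5 nm of it), the partition of frames
by bound count with the most common residue signatures, the E316/E320
contact-cluster populations, and a representative bound snapshot
selected by superposition + single-linkage clustering of ion positions.
"""

import numpy as np

from _shared import CONDITIONS, build_condition, ensure_results, \
    glutamate_groups
from ionloop.binding import (bound_ion_count, bound_state_partition,
                             cluster_populations, contact_records,
                             representative_snapshot)
from ionloop.structio import (SelectionGroup, Trajectory,
                              resolve_selection, write_structure)

results = ensure_results()
for name in CONDITIONS:
    top, traj, _ = build_condition(name)
    protein = resolve_selection(top, "not role:ion_center")
    e316, e320 = glutamate_groups(top)
    ions = top.roles["ion_center"]
    records = contact_records(top, traj, ions, protein, e316, e320)

    counts, mean, sd = bound_ion_count(records)
    print(f"{name}: bound ions per frame {mean:.2f} +/- {sd:.3f}")

    part = bound_state_partition(records)
    top_states = sorted(part.populations.items(),
                        key=lambda kv: -kv[1])[:3]
    with open(results / f"bound_states_{name}.tsv", "w") as fh:
        fh.write("n_bound\tpopulation_pct\ttop_signature\n")
        for k, frac in top_states:
            fh.write(f"{k}\t{100 * frac:.1f}\t{part.signatures[k]}\n")
    print(f"{name}: top bound states " +
          ", ".join(f"{k} ({100 * f:.1f}%)" for k, f in top_states))

    pops = cluster_populations(records)
    with open(results / f"clusters_{name}.tsv", "w") as fh:
        fh.write("cluster\tpopulation_pct\n")
        for lab, pct in pops.items():
            fh.write(f"{lab}\t{pct:.1f}\n")
    print(f"{name}: cluster populations " +
          ", ".join(f"{k}: {v:.1f}%" for k, v in list(pops.items())[:4]))

    # representative snapshot of the most populated cluster
    top_label = next(iter(pops))
    protein_heavy = resolve_selection(top,
                                      "not role:ion_center and heavy")
    per_ion = {}
    for r in records:
        if r.label == top_label:
            per_ion.setdefault(r.ion, []).append(r.frame)
    ion_id, frames = max(per_ion.items(), key=lambda kv: len(kv[1]))
    rep = representative_snapshot(
        traj, protein_heavy, SelectionGroup("ion", np.array([ion_id])),
        rmsd_cutoff=0.2, frames=np.asarray(frames))
    rep_traj = Trajectory(coords=traj.coords[[rep]],
                          temperature=traj.temperature)
    write_structure(results / f"representative_{name}.pdb", top,
                    rep_traj)
    print(f"{name}: representative frame {rep} of cluster {top_label} "
          f"(ion {ion_id}, {len(frames)} member frames) -> "
          f"representative_{name}.pdb")
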