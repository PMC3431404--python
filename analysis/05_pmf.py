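#!/usr/bin/env python
"""Free-energy profiles of ion binding by Boltzmann inversion.

For each condition: 1D PMFs of the per-ion minimum distance to the
whole protein, to E316 only and to E320 only, all normalized to zero
at 2 nm where interactions are negligible; the 2D PMF over the y-z
plane perpendicular to the channel axis; and the x-coordinate
distributions of ions versus the channel mouth (G312 alpha carbons).
The contact free energies of the two conditions are differenced into
the synthetic analogue of the trivalent-vs-divalent affinity gap.
"""

import numpy as np

from _shared import (CONDITIONS, build_condition, ensure_results,
                     glutamate_groups, per_ion_min_distances)
from ionloop.pmf import (binding_free_energy, coordinate_distribution,
                         pmf_1d, pmf_2d)
from ionloop.structio import SelectionGroup, resolve_selection

results = ensure_results()
contact = {}
for name in CONDITIONS:
    top, traj, field = build_condition(name)
    protein = resolve_selection(top, "not role:ion_center")
    e316, e320 = glutamate_groups(top)
    e316_all = resolve_selection(top, "role:E316 and heavy")
    e320_all = resolve_selection(top, "role:E320 and heavy")

    profiles = {}
    for tag, group in (("protein", protein), ("E316", e316_all),
                       ("E320", e320_all)):
        samples = per_ion_min_distances(top, traj, group).ravel()
        prof = pmf_1d(samples, 0.05, traj.temperature, r_ref=2.0,
                      ref_window=0.1, compute_se=True,
                      rng=np.random.default_rng(0))
        profiles[tag] = prof
        r_min, w_min = binding_free_energy(prof)
        print(f"{name}/{tag}: PMF minimum {w_min:.2f} kJ/mol "
              f"at {r_min:.2f} nm")
        with open(results / f"pmf_{name}_{tag}.tsv", "w") as fh:
            fh.write("r_nm\tcounts\tw_kJmol\tse_kJmol\n")
            for r, c, w, s in zip(prof.r, prof.counts, prof.w, prof.se):
                fh.write(f"{r:.3f}\t{int(c)}\t{w:.4f}\t{s:.4f}\n")
    pp = profiles["protein"]
    mask = pp.defined & (pp.r < 0.5)
    contact[name] = float(np.nanmin(np.where(mask, pp.w, np.nan)))

    # 2D PMF on the plane perpendicular to the channel axis
    ions = top.roles["ion_center"]
    yz = traj.coords[:, ions, 1:].reshape(-1, 2)
    surf = pmf_2d(yz, 0.4, traj.temperature,
                  rng=np.random.default_rng(1))
    imin = np.unravel_index(np.nanargmin(surf.w), surf.w.shape)
    yc = (surf.y_edges[:-1] + surf.y_edges[1:]) / 2
    zc = (surf.z_edges[:-1] + surf.z_edges[1:]) / 2
    rad = np.hypot(yc[imin[0]], zc[imin[1]])
    print(f"{name}: 2D PMF minimum at (y,z)=({yc[imin[0]]:.2f},"
          f"{zc[imin[1]]:.2f}) nm, {rad:.2f} nm off-axis "
          f"(loop ring radius ~1.1-1.5 nm); "
          f"median cell SE {np.nanmedian(surf.se):.3f} kJ/mol")
    np.savetxt(results / f"pmf2d_{name}.tsv", surf.w, fmt="%.4f",
               delimiter="\t")

    # x-coordinate distributions: ions vs channel-mouth marker G312 CA
    g312_ca = SelectionGroup("G312CA", np.asarray(
        [i for i in top.roles["G312"] if str(top.names[i]) == "CA"]))
    ion_group = SelectionGroup("ions", ions)
    cx, dx = coordinate_distribution(traj, ion_group, "x", 0.2)
    gx, gdx = coordinate_distribution(traj, g312_ca, "x", 0.2)
    with open(results / f"xdist_{name}.tsv", "w") as fh:
        fh.write("x_nm\tion_density\n")
        for x, d in zip(cx, dx):
            fh.write(f"{x:.2f}\t{d:.5f}\n")
    print(f"{name}: ion x-density peak at "
          f"{cx[np.argmax(dx)]:.2f} nm; G312 CA markers at "
          f"{gx[gdx > 0].min():.2f}..{gx[gdx > 0].max():.2f} nm")

ddg = contact["trivalent"] - contact["divalent"]
print(f"contact free energies: trivalent {contact['trivalent']:.2f}, "
      f"divalent {contact['divalent']:.2f} kJ/mol -> synthetic "
      f"affinity gap {ddg:.2f} kJ/mol (trivalent binds stronger)")
with open(results / "pmf_summary.tsv", "w") as fh:
    fh.write("condition\tcontact_w_kJmol\n")
    for k, v in contact.items():
        fh.write(f"{k}\t{v:.3f}\n")
    fh.write(f"ddg\t{ddg:.3f}\n")
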