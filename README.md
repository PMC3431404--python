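# ionloop

Analysis toolkit for ion binding on the flexible periplasmic loops of a
pentameric divalent-cation channel. The scientific question it serves:
where and how strongly do multivalent cations (a divalent ion such as
Mg²⁺, or a trivalent inhibitor such as cobalt(III) hexammine) bind the
ring of glutamate-bearing interhelical loops at the channel mouth, and
can the affinity difference between the two cations be quantified
consistently from free-energy profiles, contact statistics,
implicit-solvent energetics and published inhibition assays?

The package is organised as an analysis project: the computational
machinery lives in `src/ionloop/` and is fully unit-tested; the
numbered scripts under `analysis/` are thin narrative drivers that run
the study end to end on synthetic ensembles with a declared ground
truth and write their tables under `results/`.

## What it computes

* **Potentials of mean force by Boltzmann inversion.** For a sampled
  coordinate r with histogram counts g(r),

      w(r) = −k_B T ln( g(r) / g_max ),

  with empty bins masked and an optional reference shift so that
  w(2 nm) = 0, where ion–protein interactions are negligible.
  Uncertainties come from a block bootstrap over contiguous sample
  blocks. 2D surfaces over the (y, z) plane perpendicular to the
  channel axis use the same inversion per cell.
* **Contact-based binding classification.** A residue is *interacting*
  when its heavy-atom minimum distance to the ion center is < 0.5 nm;
  an ion is *bound* when it has ≥ 1 interacting residue; contact
  clusters are labelled "x-y" by the number of E316 (x) and E320 (y)
  chains within the cutoff. Representative snapshots are picked by
  least-squares superposition, single-linkage clustering of ion
  positions, and medoid selection.
* **Geometric observables.** Minimum distances (with minimum-image
  support), radius of gyration, side-chain orientation cosines against
  the channel axis, Shrake–Rupley SASA on a deterministic Fibonacci
  sphere lattice, hydration-shell counts, and radial distribution
  functions.
* **GB/SA binding energetics.** OBC generalized Born (α = 1.0,
  β = 0.8, γ = 4.85) with HCT pairwise descreening, plus vacuum
  Coulomb, Lennard-Jones and a surface-area term; binding energy =
  complex − protein − ions, term by term.
* **Replica-exchange diagnostics.** Temperature-ladder coverage and
  bottom-top-bottom round trips per replica; convergence of ensemble
  observables via histogram overlap across cumulative time windows.
* **Cheng–Prusoff affinity conversion.** K_i = IC50 / (1 + [s]/K_m)
  and ΔΔG = RT ln(IC50_A / IC50_B) between assays sharing conditions.
* **Synthetic ground truth.** A C5-symmetric loop scaffold about the
  +x channel axis, ions Boltzmann-sampled by Metropolis Monte Carlo in
  a declared field of Gaussian wells on the glutamate carboxylates,
  and replica temperature traces — so every stage is testable against
  known inputs without any external data.

## Worked example

Recover a declared binding free energy through the full stack —
sample ions in a 5 kJ/mol Gaussian well, histogram the radial
coordinate, Boltzmann-invert, and read off the well depth:

```python
import numpy as np
from ionloop import SyntheticField, Well, sample_ion_trajectory
from ionloop.pmf import pmf_1d

field = SyntheticField(wells=[Well([0, 0, 0], depth=5.0, width=0.2)],
                       box=[[-1, 1], [-0.02, 0.02], [-0.02, 0.02]])
traj = sample_ion_trajectory(field, n_ions=10, n_frames=10_000,
                             temperature=315.0, seed=7)
r = np.abs(traj.coords[..., 0].ravel())          # 100 000 samples
prof = pmf_1d(r, bin_width=0.02, temperature=315.0, r_ref=0.8,
              compute_se=True, rng=np.random.default_rng(7))
i0 = np.argmin(np.abs(prof.r))
print(f"recovered depth: {-prof.w[i0]:.2f} +/- {prof.se[i0]:.2f} kJ/mol")
```

prints

```
recovered depth: 4.97 +/- 0.05 kJ/mol
```

i.e. the imposed 5 kJ/mol well is recovered within the bootstrap
uncertainty. The affinity side of the pipeline is a one-liner from the
shell:

```
$ ionloop ddg --ic50a 0.5 --ic50b 10 --s 200 --km 20 --temp 310
Ki_A	0.04545 uM
Ki_B	0.9091 uM
DDG	-7.72 kJ/mol
```

— an IC50 ratio of 20 corresponds to RT ln 20 ≈ 7.7 kJ/mol of binding
free energy at 310 K, the gap between the two cations in the
published competition assays.

The full analysis sequence is `analysis/01_build_system.py` through
`analysis/08_affinity.py`; each script states what it finds on stdout
and writes its tables under `results/`.

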