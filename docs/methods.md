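# Methods

This note records the models behind `ionloop`, the parameter choices
that matter, what the synthetic generator does and does not emulate,
and the numerical conventions a user should know before trusting a
number.

## Units and constants

Lengths nm, energies kJ/mol, charges e, temperatures K, areas nm².
k_B = R = 0.0083145 kJ mol⁻¹ K⁻¹ and the electrostatic factor
f = 138.935458 kJ mol⁻¹ nm e⁻² live in `ionloop.constants` and nowhere
else. Atom indexing is 0-based internally, 1-based in written PDB/GRO.

## Potential of mean force

`pmf_1d`/`pmf_2d` implement raw Boltzmann inversion of histogram
counts, w = −k_B T ln(g/g_max), at the single ensemble temperature
(default 315 K). Two deliberate conventions:

* **No Jacobian correction.** No 4πr² (or any phase-volume) factor is
  divided out. Consequently a uniform gas does *not* produce a flat
  profile along a radial or minimum-distance coordinate at large r —
  the growth of accessible volume with r masquerades as a free-energy
  decrease. Profiles must therefore be read as differences between a
  contact region and the chosen reference region on the same
  coordinate, which is how the 2 nm anchoring convention is used here:
  the profile is shifted additively so that w(2 nm) = 0, averaging the
  occupied bins within ±0.05 nm (configurable) of the reference to
  damp single-bin noise. A reference with no occupied bins raises
  rather than silently extrapolating.
* **Masked, never infinite.** Empty bins carry NaN; minima, plots and
  downstream arithmetic use the defined-bin mask. The g_max convention
  pins min w = 0 at the most occupied bin, so on a *flat* landscape
  the zero sits at a maximum-order-statistic cell, about two
  per-cell standard errors above the surface mean; flatness checks in
  the tests are therefore phrased against the surface mean (or via a
  chi-square test on counts), not against zero.

Uncertainties use a block bootstrap: the sample series (kept in frame
order) is cut into 10 contiguous blocks, resampled with replacement
100 times, and each replicate re-inverted; the per-bin spread is the
reported SE. This respects the serial correlation of Monte Carlo /
MD samples at the block scale but not beyond it.

Binding free energy extraction returns the arg-min and min of w over
defined bins, ties broken toward smaller r.

## Binding classification

Cutoff conventions follow the field's: a residue interacts with an ion
when its heavy-atom minimum distance to the ion *center* is strictly
below 0.5 nm; a bound ion has ≥ 1 interacting residue; the "x-y"
cluster label counts E316 and E320 chains within the cutoff, and ions
with x = y = 0 are excluded from the cluster-population denominator.
Populations are reported over (frame, ion) pairs. Bound-state
signatures count a residue once per chain.

Representative snapshots: frames are superposed on the first frame by
a Kabsch least-squares fit over protein heavy atoms (proper rotation
only, det +1), the ion-position RMSD matrix feeds single-linkage
clustering with a 0.2 nm default cutoff (exposed as a parameter; the
value is this package's choice), and the largest cluster's medoid
(minimum summed RMSD, earliest frame on ties) is returned.

## Observables

* SASA is Shrake–Rupley with sphere points on a deterministic golden-
  spiral (Fibonacci) lattice — no RNG in any SASA number — 960 points
  and a 0.14 nm probe by default; the isolated-sphere closed form is
  reproduced to < 0.5 %. Radii are supplied per atom (Bondi-like
  values in the synthetic parameter table); which radii the original
  trajectory tools used is generally unknowable, so radii are always
  an explicit input here.
* The orientation observable is the cosine between the Cα→Cδ
  side-chain vector of a glutamate and the perpendicular foot vector
  from its Cα to the channel axis; positive cosine = side chain tilted
  toward the axis. Frames whose Cα lies on the axis are flagged NaN.
* RDFs require a periodic box (the ideal-gas normalisation needs a
  density) and refuse r_max beyond half the smallest box edge.

## GB/SA energetics

The polar solvation term is OBC-flavoured generalized Born: HCT
pairwise descreening integrals (the closed form is validated against
numerical quadrature to machine precision in the tests, including the
engulfed-atom branch), Ψ rescaled through
tanh(αΨ − βΨ² + γΨ³) with α = 1.0, β = 0.8, γ = 4.85, dielectric
offset 0.009 nm, ε_in = 1, ε_out = 78.5, no salt screening. Pair
energies use the Still interpolation f_GB = √(r² + R_iR_j e^{−r²/4R_iR_j})
with self-terms included, so one atom reproduces the Born equation
exactly. E_ele is unscreened vacuum Coulomb, E_vdw Lorentz–Berthelot
Lennard-Jones, E_SA = 0.0226 kJ mol⁻¹ nm⁻² × SASA (the common
0.0054 kcal mol⁻¹ Å⁻² tension; both offset and tension are
configurable since no single literature value is canonical). All sums
are cutoff-free: after water stripping the systems are small.

Binding energy is strictly additive: each term is evaluated
independently on complex, protein-only and ion-only structures
(effective Born radii recomputed per structure) and differenced.
Waters hydrating a divalent ion (oxygen within 0.30 nm, the first RDF
minimum region) are assigned to the ion side of the split by
`mg_bound_waters`.

Two facts of life with this model, visible in `analysis/07_gbsa.py`:
a *bare* multivalent point ion pays an enormous Born desolvation
penalty, so the synthetic table gives the cation its hydrated-sphere
Born radius (0.30 nm); and an un-neutralised scaffold (ten glutamates,
no basic residues charged) produces kJ·10³-scale Coulomb/GB terms that
largely cancel — the analysis charges the arginine/lysine side chains
+1 so the pentamer is neutral, as the real sequence is.

## Cheng–Prusoff affinity comparison

K_i = IC50 / (1 + [s]/K_m); ΔG = RT ln K_i with K_i in the assay's
concentration units, so only differences between assays sharing [s],
K_m and T are meaningful — and for those the substrate correction
cancels, leaving ΔΔG = RT ln(IC50_A/IC50_B). The within-species IC50
ratio of 20 gives |ΔΔG| = 7.7 kJ/mol at 310 K (ratio 200 gives 13.7).
The sign is reported with the convention that the trivalent inhibitor
is the stronger binder (negative ΔΔG), which matches the free-energy
profiles; note that this runs opposite to the raw IC50 ordering of the
transport-inhibition assays, an ambiguity inherent in comparing a
transported substrate with a non-transported inhibitor in the same
IC50 framework.

## Convergence diagnostics

Stationarity is judged by histogram intersection (Σ min(pᵢ, qᵢ)) of an
observable's distribution over cumulative windows sharing a start; the
pass threshold 0.9 on the last two windows is this package's
quantification of the usual visual judgement and is reported alongside
the raw overlap. Ladder traversal reports the fraction of rungs
visited and completed bottom-top-bottom round trips; the ion-trapping
diagnostic is the longest consecutive dwell of a per-ion minimum
distance below the binding cutoff.

## The synthetic generator

The scaffold places the 16-residue mobile loop span (G312..Y327) of
each of five chains at 1.5 nm from the +x channel axis, residues
0.35 nm apart, glutamate side chains extended toward the axis, then
replicates chain A by exact 72° rotations (a seeded 0.005 nm jitter is
applied to the template *before* replication, so C5 symmetry holds to
machine precision). Every residue carries a role label
(one-letter code + number) resolvable by the selection language.

The declared binding landscape is a sum of Gaussian wells, one per
glutamate carboxylate (centered on the Cδ), over a flat bulk in a
non-periodic box. Defaults are the study conditions: 10 ions at 315 K;
well depth equal to the condition's *global* ion–loop binding free
energy — 16.8 kJ/mol for the trivalent-like ensemble, 9.5 kJ/mol for
the divalent-like one (the per-glutamate profile depths of roughly
−8 to −9 and −4 to −5 kJ/mol are projections of the landscape onto
single-residue distance coordinates, not independent site depths);
well width 0.35 nm, the contact-minimum distance scale of a
carboxylate site; 1.6 nm of flat bulk padding wherever the 2 nm PMF
reference must be sampled (1.0 nm otherwise). Under these conditions
the two ensembles average about 5–6 and about 2 bound ions of 10 —
the same occupancy regime as the study system, though that agreement
is emergent, not fitted.

Sampling is Metropolis Monte Carlo with a 50/50 mixture proposal:
a local Gaussian step (auto-tuned during burn-in toward 30–50 %
acceptance, capped at 0.5 nm) folded back into the box by wall
reflection, or a uniform relocation anywhere in the box. Both
components are symmetric, so the stationary distribution is exactly
Boltzmann and the flat-field limit exactly uniform; the relocation
component exists because a purely local walk crosses between a
several-k_BT well and the bulk exponentially slowly. Burn-in is 10 %
of total sweeps, frames are recorded every 10 sweeps, and runs are
bit-reproducible from the seed. Initial placements are uniform at
random (a documented choice — how the original simulations placed
ions initially is not modelled).

What the generator does *not* emulate — and hence what passing tests
do and do not show about real data: there is no excluded volume (an
ion can overlap an atom; force-field evaluation in the GBSA analysis
therefore skips geometries with an ion inside the 0.15 nm vdW core
and reports the count), no explicit water, no protein flexibility
(the scaffold is rigid, so Rg-based convergence checks are exercised
on ion-derived series instead), no multi-site ion geometry, and no
temperature dependence beyond the single analysis ensemble. Replica
traces emulate only the exchange *bookkeeping* (adjacent-pair swaps at
a set acceptance probability, preserving one-replica-per-rung), not
the energy-dependent acceptance of real replica exchange. The tests
establish that the analysis operators are correct on known ground
truth; they cannot certify force-field or sampling quality of any real
trajectory fed to them.

## Problem sizes

Default analysis runs use 10 ions × 2000 frames per condition
(20 000 per-ion samples), 10⁵ samples for well-depth recovery, 48
replicas × 20 000 steps for ladder diagnostics, and ~70 single-ion
GBSA evaluations (every 100th frame); these sizes give standard errors
comfortably below the effects measured while keeping any script in the
tens of seconds on one CPU.

## Known limitations

* The min-distance PMF of a weakly bound ensemble is entropy-dominated
  at large r (no Jacobian, see above); its global minimum can sit in
  the bulk. Contact free energies are therefore also reported as the
  minimum over r < 0.5 nm.
* Cluster populations of the synthetic ensembles contain essentially
  only 1-0 and 0-1 labels: the scaffold geometry keeps neighbouring
  glutamate carboxylates ≥ 1.26 nm apart, so one ion cannot touch two
  of them within the 0.5 nm cutoff. Multi-glutamate labels (1-1, 2-1,
  ...) are exercised by constructed fixtures in the tests instead.
* GB/SA numbers on synthetic geometries carry large frame-to-frame
  spread (the field does not correlate ion position with favourable
  electrostatics at the atomic scale); they demonstrate the machinery
  and the electrostatics-dominated decomposition, not converged
  affinities.
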