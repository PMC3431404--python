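"""Implicit-solvent GB/SA binding energetics and affinity comparison.

The electrostatic solvation term uses the OBC flavour of the
generalized Born model: per-atom effective Born radii come from the
Hawkins-Cramer-Truhlar (HCT) pairwise descreening sum, rescaled through
the tanh formula with coefficients alpha = 1.0, beta = 0.8,
gamma = 4.85. Pair energies use the canonical Still interpolation
f_GB = sqrt(r^2 + Ri Rj exp(-r^2 / 4 Ri Rj)).

Binding energy of an ion (or ion cluster) to the protein is the
difference of per-structure energies, term by term:

    dE_term = E_term(complex) - E_term(protein) - E_term(ions)
    G_binding = dE_GB + dE_ele + dE_vdw + dE_SA

with E_ele the vacuum Coulomb energy, E_vdw Lennard-Jones, and E_SA a
surface-tension times SASA term. No cutoffs are applied: the systems
analysed are small once bulk water is stripped. Waters hydrating a
Mg2+ ion (oxygen within 0.30 nm by default) travel with the ion side.

The Cheng-Prusoff block converts inhibition IC50 values to binding
affinities, Ki = IC50 / (1 + [s]/Km), and to free-energy differences
DDG = RT ln(Ki_A / Ki_B), which the substrate correction cancels out
of whenever both assays share [s] and Km.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import EPS_WATER, F_ELEC, R_GAS
from .errors import AnalysisError, ParameterError
from .observables import sasa as shrake_rupley_sasa
from .structio import SelectionGroup, Topology

__all__ = [
    "GbParameters",
    "GbsaResult",
    "InhibitionAssay",
    "born_radii",
    "gb_energy",
    "coulomb_energy",
    "lj_energy",
    "sa_energy",
    "gbsa_binding_energy",
    "gbsa_ensemble",
    "mg_bound_waters",
    "cheng_prusoff_ki",
    "binding_dg",
    "cheng_prusoff_ddg",
]


@dataclass(frozen=True)
class GbParameters:
    """OBC generalized-Born parameters plus SA coefficients."""

    alpha: float = 1.0            # OBC tanh coefficients (dimensionless)
    beta: float = 0.8
    gamma: float = 4.85
    eps_in: float = 1.0           # solute dielectric
    eps_out: float = EPS_WATER    # solvent dielectric
    offset: float = 0.009         # dielectric offset, nm
    tension: float = 0.0226       # surface tension, kJ mol^-1 nm^-2
    probe: float = 0.14           # SASA probe radius, nm
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if not self.eps_out > self.eps_in >= 1.0:
            raise ParameterError("require eps_out > eps_in >= 1")


@dataclass
class GbsaResult:
    """Per-structure binding-energy decomposition, kJ/mol."""

    g_binding: float
    e_gb: float
    e_ele: float
    e_vdw: float
    e_sa: float
    terms: dict = field(default_factory=dict)  # per-structure raw terms


def _hct_integral(r: np.ndarray, rho_i: np.ndarray,
                  sr_j: np.ndarray) -> np.ndarray:
    """HCT pairwise descreening integral I_ij (units nm^-1).

    Equals (1/4pi) * the integral of |x|^-4 over the scaled sphere of
    neighbour j excluding the interior of sphere i; rho_i is the
    offset-reduced radius of atom i and sr_j the screened reduced
    radius of atom j.
    """
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    active = r + sr_j > rho_i       # otherwise j is buried inside i
    if not np.any(active):
        return out
    rr = r[active]
    ri = np.broadcast_to(rho_i, r.shape)[active]
    sj = np.broadcast_to(sr_j, r.shape)[active]
    U = rr + sj
    L = np.maximum(ri, np.abs(rr - sj))
    I = 0.5 * (1.0 / L - 1.0 / U
               + 0.25 * (rr - sj * sj / rr) * (1.0 / U ** 2 - 1.0 / L ** 2)
               + 0.5 * np.log(L / U) / rr)
    engulfed = sj > rr + ri         # atom i inside neighbour j's sphere
    I = I + np.where(engulfed, 1.0 / ri - 1.0 / L, 0.0)
    out[active] = I
    return out


def born_radii(top: Topology, frame: np.ndarray,
               params: GbParameters = GbParameters()) -> np.ndarray:
    """Effective Born radii (nm) by HCT descreening + OBC rescaling.

    1/R_i = 1/rho~_i - (1/rho_i) tanh(a P - b P^2 + c P^3) with
    rho~ = rho - offset and P = rho~_i * sum_j I_ij. Guarantees
    R_i >= rho~_i; an isolated atom gets exactly rho~_i.
    """
    if top.radii is None or np.any(~np.isfinite(top.radii)):
        raise ParameterError("intrinsic radii missing; apply a parameter "
                             "table first")
    rho = np.asarray(top.radii, dtype=float)
    if np.any(rho <= params.offset):
        bad = [str(n) for n, r in zip(top.names, rho) if r <= params.offset]
        raise ParameterError(
            f"intrinsic radius <= dielectric offset for atoms {bad}")
    screens = (np.full(len(rho), 0.8) if top.screens is None
               else np.asarray(top.screens, dtype=float))
    rho_red = rho - params.offset
    n = len(rho)
    psi_sum = np.zeros(n)
    if n > 1:
        d = cdist(frame, frame)
        for i in range(n):
            j = np.arange(n) != i
            psi_sum[i] = _hct_integral(
                d[i, j], rho_red[i], screens[j] * rho_red[j]).sum()
    psi = psi_sum * rho_red
    inner = params.alpha * psi - params.beta * psi ** 2 \
        + params.gamma * psi ** 3
    inv_r = 1.0 / rho_red - np.tanh(inner) / rho
    if np.any(inv_r <= 0):
        raise AnalysisError("non-physical (negative) effective Born radius")
    return 1.0 / inv_r


def gb_energy(charges: np.ndarray, frame: np.ndarray,
              effective_radii: np.ndarray,
              params: GbParameters = GbParameters()) -> float:
    """Generalized-Born polar solvation energy, kJ/mol.

    E = -(f_el/2)(1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB with
    self-terms included (f_GB(i,i) = R_i); a single ion reproduces the
    analytic Born equation exactly.
    """
    q = np.asarray(charges, dtype=float)
    R = np.asarray(effective_radii, dtype=float)
    if np.any(~np.isfinite(R)):
        raise AnalysisError("non-finite effective Born radii")
    r2 = cdist(frame, frame) ** 2
    RiRj = np.outer(R, R)
    f_gb = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
    pref = -(F_ELEC / 2.0) * (1.0 / params.eps_in - 1.0 / params.eps_out)
    return float(pref * (np.outer(q, q) / f_gb).sum())


def coulomb_energy(charges: np.ndarray, frame: np.ndarray,
                   eps_in: float = 1.0) -> float:
    """Vacuum (solute-dielectric) Coulomb energy over i < j, kJ/mol."""
    q = np.asarray(charges, dtype=float)
    n = len(q)
    if n < 2:
        return 0.0
    d = cdist(frame, frame)
    iu = np.triu_indices(n, k=1)
    return float((F_ELEC / eps_in) * (np.outer(q, q)[iu] / d[iu]).sum())


def lj_energy(sigmas: np.ndarray, epsilons: np.ndarray,
              frame: np.ndarray) -> float:
    """Lennard-Jones energy with Lorentz-Berthelot combination, kJ/mol.

    sigma_ij arithmetic mean, eps_ij geometric mean; pairs with
    eps_ij = 0 contribute nothing.
    """
    s = np.asarray(sigmas, dtype=float)
    e = np.asarray(epsilons, dtype=float)
    n = len(s)
    if n < 2:
        return 0.0
    d = cdist(frame, frame)
    iu = np.triu_indices(n, k=1)
    sig = (s[:, None] + s[None, :])[iu] / 2.0
    eps = np.sqrt(np.outer(e, e))[iu]
    r = d[iu]
    live = eps > 0
    sr6 = (sig[live] / r[live]) ** 6
    return float(np.sum(4.0 * eps[live] * (sr6 ** 2 - sr6)))


def sa_energy(top: Topology, frame: np.ndarray,
              params: GbParameters = GbParameters()) -> float:
    """Nonpolar solvation term: surface tension x total SASA, kJ/mol."""
    group = SelectionGroup("all", np.arange(top.n_atoms))
    area = shrake_rupley_sasa(frame, group, top.radii, probe=params.probe,
                              n_sphere_points=params.n_sphere_points)
    return params.tension * area["total"]


def _structure_terms(top: Topology, frame: np.ndarray,
                     params: GbParameters) -> dict[str, float]:
    radii = born_radii(top, frame, params)
    return {
        "E_GB": gb_energy(top.charges, frame, radii, params),
        "E_ele": coulomb_energy(top.charges, frame, params.eps_in),
        "E_vdw": lj_energy(top.sigmas, top.epsilons, frame),
        "E_SA": sa_energy(top, frame, params),
    }


def gbsa_binding_energy(top: Topology, frame: np.ndarray,
                        protein: SelectionGroup, ions: SelectionGroup,
                        params: GbParameters = GbParameters()) -> GbsaResult:
    """Term-by-term GB/SA binding energy of the ion group to the protein.

    The complex is the union of the two groups (they must partition it
    disjointly — Mg-bound waters belong in the ion group). Each of the
    three structures is evaluated independently, so effective Born
    radii are recomputed for the separated species.
    """
    pi, ii = protein.indices, ions.indices
    if np.intersect1d(pi, ii).size:
        raise AnalysisError("protein and ion groups overlap")
    union = np.union1d(pi, ii)
    terms = {}
    for label, idx in (("complex", union), ("protein", pi), ("ions", ii)):
        sub = top.subset(idx)
        terms[label] = _structure_terms(sub, frame[np.asarray(
            sorted(set(int(i) for i in idx)))], params)
    diff = {k: terms["complex"][k] - terms["protein"][k] - terms["ions"][k]
            for k in ("E_GB", "E_ele", "E_vdw", "E_SA")}
    return GbsaResult(
        g_binding=sum(diff.values()),
        e_gb=diff["E_GB"], e_ele=diff["E_ele"],
        e_vdw=diff["E_vdw"], e_sa=diff["E_SA"], terms=terms)


def gbsa_ensemble(results: list[GbsaResult]) -> dict[str, tuple[float, float]]:
    """Ensemble mean +/- sd of each binding term over structures."""
    if not results:
        raise AnalysisError("no GBSA results to average")
    out = {}
    for attr in ("g_binding", "e_gb", "e_ele", "e_vdw", "e_sa"):
        vals = np.asarray([getattr(r, attr) for r in results])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[attr] = (float(vals.mean()), sd)
    return out


def mg_bound_waters(top: Topology, frame: np.ndarray, mg_index: int,
                    water_oxygens: SelectionGroup,
                    cutoff: float = 0.30) -> np.ndarray:
    """Atom indices of water molecules hydrating one Mg2+ center.

    A water is kept when its oxygen lies within ``cutoff`` (default
    0.30 nm, the first minimum region of the ion-water RDF) of the Mg
    position; all atoms of the selected water residues are returned so
    they can ride with the ion side of a GB/SA split.
    """
    w_idx = water_oxygens.indices
    d = cdist(frame[[mg_index]], frame[w_idx]).ravel()
    close = w_idx[d < cutoff]
    if close.size == 0:
        return np.asarray([], dtype=int)
    keys = {(str(top.chainids[i]), int(top.resids[i])) for i in close}
    keep = [i for i in range(top.n_atoms)
            if (str(top.chainids[i]), int(top.resids[i])) in keys]
    return np.asarray(sorted(keep), dtype=int)


# ---------------------------------------------------------------------------
# Cheng-Prusoff affinity comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InhibitionAssay:
    """One inhibitor's IC50 together with the assay conditions."""

    name: str
    ic50: float          # uM
    substrate: float     # [s], uM
    km: float            # uM
    temperature: float   # K

    def __post_init__(self) -> None:
        for attr in ("ic50", "substrate", "km", "temperature"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"{attr} must be positive")


def cheng_prusoff_ki(assay: InhibitionAssay) -> float:
    """Ki = IC50 / (1 + [s]/Km), same units as IC50."""
    return assay.ic50 / (1.0 + assay.substrate / assay.km)


def binding_dg(assay: InhibitionAssay) -> float:
    """DG = RT ln Ki with Ki in the assay's concentration units (uM).

    Only differences of this quantity between assays sharing conditions
    are meaningful; the unit-dependent additive constant cancels there.
    """
    return R_GAS * assay.temperature * np.log(cheng_prusoff_ki(assay))


def cheng_prusoff_ddg(assay_a: InhibitionAssay,
                      assay_b: InhibitionAssay) -> float:
    """DDG = DG_A - DG_B = RT ln(IC50_A / IC50_B), kJ/mol.

    Both assays must share substrate concentration, Km and temperature,
    which makes the Cheng-Prusoff correction cancel exactly. A negative
    value means inhibitor A binds more strongly than B.
    """
    for attr in ("substrate", "km", "temperature"):
        if not np.isclose(getattr(assay_a, attr), getattr(assay_b, attr)):
            raise ParameterError(
                f"assays disagree on {attr}; DDG comparison undefined")
    return binding_dg(assay_a) - binding_dg(assay_b)
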