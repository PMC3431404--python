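"""Synthetic trajectories with a known ground truth.

Everything downstream of this module is exercised without external
data. Three generators are provided:

* :func:`build_scaffold` — a C5-symmetric pentameric loop scaffold
  around the +x channel axis, with role-labelled residues (E316, E320,
  G312, ...) so selection queries work exactly as on a real topology;
* :func:`sample_ion_trajectory` — ion positions Boltzmann-distributed
  in a declared potential field (Gaussian binding wells over a flat
  bulk) via a Metropolis sampler, so binding landscapes recovered by
  the PMF machinery can be checked against the imposed wells;
* :func:`generate_replica_traces` — replica temperature traces over a
  48-rung ladder with a prescribed adjacent-swap probability, feeding
  the convergence diagnostics.

The sampler is plain Metropolis Monte Carlo: any correct Boltzmann
sampler suffices for parameter-recovery tests, and Metropolis is
simple, exact and fast at these system sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .constants import KB, N_RUNGS_DEFAULT, T_LADDER_MAX, T_LADDER_MIN
from .errors import AnalysisError, ConfigurationError
from .structio import ELEMENT_MASSES, Topology, Trajectory

__all__ = [
    "Well",
    "SyntheticField",
    "ReplicaTrace",
    "LOOP_SPAN_G312_Y327",
    "build_scaffold",
    "field_from_scaffold",
    "sample_ion_trajectory",
    "generate_replica_traces",
    "default_ladder",
    "ion_topology",
    "assemble_system",
]

THREE_LETTER = {
    "G": "GLY", "M": "MET", "N": "ASN", "F": "PHE", "E": "GLU", "Y": "TYR",
    "P": "PRO", "L": "LEU", "R": "ARG", "W": "TRP", "K": "LYS", "A": "ALA",
    "S": "SER", "T": "THR", "D": "ASP", "Q": "GLN", "H": "HIS", "I": "ILE",
    "V": "VAL", "C": "CYS",
}

#: The mobile loop span modelled per chain: G312..Y327 (16 residues).
LOOP_SPAN_G312_Y327: tuple = (
    ("G", 312), ("M", 313), ("N", 314), ("F", 315), ("E", 316), ("Y", 317),
    ("M", 318), ("P", 319), ("E", 320), ("L", 321), ("R", 322), ("W", 323),
    ("K", 324), ("W", 325), ("G", 326), ("Y", 327),
)


@dataclass(frozen=True)
class Well:
    """One Gaussian binding well: U = -depth exp(-|x-c|^2 / 2 width^2)."""

    center: np.ndarray   # nm
    depth: float         # kJ/mol, >= 0
    width: float         # nm, > 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float).reshape(3))
        if self.depth < 0:
            raise ConfigurationError("well depth must be >= 0")
        if self.width <= 0:
            raise ConfigurationError("well width must be > 0")


@dataclass
class SyntheticField:
    """Declared binding landscape: Gaussian wells in an axis-aligned box.

    The box is (3, 2) bounds in nm. Non-periodic by default (the loop
    region of interest is local); the periodic option exists so the RDF
    normalisation has a defined density.
    """

    wells: list
    box: np.ndarray
    periodic: bool = False

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3, 2)
        if np.any(self.box[:, 1] <= self.box[:, 0]):
            raise ConfigurationError("box upper bounds must exceed lower")
        for w in self.wells:
            if np.any(w.center < self.box[:, 0]) or \
                    np.any(w.center > self.box[:, 1]):
                raise ConfigurationError(
                    f"well center {w.center} outside box")

    @property
    def lengths(self) -> np.ndarray:
        return self.box[:, 1] - self.box[:, 0]

    def potential(self, x: np.ndarray) -> np.ndarray:
        """U(x), kJ/mol; x has shape (..., 3). Finite everywhere."""
        x = np.asarray(x, dtype=float)
        u = np.zeros(x.shape[:-1])
        for w in self.wells:
            d2 = ((x - w.center) ** 2).sum(axis=-1)
            u -= w.depth * np.exp(-d2 / (2.0 * w.width ** 2))
        return u

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.all((x >= self.box[:, 0]) & (x <= self.box[:, 1]),
                      axis=-1)


@dataclass
class ReplicaTrace:
    """One replica's walk through the temperature ladder."""

    replica_id: int
    ladder: np.ndarray    # rung temperatures, K, ascending
    visits: np.ndarray    # per-step rung indices

    def __post_init__(self) -> None:
        self.ladder = np.asarray(self.ladder, dtype=float)
        self.visits = np.asarray(self.visits, dtype=int)
        if self.visits.size < 1:
            raise ConfigurationError("visit series must have length >= 1")
        if self.visits.min() < 0 or self.visits.max() >= len(self.ladder):
            raise ConfigurationError("visit index outside [0, n_rungs)")


# ---------------------------------------------------------------------------
# Scaffold
# ---------------------------------------------------------------------------

_BACKBONE = (
    # name, element, offset from the residue base point (nm)
    ("N", "N", (-0.12, 0.03, 0.02)),
    ("H", "H", (-0.12, 0.13, 0.02)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (0.12, 0.03, -0.02)),
    ("O", "O", (0.12, 0.15, -0.02)),
)
# Glutamate side chain runs toward the channel axis (-y from the base),
# ending at the delta carbon and carboxylate oxygens.
_GLU_SIDE = (
    ("CB", "C", (0.0, -0.15, 0.0)),
    ("CG", "C", (0.0, -0.29, 0.0)),
    ("CD", "C", (0.0, -0.43, 0.0)),
    ("OE1", "O", (0.10, -0.51, 0.0)),
    ("OE2", "O", (-0.10, -0.51, 0.0)),
)
_GENERIC_SIDE = (("CB", "C", (0.0, -0.15, 0.0)),)


def _rotation_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.asarray([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def build_scaffold(n_chains: int = 5,
                   residue_spec: tuple = LOOP_SPAN_G312_Y327,
                   radius: float = 1.5, seed: int = 0,
                   spacing: float = 0.35, jitter: float = 0.005,
                   require_roles: tuple = (),
                   temperature: float = 315.0
                   ) -> tuple[Topology, Trajectory]:
    """C(n)-symmetric loop scaffold about the +x channel axis.

    Chain A is a template placed at ``radius`` nm from the axis,
    residues spaced along x, glutamate side chains extended toward the
    axis; chains B.. are exact copies rotated by 2 pi / n_chains about
    x. Every residue gets the role label one-letter-code + resid
    (``"E316"``), resolvable through selection queries. A small seeded
    jitter is applied to the template *before* replication, so the
    rotational symmetry stays exact to machine precision.
    """
    if n_chains < 1:
        raise ConfigurationError("n_chains must be >= 1")
    roles_available = {f"{aa}{resid}" for aa, resid in residue_spec}
    for role in require_roles:
        if role not in roles_available:
            raise ConfigurationError(
                f"unknown role label {role!r}; residue spec provides "
                f"{sorted(roles_available)}")

    rng = np.random.default_rng(seed)
    t_names, t_elems, t_res, t_xyz = [], [], [], []
    for i, (aa, resid) in enumerate(residue_spec):
        if aa not in THREE_LETTER:
            raise ConfigurationError(f"unknown residue code {aa!r}")
        base = np.asarray([i * spacing, radius, 0.0])
        side = _GLU_SIDE if aa == "E" else (
            () if aa == "G" else _GENERIC_SIDE)
        for name, elem, off in _BACKBONE + side:
            t_names.append(name)
            t_elems.append(elem)
            t_res.append((aa, resid))
            t_xyz.append(base + np.asarray(off))
    t_xyz = np.asarray(t_xyz)
    if jitter > 0:
        t_xyz = t_xyz + rng.normal(0.0, jitter, size=t_xyz.shape)

    names, elems, resids, resnames, chains, xyz = [], [], [], [], [], []
    roles: dict[str, list] = {}
    for k in range(n_chains):
        R = _rotation_x(2.0 * np.pi * k / n_chains)
        chain_id = chr(ord("A") + k)
        for (name, elem, (aa, resid), pos) in zip(
                t_names, t_elems, t_res, t_xyz):
            idx = len(names)
            names.append(name)
            elems.append(elem)
            resids.append(resid)
            resnames.append(THREE_LETTER[aa])
            chains.append(chain_id)
            xyz.append(pos @ R.T)
            roles.setdefault(f"{aa}{resid}", []).append(idx)

    top = Topology(
        names=np.asarray(names, dtype=object),
        elements=np.asarray(elems, dtype=object),
        masses=np.asarray([ELEMENT_MASSES[e] for e in elems]),
        resids=np.asarray(resids, dtype=int),
        resnames=np.asarray(resnames, dtype=object),
        chainids=np.asarray(chains, dtype=object),
        roles={k: np.asarray(v, dtype=int) for k, v in roles.items()},
    )
    traj = Trajectory(coords=np.asarray(xyz)[None, :, :],
                      temperature=temperature)
    return top, traj


def field_from_scaffold(top: Topology, frame: np.ndarray,
                        depth_e316: float = 16.8, depth_e320: float = 16.8,
                        width: float = 0.35, margin: float = 1.0,
                        periodic: bool = False) -> SyntheticField:
    """Binding field with one Gaussian well per glutamate carboxylate.

    Wells sit on the CD (delta carbon) of every residue carrying an
    E316/E320 role. The default depth (16.8 kJ/mol, about 6.4 kB T at
    315 K) is the global ion-loop binding free energy of the trivalent
    condition; a divalent-like landscape uses ~9.5 kJ/mol. The width
    (0.35 nm) matches the contact-minimum distance scale of a
    carboxylate binding site. The box is the scaffold bounding box
    padded by ``margin`` nm of flat bulk.
    """
    wells = []
    for role, depth in (("E316", depth_e316), ("E320", depth_e320)):
        if role not in top.roles:
            continue
        members = top.roles[role]
        cd = [i for i in members if str(top.names[i]) == "CD"]
        for i in cd:
            wells.append(Well(center=frame[i], depth=depth, width=width))
    if not wells:
        raise ConfigurationError("scaffold provides no glutamate wells")
    lo = frame.min(axis=0) - margin
    hi = frame.max(axis=0) + margin
    return SyntheticField(wells=wells, box=np.column_stack([lo, hi]),
                          periodic=periodic)


# ---------------------------------------------------------------------------
# Metropolis ion sampler
# ---------------------------------------------------------------------------

def sample_ion_trajectory(field: SyntheticField, n_ions: int = 10,
                          n_frames: int = 1000, temperature: float = 315.0,
                          seed: int = 0, stride: int = 10,
                          burnin_fraction: float = 0.1,
                          initial_step: float = 0.05,
                          initial: np.ndarray | None = None) -> Trajectory:
    """Boltzmann-distributed ion positions by Metropolis Monte Carlo.

    ``n_ions`` independent walkers use a 50/50 mixture proposal: a
    local Gaussian step folded back into the box by reflection at the
    walls, or a uniform relocation anywhere in the box. Both components
    are symmetric, so plain Metropolis acceptance keeps the exact
    Boltzmann distribution (and the flat-potential limit exactly
    uniform); the relocation component lets walkers exchange directly
    between narrow wells and the bulk, which a purely local walk does
    exponentially slowly once wells are several kB T deep. The local
    step is auto-tuned during burn-in toward 30-50 % acceptance (capped
    at 0.5 nm so it keeps resolving well interiors); burn-in is
    ``burnin_fraction`` of the total steps, and frames are recorded
    every ``stride`` post-burn-in sweeps. Runs are bit-reproducible
    from the seed. Initial placements are uniform in the box unless
    given explicitly.
    """
    if temperature <= 0:
        raise AnalysisError("temperature must be positive")
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    lo, hi = field.box[:, 0], field.box[:, 1]
    if initial is None:
        x = lo + rng.random((n_ions, 3)) * (hi - lo)
    else:
        x = np.array(initial, dtype=float).reshape(n_ions, 3)
        if not np.all(field.contains(x)):
            raise ConfigurationError("initial positions outside box")
    u = field.potential(x)

    production = n_frames * stride
    burnin = max(1, int(np.ceil(burnin_fraction / (1 - burnin_fraction)
                                * production)))
    step = float(initial_step)
    tune_interval, accepted, attempted = 50, 0, 0
    frames = np.empty((n_frames, n_ions, 3))
    recorded = 0

    span = hi - lo

    def fold(pos):
        # reflect at the walls: measure-preserving involution per image
        s = np.mod(pos - lo, 2.0 * span)
        return lo + np.minimum(s, 2.0 * span - s)

    for sweep in range(burnin + production):
        local = rng.random(n_ions) < 0.5
        prop_local = fold(x + rng.normal(0.0, step, size=(n_ions, 3)))
        prop_global = lo + rng.random((n_ions, 3)) * span
        prop = np.where(local[:, None], prop_local, prop_global)
        u_prop = field.potential(prop)
        accept = np.log(rng.random(n_ions)) < -beta * (u_prop - u)
        x = np.where(accept[:, None], prop, x)
        u = np.where(accept, u_prop, u)
        if sweep < burnin:
            accepted += int((accept & local).sum())
            attempted += int(local.sum())
            if (sweep + 1) % tune_interval == 0 and attempted:
                rate = accepted / attempted
                if rate > 0.5:
                    step *= 1.2
                elif rate < 0.3:
                    step *= 0.8
                step = float(np.clip(step, 1e-4, 0.5))
                accepted = attempted = 0
        else:
            prod_sweep = sweep - burnin
            if (prod_sweep + 1) % stride == 0:
                frames[recorded] = x
                recorded += 1

    box = field.lengths if field.periodic else None
    return Trajectory(coords=frames[:recorded], temperature=temperature,
                      box=box)


# ---------------------------------------------------------------------------
# Replica-exchange temperature traces
# ---------------------------------------------------------------------------

def default_ladder(n_rungs: int = N_RUNGS_DEFAULT,
                   t_min: float = T_LADDER_MIN,
                   t_max: float = T_LADDER_MAX) -> np.ndarray:
    """Geometric temperature ladder (constant ratio between rungs)."""
    return t_min * (t_max / t_min) ** (np.arange(n_rungs) / (n_rungs - 1))


def generate_replica_traces(n_replicas: int = N_RUNGS_DEFAULT,
                            n_steps: int = 1000,
                            exchange_prob: float = 0.391, seed: int = 0,
                            ladder: np.ndarray | None = None,
                            return_stats: bool = False):
    """Replica temperature traces under random adjacent-rung swaps.

    At every step each adjacent rung pair (0,1), (1,2), ... attempts a
    swap of its occupants with probability ``exchange_prob``, swept in
    rung order, so rung occupancy stays a permutation of the replicas
    at all times. Returns one :class:`ReplicaTrace` per replica (and,
    with ``return_stats``, the realized swap-acceptance frequency).
    """
    if not 0.0 <= exchange_prob <= 1.0:
        raise ConfigurationError("exchange_prob must lie in [0, 1]")
    if n_replicas < 2 and exchange_prob > 0:
        raise ConfigurationError(
            "need at least two replicas to exchange")
    if ladder is None:
        ladder = default_ladder(max(n_replicas, 2))[:n_replicas] \
            if n_replicas >= 2 else np.asarray([T_LADDER_MIN])
    rng = np.random.default_rng(seed)
    occupant = np.arange(n_replicas)          # rung -> replica
    visits = np.empty((n_steps + 1, n_replicas), dtype=int)
    rung_of = np.arange(n_replicas)           # replica -> rung
    visits[0] = rung_of
    swaps = attempts = 0
    for t in range(1, n_steps + 1):
        for i in range(n_replicas - 1):
            attempts += 1
            if rng.random() < exchange_prob:
                a, b = occupant[i], occupant[i + 1]
                occupant[i], occupant[i + 1] = b, a
                rung_of[a], rung_of[b] = i + 1, i
                swaps += 1
        visits[t] = rung_of
    traces = [ReplicaTrace(replica_id=r, ladder=np.asarray(ladder),
                           visits=visits[:, r])
              for r in range(n_replicas)]
    if return_stats:
        ratio = swaps / attempts if attempts else 0.0
        return traces, ratio
    return traces


# ---------------------------------------------------------------------------
# Assembly helpers
# ---------------------------------------------------------------------------

def ion_topology(n_ions: int, element: str = "MG", resname: str = "MG",
                 chain: str = "I", start_resid: int = 1) -> Topology:
    """Topology of point ions, each its own residue, role 'ion_center'."""
    names = np.asarray([element] * n_ions, dtype=object)
    return Topology(
        names=names,
        elements=np.asarray([element] * n_ions, dtype=object),
        masses=np.full(n_ions, ELEMENT_MASSES.get(element, 0.0)),
        resids=np.arange(start_resid, start_resid + n_ions),
        resnames=np.asarray([resname] * n_ions, dtype=object),
        chainids=np.asarray([chain] * n_ions, dtype=object),
        roles={"ion_center": np.arange(n_ions)},
    )


def assemble_system(scaffold_top: Topology, scaffold_frame: np.ndarray,
                    ion_top: Topology, ion_traj: Trajectory
                    ) -> tuple[Topology, Trajectory]:
    """Merge a static scaffold with a sampled ion trajectory.

    The scaffold frame is replicated across all ion frames; role labels
    from both parts are preserved (ion roles shifted past the scaffold
    atoms).
    """
    ns = scaffold_top.n_atoms
    roles = {k: np.asarray(v, dtype=int)
             for k, v in scaffold_top.roles.items()}
    for k, v in ion_top.roles.items():
        roles[k] = np.asarray(v, dtype=int) + ns

    def cat(a, b):
        return np.concatenate([np.asarray(a), np.asarray(b)])

    top = Topology(
        names=cat(scaffold_top.names, ion_top.names).astype(object),
        elements=cat(scaffold_top.elements, ion_top.elements).astype(object),
        masses=cat(scaffold_top.masses, ion_top.masses),
        resids=cat(scaffold_top.resids, ion_top.resids).astype(int),
        resnames=cat(scaffold_top.resnames, ion_top.resnames).astype(object),
        chainids=cat(scaffold_top.chainids, ion_top.chainids).astype(object),
        roles=roles,
    )
    n_frames = ion_traj.n_frames
    coords = np.empty((n_frames, ns + ion_top.n_atoms, 3))
    coords[:, :ns] = scaffold_frame[None, :, :]
    coords[:, ns:] = ion_traj.coords
    return top, Trajectory(coords=coords, temperature=ion_traj.temperature,
                           box=ion_traj.box)
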