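"""Per-frame geometric observables.

Minimum distances, radius of gyration, side-chain orientation cosines,
Shrake-Rupley solvent-accessible surface area, hydration-shell water
counts and radial distribution functions. All lengths nm, areas nm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AnalysisError, ConfigurationError, SelectionError
from .structio import SelectionGroup, Topology, Trajectory

__all__ = [
    "ObservableSeries",
    "min_distance",
    "min_distance_series",
    "radius_of_gyration",
    "orientation_cosine",
    "sasa",
    "count_shell_waters",
    "rdf",
    "fibonacci_sphere",
]


@dataclass
class ObservableSeries:
    """A named per-frame scalar (or vector) observable with units."""

    name: str
    values: np.ndarray
    units: str
    temperature: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _pair_distances(a: np.ndarray, b: np.ndarray,
                    box: np.ndarray | None) -> np.ndarray:
    """All cross-pair distances, minimum-image if a box is given."""
    if box is None:
        return cdist(a, b)
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta ** 2).sum(axis=-1))


def min_distance(frame: np.ndarray, group_a: SelectionGroup,
                 group_b: SelectionGroup, box: np.ndarray | None = None,
                 pbc: bool = False) -> float:
    """Minimum distance over all cross pairs between two atom groups.

    Symmetric in its arguments; uses the minimum-image convention when
    ``pbc`` is set and a box is supplied. Overlapping groups trigger a
    warning because the minimum is then 0 by construction.
    """
    ia, ib = group_a.indices, group_b.indices
    if np.intersect1d(ia, ib).size:
        warnings.warn("overlapping selection groups: minimum distance is 0 "
                      "by construction", stacklevel=2)
    d = _pair_distances(frame[ia], frame[ib], box if pbc else None)
    return float(d.min())


def min_distance_series(traj: Trajectory, group_a: SelectionGroup,
                        group_b: SelectionGroup,
                        pbc: bool = False) -> ObservableSeries:
    vals = [min_distance(traj.coords[f], group_a, group_b,
                         box=traj.box, pbc=pbc)
            for f in range(traj.n_frames)]
    return ObservableSeries(
        f"mindist({group_a.name},{group_b.name})", np.asarray(vals), "nm",
        traj.temperature)


def radius_of_gyration(frame: np.ndarray, group: SelectionGroup,
                       masses: np.ndarray | None = None,
                       mass_weighted: bool = False) -> float:
    """Rg = sqrt(sum m_i |x_i - x_com|^2 / sum m_i); unweighted m_i = 1."""
    x = frame[group.indices]
    if mass_weighted:
        if masses is None:
            raise AnalysisError("mass-weighted Rg requires masses")
        m = np.asarray(masses, dtype=float)[group.indices]
        if m.sum() <= 0:
            raise AnalysisError("zero total mass in Rg group")
    else:
        m = np.ones(len(x))
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_series(traj: Trajectory, group: SelectionGroup, top: Topology,
              mass_weighted: bool = True) -> ObservableSeries:
    vals = [radius_of_gyration(traj.coords[f], group, top.masses,
                               mass_weighted) for f in range(traj.n_frames)]
    return ObservableSeries("Rg", np.asarray(vals), "nm", traj.temperature)


def orientation_cosine(frame: np.ndarray, c_alpha: int, c_delta: int,
                       axis_point: np.ndarray,
                       axis_dir: np.ndarray) -> tuple[float, float]:
    """Side-chain orientation cosine relative to the channel axis.

    v1 runs from the alpha carbon to the delta carbon; v2 is the
    perpendicular foot vector from the alpha carbon onto the axis line
    (pointing toward the axis). Returns (cos alpha, alpha in degrees).
    cos alpha > 0 means the side chain tilts toward the channel axis.

    Returns (nan, nan) for a frame whose alpha carbon lies on the axis,
    where the foot vector vanishes and the angle is undefined.
    """
    if c_alpha == c_delta:
        raise ConfigurationError("c_alpha and c_delta must differ")
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    xa, xd = frame[c_alpha], frame[c_delta]
    v1 = xd - xa
    rel = xa - np.asarray(axis_point, dtype=float)
    foot = np.asarray(axis_point) + np.dot(rel, d) * d
    v2 = foot - xa
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n2 < 1e-12 or n1 < 1e-12:
        return float("nan"), float("nan")
    cos_a = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return cos_a, float(np.degrees(np.arccos(cos_a)))


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points on the golden-spiral lattice."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(frame: np.ndarray, group: SelectionGroup, radii: np.ndarray,
         top: Topology | None = None, probe: float = 0.14,
         n_sphere_points: int = 960) -> dict:
    """Shrake-Rupley solvent-accessible surface area, nm^2.

    For each atom, the fraction of quasi-uniform sphere points at radius
    r_i + probe not buried inside any neighbour's expanded sphere, times
    4 pi (r_i + probe)^2. Sphere points come from a deterministic
    Fibonacci lattice. Returns per-atom areas plus per-residue sums when
    a topology is supplied.
    """
    if n_sphere_points < 16:
        raise ConfigurationError("n_sphere_points must be >= 16")
    idx = group.indices
    radii = np.asarray(radii, dtype=float)
    if radii.ndim == 0:
        radii = np.full(len(frame), float(radii))
    if np.any(~(radii[idx] > 0)):
        raise AnalysisError("SASA requires positive radii for all atoms")
    pts = fibonacci_sphere(n_sphere_points)
    centers = frame[idx]
    expanded = radii[idx] + probe
    per_atom = np.zeros(len(idx))
    # neighbour prefilter: atoms within r_i + r_j + 2*probe can occlude
    d = cdist(centers, centers)
    for k in range(len(idx)):
        rk = expanded[k]
        neigh = np.flatnonzero((d[k] < rk + expanded) & (d[k] > 0))
        surface = centers[k] + rk * pts
        if neigh.size:
            dd = cdist(surface, centers[neigh])
            exposed = np.all(dd >= expanded[neigh][None, :], axis=1)
        else:
            exposed = np.ones(n_sphere_points, dtype=bool)
        per_atom[k] = exposed.mean() * 4.0 * np.pi * rk * rk
    result = {"per_atom": dict(zip((int(i) for i in idx), per_atom)),
              "total": float(per_atom.sum())}
    if top is not None:
        by_res: dict[tuple[str, int], float] = {}
        for k, i in enumerate(idx):
            key = (str(top.chainids[i]), int(top.resids[i]))
            by_res[key] = by_res.get(key, 0.0) + per_atom[k]
        result["per_residue"] = by_res
    return result


def count_shell_waters(frame: np.ndarray, residue_group: SelectionGroup,
                       water_oxygens: np.ndarray | SelectionGroup,
                       cutoff: float = 0.5,
                       box: np.ndarray | None = None) -> int:
    """Number of water oxygens within ``cutoff`` of the residue group."""
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    if isinstance(water_oxygens, SelectionGroup):
        w_idx = water_oxygens.indices
    else:
        w_idx = np.asarray(water_oxygens, dtype=int)
    if w_idx.size == 0:
        return 0
    d = _pair_distances(frame[w_idx], frame[residue_group.indices], box)
    return int(np.sum(d.min(axis=1) < cutoff))


def rdf(traj: Trajectory, centers: SelectionGroup, targets: SelectionGroup,
        bin_width: float = 0.02, r_max: float | None = None,
        allow_empty_targets: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) of targets around centers.

    Shell counts are normalised by the ideal-gas expectation
    rho * 4 pi r^2 dr per center per frame; requires a periodic box so
    the target density is defined. r_max defaults to (and may not
    exceed) half the smallest box edge, the minimum-image validity
    limit.
    """
    if traj.box is None:
        raise AnalysisError("RDF requires a periodic box (density "
                            "normalisation needs a volume)")
    half = float(traj.box.min()) / 2.0
    if r_max is None:
        r_max = half
    if r_max > half + 1e-12:
        raise AnalysisError(
            f"r_max {r_max} exceeds half the smallest box edge {half}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    try:
        t_idx = targets.indices
    except AttributeError:
        t_idx = np.asarray(targets, dtype=int)
    if t_idx.size == 0:
        centers_r = (edges[:-1] + edges[1:]) / 2
        return centers_r, counts
    for f in range(traj.n_frames):
        d = _pair_distances(traj.coords[f][centers.indices],
                            traj.coords[f][t_idx], traj.box)
        counts += np.histogram(d.ravel(), bins=edges)[0]
    volume = float(np.prod(traj.box))
    rho = t_idx.size / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = rho * shell * len(centers.indices) * traj.n_frames
    g = np.divide(counts, norm, out=np.zeros_like(counts), where=norm > 0)
    centers_r = (edges[:-1] + edges[1:]) / 2
    return centers_r, g
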