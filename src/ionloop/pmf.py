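"""Potentials of mean force by Boltzmann inversion of sampled histograms.

The free energy on a bin is w(r) = -kB T ln(g(r) / gmax), where g(r) is
the sample count in the bin and gmax the maximum count. Empty bins are
masked (NaN), never +/- infinity. An optional reference distance r_ref
shifts the profile so that w(r_ref) = 0 — the convention used to anchor
ion-protein profiles in the non-interacting bulk at 2 nm.

No 4 pi r^2 Jacobian correction is applied: this is raw Boltzmann
inversion of counts along the chosen coordinate, which matters for the
interpretation of radial profiles at large r (a uniform gas would not
give a flat radial profile after inversion; profiles here are read as
differences between well and reference regions on the same coordinate).

Uncertainties come from a block bootstrap over contiguous sample blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .errors import AnalysisError, ConfigurationError
from .structio import SelectionGroup, Trajectory

__all__ = [
    "PmfProfile",
    "Pmf2D",
    "pmf_1d",
    "pmf_2d",
    "binding_free_energy",
    "coordinate_distribution",
    "block_bootstrap_se",
]


def _invert(counts: np.ndarray, temperature: float) -> np.ndarray:
    """-kB T ln(g/gmax), with empty bins masked as NaN."""
    counts = np.asarray(counts, dtype=float)
    gmax = counts.max()
    if gmax <= 0:
        raise AnalysisError("all histogram bins are empty")
    w = np.full(counts.shape, np.nan)
    occupied = counts > 0
    w[occupied] = -KB * temperature * np.log(counts[occupied] / gmax)
    return w


@dataclass
class PmfProfile:
    """1D free-energy profile over distance bins."""

    r: np.ndarray                 # bin centers, nm
    counts: np.ndarray
    w: np.ndarray                 # kJ/mol; NaN on empty bins
    temperature: float            # K
    r_ref: float | None = None    # nm; bin(s) where w was anchored to 0
    se: np.ndarray | None = None  # per-bin standard error, kJ/mol
    bin_width: float = field(default=0.0)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.w)


@dataclass
class Pmf2D:
    """2D free-energy surface over a y-z grid."""

    y_edges: np.ndarray
    z_edges: np.ndarray
    counts: np.ndarray            # (ny, nz)
    w: np.ndarray                 # kJ/mol; NaN on empty cells
    temperature: float
    se: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.w)


def pmf_1d(samples: np.ndarray, bin_width: float, temperature: float,
           r_ref: float | None = None, ref_window: float = 0.05,
           n_blocks: int = 10, n_boot: int = 100,
           rng: np.random.Generator | None = None,
           compute_se: bool = False) -> PmfProfile:
    """Boltzmann-invert a 1D histogram of distance samples.

    Parameters
    ----------
    samples : distances (nm), in frame order (block bootstrap assumes
        contiguous blocks are approximately independent).
    bin_width : histogram bin width, nm.
    temperature : ensemble temperature, K.
    r_ref : optional reference distance; the profile is shifted by the
        mean w over defined bins within ``ref_window`` of r_ref so that
        w(r_ref) = 0.
    compute_se : also estimate per-bin standard errors by block
        bootstrap (``n_blocks`` contiguous blocks, ``n_boot`` resamples).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 1:
        raise AnalysisError("need at least one sample")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    lo = np.floor(samples.min() / bin_width) * bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width
    if r_ref is not None:
        lo = min(lo, np.floor((r_ref - ref_window) / bin_width) * bin_width)
        hi = max(hi, np.ceil((r_ref + ref_window) / bin_width) * bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.asarray([lo, lo + bin_width])
    counts, edges = np.histogram(samples, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    w = _invert(counts, temperature)
    w = _apply_reference(centers, w, r_ref, ref_window)
    se = None
    if compute_se:
        se = block_bootstrap_se(
            samples, edges, temperature, r_ref=r_ref, ref_window=ref_window,
            n_blocks=n_blocks, n_boot=n_boot, rng=rng)
    return PmfProfile(r=centers, counts=counts, w=w,
                      temperature=temperature, r_ref=r_ref, se=se,
                      bin_width=bin_width)


def _apply_reference(centers, w, r_ref, ref_window):
    if r_ref is None:
        # gmax-referencing: min over defined bins is 0 by construction
        return w
    near = (np.abs(centers - r_ref) <= ref_window) & ~np.isnan(w)
    if not near.any():
        raise AnalysisError(
            f"no occupied bin within {ref_window} nm of r_ref={r_ref}; "
            "widen the bins or choose a different reference")
    return w - np.nanmean(w[near])


def block_bootstrap_se(samples: np.ndarray, edges: np.ndarray,
                       temperature: float, r_ref: float | None = None,
                       ref_window: float = 0.05, n_blocks: int = 10,
                       n_boot: int = 100,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-bin standard error of w by contiguous-block bootstrap."""
    rng = np.random.default_rng(0) if rng is None else rng
    samples = np.asarray(samples, dtype=float).ravel()
    blocks = np.array_split(samples, n_blocks)
    centers = (edges[:-1] + edges[1:]) / 2
    replicas = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        resampled = np.concatenate([blocks[b] for b in pick])
        counts = np.histogram(resampled, bins=edges)[0]
        if counts.max() == 0:
            continue
        wb = _invert(counts, temperature)
        try:
            wb = _apply_reference(centers, wb, r_ref, ref_window)
        except AnalysisError:
            continue
        replicas.append(wb)
    if not replicas:
        raise AnalysisError("bootstrap produced no valid replicas")
    with warnings.catch_warnings():
        # bins occupied in < 2 replicas have undefined spread -> NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(np.asarray(replicas), axis=0, ddof=1)


def binding_free_energy(profile: PmfProfile) -> tuple[float, float]:
    """(r_min, w_min): location and depth of the global PMF minimum.

    Ties are broken toward smaller r. All-masked profiles raise.
    """
    if not profile.defined.any():
        raise AnalysisError("profile has no defined bins")
    w = np.where(profile.defined, profile.w, np.inf)
    i = int(np.argmin(w))  # argmin returns the first (smallest-r) tie
    return float(profile.r[i]), float(profile.w[i])


def pmf_2d(samples: np.ndarray, bin_width: float, temperature: float,
           n_blocks: int = 10, n_boot: int = 100,
           rng: np.random.Generator | None = None,
           compute_se: bool = True) -> Pmf2D:
    """Boltzmann inversion on a (y, z) grid with block-bootstrap SEs.

    ``samples`` is (n, 2) in frame order. Cell standard errors come
    from resampling ``n_blocks`` contiguous blocks of samples.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise AnalysisError("2D PMF needs (n, 2) samples")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")

    def grid_edges(vals):
        lo = np.floor(vals.min() / bin_width) * bin_width
        hi = np.ceil(vals.max() / bin_width) * bin_width
        e = np.arange(lo, hi + bin_width / 2, bin_width)
        return e if len(e) >= 2 else np.asarray([lo, lo + bin_width])

    ye, ze = grid_edges(samples[:, 0]), grid_edges(samples[:, 1])
    counts = np.histogram2d(samples[:, 0], samples[:, 1], bins=(ye, ze))[0]
    w = _invert(counts, temperature)
    se = None
    if compute_se:
        rng = np.random.default_rng(0) if rng is None else rng
        blocks = np.array_split(np.arange(len(samples)), n_blocks)
        reps = []
        for _ in range(n_boot):
            pick = rng.integers(0, n_blocks, size=n_blocks)
            idx = np.concatenate([blocks[b] for b in pick])
            cb = np.histogram2d(samples[idx, 0], samples[idx, 1],
                                bins=(ye, ze))[0]
            if cb.max() > 0:
                reps.append(_invert(cb, temperature))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se = np.nanstd(np.asarray(reps), axis=0, ddof=1)
    return Pmf2D(y_edges=ye, z_edges=ze, counts=counts, w=w,
                 temperature=temperature, se=se)


def coordinate_distribution(traj: Trajectory, group: SelectionGroup,
                            axis: str, bin_width: float = 0.05
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized density of one Cartesian coordinate, pooled over the
    group's atoms and all frames (e.g. ion X-positions vs the channel
    mouth marked by G312 alpha carbons)."""
    ax = {"x": 0, "y": 1, "z": 2}.get(axis.lower())
    if ax is None:
        raise ConfigurationError(f"axis must be x, y or z, got {axis!r}")
    vals = traj.coords[:, group.indices, ax].ravel()
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.asarray([lo, lo + bin_width])
    dens, edges = np.histogram(vals, bins=edges, density=True)
    return (edges[:-1] + edges[1:]) / 2, dens
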