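"""Ion binding classification.

Definitions used throughout (distance cutoff 0.5 nm unless overridden):

* interacting residue — a residue whose heavy-atom minimum distance to
  the ion center is strictly less than the cutoff;
* bound ion — an ion with at least one interacting residue in a frame;
* contact cluster "x-y" — x is the number of E316 chains and y the
  number of E320 chains within the cutoff of an ion; ions with
  x = y = 0 are excluded from cluster populations;
* representative snapshot — after least-squares superposition on
  protein heavy atoms, single-linkage clustering of frames by
  ion-position RMSD; the medoid of the largest cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .errors import AnalysisError
from .structio import SelectionGroup, Topology, Trajectory

__all__ = [
    "BoundContactRecord",
    "BoundStatePartition",
    "interacting_residues",
    "contact_records",
    "bound_ion_count",
    "contact_cluster_label",
    "cluster_populations",
    "bound_state_partition",
    "representative_snapshot",
    "kabsch_rotation",
    "single_ion_frames",
]


@dataclass(frozen=True)
class BoundContactRecord:
    """Contacts of one ion in one frame."""

    frame: int
    ion: int
    residues: tuple          # ((chain, resname, resid), ...) within cutoff
    cluster: tuple           # (n_E316, n_E320)

    @property
    def bound(self) -> bool:
        return len(self.residues) > 0

    @property
    def label(self) -> str:
        return f"{self.cluster[0]}-{self.cluster[1]}"


@dataclass
class BoundStatePartition:
    """Frames grouped by the number of bound ions."""

    per_frame_count: np.ndarray
    mean: float
    sd: float
    populations: dict        # bound count -> fraction of frames
    signatures: dict         # bound count -> most frequent state string


def interacting_residues(top: Topology, frame: np.ndarray, ion_index: int,
                         protein: SelectionGroup,
                         cutoff: float = 0.5) -> list[tuple[str, str, int]]:
    """Residues whose heavy-atom minimum distance to the ion center is
    strictly below the cutoff (an ion exactly at the cutoff is out)."""
    heavy = top.heavy_mask
    prot = protein.indices[heavy[protein.indices]]
    if prot.size == 0:
        return []
    d = cdist(frame[[ion_index]], frame[prot]).ravel()
    out: dict[tuple[str, str, int], float] = {}
    for j, dist in zip(prot, d):
        key = (str(top.chainids[j]), str(top.resnames[j]), int(top.resids[j]))
        if dist < out.get(key, np.inf):
            out[key] = dist
    return [k for k, v in sorted(out.items()) if v < cutoff]


def contact_cluster_label(top: Topology, frame: np.ndarray, ion_index: int,
                          e316_groups: list[SelectionGroup],
                          e320_groups: list[SelectionGroup],
                          cutoff: float = 0.5) -> tuple[int, int]:
    """(x, y) = number of E316 / E320 chains within the cutoff."""
    heavy = top.heavy_mask

    def count(groups):
        n = 0
        for g in groups:
            idx = g.indices[heavy[g.indices]]
            if idx.size and cdist(frame[[ion_index]],
                                  frame[idx]).min() < cutoff:
                n += 1
        return n

    return count(e316_groups), count(e320_groups)


def contact_records(top: Topology, traj: Trajectory,
                    ion_indices: np.ndarray, protein: SelectionGroup,
                    e316_groups: list[SelectionGroup],
                    e320_groups: list[SelectionGroup],
                    cutoff: float = 0.5) -> list[BoundContactRecord]:
    """Full per-frame, per-ion contact classification."""
    records = []
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        for ion in ion_indices:
            res = interacting_residues(top, frame, int(ion), protein, cutoff)
            cl = contact_cluster_label(top, frame, int(ion), e316_groups,
                                       e320_groups, cutoff)
            records.append(BoundContactRecord(
                frame=f, ion=int(ion), residues=tuple(res), cluster=cl))
    return records


def bound_ion_count(records: list[BoundContactRecord]
                    ) -> tuple[np.ndarray, float, float]:
    """Per-frame bound-ion counts and their ensemble mean +/- sd."""
    frames = sorted({r.frame for r in records})
    counts = np.zeros(len(frames), dtype=int)
    pos = {f: i for i, f in enumerate(frames)}
    for r in records:
        if r.bound:
            counts[pos[r.frame]] += 1
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return counts, mean, sd


def cluster_populations(records: list[BoundContactRecord]) -> dict[str, float]:
    """Cluster label -> percentage among (frame, ion) pairs with at
    least one E316 or E320 within the cutoff (x + y >= 1)."""
    eligible = [r for r in records if sum(r.cluster) >= 1]
    if not eligible:
        raise AnalysisError("no ion has any E316/E320 contact; "
                            "cluster populations undefined")
    counts = Counter(r.label for r in eligible)
    total = sum(counts.values())
    return {lab: 100.0 * c / total
            for lab, c in sorted(counts.items(),
                                 key=lambda kv: -kv[1])}


def _state_signature(frame_records: list[BoundContactRecord]) -> str:
    """Table-style state string: per bound ion, residues joined by '/',
    ions separated by ', '; residue rendered RESNAME(chain)."""
    parts = []
    for r in frame_records:
        if r.bound:
            parts.append("/".join(f"{resname}({chain})"
                                  for chain, resname, _ in r.residues))
    return ", ".join(sorted(parts))


def bound_state_partition(records: list[BoundContactRecord]
                          ) -> BoundStatePartition:
    """Group frames by bound-ion count; report per-count populations
    and the most frequent residue signature within each count."""
    by_frame: dict[int, list[BoundContactRecord]] = {}
    for r in records:
        by_frame.setdefault(r.frame, []).append(r)
    counts, mean, sd = bound_ion_count(records)
    n_frames = len(by_frame)
    populations: dict[int, float] = {}
    sig_counter: dict[int, Counter] = {}
    for f, recs in by_frame.items():
        k = sum(r.bound for r in recs)
        populations[k] = populations.get(k, 0.0) + 1.0 / n_frames
        sig_counter.setdefault(k, Counter())[_state_signature(recs)] += 1
    signatures = {k: c.most_common(1)[0][0] for k, c in sig_counter.items()}
    return BoundStatePartition(per_frame_count=counts, mean=mean, sd=sd,
                               populations=dict(sorted(populations.items())),
                               signatures=signatures)


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation (det = +1) minimizing RMSD of P onto Q, both
    already centered."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _superpose(mobile: np.ndarray, ref: np.ndarray, fit_idx: np.ndarray
               ) -> np.ndarray:
    """Least-squares fit of a whole frame using the fit atoms."""
    mp = mobile[fit_idx].mean(axis=0)
    rp = ref[fit_idx].mean(axis=0)
    R = kabsch_rotation(mobile[fit_idx] - mp, ref[fit_idx] - rp)
    return (mobile - mp) @ R.T + rp


def representative_snapshot(traj: Trajectory, protein_heavy: SelectionGroup,
                            ion: SelectionGroup,
                            rmsd_cutoff: float = 0.2,
                            frames: np.ndarray | None = None) -> int:
    """Representative frame of a contact cluster.

    1. superpose every frame on the first via least-squares fit over
       protein heavy atoms (proper rotation only);
    2. single-linkage cluster the frames by ion-position RMSD with the
       given cutoff;
    3. in the largest cluster return the frame minimizing the summed
       RMSD to its members (ties: earliest frame).
    """
    frames = (np.arange(traj.n_frames) if frames is None
              else np.asarray(frames, dtype=int))
    if frames.size == 0:
        raise AnalysisError("no frames to cluster")
    if frames.size == 1:
        return int(frames[0])
    fit_idx = protein_heavy.indices
    ref = traj.coords[frames[0]]
    ion_pos = np.stack([
        _superpose(traj.coords[f], ref, fit_idx)[ion.indices]
        for f in frames])
    n = len(frames)
    rmsd = np.zeros((n, n))
    for i in range(n):
        diff = ion_pos - ion_pos[i]
        rmsd[i] = np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))
    rmsd = (rmsd + rmsd.T) / 2
    labels = fcluster(linkage(squareform(rmsd, checks=False),
                              method="single"),
                      t=rmsd_cutoff, criterion="distance")
    sizes = Counter(labels)
    best_size = max(sizes.values())
    # tie on size -> cluster containing the earliest frame
    winners = [lab for lab, s in sizes.items() if s == best_size]
    members = min((np.flatnonzero(labels == lab) for lab in winners),
                  key=lambda m: m.min())
    summed = rmsd[np.ix_(members, members)].sum(axis=1)
    return int(frames[members[int(np.argmin(summed))]])


def single_ion_frames(traj: Trajectory, ion_groups: list[SelectionGroup]):
    """Iterate (ion_group, frame_index) masking all but one ion.

    Emulates splitting a multi-ion trajectory into per-ion segments for
    single-ion energetics: each ion in turn is treated as the only ion
    present over all frames.
    """
    for g in ion_groups:
        for f in range(traj.n_frames):
            yield g, f
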