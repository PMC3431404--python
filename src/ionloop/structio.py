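"""Structures, trajectories, selections and per-atom parameters.

The shared data model is a :class:`Topology` (per-atom identity, residue
and chain labels, masses, charges, intrinsic Born radii, LJ parameters,
plus named *role* labels such as ``"E316"`` or ``"ion_center"``) and a
:class:`Trajectory` (frames of coordinates in nm at one ensemble
temperature, optionally with an orthorhombic box).

File reading is delegated to MDAnalysis (multi-model PDB, GRO, XYZ);
coordinates are converted to nm on input (PDB/XYZ Angstrom / 10).
Writers emit multi-model PDB, GRO and plain XYZ.

Charges, Born radii and LJ parameters are never taken from structure
files: they come from a plain-text parameter table (TSV with columns
``name  charge_e  radius_nm  sigma_nm  epsilon_kJmol  [screen]``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SelectionError

__all__ = [
    "Topology",
    "Trajectory",
    "SelectionGroup",
    "read_structure",
    "write_structure",
    "load_parameter_table",
    "apply_parameters",
    "resolve_selection",
]

# Atomic masses (u) for the elements this pipeline meets.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "MG": 24.305, "CO": 58.933, "CL": 35.45, "NA": 22.990,
    "K": 39.098, "CA": 40.078, "FE": 55.845, "ZN": 65.38,
}

_ANGSTROM = 0.1  # nm per Angstrom


def _element_from_name(name: str) -> str:
    """Guess an element symbol from an atom name (PDB conventions)."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped.upper() in ELEMENT_MASSES:
        return stripped.upper()
    head = stripped.lstrip("0123456789")
    if len(head) >= 2 and head[:2].upper() in ("MG", "CO", "CL", "NA", "FE", "ZN"):
        return head[:2].upper()
    return head[:1].upper()


@dataclass
class Topology:
    """Per-atom identity and parameters; atom indices contiguous from 0."""

    names: np.ndarray          # str per atom
    elements: np.ndarray       # str per atom ("" if unknown)
    masses: np.ndarray         # u; 0 for unknown elements
    resids: np.ndarray         # int per atom
    resnames: np.ndarray       # str per atom
    chainids: np.ndarray       # str per atom
    charges: np.ndarray | None = None   # e, from parameter table
    radii: np.ndarray | None = None     # intrinsic Born radii, nm
    sigmas: np.ndarray | None = None    # LJ sigma, nm
    epsilons: np.ndarray | None = None  # LJ epsilon, kJ/mol
    screens: np.ndarray | None = None   # GB descreening scale factors
    roles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "masses", "resids", "resnames", "chainids"):
            if len(getattr(self, attr)) != n:
                raise FormatError(f"topology field {attr!r} length != n_atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e != "H" for e in self.elements])

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resid) keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chainids, self.resids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_atoms(self) -> dict[tuple[str, int], np.ndarray]:
        """(chain, resid) -> atom index array."""
        out: dict[tuple[str, int], list[int]] = {}
        for i, (c, r) in enumerate(zip(self.chainids, self.resids)):
            out.setdefault((str(c), int(r)), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def residue_name(self, key: tuple[str, int]) -> str:
        idx = np.flatnonzero(
            (self.chainids == key[0]) & (self.resids == key[1]))
        return str(self.resnames[idx[0]])

    def subset(self, indices: np.ndarray) -> "Topology":
        """New topology over the given atoms, reindexed from 0."""
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        remap = {old: new for new, old in enumerate(idx)}
        roles = {}
        for label, members in self.roles.items():
            kept = [remap[i] for i in members if i in remap]
            if kept:
                roles[label] = np.asarray(kept, dtype=int)

        def take(arr):
            return None if arr is None else np.asarray(arr)[idx].copy()

        return Topology(
            names=self.names[idx].copy(), elements=self.elements[idx].copy(),
            masses=self.masses[idx].copy(), resids=self.resids[idx].copy(),
            resnames=self.resnames[idx].copy(),
            chainids=self.chainids[idx].copy(),
            charges=take(self.charges), radii=take(self.radii),
            sigmas=take(self.sigmas), epsilons=take(self.epsilons),
            screens=take(self.screens), roles=roles,
        )


@dataclass
class Trajectory:
    """Frames of coordinates in nm at one ensemble temperature."""

    coords: np.ndarray            # (n_frames, n_atoms, 3), nm
    temperature: float            # K
    box: np.ndarray | None = None  # orthorhombic edge lengths, nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        if self.temperature <= 0:
            raise FormatError("ensemble temperature must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class SelectionGroup:
    """Named, sorted, unique atom indices."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size == 0:
            raise SelectionError(f"selection {self.name!r} is empty")
        if idx[0] < 0:
            raise SelectionError(f"selection {self.name!r} has negative index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def union(self, other: "SelectionGroup") -> "SelectionGroup":
        return SelectionGroup(
            f"({self.name} or {other.name})",
            np.union1d(self.indices, other.indices))

    def intersection(self, other: "SelectionGroup") -> "SelectionGroup":
        return SelectionGroup(
            f"({self.name} and {other.name})",
            np.intersect1d(self.indices, other.indices))


# ---------------------------------------------------------------------------
# File input (MDAnalysis backend) and output
# ---------------------------------------------------------------------------

def read_structure(path, fmt: str | None = None,
                   temperature: float = 315.0) -> tuple[Topology, Trajectory]:
    """Read a structure + trajectory from multi-model PDB, GRO or XYZ.

    MODEL records become frames; chain/residue labels are preserved;
    coordinates are stored in nm (PDB and XYZ files carry Angstrom).
    Unknown elements get mass 0 with a warning — energetics then
    requires an explicit parameter table.
    """
    import MDAnalysis as mda

    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("pdb", "gro", "xyz"):
        raise FormatError(f"unsupported format {fmt!r}")
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt)
        except Exception as exc:  # mda raises many flavours
            raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

        names = np.asarray([a.name for a in u.atoms], dtype=object)
        try:
            resids = np.asarray(u.atoms.resids, dtype=int)
            resnames = np.asarray(u.atoms.resnames, dtype=object)
        except (AttributeError, mda.exceptions.NoDataError):
            resids = np.ones(len(names), dtype=int)
            resnames = np.asarray(["UNK"] * len(names), dtype=object)
        try:
            chains = np.asarray(u.atoms.chainIDs, dtype=object)
        except (AttributeError, mda.exceptions.NoDataError):
            try:
                chains = np.asarray(u.atoms.segids, dtype=object)
            except (AttributeError, mda.exceptions.NoDataError):
                chains = np.asarray(["A"] * len(names), dtype=object)
        chains = np.asarray(
            [c if str(c).strip() else "A" for c in chains], dtype=object)

        elements = np.asarray(
            [_element_from_name(n) for n in names], dtype=object)
        masses = np.empty(len(names))
        for i, e in enumerate(elements):
            if e in ELEMENT_MASSES:
                masses[i] = ELEMENT_MASSES[e]
            else:
                warnings.warn(
                    f"unknown element for atom {names[i]!r}; mass set to 0 — "
                    "supply a parameter table before energetics",
                    stacklevel=2)
                masses[i] = 0.0

        # MDAnalysis reports Angstrom internally for every format.
        scale = _ANGSTROM
        frames = []
        for ts in u.trajectory:
            if ts.positions.shape[0] != len(names):
                raise FormatError(
                    f"frame {ts.frame} atom count {ts.positions.shape[0]} "
                    f"!= topology {len(names)}")
            frames.append(ts.positions.astype(float) * scale)
        box = None
        if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
            box = u.dimensions[:3].astype(float) * _ANGSTROM

    top = Topology(names=names, elements=elements, masses=masses,
                   resids=resids, resnames=resnames, chainids=chains)
    traj = Trajectory(coords=np.stack(frames), temperature=temperature,
                      box=box)
    return top, traj


def write_structure(path, top: Topology, traj: Trajectory,
                    fmt: str | None = None) -> None:
    """Write a multi-model PDB, GRO or plain XYZ trajectory."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        _write_pdb(path, top, traj)
    elif fmt == "gro":
        _write_gro(path, top, traj)
    elif fmt == "xyz":
        _write_xyz(path, top, traj)
    else:
        raise FormatError(f"unsupported format {fmt!r}")


def _write_pdb(path, top, traj):
    with open(path, "w") as fh:
        if traj.box is not None:
            bx, by, bz = traj.box * 10.0
            fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            xyz = traj.coords[m] / _ANGSTROM
            for i in range(top.n_atoms):
                name = str(top.names[i])[:4]
                # PDB column 13-16: pad 1-3 char names with a leading space
                name_f = f" {name:<3s}" if len(name) < 4 else name
                serial = (i + 1) % 100000
                elem = str(top.elements[i])[:2].rjust(2)
                fh.write(
                    "ATOM  {serial:5d} {name} {res:<4s}{chain}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{elem}\n".format(
                        serial=serial, name=name_f,
                        res=str(top.resnames[i])[:4],
                        chain=str(top.chainids[i])[:1],
                        resid=int(top.resids[i]) % 10000,
                        x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                        occ=1.0, b=0.0, elem=elem))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_gro(path, top, traj):
    box = traj.box if traj.box is not None else np.zeros(3)
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"frame {m} t= {float(m):.3f}\n{top.n_atoms:5d}\n")
            for i in range(top.n_atoms):
                fh.write("{resid:>5d}{res:<5s}{name:>5s}{serial:>5d}"
                         "{x:8.3f}{y:8.3f}{z:8.3f}\n".format(
                             resid=int(top.resids[i]) % 100000,
                             res=str(top.resnames[i])[:5],
                             name=str(top.names[i])[:5],
                             serial=(i + 1) % 100000,
                             x=traj.coords[m, i, 0],
                             y=traj.coords[m, i, 1],
                             z=traj.coords[m, i, 2]))
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def _write_xyz(path, top, traj):
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"{top.n_atoms}\nframe {m}\n")
            xyz = traj.coords[m] / _ANGSTROM
            for i in range(top.n_atoms):
                label = str(top.elements[i]) or str(top.names[i])
                fh.write(f"{label:<4s} {xyz[i, 0]:12.6f} "
                         f"{xyz[i, 1]:12.6f} {xyz[i, 2]:12.6f}\n")


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

def load_parameter_table(path) -> pd.DataFrame:
    """Load a TSV parameter table keyed by atom name.

    Columns: name, charge_e, radius_nm, sigma_nm, epsilon_kJmol and an
    optional screen (GB descreening scale, default 0.8).
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    required = {"name", "charge_e", "radius_nm", "sigma_nm", "epsilon_kJmol"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"parameter table missing columns: {missing}")
    if "screen" not in df.columns:
        df["screen"] = 0.8
    if (df["radius_nm"] <= 0).any():
        bad = df.loc[df["radius_nm"] <= 0, "name"].tolist()
        raise ParameterError(f"non-positive radius for atoms: {bad}")
    return df.set_index("name")


def apply_parameters(top: Topology, table: pd.DataFrame,
                     strict: bool = True) -> Topology:
    """Attach charges/radii/LJ parameters from a table to a topology.

    Lookup is by atom name, falling back to the element symbol. With
    ``strict`` a missing entry raises; otherwise the atom gets charge 0,
    and the Born radius stays unset (NaN) so energetics refuses it.
    """
    n = top.n_atoms
    charges = np.zeros(n)
    radii = np.full(n, np.nan)
    sigmas = np.zeros(n)
    epsilons = np.zeros(n)
    screens = np.full(n, 0.8)
    for i in range(n):
        key = None
        if str(top.names[i]) in table.index:
            key = str(top.names[i])
        elif str(top.elements[i]) in table.index:
            key = str(top.elements[i])
        if key is None:
            if strict:
                raise ParameterError(
                    f"no parameters for atom {top.names[i]!r} "
                    f"(element {top.elements[i]!r})")
            continue
        row = table.loc[key]
        charges[i] = float(row["charge_e"])
        radii[i] = float(row["radius_nm"])
        sigmas[i] = float(row["sigma_nm"])
        epsilons[i] = float(row["epsilon_kJmol"])
        screens[i] = float(row["screen"])
    top.charges, top.radii = charges, radii
    top.sigmas, top.epsilons, top.screens = sigmas, epsilons, screens
    return top


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
#
# expr     := term ("or" term)*
# term     := factor ("and" factor)*
# factor   := "not" factor | "(" expr ")" | primitive
# primitive:= role:LABEL | chain:X | resid:N | resid:N-M | resname:XXX
#             | name:XX | element:X | heavy | hydrogen | all

def _tokenize(expr: str) -> list[str]:
    out, buf = [], ""
    for ch in expr:
        if ch in "()":
            if buf:
                out.append(buf)
                buf = ""
            out.append(ch)
        elif ch.isspace():
            if buf:
                out.append(buf)
                buf = ""
        else:
            buf += ch
    if buf:
        out.append(buf)
    return out


def _primitive_mask(top: Topology, token: str) -> np.ndarray:
    n = top.n_atoms
    low = token.lower()
    if low == "all":
        return np.ones(n, dtype=bool)
    if low == "heavy":
        return top.heavy_mask
    if low == "hydrogen":
        return ~top.heavy_mask
    if ":" not in token:
        raise SelectionError(f"unknown selection token {token!r}")
    kind, _, value = token.partition(":")
    kind = kind.lower()
    if kind == "role":
        if value not in top.roles:
            raise SelectionError(
                f"unknown role label {value!r}; "
                f"known roles: {sorted(top.roles)}")
        mask = np.zeros(n, dtype=bool)
        mask[top.roles[value]] = True
        return mask
    if kind == "chain":
        return np.asarray([str(c) == value for c in top.chainids])
    if kind == "resname":
        return np.asarray([str(r) == value for r in top.resnames])
    if kind == "name":
        return np.asarray([str(x) == value for x in top.names])
    if kind == "element":
        return np.asarray(
            [str(e) == value.upper() for e in top.elements])
    if kind == "resid":
        if "-" in value:
            lo, hi = value.split("-")
            lo, hi = int(lo), int(hi)
        else:
            lo = hi = int(value)
        return (top.resids >= lo) & (top.resids <= hi)
    raise SelectionError(f"unknown selection keyword {kind!r}")


class _Parser:
    def __init__(self, top: Topology, tokens: list[str]):
        self.top, self.tokens, self.pos = top, tokens, 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if tok is None or tok in (")", "and", "or"):
            raise SelectionError(f"unexpected token {tok!r}")
        self.next()
        return _primitive_mask(self.top, tok)


def resolve_selection(top: Topology, expr: str) -> SelectionGroup:
    """Resolve a selection expression to a sorted unique atom group.

    ``heavy`` excludes hydrogens; queries compose with and/or/not and
    parentheses. An empty result raises :class:`SelectionError`.
    """
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    parser = _Parser(top, tokens)
    mask = parser.expr()
    if parser.peek() is not None:
        raise SelectionError(f"trailing tokens from {parser.peek()!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return SelectionGroup(expr, idx)
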