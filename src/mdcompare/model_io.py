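"""Data model for structures, trajectories, domains and interfaces.

Coordinates are Cartesian angstroms; times are nanoseconds.  Residues are
indexed 0-based and contiguously in file order internally, while the PDB
residue numbers (author numbering, e.g. G323, T324) are preserved as
metadata and used in all report labels.

PDB reading and writing is delegated to biotite; XTC/DCD are optional
adapters.  Bonds are taken from an explicit list when available, else
hydrogens are paired to their nearest heavy atom by distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

POLAR_ELEMENTS = {"N", "O", "S", "P"}
WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3"}
DEFAULT_FRAME_SPACING_NS = 0.1
_H_BOND_MAX = 1.3  # angstrom, H-heavy pairing cutoff


class ParseError(ValueError):
    """Malformed input file."""


class EmptyInputError(ValueError):
    """Input contains no usable records."""


class TopologyMismatchError(ValueError):
    """Coordinate set does not match the topology."""


@dataclass
class Atom:
    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    is_polar: bool = False
    partial_charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None
    res_seq: int | None = None  # author residue number (PDB metadata)

    def __post_init__(self):
        if self.lj_sigma is not None and self.lj_sigma <= 0:
            raise ValueError(f"atom {self.index}: lj_sigma must be > 0")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.index}: lj_epsilon must be >= 0")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Topology:
    """Ordered atoms, residues and an explicit bond list."""

    atoms: list[Atom]
    bonds: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("atom indices must be 0..A-1 in order")
        for i, j in self.bonds:
            if not (0 <= i < len(self.atoms) and 0 <= j < len(self.atoms)):
                raise ValueError(f"bond ({i},{j}) references unknown atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[tuple[int, str, str]]:
        """Ordered (residue_index, residue_name, chain_id) tuples."""
        seen: dict[int, tuple[int, str, str]] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, (a.residue_index, a.residue_name, a.chain_id))
        return [seen[k] for k in sorted(seen)]

    @property
    def n_residues(self) -> int:
        return len({a.residue_index for a in self.atoms})

    def residue_label(self, residue_index: int) -> str:
        """Human-facing label using author numbering, e.g. ``A:GLY 323``."""
        for a in self.atoms:
            if a.residue_index == residue_index:
                num = a.res_seq if a.res_seq is not None else residue_index
                return f"{a.chain_id}:{a.residue_name} {num}"
        raise KeyError(f"no residue with index {residue_index}")

    def atom_indices(self, residue_index: int | None = None,
                     name: str | None = None, chain_id: str | None = None,
                     element: str | None = None,
                     heavy_only: bool = False) -> np.ndarray:
        """Indices of atoms matching all given filters, in topology order."""
        out = []
        for a in self.atoms:
            if residue_index is not None and a.residue_index != residue_index:
                continue
            if name is not None and a.name != name:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if element is not None and a.element != element:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            out.append(a.index)
        return np.array(out, dtype=int)

    def find_atom(self, chain_id: str, res_seq: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain_id == chain_id and a.res_seq == res_seq and a.name == name:
                return a
        raise KeyError(f"no atom {chain_id}:{res_seq}:{name}")

    def bonded_hydrogens(self, heavy_index: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == heavy_index and self.atoms[j].is_hydrogen:
                out.append(j)
            elif j == heavy_index and self.atoms[i].is_hydrogen:
                out.append(i)
        return sorted(out)

    def hydrogen_parent(self, h_index: int) -> int | None:
        for i, j in self.bonds:
            if i == h_index and not self.atoms[j].is_hydrogen:
                return j
            if j == h_index and not self.atoms[i].is_hydrogen:
                return i
        return None

    def validate_hydrogen_bonding(self) -> None:
        """Each hydrogen must be bonded to exactly one heavy atom."""
        for a in self.atoms:
            if a.is_hydrogen:
                parents = [self.hydrogen_parent(a.index)]
                n = sum(1 for i, j in self.bonds
                        if (i == a.index and not self.atoms[j].is_hydrogen)
                        or (j == a.index and not self.atoms[i].is_hydrogen))
                if n != 1:
                    raise ValueError(
                        f"hydrogen {a.index} ({a.name}) bonded to {n} heavy atoms")


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates bound to a topology.

    ``provenance`` optionally records, per frame, the index of the source
    replicate a frame came from (kept through concatenation).
    """

    topology: Topology
    coords: np.ndarray  # (F, A, 3) angstrom
    times: np.ndarray  # (F,) ns, strictly increasing
    provenance: np.ndarray | None = None  # (F,) int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, A, 3)")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("trajectory must have at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"coords have {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}")
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=int)
            if self.provenance.shape != self.times.shape:
                raise ValueError("provenance must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def subset(self, frame_indices) -> "Trajectory":
        idx = np.asarray(frame_indices, dtype=int)
        prov = None if self.provenance is None else self.provenance[idx]
        return Trajectory(self.topology, self.coords[idx], self.times[idx], prov)


@dataclass
class StateEnsemble:
    """Replicate trajectories sharing one topology, labelled by state."""

    state_label: str
    replicates: list[Trajectory]

    def __post_init__(self):
        if not self.replicates:
            raise EmptyInputError("state ensemble requires >= 1 replicate")
        top = self.replicates[0].topology
        for r in self.replicates[1:]:
            if r.topology is not top:
                raise TopologyMismatchError(
                    "all replicates must share one Topology object")

    @property
    def topology(self) -> Topology:
        return self.replicates[0].topology

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass
class DomainMap:
    """Named domains (chain + inclusive author-numbered residue range),
    per-residue order flags, and numbered domain-pair interfaces."""

    domains: dict[str, tuple[str, tuple[int, int]]]
    interfaces: dict[int, tuple[str, str]]
    disordered: set[tuple[str, int]] = field(default_factory=set)  # (chain, res_seq)

    def __post_init__(self):
        by_chain: dict[str, list[tuple[int, int, str]]] = {}
        for name, (chain, (lo, hi)) in self.domains.items():
            if lo > hi:
                raise ValueError(f"domain {name}: range {lo}..{hi} inverted")
            by_chain.setdefault(chain, []).append((lo, hi, name))
        for chain, ranges in by_chain.items():
            ranges.sort()
            for (lo1, hi1, n1), (lo2, hi2, n2) in zip(ranges, ranges[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"domains {n1} and {n2} overlap on chain {chain}")
        for iid, (a, b) in self.interfaces.items():
            for d in (a, b):
                if d not in self.domains:
                    raise ValueError(f"interface {iid} references unknown domain {d!r}")

    def domain_residues(self, name: str) -> tuple[str, list[int]]:
        chain, (lo, hi) = self.domains[name]
        return chain, list(range(lo, hi + 1))

    def validate_against(self, topology: "Topology") -> None:
        """Check every domain residue exists on its chain in the topology."""
        present: dict[str, set[int]] = {}
        for a in topology.atoms:
            if a.res_seq is not None:
                present.setdefault(a.chain_id, set()).add(a.res_seq)
        for name, (chain, (lo, hi)) in self.domains.items():
            have = present.get(chain, set())
            missing = [r for r in range(lo, hi + 1) if r not in have]
            if missing:
                raise ValueError(
                    f"domain {name}: residues {missing[:5]}... outside "
                    f"chain {chain} range" if len(missing) > 5 else
                    f"domain {name}: residues {missing} outside chain {chain}")

    def is_disordered(self, chain_id: str, res_seq: int) -> bool:
        return (chain_id, res_seq) in self.disordered


# ---------------------------------------------------------------------------
# PDB input / output (biotite-backed)
# ---------------------------------------------------------------------------

def _prescan_pdb(path) -> None:
    """Light validation pass so coordinate errors report a line number."""
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_atoms += 1
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    raise ParseError(
                        f"{path}: malformed coordinate record at line {lineno}")
    if n_atoms == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")


def _infer_bonds(atoms: list[Atom], coords: np.ndarray) -> set[tuple[int, int]]:
    """Pair each hydrogen with its nearest heavy atom within 1.3 A."""
    bonds: set[tuple[int, int]] = set()
    heavy = np.array([a.index for a in atoms if not a.is_hydrogen], dtype=int)
    if heavy.size == 0:
        return bonds
    for a in atoms:
        if not a.is_hydrogen:
            continue
        d = np.linalg.norm(coords[heavy] - coords[a.index], axis=1)
        k = int(np.argmin(d))
        if d[k] <= _H_BOND_MAX:
            bonds.add((int(heavy[k]), a.index))
    return bonds


def _mark_polar(atoms: list[Atom], bonds: set[tuple[int, int]]) -> None:
    polar_heavy = {a.index for a in atoms if a.element in POLAR_ELEMENTS}
    for a in atoms:
        if a.element in POLAR_ELEMENTS:
            a.is_polar = True
    for i, j in bonds:
        ai, aj = atoms[i], atoms[j]
        if ai.is_hydrogen and j in polar_heavy:
            ai.is_polar = True
        if aj.is_hydrogen and i in polar_heavy:
            aj.is_polar = True


def _topology_from_atom_array(arr) -> tuple[Topology, np.ndarray]:
    import biotite.structure as struc

    elements = arr.element
    atoms: list[Atom] = []
    res_key_to_index: dict[tuple, int] = {}
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], int(arr.res_id[i]), arr.res_name[i])
        if key not in res_key_to_index:
            res_key_to_index[key] = len(res_key_to_index)
        atoms.append(Atom(
            index=i,
            name=str(arr.atom_name[i]),
            element=str(elements[i]).upper() or "C",
            residue_index=res_key_to_index[key],
            residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]),
            res_seq=int(arr.res_id[i]),
        ))
    coords = np.asarray(arr.coord, dtype=float)
    bonds = _infer_bonds(atoms, coords)
    _mark_polar(atoms, bonds)
    return Topology(atoms=atoms, bonds=bonds), coords


def read_structure(path) -> tuple[Topology, np.ndarray]:
    """Read a single-model PDB file into a topology and A x 3 coordinates.

    Atom order, chain ids and hydrogens are preserved exactly as in the
    file.
    """
    from biotite.structure.io.pdb import PDBFile

    _prescan_pdb(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - biotite error paths
        raise ParseError(f"{path}: {exc}") from exc
    return _topology_from_atom_array(arr)


def read_trajectory(path, topology: Topology | None = None,
                    frame_spacing_ns: float = DEFAULT_FRAME_SPACING_NS) -> Trajectory:
    """Read a multi-model PDB (or XTC/DCD with a supplied topology).

    PDB models carry no time information; frame times are synthesised at
    ``frame_spacing_ns`` intervals starting at ``frame_spacing_ns``.
    """
    path = Path(path)
    if path.suffix.lower() in (".xtc", ".dcd"):
        return _read_binary_trajectory(path, topology, frame_spacing_ns)
    from biotite.structure.io.pdb import PDBFile

    _prescan_pdb(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack, all models
    top, _ = _topology_from_atom_array(stack[0])
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if topology is not None:
        if coords.shape[1] != topology.n_atoms:
            raise TopologyMismatchError(
                f"file has {coords.shape[1]} atoms, topology has "
                f"{topology.n_atoms}")
        top = topology
    times = frame_spacing_ns * np.arange(1, coords.shape[0] + 1)
    return Trajectory(top, coords, times)


def _read_binary_trajectory(path: Path, topology: Topology | None,
                            frame_spacing_ns: float) -> Trajectory:
    if topology is None:
        raise ValueError("XTC/DCD reading requires an explicit topology")
    if path.suffix.lower() == ".xtc":
        from biotite.structure.io.xtc import XTCFile as File
    else:
        from biotite.structure.io.dcd import DCDFile as File
    f = File.read(str(path))
    coords = np.asarray(f.get_coord(), dtype=float)
    if coords.shape[1] != topology.n_atoms:
        raise TopologyMismatchError(
            f"file has {coords.shape[1]} atoms, topology has {topology.n_atoms}")
    t = f.get_time()
    if t is not None and len(t) == coords.shape[0] and np.all(np.diff(t) > 0):
        times = np.asarray(t, dtype=float) / 1000.0  # ps -> ns
    else:
        times = frame_spacing_ns * np.arange(1, coords.shape[0] + 1)
    return Trajectory(topology, coords, times)


def _to_atom_array_stack(traj: Trajectory):
    import biotite.structure as struc

    top = traj.topology
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.array([a.chain_id for a in top.atoms])
    arr.res_id = np.array([a.res_seq if a.res_seq is not None else a.residue_index
                           for a in top.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in top.atoms])
    arr.atom_name = np.array([a.name for a in top.atoms])
    arr.element = np.array([a.element for a in top.atoms])
    arr.hetero = np.array([a.residue_name in WATER_RESNAMES or
                           len(a.residue_name) < 3 for a in top.atoms])
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    return stack


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(traj))
    pdb.write(str(path))


def write_structure(topology: Topology, coords: np.ndarray, path) -> None:
    """Write a single-model PDB file."""
    traj = Trajectory(topology, np.asarray(coords, dtype=float)[None],
                      np.array([DEFAULT_FRAME_SPACING_NS]))
    write_trajectory(traj, path)


# ---------------------------------------------------------------------------
# Frame sampling
# ---------------------------------------------------------------------------

def window_frames(traj: Trajectory, time_window: tuple[float, float],
                  n_samples: int) -> Trajectory:
    """Evenly sample ``n_samples`` frames from a time window.

    The first and last in-window frames are always included when
    ``n_samples >= 2``; ``n_samples = 1`` returns the first frame at or
    after the window start.  Sampling never duplicates frames.
    """
    t0, t1 = time_window
    if not t0 < t1:
        raise ValueError(f"window ({t0}, {t1}) requires t0 < t1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    in_window = np.nonzero((traj.times >= t0) & (traj.times <= t1))[0]
    if in_window.size == 0:
        raise ValueError(
            f"window ({t0}, {t1}) ns does not overlap trajectory times "
            f"[{traj.times[0]}, {traj.times[-1]}] ns")
    if n_samples > in_window.size:
        raise ValueError(
            f"requested {n_samples} samples but only {in_window.size} frames "
            "fall in the window (frame duplication is not allowed)")
    if n_samples == 1:
        picked = in_window[:1]
    else:
        rel = np.round(np.linspace(0, in_window.size - 1, n_samples)).astype(int)
        picked = in_window[rel]
    return traj.subset(picked)


def concatenate(trajs: Sequence[Trajectory]) -> Trajectory:
    """Join trajectories frame-wise, re-indexing times monotonically.

    The source replicate of every frame is retained in ``provenance`` so
    that per-replicate analyses remain possible after concatenation.
    """
    if not trajs:
        raise EmptyInputError("concatenate requires >= 1 trajectory")
    top = trajs[0].topology
    for t in trajs[1:]:
        if t.topology is not top:
            raise TopologyMismatchError("all trajectories must share one Topology")
    coords = np.concatenate([t.coords for t in trajs], axis=0)
    prov_parts, time_parts = [], []
    offset = 0.0
    for k, t in enumerate(trajs):
        rel = t.times - t.times[0]
        dt = np.median(np.diff(t.times)) if t.n_frames > 1 else DEFAULT_FRAME_SPACING_NS
        time_parts.append(offset + dt + rel)
        offset = time_parts[-1][-1]
        if t.provenance is not None:
            prov_parts.append(t.provenance)
        else:
            prov_parts.append(np.full(t.n_frames, k, dtype=int))
    return Trajectory(top, coords, np.concatenate(time_parts),
                      np.concatenate(prov_parts))


def split_by_provenance(traj: Trajectory) -> list[Trajectory]:
    """Inverse of :func:`concatenate` with respect to frame grouping."""
    if traj.provenance is None:
        return [traj]
    out = []
    for k in np.unique(traj.provenance):
        idx = np.nonzero(traj.provenance == k)[0]
        sub = traj.subset(idx)
        dt = (np.median(np.diff(sub.times)) if sub.n_frames > 1
              else DEFAULT_FRAME_SPACING_NS)
        out.append(Trajectory(traj.topology, sub.coords,
                              sub.times - sub.times[0] + dt, None))
    return out


# ---------------------------------------------------------------------------
# Domain / interface configuration
# ---------------------------------------------------------------------------

def load_domain_map(source) -> DomainMap:
    """Build a validated :class:`DomainMap` from a YAML/TOML file or dict.

    Expected layout::

        domains:
          hif2a_pasb: {chain: A, start: 240, end: 350}
        interfaces:
          "4": [hif2a_pasb, arnt_pasb]
        disordered:
          - {chain: A, start: 201, end: 239}
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if path.suffix in (".toml", ".tml"):
            import tomllib

            cfg = tomllib.loads(text)
        else:
            import yaml

            cfg = yaml.safe_load(text)
    else:
        cfg = dict(source)

    domains = {}
    for name, d in cfg.get("domains", {}).items():
        domains[name] = (str(d["chain"]), (int(d["start"]), int(d["end"])))
    interfaces = {}
    for iid, pair in cfg.get("interfaces", {}).items():
        interfaces[int(iid)] = (str(pair[0]), str(pair[1]))
    disordered: set[tuple[str, int]] = set()
    for d in cfg.get("disordered", []):
        for r in range(int(d["start"]), int(d["end"]) + 1):
            disordered.add((str(d["chain"]), r))
    return DomainMap(domains=domains, interfaces=interfaces, disordered=disordered)


def default_domain_map() -> DomainMap:
    """The shipped six-interface template for a two-chain bHLH-PAS dimer."""
    from importlib.resources import files

    return load_domain_map(files("mdcompare.data") / "domain_map.yaml")


# ---------------------------------------------------------------------------
# Per-atom force-field parameter tables
# ---------------------------------------------------------------------------

def read_parameter_table(path):
    """Read a per-atom parameter table.

    Columns (comma- or whitespace-delimited, header required):
    ``chain, residue_index, atom_name, charge_e, sigma_A, epsilon_kJmol``.
    ``residue_index`` is the author residue number.
    """
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"chain", "residue_index", "atom_name", "charge_e",
                "sigma_A", "epsilon_kJmol"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing parameter columns {sorted(missing)}")
    return df


def apply_parameters(topology: Topology, table) -> None:
    """Attach charges and LJ parameters from a parameter table in place."""
    lookup = {}
    for row in table.itertuples(index=False):
        lookup[(str(row.chain), int(row.residue_index), str(row.atom_name))] = (
            float(row.charge_e), float(row.sigma_A), float(row.epsilon_kJmol))
    for a in topology.atoms:
        key = (a.chain_id, a.res_seq if a.res_seq is not None else a.residue_index,
               a.name)
        if key in lookup:
            a.partial_charge, a.lj_sigma, a.lj_epsilon = lookup[key]


def write_parameter_table(topology: Topology, path) -> None:
    import pandas as pd

    rows = []
    for a in topology.atoms:
        if a.partial_charge is None:
            continue
        rows.append({
            "chain": a.chain_id,
            "residue_index": a.res_seq if a.res_seq is not None else a.residue_index,
            "atom_name": a.name,
            "charge_e": a.partial_charge,
            "sigma_A": a.lj_sigma,
            "epsilon_kJmol": a.lj_epsilon,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
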