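"""Geometric hydrogen-bond detection, occupancy tables and water bridges.

A hydrogen bond (D, H, A) is recorded when the donor-acceptor distance is
at most 3.5 A and the angle between the D->H bond vector and the D->A
vector is at most 30 degrees (the out-of-linearity convention), with only
polar atoms considered.  Occupancy is the percentage of analysed frames
in which a specific (D, H, A) triple satisfies the criteria; comparison
tables keep a triple when it reaches 10 % occupancy in at least one
replicate of either compared state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_io import Topology, Trajectory, WATER_RESNAMES

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondOccupancyTable",
    "WaterBridgeRecord",
    "detect_hbonds",
    "occupancy",
    "filter_occupancy",
    "water_bridges",
    "pair_distance_series",
]


@dataclass(frozen=True)
class HBondCriteria:
    d_DA_max: float = 3.5  # angstrom
    angle_max: float = 30.0  # degrees, D->H vs D->A out-of-linearity
    polar_only: bool = True

    def __post_init__(self):
        if self.d_DA_max <= 0:
            raise ValueError("d_DA_max must be > 0")
        if not 0 < self.angle_max < 90:
            raise ValueError("angle_max must be in (0, 90) degrees")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int


@dataclass
class HBondOccupancyTable:
    """Occupancy (percent of frames) per (D, H, A) key and replicate column.

    Keys are human-facing strings ``CHAIN:RES NUM ATOM -> CHAIN:RES NUM
    ATOM(H)``; ``columns`` are replicate labels such as ``h1..h5``.
    """

    columns: list[str]
    rows: dict[str, np.ndarray] = field(default_factory=dict)
    low_occupancy_mark: float = 1.0  # analog of graying out values < 1 %

    def as_frame(self):
        import pandas as pd

        df = pd.DataFrame.from_dict(self.rows, orient="index",
                                    columns=self.columns)
        df.index.name = "donor_hydrogen_acceptor"
        return df

    def flagged_low(self) -> dict[str, np.ndarray]:
        """Boolean mask of sub-1 % cells (reported but marked)."""
        return {k: v < self.low_occupancy_mark for k, v in self.rows.items()}


@dataclass(frozen=True)
class WaterBridgeRecord:
    frame: int
    ligand_atom: int
    water_residue: int
    protein_atom: int
    ligand_leg: HBond
    protein_leg: HBond


def _donor_candidates(top: Topology, selection, criteria: HBondCriteria):
    """(donor, hydrogen) pairs within the selection."""
    out = []
    for i in selection:
        a = top.atoms[int(i)]
        if a.is_hydrogen:
            continue
        if criteria.polar_only and not a.is_polar:
            continue
        hydrogens = top.bonded_hydrogens(a.index)
        if not hydrogens:
            continue
        for h in hydrogens:
            out.append((a.index, h))
    return out


def _acceptor_candidates(top: Topology, selection, criteria: HBondCriteria):
    out = []
    for i in selection:
        a = top.atoms[int(i)]
        if a.is_hydrogen:
            continue
        if criteria.polar_only and not a.is_polar:
            continue
        out.append(a.index)
    return out


def detect_hbonds(coords: np.ndarray, topology: Topology,
                  criteria: HBondCriteria = HBondCriteria(),
                  donors=None, acceptors=None,
                  exclude_intra_residue: bool = True) -> list[HBond]:
    """All (D, H, A) triples in one frame satisfying the criteria.

    ``donors`` / ``acceptors`` are atom-index selections; default all
    atoms.  Donors with no bonded hydrogen are skipped with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    all_atoms = np.arange(topology.n_atoms)
    donor_sel = all_atoms if donors is None else np.asarray(donors)
    acc_sel = all_atoms if acceptors is None else np.asarray(acceptors)

    if donors is not None:
        for i in donor_sel:
            a = topology.atoms[int(i)]
            if (not a.is_hydrogen and (a.is_polar or not criteria.polar_only)
                    and not topology.bonded_hydrogens(a.index)):
                warnings.warn(f"donor atom {a.index} ({a.name}) has no bonded "
                              "hydrogen; skipped")

    dh = _donor_candidates(topology, donor_sel, criteria)
    accs = _acceptor_candidates(topology, acc_sel, criteria)
    if not dh or not accs:
        return []
    accs_arr = np.array(accs, dtype=int)
    cos_max = np.cos(np.deg2rad(criteria.angle_max))
    out: list[HBond] = []
    for d, h in dh:
        da = coords[accs_arr] - coords[d]
        dist = np.linalg.norm(da, axis=1)
        ok = (dist <= criteria.d_DA_max) & (dist > 1e-9)
        if not ok.any():
            continue
        vh = coords[h] - coords[d]
        nh = np.linalg.norm(vh)
        if nh < 1e-9:
            continue
        cosang = (da[ok] @ vh) / (dist[ok] * nh)
        d_res = topology.atoms[d].residue_index
        for a_idx, c in zip(accs_arr[ok], cosang):
            if a_idx == d:
                continue
            if exclude_intra_residue and \
                    topology.atoms[int(a_idx)].residue_index == d_res:
                continue
            if c >= cos_max:
                out.append(HBond(donor=d, hydrogen=h, acceptor=int(a_idx)))
    return out


def triple_label(top: Topology, hb: HBond) -> str:
    def atom_label(i: int) -> str:
        a = top.atoms[i]
        num = a.res_seq if a.res_seq is not None else a.residue_index
        return f"{a.chain_id}:{a.residue_name} {num} {a.name}"

    return f"{atom_label(hb.donor)} ({top.atoms[hb.hydrogen].name}) -> " \
           f"{atom_label(hb.acceptor)}"


def occupancy(traj: Trajectory, criteria: HBondCriteria = HBondCriteria(),
              donors=None, acceptors=None, column: str = "rep1",
              exclude_intra_residue: bool = True) -> HBondOccupancyTable:
    """Occupancy of every observed (D, H, A) triple over the trajectory.

    The denominator is the trajectory's frame count; window the
    trajectory to the analysis span before calling.  Triples never
    observed are absent (implicitly 0 %).
    """
    if donors is not None and len(np.asarray(donors)) == 0:
        raise ValueError("empty donor selection")
    if acceptors is not None and len(np.asarray(acceptors)) == 0:
        raise ValueError("empty acceptor selection")
    counts: dict[str, int] = {}
    for f in range(traj.n_frames):
        seen = set()
        for hb in detect_hbonds(traj.coords[f], traj.topology, criteria,
                                donors, acceptors, exclude_intra_residue):
            key = triple_label(traj.topology, hb)
            if key not in seen:
                seen.add(key)
                counts[key] = counts.get(key, 0) + 1
    table = HBondOccupancyTable(columns=[column])
    for key, c in sorted(counts.items()):
        table.rows[key] = np.array([100.0 * c / traj.n_frames])
    return table


def merge_tables(tables: list[HBondOccupancyTable]) -> HBondOccupancyTable:
    """Align row keys across replicate/state tables (missing cells -> 0)."""
    columns: list[str] = []
    for t in tables:
        columns.extend(t.columns)
    keys = sorted(set().union(*[t.rows.keys() for t in tables])) if tables else []
    merged = HBondOccupancyTable(columns=columns)
    for key in keys:
        row = []
        for t in tables:
            row.extend(t.rows.get(key, np.zeros(len(t.columns))))
        merged.rows[key] = np.array(row)
    return merged


def filter_occupancy(tables: list[HBondOccupancyTable],
                     min_pct: float = 10.0) -> HBondOccupancyTable:
    """Keep a (D, H, A) row iff occupancy >= ``min_pct`` (inclusive) in at
    least one replicate column of the compared tables; sub-threshold cells
    are retained in kept rows (cells < 1 % can be marked via
    ``flagged_low``)."""
    merged = merge_tables(tables)
    out = HBondOccupancyTable(columns=merged.columns)
    for key, row in merged.rows.items():
        if np.any(row >= min_pct):
            out.rows[key] = row
    return out


def water_bridges(traj: Trajectory, ligand_sel, protein_sel,
                  criteria: HBondCriteria = HBondCriteria()
                  ) -> tuple[list[WaterBridgeRecord], dict]:
    """Scan frames for water-mediated ligand-protein hydrogen bonds.

    A bridge requires one water simultaneously H-bonded (either
    donor/acceptor role) to a ligand atom and to a protein atom in the
    same frame.  Returns all records plus a network summary mapping
    distinct (ligand atom, protein atom) pairs to their bridge frequency
    (fraction of frames bridged).
    """
    top = traj.topology
    water_res = {a.residue_index for a in top.atoms
                 if a.residue_name in WATER_RESNAMES}
    if not water_res:
        warnings.warn("no water residues in topology; no bridges possible")
        return [], {}
    water_sel = np.array([a.index for a in top.atoms
                          if a.residue_index in water_res], dtype=int)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    protein_sel = np.asarray(protein_sel, dtype=int)

    records: list[WaterBridgeRecord] = []
    pair_frames: dict[tuple[int, int], set[int]] = {}
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        lw = detect_hbonds(coords, top, criteria,
                           donors=np.concatenate([ligand_sel, water_sel]),
                           acceptors=np.concatenate([ligand_sel, water_sel]))
        pw = detect_hbonds(coords, top, criteria,
                           donors=np.concatenate([protein_sel, water_sel]),
                           acceptors=np.concatenate([protein_sel, water_sel]))
        lig_set, prot_set = set(ligand_sel.tolist()), set(protein_sel.tolist())

        def water_of(hb: HBond) -> int | None:
            for idx in (hb.donor, hb.acceptor):
                if top.atoms[idx].residue_index in water_res:
                    return top.atoms[idx].residue_index
            return None

        lig_legs: dict[int, list[tuple[int, HBond]]] = {}
        for hb in lw:
            w = water_of(hb)
            other = hb.acceptor if top.atoms[hb.donor].residue_index in water_res \
                else hb.donor
            if w is not None and other in lig_set:
                lig_legs.setdefault(w, []).append((other, hb))
        for hb in pw:
            w = water_of(hb)
            other = hb.acceptor if top.atoms[hb.donor].residue_index in water_res \
                else hb.donor
            if w is not None and other in prot_set and w in lig_legs:
                for lig_atom, lig_hb in lig_legs[w]:
                    records.append(WaterBridgeRecord(
                        frame=f, ligand_atom=lig_atom, water_residue=w,
                        protein_atom=other, ligand_leg=lig_hb, protein_leg=hb))
                    pair_frames.setdefault((lig_atom, other), set()).add(f)
    summary = {
        "n_frames": traj.n_frames,
        "pairs": {
            f"{triple_label_atom(top, la)} | {triple_label_atom(top, pa)}":
                len(frames) / traj.n_frames
            for (la, pa), frames in sorted(pair_frames.items())
        },
    }
    return records, summary


def triple_label_atom(top: Topology, i: int) -> str:
    a = top.atoms[i]
    num = a.res_seq if a.res_seq is not None else a.residue_index
    return f"{a.chain_id}:{a.residue_name} {num} {a.name}"


def pair_distance_series(traj: Trajectory, atom_pairs) -> np.ndarray:
    """Per-frame Euclidean distances for each (i, j) atom pair.

    Returns shape (F, P).  Per-replicate means of these series feed the
    exact Mann-Whitney comparison of donor-acceptor distances between
    states.
    """
    pairs = np.asarray(atom_pairs, dtype=int)
    if pairs.ndim == 1:
        pairs = pairs[None, :]
    n = traj.topology.n_atoms
    if np.any(pairs < 0) or np.any(pairs >= n):
        raise ValueError("atom pair index out of range")
    diff = traj.coords[:, pairs[:, 0], :] - traj.coords[:, pairs[:, 1], :]
    return np.linalg.norm(diff, axis=2)
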