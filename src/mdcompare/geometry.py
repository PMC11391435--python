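"""Superposition, flexibility profiling, SASA and secondary structure.

Flexibility is profiled as the C-alpha root-mean-square fluctuation
(RMSF) about a fixed reference structure after least-squares backbone
superposition; state comparisons flag residues whose |delta RMSF|
reaches 1 A in ordered regions or 3 A in disordered regions (inclusive
thresholds).  Solvent-accessible surface area uses the Shrake-Rupley
sphere-point algorithm.  Secondary structure uses a simplified
Kabsch-Sander assignment over four codes {H, E, T, C}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_io import Topology, Trajectory

ORDERED_DELTA_RMSF_A = 1.0
DISORDERED_DELTA_RMSF_A = 3.0
DEFAULT_PROBE_A = 1.4
DEFAULT_SPHERE_POINTS = 960
# van der Waals radii (angstrom) by element; overridable per call
DEFAULT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}

KS_COUPLING = 27.888  # kcal/mol * angstrom, Kabsch-Sander electrostatic factor
KS_CUTOFF = -0.5  # kcal/mol


class DegenerateSelectionError(ValueError):
    """Superposition selection is collinear or coincident."""


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, angstrom
    rmsd: float  # angstrom, over the fitted selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (and, for paired profiles, delta RMSF + flags)."""

    residue_indices: np.ndarray  # internal residue indices
    labels: list[str]  # author-numbered labels
    rmsf: np.ndarray  # angstrom
    reference_id: str = ""
    delta_rmsf: np.ndarray | None = None
    flags: np.ndarray | None = None

    def as_frame(self):
        import pandas as pd

        data = {"residue": self.labels, "rmsf_A": self.rmsf}
        if self.delta_rmsf is not None:
            data["delta_rmsf_A"] = self.delta_rmsf
            data["flagged"] = self.flags
        return pd.DataFrame(data)


@dataclass
class SecondaryStructureProfile:
    residue_indices: np.ndarray
    labels: list[str]
    fractions: np.ndarray  # (R, 4) percent per code, order H E T C
    codes: tuple[str, ...] = ("H", "E", "T", "C")

    def as_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.fractions, columns=[f"pct_{c}" for c in self.codes])
        df.insert(0, "residue", self.labels)
        return df


@dataclass
class SasaResult:
    atom_sasa: np.ndarray  # angstrom^2 per atom
    residue_sasa: dict[int, float]  # residue_index -> angstrom^2

    @property
    def total_A2(self) -> float:
        return float(self.atom_sasa.sum())

    @property
    def total_nm2(self) -> float:
        return self.total_A2 / 100.0


# ---------------------------------------------------------------------------
# Superposition and RMSD / RMSF
# ---------------------------------------------------------------------------

def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               selection=None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det +1) and translation minimising the
    RMSD over ``selection`` (all atoms when None), and that minimal RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise DegenerateSelectionError("superposition requires >= 3 atoms")
    m, r = mobile[sel], reference[sel]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    p, q = m - mc, r - rc
    # collinearity check: rank of centred coordinates
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise DegenerateSelectionError("selection is collinear or coincident")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                fit_selection=None, measure_selection=None) -> np.ndarray:
    """Per-frame RMSD after superposing each frame on ``fit_selection``.

    ``measure_selection`` may differ from the fit selection — e.g. ligand
    RMSD measured after a protein-backbone fit.
    """
    fit_sel = (np.arange(traj.topology.n_atoms) if fit_selection is None
               else np.asarray(fit_selection))
    meas_sel = fit_sel if measure_selection is None else np.asarray(measure_selection)
    if fit_sel.size == 0 or meas_sel.size == 0:
        raise ValueError("fit and measure selections must be non-empty")
    ref = np.asarray(reference, dtype=float)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sup = kabsch_fit(traj.coords[f], ref, fit_sel)
        moved = sup.apply(traj.coords[f][meas_sel])
        out[f] = np.sqrt(np.mean(np.sum((moved - ref[meas_sel]) ** 2, axis=1)))
    return out


def superpose_frames(traj: Trajectory, reference: np.ndarray,
                     fit_selection=None) -> np.ndarray:
    """All frames rigidly fitted to the reference; returns (F, A, 3)."""
    fit_sel = (np.arange(traj.topology.n_atoms) if fit_selection is None
               else np.asarray(fit_selection))
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        sup = kabsch_fit(traj.coords[f], reference, fit_sel)
        out[f] = sup.apply(traj.coords[f])
    return out


def rmsf_profile(traj: Trajectory, reference: np.ndarray,
                 fit_selection=None, reference_id: str = "",
                 mode: str = "reference", prefit: bool = True) -> FlexibilityProfile:
    """Per-residue C-alpha RMSF.

    The deviation is measured from the *fixed reference* position of each
    C-alpha (default), not from the trajectory mean; ``mode="mean"``
    switches to the mean-structure convention for comparison.  Frames are
    first least-squares fitted to the reference over ``fit_selection``
    (backbone atoms when None) unless ``prefit=False``.
    """
    top = traj.topology
    ref = np.asarray(reference, dtype=float)
    if fit_selection is None:
        fit_selection = top.atom_indices(name="CA")
    coords = superpose_frames(traj, ref, fit_selection) if prefit else traj.coords

    res_idx, labels, values = [], [], []
    for rid, rname, chain in top.residues:
        ca = top.atom_indices(residue_index=rid, name="CA")
        if ca.size == 0:
            if rname not in ("HOH", "SOL", "WAT", "TIP3"):
                warnings.warn(f"residue {rid} ({rname}) has no CA; omitted")
            continue
        a = int(ca[0])
        center = ref[a] if mode == "reference" else coords[:, a, :].mean(axis=0)
        dev2 = np.sum((coords[:, a, :] - center) ** 2, axis=1)
        res_idx.append(rid)
        labels.append(top.residue_label(rid))
        values.append(np.sqrt(dev2.mean()))
    return FlexibilityProfile(residue_indices=np.array(res_idx, dtype=int),
                              labels=labels, rmsf=np.array(values),
                              reference_id=reference_id)


def flag_flexible_regions(profile_a: FlexibilityProfile,
                          profile_b: FlexibilityProfile,
                          disordered_mask=None,
                          ordered_threshold: float = ORDERED_DELTA_RMSF_A,
                          disordered_threshold: float = DISORDERED_DELTA_RMSF_A,
                          ) -> tuple[FlexibilityProfile, list[tuple[int, int, float]]]:
    """Difference two RMSF profiles and flag threshold-exceeding residues.

    A residue is flagged iff |RMSF_b - RMSF_a| >= 1 A (ordered) or
    >= 3 A (disordered); both thresholds are inclusive.  Returns the
    differenced profile and the maximal contiguous flagged runs as
    (start_position, end_position, max |delta|) tuples over profile
    positions.
    """
    if (profile_a.residue_indices.shape != profile_b.residue_indices.shape or
            np.any(profile_a.residue_indices != profile_b.residue_indices)):
        raise ValueError("profiles cover different residue sets")
    delta = profile_b.rmsf - profile_a.rmsf
    n = delta.size
    if disordered_mask is None:
        disordered_mask = np.zeros(n, dtype=bool)
    disordered_mask = np.asarray(disordered_mask, dtype=bool)
    thr = np.where(disordered_mask, disordered_threshold, ordered_threshold)
    flags = np.abs(delta) >= thr

    regions: list[tuple[int, int, float]] = []
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            regions.append((i, j, float(np.abs(delta[i:j + 1]).max())))
            i = j + 1
        else:
            i += 1
    out = FlexibilityProfile(residue_indices=profile_a.residue_indices.copy(),
                             labels=list(profile_a.labels), rmsf=profile_b.rmsf.copy(),
                             reference_id=profile_a.reference_id,
                             delta_rmsf=delta, flags=flags)
    return out, regions


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points by the golden-spiral construction."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def shrake_rupley_sasa(coords: np.ndarray, topology: Topology | None = None,
                       radii=None, probe: float = DEFAULT_PROBE_A,
                       n_points: int = DEFAULT_SPHERE_POINTS,
                       atom_subset=None) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    ``radii`` may be an explicit per-atom array; otherwise element-based
    defaults are looked up from the topology.  Each atom's SASA is the
    fraction of ``n_points`` sphere points on its probe-expanded sphere
    not buried inside any neighbour's expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if radii is None:
        if topology is None:
            raise ValueError("need either explicit radii or a topology")
        radii = np.empty(n)
        for a in topology.atoms:
            try:
                radii[a.index] = DEFAULT_RADII[a.element]
            except KeyError:
                raise ValueError(
                    f"no default radius for element {a.element!r} "
                    f"(atom {a.index}); pass explicit radii") from None
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe
    pts = _sphere_points(n_points)
    subset = np.arange(n) if atom_subset is None else np.asarray(atom_subset)

    atom_sasa = np.zeros(n)
    sub_set = set(int(i) for i in subset)
    sub_sorted = sorted(sub_set)
    for i in subset:
        i = int(i)
        sphere = coords[i] + expanded[i] * pts
        d = np.linalg.norm(coords[sub_sorted] - coords[i], axis=1)
        neighbours = [j for j, dj in zip(sub_sorted, d)
                      if j != i and dj < expanded[i] + expanded[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            dj = np.linalg.norm(coords[j] - coords[i])
            if dj < 1e-9 and abs(expanded[j] - expanded[i]) < 1e-9:
                # exactly coincident duplicates: surface kept by lower index
                if j < i:
                    accessible[:] = False
                    break
                continue
            dist2 = np.sum((sphere - coords[j]) ** 2, axis=1)
            accessible &= dist2 > expanded[j] ** 2
            if not accessible.any():
                break
        atom_sasa[i] = (4.0 * np.pi * expanded[i] ** 2 *
                        accessible.sum() / n_points)

    residue_sasa: dict[int, float] = {}
    if topology is not None:
        for a in topology.atoms:
            if a.index in sub_set:
                residue_sasa[a.residue_index] = (
                    residue_sasa.get(a.residue_index, 0.0) + atom_sasa[a.index])
    return SasaResult(atom_sasa=atom_sasa, residue_sasa=residue_sasa)


# ---------------------------------------------------------------------------
# Simplified Kabsch-Sander secondary structure
# ---------------------------------------------------------------------------

def _backbone_table(topology: Topology):
    """Residue -> indices of N, CA, C, O (and H if present), chain-ordered."""
    table = []
    for rid, rname, chain in topology.residues:
        if rname in ("HOH", "SOL", "WAT", "TIP3"):
            continue
        entry = {"rid": rid, "chain": chain}
        for name in ("N", "CA", "C", "O", "H"):
            idx = topology.atom_indices(residue_index=rid, name=name)
            entry[name] = int(idx[0]) if idx.size else None
        table.append(entry)
    return table


def _place_amide_h(coords, n_i, ca_i, c_prev) -> np.ndarray:
    """Reconstruct the amide hydrogen on N along the bisector convention."""
    n = coords[n_i]
    v1 = n - coords[ca_i]
    v2 = n - coords[c_prev]
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    d = v1 + v2
    nd = np.linalg.norm(d)
    if nd < 1e-8:
        d = v1
        nd = 1.0
    return n + 1.01 * d / nd


def _ks_hbond_matrix(coords: np.ndarray, table) -> np.ndarray:
    """hb[i, j] True when donor NH(i) -> acceptor C=O(j) with E < -0.5."""
    n = len(table)
    hb = np.zeros((n, n), dtype=bool)
    h_pos: list[np.ndarray | None] = []
    for k, e in enumerate(table):
        if e["N"] is None:
            h_pos.append(None)
            continue
        if e["H"] is not None:
            h_pos.append(coords[e["H"]])
        else:
            prev = table[k - 1] if k > 0 else None
            if (prev is not None and prev["chain"] == e["chain"]
                    and prev["C"] is not None and e["CA"] is not None):
                h_pos.append(_place_amide_h(coords, e["N"], e["CA"], prev["C"]))
            else:
                h_pos.append(None)  # chain N-terminus: no amide H
    for i, ei in enumerate(table):  # donor
        if ei["N"] is None or h_pos[i] is None:
            continue
        npos, hpos = coords[ei["N"]], h_pos[i]
        for j, ej in enumerate(table):  # acceptor
            if i == j or abs(i - j) < 2:
                continue
            if ej["C"] is None or ej["O"] is None:
                continue
            cpos, opos = coords[ej["C"]], coords[ej["O"]]
            r_on = np.linalg.norm(opos - npos)
            if r_on > 5.2:  # beyond any plausible H-bond
                continue
            r_ch = np.linalg.norm(cpos - hpos)
            r_oh = np.linalg.norm(opos - hpos)
            r_cn = np.linalg.norm(cpos - npos)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e_kcal = KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e_kcal < KS_CUTOFF:
                hb[i, j] = True
    return hb


def assign_ss(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """Per-residue secondary-structure code in {H, E, T, C} for one frame.

    Simplified Kabsch-Sander scheme: backbone NH->CO hydrogen bonds from
    the electrostatic energy model (bond iff E < -0.5 kcal/mol); two
    consecutive i+4 turns make a helix (codes G/I collapse to H), paired
    bridges make strands, isolated 3/4/5-turns make T, everything else C.
    Residues missing backbone atoms are assigned C.
    """
    table = _backbone_table(topology)
    n = len(table)
    hb = _ks_hbond_matrix(np.asarray(coords, dtype=float), table)
    codes = np.array(["C"] * n, dtype="<U1")

    # n-turns: donor i+k -> acceptor i
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if (table[i]["chain"] == table[i + k]["chain"]) and hb[i + k, i]:
                turn[k][i] = True

    # helix: two consecutive 4-turns at i-1 and i -> residues i..i+3 helical
    helix = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turn[4][i - 1] and turn[4][i]:
            helix[i:i + 4] = True

    # bridges (strands): antiparallel (hb[i,j] & hb[j,i]) or
    # parallel (hb[i-1,j] & hb[j,i+1]) or (hb[j-1,i] & hb[i,j+1])
    strand = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 3:
                continue
            anti = (hb[i, j] and hb[j, i]) or (
                0 <= i - 1 and i + 1 < n and hb[i + 1, j] and hb[j, i - 1])
            para = (0 <= i - 1 and i + 1 < n and hb[i - 1, j] and hb[j, i + 1])
            if anti or para:
                strand[i] = strand[j] = True

    codes[strand & ~helix] = "E"
    codes[helix] = "H"

    # isolated turns
    turn_any = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn[k][i]:
                turn_any[i + 1:i + k] = True
    codes[(codes == "C") & turn_any] = "T"
    return codes


def ss_fractions(traj: Trajectory) -> SecondaryStructureProfile:
    """Percent of frames assigned to each code {H, E, T, C} per residue."""
    top = traj.topology
    table = _backbone_table(top)
    rids = [e["rid"] for e in table]
    counts = np.zeros((len(rids), 4))
    order = {"H": 0, "E": 1, "T": 2, "C": 3}
    for f in range(traj.n_frames):
        codes = assign_ss(traj.coords[f], top)
        for r, c in enumerate(codes):
            counts[r, order[c]] += 1
    fractions = 100.0 * counts / traj.n_frames
    return SecondaryStructureProfile(
        residue_indices=np.array(rids, dtype=int),
        labels=[top.residue_label(r) for r in rids],
        fractions=fractions)
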