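"""MM/PBSA-style binding-energy layer.

The interaction energy between two atom groups is the explicit pairwise
Coulomb + Lennard-Jones sum (no cutoff, configurable relative
dielectric).  Nonpolar solvation uses the linear SASA model
``g = gamma * SASA + b`` per species; the polar (Poisson-Boltzmann)
solvation term is never solved internally — it is ingested from external
per-residue or per-frame tables, or set to zero with a logged caveat.
The single-trajectory convention applies throughout: complex and unbound
partner conformations are taken from the same frame, so internal terms
cancel and only cross-group interactions contribute to the MM part.

Replicate/state summaries follow the tabulation convention of replicate
means with a sample (n-1) standard deviation, and state deltas formed by
differencing means rounded to one decimal (reproducing printed tables)
alongside the raw difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import shrake_rupley_sasa
from .model_io import Topology, Trajectory
from .stats import ReplicateSummary, replicate_summary, state_delta

logger = logging.getLogger(__name__)

COULOMB_CONSTANT_A = 1389.35458  # kJ/mol * angstrom / e^2
GAMMA_KJ_PER_A2 = 0.0226778  # nonpolar surface-tension coefficient
NONPOLAR_OFFSET_KJ = 3.84928  # per-species constant b


class MissingParameterError(ValueError):
    pass


class SingularityError(ValueError):
    pass


@dataclass
class EnergyComponents:
    """kJ/mol components; ``g_total = e_mm + g_polar + g_nonpolar``."""

    coulomb: float = 0.0
    lj: float = 0.0
    g_polar: float = 0.0
    g_nonpolar: float = 0.0

    @property
    def e_mm(self) -> float:
        return self.coulomb + self.lj

    @property
    def g_total(self) -> float:
        return self.e_mm + self.g_polar + self.g_nonpolar

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(self.coulomb + other.coulomb,
                                self.lj + other.lj,
                                self.g_polar + other.g_polar,
                                self.g_nonpolar + other.g_nonpolar)


@dataclass
class DecompositionTable:
    """Per-residue mean energy components for one replicate/state."""

    state_label: str
    components: dict[str, EnergyComponents] = field(default_factory=dict)
    system_constant_kj: float = 0.0  # whole-complex nonpolar offset (-b terms)

    def total(self) -> EnergyComponents:
        out = EnergyComponents()
        for c in self.components.values():
            out = out + c
        return out

    def as_frame(self):
        import pandas as pd

        rows = []
        for label, c in self.components.items():
            rows.append({"residue": label, "e_mm": c.e_mm, "g_polar": c.g_polar,
                         "g_nonpolar": c.g_nonpolar, "g_total": c.g_total})
        return pd.DataFrame(rows)


@dataclass
class BfeSummary:
    """Replicate-level binding-free-energy summary for a pair of states."""

    state_a: str
    state_b: str
    summary_a: ReplicateSummary
    summary_b: ReplicateSummary
    delta_rounded: float  # difference of one-decimal rounded means (b - a)
    delta_raw: float
    per_residue_delta: dict[str, float] = field(default_factory=dict)

    def top_residues(self, k: int = 10, destabilizing: bool = True):
        items = sorted(self.per_residue_delta.items(), key=lambda kv: kv[1],
                       reverse=destabilizing)
        return items[:k]


def _params(topology: Topology, indices: np.ndarray):
    q = np.empty(indices.size)
    sig = np.empty(indices.size)
    eps = np.empty(indices.size)
    for k, i in enumerate(indices):
        a = topology.atoms[int(i)]
        if a.partial_charge is None or a.lj_sigma is None or a.lj_epsilon is None:
            raise MissingParameterError(
                f"atom {a.index} ({a.chain_id}:{a.residue_name} "
                f"{a.res_seq} {a.name}) lacks charge/LJ parameters")
        q[k], sig[k], eps[k] = a.partial_charge, a.lj_sigma, a.lj_epsilon
    return q, sig, eps


def coulomb_lj_energy(coords: np.ndarray, topology: Topology,
                      group_a, group_b, eps_r: float = 1.0,
                      cutoff: float | None = None) -> tuple[float, float]:
    """Pairwise Coulomb and Lennard-Jones cross-group energies (kJ/mol).

    Coulomb: sum f q_i q_j / (eps_r r_ij) with f = 1389.35458 on the
    angstrom scale.  LJ: sum 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6] with
    Lorentz-Berthelot combining.  No cutoff unless given.
    """
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if np.intersect1d(ga, gb).size:
        raise ValueError("group_a and group_b must be disjoint")
    qa, sa, ea = _params(topology, ga)
    qb, sb, eb = _params(topology, gb)
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[ga][:, None, :] - coords[gb][None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise SingularityError("overlapping atoms (r < 1e-6 A) between groups")
    mask = np.ones_like(d, dtype=bool) if cutoff is None else d <= cutoff
    coul = COULOMB_CONSTANT_A / eps_r * (qa[:, None] * qb[None, :]) / d
    sig = 0.5 * (sa[:, None] + sb[None, :])
    eps = np.sqrt(ea[:, None] * eb[None, :])
    sr6 = (sig / d) ** 6
    lj = 4.0 * eps * (sr6**2 - sr6)
    return float(coul[mask].sum()), float(lj[mask].sum())


def nonpolar_term(coords: np.ndarray, topology: Topology, complex_sel,
                  part_a, part_b, gamma: float = GAMMA_KJ_PER_A2,
                  b: float = NONPOLAR_OFFSET_KJ, probe: float = 1.4,
                  n_points: int = 240, convention: str = "per_species",
                  radii=None) -> float:
    """SASA-based nonpolar solvation change on binding (kJ/mol).

    ``per_species`` applies g = gamma*SASA + b to complex, A and B
    separately (delta = gamma*dSASA - b); ``difference`` applies the
    linear model to the buried-area difference only (delta =
    gamma*dSASA).
    """
    kw = dict(topology=topology, probe=probe, n_points=n_points, radii=radii)
    s_complex = shrake_rupley_sasa(coords, atom_subset=complex_sel, **kw).atom_sasa
    s_a = shrake_rupley_sasa(coords, atom_subset=part_a, **kw).atom_sasa
    s_b = shrake_rupley_sasa(coords, atom_subset=part_b, **kw).atom_sasa
    d_area = float(s_complex.sum() - s_a.sum() - s_b.sum())
    if convention == "per_species":
        return gamma * d_area - b  # (gS_c + b) - (gS_a + b) - (gS_b + b)
    if convention == "difference":
        return gamma * d_area
    raise ValueError(f"unknown nonpolar convention {convention!r}")


def binding_energy(sample: Trajectory, group_a, group_b,
                   polar_source=None, eps_r: float = 1.0,
                   gamma: float = GAMMA_KJ_PER_A2, b: float = NONPOLAR_OFFSET_KJ,
                   nonpolar_convention: str = "per_species",
                   n_points: int = 240, radii=None,
                   ) -> tuple[list[EnergyComponents], ReplicateSummary]:
    """Per-frame binding energy components and their replicate summary.

    ``polar_source`` supplies the polar solvation term: None (zero, with
    a logged caveat), a scalar per-frame constant, an (F,) array, or a
    :class:`DecompositionTable` whose residue ``g_polar`` values are
    summed.  Complex/partner conformations come from the same frame
    (single-trajectory convention).
    """
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    complex_sel = np.concatenate([ga, gb])
    polar = _polar_per_frame(polar_source, sample.n_frames)
    out: list[EnergyComponents] = []
    for f in range(sample.n_frames):
        coul, lj = coulomb_lj_energy(sample.coords[f], sample.topology, ga, gb,
                                     eps_r=eps_r)
        gnp = nonpolar_term(sample.coords[f], sample.topology, complex_sel,
                            ga, gb, gamma=gamma, b=b, n_points=n_points,
                            convention=nonpolar_convention, radii=radii)
        out.append(EnergyComponents(coulomb=coul, lj=lj, g_polar=polar[f],
                                    g_nonpolar=gnp))
    totals = [c.g_total for c in out]
    return out, replicate_summary(totals)


def _polar_per_frame(polar_source, n_frames: int) -> np.ndarray:
    if polar_source is None:
        logger.warning("polar solvation source is None: dG_polar set to 0 "
                       "for all frames (MM + nonpolar only)")
        return np.zeros(n_frames)
    if isinstance(polar_source, DecompositionTable):
        total = sum(c.g_polar for c in polar_source.components.values())
        return np.full(n_frames, total)
    arr = np.asarray(polar_source, dtype=float)
    if arr.ndim == 0:
        return np.full(n_frames, float(arr))
    if arr.shape != (n_frames,):
        raise ValueError(
            f"polar table has {arr.shape[0]} frames, sample has {n_frames}")
    return arr


def per_residue_decomposition(sample: Trajectory, group_a, group_b,
                              polar_source: "DecompositionTable | None" = None,
                              eps_r: float = 1.0,
                              gamma: float = GAMMA_KJ_PER_A2,
                              n_points: int = 240, radii=None,
                              state_label: str = "") -> DecompositionTable:
    """Per-residue mean energy decomposition over the sample frames.

    Each cross-group pairwise MM term is split half-and-half between the
    two residues involved, so residue contributions sum exactly to the
    total cross-group MM energy.  The nonpolar share of a residue is
    gamma times its buried-area change; the per-species constant is kept
    as a whole-system term in ``system_constant_kj``.  Polar shares come
    from an ingested table when given.
    """
    top = sample.topology
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if np.intersect1d(ga, gb).size:
        raise ValueError("group_a and group_b must be disjoint")
    qa, sa, ea = _params(top, ga)
    qb, sb, eb = _params(top, gb)
    res_a = np.array([top.atoms[int(i)].residue_index for i in ga])
    res_b = np.array([top.atoms[int(i)].residue_index for i in gb])
    residues = sorted(set(res_a) | set(res_b))
    complex_sel = np.concatenate([ga, gb])
    atom_res = np.empty(top.n_atoms, dtype=int)
    for a in top.atoms:
        atom_res[a.index] = a.residue_index

    acc_coul = {r: 0.0 for r in residues}
    acc_lj = {r: 0.0 for r in residues}
    acc_np = {r: 0.0 for r in residues}
    for f in range(sample.n_frames):
        coords = sample.coords[f]
        d = np.linalg.norm(coords[ga][:, None, :] - coords[gb][None, :, :], axis=2)
        if np.any(d < 1e-6):
            raise SingularityError("overlapping atoms between groups")
        coul = COULOMB_CONSTANT_A / eps_r * (qa[:, None] * qb[None, :]) / d
        sig = 0.5 * (sa[:, None] + sb[None, :])
        eps = np.sqrt(ea[:, None] * eb[None, :])
        sr6 = (sig / d) ** 6
        lj = 4.0 * eps * (sr6**2 - sr6)
        for r in residues:
            row = res_a == r
            col = res_b == r
            acc_coul[r] += 0.5 * (coul[row, :].sum() + coul[:, col].sum())
            acc_lj[r] += 0.5 * (lj[row, :].sum() + lj[:, col].sum())
        kw = dict(topology=top, n_points=n_points, radii=radii)
        s_c = shrake_rupley_sasa(coords, atom_subset=complex_sel, **kw).atom_sasa
        s_a = shrake_rupley_sasa(coords, atom_subset=ga, **kw).atom_sasa
        s_b = shrake_rupley_sasa(coords, atom_subset=gb, **kw).atom_sasa
        d_atom = s_c - s_a - s_b  # negative where area is buried
        for r in residues:
            acc_np[r] += gamma * float(d_atom[atom_res == r].sum())

    table = DecompositionTable(state_label=state_label)
    nf = sample.n_frames
    for r in residues:
        label = top.residue_label(r)
        polar = 0.0
        if polar_source is not None and label in polar_source.components:
            polar = polar_source.components[label].g_polar
        table.components[label] = EnergyComponents(
            coulomb=acc_coul[r] / nf, lj=acc_lj[r] / nf,
            g_polar=polar, g_nonpolar=acc_np[r] / nf)
    return table


# ---------------------------------------------------------------------------
# External decomposition tables
# ---------------------------------------------------------------------------

def read_decomposition(path, state_label: str = "",
                       tolerance: float = 0.05) -> DecompositionTable:
    """Read a per-residue decomposition table.

    Two dialects are accepted:

    * CSV with header ``residue_label, e_mm, g_polar, g_nonpolar,
      g_total`` (one row per residue);
    * the g_mmpbsa contribution-file dialect: a header line of residue
      labels, then whitespace-separated per-frame rows whose columns are
      averaged into a single (g_total-only) value per residue.

    Rows whose ``g_total`` deviates from the component sum by more than
    ``tolerance`` trigger a validation warning.
    """
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
    table = DecompositionTable(state_label=state_label)
    if "," in first and "residue_label" in first:
        df = pd.read_csv(path)
        for row in df.itertuples(index=False):
            comp = EnergyComponents(coulomb=float(row.e_mm), lj=0.0,
                                    g_polar=float(row.g_polar),
                                    g_nonpolar=float(row.g_nonpolar))
            if abs(comp.g_total - float(row.g_total)) > tolerance:
                warnings.warn(
                    f"{path}: residue {row.residue_label} g_total "
                    f"{row.g_total} != component sum {comp.g_total:.4f}")
            table.components[str(row.residue_label)] = comp
    else:
        labels = first.split()
        data = np.loadtxt(path, skiprows=1, ndmin=2)
        if data.shape[1] == len(labels) + 1:  # leading frame/time column
            data = data[:, 1:]
        if data.shape[1] != len(labels):
            raise ValueError(f"{path}: {len(labels)} labels but "
                             f"{data.shape[1]} value columns")
        means = data.mean(axis=0)
        for label, v in zip(labels, means):
            table.components[label] = EnergyComponents(coulomb=float(v))
    return table


def write_decomposition(table: DecompositionTable, path) -> None:
    import pandas as pd

    df = table.as_frame()
    df.insert(0, "residue_label", df.pop("residue"))
    df.to_csv(path, index=False)


def summarize_bfe(values_by_state: dict[str, "np.ndarray | list"],
                  pairings: list[tuple[str, str]],
                  per_residue: dict[str, dict[str, float]] | None = None,
                  ) -> list[BfeSummary]:
    """Replicate/state summaries and deltas for configured state pairs.

    ``values_by_state`` maps state label to its replicate values;
    ``pairings`` lists (reference, modified) comparisons; ``per_residue``
    optionally maps state label to residue -> mean residue BFE so that
    per-residue deltas (modified - reference) are attached.
    """
    summaries = {s: replicate_summary(v) for s, v in values_by_state.items()}
    ns = {s: len(np.asarray(v)) for s, v in values_by_state.items()}
    if len(set(ns.values())) > 1:
        logger.warning("mismatched replicate counts across states: %s", ns)
    out = []
    for ref, mod in pairings:
        pr: dict[str, float] = {}
        if per_residue is not None and ref in per_residue and mod in per_residue:
            keys = set(per_residue[ref]) | set(per_residue[mod])
            for k in sorted(keys):
                pr[k] = per_residue[mod].get(k, 0.0) - per_residue[ref].get(k, 0.0)
        out.append(BfeSummary(
            state_a=ref, state_b=mod,
            summary_a=summaries[ref], summary_b=summaries[mod],
            delta_rounded=state_delta(summaries[ref], summaries[mod], "rounded"),
            delta_raw=state_delta(summaries[ref], summaries[mod], "raw"),
            per_residue_delta=pr))
    return out
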