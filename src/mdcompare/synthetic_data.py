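"""Synthetic two-chain complexes and replicate ensembles with ground truth.

The generator builds a toy complex of two ideal alpha-helical backbone
chains (N, CA, C, O, H per residue) facing each other across an
interface, then emits state-labelled replicate ensembles in which the
planted quantities every downstream stage estimates are known exactly:

* per-residue positional fluctuation amplitudes (per-axis Gaussian sd,
  applied as rigid per-residue displacements so local geometry survives),
* interfacial contact pairs whose CA-CA distance is drawn from a
  state-specific normal distribution (state-separable contacts),
* hydrogen-bond donor/acceptor pairs placed inside the geometric
  criteria in a Bernoulli(q) fraction of frames and well outside
  otherwise (controlled occupancy),
* per-atom charges and Lennard-Jones parameters so interaction energies
  are computable and their reference-geometry values known.

Replicates of a state differ only by RNG stream; the same seed gives
bit-identical ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Atom, StateEnsemble, Topology, Trajectory

# internal coordinates of an ideal alpha helix (angstrom / degrees)
_BOND_N_CA, _BOND_CA_C, _BOND_C_N = 1.458, 1.525, 1.329
_BOND_C_O, _BOND_N_H = 1.231, 1.010
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_ANG_CA_C_O = 120.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0

# simple backbone charge scheme (elementary charges) and per-element LJ
_CHARGES = {"N": -0.4157, "H": 0.2719, "CA": 0.0337, "C": 0.5973, "O": -0.5679}
_LJ = {"N": (3.25, 0.711), "C": (3.40, 0.359), "O": (2.96, 0.880),
       "H": (1.07, 0.066)}


class SpecError(ValueError):
    """Contradictory synthetic-spec constraints."""


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic two-state study.

    ``planted_contacts`` entries are (residue_a, residue_b, mean distance
    in state A, mean distance in state B, jitter sd), residues given as
    internal indices (chain A residues come first).  The controlled
    distance is CA-CA.  ``planted_fluctuations`` maps residue index to
    (sd state A, sd state B) per-axis angstroms, overriding
    ``base_sigma``.  ``planted_hbonds`` entries are (donor residue,
    acceptor residue, occupancy fraction): the donor's backbone N-H
    points at the acceptor's O inside criteria in that fraction of
    frames.
    """

    residues_per_chain: int = 16
    replicates_per_state: int = 5
    frames_per_replicate: int = 200
    frame_spacing_ns: float = 0.1
    interface_separation: float = 9.0  # angstrom between helix axes
    base_sigma: tuple[float, float] = (0.15, 0.15)  # per-axis sd per state
    planted_contacts: list[tuple[int, int, float, float, float]] = field(
        default_factory=list)
    planted_fluctuations: dict[int, tuple[float, float]] = field(
        default_factory=dict)
    planted_hbonds: list[tuple[int, int, float]] = field(default_factory=list)
    charge_scheme: str = "backbone"  # "backbone" | "zero"
    n_waters: int = 0
    state_labels: tuple[str, str] = ("stateA", "stateB")
    seed: int = 0

    def __post_init__(self):
        if self.residues_per_chain < 4:
            raise SpecError("residues_per_chain must be >= 4")
        if self.replicates_per_state < 2:
            raise SpecError("replicates_per_state must be >= 2")
        moved: set[int] = set()
        for ra, rb, da, db, _ in self.planted_contacts:
            if da <= 0 or db <= 0:
                raise SpecError("planted contact distances must be > 0")
            if rb in moved:
                raise SpecError(
                    f"residue {rb} is moved by more than one planted contact")
            moved.add(rb)
        for rd, racc, q in self.planted_hbonds:
            if not 0 <= q <= 1:
                raise SpecError("planted occupancy must be in [0, 1]")
            if racc in moved:
                raise SpecError(
                    f"residue {racc} is moved by both a contact and an H-bond plant")
            moved.add(racc)


@dataclass
class GroundTruth:
    """Exact planted values derived deterministically from the spec."""

    important_residues: set[int]
    expected_delta_rmsf: dict[int, float]  # sqrt(3)*|sd_B - sd_A| (approximate)
    expected_occupancies: dict[tuple[int, int], float]
    expected_contact_distances: dict[tuple[int, int], tuple[float, float]]
    reference_interchain_energy: tuple[float, float] | None  # (coulomb, lj)


# ---------------------------------------------------------------------------
# Ideal helix construction (internal -> Cartesian)
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position a fourth atom from three predecessors (NeRF construction)."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(dih),
                   bond * np.sin(ang) * np.sin(dih)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def ideal_helix_backbone(n_residues: int) -> dict[str, np.ndarray]:
    """N, CA, C, O, H coordinates of an ideal alpha helix, axis on x.

    Built from standard internal coordinates (phi -57, psi -47) and then
    rotated so the principal axis lies along +x with the centroid at the
    origin.
    """
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_BOND_N_CA, 0.0, 0.0])]
    c_pos = [_place_atom(np.array([0.0, 0.0, 1.0]), n_pos[0], ca_pos[0],
                         _BOND_CA_C, _ANG_N_CA_C, _PSI + 180.0)]
    for i in range(1, n_residues):
        n_i = _place_atom(n_pos[-1], ca_pos[-1], c_pos[-1],
                          _BOND_C_N, _ANG_CA_C_N, _PSI)
        ca_i = _place_atom(ca_pos[-1], c_pos[-1], n_i,
                           _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c_i = _place_atom(c_pos[-1], n_i, ca_i, _BOND_CA_C, _ANG_N_CA_C, _PHI)
        n_pos.append(n_i); ca_pos.append(ca_i); c_pos.append(c_i)
    o_pos, h_pos = [], []
    for i in range(n_residues):
        if i + 1 < n_residues:
            # O anti to the next amide N
            o_pos.append(_place_atom(n_pos[i + 1], ca_pos[i], c_pos[i],
                                     _BOND_C_O, _ANG_CA_C_O, 180.0))
        else:
            o_pos.append(_place_atom(n_pos[i], ca_pos[i], c_pos[i],
                                     _BOND_C_O, _ANG_CA_C_O, _PSI + 180.0))
        if i == 0:
            h_pos.append(n_pos[0] + np.array([0.0, -_BOND_N_H, 0.0]))
        else:
            v1 = n_pos[i] - ca_pos[i]
            v2 = n_pos[i] - c_pos[i - 1]
            d = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
            h_pos.append(n_pos[i] + _BOND_N_H * d / np.linalg.norm(d))

    coords = {"N": np.array(n_pos), "CA": np.array(ca_pos),
              "C": np.array(c_pos), "O": np.array(o_pos), "H": np.array(h_pos)}
    allc = np.concatenate(list(coords.values()))
    center = allc.mean(axis=0)
    ca = coords["CA"] - center
    # principal axis of the CA trace -> +x
    _, _, vt = np.linalg.svd(ca - ca.mean(axis=0))
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, axis)
    if np.linalg.norm(y) < 1e-8:
        y = np.array([0.0, 1.0, 0.0])
    y /= np.linalg.norm(y)
    zz = np.cross(axis, y)
    rot = np.stack([axis, y, zz])
    for k in coords:
        coords[k] = (coords[k] - center) @ rot.T
    return coords


def build_toy_topology(spec: SyntheticSpec) -> tuple[Topology, np.ndarray]:
    """Two ideal helical backbone chains facing across an interface.

    Chain A residues have internal indices 0..R-1, chain B R..2R-1;
    author numbering restarts at 1 per chain.  Charges/LJ parameters are
    assigned per the spec's scheme; optional waters (isolated 3-atom HOH
    residues) are placed near the interface midline.
    """
    r = spec.residues_per_chain
    helix = ideal_helix_backbone(r)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: set[tuple[int, int]] = set()

    def add_chain(chain_id: str, offset: np.ndarray, res_offset: int):
        prev_c = None
        for i in range(r):
            rid = res_offset + i
            for name in ("N", "H", "CA", "C", "O"):
                idx = len(atoms)
                element = name[0] if name != "CA" else "C"
                q = _CHARGES[name if name != "CA" else "CA"] \
                    if spec.charge_scheme == "backbone" else 0.0
                sig, eps = _LJ[element]
                atoms.append(Atom(index=idx, name=name, element=element,
                                  residue_index=rid, residue_name="ALA",
                                  chain_id=chain_id, res_seq=i + 1,
                                  partial_charge=q, lj_sigma=sig,
                                  lj_epsilon=eps))
                coords.append(helix[name][i] + offset)
            base = len(atoms) - 5  # N H CA C O
            bonds.update({(base, base + 1), (base, base + 2),
                          (base + 2, base + 3), (base + 3, base + 4)})
            if prev_c is not None:
                bonds.add((prev_c, base))
            prev_c = base + 3

    add_chain("A", np.zeros(3), 0)
    add_chain("B", np.array([0.0, spec.interface_separation, 0.0]), r)

    if spec.n_waters:
        rng = np.random.default_rng(spec.seed + 991)
        for w in range(spec.n_waters):
            rid = 2 * r + w
            center = np.array([
                rng.uniform(-4.0, 4.0), spec.interface_separation / 2.0,
                rng.uniform(-4.0, 4.0)])
            base = len(atoms)
            for name, off in (("O", np.zeros(3)),
                              ("H1", np.array([0.9572, 0.0, 0.0])),
                              ("H2", np.array([-0.2400, 0.9266, 0.0]))):
                atoms.append(Atom(index=len(atoms), name=name,
                                  element=name[0], residue_index=rid,
                                  residue_name="HOH", chain_id="W",
                                  res_seq=w + 1,
                                  partial_charge=(-0.834 if name == "O" else 0.417)
                                  if spec.charge_scheme == "backbone" else 0.0,
                                  lj_sigma=_LJ[name[0]][0],
                                  lj_epsilon=_LJ[name[0]][1]))
                coords.append(center + off)
            bonds.update({(base, base + 1), (base, base + 2)})

    ref = np.array(coords)
    top = Topology(atoms=atoms, bonds=bonds)
    for a in top.atoms:  # polar flags: N/O plus their hydrogens
        if a.element in ("N", "O"):
            a.is_polar = True
    for i, j in bonds:
        hi, hj = top.atoms[i], top.atoms[j]
        if hj.is_hydrogen and hi.is_polar:
            hj.is_polar = True
        if hi.is_hydrogen and hj.is_polar:
            hi.is_polar = True
    return top, ref


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def _residue_atom_map(top: Topology) -> dict[int, np.ndarray]:
    out: dict[int, list[int]] = {}
    for a in top.atoms:
        out.setdefault(a.residue_index, []).append(a.index)
    return {k: np.array(v, dtype=int) for k, v in out.items()}


def _sigma_for(spec: SyntheticSpec, residue: int, state: int) -> float:
    if residue in spec.planted_fluctuations:
        return spec.planted_fluctuations[residue][state]
    return spec.base_sigma[state]


def generate_ensembles(spec: SyntheticSpec
                       ) -> tuple[StateEnsemble, StateEnsemble, GroundTruth]:
    """Generate the two state ensembles plus their ground truth.

    Per frame each residue receives an independent rigid Gaussian
    displacement (per-axis sd from the spec); planted contact pairs then
    have the second residue translated along the pair axis so the CA-CA
    distance is Normal(state mean, jitter); planted H-bond acceptors are
    snapped inside the geometric criteria in a Bernoulli(q) fraction of
    frames and pushed to ~6 A otherwise.
    """
    top, ref = build_toy_topology(spec)
    res_atoms = _residue_atom_map(top)
    ca = {rid: int(top.atom_indices(residue_index=rid, name="CA")[0])
          for rid, rname, _ in top.residues if rname != "HOH"}

    ensembles = []
    for s, label in enumerate(spec.state_labels):
        replicates = []
        for rep in range(spec.replicates_per_state):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, s, rep]))
            frames = np.empty((spec.frames_per_replicate, top.n_atoms, 3))
            for f in range(spec.frames_per_replicate):
                c = ref.copy()
                for rid, idx in res_atoms.items():
                    sigma = _sigma_for(spec, rid, s)
                    c[idx] += rng.normal(0.0, sigma, size=3)
                for ra, rb, da, db, jit in spec.planted_contacts:
                    target = rng.normal((da, db)[s], jit)
                    u = c[ca[rb]] - c[ca[ra]]
                    u /= np.linalg.norm(u)
                    shift = c[ca[ra]] + target * u - c[ca[rb]]
                    c[res_atoms[rb]] += shift
                for rd, racc, q in spec.planted_hbonds:
                    n_i = int(top.atom_indices(residue_index=rd, name="N")[0])
                    h_i = int(top.atom_indices(residue_index=rd, name="H")[0])
                    o_j = int(top.atom_indices(residue_index=racc, name="O")[0])
                    vh = c[h_i] - c[n_i]
                    vh /= np.linalg.norm(vh)
                    dist = 2.9 if rng.random() < q else 6.0
                    c[res_atoms[racc]] += c[n_i] + dist * vh - c[o_j]
                frames[f] = c
            times = spec.frame_spacing_ns * np.arange(
                1, spec.frames_per_replicate + 1)
            replicates.append(Trajectory(top, frames, times))
        ensembles.append(StateEnsemble(state_label=label, replicates=replicates))

    # replicates of both states must share one Topology object
    shared = ensembles[0].replicates + ensembles[1].replicates
    for t in shared:
        t.topology = top
    return ensembles[0], ensembles[1], ground_truth(spec)


def ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Exact expectations implied by the spec (no simulation involved)."""
    important = {r for pc in spec.planted_contacts for r in pc[:2]}
    delta_rmsf = {}
    all_res = range(2 * spec.residues_per_chain)
    for rid in all_res:
        sa = _sigma_for(spec, rid, 0)
        sb = _sigma_for(spec, rid, 1)
        delta_rmsf[rid] = np.sqrt(3.0) * abs(sb - sa)
    occupancies = {(rd, racc): q for rd, racc, q in spec.planted_hbonds}
    contacts = {(ra, rb): (da, db) for ra, rb, da, db, _ in spec.planted_contacts}

    energy = None
    if spec.charge_scheme != "zero":
        from .energetics import coulomb_lj_energy

        top, ref = build_toy_topology(spec)
        ga = top.atom_indices(chain_id="A")
        gb = top.atom_indices(chain_id="B")
        energy = coulomb_lj_energy(ref, top, ga, gb)
    return GroundTruth(important_residues=important,
                       expected_delta_rmsf=delta_rmsf,
                       expected_occupancies=occupancies,
                       expected_contact_distances=contacts,
                       reference_interchain_energy=energy)


# ---------------------------------------------------------------------------
# Pair-level contact-feature ensembles
# ---------------------------------------------------------------------------

def generate_contact_features(n_pairs: int = 60, n_planted: int = 3,
                              replicates_per_state: int = 5,
                              frames_per_replicate: int = 1000,
                              noise_mean: float = 7.5, noise_sd: float = 0.5,
                              planted_means: tuple[float, float] = (6.0, 9.0),
                              planted_half_width: float = 1.2, seed: int = 0,
                              state_labels: tuple[str, str] = ("stateA", "stateB"),
                              standardize: bool = True):
    """Contact-feature matrix with independent per-pair distance series.

    Each residue pair's minimum contact distance is drawn independently
    per frame: noise pairs from Normal(noise_mean, noise_sd) in both
    states, planted pairs from Uniform(planted_means[state] +/-
    planted_half_width).  The bounded planted jitter keeps the two state
    distributions disjoint (states are exactly separable, training
    accuracy 1.0) while holding the correlation between planted features
    below the 0.9 pruning threshold, so all planted pairs survive
    pruning.  Residues are disjoint across pairs (pair k joins residues k and
    n_pairs + k), so the planted-residue set is exactly the residues of
    the first ``n_planted`` pairs.  Returns (ContactFeatureMatrix,
    planted residue set).

    This construction plants the separation in the pair features alone;
    the geometric ensembles of :func:`generate_ensembles` instead move
    whole residues, which also perturbs neighbouring pair distances.
    """
    from .ml_importance import ContactFeatureMatrix

    if n_planted > n_pairs:
        raise SpecError("n_planted cannot exceed n_pairs")
    pairs = [(k, n_pairs + k) for k in range(n_pairs)]
    blocks, labels, reps = [], [], []
    for s, label in enumerate(state_labels):
        for rep in range(replicates_per_state):
            rng = np.random.default_rng(np.random.SeedSequence([seed, s, rep]))
            d = rng.normal(noise_mean, noise_sd,
                           size=(frames_per_replicate, n_pairs))
            for k in range(n_planted):
                d[:, k] = rng.uniform(planted_means[s] - planted_half_width,
                                      planted_means[s] + planted_half_width,
                                      size=frames_per_replicate)
            np.clip(d, 0.5, None, out=d)
            blocks.append(d)
            labels.extend([label] * frames_per_replicate)
            reps.extend([rep] * frames_per_replicate)
    dmat = np.concatenate(blocks, axis=0)
    feats = 1.0 / dmat
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0)
    if standardize:
        feats = (feats - mean) / np.where(sd > 0, sd, 1.0)
    matrix = ContactFeatureMatrix(values=feats, labels=np.array(labels),
                                  replicate=np.array(reps, dtype=int),
                                  pairs=pairs, interface_id=None,
                                  mean_=mean, sd_=sd)
    planted = {r for p in pairs[:n_planted] for r in p}
    return matrix, planted
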