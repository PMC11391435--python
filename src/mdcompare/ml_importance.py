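"""Ensemble-ML interfacial residue importance and residue categories.

Frames from two simulated states are described by contact features — the
standardized inverse of the minimum heavy-atom distance of each eligible
interfacial residue pair (eligible: closer than 10 A in at least one
frame of any replicate of either state).  Twenty iterations each prune
highly correlated features (|r| > 0.9, seeded shuffled order) and train
logistic-regression, random-forest and multilayer-perceptron classifiers
to distinguish the states; residue importance sums a residue's pair
importances, is averaged over the iterations, and is normalized to a max
of 1 per model per interface.

Residues are then classified: category 1 = ML importance > 0.8 in at
least one model only; category 2 = ML flag plus |ddG_Total| >= 2 kJ/mol
or a threshold-exceeding |dRMSF|; category 3 = all three criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (DISORDERED_DELTA_RMSF_A, FlexibilityProfile,
                       ORDERED_DELTA_RMSF_A)
from .model_io import StateEnsemble, Topology, window_frames

ELIGIBILITY_CUTOFF_A = 10.0
CORRELATION_MAX = 0.9
IMPORTANCE_THRESHOLD = 0.8
DDG_THRESHOLD_KJ = 2.0
N_ITERATIONS = 20


class EmptyFeatureError(ValueError):
    pass


@dataclass
class ContactFeatureMatrix:
    """Standardized inverse-contact-distance features.

    ``values`` is (n_frames_total, n_pairs); rows carry state labels and
    replicate provenance; ``pairs`` are (residue_index_a, residue_index_b)
    tuples in internal numbering.
    """

    values: np.ndarray
    labels: np.ndarray  # (N,) state label per row
    replicate: np.ndarray  # (N,) replicate id per row
    pairs: list[tuple[int, int]]
    interface_id: int | None = None
    mean_: np.ndarray | None = None  # standardization parameters
    sd_: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def select(self, columns) -> "ContactFeatureMatrix":
        cols = np.asarray(columns, dtype=int)
        return ContactFeatureMatrix(
            values=self.values[:, cols], labels=self.labels,
            replicate=self.replicate, pairs=[self.pairs[c] for c in cols],
            interface_id=self.interface_id)


@dataclass
class ImportanceTable:
    """Residue -> importance per model, averaged and max-normalized."""

    residues: list[int]
    importance: dict[str, np.ndarray]  # model -> (R,) in [0, 1]
    n_iterations: int
    training_accuracies: dict[str, list[float]] = field(default_factory=dict)
    interface_id: int | None = None

    def max_importance(self) -> np.ndarray:
        return np.max(np.stack(list(self.importance.values())), axis=0)

    def as_frame(self, topology: Topology | None = None):
        import pandas as pd

        data = {"residue_index": self.residues}
        if topology is not None:
            data["residue"] = [topology.residue_label(r) for r in self.residues]
        for m, v in self.importance.items():
            data[f"importance_{m}"] = v
        return pd.DataFrame(data)


@dataclass
class CategoryAssignment:
    """Per-residue category {0 (none), 1, 2, 3} with criterion flags."""

    residues: list[int]
    category: np.ndarray
    ml_flag: np.ndarray
    energy_flag: np.ndarray
    rmsf_flag: np.ndarray

    def as_frame(self, topology: Topology | None = None):
        import pandas as pd

        data = {"residue_index": self.residues}
        if topology is not None:
            data["residue"] = [topology.residue_label(r) for r in self.residues]
        data.update(category=self.category, ml_flag=self.ml_flag,
                    energy_flag=self.energy_flag, rmsf_flag=self.rmsf_flag)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _residue_heavy_atoms(top: Topology, residues) -> dict[int, np.ndarray]:
    return {int(r): top.atom_indices(residue_index=int(r), heavy_only=True)
            for r in residues}


def min_heavy_distance_series(coords: np.ndarray, atoms_a: np.ndarray,
                              atoms_b: np.ndarray) -> np.ndarray:
    """Per-frame minimum heavy-atom distance between two residues."""
    d = np.linalg.norm(coords[:, atoms_a, None, :] - coords[:, None, atoms_b, :],
                       axis=3)
    return d.min(axis=(1, 2))


def extract_pair_features(state_a: StateEnsemble, state_b: StateEnsemble,
                          residues_a, residues_b,
                          frames_per_replicate: int = 5000,
                          window: tuple[float, float] | None = None,
                          cutoff: float = ELIGIBILITY_CUTOFF_A,
                          interface_id: int | None = None,
                          standardize: bool = True) -> ContactFeatureMatrix:
    """Contact feature matrix for one interface between two states.

    ``residues_a`` / ``residues_b`` are the internal residue indices of
    the two interface sides.  Every replicate contributes
    ``frames_per_replicate`` evenly spaced frames from ``window``
    (default: the final part of each replicate covered by its times).
    Cross pairs qualify when their minimum heavy-atom distance falls
    below ``cutoff`` in at least one sampled frame of any replicate of
    either state; features are 1/d, standardized per column over all
    rows of both states.
    """
    top = state_a.topology
    heavy_a = _residue_heavy_atoms(top, residues_a)
    heavy_b = _residue_heavy_atoms(top, residues_b)
    pairs = [(ra, rb) for ra in heavy_a for rb in heavy_b
             if ra != rb and heavy_a[ra].size and heavy_b[rb].size]
    if not pairs:
        raise EmptyFeatureError("no candidate residue pairs at the interface")

    blocks, labels, reps = [], [], []
    for ens in (state_a, state_b):
        for k, traj in enumerate(ens.replicates):
            if window is not None:
                traj = window_frames(traj, window,
                                     min(frames_per_replicate, traj.n_frames))
            elif traj.n_frames > frames_per_replicate:
                idx = np.round(np.linspace(0, traj.n_frames - 1,
                                           frames_per_replicate)).astype(int)
                traj = traj.subset(idx)
            dists = np.stack([
                min_heavy_distance_series(traj.coords, heavy_a[ra], heavy_b[rb])
                for ra, rb in pairs], axis=1)  # (F, P)
            blocks.append(dists)
            labels.extend([ens.state_label] * dists.shape[0])
            reps.extend([k] * dists.shape[0])
    dmat = np.concatenate(blocks, axis=0)
    eligible = np.nonzero((dmat < cutoff).any(axis=0))[0]
    if eligible.size == 0:
        raise EmptyFeatureError(
            f"no residue pair ever comes within {cutoff} A")
    dmat = dmat[:, eligible]
    kept_pairs = [pairs[i] for i in eligible]
    feats = 1.0 / dmat
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0)
    if standardize:
        sd_safe = np.where(sd > 0, sd, 1.0)
        feats = (feats - mean) / sd_safe
    return ContactFeatureMatrix(values=feats, labels=np.array(labels),
                                replicate=np.array(reps, dtype=int),
                                pairs=kept_pairs, interface_id=interface_id,
                                mean_=mean, sd_=sd)


# ---------------------------------------------------------------------------
# Pruning, training, aggregation
# ---------------------------------------------------------------------------

def prune_correlated(matrix: ContactFeatureMatrix, r_max: float = CORRELATION_MAX,
                     rng_seed: int = 0) -> tuple[ContactFeatureMatrix, list[int], list[int]]:
    """Greedy correlation pruning in a seeded random column order.

    A column is kept iff its absolute Pearson correlation with every
    already-kept column is <= ``r_max``.  Deterministic given the seed.
    Returns (reduced matrix, kept column indices, dropped column indices)
    with indices referring to the input column order.
    """
    x = matrix.values
    p = x.shape[1]
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(p)
    xc = x - x.mean(axis=0)
    norms = np.linalg.norm(xc, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    xn = xc / norms
    kept: list[int] = []
    for col in order:
        if not kept:
            kept.append(int(col))
            continue
        corr = np.abs(xn[:, kept].T @ xn[:, col])
        if np.all(corr <= r_max):
            kept.append(int(col))
    kept_sorted = sorted(kept)
    dropped = sorted(set(range(p)) - set(kept))
    return matrix.select(kept_sorted), kept_sorted, dropped


def train_models(matrix: ContactFeatureMatrix, rng_seed: int = 0,
                 mlp_hidden: tuple[int, ...] = (32,), mlp_max_iter: int = 400,
                 rf_estimators: int = 100,
                 mlp_importance: str = "first_layer",
                 ) -> tuple[dict, dict[str, np.ndarray], dict[str, float]]:
    """Fit LR, RF and MLP classifiers on the full matrix.

    Returns (fitted models, per-feature importances >= 0, training
    accuracies).  Importance conventions: LR |coefficient|, RF impurity
    importance, MLP mean absolute first-layer weight per input (or
    permutation importance when ``mlp_importance='permutation'``).  A
    warning is raised when any training accuracy is below 1.0.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier

    x = matrix.values
    classes = np.unique(matrix.labels)
    if classes.size < 2:
        raise ValueError("training requires both state labels present")
    y = (matrix.labels == classes[1]).astype(int)

    models = {
        "LR": LogisticRegression(max_iter=2000),
        "RF": RandomForestClassifier(n_estimators=rf_estimators,
                                     random_state=rng_seed),
        "MLP": MLPClassifier(hidden_layer_sizes=mlp_hidden,
                             max_iter=mlp_max_iter, random_state=rng_seed),
    }
    importances: dict[str, np.ndarray] = {}
    accuracies: dict[str, float] = {}
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        for name, model in models.items():
            model.fit(x, y)
            acc = float(model.score(x, y))
            accuracies[name] = acc
            if acc < 1.0:
                warnings.warn(f"{name} training accuracy {acc:.3f} < 1.0; "
                              "states may not be separable at this interface")
            if name == "LR":
                importances[name] = np.abs(model.coef_[0])
            elif name == "RF":
                importances[name] = model.feature_importances_
            else:
                if mlp_importance == "permutation":
                    from sklearn.inspection import permutation_importance

                    r = permutation_importance(model, x, y, n_repeats=5,
                                               random_state=rng_seed)
                    importances[name] = np.clip(r.importances_mean, 0, None)
                else:
                    importances[name] = np.abs(model.coefs_[0]).mean(axis=1)
    return models, importances, accuracies


def aggregate_importance(matrix: ContactFeatureMatrix, rng_seed: int = 0,
                         n_iterations: int = N_ITERATIONS,
                         r_max: float = CORRELATION_MAX,
                         require_separable: bool = False,
                         **train_kw) -> ImportanceTable:
    """The full iterated procedure: prune, train, sum to residues, average.

    Iteration i uses seed ``rng_seed + i`` for both the pruning order and
    the stochastic model initializations.  Per model, a residue's score
    sums the importances of all surviving pairs containing it; scores are
    averaged over iterations and normalized to max 1 per model (per
    interface).  With ``require_separable=True``, an iteration contributes
    zero importance unless all three models reach training accuracy 1.0
    (tree ensembles memorise training noise, so the gate is the weakest
    model); this guards the >0.8 flag against unseparable states.
    """
    residues = sorted({r for p in matrix.pairs for r in p})
    r_index = {r: k for k, r in enumerate(residues)}
    model_names = ("LR", "RF", "MLP")
    sums = {m: np.zeros(len(residues)) for m in model_names}
    accs: dict[str, list[float]] = {m: [] for m in model_names}
    for it in range(n_iterations):
        seed = rng_seed + it
        pruned, kept, _ = prune_correlated(matrix, r_max=r_max, rng_seed=seed)
        _, imps, acc = train_models(pruned, rng_seed=seed, **train_kw)
        gate = require_separable and min(acc.values()) < 1.0
        for m in model_names:
            accs[m].append(acc[m])
            if gate:
                continue
            for col, (ra, rb) in enumerate(pruned.pairs):
                sums[m][r_index[ra]] += imps[m][col]
                sums[m][r_index[rb]] += imps[m][col]
    importance: dict[str, np.ndarray] = {}
    for m in model_names:
        avg = sums[m] / n_iterations
        peak = avg.max()
        importance[m] = avg / peak if peak > 0 else avg
    return ImportanceTable(residues=residues, importance=importance,
                           n_iterations=n_iterations,
                           training_accuracies=accs,
                           interface_id=matrix.interface_id)


# ---------------------------------------------------------------------------
# Category classification
# ---------------------------------------------------------------------------

def classify_categories(imp: ImportanceTable,
                        ddg: dict[int, float],
                        drmsf: FlexibilityProfile | None = None,
                        disordered_mask=None,
                        importance_threshold: float = IMPORTANCE_THRESHOLD,
                        ddg_threshold: float = DDG_THRESHOLD_KJ,
                        ) -> CategoryAssignment:
    """Combine ML importance, per-residue |ddG_Total| and |dRMSF| flags.

    ``ddg`` maps residue index to the ddG_Total difference between states
    (kJ/mol); ``drmsf`` is a differenced flexibility profile.  Flags:
    ml = importance > 0.8 (strict) in >= 1 model; energy = |ddG| >= 2
    kJ/mol; rmsf = |dRMSF| >= 1 A ordered / >= 3 A disordered.  Category
    3 = all three; category 2 = ml and (energy or rmsf); category 1 = ml
    only; 0 otherwise.  Residues missing from a table get partial flags
    and a warning.
    """
    residues = imp.residues
    n = len(residues)
    ml = np.zeros(n, dtype=bool)
    energy = np.zeros(n, dtype=bool)
    rmsf = np.zeros(n, dtype=bool)

    drmsf_map: dict[int, float] = {}
    dis_map: dict[int, bool] = {}
    if drmsf is not None and drmsf.delta_rmsf is not None:
        if disordered_mask is None:
            disordered_mask = np.zeros(drmsf.delta_rmsf.size, dtype=bool)
        for k, rid in enumerate(drmsf.residue_indices):
            drmsf_map[int(rid)] = float(drmsf.delta_rmsf[k])
            dis_map[int(rid)] = bool(np.asarray(disordered_mask)[k])

    for k, rid in enumerate(residues):
        ml[k] = any(imp.importance[m][k] > importance_threshold
                    for m in imp.importance)
        if rid in ddg:
            energy[k] = abs(ddg[rid]) >= ddg_threshold
        else:
            warnings.warn(f"residue {rid} missing from ddG table; "
                          "energy flag defaults to False")
        if rid in drmsf_map:
            thr = (DISORDERED_DELTA_RMSF_A if dis_map.get(rid, False)
                   else ORDERED_DELTA_RMSF_A)
            rmsf[k] = abs(drmsf_map[rid]) >= thr
        elif drmsf is not None:
            warnings.warn(f"residue {rid} missing from dRMSF profile; "
                          "rmsf flag defaults to False")

    category = np.zeros(n, dtype=int)
    category[ml] = 1
    category[ml & (energy | rmsf)] = 2
    category[ml & energy & rmsf] = 3
    return CategoryAssignment(residues=list(residues), category=category,
                              ml_flag=ml, energy_flag=energy, rmsf_flag=rmsf)
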