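"""Contact features, correlation pruning, ensemble importance, categories."""

import itertools
import warnings

import numpy as np
import pytest

from mdcompare.geometry import FlexibilityProfile
from mdcompare.ml_importance import (ContactFeatureMatrix, ImportanceTable,
                                     aggregate_importance, classify_categories,
                                     extract_pair_features,
                                     min_heavy_distance_series,
                                     prune_correlated, train_models)
from mdcompare.model_io import StateEnsemble, Trajectory
from mdcompare.synthetic_data import (SyntheticSpec, generate_contact_features,
                                      generate_ensembles)


def matrix_from(values, labels=None, pairs=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if labels is None:
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    if pairs is None:
        pairs = [(k, p + k) for k in range(p)]
    return ContactFeatureMatrix(values=values, labels=np.asarray(labels),
                                replicate=np.zeros(n, dtype=int), pairs=pairs)


@pytest.fixture(scope="module")
def small_states():
    spec = SyntheticSpec(residues_per_chain=8, replicates_per_state=2,
                         frames_per_replicate=30, seed=5)
    a, b, _ = generate_ensembles(spec)
    return spec, a, b


class TestExtractFeatures:
    def test_eligibility_matches_bruteforce_scan(self, small_states):
        spec, a, b = small_states
        r = spec.residues_per_chain
        m = extract_pair_features(a, b, range(r), range(r, 2 * r),
                                  frames_per_replicate=30)
        top = a.topology
        eligible = set()
        for ra in range(r):
            for rb in range(r, 2 * r):
                ha = top.atom_indices(residue_index=ra, heavy_only=True)
                hb = top.atom_indices(residue_index=rb, heavy_only=True)
                for traj in a.replicates + b.replicates:
                    d = min_heavy_distance_series(traj.coords, ha, hb)
                    if (d < 10.0).any():
                        eligible.add((ra, rb))
                        break
        assert set(m.pairs) == eligible

    def test_distant_pair_excluded(self, small_states):
        spec, a, b = small_states
        r = spec.residues_per_chain
        m = extract_pair_features(a, b, range(r), range(r, 2 * r),
                                  frames_per_replicate=30)
        # opposite helix ends are far beyond 10 A on this geometry
        assert (0, 2 * r - 1) not in m.pairs

    def test_columns_standardized(self, small_states):
        spec, a, b = small_states
        r = spec.residues_per_chain
        m = extract_pair_features(a, b, range(r), range(r, 2 * r),
                                  frames_per_replicate=30)
        assert np.allclose(m.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(m.values.std(axis=0), 1.0, atol=1e-9)


class TestPruning:
    def test_identical_columns_keep_exactly_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=100)
        m = matrix_from(np.stack([col, col], axis=1))
        reduced, kept, dropped = prune_correlated(m, rng_seed=1)
        assert len(kept) == 1 and len(dropped) == 1

    def test_independent_columns_all_kept(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.normal(size=(500, 6)))
        reduced, kept, dropped = prune_correlated(m, rng_seed=0)
        assert len(kept) == 6 and dropped == []

    def test_three_column_case_matches_order_enumeration(self):
        """r(0,1)=r(0,2)~0.95, r(1,2)~0.2 -> always 2 survivors, and the
        kept set matches a brute-force greedy pass in the same order."""
        rng = np.random.default_rng(2)
        z = rng.normal(size=4000)
        a = z + rng.normal(0, 0.3, 4000)
        b = z + rng.normal(0, 0.3, 4000)
        c = rng.normal(size=4000)
        x = np.stack([a, b, c], axis=1)
        corr = np.corrcoef(x.T)
        assert corr[0, 1] > 0.9 and abs(corr[1, 2]) < 0.9
        m = matrix_from(x)

        for seed in range(10):
            reduced, kept, _ = prune_correlated(m, rng_seed=seed)
            assert len(kept) == 2
            # oracle: greedy over the same seeded order
            order = np.random.default_rng(seed).permutation(3)
            oracle_kept = []
            for col in order:
                if all(abs(corr[col, k]) <= 0.9 for k in oracle_kept):
                    oracle_kept.append(int(col))
            assert sorted(oracle_kept) == kept

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.normal(size=(200, 8)))
        r1 = prune_correlated(m, rng_seed=42)
        r2 = prune_correlated(m, rng_seed=42)
        assert r1[1] == r2[1]
        assert np.array_equal(r1[0].values, r2[0].values)

    def test_never_increases_columns(self):
        rng = np.random.default_rng(4)
        m = matrix_from(rng.normal(size=(100, 5)))
        reduced, kept, _ = prune_correlated(m, rng_seed=0)
        assert reduced.n_pairs <= m.n_pairs


class TestTraining:
    def test_separating_feature_dominates_all_models(self):
        rng = np.random.default_rng(5)
        n = 400
        labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        signal = np.where(labels == "a", -1.0, 1.0) + rng.normal(0, 0.05, n)
        noise = rng.normal(size=(n, 4))
        x = np.column_stack([noise[:, :2], signal, noise[:, 2:]])
        x = (x - x.mean(0)) / x.std(0)
        m = matrix_from(x, labels=labels)
        _, imps, accs = train_models(m, rng_seed=0)
        for name, imp in imps.items():
            assert np.argmax(imp) == 2, name
            assert accs[name] == 1.0

    def test_shuffled_labels_warn_and_score_near_chance(self):
        rng = np.random.default_rng(6)
        n = 300
        labels = rng.permutation(np.array(["a", "b"] * (n // 2)))
        x = rng.normal(size=(n, 3))
        m = matrix_from(x, labels=labels)
        with pytest.warns(UserWarning, match="accuracy"):
            _, _, accs = train_models(m, rng_seed=0)
        assert accs["LR"] < 0.7  # linear model cannot memorise noise

    def test_single_class_rejected(self):
        m = matrix_from(np.random.default_rng(0).normal(size=(10, 2)),
                        labels=np.array(["a"] * 10))
        with pytest.raises(ValueError):
            train_models(m)


class TestAggregation:
    def test_single_signal_pair_gives_both_residues_unit_importance(self):
        m, planted = generate_contact_features(n_pairs=8, n_planted=1,
                                               replicates_per_state=2,
                                               frames_per_replicate=100, seed=2)
        imp = aggregate_importance(m, rng_seed=0, n_iterations=2)
        res = np.array(imp.residues)
        for model, v in imp.importance.items():
            assert np.allclose(v[np.isin(res, list(planted))], 1.0), model

    def test_residue_in_two_pairs_scores_higher_prenormalization(self):
        """Additive construction: shared residue accumulates both pairs."""
        rng = np.random.default_rng(7)
        n = 200
        labels = np.array(["a"] * 100 + ["b"] * 100)
        sig = np.where(labels == "a", -1.0, 1.0)
        x = np.column_stack([
            sig + rng.normal(0, 0.05, n),      # pair (0, 10): residue 0 shared
            sig + rng.normal(0, 0.05, n),      # pair (0, 11)
            rng.normal(size=n)])               # pair (5, 12): noise
        x = (x - x.mean(0)) / x.std(0)
        m = matrix_from(x, labels=labels,
                        pairs=[(0, 10), (0, 11), (5, 12)])
        imp = aggregate_importance(m, rng_seed=0, n_iterations=2, r_max=0.999)
        res = np.array(imp.residues)
        lr = imp.importance["LR"]
        assert lr[res == 0][0] == 1.0  # max by construction
        assert lr[res == 10][0] < 1.0

    def test_zero_signal_interface_yields_no_normalization_blowup(self):
        rng = np.random.default_rng(8)
        labels = np.array(["a"] * 50 + ["b"] * 50)
        m = matrix_from(rng.normal(size=(100, 4)), labels=labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imp = aggregate_importance(m, rng_seed=0, n_iterations=2,
                                       require_separable=True)
        for v in imp.importance.values():
            assert np.all(v == 0.0)

    def test_importances_bounded_and_seed_reproducible(self):
        m, _ = generate_contact_features(n_pairs=6, n_planted=1,
                                         replicates_per_state=2,
                                         frames_per_replicate=80, seed=3)
        i1 = aggregate_importance(m, rng_seed=9, n_iterations=2)
        i2 = aggregate_importance(m, rng_seed=9, n_iterations=2)
        for model in i1.importance:
            assert np.array_equal(i1.importance[model], i2.importance[model])
            assert np.all((0 <= i1.importance[model])
                          & (i1.importance[model] <= 1))


class TestCategories:
    def _imp(self, scores):
        res = list(range(len(scores)))
        return ImportanceTable(residues=res,
                               importance={"LR": np.asarray(scores),
                                           "RF": np.zeros(len(scores)),
                                           "MLP": np.zeros(len(scores))},
                               n_iterations=1)

    def _drmsf(self, deltas):
        n = len(deltas)
        return FlexibilityProfile(residue_indices=np.arange(n),
                                  labels=[str(i) for i in range(n)],
                                  rmsf=np.zeros(n),
                                  delta_rmsf=np.asarray(deltas, dtype=float),
                                  flags=None)

    def test_all_three_criteria_is_category_3(self):
        cats = classify_categories(self._imp([0.9]), {0: 5.0},
                                   self._drmsf([1.2]))
        assert cats.category[0] == 3

    def test_ml_plus_energy_without_rmsf_is_category_2(self):
        cats = classify_categories(self._imp([0.9]), {0: 5.0},
                                   self._drmsf([0.2]))
        assert cats.category[0] == 2
        assert cats.ml_flag[0] and cats.energy_flag[0] and not cats.rmsf_flag[0]

    def test_strict_importance_threshold(self):
        cats = classify_categories(self._imp([0.79, 0.8, 0.81]),
                                   {0: 5.0, 1: 5.0, 2: 0.0},
                                   self._drmsf([2.0, 2.0, 0.0]))
        assert list(cats.category) == [0, 0, 1]

    def test_energy_and_rmsf_thresholds_inclusive(self):
        cats = classify_categories(self._imp([0.9, 0.9]),
                                   {0: 2.0, 1: -2.0},
                                   self._drmsf([1.0, -1.0]))
        assert list(cats.category) == [3, 3]

    def test_disordered_rmsf_threshold(self):
        cats = classify_categories(self._imp([0.9]), {0: 0.0},
                                   self._drmsf([2.5]),
                                   disordered_mask=[True])
        assert cats.category[0] == 1  # 2.5 < 3 A disordered threshold

    def test_missing_residue_partial_flags_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            cats = classify_categories(self._imp([0.9]), {},
                                       self._drmsf([]) if False else None)
        assert cats.category[0] == 1

    def test_permutation_equivariance_of_residue_relabeling(self):
        m, planted = generate_contact_features(n_pairs=6, n_planted=1,
                                               replicates_per_state=2,
                                               frames_per_replicate=80, seed=4)
        imp = aggregate_importance(m, rng_seed=0, n_iterations=1)
        # relabel residues by an offset; importances must follow the map
        m2 = ContactFeatureMatrix(values=m.values, labels=m.labels,
                                  replicate=m.replicate,
                                  pairs=[(a + 100, b + 100) for a, b in m.pairs])
        imp2 = aggregate_importance(m2, rng_seed=0, n_iterations=1)
        for model in imp.importance:
            assert np.array_equal(imp.importance[model],
                                  imp2.importance[model])
        assert [r + 100 for r in imp.residues] == imp2.residues
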