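import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from femtime.clustering import (
    ModelProfile,
    assign_genes,
    cluster_feminization,
    correlation_matrix,
    generate_model_profiles,
    select_for_clustering,
)


class TestGenerateModelProfiles:
    def test_tiny_space_enumerated_and_extremes_selected(self):
        # T=3, step bound 1: nine candidate paths; the two seeds (flat and
        # monotone up) are mandatory, and the next pick under max-min
        # correlation distance must be maximally anticorrelated: monotone down
        profiles = generate_model_profiles(3, max_step=1, n_profiles=3, seed=0)
        values = [p.values for p in profiles]
        assert values[0] == (0, 0, 0)
        assert values[1] == (0, 1, 2)
        assert values[2] == (0, -1, -2)
        steps = np.arange(-1, 2)
        n_candidates = len(list(itertools.product(steps, repeat=2)))
        assert n_candidates == 9

    def test_step_bound_respected(self):
        for p in generate_model_profiles(6, max_step=10, n_profiles=8, seed=1):
            diffs = np.abs(np.diff(p.values))
            assert (diffs <= 10).all()
            assert p.values[0] == 0

    def test_deterministic_under_seed(self):
        a = generate_model_profiles(6, n_profiles=8, seed=42)
        b = generate_model_profiles(6, n_profiles=8, seed=42)
        assert [p.values for p in a] == [p.values for p in b]

    def test_too_many_profiles_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_model_profiles(3, max_step=1, n_profiles=20)


class TestAssignGenes:
    @pytest.fixture()
    def profiles(self):
        return generate_model_profiles(6, max_step=10, n_profiles=8, seed=0)

    def test_exact_profile_match_assigned_with_corr_1(self, profiles):
        vec = pd.DataFrame(
            [np.array(profiles[3].values, dtype=float)], index=["g"]
        )
        assignments, _ = assign_genes(profiles, vec, n_permutations=10)
        assert assignments.loc["g", "profile_id"] == profiles[3].profile_id
        assert assignments.loc["g", "correlation"] == pytest.approx(1.0)

    def test_assigned_profile_dominates_all_others(self, profiles):
        rng = np.random.default_rng(5)
        vec = pd.DataFrame(rng.normal(size=(40, 6)))
        assignments, _ = assign_genes(profiles, vec, n_permutations=10)
        prof_mat = np.array([p.values for p in profiles], dtype=float)
        corr = correlation_matrix(vec.to_numpy(), prof_mat)
        for i, (pid, c) in enumerate(
            zip(assignments["profile_id"], assignments["correlation"])
        ):
            assert c == pytest.approx(corr[i].max())

    def test_zero_variance_gene_goes_to_flat_profile(self, profiles):
        vec = pd.DataFrame([[3.0] * 6], index=["const"])
        assignments, _ = assign_genes(profiles, vec, n_permutations=10)
        assert assignments.loc["const", "profile_id"] == 0  # the flat profile

    def test_negated_profile_prefers_its_mirror(self):
        bank = [
            ModelProfile(0, (0, 0, 0, 0, 0, 0)),
            ModelProfile(1, (0, 2, 4, 6, 8, 10)),
            ModelProfile(2, (0, -2, -4, -6, -8, -10)),
            ModelProfile(3, (0, 10, 10, 10, 10, 10)),
        ]
        vec = pd.DataFrame(
            [np.array(bank[1].values, dtype=float) * -1.0], index=["g"]
        )
        a, _ = assign_genes(bank, vec, n_permutations=10)
        assert a.loc["g", "profile_id"] == 2


class TestSelection:
    def test_stage1_requires_correlation_and_positive_trend(self):
        profiles = [
            ModelProfile(0, (0, 0, 0)),
            ModelProfile(1, (0, 5, 10)),
            ModelProfile(2, (0, -5, -10)),
        ]
        assignments = pd.DataFrame(
            {
                "profile_id": [1, 1, 2],
                "correlation": [0.9, 0.5, 0.95],
            },
            index=["keep", "weak", "down"],
        )
        kept = select_for_clustering(profiles, assignments)
        assert list(kept) == ["keep"]

    def test_stage2_rescues_induced_but_unfeminized_genes(self):
        profiles = [ModelProfile(0, (0, 0, 0)), ModelProfile(1, (0, 5, 10))]
        assignments = pd.DataFrame(
            {"profile_id": [1, 0], "correlation": [0.9, 0.1]},
            index=["keep", "sult_like"],
        )
        fold = pd.Series({"keep": 2.0, "sult_like": 919.0})
        fem = pd.Series({"keep": 90.0, "sult_like": 12.8})
        kept = select_for_clustering(
            profiles, assignments, max_fold_induction=fold, max_feminization=fem
        )
        assert set(kept) == {"keep", "sult_like"}


class TestClusterFeminization:
    def test_two_separated_groups_fully_recovered(self):
        rng = np.random.default_rng(0)
        early = np.array([90, 100, 100, 100, 100], dtype=float)
        late = np.array([0, 5, 10, 20, 60], dtype=float)
        rows, truth = [], []
        for i in range(20):
            rows.append(early + rng.normal(0, 1, 5))
            truth.append(0)
            rows.append(late + rng.normal(0, 1, 5))
            truth.append(1)
        labels = cluster_feminization(pd.DataFrame(rows), k=2)
        assert adjusted_rand_score(truth, labels) == 1.0
        # label 1 is the earliest-onset cluster
        onset_means = pd.DataFrame(rows).groupby(labels).mean()
        assert onset_means.loc[1, 0] > onset_means.loc[2, 0]

    def test_k1_and_k_too_large(self):
        vec = pd.DataFrame(np.eye(3))
        assert (cluster_feminization(vec, k=1) == 1).all()
        with pytest.raises(ValueError, match="exceeds"):
            cluster_feminization(vec, k=5)

    def test_na_rows_excluded(self):
        vec = pd.DataFrame(
            [[1.0, 2.0], [np.nan, 1.0], [3.0, 1.0]], index=["a", "b", "c"]
        )
        labels = cluster_feminization(vec, k=2)
        assert "b" not in labels.index

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        vec = pd.DataFrame(rng.normal(size=(30, 5)))
        l1 = cluster_feminization(vec, k=4)
        l2 = cluster_feminization(vec.copy(), k=4)
        assert (l1 == l2).all()
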