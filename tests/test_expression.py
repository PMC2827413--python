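"""Normalization, volcano selection, BH, Venn intersection, clustering,
functional summaries and TF candidate extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from tuberome.expression import (
    ExperimentDesign,
    bh_adjust,
    cluster_kmeans_pearson,
    extract_tf_candidates,
    intersect_feature_sets,
    normalize,
    select_clusters,
    select_differential,
    summarize_function,
)
from tuberome.simulate.expression import DEFAULT_CONTRASTS


def two_condition_design(reps=2, experiment="exp", conditions=("A", "B")):
    rows = [
        {"sample": f"{c}{r}", "experiment": experiment, "condition": c, "replicate": r}
        for c in conditions
        for r in range(1, reps + 1)
    ]
    return ExperimentDesign(pd.DataFrame(rows))


class TestNormalize:
    def test_worked_example_steps_1_and_2(self):
        raw = pd.DataFrame({"chip": [3.0, 10.0, 20.0, 40.0, 100.0]})
        floored = raw.clip(lower=5.0)
        scaled = floored / floored.quantile(0.5)
        assert list(scaled["chip"]) == pytest.approx([0.25, 0.5, 1.0, 2.0, 5.0])
        # and the full three-step output divides rows by their medians
        norm = normalize(raw)
        expected = scaled.div(scaled.median(axis=1), axis=0)
        pd.testing.assert_frame_equal(norm.values, expected)

    def test_constant_matrix_normalizes_to_one(self):
        raw = pd.DataFrame(np.full((4, 3), 42.0))
        assert np.allclose(normalize(raw).values, 1.0)

    def test_per_feature_median_is_one(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 1000, size=(50, 6)))
        med = normalize(raw).values.median(axis=1)
        assert np.allclose(med, 1.0, atol=1e-9)

    @given(factor=st.floats(min_value=0.01, max_value=100))
    def test_per_chip_scale_invariance(self, factor):
        rng = np.random.default_rng(7)
        raw = pd.DataFrame(rng.uniform(5, 500, size=(20, 4)))
        scaled = raw.copy()
        scaled.iloc[:, 1] *= factor
        a, b = normalize(raw).values, normalize(scaled).values
        if (scaled.values >= 5).all():
            pd.testing.assert_frame_equal(a, b)

    def test_floor_recorded_in_provenance(self):
        norm = normalize(pd.DataFrame({"c": [1.0, 10.0, 20.0]}), floor=5.0)
        assert norm.provenance["floor"] == 5.0
        assert norm.provenance["chip_percentile"] == 50.0

    def test_empty_and_bad_floor_rejected(self):
        with pytest.raises(ValueError):
            normalize(pd.DataFrame())
        with pytest.raises(ValueError):
            normalize(pd.DataFrame({"c": [1.0]}), floor=0)


class TestSelectDifferential:
    def make_norm(self, a_vals, b_vals, n_null=0, reps=2, rng=None):
        """Matrix with one feature at given per-replicate values plus nulls."""
        data = {}
        for r in range(reps):
            data[f"A{r+1}"] = [a_vals[r]]
            data[f"B{r+1}"] = [b_vals[r]]
        df = pd.DataFrame(data, index=["f0"])
        if n_null:
            null = pd.DataFrame(
                rng.lognormal(0, 0.1, size=(n_null, 2 * reps)),
                index=[f"n{i}" for i in range(n_null)],
                columns=df.columns,
            )
            df = pd.concat([df, null])
        return df

    def wrap(self, values):
        from tuberome.expression import NormalizedMatrix

        return NormalizedMatrix(values=values)

    def test_fourfold_feature(self, rng):
        values = self.make_norm([1.0, 1.0], [4.0, 4.0], n_null=5, rng=rng)
        design = two_condition_design()
        de = select_differential(self.wrap(values), design, "exp", pair=("A", "B"))
        assert de.loc["f0", "fold_change"] == pytest.approx(4.0)

    def test_null_feature_fold_one_fails(self):
        values = pd.DataFrame(
            {"A1": [2.0, 1.0], "A2": [2.0, 2.0], "B1": [2.0, 1.5], "B2": [2.0, 1.2]},
            index=["flat", "other"],
        )
        de = select_differential(self.wrap(values), two_condition_design(), "exp", pair=("A", "B"))
        assert de.loc["flat", "fold_change"] == pytest.approx(1.0)
        assert not de.loc["flat", "passes"]

    def test_orientation_free_fold_change(self, rng):
        values = self.make_norm([1.0, 1.2], [3.8, 4.1], n_null=10, rng=rng)
        design = two_condition_design()
        ab = select_differential(self.wrap(values), design, "exp", pair=("A", "B"))
        ba = select_differential(self.wrap(values), design, "exp", pair=("B", "A"))
        pd.testing.assert_series_equal(ab["fold_change"], ba["fold_change"])
        pd.testing.assert_series_equal(ab["passes"], ba["passes"])

    def test_bh_gated_on_replicate_count(self, rng):
        for reps, expect_bh in ((2, False), (4, True)):
            vals = pd.DataFrame(
                rng.lognormal(0, 0.2, size=(20, 2 * reps)),
                columns=[f"{c}{r+1}" for c in "AB" for r in range(reps)],
            )
            design = two_condition_design(reps=reps)
            de = select_differential(self.wrap(vals), design, "exp", pair=("A", "B"))
            assert de.attrs["bh_applied"] is expect_bh
            assert bool(de["adjusted_p"].notna().all()) == expect_bh

    def test_false_positive_control_under_null(self):
        """Raw-p false positives ~alpha; BH controls the selected set."""
        raw_rates, bh_any = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            vals = pd.DataFrame(
                rng.lognormal(0, 0.25 * np.log(2), size=(200, 8)),
                columns=[f"{c}{r}" for c in "AB" for r in range(1, 5)],
            )
            design = two_condition_design(reps=4)
            de = select_differential(self.wrap(vals), design, "exp", pair=("A", "B"))
            raw_rates.append((de["p_value"] <= 0.05).mean())
            bh_any.append(de["passes"].sum())
        assert np.mean(raw_rates) < 0.065  # ~5% within sampling error
        assert np.mean(bh_any) < 0.25  # BH under a complete null rejects rarely

    def test_unknown_condition_rejected(self, rng):
        values = self.make_norm([1, 1], [2, 2], n_null=3, rng=rng)
        with pytest.raises(ValueError, match="not in experiment"):
            select_differential(self.wrap(values), two_condition_design(), "exp", pair=("A", "Z"))


class TestBenjaminiHochberg:
    @staticmethod
    def step_up_oracle(p):
        """Literal BH definition: adj_i = min_{k: p_(k) >= p_i rank} p_(k)*n/k, capped."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        for pos, i in enumerate(order):
            candidates = [p[order[k]] * n / (k + 1) for k in range(pos, n)]
            adj[i] = min(1.0, min(candidates))
        return adj

    def test_matches_oracle_on_all_sorted_grids_up_to_len8(self):
        grid = np.round(np.linspace(0.01, 0.99, 10), 4)
        checked = 0
        for length in range(1, 9):
            for combo in itertools.combinations_with_replacement(grid, length):
                p = np.array(combo)
                np.testing.assert_allclose(bh_adjust(p), self.step_up_oracle(p), atol=1e-12)
                checked += 1
        assert checked > 40_000

    @given(st.lists(st.floats(0.001, 0.999), min_size=2, max_size=8), st.randoms())
    @settings(max_examples=100)
    def test_permutation_equivariance_and_monotonicity(self, p, rnd):
        p = np.asarray(p)
        adj = bh_adjust(p)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)


class TestIntersect:
    def test_simple_intersection(self):
        common, regions = intersect_feature_sets([{"a", "b", "c"}, {"b", "c", "d"}, {"c"}])
        assert common == {"c"}
        assert regions[("set1", "set2", "set3")] == 1

    def test_self_intersection_idempotent(self):
        s = {"x", "y"}
        common, _ = intersect_feature_sets([s, set(s)])
        assert common == s

    def test_region_counts_sum_to_union(self, rng):
        universe = [f"g{i}" for i in range(5000)]
        sets = {
            name: set(rng.choice(universe, size=500, replace=False))
            for name in ("s1", "s2", "s3")
        }
        common, regions = intersect_feature_sets(sets)
        assert sum(regions.values()) == len(set.union(*sets.values()))
        # brute-force region enumeration oracle
        for inside, count in regions.items():
            members = 0
            for g in set.union(*sets.values()):
                membership = tuple(n for n in sets if g in sets[n])
                if membership == inside:
                    members += 1
            assert members == count

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            intersect_feature_sets([{"a"}])


class TestClustering:
    def planted_profiles(self, rng, noise=0.2, members=50, n_samples=12):
        x = np.linspace(0, 2 * np.pi, n_samples)
        templates = {
            "sin": np.sin(x),
            "ramp": np.linspace(-1, 1, n_samples),
            "step": np.where(np.arange(n_samples) < n_samples // 2, -1.0, 1.0),
        }
        rows, labels = [], []
        for name, tpl in templates.items():
            for _ in range(members):
                rows.append(tpl + rng.normal(0, noise, size=n_samples))
                labels.append(name)
        idx = [f"f{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx), pd.Series(labels, index=idx)

    def test_affine_profiles_co_cluster(self, rng):
        base, _ = self.planted_profiles(rng, members=5)
        y = base.iloc[0]
        base.loc["affine"] = 3 * y + 7
        result = cluster_kmeans_pearson(base, k=3, seed=0)
        assert result.assignment["f0"] == result.assignment["affine"]

    def test_k_equals_n_zero_inertia(self, rng):
        profiles, _ = self.planted_profiles(rng, members=2)
        result = cluster_kmeans_pearson(profiles, k=len(profiles), seed=1)
        assert result.inertia == pytest.approx(0.0, abs=1e-9)
        assert result.assignment.nunique() == len(profiles)

    def test_planted_groups_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            profiles, labels = self.planted_profiles(rng)
            result = cluster_kmeans_pearson(profiles, k=3, n_init=25, seed=seed)
            if adjusted_rand_score(labels, result.assignment) >= 0.9:
                hits += 1
        assert hits >= 18

    def test_sample_order_and_row_affine_invariance(self, rng):
        profiles, _ = self.planted_profiles(rng, members=4)
        result = cluster_kmeans_pearson(profiles, k=3, seed=5)
        shuffled = profiles[list(rng.permutation(profiles.columns))]
        transformed = shuffled.mul(rng.uniform(0.5, 3, len(profiles)), axis=0).add(
            rng.uniform(-5, 5, len(profiles)), axis=0
        )
        r2 = cluster_kmeans_pearson(transformed[profiles.columns], k=3, seed=5)
        assert adjusted_rand_score(result.assignment, r2.assignment) == pytest.approx(1.0)

    def test_zero_variance_profile_named_in_error(self, rng):
        profiles, _ = self.planted_profiles(rng, members=3)
        profiles.loc["f0"] = 1.0
        with pytest.raises(ValueError, match="f0"):
            cluster_kmeans_pearson(profiles, k=2)

    def test_too_few_features_rejected(self, rng):
        profiles, _ = self.planted_profiles(rng, members=1)
        with pytest.raises(ValueError):
            cluster_kmeans_pearson(profiles, k=10)


class TestClusterSelectionAndSummaries:
    def clustered(self, rng):
        helper = TestClustering()
        profiles, labels = helper.planted_profiles(rng, members=10)
        result = cluster_kmeans_pearson(profiles, k=3, seed=2)
        return profiles, labels, result

    def test_all_markers_one_cluster(self, rng):
        _, labels, result = self.clustered(rng)
        markers = list(labels.index[labels == "sin"])[:4]
        selected = select_clusters(result, markers)
        assert len(selected) == 1
        assert set(markers) <= set(result.members(selected[0]))

    def test_markers_absent_gives_empty_selection(self, rng):
        _, _, result = self.clustered(rng)
        assert select_clusters(result, ["nope"]) == []

    def test_markers_across_three_clusters(self, rng):
        _, labels, result = self.clustered(rng)
        markers = [labels.index[labels == n][0] for n in ("sin", "ramp", "step")]
        assert sorted(select_clusters(result, markers)) == sorted(
            result.assignment[markers].unique()
        )

    def test_summarize_function_percentages(self):
        ann = pd.Series(
            {"a": "metabolism", "b": "metabolism", "c": "storage protein", "d": "unknown"}
        )
        out = summarize_function(["a", "b", "c", "d", "e"], ann)
        assert out.loc["metabolism", "percent"] == pytest.approx(40.0)
        assert out.loc["unknown", "count"] == 2  # 'd' annotated, 'e' missing
        assert out["percent"].sum() == pytest.approx(100.0)
        with pytest.raises(ValueError):
            summarize_function([], ann)

    def test_tf_fraction_recovered_binomially(self, study_data):
        _, _, _, annotation, truth = study_data
        planted = truth.cluster_labels[truth.cluster_labels != ""].index
        out = summarize_function(planted, annotation)
        n = len(planted)
        tf_pct = out.loc["transcription factor", "percent"]
        se = 100 * np.sqrt(0.06 * 0.94 / n)
        assert abs(tf_pct - 6.0) <= 3 * se + 100.0 / n  # binomial + rounding slack

    def test_tf_candidates_ranked_by_marker_correlation(self, rng):
        profiles, labels, result = self.clustered(rng)
        markers = list(labels.index[labels == "sin"])[:3]
        sin_members = list(labels.index[labels == "sin"])
        tf_up = sin_members[5]
        profiles.loc["tf_anti"] = -profiles.loc[tf_up]
        ann = pd.Series("metabolism", index=list(profiles.index))
        ann[tf_up] = "transcription factor"
        ann["tf_anti"] = "transcription factor"
        cands = extract_tf_candidates(
            list(profiles.index), profiles, ann, markers
        )
        assert cands == [tf_up, "tf_anti"]

    def test_no_tf_gives_empty_list(self, rng):
        profiles, labels, _ = self.clustered(rng)
        ann = pd.Series("metabolism", index=list(profiles.index))
        assert extract_tf_candidates(list(profiles.index), profiles, ann, ["f0"]) == []


class TestEndToEnd:
    def test_planted_features_recovered_through_full_chain(self, study_data):
        spec, matrices, design, annotation, truth = study_data
        de_sets, norms = {}, {}
        for exp_id, raw in matrices.items():
            norm = normalize(raw)
            norms[exp_id] = norm
            de = select_differential(norm, design, exp_id, pair=DEFAULT_CONTRASTS[exp_id])
            de_sets[exp_id] = set(de.index[de["passes"]])
        common, _ = intersect_feature_sets(de_sets)
        planted = set.intersection(
            *[truth.true_de(e, DEFAULT_CONTRASTS[e]) for e in matrices]
        )
        sensitivity = len(common & planted) / len(planted)
        fdr = len(common - planted) / max(len(common), 1)
        assert sensitivity >= 0.85  # single-realisation bound; acceptance averages seeds
        assert fdr <= 0.1

        joint = pd.concat([norms[e].values for e in matrices], axis=1)
        profiles = joint.loc[sorted(common)]
        clusters = cluster_kmeans_pearson(profiles, k=5, seed=0)
        markers = []
        for prefix in ("B_", "C_", "D_"):
            markers += [
                f
                for f in truth.cluster_labels.index
                if str(truth.cluster_labels[f]).startswith(prefix)
                and f not in truth.tf_features
            ][:3]
        selected = select_clusters(clusters, markers)
        members = [f for c in selected for f in clusters.members(c)]
        cands = set(extract_tf_candidates(members, profiles, annotation, markers))
        planted_tf = {
            f
            for f in truth.tf_features
            if str(truth.cluster_labels[f]).startswith(("B_", "C_", "D_"))
        }
        assert len(cands & planted_tf) / len(planted_tf) >= 0.8
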