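"""Stage design, Venn partition, Pearson k-means and figure of merit."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tagdge.trajectory import (
    StageDesign,
    cluster_profiles,
    default_design,
    figure_of_merit,
    kmeans_objective,
    kmeans_pearson,
    process_venn,
    select_k,
    standardize_profiles,
    updown_histogram,
)


def fake_de_table(genes, de_genes, directions=None):
    """Minimal DE table: is_de flag plus direction."""
    is_de = [g in de_genes for g in genes]
    if directions is None:
        directions = {g: "up" for g in de_genes}
    return pd.DataFrame(
        {"is_de": is_de, "direction": [directions.get(g, "up") for g in genes]},
        index=genes,
    )


class TestDesign:
    def test_default_covers_all_consecutive_pairs_once(self):
        design = default_design()
        assigned = [c for comps in design.windows.values() for c in comps]
        assert sorted(assigned) == sorted(design.comparisons)

    def test_non_consecutive_comparison_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            StageDesign(stages=("a", "b", "c"), windows={"w": (("a", "c"),)})

    def test_double_assignment_rejected(self):
        with pytest.raises(ValueError, match="two processes"):
            StageDesign(
                stages=("a", "b", "c"),
                windows={"w1": (("a", "b"),), "w2": (("a", "b"),)},
            )


class TestHistogram:
    def test_counts_by_direction(self):
        design = StageDesign(stages=("a", "b"), windows={"w": (("a", "b"),)})
        genes = [f"g{i}" for i in range(10)]
        directions = {g: ("up" if i < 4 else "down")
                      for i, g in enumerate(genes[:7])}
        tables = {("a", "b"): fake_de_table(genes, set(genes[:7]), directions)}
        hist = updown_histogram(tables, design)
        assert hist.loc["a->b", "n_up"] == 4
        assert hist.loc["a->b", "n_down"] == 3

    def test_empty_comparison_gives_zeros(self):
        design = StageDesign(stages=("a", "b"), windows={"w": (("a", "b"),)})
        hist = updown_histogram({("a", "b"): fake_de_table(["g"], set())}, design)
        assert (hist.loc["a->b"] == 0).all()

    def test_missing_comparison_rejected(self):
        with pytest.raises(KeyError):
            updown_histogram({}, default_design())


class TestVenn:
    def _design(self):
        return default_design()

    def _tables_from_membership(self, membership):
        """membership: gene -> set of process names; builds DE tables that
        make each gene DE in the first comparison of each such process."""
        design = self._design()
        genes = sorted(membership)
        tables = {}
        for process, comps in design.windows.items():
            in_process = {g for g, procs in membership.items()
                          if process in procs}
            for i, comp in enumerate(comps):
                tables[comp] = fake_de_table(genes,
                                             in_process if i == 0 else set())
        return tables

    def test_single_process_gene_lands_in_exclusive_region(self):
        tables = self._tables_from_membership({"g": {"transition"}})
        venn = process_venn(tables, self._design())
        assert venn.loc["transition", "n_genes"] == 1
        assert venn.drop("transition")["n_genes"].sum() == 0

    def test_gene_in_all_processes_lands_in_center(self):
        membership = {"g": {"dedifferentiation", "transition", "development"}}
        venn = process_venn(self._tables_from_membership(membership),
                            self._design())
        assert venn.loc["dedifferentiation&transition&development",
                        "n_genes"] == 1

    def test_random_membership_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(59)
        processes = ["dedifferentiation", "transition", "development"]
        membership = {}
        for i in range(500):
            k = int(rng.integers(0, 4))
            membership[f"g{i:03d}"] = set(
                rng.choice(processes, size=k, replace=False))
        venn = process_venn(self._tables_from_membership(membership),
                            self._design())
        # oracle: brute-force region computation
        for size in range(1, 4):
            for combo in itertools.combinations(processes, size):
                expected = sum(
                    1 for procs in membership.values() if set(combo) <= procs
                    and not (procs - set(combo))
                )
                assert venn.loc["&".join(combo), "n_genes"] == expected
        n_any = sum(1 for procs in membership.values() if procs)
        assert venn["n_genes"].sum() == n_any == venn.attrs["n_any_process"]


class TestKMeans:
    def test_identical_profiles_always_co_cluster(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = np.vstack([base, base, base + 10, -base, -base + 4])
        fit = kmeans_pearson(x, 2, seed=0, n_restarts=5)
        labels = fit.labels
        assert labels[0] == labels[1] == labels[2]  # r = 1 group
        assert labels[3] == labels[4]

    def test_anticorrelated_profiles_at_maximal_distance(self):
        u = standardize_profiles(np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]]))
        d = ((u[0] - u[1]) ** 2).sum() / 2  # Pearson distance = 1 - r
        assert d == pytest.approx(2.0)

    def test_zero_variance_profile_neutral(self):
        u = standardize_profiles(np.array([[5.0, 5, 5, 5], [1.0, 2, 3, 4]]))
        assert np.allclose(u[0], 0)  # r = 0 convention -> distance 1

    def test_objective_history_monotone_descent(self):
        rng = np.random.default_rng(61)
        x = rng.normal(size=(40, 9))
        fit = kmeans_pearson(x, 4, seed=3, n_restarts=1)
        assert (np.diff(fit.objective_history) <= 1e-9).all()

    def test_agrees_with_euclidean_kmeans_on_unit_profiles(self):
        """On unit-standardized profiles Pearson k-means is Euclidean
        k-means; an independent solver must reach the same optimum on a
        well-separated instance."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(97)
        templates = [np.linspace(0, 6, 9), np.linspace(6, 0, 9),
                     np.array([0.0, 2, 4, 6, 4, 2, 0, 2, 4])]
        x = np.array([t + rng.normal(0, 0.3, 9)
                      for t in templates for _ in range(15)])
        fit = kmeans_pearson(x, 3, seed=1, n_restarts=10)
        u = standardize_profiles(x)
        ref = KMeans(n_clusters=3, n_init=10, random_state=1).fit(u)
        assert fit.objective == pytest.approx(ref.inertia_, rel=1e-6)

    def test_small_instance_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(67)
        t1 = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8])
        t2 = np.array([4.0, 0, 4, 0, 4, 0, 4, 0, 4])
        x = np.vstack(
            [t1 + rng.normal(0, 0.3, 9) for _ in range(6)]
            + [t2 + rng.normal(0, 0.3, 9) for _ in range(6)]
        )
        fit = kmeans_pearson(x, 2, seed=5, n_restarts=10)
        u = standardize_profiles(x)
        best = min(
            kmeans_objective(u, np.array([(mask >> i) & 1 for i in range(12)]), 2)
            for mask in range(1, 1 << 11)  # non-trivial bipartitions
        )
        assert fit.objective == pytest.approx(best, abs=1e-9)
        assert set(fit.labels[:6]) != set(fit.labels[6:])


class TestFOM:
    def _three_template_data(self, n_per=20, noise=0.3, seed=71):
        rng = np.random.default_rng(seed)
        templates = [
            np.linspace(0, 6, 9),
            np.linspace(6, 0, 9),
            np.array([0.0, 2, 4, 6, 4, 2, 0, 2, 4]),
        ]
        rows = [t + rng.normal(0, noise, 9) for t in templates
                for _ in range(n_per)]
        return np.array(
            [rows[i] for i in rng.permutation(len(rows))]
        )

    def test_knee_detects_three_templates(self):
        x = self._three_template_data()
        k, fom = select_k(x, k_min=2, k_max=6, seed=2)
        assert k == 3
        # margin: big improvement into k=3, small beyond
        assert (fom[2] - fom[3]) / fom[2] >= 0.10
        assert (fom[3] - fom[4]) / fom[3] < 0.10

    def test_near_singleton_clusters_reach_floor(self):
        x = self._three_template_data(n_per=5)
        fom = figure_of_merit(x, [2, 14], seed=4, n_restarts=3)
        assert fom[14] < fom[2] / 2

    def test_deterministic_given_seed(self):
        x = self._three_template_data()
        a = figure_of_merit(x, [2, 3], seed=9, n_restarts=3)
        b = figure_of_merit(x, [2, 3], seed=9, n_restarts=3)
        pd.testing.assert_series_equal(a, b)

    def test_k_not_below_gene_count(self):
        with pytest.raises(ValueError):
            figure_of_merit(np.zeros((5, 9)), [5], seed=0)


class TestClusterProfiles:
    def test_assignments_unique_and_complete(self):
        rng = np.random.default_rng(73)
        tpm = pd.DataFrame(
            2 ** rng.normal(5, 2, size=(40, 9)),
            index=[f"g{i}" for i in range(40)],
            columns=list("abcdefghi"),
        )
        result = cluster_profiles(tpm, k=5, seed=1, subclusters=True)
        assert len(result.assignments) == 40
        assert result.assignments["type"].between(1, 5).all()
        assert result.assignments["subcluster"].ge(1).all()
        assert result.centroids.shape[1] == 9
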