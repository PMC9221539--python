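"""Ensemble dissimilarity, clustering, outlier test, resolution correlation."""

import numpy as np
import pytest

from structvalid.ensemble import (
    DissimilarityMatrix,
    group_comparison,
    hcluster,
    outlier_test,
    pairwise_dissimilarity,
    resolution_correlation,
    split_groups,
)
from structvalid.synthfix import SyntheticEnsembleSpec, make_ensemble

from conftest import ca_structure, rigid_motion


@pytest.fixture(scope="module")
def noisy_ensemble():
    spec = SyntheticEnsembleSpec(n_residues=200, noise_profile=0.3, n_members=6, seed=42)
    return make_ensemble(spec)


class TestPairwiseDissimilarity:
    def test_rigid_copies_all_zero(self):
        coords = np.random.default_rng(0).uniform(-20, 20, size=(30, 3))
        structures = [ca_structure(rigid_motion(coords, seed=i), f"s{i}") for i in range(4)]
        for kind in ("rmsd", "irdm"):
            dm = pairwise_dissimilarity(structures, metric_kind=kind)
            np.testing.assert_allclose(dm.values, 0.0, atol=1e-7)

    def test_symmetric_zero_diagonal_label_order(self, noisy_ensemble):
        base, members, _ = noisy_ensemble
        dm = pairwise_dissimilarity([base] + members[:3], metric_kind="rmsd")
        assert dm.labels == [base.id] + [m.id for m in members[:3]]
        np.testing.assert_allclose(dm.values, dm.values.T)
        np.testing.assert_allclose(np.diag(dm.values), 0.0)

    def test_noise_injection_matches_analytic_expectation(self):
        # member-vs-member RMSD ≈ sqrt(3(σ²+σ²)) for iid coordinate noise
        sigma = 0.5
        spec = SyntheticEnsembleSpec(n_residues=200, noise_profile=sigma, n_members=3, seed=7)
        _, members, _ = make_ensemble(spec)
        dm = pairwise_dissimilarity(members, metric_kind="rmsd")
        expected = np.sqrt(3 * 2 * sigma**2)
        off = dm.values[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, expected, rtol=0.10)

    def test_single_structure_rejected(self, noisy_ensemble):
        base, _, _ = noisy_ensemble
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_dissimilarity([base])


class TestHcluster:
    def _planted(self, gap=20.0, sigma=0.2, seed=0):
        spec = SyntheticEnsembleSpec(
            n_residues=100, noise_profile=sigma, n_members=6, seed=seed,
            apply_rigid_motions=True, group_offsets=[0, 0, 0, gap, gap, gap],
        )
        _, members, _ = make_ensemble(spec)
        return members

    def test_two_planted_groups_recovered(self):
        members = self._planted()
        dm = pairwise_dissimilarity(members, metric_kind="rmsd")
        tree = hcluster(dm)
        heights = tree.linkage_matrix[:, 2]
        cut = (heights[-1] + heights[-2]) / 2
        assign = tree.cut(cut)
        groups = {}
        for label, c in assign.items():
            groups.setdefault(c, set()).add(label)
        assert sorted(map(sorted, groups.values())) == [
            ["member00", "member01", "member02"],
            ["member03", "member04", "member05"],
        ]

    def test_duplicated_structure_one_cluster_at_zero(self):
        coords = np.random.default_rng(1).uniform(-20, 20, size=(30, 3))
        structures = [ca_structure(rigid_motion(coords, seed=i), f"s{i}") for i in range(5)]
        tree = hcluster(pairwise_dissimilarity(structures))
        assert tree.n_clusters_at(1e-6) == 1

    def test_permuted_input_same_partition(self):
        members = self._planted(seed=3)
        dm = pairwise_dissimilarity(members, metric_kind="rmsd")
        perm = [3, 0, 5, 1, 4, 2]
        dm_perm = DissimilarityMatrix(
            labels=[dm.labels[i] for i in perm],
            values=dm.values[np.ix_(perm, perm)],
            metric_kind="rmsd", level="calpha",
        )
        t1, t2 = hcluster(dm), hcluster(dm_perm)
        h = (t1.linkage_matrix[-1, 2] + t1.linkage_matrix[-2, 2]) / 2

        def partition(tree):
            assign = tree.cut(h)
            return {frozenset(l for l, c in assign.items() if c == k) for k in set(assign.values())}

        assert partition(t1) == partition(t2)

    def test_heights_non_decreasing_average_linkage(self, noisy_ensemble):
        base, members, _ = noisy_ensemble
        tree = hcluster(pairwise_dissimilarity([base] + members))
        heights = tree.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_newick_export_parses(self, noisy_ensemble):
        import io

        from Bio import Phylo

        base, members, _ = noisy_ensemble
        tree = hcluster(pairwise_dissimilarity([base] + members[:4]))
        parsed = Phylo.read(io.StringIO(tree.newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted([base.id] + [m.id for m in members[:4]])


class TestGroups:
    def test_split_groups_sizes(self, noisy_ensemble):
        base, members, _ = noisy_ensemble
        dm = pairwise_dissimilarity([base] + members, metric_kind="rmsd")
        af_vals, crystal_vals = split_groups(dm, base.id)
        m = len(members)
        assert len(af_vals) == m
        assert len(crystal_vals) == m * (m - 1) // 2

    def test_group_comparison_detects_separation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.4, 0.05, size=10)
        b = rng.normal(0.7, 0.05, size=15)
        rep = group_comparison(a, b)
        assert rep["median_af_vs_crystal"] < rep["median_within_crystal"]
        assert rep["welch"].p < 0.001

    def test_medians_match_direct_recomputation(self, noisy_ensemble):
        base, members, _ = noisy_ensemble
        dm = pairwise_dissimilarity([base] + members, metric_kind="irdm")
        af_vals, crystal_vals = split_groups(dm, base.id)
        rep = group_comparison(af_vals, crystal_vals)
        assert rep["median_af_vs_crystal"] == pytest.approx(np.median(af_vals))
        assert rep["median_within_crystal"] == pytest.approx(np.median(crystal_vals))


class TestOutlier:
    def test_member_of_tight_group_not_singleton(self):
        spec = SyntheticEnsembleSpec(n_residues=100, noise_profile=0.2, n_members=5, seed=9)
        base, members, _ = make_ensemble(spec)
        dm = pairwise_dissimilarity([base] + members)
        tree = hcluster(dm)
        res = outlier_test(tree, base.id, height=float(tree.linkage_matrix[-1, 2]) + 0.1)
        assert not res["is_singleton"]
        assert len(res["cluster_members"]) == 5

    def test_displaced_member_is_singleton(self):
        spec = SyntheticEnsembleSpec(
            n_residues=100, noise_profile=0.2, n_members=5, seed=11,
            group_offsets=[0, 0, 0, 0, 40.0],
        )
        _, members, _ = make_ensemble(spec)
        dm = pairwise_dissimilarity(members)
        tree = hcluster(dm)
        mid = float(tree.linkage_matrix[-1, 2]) / 2
        res = outlier_test(tree, "member04", height=mid)
        assert res["is_singleton"]

    def test_height_zero_all_singletons(self, noisy_ensemble):
        base, members, _ = noisy_ensemble
        tree = hcluster(pairwise_dissimilarity([base] + members))
        for label in tree.labels:
            assert outlier_test(tree, label, height=0.0)["is_singleton"]

    def test_unknown_label_error(self, noisy_ensemble):
        base, members, _ = noisy_ensemble
        tree = hcluster(pairwise_dissimilarity([base] + members))
        with pytest.raises(ValueError, match="unknown"):
            outlier_test(tree, "nope", 1.0)


class TestResolutionCorrelation:
    def test_noise_growing_with_resolution_gives_high_cc(self):
        resolutions = np.linspace(1.2, 3.2, 8)
        sigma_per_member = 0.15 * resolutions  # deviation grows with resolution
        rng = np.random.default_rng(13)
        base_coords = rng.uniform(-30, 30, size=(150, 3))
        reference = ca_structure(base_coords, "ref", source="crystal")
        members = []
        for i, (res, sig) in enumerate(zip(resolutions, sigma_per_member)):
            noisy = base_coords + rng.normal(scale=sig, size=base_coords.shape)
            members.append(ca_structure(noisy, f"x{i}", source="crystal", resolution=float(res)))
        out = resolution_correlation(members, reference)
        assert out["cc"] > 0.8
        assert out["p"] < 0.01
        assert out["n"] == 8

    def test_constant_noise_near_zero_cc(self):
        rng = np.random.default_rng(17)
        base_coords = rng.uniform(-30, 30, size=(150, 3))
        reference = ca_structure(base_coords, "ref", source="crystal")
        members = []
        for i, res in enumerate(np.linspace(1.2, 3.2, 10)):
            noisy = base_coords + rng.normal(scale=0.4, size=base_coords.shape)
            members.append(ca_structure(noisy, f"x{i}", source="crystal", resolution=float(res)))
        out = resolution_correlation(members, reference)
        assert abs(out["cc"]) < 0.65

    def test_reference_excluded_and_min_points(self):
        rng = np.random.default_rng(19)
        coords = rng.uniform(-20, 20, size=(50, 3))
        reference = ca_structure(coords, "ref", source="crystal", resolution=1.0)
        members = [ca_structure(coords + rng.normal(scale=0.2, size=coords.shape), f"x{i}",
                                source="crystal", resolution=1.5 + i) for i in range(2)]
        with pytest.raises(ValueError, match="at least 3"):
            resolution_correlation(members + [reference], reference)
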