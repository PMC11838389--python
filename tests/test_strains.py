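import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from lumenstrain.io import SNVTable
from lumenstrain.strains import (
    PhasingSiteSet,
    StrainCluster,
    StrainClusterSet,
    anova_eligibility,
    bootstrap_strain_ci,
    estimate_strain_frequencies,
    filter_phasing_sites,
    infer_inoculum_only_strains,
    infer_strain_clusters,
    pairwise_distances,
    partition_strain_variance,
    snv_pair_distance,
)

from _reference import ref_adjacency, ref_distance, ref_greedy_clusters
from conftest import eight_mouse_meta, make_table


def make_siteset(freq, depth, species="spX"):
    freq = np.atleast_2d(np.asarray(freq, dtype=float))
    depth = np.atleast_2d(np.asarray(depth, dtype=float))
    idx = pd.Index([f"s{i:04d}" for i in range(freq.shape[0])], name="site_id")
    cols = [f"smp{j}" for j in range(freq.shape[1])]
    return PhasingSiteSet(
        species,
        pd.DataFrame(freq, index=idx, columns=cols),
        pd.DataFrame(depth, index=idx, columns=cols),
    )


class TestFilterPhasingSites:
    def test_fixed_sites_removed(self):
        depth = np.full((3, 10), 50)
        alt = np.vstack(
            [np.full(10, 50), np.full(10, 0), np.full(10, 25)]
        )
        s = filter_phasing_sites(make_table(depth, alt))
        assert s.site_ids == ["spX|s0002"]

    def test_minor_support_below_four_removed(self):
        depth = np.full((1, 10), 50)
        alt = np.full((1, 10), 3)
        s = filter_phasing_sites(make_table(depth, alt))
        assert s.site_ids == []

    def test_twenty_percent_boundary_inclusive(self):
        depth = np.full((1, 20), 50)
        alt = np.zeros((1, 20), dtype=int)
        alt[0, :4] = 25  # polymorphic in exactly 4 / 20 samples
        s = filter_phasing_sites(make_table(depth, alt))
        assert len(s.site_ids) == 1
        alt[0, 3] = 0  # 3 / 20 < 20%
        s = filter_phasing_sites(make_table(depth, alt))
        assert s.site_ids == []

    def test_low_depth_samples_not_counted(self):
        depth = np.full((1, 10), 9)
        alt = np.full((1, 10), 4)
        s = filter_phasing_sites(make_table(depth, alt))
        assert s.site_ids == []


class TestPairDistance:
    def test_identical_trajectories_zero(self):
        f = [0.3, 0.6, 0.4]
        assert snv_pair_distance(f, f, [20] * 3, [20] * 3) == 0.0

    def test_hand_value(self):
        d = snv_pair_distance([0.3], [0.5], [10], [10], min_overlap=1)
        assert d == pytest.approx(2 * 20 * 0.04 / (0.8 * 1.2), abs=1e-4)

    def test_mirrored_trajectories_zero_after_polarization(self):
        f = np.array([0.2, 0.7, 0.45, 0.9])
        d = snv_pair_distance(f, 1 - f, [30] * 4, [30] * 4)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_overlap_nan(self):
        assert np.isnan(
            snv_pair_distance([0.3, 0.4], [0.5, 0.5], [10, 5], [10, 10])
        )

    def test_zero_denominator_contributes_zero(self):
        d = snv_pair_distance(
            [0.0, 0.3], [0.0, 0.5], [20, 20], [20, 20], min_overlap=1
        )
        expected = (0.0 + 2 * 40 * 0.04 / (0.8 * 1.2)) / 2
        assert d == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.integers(0, 10_000))
    def test_symmetry_and_polarization_invariance(self, seed):
        rng = np.random.default_rng(seed)
        S = 5
        fi, fj = rng.random(S), rng.random(S)
        di, dj = rng.integers(10, 60, S), rng.integers(10, 60, S)
        d_ij = snv_pair_distance(fi, fj, di, dj)
        d_ji = snv_pair_distance(fj, fi, dj, di)
        assert d_ij == pytest.approx(d_ji, rel=1e-9)
        # flipping either trajectory leaves the polarized distance unchanged
        assert snv_pair_distance(1 - fi, fj, di, dj) == pytest.approx(
            d_ij, rel=1e-9
        )
        assert snv_pair_distance(fi, 1 - fj, di, dj) == pytest.approx(
            d_ij, rel=1e-9
        )

    def test_matrix_matches_scalar_reference(self):
        rng = np.random.default_rng(3)
        n, S = 25, 6
        F = rng.random((n, S))
        D = rng.integers(0, 50, (n, S))
        ss = make_siteset(F, D)
        dist, _ = pairwise_distances(ss)
        for i in range(n):
            for j in range(n):
                expected = ref_distance(F[i], F[j], D[i], D[j]) if i != j else 0.0
                if np.isnan(expected):
                    assert np.isnan(dist[i, j])
                else:
                    assert dist[i, j] == pytest.approx(expected, rel=1e-4)


def _random_instance(seed, n_max=50):
    """Random small clustering instance with block structure plus noise."""
    rng = np.random.default_rng(seed)
    n = rng.integers(8, n_max + 1)
    S = rng.integers(4, 9)
    n_blocks = rng.integers(1, 4)
    centers = rng.random((n_blocks, S)) * 0.8 + 0.1
    assign = rng.integers(0, n_blocks, n)
    F = np.clip(centers[assign] + rng.normal(0, 0.07, (n, S)), 0, 1)
    # a few pure-noise rows and random polarization flips
    noise = rng.random(n) < 0.2
    F[noise] = rng.random((noise.sum(), S))
    flips = rng.random(n) < 0.5
    F[flips] = 1 - F[flips]
    D = rng.integers(5, 60, (n, S))
    return F, D


class TestGreedyClustering:
    def test_matches_bruteforce_reference(self):
        for seed in range(20):
            F, D = _random_instance(seed)
            ss = make_siteset(F, D)
            got = infer_strain_clusters(ss, min_cluster=4)
            adj = ref_adjacency(list(F), list(D.astype(float)))
            expected = ref_greedy_clusters(adj, min_cluster=4)
            got_idx = [
                sorted(int(s[1:]) for s in c.site_ids) for c in got.clusters
            ]
            assert got_idx == expected, f"seed {seed}"

    def test_invariant_under_site_order_permutation(self):
        rng = np.random.default_rng(5)
        F, D = _random_instance(17)
        ss = make_siteset(F, D)
        a = infer_strain_clusters(ss, min_cluster=4)
        perm = rng.permutation(len(F))
        shuffled = PhasingSiteSet(
            "spX", ss.freq.iloc[perm].sort_index(), ss.depth.iloc[perm].sort_index()
        )
        b = infer_strain_clusters(shuffled, min_cluster=4)
        assert [c.site_ids for c in a.clusters] == [c.site_ids for c in b.clusters]

    def test_clusters_disjoint_and_min_size(self):
        F, D = _random_instance(23)
        ss = make_siteset(F, D)
        out = infer_strain_clusters(ss, min_cluster=4)
        seen = set()
        for c in out.clusters:
            assert c.size >= 4
            assert not (set(c.site_ids) & seen)
            seen |= set(c.site_ids)

    def test_empty_siteset_zero_clusters(self):
        ss = make_siteset(np.zeros((0, 4)), np.zeros((0, 4)))
        assert infer_strain_clusters(ss).n_clusters == 0

    def test_mean_focal_mode_merges_split_cluster(self):
        # one mutation class with high per-SNV variance: same mean trajectory,
        # individual SNVs scattered around it
        rng = np.random.default_rng(2)
        n, S = 60, 10
        center = np.linspace(0.25, 0.75, S)
        F = np.clip(center + rng.normal(0, 0.10, (n, S)), 0.02, 0.98)
        D = np.full((n, S), 40)
        ss = make_siteset(F, D)
        out = infer_strain_clusters(ss, min_cluster=30, mode="mean_focal")
        assert out.n_clusters == 1
        assert out.clusters[0].size >= 50


class TestStrainFrequencies:
    def _cluster_set(self, site_ids, polarity=None):
        polarity = polarity or {s: False for s in site_ids}
        return StrainClusterSet(
            "spX",
            [StrainCluster(site_ids, polarity, focal=site_ids[0])],
            min_cluster=1,
        )

    def test_constant_cluster_frequency(self):
        n = 120
        F = np.full((n, 2), 0.42)
        D = np.full((n, 2), 30)
        ss = make_siteset(F, D)
        prof = estimate_strain_frequencies(
            self._cluster_set(ss.site_ids), ss, n_boot=100
        )
        row = prof.frame[
            (prof.frame.sample_id == "smp0") & (prof.frame.strain_index == 0)
        ].iloc[0]
        assert row["freq"] == pytest.approx(0.42)
        assert row["reported"]
        comp = prof.frame[
            (prof.frame.sample_id == "smp0") & (prof.frame.strain_index == 1)
        ].iloc[0]
        assert comp["freq"] == pytest.approx(0.58)

    def test_polarity_correction_applied(self):
        F = np.vstack([np.full((60, 1), 0.3), np.full((60, 1), 0.7)])
        D = np.full((120, 1), 30)
        ss = make_siteset(F, D)
        polarity = {s: i >= 60 for i, s in enumerate(ss.site_ids)}
        prof = estimate_strain_frequencies(
            self._cluster_set(ss.site_ids, polarity), ss, n_boot=100
        )
        assert prof.frame.iloc[0]["freq"] == pytest.approx(0.3)

    def test_support_gate_at_hundred_snvs(self):
        F = np.full((99, 1), 0.4)
        D = np.full((99, 1), 30)
        ss = make_siteset(F, D)
        prof = estimate_strain_frequencies(
            self._cluster_set(ss.site_ids), ss, n_boot=50
        )
        assert not prof.frame.iloc[0]["reported"]

    def test_low_depth_snvs_not_counted_as_support(self):
        F = np.full((150, 1), 0.4)
        D = np.vstack([np.full((120, 1), 30), np.full((30, 1), 9)])
        ss = make_siteset(F, D)
        prof = estimate_strain_frequencies(
            self._cluster_set(ss.site_ids), ss, n_boot=50
        )
        assert prof.frame.iloc[0]["n_support"] == 120

    def test_multi_cluster_frequencies_not_identified(self):
        F = np.hstack(
            [np.full((300, 1), 0.2), np.full((300, 1), 0.5)]
        )
        rng = np.random.default_rng(0)
        F = F + rng.normal(0, 0.01, F.shape)
        D = np.full((300, 2), 40)
        ss = make_siteset(F, D)
        ids = ss.site_ids
        clusters = StrainClusterSet(
            "spX",
            [
                StrainCluster(ids[:150], {s: False for s in ids[:150]}, ids[0]),
                StrainCluster(ids[150:], {s: False for s in ids[150:]}, ids[150]),
            ],
            min_cluster=1,
        )
        prof = estimate_strain_frequencies(clusters, ss, n_boot=50)
        assert prof.n_clusters == 2 and not prof.frequencies_identified
        assert set(prof.frame["strain_index"]) == {0, 1}


class TestBootstrapCI:
    def test_constant_values_zero_width(self):
        lo, hi = bootstrap_strain_ci(np.full(200, 0.37), seed=0)
        assert lo == hi == pytest.approx(0.37)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        vals = rng.binomial(40, 0.3, 500) / 40
        lo, hi = bootstrap_strain_ci(vals, seed=2)
        assert lo <= vals.mean() <= hi

    def test_deterministic_under_seed(self):
        vals = np.random.default_rng(0).random(300)
        assert bootstrap_strain_ci(vals, seed=9) == bootstrap_strain_ci(
            vals, seed=9
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_strain_ci([])


class TestInoculumOnlyFallback:
    def _table(self, n_poly, freq=0.25, depth=40, n_mono=50):
        n = n_poly + n_mono
        d = np.full((n, 1), depth)
        alt = np.zeros((n, 1), dtype=int)
        alt[:n_poly, 0] = int(round(freq * depth))
        t = make_table(d, alt)
        t.depth.columns = ["inoculum"]
        t.alt.columns = ["inoculum"]
        return t

    def test_below_snv_threshold_single_strain(self):
        prof = infer_inoculum_only_strains(
            self._table(999), "inoculum", min_snvs=1000
        )
        assert prof.source == "inoculum_single"
        assert len(prof.frame) == 1 and prof.frame.iloc[0]["freq"] == 1.0

    def test_two_strains_at_mean_minor_frequency(self):
        prof = infer_inoculum_only_strains(
            self._table(1200, freq=0.25), "inoculum", min_snvs=1000, seed=1
        )
        assert prof.source == "inoculum_only"
        freqs = sorted(prof.frame["freq"])
        assert freqs[0] == pytest.approx(0.25, abs=0.01)
        assert freqs[1] == pytest.approx(0.75, abs=0.01)

    def test_minor_strain_colonization_failure_scenario(self):
        # inoculum polymorphic at ~0.3; mouse samples fixed: clustering sees
        # nothing, the fallback still reports two inoculum strains
        rng = np.random.default_rng(4)
        n = 1500
        depth = np.full((n, 6), 40)
        alt = np.column_stack(
            [rng.binomial(40, 0.3, n)] + [np.zeros(n, dtype=int)] * 5
        )
        t = make_table(depth, alt)
        t.depth.columns = t.alt.columns = ["inoculum"] + [
            f"m1_{r}" for r in ("duodenum", "jejunum", "ileum", "cecum", "colon")
        ]
        sites = filter_phasing_sites(t)
        clusters = infer_strain_clusters(sites, min_cluster=1000)
        assert clusters.n_clusters == 0
        prof = infer_inoculum_only_strains(t, "inoculum", seed=0)
        assert prof.source == "inoculum_only"
        assert prof.frame.iloc[0]["freq"] == pytest.approx(0.3, abs=0.02)


class TestVariancePartition:
    def _freqs(self, fn):
        samples = eight_mouse_meta()
        return (
            pd.Series(
                {
                    s.sample_id: fn(s)
                    for s in samples
                    if not s.is_inoculum
                }
            ),
            samples,
        )

    def test_cage_only_variation(self):
        freqs, samples = self._freqs(
            lambda s: {"c1": 0.3, "c2": 0.6, "c3": 0.8}[s.cage_id]
        )
        vp = partition_strain_variance(freqs, samples)
        assert vp.fractions["cage"] == pytest.approx(1.0, abs=1e-9)
        assert vp.fractions["gut_region"] == pytest.approx(0.0, abs=1e-9)

    def test_half_frequency_everywhere_degenerate(self):
        freqs, samples = self._freqs(lambda s: 0.5)
        vp = partition_strain_variance(freqs, samples)
        assert vp.degenerate and "zero variance" in vp.reason

    def test_components_sum_to_one(self):
        rng = np.random.default_rng(0)
        freqs, samples = self._freqs(lambda s: rng.uniform(0.2, 0.8))
        vp = partition_strain_variance(freqs, samples)
        assert sum(vp.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in vp.fractions.values())

    def test_known_sigma_ordering(self):
        # strong mouse effect, weak region effect -> mouse >> region
        rng = np.random.default_rng(7)
        samples = eight_mouse_meta()
        mouse_eff = {f"m{i}": rng.normal(0, 1.0) for i in range(1, 9)}
        freqs = pd.Series(
            {
                s.sample_id: 1 / (1 + np.exp(-(mouse_eff[s.mouse_id]
                                               + rng.normal(0, 0.05))))
                for s in samples
                if not s.is_inoculum
            }
        )
        vp = partition_strain_variance(freqs, samples)
        assert vp.fractions["cage"] + vp.fractions["mouse"] > 0.9
        assert vp.fractions["gut_region"] < 0.05

    def test_eligibility_rules(self):
        samples = eight_mouse_meta()
        meta = pd.DataFrame(
            [
                {"cage_id": s.cage_id, "mouse_id": s.mouse_id,
                 "gut_region": s.gut_region}
                for s in samples
                if not s.is_inoculum
            ]
        )
        ok, _ = anova_eligibility(meta)
        assert ok
        one_cage = meta[meta["cage_id"] == "c1"]
        ok, reason = anova_eligibility(one_cage)
        assert not ok and "cages" in reason
        one_region = meta[meta["gut_region"] == "colon"]
        ok, reason = anova_eligibility(one_region)
        assert not ok
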