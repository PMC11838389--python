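import numpy as np
import pandas as pd
import pytest

from lumenstrain.evolution import (
    QPCall,
    bootstrap_change_rates,
    calibrate_qp_threshold_from_truth,
    call_qp_samples,
    detect_all_changes,
    detect_snv_changes,
    load_calibration,
    pair_category,
    summarize_unique_changes,
)
from lumenstrain.io import SampleMeta
from lumenstrain.simulate import (
    ColonizationConfig,
    CommunityConfig,
    SequencingConfig,
    generate_truth,
    render_observations,
)

from conftest import make_table


def _meta(sample_id, mouse, cage, region):
    return SampleMeta(sample_id, mouse, cage, region)


M_A = _meta("m1_colon", "m1", "c1", "colon")
M_B = _meta("m1_cecum", "m1", "c1", "cecum")
M_C = _meta("m2_colon", "m2", "c1", "colon")
M_D = _meta("m4_colon", "m4", "c2", "colon")
M_I = SampleMeta("inoculum", "inoculum", None, "inoculum")


class TestCalibration:
    def test_truth_passthrough(self):
        truth = generate_truth(
            CommunityConfig(n_species=2, pairwise_divergence=[1000, 10_000]),
            ColonizationConfig(),
            seed=0,
        )
        cal = calibrate_qp_threshold_from_truth(truth)
        assert cal == {"species_01": 1000.0, "species_02": 10_000.0}

    def test_load_calibration_rejects_nonpositive(self, tmp_path):
        p = tmp_path / "cal.tsv"
        p.write_text("species_id\tdivergence\nspA\t0\n")
        with pytest.raises(ValueError):
            load_calibration(p)

    def test_missing_species_skipped_with_reason(self):
        t = make_table(np.full((10, 1), 30), np.zeros((10, 1)))
        calls = call_qp_samples(t, {"other_species": 1000.0})
        assert not calls[0].is_qp
        assert "calibration" in calls[0].reason


class TestQPCalls:
    def _table(self, n_intermediate, n_total=2000, depth=30):
        alt = np.zeros((n_total, 1), dtype=int)
        alt[:n_intermediate, 0] = depth // 2  # f = 0.5
        return make_table(np.full((n_total, 1), depth), alt)

    @pytest.mark.parametrize(
        "n_inter, expected_qp", [(400, True), (500, True), (501, False)]
    )
    def test_ten_percent_threshold_arithmetic(self, n_inter, expected_qp):
        calls = call_qp_samples(self._table(n_inter), {"spX": 5000.0})
        call = calls[0]
        assert call.threshold == 500.0
        assert call.n_intermediate == n_inter
        assert call.is_qp is expected_qp

    def test_median_depth_gate(self):
        calls = call_qp_samples(self._table(0, depth=19), {"spX": 5000.0})
        assert not calls[0].is_qp

    def test_genotype_assigns_both_orientations(self):
        depth = np.full((3, 1), 40)
        alt = np.array([[38], [1], [20]])  # f = 0.95, 0.025, 0.5
        calls = call_qp_samples(make_table(depth, alt), {"spX": 5000.0})
        g = calls[0].genotype
        assert g["spX|s0000"] == 1 and g["spX|s0001"] == 0
        assert "spX|s0002" not in g.index  # intermediate: not phaseable

    def test_mixture_dominance_boundary(self):
        # a 60:40 strain mixture leaves most divergent sites intermediate;
        # an 85:15 mixture leaves them outside (0.2, 0.8) except through noise
        def qp_for(mix):
            comm = CommunityConfig(
                n_species=1, strains_per_species=2, pairwise_divergence=2000,
                inoculum_strain_freqs=[mix],
            )
            truth = generate_truth(comm, ColonizationConfig(), seed=5)
            tables, _ = render_observations(
                truth, SequencingConfig(mean_depth=100.0), seed=5
            )
            cal = calibrate_qp_threshold_from_truth(truth)
            calls = call_qp_samples(
                tables["species_01"], cal, samples=["inoculum"]
            )
            return calls[0]

        assert not qp_for((0.6, 0.4)).is_qp
        assert qp_for((0.85, 0.15)).is_qp


class TestPairCategory:
    def test_exhaustive_and_exclusive(self):
        assert pair_category(M_A, M_B) == ("within_host", False)
        assert pair_category(M_A, M_C) == ("between_host", True)
        assert pair_category(M_A, M_D) == ("between_host", False)
        assert pair_category(M_A, M_I) == ("inoculum_vs_host", False)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            pair_category(M_A, M_A)


def _qp(sample_id, species="spX"):
    return QPCall(species, sample_id, True, 30.0, 0, 100.0)


class TestDetectChanges:
    def _pair_table(self, fa, fb, da=30, db=30):
        fa, fb = np.atleast_1d(fa), np.atleast_1d(fb)
        da = np.full(fa.shape, da)
        db = np.full(fb.shape, db)
        depth = np.column_stack([da, db])
        alt = np.column_stack(
            [np.round(fa * da).astype(int), np.round(fb * db).astype(int)]
        )
        t = make_table(depth, alt)
        t.depth.columns = t.alt.columns = ["m1_colon", "m1_cecum"]
        return t

    def test_extreme_change_detected(self):
        t = self._pair_table([0.1], [0.9])
        res = detect_snv_changes(t, _qp("m1_colon"), _qp("m1_cecum"), M_A, M_B)
        assert res.n_changes == 1 and res.n_loci == 1

    def test_partial_rise_not_a_change(self):
        t = self._pair_table([0.1], [0.7])
        res = detect_snv_changes(t, _qp("m1_colon"), _qp("m1_cecum"), M_A, M_B)
        assert res.n_changes == 0

    def test_depth_ratio_rule_within_mouse_only(self):
        t = self._pair_table([0.1], [0.9], da=25, db=80)
        within = detect_snv_changes(
            t, _qp("m1_colon"), _qp("m1_cecum"), M_A, M_B
        )
        assert within.n_loci == 0 and within.n_changes == 0
        t2 = self._pair_table([0.1], [0.9], da=25, db=80)
        t2.depth.columns = t2.alt.columns = ["m1_colon", "m2_colon"]
        between = detect_snv_changes(
            t2, _qp("m1_colon"), _qp("m2_colon"), M_A, M_C
        )
        assert between.n_changes == 1

    def test_low_coverage_loci_not_candidates(self):
        t = self._pair_table([0.1], [0.9], da=19, db=30)
        res = detect_snv_changes(t, _qp("m1_colon"), _qp("m1_cecum"), M_A, M_B)
        assert res.n_loci == 0

    def test_symmetric_in_sample_order(self):
        rng = np.random.default_rng(0)
        fa, fb = rng.random(50), rng.random(50)
        t = self._pair_table(fa, fb)
        r1 = detect_snv_changes(t, _qp("m1_colon"), _qp("m1_cecum"), M_A, M_B)
        r2 = detect_snv_changes(t, _qp("m1_cecum"), _qp("m1_colon"), M_B, M_A)
        assert {c.site_id for c in r1.changes} == {c.site_id for c in r2.changes}

    def test_pair_cap_flags_distinct_strains(self):
        fa = np.full(60, 0.05)
        fb = np.full(60, 0.95)
        t = self._pair_table(fa, fb)
        res = detect_snv_changes(t, _qp("m1_colon"), _qp("m1_cecum"), M_A, M_B)
        assert res.excluded and res.n_changes == 60

    def test_non_qp_sample_rejected(self):
        t = self._pair_table([0.1], [0.9])
        bad = QPCall("spX", "m1_colon", False, 30.0, 999, 100.0)
        with pytest.raises(ValueError):
            detect_snv_changes(t, bad, _qp("m1_cecum"), M_A, M_B)


class TestSummarize:
    def _setup(self):
        # one site swept high in mice from two cages, observable vs inoculum
        samples = [M_I, M_A, M_D]
        depth = np.full((2, 3), 40)
        alt = np.array([[2, 36, 38], [0, 0, 0]])  # site 0: 0.05 -> 0.9 / 0.95
        t = make_table(depth, alt)
        t.depth.columns = t.alt.columns = ["inoculum", "m1_colon", "m4_colon"]
        calls = call_qp_samples(t, {"spX": 1000.0})
        pairs = detect_all_changes(t, calls, samples)
        return t, samples, pairs

    def test_parallel_cage_count_and_sgv(self):
        t, samples, pairs = self._setup()
        uniq = summarize_unique_changes(pairs, {"spX": t}, samples)
        assert len(uniq) == 1
        row = uniq.iloc[0]
        assert row["parallel_cage_count"] == 2 and row["parallel"]
        assert row["sgv"] == "true"
        assert row["inoculum_freq"] == pytest.approx(0.05)

    def test_sgv_unknown_at_low_inoculum_depth(self):
        t, samples, _ = self._setup()
        # shallow inoculum: its pairs lose the site, but a between-host
        # contrast (m1 at 0.9 vs m4 at 0.05) still carries the change
        t.depth.loc["spX|s0000", "inoculum"] = 15
        t.alt.loc["spX|s0000", "inoculum"] = 1
        t.alt.loc["spX|s0000", "m4_colon"] = 2
        pairs = detect_all_changes(
            t, call_qp_samples(t, {"spX": 1000.0}), samples
        )
        uniq = summarize_unique_changes(pairs, {"spX": t}, samples)
        assert uniq.iloc[0]["sgv"] == "unknown"

    def test_excluded_pairs_contribute_nothing(self):
        t, samples, pairs = self._setup()
        for p in pairs:
            p.excluded = True
        uniq = summarize_unique_changes(pairs, {"spX": t}, samples)
        assert uniq.empty


class TestRateBootstrap:
    def _pair(self, category, n_changes, n_loci, same_cage=False):
        from lumenstrain.evolution import PairResult, SNVChange

        changes = [
            SNVChange("spX", f"s{i}", "a", "b", 0.1, 0.9, 30, 30, category, "syn")
            for i in range(n_changes)
        ]
        return PairResult("spX", "a", "b", category, same_cage, n_loci, changes)

    def test_zero_changes_ci_lower_zero(self):
        pairs = [self._pair("within_host", 0, 1000) for _ in range(10)]
        rates = bootstrap_change_rates(pairs, n_boot=200, seed=0)
        r = rates["within_host"]
        assert r.rate == 0.0 and r.ci_lo == 0.0 and r.ci_hi == 0.0

    def test_identical_pairs_zero_width_ci(self):
        pairs = [self._pair("between_host", 2, 1000) for _ in range(10)]
        rates = bootstrap_change_rates(pairs, n_boot=200, seed=0)
        r = rates["between_host"]
        assert r.rate == pytest.approx(0.002)
        assert r.ci_lo == r.ci_hi == pytest.approx(0.002)

    def test_within_cage_category_is_same_cage_subset(self):
        pairs = [
            self._pair("between_host", 5, 1000, same_cage=True),
            self._pair("between_host", 0, 1000, same_cage=False),
        ]
        rates = bootstrap_change_rates(pairs, n_boot=100, seed=0)
        assert rates["between_host"].n_pairs == 2
        assert rates["within_cage_between_host"].n_pairs == 1
        assert rates["within_cage_between_host"].rate == pytest.approx(0.005)

    def test_excluded_pairs_ignored(self):
        good = self._pair("between_host", 1, 1000)
        bad = self._pair("between_host", 60, 1000)
        bad.excluded = True
        rates = bootstrap_change_rates([good, bad], n_boot=100, seed=0)
        assert rates["between_host"].total_changes == 1

    def test_empty_category_omitted(self):
        pairs = [self._pair("between_host", 1, 100)]
        rates = bootstrap_change_rates(pairs, n_boot=50, seed=0)
        assert "within_host" not in rates

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        pairs = [
            self._pair("between_host", int(rng.integers(0, 4)), 500)
            for _ in range(30)
        ]
        a = bootstrap_change_rates(pairs, seed=11)["between_host"]
        b = bootstrap_change_rates(pairs, seed=11)["between_host"]
        assert (a.ci_lo, a.ci_hi) == (b.ci_lo, b.ci_hi)
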