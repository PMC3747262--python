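import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tilemeth as tm
from tilemeth.errors import DomainError

from .conftest import brute_force_bh, brute_force_rank_sum


class TestPartitionRegions:
    def test_even_partition(self):
        design = tm.simulate_design([("L", "chr1", 0, 3000)], 100)
        regions, assignment = tm.partition_regions(design, 1000)
        assert len(regions) == 3
        assert regions["n_probes"].tolist() == [10, 10, 10]
        assert assignment.nunique() == 3

    def test_truncated_last_window(self):
        design = tm.simulate_design([("L", "chr1", 0, 2500)], 100)
        regions, _ = tm.partition_regions(design, 1000)
        assert len(regions) == 3
        last = regions.iloc[-1]
        assert (last["start"], last["end"]) == (2000, 2500)
        assert last["n_probes"] == 5

    def test_probes_per_full_region_at_study_spacing(self):
        design = tm.simulate_design([("L", "chr1", 0, 10_000)], 100)
        regions, _ = tm.partition_regions(design, 1000)
        assert (regions["n_probes"] == 10).all()

    def test_small_regions_untestable(self):
        design = tm.simulate_design([("L", "chr1", 0, 1200)], 100)
        regions, _ = tm.partition_regions(design, 1000, min_probes=3)
        assert regions["testable"].tolist() == [True, False]

    def test_windows_anchored_at_locus_start(self):
        design = tm.simulate_design([("L", "chr5", 7_300, 2000)], 100)
        regions, _ = tm.partition_regions(design, 1000)
        assert regions["start"].tolist() == [7_300, 8_300]


class TestRegionRankSum:
    def test_worked_exact_case(self):
        """Three region scores above all 7 background scores: one-sided
        p = 1/C(10,3) = 1/120, doubled to ~0.0167, upward direction."""
        p, direction = tm.region_rank_sum([3.1, 3.4, 2.9], [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        assert p == pytest.approx(2.0 / 120.0)
        assert direction == "up"

    def test_all_ties_give_p_one(self):
        p, _ = tm.region_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_negation_flips_direction_keeps_p(self):
        rng = np.random.default_rng(3)
        region = rng.normal(1, 1, 4)
        background = rng.normal(0, 1, 9)
        p1, d1 = tm.region_rank_sum(region, background)
        p2, d2 = tm.region_rank_sum(-region, -background)
        assert p1 == pytest.approx(p2)
        assert {d1, d2} == {"up", "down"}

    def test_empty_sets_rejected(self):
        with pytest.raises(DomainError):
            tm.region_rank_sum([], [1.0])

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        n_region=st.integers(1, 6),
        n_background=st.integers(1, 8),
        values=st.data(),
    )
    def test_exact_path_matches_brute_force_enumeration(self, n_region, n_background, values):
        """For every split with <= 12 probes the DP-based exact test equals
        exhaustive enumeration of all rank assignments (ties included)."""
        total = n_region + n_background
        if total > 12:
            n_background = 12 - n_region
            total = 12
        # draw from a small grid to provoke ties
        scores = values.draw(
            st.lists(
                st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0, -1.0]),
                min_size=total,
                max_size=total,
            )
        )
        region = np.array(scores[:n_region])
        background = np.array(scores[n_region:])
        p_up, p_down = brute_force_rank_sum(region, background)
        expected = min(1.0, 2.0 * min(p_up, p_down))
        p, _ = tm.region_rank_sum(region, background)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        """Just above the exact-enumeration cutoff the normal approximation
        with continuity correction tracks the exact p closely."""
        rng = np.random.default_rng(5)
        region = rng.normal(0.8, 1, 6)
        background = rng.normal(0, 1, 22)
        p_exact, _ = tm.region_rank_sum(region, background, exact_limit=30)
        p_norm, _ = tm.region_rank_sum(region, background, exact_limit=10)
        assert p_norm == pytest.approx(p_exact, rel=0.2, abs=0.01)


class TestBHFdr:
    def test_hand_case(self):
        np.testing.assert_allclose(tm.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(tm.bh_fdr([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(tm.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            tm.bh_fdr([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=50)
    )
    def test_matches_brute_force_reference(self, p_values):
        np.testing.assert_allclose(
            tm.bh_fdr(p_values), brute_force_bh(p_values), atol=1e-12
        )

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(11)
        p = np.sort(rng.uniform(size=40))
        q = tm.bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()


def _stats_table(design, values):
    """Helper: fake per-probe contrast statistics keyed to a design."""
    return pd.DataFrame(
        {
            "probe_id": design["probe_id"],
            "lfc": values["lfc"],
            "t_mod": values["t_mod"],
            "p_t": values["p_t"],
        }
    )


class TestCallRegions:
    def _setup(self, region_t=4.0, region_lfc=0.6, region_p=0.01):
        design = tm.simulate_design([("L", "chr1", 0, 10_000)], 100)
        rng = np.random.default_rng(0)
        n = len(design)
        t_mod = rng.normal(0, 1, n)
        lfc = rng.normal(0, 0.05, n)
        p_t = np.full(n, 0.5)
        # region 3 carries a strong consistent signal
        mask = (design["start"] >= 3000) & (design["start"] < 4000)
        t_mod[mask] = region_t
        lfc[mask] = region_lfc
        p_t[mask] = region_p
        stats = _stats_table(design, {"lfc": lfc, "t_mod": t_mod, "p_t": p_t})
        regions, assignment = tm.partition_regions(design, 1000)
        return stats, regions, assignment

    def test_strong_region_called_with_direction(self):
        stats, regions, assignment = self._setup()
        calls = tm.call_regions(stats, regions, assignment).set_index("region_id")
        assert calls.loc["L_r0003", "called"]
        assert calls.loc["L_r0003", "direction"] == "higher_in_A"
        assert calls.loc["L_r0003", "n_sig_probes"] == 10

    def test_fdr_threshold_blocks_call(self):
        stats, regions, assignment = self._setup()
        thr = tm.CallingThresholds(region_fdr_max=0.0)
        calls = tm.call_regions(stats, regions, assignment, thr)
        assert not calls["called"].any()

    def test_probe_lfc_rule_blocks_call(self):
        """A region with significant rank-sum but sub-threshold probe effect
        sizes must not be called."""
        stats, regions, assignment = self._setup(region_lfc=0.10)
        calls = tm.call_regions(stats, regions, assignment).set_index("region_id")
        assert calls.loc["L_r0003", "q_region"] < 0.2
        assert not calls.loc["L_r0003", "called"]

    def test_fdr_relaxation_is_monotone(self):
        stats, regions, assignment = self._setup()
        tight = tm.call_regions(
            stats, regions, assignment, tm.CallingThresholds(region_fdr_max=0.1)
        )
        loose = tm.call_regions(
            stats, regions, assignment, tm.CallingThresholds(region_fdr_max=0.2)
        )
        tight_called = set(tight.loc[tight["called"], "region_id"])
        loose_called = set(loose.loc[loose["called"], "region_id"])
        assert tight_called <= loose_called

    def test_locus_relabeling_invariance(self):
        stats, regions, assignment = self._setup()
        calls1 = tm.call_regions(stats, regions, assignment)
        renamed_regions = regions.assign(locus_id=regions["locus_id"].map({"L": "ZZZ"}))
        calls2 = tm.call_regions(stats, renamed_regions, assignment)
        np.testing.assert_allclose(calls1["p_region"], calls2["p_region"])
        assert (calls1["called"] == calls2["called"]).all()

    def test_probe_order_invariance(self):
        stats, regions, assignment = self._setup()
        rng = np.random.default_rng(8)
        shuffled = stats.sample(frac=1.0, random_state=3).reset_index(drop=True)
        calls1 = tm.call_regions(stats, regions, assignment).set_index("region_id")
        calls2 = tm.call_regions(shuffled, regions, assignment).set_index("region_id")
        np.testing.assert_allclose(calls1["p_region"], calls2["p_region"])


class TestPipelines:
    def test_planted_dmrs_recovered_with_direction(self, planted_matrix):
        matrix, sheet, truth = planted_matrix
        calls = tm.run_contrast_pipeline(
            matrix, tm.GroupDesign.from_sample_sheet(sheet), truth.design
        ).set_index("region_id")
        assert calls.loc["L1_r0005", "called"]
        assert calls.loc["L1_r0005", "direction"] == "higher_in_A"
        assert calls.loc["L2_r0010", "called"]
        assert calls.loc["L2_r0010", "direction"] == "higher_in_B"

    def test_phenotype_linked_region_recovered(self, planted_matrix):
        matrix, sheet, truth = planted_matrix
        phenotype = tm.simulate_phenotype(truth)
        calls = tm.run_correlation_pipeline(
            matrix, phenotype, "IL6", truth.design
        ).set_index("region_id")
        assert calls.loc["L1_r0005", "called"]
        assert calls.loc["L1_r0005", "direction"] == "positive"

    def test_pipeline_deterministic(self, planted_matrix):
        matrix, sheet, truth = planted_matrix
        gd = tm.GroupDesign.from_sample_sheet(sheet)
        c1 = tm.run_contrast_pipeline(matrix, gd, truth.design)
        c2 = tm.run_contrast_pipeline(matrix, gd, truth.design)
        pd.testing.assert_frame_equal(c1, c2)
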