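import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmrscape import (ClusterPolicy, call_dmrs, cluster_dms, filter_dmrs,
                      score_cluster, threshold_subset_check)
from conftest import random_dms


def _dms(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "direction",
                                       "meth_diff", "p_value", "q_value"])


class TestClusterDms:
    def test_nearby_same_direction_sites_form_one_cluster(self):
        dms = _dms([("chr1", 100, "hypo", -0.4, 1e-4, 1e-3),
                    ("chr1", 400, "hypo", -0.3, 1e-4, 1e-3),
                    ("chr1", 900, "hypo", -0.5, 1e-4, 1e-3)])
        (cluster,) = cluster_dms(dms, ClusterPolicy())
        assert len(cluster) == 3
        assert cluster["pos"].iloc[0] == 100 and cluster["pos"].iloc[-1] == 900

    def test_direction_change_breaks_cluster(self):
        dms = _dms([("chr1", 100, "hypo", -0.4, 1e-4, 1e-3),
                    ("chr1", 400, "hyper", 0.3, 1e-4, 1e-3),
                    ("chr1", 700, "hypo", -0.5, 1e-4, 1e-3)])
        assert cluster_dms(dms, ClusterPolicy()) == []

    def test_large_gap_breaks_cluster(self):
        dms = _dms([("chr1", 100, "hypo", -0.4, 1e-4, 1e-3),
                    ("chr1", 1200, "hypo", -0.3, 1e-4, 1e-3),
                    ("chr1", 2300, "hypo", -0.5, 1e-4, 1e-3)])
        assert cluster_dms(dms, ClusterPolicy(max_gap=1000)) == []

    def test_gap_exactly_max_gap_is_merged(self):
        dms = _dms([("chr1", 0, "hypo", -0.4, 1e-4, 1e-3),
                    ("chr1", 1000, "hypo", -0.3, 1e-4, 1e-3),
                    ("chr1", 2000, "hypo", -0.5, 1e-4, 1e-3)])
        (cluster,) = cluster_dms(dms, ClusterPolicy(max_gap=1000))
        assert len(cluster) == 3

    def test_unsorted_input_rejected(self):
        dms = _dms([("chr1", 400, "hypo", -0.4, 1e-4, 1e-3),
                    ("chr1", 100, "hypo", -0.3, 1e-4, 1e-3)])
        with pytest.raises(ValueError, match="sorted"):
            cluster_dms(dms, ClusterPolicy())


class TestScoreCluster:
    def test_matches_stouffer_oracle(self):
        cluster = _dms([("chr1", i, "hypo", -0.4, 0.01, 0.05)
                        for i in (100, 200, 300)])
        # independent oracle: scipy's one-sided Stouffer combination,
        # two-sided via the symmetric tail
        one_sided = stats.combine_pvalues([0.01] * 3, method="stouffer").pvalue
        expected = min(2 * min(one_sided, 1 - one_sided), 1.0)
        assert score_cluster(cluster) == pytest.approx(expected, rel=1e-10)

    def test_null_members_combine_to_one(self):
        cluster = _dms([("chr1", 100, "hypo", -0.1, 0.5, 0.6),
                        ("chr1", 200, "hypo", -0.1, 0.5, 0.6)])
        assert score_cluster(cluster) == pytest.approx(1.0)

    def test_zero_p_clamped_not_crashing(self):
        cluster = _dms([("chr1", 100, "hypo", -0.4, 0.0, 0.0),
                        ("chr1", 200, "hypo", -0.4, 0.0, 0.0)])
        assert 0 <= score_cluster(cluster) < 1e-30

    def test_appending_strong_member_never_weakens(self):
        # appending a member at least as significant as the current best
        # cannot increase the combined p (checked over exhaustive small cases)
        for base in ([0.3, 0.2], [0.05, 0.04, 0.03], [0.4, 0.4, 0.1, 0.1]):
            cluster = _dms([("chr1", 100 * (i + 1), "hypo", -0.4, p, p)
                            for i, p in enumerate(base)])
            before = score_cluster(cluster)
            extended = _dms([("chr1", 100 * (i + 1), "hypo", -0.4, p, p)
                             for i, p in enumerate(base + [min(base)])])
            assert score_cluster(extended) <= before + 1e-12


class TestFilterDmrs:
    def _cluster(self, diffs, p=1e-5):
        return _dms([("chr1", 100 + 10 * i, "hypo" if d < 0 else "hyper", d, p, p)
                     for i, d in enumerate(diffs)])

    def test_diff_threshold_pair(self):
        cluster = self._cluster([-0.30, -0.30, -0.30])
        kept = filter_dmrs([cluster], ClusterPolicy(min_abs_diff=0.25))
        dropped = filter_dmrs([cluster], ClusterPolicy(min_abs_diff=0.35))
        assert len(kept) == 1 and kept["direction"].iloc[0] == "hypo"
        assert dropped.empty

    def test_exact_threshold_is_inclusive(self):
        cluster = self._cluster([0.25, 0.25, 0.25])
        kept = filter_dmrs([cluster], ClusterPolicy(min_abs_diff=0.25))
        assert len(kept) == 1

    def test_insignificant_cluster_dropped_regardless_of_diff(self):
        cluster = self._cluster([-0.9, -0.9, -0.9], p=0.45)
        assert filter_dmrs([cluster], ClusterPolicy()).empty

    def test_interval_covers_last_dyad(self):
        cluster = self._cluster([-0.4, -0.4, -0.4])
        (row,) = filter_dmrs([cluster], ClusterPolicy()).itertuples(index=False)
        assert row.start == 100 and row.end == 120 + 2


class TestThresholdSubset:
    def test_same_run_sets_are_nested(self):
        rng = np.random.default_rng(0)
        dms = random_dms(rng, n=60)
        dms = dms.sort_values("pos", kind="stable").reset_index(drop=True)
        lenient = call_dmrs(dms, ClusterPolicy(min_abs_diff=0.25))
        strict = call_dmrs(dms, ClusterPolicy(min_abs_diff=0.35))
        assert threshold_subset_check(lenient, strict)

    def test_disjoint_sets_fail(self):
        a = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10,
                           "direction": "hypo", "n_dms": 3}])
        b = pd.DataFrame([{"chrom": "chr2", "start": 0, "end": 10,
                           "direction": "hypo", "n_dms": 3}])
        assert not threshold_subset_check(a, b)

    def test_empty_strict_set_passes_vacuously(self):
        a = pd.DataFrame(columns=["chrom", "start", "end", "direction", "n_dms"])
        assert threshold_subset_check(a, a)


class TestInvariants:
    def test_dmr_count_monotone_in_policy(self):
        rng = np.random.default_rng(3)
        dms = random_dms(rng, n=80).sort_values("pos").reset_index(drop=True)
        dms["p_value"] = rng.uniform(1e-8, 1e-3, size=len(dms))
        base = len(call_dmrs(dms, ClusterPolicy()))
        assert len(call_dmrs(dms, ClusterPolicy(min_abs_diff=0.35))) <= base
        assert len(call_dmrs(dms, ClusterPolicy(min_dms=5))) <= base
        assert len(call_dmrs(dms, ClusterPolicy(max_gap=300))) <= base

    def test_same_direction_dmrs_do_not_overlap(self):
        rng = np.random.default_rng(4)
        dms = random_dms(rng, n=100).sort_values("pos").reset_index(drop=True)
        dms["p_value"] = 1e-6
        dmrs = call_dmrs(dms, ClusterPolicy())
        for direction in ("hypo", "hyper"):
            sub = dmrs[dmrs["direction"] == direction].sort_values("start")
            starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
            assert all(starts[i + 1] >= ends[i] for i in range(len(sub) - 1))
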