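from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from dmrscape import (STATE_GROUPS, STATE_TO_GROUP, cgi_overlap, dominant_state,
                      group_states, prom_chrom_width, shore_overlap, tf_overlap)
from dmrscape.overlap import TIE_PRECEDENCE
from oracle_utils import brute_cgi_fraction, brute_dominant, brute_shore_mask, \
    per_base_group_counts


def _seg(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _dmr(start, end, chrom="chr1"):
    return SimpleNamespace(chrom=chrom, start=start, end=end)


class TestGroupStates:
    @pytest.mark.parametrize("state,group", [
        (1, "Prom"), (2, "WkProm"), (3, "PromEnh"), (4, "WkProm"),
        (5, "Txn"), (6, "Txn"), (7, "EnhG"), (8, "EnhG"),
        (9, "EnhA"), (10, "EnhA"), (11, "WkEnh"),
        (12, "Repr"), (13, "Repr"), (17, "Repr"), (18, "Low"),
    ])
    def test_full_18_to_9_mapping(self, state, group):
        assert STATE_TO_GROUP[state] == group

    def test_adjacent_same_group_segments_merge(self):
        grouped = group_states(_seg([("chr1", 0, 100, 7), ("chr1", 100, 250, 8)]))
        assert len(grouped) == 1
        assert grouped.iloc[0]["group"] == "EnhG"
        assert grouped.iloc[0]["end"] == 250

    def test_state_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..18"):
            group_states(_seg([("chr1", 0, 100, 19)]))


class TestDominantState:
    def test_fully_contained_dmr(self):
        grouped = group_states(_seg([("chr1", 0, 5000, 5)]))
        dom, fracs = dominant_state(_dmr(1000, 2000), grouped)
        assert dom == "Txn" and fracs["Txn"] == 1.0

    def test_tie_broken_by_precedence(self):
        grouped = group_states(_seg([("chr1", 0, 500, 1), ("chr1", 500, 1000, 13)]))
        dom, _ = dominant_state(_dmr(0, 1000), grouped)
        assert dom == "Prom"

    def test_uncovered_bases_count_as_low(self):
        grouped = group_states(_seg([("chr1", 0, 100, 1)]))
        dom, fracs = dominant_state(_dmr(0, 1000), grouped)
        assert dom == "Low"
        assert fracs["Low"] == pytest.approx(0.9)

    def test_fractions_sum_to_one(self):
        grouped = group_states(_seg([("chr1", 100, 300, 1), ("chr1", 300, 450, 9),
                                     ("chr1", 600, 900, 13)]))
        _, fracs = dominant_state(_dmr(50, 1000), grouped)
        assert sum(fracs.values()) == pytest.approx(1.0)

    def test_matches_per_base_oracle_on_random_tracks(self):
        rng = np.random.default_rng(17)
        length = 5000
        for _ in range(200):
            cuts = np.sort(rng.choice(np.arange(1, length), size=8, replace=False))
            bounds = [0, *cuts.tolist(), length]
            segs, oracle_segs = [], []
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                if rng.random() < 0.3:
                    continue  # leave uncovered stretches
                state = int(rng.integers(1, 19))
                segs.append(("chr1", lo, hi, state))
                oracle_segs.append((lo, hi, STATE_TO_GROUP[state]))
            grouped = group_states(_seg(segs)) if segs else _seg([]).assign(group=[])
            s = int(rng.integers(0, length - 100))
            e = s + int(rng.integers(50, 1500))
            dom, fracs = dominant_state(_dmr(s, min(e, length)), grouped)
            labels = per_base_group_counts(length, oracle_segs)
            odom, ofracs = brute_dominant(s, min(e, length), labels, TIE_PRECEDENCE)
            assert dom == odom
            for g in STATE_GROUPS:
                assert fracs[g] == pytest.approx(ofracs[g])


class TestCgiOverlap:
    def test_exact_30_percent_is_flagged(self):
        frac, flag = cgi_overlap(_dmr(0, 1000), _bed([("chr1", 700, 2000, "c")]))
        assert frac == pytest.approx(0.30) and flag

    def test_no_cgi_on_chromosome(self):
        frac, flag = cgi_overlap(_dmr(0, 1000), _bed([("chr2", 0, 100, "c")]))
        assert frac == 0.0 and not flag

    def test_dmr_inside_cgi(self):
        frac, flag = cgi_overlap(_dmr(100, 200), _bed([("chr1", 0, 1000, "c")]))
        assert frac == 1.0 and flag

    def test_invariant_to_cgi_splitting(self):
        whole = _bed([("chr1", 100, 900, "c")])
        split = _bed([("chr1", 100, 400, "a"), ("chr1", 400, 900, "b")])
        assert cgi_overlap(_dmr(0, 1000), whole) == cgi_overlap(_dmr(0, 1000), split)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(23)
        length = 10000
        for _ in range(200):
            cgis = []
            for _ in range(rng.integers(0, 4)):
                s = int(rng.integers(0, length - 500))
                cgis.append(("chr1", s, s + int(rng.integers(100, 1500)), "c"))
            s = int(rng.integers(0, length - 200))
            e = s + int(rng.integers(100, 2000))
            frac, _ = cgi_overlap(_dmr(s, e), _bed(cgis))
            expected = brute_cgi_fraction(s, e, [(a, b) for _, a, b, _ in cgis],
                                          length + 2000)
            assert frac == pytest.approx(expected)


class TestShoreOverlap:
    def test_left_shore_hit(self):
        assert shore_overlap(_dmr(500, 900), _bed([("chr1", 1000, 2000, "c")]))

    def test_inside_cgi_is_not_shore(self):
        assert not shore_overlap(_dmr(1200, 1400), _bed([("chr1", 1000, 2000, "c")]))

    def test_inter_cgi_gap_counts_once(self):
        cgis = _bed([("chr1", 1000, 2000, "a"), ("chr1", 3000, 4000, "b")])
        assert shore_overlap(_dmr(2400, 2600), cgis)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(29)
        length = 20000
        for _ in range(200):
            ivs = []
            for _ in range(rng.integers(1, 4)):
                s = int(rng.integers(2500, length - 3000))
                ivs.append((s, s + int(rng.integers(200, 1500))))
            cgis = _bed([("chr1", s, e, "c") for s, e in ivs])
            s = int(rng.integers(0, length - 100))
            e = s + int(rng.integers(50, 1200))
            mask = brute_shore_mask(ivs, length + 3000)
            assert shore_overlap(_dmr(s, e), cgis) == bool(mask[s:e].any())


class TestTfOverlap:
    def test_per_factor_flags(self):
        sites = {"MYOD": _bed([("chr1", 100, 300, "m")]),
                 "CTCF": _bed([("chr1", 5000, 5200, "c")])}
        flags = tf_overlap(_dmr(200, 400), sites)
        assert flags == {"MYOD": True, "CTCF": False}

    def test_no_sites_all_false(self):
        flags = tf_overlap(_dmr(0, 100), {"MYOD": _bed([])})
        assert flags == {"MYOD": False}

    def test_abutting_halfopen_site_is_no_overlap(self):
        flags = tf_overlap(_dmr(0, 100), {"MYOD": _bed([("chr1", 100, 200, "m")])})
        assert flags == {"MYOD": False}


class TestPromChromWidth:
    def _gene(self, tss=10000):
        return SimpleNamespace(chrom="chr1", tss=tss)

    def test_single_broad_segment(self):
        grouped = group_states(_seg([("chr1", 9500, 13000, 1)]))
        width, cls = prom_chrom_width(self._gene(), grouped)
        assert width == 3500 and cls == "broad"

    def test_bridged_gap_counts_in_width(self):
        grouped = group_states(_seg([("chr1", 8000, 9000, 1),
                                     ("chr1", 9100, 10000, 1)]))
        width, cls = prom_chrom_width(self._gene(), grouped)
        assert width == 2000 and cls == "standard"

    def test_very_broad_class(self):
        grouped = group_states(_seg([("chr1", 8000, 13000, 1)]))
        width, cls = prom_chrom_width(self._gene(), grouped)
        assert width == 5000 and cls == "very_broad"

    def test_no_promoter_chromatin(self):
        grouped = group_states(_seg([("chr1", 0, 1000, 13)]))
        assert prom_chrom_width(self._gene(), grouped) == (0, "none")
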