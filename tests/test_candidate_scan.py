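"""Site filtering, seed distances and candidate pairing (workflow steps I-II)."""

import random

import pytest

from triplexkit.candidate_scan import (
    extract_window,
    filter_sites,
    group_sites_by_transcript,
    pair_sites,
    seed_distance,
)
from triplexkit.io_model import CoordinateError, OrderingError

from conftest import make_site


class TestFilterSites:
    def test_mirsvr_boundary_is_inclusive(self):
        kept = filter_sites([make_site(10, mirsvr=-0.1)])
        assert len(kept) == 1

    def test_above_threshold_dropped(self):
        assert filter_sites([make_site(10, mirsvr=-0.05)]) == []

    def test_permissive_settings_are_identity(self):
        sites = [make_site(10, mirsvr=5.0), make_site(30, mirsvr=-0.5)]
        assert filter_sites(sites, mirsvr_max=float("inf"), conserved_only=False) == sites

    def test_nonconserved_mirna_dropped_when_required(self):
        sites = [make_site(10, mirna_id="miR-a"), make_site(30, mirna_id="miR-b")]
        kept = filter_sites(sites, mirna_conservation={"miR-a": False, "miR-b": True})
        assert [s.mirna_id for s in kept] == ["miR-b"]


class TestSeedDistance:
    def test_gap_metric(self):
        a = make_site(94, 100)
        b = make_site(114, 120)
        assert seed_distance(a, b) == 13

    def test_adjacent_seeds_have_distance_zero(self):
        assert seed_distance(make_site(94, 100), make_site(101, 107)) == 0

    def test_start_to_start_metric(self):
        assert seed_distance(make_site(50), make_site(80), metric="start_to_start") == 30

    def test_overlapping_seeds_raise(self):
        with pytest.raises(OrderingError):
            seed_distance(make_site(50), make_site(52))


def _utr(n=400):
    return "A" * n


class TestPairSites:
    def bundle(self, seed_starts, mirna_ids=None):
        sites = [
            make_site(s, mirna_id=(mirna_ids[i] if mirna_ids else f"miR-{i}"))
            for i, s in enumerate(seed_starts)
        ]
        return group_sites_by_transcript(sites)

    def test_distance_13_pairs(self):
        grouped = self.bundle([50, 70])  # gap = 70 - 56 - 1 = 13
        assert len(pair_sites(grouped, {"T1": _utr()})) == 1

    def test_distance_36_does_not_pair(self):
        grouped = self.bundle([50, 93])  # gap = 36
        assert pair_sites(grouped, {"T1": _utr()}) == []

    def test_homotypic_pair_kept(self):
        grouped = self.bundle([50, 80], mirna_ids=["miR-20a", "miR-20a"])
        cands = pair_sites(grouped, {"T1": _utr()})
        assert len(cands) == 1
        assert cands[0].upstream_site.mirna_id == cands[0].downstream_site.mirna_id

    def test_four_mutually_in_range_sites_give_six_candidates(self):
        # brute-force expectation: all C(4,2) ordered pairs are in range
        grouped = self.bundle([50, 70, 90, 110])  # consecutive gaps 13 each
        cands = pair_sites(grouped, {"T1": _utr()}, d_min=0, d_max=60)
        assert len(cands) == 6

    def test_matches_brute_force_on_random_fixtures(self):
        rng = random.Random(1234)
        for _ in range(30):
            starts = sorted(rng.sample(range(10, 350, 9), rng.randint(2, 7)))
            sites = [make_site(s, mirna_id=f"m{i}") for i, s in enumerate(starts)]
            d_min, d_max = sorted((rng.randint(0, 40), rng.randint(0, 40)))
            got = pair_sites(
                group_sites_by_transcript(sites), {"T1": _utr()}, d_min=d_min, d_max=d_max
            )
            expected = 0
            for i in range(len(sites)):
                for j in range(len(sites)):
                    a, b = sites[i], sites[j]
                    if a.seed_end < b.seed_start and d_min <= (
                        b.seed_start - a.seed_end - 1
                    ) <= d_max:
                        expected += 1
            assert len(got) == expected

    def test_widening_range_never_removes_candidates(self):
        grouped = self.bundle([50, 70, 100, 140])
        narrow = pair_sites(grouped, {"T1": _utr()}, d_min=13, d_max=35)
        wide = pair_sites(grouped, {"T1": _utr()}, d_min=0, d_max=80)
        narrow_keys = {(c.upstream_site.seed_start, c.downstream_site.seed_start) for c in narrow}
        wide_keys = {(c.upstream_site.seed_start, c.downstream_site.seed_start) for c in wide}
        assert narrow_keys <= wide_keys

    def test_windows_contain_both_seed_intervals(self):
        grouped = self.bundle([50, 70, 90])
        for c in pair_sites(grouped, {"T1": _utr()}, d_min=0, d_max=60):
            lo = c.window_offset
            hi = c.window_offset + len(c.window_seq) - 1
            for site in (c.upstream_site, c.downstream_site):
                assert lo <= site.seed_start <= site.seed_end <= hi


class TestExtractWindow:
    def test_window_spans_both_sites(self):
        utr = "ACGU" * 30
        a = make_site(13, 19, pad=3)  # site [10, 22]
        b = make_site(53, 59, pad=3)  # site [50, 62]
        window, offset = extract_window(utr, a, b)
        assert offset == 10
        assert len(window) == 62 - 10 + 1
        assert window == utr[9:62]

    def test_flank_clips_at_utr_start(self):
        utr = "ACGU" * 30
        a = make_site(4, 10, pad=3)  # site starts at position 1
        b = make_site(30, 36, pad=3)
        window, offset = extract_window(utr, a, b, flank=5)
        assert offset == 1

    def test_window_round_trips_to_utr_positions(self):
        utr = "".join("ACGU"[(i * 7) % 4] for i in range(200))
        a, b = make_site(40), make_site(90)
        window, offset = extract_window(utr, a, b, flank=4)
        for idx in range(len(window)):
            assert window[idx] == utr[idx + offset - 1]

    def test_site_outside_utr_raises(self):
        with pytest.raises(CoordinateError):
            extract_window("ACGU" * 5, make_site(10), make_site(40))
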