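"""Persistence fractions, filters, residue counts, native-fraction series."""

import numpy as np
import pandas as pd
import pytest

from cardkit import synth
from cardkit.interactions import InteractionRecord, detect_trajectory
from cardkit.structures import ResidueKey
from cardkit.persistence import (persistence, report_filter, type_heatmap,
                                 residue_counts, key_residues,
                                 native_reference_from_complex,
                                 native_fraction_series, NativeReferenceSet,
                                 DegenerateReferenceError)


def rec(frame, a, b, itype="salt_bridge"):
    ka = ResidueKey("A", a, "", "ASP")
    kb = ResidueKey("B", b, "", "ARG")
    return InteractionRecord(frame, (ka, kb), itype, ("OD1", "NH1"), 3.0)


class TestPersistence:
    def test_fraction_is_frames_over_total(self):
        records = [rec(f, 1, 1) for f in range(90)]
        table = persistence(records, n_frames=100)
        assert table.per_type["fraction"].tolist() == [0.90]

    def test_summed_fraction_can_exceed_one(self):
        records = ([rec(f, 1, 1, "hbond") for f in range(100)]
                   + [rec(f, 1, 1, "salt_bridge") for f in range(100)])
        table = persistence(records, n_frames=100)
        assert table.pair_sum["summed_fraction"].tolist() == [2.0]

    def test_duplicate_records_in_frame_count_once(self):
        records = [rec(0, 1, 1), rec(0, 1, 1)]
        table = persistence(records, n_frames=10)
        assert table.per_type["fraction"].tolist() == [0.1]

    def test_matches_brute_force_set_counting(self, rng):
        records = [rec(int(rng.integers(50)), int(rng.integers(3)) + 1,
                       int(rng.integers(3)) + 1,
                       ("hbond", "salt_bridge")[int(rng.integers(2))])
                   for _ in range(400)]
        table = persistence(records, n_frames=50)
        for row in table.per_type.itertuples(index=False):
            frames = {r.frame_index for r in records
                      if str(r.pair[0]) == row.pairA
                      and str(r.pair[1]) == row.pairB and r.itype == row.type}
            assert row.fraction == pytest.approx(len(frames) / 50)

    def test_order_invariance(self, rng):
        records = [rec(int(rng.integers(20)), 1, 1) for _ in range(100)]
        t1 = persistence(records, 20)
        t2 = persistence(list(reversed(records)), 20)
        pd.testing.assert_frame_equal(t1.per_type, t2.per_type)


class TestReportFilter:
    def test_strictly_above_threshold(self):
        records = ([rec(f, 1, 1) for f in range(10)]          # exactly 0.10
                   + [rec(f, 2, 2) for f in range(11)])       # 0.11
        table = persistence(records, n_frames=100)
        kept = report_filter(table, 0.10).per_type
        assert kept["pairA"].tolist() == ["A:ASP2"]

    def test_empty_table_stays_empty(self):
        table = persistence([], n_frames=10)
        assert report_filter(table).per_type.empty


class TestHeatmap:
    def test_counts_conserved_and_binned(self):
        records = [rec(f, 1, 1) for f in range(10)]
        heat = type_heatmap(records, times_ns=np.arange(10) * 3.0,
                            bin_width_ns=3.0, total_time_ns=30.0)
        assert heat.counts.to_numpy().sum() == 10
        assert (heat.counts["salt_bridge"] > 0).sum() == 10

    def test_all_records_in_first_bin(self):
        records = [rec(0, 1, 1, t) for t in ("hbond", "salt_bridge")]
        heat = type_heatmap(records, times_ns=[0.0, 3.0], bin_width_ns=3.0,
                            total_time_ns=6.0)
        assert heat.counts.iloc[0].sum() == 2
        assert heat.counts.iloc[1:].to_numpy().sum() == 0

    def test_zero_records_all_zero(self):
        heat = type_heatmap([], times_ns=[0.0], bin_width_ns=3.0,
                            total_time_ns=9.0)
        assert heat.counts.to_numpy().sum() == 0


class TestResidueCounts:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["pairA", "pairB", "type", "fraction"])
        from cardkit.persistence import PersistenceTable
        return PersistenceTable(per_type=df, n_frames=100)

    def test_pair_with_two_types_counts_twice(self):
        t = self._table([("A:ASP1", "B:ARG1", "hbond", 0.5),
                         ("A:ASP1", "B:ARG1", "salt_bridge", 0.9)])
        counts = residue_counts([t])
        assert dict(zip(counts.residue, counts["count"])) == {
            "A:ASP1": 2, "B:ARG1": 2}

    def test_triplicate_triples_counts(self):
        t = self._table([("A:ASP1", "B:ARG1", "salt_bridge", 0.9)])
        counts = residue_counts([t, t, t])
        assert counts["count"].tolist() == [3, 3]

    def test_conservation_total_is_twice_rows(self, rng):
        rows = [(f"A:ASP{rng.integers(5)}", f"B:ARG{rng.integers(5)}",
                 ("hbond", "hydrophobic")[rng.integers(2)],
                 float(rng.uniform(0.2, 1.0))) for _ in range(30)]
        # deduplicate (pair, type) keys as a real table would be
        rows = list({(a, b, t): (a, b, t, f) for a, b, t, f in rows}.values())
        t = self._table(rows)
        counts = residue_counts([t])
        assert counts["count"].sum() == 2 * len(rows)

    def test_display_filter_applied_before_counting(self):
        t = self._table([("A:ASP1", "B:ARG1", "hbond", 0.05)])
        assert residue_counts([t]).empty


class TestKeyResidues:
    def test_strict_threshold(self):
        counts = pd.DataFrame({"residue": ["A:ASP1", "A:TYR2"], "count": [5, 6]})
        assert key_residues(counts, 5) == {"A:TYR2"}

    def test_empty(self):
        assert key_residues(pd.DataFrame(columns=["residue", "count"])) == set()


class TestNativeFraction:
    def test_reference_extraction_matches_planted_contacts(self, mixed_dimer):
        ref = native_reference_from_complex(mixed_dimer.frame, {"A"}, {"B"})
        assert ref.pairs == {(a, b) for a, b, _ in mixed_dimer.contact_pairs}

    def test_far_separated_reference_raises(self):
        dimer = synth.build_dimer(synth.DimerSpec(contacts=()))
        with pytest.raises(DegenerateReferenceError):
            native_reference_from_complex(dimer.frame, {"A"}, {"B"})

    def test_exact_reproduction_gives_100(self, mixed_dimer):
        ref = native_reference_from_complex(mixed_dimer.frame, {"A"}, {"B"})
        from cardkit.interactions import detect_interactions
        records = detect_interactions(mixed_dimer.frame, {"A"}, {"B"})
        series = native_fraction_series(records, ref, [0.0], n_frames=1)
        assert series.percent[0] == 100.0

    def test_no_records_gives_0(self, mixed_dimer):
        ref = native_reference_from_complex(mixed_dimer.frame, {"A"}, {"B"})
        series = native_fraction_series([], ref, [0.0], n_frames=1)
        assert series.percent[0] == 0.0

    def test_step_schedule_ground_truth(self, mixed_dimer):
        """Breaking k of N planted contacts at frame f steps the series."""
        n = len(mixed_dimer.contact_pairs)            # 5 planted
        schedules = (("break_at", 10), ("break_at", 10)) + (True,) * (n - 2)
        traj, present = synth.build_trajectory(
            mixed_dimer, synth.TrajectorySpec(n_frames=20, schedules=schedules,
                                              seed=11))
        records = detect_trajectory(traj, {"A"}, {"B"})
        ref = native_reference_from_complex(mixed_dimer.frame, {"A"}, {"B"})
        series = native_fraction_series(records, ref, traj.times, n_frames=20)
        expected = np.where(np.arange(20) < 10, 100.0, 100.0 * (n - 2) / n)
        assert np.array_equal(series.percent, expected)

    def test_one_sided_mode_counts_groupA_residues(self, mixed_dimer):
        pairs = {(a, b) for a, b, _ in mixed_dimer.contact_pairs}
        ref = NativeReferenceSet(pairs=pairs, mode="one_sided_groupA")
        from cardkit.interactions import detect_interactions
        records = detect_interactions(mixed_dimer.frame, {"A"}, {"B"})
        series = native_fraction_series(records, ref, [0.0], n_frames=1)
        assert series.percent[0] == 100.0
        # a groupA residue contacting ANY partner counts
        one = [r for r in records if r.pair[0] == mixed_dimer.contact_pairs[0][0]]
        series1 = native_fraction_series(one, ref, [0.0], n_frames=1)
        assert series1.percent[0] == pytest.approx(100.0 / len(ref.groupA_residues))
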