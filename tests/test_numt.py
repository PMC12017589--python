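"""NUMT unwrapping, merging, clustering, frequency classes and dating."""

import numpy as np
import pytest

from pigpan import numt as nt
from pigpan.core import GenomicInterval
from pigpan.numt import ClockParameters, Hit, NUMTRecord


def _hit(q_start, q_end, s_start=None, s_end=None, subject="nchr1"):
    if s_start is None:
        s_start, s_end = 10_000, 10_000 + (q_end - q_start)
    return Hit("mt2", subject, 99.0, q_start, q_end, s_start, s_end)


class TestUnwrap:
    def test_second_copy_shifts_down(self):
        (h,) = nt.unwrap_doubled_hits([_hit(16_010, 16_110)], 16_000)
        assert (h.q_start, h.q_end) == (10, 110)
        assert not h.wraps_junction

    def test_junction_spanning_hit_flagged(self):
        (h,) = nt.unwrap_doubled_hits([_hit(15_950, 16_050)], 16_000)
        assert h.wraps_junction
        ivs = nt.mt_intervals_of(h, 16_000)
        assert [(iv.start, iv.end) for iv in ivs] == [(15_950, 16_000), (0, 50)]

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        hits = []
        for _ in range(50):
            s = int(rng.integers(0, 30_000))
            hits.append(_hit(s, s + int(rng.integers(60, 1500))))
        once = nt.unwrap_doubled_hits(hits, 16_000)
        twice = nt.unwrap_doubled_hits(once, 16_000)
        assert [(h.q_start, h.q_end, h.wraps_junction) for h in once] == [
            (h.q_start, h.q_end, h.wraps_junction) for h in twice
        ]

    def test_hit_longer_than_circle_is_error(self):
        with pytest.raises(ValueError, match="longer"):
            nt.unwrap_doubled_hits([_hit(0, 17_000)], 16_000)


class TestMergeHits:
    def test_gap_rule(self):
        near = [_hit(0, 100, 10_000, 10_100), _hit(200, 300, 10_600, 10_700)]
        far = [_hit(0, 100, 10_000, 10_100), _hit(200, 300, 15_600, 15_700)]
        assert len(nt.merge_hits_to_numts(near, 16_000, max_gap=1000)) == 1
        assert len(nt.merge_hits_to_numts(far, 16_000, max_gap=1000)) == 2

    def test_single_hit_single_numt(self):
        (rec,) = nt.merge_hits_to_numts([_hit(5, 105, 20_000, 20_100)], 16_000)
        assert rec.size == 100
        assert (rec.nuclear.start, rec.nuclear.end) == (20_000, 20_100)


class TestClusterAcrossAssemblies:
    def _rec(self, start, end, mt_start=100):
        return NUMTRecord(
            nuclear=GenomicInterval("nchr1", start, end),
            mt_intervals=[GenomicInterval("MT", mt_start, mt_start + end - start)],
            presence=np.asarray([True]),
            assemblies=["self"],
        )

    def test_shared_numt_collapses_with_full_frequency(self):
        per = {f"a{i}": [self._rec(50_000, 50_600)] for i in range(19)}
        (rec,) = nt.cluster_across_assemblies(per)
        assert rec.frequency == 1.0 and rec.n_present == 19

    def test_assembly_unique_numt_is_private(self):
        per = {f"a{i}": [] for i in range(19)}
        per["a0"] = [self._rec(50_000, 50_600)]
        (rec,) = nt.cluster_across_assemblies(per)
        nt.classify_numt_frequency([rec])
        assert rec.frequency == pytest.approx(1 / 19)
        assert rec.freq_class == "private"

    def test_distinct_mt_origins_stay_separate(self):
        per = {
            "a0": [self._rec(50_000, 50_600, mt_start=100)],
            "a1": [self._rec(50_050, 50_650, mt_start=9_000)],
        }
        assert len(nt.cluster_across_assemblies(per)) == 2

    def test_simulated_presence_matrix_recovered(self, numt_landscape_small):
        data, truth = numt_landscape_small
        per = {}
        for name, hits in data["hit_tables"].items():
            unwrapped = nt.unwrap_doubled_hits(hits, data["mt_length"])
            per[name] = nt.merge_hits_to_numts(unwrapped, data["mt_length"])
        records = nt.cluster_across_assemblies(per)
        assert len(records) == len(truth.ages)
        by_start = {r.nuclear.start: r for r in records}
        for i, (_, s, _) in enumerate(truth.nuclear_intervals):
            assert (by_start[s].presence == truth.presence[i]).all()


class TestFrequencyClasses:
    def test_private_takes_precedence_over_rare(self):
        rec = NUMTRecord(
            nuclear=GenomicInterval("nchr1", 0, 100),
            mt_intervals=[GenomicInterval("MT", 0, 100)],
            presence=np.array([True] + [False] * 18),
            assemblies=[f"a{i}" for i in range(19)],
        )
        nt.classify_numt_frequency([rec])
        assert rec.freq_class == "private"  # F = 0.053 < 0.1 but presence = 1

    def test_published_style_summary_percentages(self):
        # 902 common / 40 rare / 314 private of 1256 records
        summary = nt.numt_frequency_summary({"common": 902, "rare": 40, "private": 314})
        assert summary["percent"]["common"] == 71.82


class TestAgeEstimation:
    def _record(self, size=100):
        return NUMTRecord(
            nuclear=GenomicInterval("nchr1", 0, size),
            mt_intervals=[GenomicInterval("MT", 0, size)],
            presence=np.asarray([True]),
            assemblies=["a"],
        )

    def test_formula_endpoints(self):
        clock = ClockParameters()
        # 12 diagnostic sites, all matching modern -> age 0
        modern = "A" * 12 + "C" * 88
        outgroup = "G" * 12 + "C" * 88
        rec = self._record()
        assert nt.estimate_numt_age(rec, clock, modern, modern, outgroup) == pytest.approx(0.0)
        assert (rec.d, rec.m) == (12, 12)
        # all matching the outgroup -> full divergence time
        rec2 = self._record()
        assert nt.estimate_numt_age(rec2, clock, outgroup, modern, outgroup) == pytest.approx(9.7)

    def test_half_matching_gives_midpoint_age(self):
        clock = ClockParameters()
        modern = "A" * 12 + "C" * 88
        outgroup = "G" * 12 + "C" * 88
        numt = "A" * 6 + "G" * 6 + "C" * 88
        rec = self._record()
        age = nt.estimate_numt_age(rec, clock, numt, modern, outgroup)
        assert (rec.d, rec.m) == (12, 6)
        assert age == pytest.approx(9.7 * 0.5)  # 4.85 MY

    def test_no_diagnostic_sites_undefined(self):
        rec = self._record()
        assert nt.estimate_numt_age(rec, ClockParameters(), "A" * 100, "A" * 100, "A" * 100) is None
        assert rec.d == 0 and rec.age is None

    def test_size_band_excludes_long_records(self):
        rec = self._record(size=1500)
        out = nt.estimate_numt_age(
            rec, ClockParameters(), "A" * 1500, "C" * 1500, "G" * 1500
        )
        assert out is None

    def test_simulated_ages_recovered(self, numt_landscape_small):
        data, truth = numt_landscape_small
        per = {}
        for name, hits in data["hit_tables"].items():
            unwrapped = nt.unwrap_doubled_hits(hits, data["mt_length"])
            per[name] = nt.merge_hits_to_numts(unwrapped, data["mt_length"])
        records = nt.cluster_across_assemblies(per)
        clock = ClockParameters()
        by_start = {r.nuclear.start: r for r in records}
        errors = []
        for i, (_, s, e) in enumerate(truth.nuclear_intervals):
            rec = by_start[s]
            asm = [a for a, p in zip(rec.assemblies, rec.presence) if p][0]
            seq = data["assemblies"][asm]["nchr1"][s:e]
            iv = rec.mt_intervals[0]
            age = nt.estimate_numt_age(
                rec, clock, seq,
                data["modern_mt"][iv.start : iv.end],
                data["outgroup_mt"][iv.start : iv.end],
            )
            assert age is not None
            errors.append(abs(age - truth.ages[i]))
        assert np.mean(np.asarray(errors) <= 1.0) >= 0.8


class TestAgeClasses:
    def _dated(self, ages):
        out = []
        for a in ages:
            rec = NUMTRecord(
                nuclear=GenomicInterval("nchr1", 0, 100),
                mt_intervals=[], presence=np.asarray([True]), assemblies=["a"],
            )
            rec.age = a
            out.append(rec)
        return out

    def test_boundary_is_strictly_less_than(self):
        out = nt.age_classes(self._dated([2.0, 5.3, 5.29, 9.0]))
        assert out["younger"] == 2 and out["older"] == 2

    def test_pliocene_epoch_binning(self):
        out = nt.age_classes(self._dated([2.0, 2.5, 4.0, 5.3, 6.0]))
        assert out["epochs"]["Pliocene"] == 2  # 2.5 and 4.0 in [2.5, 5.3)
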