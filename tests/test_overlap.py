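"""Overlap log-odds enrichment, matched controls, derived chromatin maps."""
import numpy as np
import pytest

from endosig.intervals import GenomicInterval, RegionSet
from endosig.overlap import (
    AnnotationTrack,
    cross_track_overlap,
    derived_chromatin_maps,
    overlap_log_odds,
    sample_matched_control,
)

from conftest import GENOME, bitmap, bitmap_overlaps, random_region_set


class TestMatchedControl:
    def test_all_lengths_equal_query_median(self, rng):
        query = random_region_set(rng, 31)
        med = int(round(float(np.median(query.lengths()))))
        ctrl = sample_matched_control(query, GENOME, 500, seed=1)
        assert set(ctrl.lengths()) == {med}
        assert len(ctrl) == 500

    def test_chrom_counts_proportional_to_length(self, rng):
        query = random_region_set(rng, 20)
        ctrl = sample_matched_control(query, GENOME, 10_000, seed=2)
        total = sum(GENOME.values())
        counts = {c: 0 for c in GENOME}
        for iv in ctrl:
            counts[iv.chrom] += 1
        for c, size in GENOME.items():
            expect = 10_000 * size / total
            sd = np.sqrt(10_000 * (size / total) * (1 - size / total))
            assert abs(counts[c] - expect) <= 3 * sd

    def test_same_seed_identical(self, rng):
        query = random_region_set(rng, 10)
        c1 = sample_matched_control(query, GENOME, 100, seed=9)
        c2 = sample_matched_control(query, GENOME, 100, seed=9)
        assert c1.intervals == c2.intervals

    def test_bad_arguments_rejected(self, rng):
        query = random_region_set(rng, 5)
        with pytest.raises(ValueError):
            sample_matched_control(query, GENOME, 0, seed=1)
        with pytest.raises(ValueError):
            sample_matched_control(query, {"chr1": 50_000}, 10, seed=1)


class TestLogOdds:
    def test_continuity_corrected_extreme_table(self):
        # a=10, b=0, c=0, d=10 -> ln(10.5*10.5/(0.5*0.5)) = ln(441)
        query = RegionSet.from_tuples(
            [("chr1", i * 100, i * 100 + 50) for i in range(10)], name="q"
        )
        track = RegionSet.from_tuples([("chr1", 0, 1000)], name="t")
        control = RegionSet.from_tuples(
            [("chr2", i * 100, i * 100 + 50) for i in range(10)], name="c"
        )
        enr = overlap_log_odds(query, track, control)
        assert (enr.a, enr.b, enr.c, enr.d) == (10, 0, 0, 10)
        assert enr.log_odds == pytest.approx(np.log(441), abs=1e-12)

    def test_counts_match_brute_force(self, rng):
        for _ in range(20):
            query = random_region_set(rng, 12)
            track = random_region_set(rng, 8)
            control = random_region_set(rng, 12)
            enr = overlap_log_odds(query, track, control)
            m = bitmap(track)
            a = sum(bitmap_overlaps(iv, m) for iv in query)
            c = sum(bitmap_overlaps(iv, m) for iv in control)
            assert (enr.a, enr.b) == (a, len(query) - a)
            assert (enr.c, enr.d) == (c, len(control) - c)

    def test_antisymmetry_under_query_control_swap(self, rng):
        query = random_region_set(rng, 20)
        track = random_region_set(rng, 10)
        control = random_region_set(rng, 20)
        e1 = overlap_log_odds(query, track, control)
        e2 = overlap_log_odds(control, track, query)
        assert e1.log_odds == pytest.approx(-e2.log_odds, abs=1e-12)

    def test_log2_option(self, rng):
        query = random_region_set(rng, 10)
        track = random_region_set(rng, 10)
        control = random_region_set(rng, 10)
        e_ln = overlap_log_odds(query, track, control)
        e_2 = overlap_log_odds(query, track, control, log_base="2")
        assert e_2.log_odds == pytest.approx(e_ln.log_odds / np.log(2), abs=1e-12)

    def test_empty_query_rejected(self, rng):
        with pytest.raises(ValueError):
            overlap_log_odds(
                RegionSet(), random_region_set(rng, 3), random_region_set(rng, 3)
            )


class TestDerivedChromatinMaps:
    def _track(self, name, tuples_by_label):
        return AnnotationTrack(
            name,
            {
                lab: RegionSet.from_tuples(tups, name=lab)
                for lab, tups in tuples_by_label.items()
            },
        )

    def test_identical_other_gives_empty_unique_and_excluded(self):
        t = self._track("HUVEC", {"promoter": [("chr1", 0, 100)]})
        o = self._track("K562", {"promoter": [("chr1", 0, 100)]})
        comp, uniq, excl = derived_chromatin_maps({"HUVEC": t, "K562": o})
        assert len(uniq.by_label["promoter"]) == 0
        assert len(excl.by_label["promoter"]) == 0
        assert [(iv.start, iv.end) for iv in comp.by_label["promoter"]] == [(0, 100)]

    def test_disjoint_focal_is_fully_unique(self):
        t = self._track("HUVEC", {"enhancer": [("chr1", 0, 100)]})
        o = self._track("K562", {"enhancer": [("chr1", 500, 600)]})
        _, uniq, excl = derived_chromatin_maps({"HUVEC": t, "K562": o})
        assert [(iv.start, iv.end) for iv in uniq.by_label["enhancer"]] == [(0, 100)]
        assert [(iv.start, iv.end) for iv in excl.by_label["enhancer"]] == [(500, 600)]

    def test_three_celltypes_match_bitmap_oracle(self, rng):
        tracks = {
            ct: AnnotationTrack(
                ct, {"state": random_region_set(rng, 8, name="state")}
            )
            for ct in ("HUVEC", "K562", "GM12878")
        }
        comp, uniq, excl = derived_chromatin_maps(tracks)
        m = {ct: bitmap(tr.by_label["state"]) for ct, tr in tracks.items()}
        other = {
            c: m["K562"][c] | m["GM12878"][c] for c in GENOME
        }
        for chrom in GENOME:
            np.testing.assert_array_equal(
                bitmap(comp.by_label["state"])[chrom],
                m["HUVEC"][chrom] | other[chrom],
            )
            np.testing.assert_array_equal(
                bitmap(uniq.by_label["state"])[chrom],
                m["HUVEC"][chrom] & ~other[chrom],
            )
            np.testing.assert_array_equal(
                bitmap(excl.by_label["state"])[chrom],
                other[chrom] & ~m["HUVEC"][chrom],
            )

    def test_missing_focal_rejected(self):
        t = self._track("K562", {"promoter": [("chr1", 0, 100)]})
        with pytest.raises(ValueError):
            derived_chromatin_maps({"K562": t}, focal_celltype="HUVEC")


class TestCrossTrackOverlap:
    def test_identical_queries_identical_log_odds(self, rng):
        q = random_region_set(rng, 15, name="q1")
        q2 = RegionSet(list(q), name="q2")
        track = random_region_set(rng, 10, name="t")
        table = cross_track_overlap(
            [q, q2], track, chrom_sizes=GENOME, n_control=2000, seed=5
        )
        assert table["log_odds"][0] == table["log_odds"][1]

    def test_inside_vs_outside_strictly_ordered(self):
        track = RegionSet.from_tuples([("chr1", 0, 10_000)], name="t")
        inside = RegionSet.from_tuples(
            [("chr1", i * 500, i * 500 + 100) for i in range(10)], name="in"
        )
        outside = RegionSet.from_tuples(
            [("chr2", i * 500, i * 500 + 100) for i in range(10)], name="out"
        )
        table = cross_track_overlap(
            [inside, outside], track, chrom_sizes=GENOME, n_control=2000, seed=3
        )
        assert table["log_odds"][0] > table["log_odds"][1]

    def test_rows_match_single_set_operation(self, rng):
        queries = [random_region_set(rng, 10, name=f"q{i}") for i in range(3)]
        track = random_region_set(rng, 8, name="t")
        control = random_region_set(rng, 30, name="ctrl")
        from endosig.overlap import overlap_log_odds

        table = cross_track_overlap(queries, track, control=control)
        for i, q in enumerate(queries):
            single = overlap_log_odds(q, track, control)
            assert table["log_odds"][i] == pytest.approx(single.log_odds)
            assert table["a"][i] == single.a
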