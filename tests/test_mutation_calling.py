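"""Pileup accumulation, rate tracks, thresholding, calling, windows."""

import numpy as np
import pytest

from rdnaquant.models import Pileup
from rdnaquant import mutation_calling as mc
from rdnaquant.synthetic_data import (
    default_unit_model,
    simulate_amplicon_pileup,
    write_pileup_tsv,
)

REF = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 bp toy reference


def _write_sam(path):
    """Three reads: a perfect match, one substitution, one read with a
    soft clip, an insertion and a deletion."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:toy\tLN:{len(REF)}",
        # perfect 10 bp match at position 1
        f"r1\t0\ttoy\t1\t60\t10M\t*\t0\t0\t{REF[:10]}\t*",
        # 10 bp at position 5 with a substitution at reference position 8 (A->G)
        "r2\t0\ttoy\t5\t60\t10M\t*\t0\t0\t"
        + REF[4:7] + "G" + REF[8:14] + "\t*",
        # soft clip 2, match 4 (pos 11-14), insert 2, match 2 (15-16), delete 3 (17-19), match 2 (20-21)
        "r3\t0\ttoy\t11\t60\t2S4M2I2M3D2M\t*\t0\t0\t"
        + "TT" + REF[10:14] + "CC" + REF[14:16] + REF[19:21] + "\t*",
    ]
    path.write_text("\n".join(lines) + "\n")


def _write_tsv(path):
    """The same events encoded as one row per aligned base."""
    rows = ["position\tbase"]
    for pos in range(1, 11):  # r1
        rows.append(f"{pos}\t{REF[pos - 1]}")
    for pos in range(5, 15):  # r2 with substitution at 8
        rows.append(f"{pos}\t{'G' if pos == 8 else REF[pos - 1]}")
    for pos in range(11, 15):  # r3 aligned block
        rows.append(f"{pos}\t{REF[pos - 1]}")
    rows.append("14\t+CC")  # insertion recorded at the preceding reference position
    for pos in range(15, 17):
        rows.append(f"{pos}\t{REF[pos - 1]}")
    for pos in range(17, 20):
        rows.append(f"{pos}\t-")
    for pos in range(20, 22):
        rows.append(f"{pos}\t{REF[pos - 1]}")
    path.write_text("\n".join(rows) + "\n")


class TestPileupReaders:
    def test_sam_and_tsv_encodings_agree(self, tmp_path):
        sam, tsv = tmp_path / "toy.sam", tmp_path / "toy.tsv"
        _write_sam(sam)
        _write_tsv(tsv)
        ref = {"toy": REF}
        p_sam = mc.pileup_from_alignments(sam, ref)
        p_tsv = mc.pileup_from_alignments(tsv, ref, locus="toy")
        assert (p_sam.counts == p_tsv.counts).all()

    def test_substitution_counted_once(self, tmp_path):
        sam = tmp_path / "toy.sam"
        _write_sam(sam)
        p = mc.pileup_from_alignments(sam, {"toy": REF})
        pos8 = p.counts[7]
        assert pos8[2] == 1  # the G substitution
        assert p.depth[7] == 2  # r1 and r2 cover position 8

    def test_indels_and_clips(self, tmp_path):
        sam = tmp_path / "toy.sam"
        _write_sam(sam)
        p = mc.pileup_from_alignments(sam, {"toy": REF})
        assert p.counts[13, 4] == 1  # insertion at position 14
        assert (p.counts[16:19, 5] == 1).all()  # deletion spans 17-19
        assert p.depth[16] == 1
        assert p.depth[9] == 2  # soft-clipped bases not counted at 10

    def test_unknown_reference_is_an_error(self, tmp_path):
        sam = tmp_path / "toy.sam"
        _write_sam(sam)
        with pytest.raises(ValueError, match="not found"):
            mc.pileup_from_alignments(sam, {"other": REF})

    def test_empty_input_warns_and_returns_empty(self, tmp_path):
        sam = tmp_path / "empty.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:toy\tLN:30\n")
        with pytest.warns(UserWarning, match="no mapped reads"):
            p = mc.pileup_from_alignments(sam, {"toy": REF}, locus="toy")
        assert p.counts.sum() == 0

    def test_tsv_round_trip_through_writer(self, tmp_path):
        unit = default_unit_model()
        p = simulate_amplicon_pileup(unit, "old", 200, 1e-3, seed=3, locus="control")
        path = tmp_path / "pileup.tsv"
        write_pileup_tsv(p, path)
        df_cols = path.read_text().splitlines()[0].split("\t")
        assert df_cols[:3] == ["locus", "position", "ref"]


class TestRateTrack:
    def _pileup(self, a, c, g, t, ins=0, dele=0, ref="A"):
        counts = np.array([[a, c, g, t, ins, dele]])
        return Pileup(locus="toy", ref=ref, counts=counts)

    def test_two_per_mille(self):
        track = mc.mutation_rate_track(self._pileup(998, 2, 0, 0))
        assert track.rates[0] == pytest.approx(0.002)

    def test_fixed_difference_rate_is_one(self):
        track = mc.mutation_rate_track(self._pileup(0, 1000, 0, 0))
        assert track.rates[0] == 1.0

    def test_zero_depth_masked_not_zero(self):
        track = mc.mutation_rate_track(self._pileup(0, 0, 0, 0))
        assert np.isnan(track.rates[0])

    def test_indels_pooled_into_rate(self):
        track = mc.mutation_rate_track(self._pileup(96, 0, 0, 0, ins=2, dele=4))
        # depth 100 (96 bases + 4 deletions); numerator 2 ins + 4 del
        assert track.rates[0] == pytest.approx(0.06)
        assert track.insertion_rates[0] == pytest.approx(0.02)
        assert track.deletion_rates[0] == pytest.approx(0.04)

    def test_rate_conservation_on_random_pileups(self, rng):
        # with no insertions, reference fraction + mutation rate = 1 exactly
        n = 50
        counts = rng.integers(0, 200, size=(n, 6))
        counts[:, 4] = 0
        ref = "".join(rng.choice(list("ACGT"), size=n))
        track = mc.mutation_rate_track(Pileup("toy", ref, counts))
        depth = counts[:, :4].sum(axis=1) + counts[:, 5]
        ref_idx = np.array(["ACGT".index(b) for b in ref])
        ref_frac = counts[np.arange(n), ref_idx] / np.where(depth > 0, depth, 1)
        ok = depth > 0
        assert np.allclose(ref_frac[ok] + track.rates[ok], 1.0)


class TestControlThreshold:
    def _track(self, rates, age="young"):
        r = np.asarray(rates, dtype=float)
        return mc.MutationRateTrack("s", age, "control", r, np.full(r.shape, 100))

    def test_maximum_of_control_rates(self):
        assert mc.control_gene_threshold([self._track([0.0005, 0.0011, 0.0028])]) == 0.0028

    def test_fixed_differences_excluded_before_max(self):
        assert mc.control_gene_threshold([self._track([0.001, 0.95, 0.002])]) == 0.002

    def test_all_zero_control_gives_zero(self):
        assert mc.control_gene_threshold([self._track([0.0, 0.0])]) == 0.0

    def test_unusable_control_is_an_error(self):
        with pytest.raises(ValueError):
            mc.control_gene_threshold([])
        t = self._track([0.95, 0.99])
        with pytest.raises(ValueError, match="no usable"):
            mc.control_gene_threshold([t])


def _tracks(rate_rows, age, locus="28S"):
    out = []
    for i, row in enumerate(rate_rows):
        r = np.asarray(row, dtype=float)
        out.append(
            mc.MutationRateTrack(f"{age}{i}", age, locus, r, np.full(r.shape, 10_000))
        )
    return out


class TestAgeDifferentialCalls:
    def test_strong_old_specific_site_passes(self):
        # rates elsewhere zero; the planted column mirrors a real old-specific site
        y = _tracks([[0.0, 0.000], [0.0, 0.001]], "young")
        o = _tracks([[0.0, 0.441], [0.0, 0.396]], "old")
        calls = mc.call_age_differential_sites(y, o, threshold=0.0028)
        assert len(calls) == 1
        c = calls[0]
        assert c.position == 2 and c.passes
        assert c.old_mean == pytest.approx(0.4185)
        assert c.difference == pytest.approx(0.418)

    def test_null_difference_not_called(self):
        y = _tracks([[0.002], [0.002]], "young")
        o = _tracks([[0.002], [0.002]], "old")
        assert mc.call_age_differential_sites(y, o, threshold=0.0028) == []

    def test_fixed_difference_positions_excluded(self):
        y = _tracks([[0.95, 0.0], [0.96, 0.0]], "young")
        o = _tracks([[0.2, 0.0], [0.3, 0.0]], "old")
        assert mc.call_age_differential_sites(y, o, threshold=0.01) == []

    def test_young_high_site_called_with_negative_difference(self):
        y = _tracks([[0.036], [0.038]], "young")
        o = _tracks([[0.009], [0.007]], "old")
        (c,) = mc.call_age_differential_sites(y, o, threshold=0.0028)
        assert c.difference == pytest.approx(-0.029)
        assert c.passes

    def test_overlapping_groups_fail_separation(self):
        y = _tracks([[0.001], [0.040]], "young")
        o = _tracks([[0.030], [0.050]], "old")
        (c,) = mc.call_age_differential_sites(y, o, threshold=0.001)
        assert not c.passes
        (c2,) = mc.call_age_differential_sites(y, o, threshold=0.001, require_separation=False)
        assert c2.passes

    def test_conserved_positions_annotated_with_yeast_coordinates(self):
        n = 4700
        base = np.zeros(n)
        y_row = base.copy()
        o_row = base.copy()
        o_row[4613] = 0.44  # mouse 28S position 4614
        o_row[3290] = 0.04  # position 3291
        y = _tracks([y_row, y_row], "young")
        o = _tracks([o_row, o_row], "old")
        calls = mc.call_age_differential_sites(y, o, threshold=0.0028)
        by_pos = {c.position: c for c in calls}
        assert by_pos[4614].yeast_position == 3295
        assert by_pos[3291].yeast_position == 2131

    def test_calls_sorted_by_absolute_difference(self):
        y = _tracks([[0.0, 0.03], [0.0, 0.04]], "young")
        o = _tracks([[0.2, 0.0], [0.3, 0.0]], "old")
        calls = mc.call_age_differential_sites(y, o, threshold=0.001)
        assert [c.position for c in calls] == [1, 2]

    def test_empty_group_is_an_error(self):
        y = _tracks([[0.0]], "young")
        with pytest.raises(ValueError):
            mc.call_age_differential_sites(y, [], threshold=0.01)


class TestHotspotWindows:
    def _track(self, rates):
        r = np.asarray(rates, dtype=float)
        return mc.MutationRateTrack("s", "old", "28S", r, np.full(r.shape, 1000))

    def test_forty_position_example(self):
        rates = np.full(40, 0.001)
        rates[4] = 0.01   # position 5
        rates[24] = 0.004  # position 25
        windows = mc.hotspot_window_sums(self._track(rates), threshold=0.0028)
        assert [w.summed_rate for w in windows] == pytest.approx([0.010, 0.004])
        assert [w.start for w in windows] == [1, 21]

    def test_all_below_threshold_sums_to_zero(self):
        windows = mc.hotspot_window_sums(self._track(np.full(60, 0.002)), threshold=0.0028)
        assert all(w.summed_rate == 0.0 for w in windows)

    def test_merged_tracks_sum_linearly(self):
        rates = np.zeros(45)
        rates[3] = 0.02
        a = mc.hotspot_window_sums(self._track(rates), threshold=0.001)
        b = mc.hotspot_window_sums(self._track(rates * 2), threshold=0.001)
        merged = mc.merge_window_sums(a, b)
        assert merged[0].summed_rate == pytest.approx(a[0].summed_rate + b[0].summed_rate)
        assert merged[-1].partial and merged[-1].n_positions == 5

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 120))
            rates = rng.uniform(0, 1, size=n)
            thr = float(rng.uniform(0, 0.5))
            track = self._track(rates)
            windows = mc.hotspot_window_sums(track, threshold=thr, width=20)
            # brute force double loop
            expected = []
            for start in range(0, n, 20):
                total = 0.0
                for pos in range(start, min(start + 20, n)):
                    if thr < rates[pos] <= 0.9:
                        total += rates[pos]
                expected.append(total)
            assert [w.summed_rate for w in windows] == pytest.approx(expected)


class TestRestrictionSiteSummary:
    def _tracks_by_sample(self, rows):
        out = {}
        for sid, age, rates in rows:
            r = np.asarray(rates, dtype=float)
            out[sid] = mc.MutationRateTrack(sid, age, "28S", r, np.full(r.shape, 1000))
        return out

    def test_bamhi_site_group_averages(self):
        tracks = self._tracks_by_sample(
            [
                ("y1", "young", [0.23, 0.0, 0.0]),
                ("y2", "young", [0.27, 0.0, 0.0]),
                ("o1", "old", [0.35, 0.19, 0.19]),
                ("o2", "old", [0.32, 0.16, 0.16]),
            ]
        )
        per_sample, per_group = mc.restriction_site_variant_summary(tracks, [1, 2, 3])
        assert per_sample["o1"] == pytest.approx(0.73)
        assert per_group["young"] == pytest.approx(0.25)
        assert per_group["old"] == pytest.approx(0.685)

    def test_all_zero_rates_average_zero(self):
        tracks = self._tracks_by_sample([("s1", "young", [0.0, 0.0])])
        _, per_group = mc.restriction_site_variant_summary(tracks, [1, 2])
        assert per_group["young"] == 0.0

    def test_missing_position_error_names_it(self):
        tracks = self._tracks_by_sample([("s1", "young", [0.1])])
        with pytest.raises(ValueError, match="position 7"):
            mc.restriction_site_variant_summary(tracks, [7])
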