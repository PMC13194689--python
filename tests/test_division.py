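"""Division geometry: PPB tallies and category tests, nuclear positioning,
mitotic proportions, stage durations and phragmoplast expansion."""

import numpy as np
import pytest

from katquant.division import (
    REFERENCE_PPB_COUNTS,
    DivisionCellRecord,
    DivisionTimelapse,
    mitotic_proportion,
    nuclear_offset_percent,
    nuclear_position_along_axis,
    phragmoplast_expansion_rate,
    reference_count_table,
    stage_durations,
    tally_and_test,
    category_fisher_tests,
)
from katquant.synth import gen_division_records, gen_stage_records


def _record(nucleus=(0.0, 0.0), side="none", angle=0.0, stage="ppb", cat="normal"):
    # 40 x 10 um rectangle centered at the origin, long axis along +x
    verts = np.array([(-20.0, -5.0), (20.0, -5.0), (20.0, 5.0), (-20.0, 5.0)])
    nucleus = np.asarray(nucleus, dtype=float)
    direction = np.array([1.0, 0.0])
    if angle:
        t = np.radians(angle)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        verts = verts @ rot.T
        nucleus = rot @ nucleus
        direction = rot @ direction
    return DivisionCellRecord(
        cell_id="c", plant_id="p", genotype="g", stage=stage,
        ppb_category=cat if stage == "ppb" else "none",
        cell_polygon=tuple(map(tuple, verts)),
        long_axis_direction=tuple(direction),
        long_axis_length=40.0,
        nucleus_centroid=tuple(nucleus),
        dominant_accumulation_side=side,
    )


class TestNuclearPositioning:
    def test_centered_nucleus_zero_offset(self):
        assert nuclear_offset_percent(_record()) == pytest.approx(0.0, abs=1e-12)

    def test_four_micron_displacement_is_ten_percent(self):
        assert nuclear_offset_percent(_record(nucleus=(4.0, 0.0))) == pytest.approx(10.0)

    @pytest.mark.parametrize("angle", [0.0, 37.0, 90.0, 145.0])
    def test_offset_invariant_under_rotation(self, angle):
        r = _record(nucleus=(4.0, 2.0), angle=angle)
        assert nuclear_offset_percent(r) == pytest.approx(
            nuclear_offset_percent(_record(nucleus=(4.0, 2.0))), rel=1e-9)

    def test_position_conventions(self):
        assert nuclear_position_along_axis(_record(side="right")) == pytest.approx(50.0)
        # nucleus at the dominant-accumulation (+x) end
        at_end = _record(nucleus=(20.0, 0.0), side="right")
        assert nuclear_position_along_axis(at_end) == pytest.approx(100.0)
        # flipping the dominant side mirrors the scale
        at_end_left = _record(nucleus=(20.0, 0.0), side="left")
        assert nuclear_position_along_axis(at_end_left) == pytest.approx(0.0)

    def test_offset_equals_axis_deviation_for_on_axis_nuclei(self):
        for x in (2.0, -6.0, 11.0):
            r = _record(nucleus=(x, 0.0), side="right")
            assert abs(nuclear_position_along_axis(r) - 50.0) == pytest.approx(
                nuclear_offset_percent(r), rel=1e-9)

    def test_category_stage_consistency_enforced(self):
        with pytest.raises(ValueError):
            DivisionCellRecord(cell_id="c", plant_id="p", genotype="g",
                               stage="interphase", ppb_category="uneven")
        with pytest.raises(ValueError):
            DivisionCellRecord(cell_id="c", plant_id="p", genotype="g",
                               stage="ppb", ppb_category="none")


class TestTallyAndTest:
    def test_reference_counts_reproduced_by_quota_generator(self):
        """Quota sampling at the published frequencies reproduces the tally."""
        wt_total, mut_total = 161, 182
        probs = {
            "a_wild_type": {c: v[0] / wt_total for c, v in REFERENCE_PPB_COUNTS.items()},
            "b_mutant": {c: v[1] / mut_total for c, v in REFERENCE_PPB_COUNTS.items()},
        }
        records = gen_division_records(probs, {"a_wild_type": wt_total, "b_mutant": mut_total},
                                       seed=0, quota=True)
        table, results = tally_and_test(records)
        assert table.totals == (wt_total, mut_total)
        for cat, (wt, mut) in REFERENCE_PPB_COUNTS.items():
            assert table.counts[cat] == (wt, mut)
        assert results["normal"].p_value == pytest.approx(3.5e-20, rel=0.05)
        assert results["uneven"].p_value == pytest.approx(5.7e-11, rel=0.05)

    def test_symmetric_counts_give_p_one(self):
        records = gen_division_records(
            {"g1": {"normal": 0.5, "four_sided": 0.5}, "g2": {"normal": 0.5, "four_sided": 0.5}},
            {"g1": 10, "g2": 10}, seed=1, quota=True)
        _, results = tally_and_test(records)
        assert results["four_sided"].p_value == 1.0

    def test_order_invariance_and_total_conservation(self):
        probs = {"g1": {"normal": 0.7, "uneven": 0.3}, "g2": {"normal": 0.4, "uneven": 0.6}}
        records = gen_division_records(probs, {"g1": 40, "g2": 50}, seed=5)
        table, results = tally_and_test(records)
        rng = np.random.default_rng(0)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        table2, results2 = tally_and_test(shuffled)
        assert table.counts == table2.counts
        for cat in results:
            assert results[cat].p_value == results2[cat].p_value
        assert tuple(sum(table.counts[c][i] for c in table.counts) for i in range(2)) \
            == table.totals

    def test_single_genotype_rejected(self):
        records = gen_division_records({"g1": {"normal": 1.0}}, {"g1": 10}, seed=0)
        with pytest.raises(ValueError):
            tally_and_test(records)

    def test_reference_significance_calls(self):
        """At threshold 0.05/7 the published table flags normal, uneven,
        one-sided and misoriented; four-sided, three-sided and split are NS."""
        results = category_fisher_tests(reference_count_table())
        significant = {c for c, r in results.items() if r.extra["significant"]}
        assert significant == {"normal", "uneven", "one_sided", "misoriented"}


class TestMitoticProportion:
    def test_trivial_fractions(self):
        records = [_record(stage="interphase", cat="none") for _ in range(9)] + \
                  [_record(stage="metaphase", cat="none") for _ in range(3)]
        assert mitotic_proportion(records) == pytest.approx(0.25)
        assert mitotic_proportion(records[:9]) == 0.0

    def test_generator_probability_recovery(self):
        p = 0.2
        records = gen_stage_records(2000, p_division=p, seed=3)
        est = mitotic_proportion(records)
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(est - p) < 3 * se


class TestTimings:
    def test_metaphase_frames_times_interval(self):
        tl = DivisionTimelapse(cell_id="c", frame_interval=10.0,
                               stages=("metaphase",) * 4)
        assert stage_durations(tl)["metaphase_min"] == 40.0

    def test_inclusive_frame_counting(self):
        tl = DivisionTimelapse(cell_id="c", frame_interval=10.0,
                               stages=("ppb",) * 2 + ("metaphase",) * 3 + ("telophase",) * 5)
        d = stage_durations(tl)
        assert (d["metaphase_min"], d["telophase_min"], d["total_min"]) == (30.0, 50.0, 80.0)

    def test_durations_scale_with_interval(self):
        stages = ("ppb",) * 2 + ("metaphase",) * 3 + ("telophase",) * 5
        d1 = stage_durations(DivisionTimelapse("c", 10.0, stages))
        d2 = stage_durations(DivisionTimelapse("c", 20.0, stages))
        for key in ("metaphase_min", "telophase_min", "total_min"):
            assert d2[key] == 2 * d1[key]

    def test_missing_stage_is_none(self):
        tl = DivisionTimelapse("c", 10.0, ("ppb", "ppb", "telophase"))
        assert stage_durations(tl)["metaphase_min"] is None

    def test_out_of_order_stages_rejected(self):
        with pytest.raises(ValueError):
            DivisionTimelapse("c", 10.0, ("telophase", "metaphase"))


class TestPhragmoplast:
    def test_exact_slope(self):
        tl = DivisionTimelapse("c", 10.0, ("telophase",) * 3,
                               phragmoplast_length=(0.0, 3.0, 6.0))
        assert phragmoplast_expansion_rate(tl) == pytest.approx(0.3)

    def test_constant_length_zero_rate(self):
        tl = DivisionTimelapse("c", 10.0, ("telophase",) * 4,
                               phragmoplast_length=(4.0,) * 4)
        assert phragmoplast_expansion_rate(tl) == 0.0

    def test_noisy_track_within_three_se(self):
        rng = np.random.default_rng(17)
        n, rate, sigma = 8, 0.31, 0.15
        t = np.arange(n) * 10.0
        lengths = tuple(rate * t + rng.normal(0, sigma, n))
        tl = DivisionTimelapse("c", 10.0, ("telophase",) * n,
                               phragmoplast_length=lengths)
        se = sigma / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(phragmoplast_expansion_rate(tl) - rate) < 3 * se

    def test_too_few_frames_rejected(self):
        tl = DivisionTimelapse("c", 10.0, ("metaphase", "telophase"),
                               phragmoplast_length=(np.nan, 2.0))
        with pytest.raises(ValueError):
            phragmoplast_expansion_rate(tl)
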