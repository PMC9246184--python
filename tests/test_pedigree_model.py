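import numpy as np
import pytest

import kincal as kc
from kincal.pedigree_model import determinations_from_table


@pytest.fixture(scope="module")
def table():
    return kc.load_date_table()


@pytest.fixture(scope="module")
def dates(table):
    return determinations_from_table(table)


class TestHBCO:
    def test_offset_subtracted_once(self, dates):
        det = dates["POST_44"]
        corrected = kc.apply_hbco(det)
        assert det.age == 3681 and corrected.age == 3666
        assert corrected.hbco_applied

    def test_zero_offset_is_identity_on_age(self, dates):
        det = dates["OBKR_6"]
        assert kc.apply_hbco(det).age == 3611

    def test_double_application_rejected(self, dates):
        corrected = kc.apply_hbco(dates["POST_44"])
        with pytest.raises(ValueError, match="already"):
            kc.apply_hbco(corrected)

    def test_correction_moves_calibrated_mode_younger(self):
        """Subtracting the offset lowers the BP age; on a monotone curve the
        calibrated distribution must shift younger, never older."""
        curve = kc.linear_curve(start=-3000, end=-1000, slope=1.0, sigma=10)
        det = kc.C14Determination(id="x", age=3900, err=20, hbco_offset=20)
        before = kc.calibrate(det, curve).mean()
        after = kc.calibrate(kc.apply_hbco(det), curve).mean()
        assert after > before


class TestCNQC:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(3.2, True), (2.9, True), (3.6, True), (2.89, False), (3.7, False)],
    )
    def test_acceptance_window(self, ratio, expected):
        assert kc.cn_qc(ratio) is expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            kc.cn_qc(0.0)


class TestBuildModel:
    def test_obkr_collapses_to_three_phases(self, dates):
        ped = kc.load_pedigree("obkr")
        spec, used = kc.build_model(ped, dates)
        assert spec.phases == (("OBKR_6",), ("OBKR_80", "OBKR_86"), ("OBKR_81", "OBKR_82"))
        assert len(used) == 5

    def test_post_uncle_right_strand_is_four_phases(self, dates):
        ped = kc.load_pedigree("post")
        include = {"POST_44", "POST_50", "POST_35", "POST_140", "POST_28", "POST_47"}
        spec, used = kc.build_model(ped, dates, include=include)
        assert spec.phases == (
            ("POST_44",),
            ("POST_50", "POST_35"),
            ("POST_140",),
            ("POST_28", "POST_47"),
        )

    def test_post_grandfather_gap_carries_interval(self, dates):
        ped = kc.load_pedigree("post_grandfather")
        include = {"POST_44", "POST_50", "POST_35", "POST_140", "POST_28", "POST_47"}
        spec, _ = kc.build_model(
            ped, dates, include=include, use_intervals=True, interval_means={0: 25.0}
        )
        assert spec.n_gen == 4
        assert spec.intervals == {0: (25.0, 10.0)}

    def test_fixture_pedigrees_are_total(self, dates):
        for site, n in (("post", 8), ("obkr", 5), ("aiti", 4)):
            ped = kc.load_pedigree(site)
            spec, used = kc.build_model(ped, dates)
            assert len(used) == n
            assert len(spec.date_ids) == n

    def test_single_individual_pedigree(self, dates):
        ped = kc.Pedigree(
            individuals=(kc.Individual(id="OBKR_6", generation_level=1, aad_min=15, aad_max=18),)
        )
        spec, _ = kc.build_model(ped, dates)
        assert spec.n_gen == 1

    def test_missing_date_lists_ids(self):
        ped = kc.load_pedigree("aiti")
        with pytest.raises(ValueError, match="AITI_87"):
            kc.build_model(ped, {})

    def test_hbco_applied_on_request(self, dates):
        ped = kc.load_pedigree("obkr")
        _, used = kc.build_model(ped, dates, use_hbco=True)
        by_id = {d.id: d for d in used}
        assert by_id["OBKR_80"].age == 3649
        assert by_id["OBKR_6"].age == 3611


class TestPedigreeValidation:
    def test_edge_level_mismatch_rejected(self):
        with pytest.raises(ValueError, match="generation level"):
            kc.Pedigree(
                individuals=(
                    kc.Individual(id="a", generation_level=1, aad_min=30, aad_max=40),
                    kc.Individual(id="b", generation_level=3, aad_min=30, aad_max=40),
                ),
                edges=(("a", "b"),),
            )

    def test_unknown_edge_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            kc.Pedigree(
                individuals=(kc.Individual(id="a", generation_level=1, aad_min=1, aad_max=2),),
                edges=(("a", "zz"),),
            )


class TestPairwiseDeathOrder:
    def test_five_aiti_scenarios_build(self, dates):
        ped = kc.load_pedigree("aiti")
        mother = ped.by_id("AITI_87")
        scenarios = [
            (("AITI_87", "AITI_120"), 20.0, 10.0),
            (("AITI_87", "AITI_119"), 7.5, 7.5),
            (("AITI_119", "AITI_87"), 5.0, 5.0),
            (("AITI_87", "AITI_86"), 2.5, 2.5),
            (("AITI_86", "AITI_87"), 10.0, 10.0),
        ]
        models = []
        for (first, second), mean, sd in scenarios:
            child_id = first if first != "AITI_87" else second
            child = ped.by_id(child_id)
            models += kc.pairwise_death_order_models(
                mother, child, dates, [((first, second), mean, sd)]
            )
        assert len(models) == 5
        label, spec, used = models[0]
        assert spec.phases == (("AITI_87",), ("AITI_120",))
        assert spec.intervals == {0: (20.0, 10.0)}
        assert len(used) == 2

    def test_empty_scenario_list_rejected(self, dates):
        ped = kc.load_pedigree("aiti")
        with pytest.raises(ValueError):
            kc.pairwise_death_order_models(
                ped.by_id("AITI_87"), ped.by_id("AITI_86"), dates, []
            )


class TestSeparationCap:
    def test_cap_arithmetic_five_generations(self):
        """End of generation 1 at 772 cal BC, five generations, 20-year
        separation: generation 5 capped at 692 cal BC."""
        assert kc.separation_cap(-772.0, 5, 20.0) == pytest.approx(-692.0)

    def test_known_small_gap_clips_the_separation(self):
        # a 26-year first gap clips a 30-year separation to 26
        cap = kc.separation_cap(-772.0, 5, 30.0, gaps=[26.0, 35.0, 40.0, 33.0])
        assert cap == pytest.approx(-772.0 + 26 + 30 + 30 + 30)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            kc.separation_cap(-772.0, 5, 0.0)
        with pytest.raises(ValueError):
            kc.separation_cap(-772.0, 0, 20.0)

    def test_capping_never_widens_and_preserves_order(self, curve):
        ped = kc.make_pedigree(kc.scenario("anchor", seed=1))
        dets = kc.simulate_dataset(ped, curve)
        spec = kc.ModelSpec(
            phases=tuple(
                tuple(i.id for i in ped.individuals if i.generation_level == k + 1)
                for k in range(5)
            )
        )
        summary = kc.run_model(spec, dets, curve, kc.SamplerSettings(seed=9))
        capped = kc.yod_separation_cap(summary, 20.0)
        for did, ranges in capped.items():
            assert ranges.outer_span <= summary.ranges2[did].outer_span + 1e-9
        # the cumulative caps increase with the phase index (order preserved)
        end1 = max(summary.ranges2[d].youngest for d in spec.phases[0])
        for j in range(1, 5):
            cap_j = kc.separation_cap(end1, j + 1, 20.0)
            for did in spec.phases[j]:
                assert capped[did].youngest <= cap_j + 1e-9

    def test_single_generation_unchanged(self, linear):
        det = kc.C14Determination(id="x", age=3940, err=25)
        spec = kc.ModelSpec(phases=(("x",),))
        summary = kc.run_model(spec, [det], linear, kc.SamplerSettings(seed=4))
        capped = kc.yod_separation_cap(summary, 20.0)
        assert capped["x"] == summary.ranges2["x"]


class TestDateTable:
    def test_all_seventeen_rows_bundled(self, table):
        assert len(table) == 17
        assert sorted(table.site.unique()) == ["AITI", "OBKR", "POST"]
        assert (table.groupby("site").size()[["POST", "OBKR", "AITI"]] == [8, 5, 4]).all()

    def test_site_filter(self):
        aiti = kc.load_date_table(site="AITI")
        assert len(aiti) == 4
        assert set(aiti.id) == {"AITI_87", "AITI_86", "AITI_119", "AITI_120"}
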