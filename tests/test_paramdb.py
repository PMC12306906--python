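import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import osteovox as ov
from osteovox.errors import NotModeledAtAgeError, OsteovoxError, UnknownSegmentError
from osteovox.paramdb import MicroParams, ParameterDatabase

PER_AGE = dict(zip(ov.AGES, [34, 39, 43, 38, 64, 71]))


class TestRegistry:
    def test_per_age_unique_segment_counts(self, db):
        for age, n in PER_AGE.items():
            assert db.count_bps([age]) == n
        assert db.count_bps(ov.AGES) == 289
        assert db.count_bps([]) == 0

    def test_adult_count_includes_sex_variants(self, db):
        adult = db.registry[db.registry.age == "adult"]
        assert (adult.sex == "m").sum() == (adult.sex == "f").sum() == 24

    def test_clavicle_body_adult_micro(self, db):
        m = db.get_segment("clavicle", "body", "adult").micro
        assert (m.bvtv_mean, m.bvtv_sd) == (0.15, 0.03)
        assert (m.tbth_mean, m.tbth_sd) == (0.19, 0.06)
        assert (m.tbsp_mean, m.tbsp_sd) == (1.1, 0.14)

    def test_scapula_glenoid_adult_dimensions(self, db):
        s = db.get_segment("scapula", "glenoid", "adult")
        by_role = {d.role: (d.mean, d.sd) for d in s.dims}
        assert by_role == {"d1": (36.0, 3.2), "d2": (26.0, 2.6), "h": (20.0, 2.0)}
        assert (s.ctth_mean, s.ctth_sd) == (0.9, 0.25)
        assert s.shape == "elliptic-cylinder"

    @pytest.mark.parametrize("site,part,age", [
        ("femur", "diaphysis", "10-Y"),
        ("sternum", "body", "0-Y"),
        ("tibia", "diaphysis", "10-Y"),
        ("radius_ulna", "diaphysis", "10-Y"),
        ("humerus", "diaphysis", "adult"),
        ("wrist_hand_foot", "phalanx", "1-Y"),
    ])
    def test_dark_fields_raise_not_modeled(self, db, site, part, age):
        with pytest.raises(NotModeledAtAgeError):
            db.get_segment(site, part, age)

    def test_unknown_segment(self, db):
        with pytest.raises(UnknownSegmentError):
            db.get_segment("femur", "head_of_garlic", "adult")

    def test_every_registry_row_resolves(self, db):
        """Non-dark cells all resolve with valid micro-parameters."""
        for r in db.registry.itertuples():
            spec = db.get_segment(r.site, r.part, r.age,
                                  None if r.sex == "u" else r.sex)
            assert 0 < spec.micro.bvtv_mean < 1
            assert spec.micro.tbth_mean > 0 and spec.micro.tbsp_mean > 0
            assert spec.multiplicity >= 1
            assert r.age in spec.modeled_ages

    def test_sex_specific_rows(self, db):
        m = db.get_segment("vertebrae_l", "body", "adult", "m")
        f = db.get_segment("vertebrae_l", "body", "adult", "f")
        assert m.sex == "m" and f.sex == "f"
        assert f.dim("d1").mean == pytest.approx(0.92 * m.dim("d1").mean, rel=1e-3)
        # unisex parts are served to either sex
        u = db.get_segment("vertebrae_l", "spinous_process", "adult", "f")
        assert u.sex == "u"

    def test_distal_femur_bvtv_is_three_quarters_of_proximal(self, db):
        for age in ("5-Y", "10-Y"):
            prox = db.get_segment("femur", "neck", age).micro.bvtv_mean
            dist = db.get_segment("femur", "distal", age).micro.bvtv_mean
            assert dist == pytest.approx(0.75 * prox, abs=0.005)


class TestShapeCensus:
    def test_published_census(self, db):
        c = db.shape_census()
        assert c["box"] == pytest.approx(48.5, abs=0.5)
        assert c["cylinder"] == pytest.approx(30.0, abs=0.5)
        assert c["cone"] == pytest.approx(20.0, abs=0.5)
        assert c["prism"] == pytest.approx(1.5, abs=0.5)
        assert sum(c.values()) == pytest.approx(100.0, abs=1e-9)

    def test_tiny_registries(self, db):
        def mini(shapes):
            reg = pd.DataFrame([
                dict(site="clavicle", part=f"p{i}", age="adult", sex="u",
                     shape=s, micro_site="clavicle", micro_group="body",
                     multiplicity=1, am_fraction_scale=1.0)
                for i, s in enumerate(shapes)])
            return ParameterDatabase(reg, db.micro, db.cvis, db._densities,
                                     db.dimensions)

        assert mini(["box"]).shape_census() == {"box": 100.0}
        two = mini(["box", "box", "cylinder", "cylinder"]).shape_census()
        assert two == {"box": 50.0, "cylinder": 50.0}


class TestEvidencePooling:
    @pytest.mark.parametrize("n,flag,context,expected", [
        (25, False, "micro", 1.0),
        (5, False, "micro", 0.2),
        (30, True, "micro", 0.75),
        (30, True, "size", 1.0),   # only W_N for bone sizes
        (10, True, "micro", 10 / 25 * 0.75),
    ])
    def test_study_weight(self, n, flag, context, expected):
        rec = ov.StudyRecord(n_subjects=n, mean=0.0, sd=0.0, age_range_flag=flag)
        assert ov.study_weight(rec, context) == pytest.approx(expected)

    def test_pool_single_study(self):
        est = ov.pool_studies([ov.StudyRecord(30, 0.15, 0.03)])
        assert est.mean == pytest.approx(0.15)
        assert est.sd == pytest.approx(0.03)
        assert est.range == pytest.approx((0.09, 0.21))

    def test_pool_equal_weights(self):
        est = ov.pool_studies([ov.StudyRecord(30, 0.10, 0.02),
                               ov.StudyRecord(30, 0.20, 0.04)])
        assert est.mean == pytest.approx(0.15)
        assert est.sd == pytest.approx(0.03)
        assert est.range == pytest.approx((0.09, 0.21))

    def test_pool_unequal_weights(self):
        est = ov.pool_studies([ov.StudyRecord(25, 0.10, 0.0),
                               ov.StudyRecord(5, 0.20, 0.0)])
        assert est.mean == pytest.approx((1.0 * 0.10 + 0.2 * 0.20) / 1.2)

    def test_pool_empty_raises(self):
        with pytest.raises(OsteovoxError):
            ov.pool_studies([])

    @settings(max_examples=50, derandomize=True)
    @given(mean=st.floats(0.01, 10), sd=st.floats(0, 1),
           n=st.integers(1, 100), k=st.integers(1, 5))
    def test_pool_idempotent_on_identical_records(self, mean, sd, n, k):
        recs = [ov.StudyRecord(n, mean, sd)] * k
        est = ov.pool_studies(recs)
        assert est.mean == pytest.approx(mean)
        assert est.sd == pytest.approx(sd)

    def test_stated_range_overrides(self):
        est = ov.pool_studies([ov.StudyRecord(30, 0.5, 0.1)],
                              stated_range=(0.2, 0.9))
        assert est.range == (0.2, 0.9)


class TestCvIs:
    def test_group_averages_match_other_bones_row(self, db):
        assert ov.cvis_group_average(db.measured_cvis("tbth")) == 22
        assert ov.cvis_group_average(db.measured_cvis("tbsp")) == 23

    def test_single_element_mean(self):
        assert ov.cvis_group_average([7.0]) == 7

    def test_round_half_up(self):
        assert ov.cvis_group_average([10, 43, 15]) == 23  # 22.67
        assert ov.cvis_group_average([1, 2]) == 2         # 1.5 rounds up

    def test_empty_raises(self):
        with pytest.raises(OsteovoxError):
            ov.cvis_group_average([])

    def test_site_mapping(self, db):
        assert db.cvis_for_site("vertebrae_t") == (48.0, 43.0)
        assert db.cvis_for_site("skull") == (8.0, 15.0)
        assert db.cvis_for_site("clavicle") == (22.0, 23.0)


class TestTypes:
    def test_micro_params_invariants(self):
        with pytest.raises(OsteovoxError):
            MicroParams(1.2, 0.1, 0.2, 0.02, 0.6, 0.1, 10, 10)
        with pytest.raises(OsteovoxError):
            MicroParams(0.2, 0.1, -0.2, 0.02, 0.6, 0.1, 10, 10)
        with pytest.raises(OsteovoxError):
            MicroParams(0.2, -0.1, 0.2, 0.02, 0.6, 0.1, 10, 10)

    def test_density_table_values(self, densities):
        assert [densities.mineral_density[a] for a in ov.AGES] == \
            [1.65, 1.7, 1.8, 1.83, 1.85, 1.9]
        assert densities.marrow_density["adult"] == 0.98
        assert all(densities.marrow_density[a] == 1.0 for a in ov.AGES[:5])

    def test_study_record_invariants(self):
        with pytest.raises(OsteovoxError):
            ov.StudyRecord(0, 1.0, 0.1)
        with pytest.raises(OsteovoxError):
            ov.StudyRecord(10, 1.0, -0.1)
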