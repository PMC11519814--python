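"""Schema contents, driver staging, categorical encoding, exclusions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cmbnet import (
    ClinicalProfile,
    StagingRuleSet,
    apply_exclusions,
    build_default_schema,
    encode_record,
    stage_cmbcd,
    stage_driver,
)
from cmbnet.schema import (
    DRIVERS,
    InvalidInputError,
    age_band,
    alcohol_band,
    income_band,
)


class TestDefaultSchema:
    def test_has_exactly_18_variables(self, schema):
        assert len(schema) == 18
        assert len(set(schema.names)) == 18

    def test_level_labels_are_verbatim(self, schema):
        assert schema.levels("Diet") == ("Not DASH-accordant", "DASH-accordant")
        assert schema.levels("ABCD") == tuple(f"Stage {k}" for k in range(5))
        assert schema.levels("CMBCD") == ("Stage 0", "Stage 1", "Stage 2–4")
        assert schema.levels("Income") == (
            "<100% FPL", "100–199% FPL", "200–399% FPL", ">400% FPL"
        )

    def test_tier_ordering(self, schema):
        assert schema.tier("Ethno-racial group") == 1
        assert schema.tier("Education") == 2
        assert schema.tier("Ethno-racial group") < schema.tier("Education")
        assert schema.tier("Household food security") == 3
        assert schema.tier("Diet") == 4
        assert all(schema.tier(d) == 5 for d in DRIVERS)
        assert schema.tier("CMBCD") == 6

    def test_every_variable_has_at_least_two_levels(self, schema):
        assert all(len(v.levels) >= 2 for v in schema.variables)


class TestStageDriver:
    @pytest.mark.parametrize(
        "profile, driver, expected",
        [
            (ClinicalProfile(bmi=23.0, dash_accordant=True), "ABCD", 0),
            (ClinicalProfile(bmi=27.0), "ABCD", 2),
            (ClinicalProfile(bmi=31.0, diabetes_dx=True), "ABCD", 4),
            (ClinicalProfile(bmi=31.0), "ABCD", 3),
            (ClinicalProfile(bmi=23.0, smoking="Current"), "ABCD", 1),
            (ClinicalProfile(fpg_mg_dl=90.0), "DBCD", 0),
            (ClinicalProfile(fpg_mg_dl=110.0), "DBCD", 2),
            (ClinicalProfile(hba1c_pct=7.0), "DBCD", 3),
            (ClinicalProfile(fpg_mg_dl=130.0, cvd_history=True), "DBCD", 4),
            (ClinicalProfile(sbp_mmHg=110.0, dbp_mmHg=70.0), "HBCD", 0),
            (ClinicalProfile(sbp_mmHg=124.0, dbp_mmHg=75.0), "HBCD", 2),
            (ClinicalProfile(sbp_mmHg=142.0, dbp_mmHg=75.0), "HBCD", 3),
            (ClinicalProfile(sbp_mmHg=142.0, dbp_mmHg=92.0, cvd_history=True),
             "HBCD", 4),
            (ClinicalProfile(ldl_mg_dl=100.0, hdl_mg_dl=55.0, tg_mg_dl=100.0),
             "LBCD", 0),
            (ClinicalProfile(ldl_mg_dl=140.0, hdl_mg_dl=55.0), "LBCD", 2),
            (ClinicalProfile(ldl_mg_dl=170.0), "LBCD", 3),
            (ClinicalProfile(lipid_dx_or_meds=True, cvd_history=True), "LBCD", 4),
        ],
    )
    def test_default_rules(self, profile, driver, expected):
        assert stage_driver(profile, driver) == expected

    def test_missing_required_inputs_yield_missing_stage(self):
        assert stage_driver(ClinicalProfile(), "ABCD") is None
        assert stage_driver(ClinicalProfile(), "DBCD") is None
        assert stage_driver(ClinicalProfile(), "HBCD") is None
        assert stage_driver(ClinicalProfile(), "LBCD") is None

    def test_unknown_driver_rejected(self):
        with pytest.raises(InvalidInputError):
            stage_driver(ClinicalProfile(bmi=25.0), "XBCD")

    def test_adding_complications_never_lowers_any_stage(self):
        """Severity monotonicity: complication flags can only raise stages."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            profile = ClinicalProfile(
                bmi=float(rng.uniform(18, 40)),
                fpg_mg_dl=float(rng.uniform(80, 180)),
                sbp_mmHg=float(rng.uniform(100, 170)),
                dbp_mmHg=float(rng.uniform(60, 100)),
                ldl_mg_dl=float(rng.uniform(80, 200)),
                smoking=str(rng.choice(["Never", "Current"])),
            )
            worse = ClinicalProfile(
                **{**profile.__dict__,
                   "complications": {"adiposity", "dysglycemia",
                                     "hypertension", "lipids"},
                   "cvd_history": True},
            )
            for driver in DRIVERS:
                assert stage_driver(worse, driver) >= stage_driver(profile, driver)


class TestStageCmbcd:
    @pytest.mark.parametrize(
        "cvd, stages, expected",
        [
            (False, (0, 0, 0, 0), "Stage 0"),
            (False, (2, 0, 0, 0), "Stage 1"),
            (True, (0, 1, 0, 0), "Stage 2–4"),
        ],
    )
    def test_quoted_rule_cases(self, cvd, stages, expected):
        assert stage_cmbcd(cvd, stages) == expected

    def test_uncovered_cell_warns_and_dominates(self):
        with pytest.warns(UserWarning):
            assert stage_cmbcd(True, (0, 0, 0, 0)) == "Stage 2–4"

    def test_matches_exhaustive_rule_oracle(self):
        """All 2 x 5^4 inputs agree with a direct statement of the rule."""

        def oracle(cvd, stages):
            if not cvd and all(s == 0 for s in stages):
                return "Stage 0"
            if not cvd and any(s >= 1 for s in stages):
                return "Stage 1"
            return "Stage 2–4"  # CVD history (incl. the uncovered all-zero cell)

        for cvd in (False, True):
            for stages in itertools.product(range(5), repeat=4):
                with pytest.warns(UserWarning) if (cvd and not any(stages)) \
                        else _no_warning_context():
                    assert stage_cmbcd(cvd, stages) == oracle(cvd, stages)

    def test_invalid_stage_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            stage_cmbcd(False, (0, 0, 5, 0))
        with pytest.raises(InvalidInputError):
            stage_cmbcd(False, (0, 0, 0))


def _no_warning_context():
    import contextlib

    return contextlib.nullcontext()


class TestEncodeRecord:
    @pytest.mark.parametrize(
        "age, band", [(45.0, "40–59"), (20.0, "20–39"), (39.999, "20–39"),
                      (40.0, "40–59"), (60.0, "60+"), (95.0, "60+")]
    )
    def test_age_bands_closed_on_left(self, age, band):
        assert age_band(age) == band

    def test_age_below_adult_domain_is_missing(self):
        assert age_band(19.0) is None

    @pytest.mark.parametrize(
        "ratio, band",
        [(0.5, "<100% FPL"), (1.0, "100–199% FPL"), (2.5, "200–399% FPL"),
         (4.0, ">400% FPL")],
    )
    def test_income_bands(self, ratio, band):
        assert income_band(ratio) == band

    @pytest.mark.parametrize(
        "drinks, band", [(0.0, "None"), (2.0, "Light"), (7.0, "Moderate"),
                         (20.0, "Heavy")]
    )
    def test_alcohol_bands(self, drinks, band):
        assert alcohol_band(drinks) == band

    @pytest.mark.parametrize(
        "fn, domain",
        [
            (age_band, np.linspace(20, 110, 901)),
            (income_band, np.linspace(0, 12, 1201)),
            (alcohol_band, np.linspace(0, 80, 801)),
        ],
    )
    def test_bands_partition_their_domain(self, fn, domain):
        """Every grid point maps to exactly one band, with no gaps and
        non-decreasing band order along the grid."""
        labels = [fn(float(x)) for x in domain]
        assert all(isinstance(lab, str) for lab in labels)
        seen = list(dict.fromkeys(labels))
        # once a band is left it is never revisited (no overlaps)
        assert labels == sorted(labels, key=seen.index)

    def test_negative_values_rejected(self):
        for fn in (age_band, income_band, alcohol_band):
            with pytest.raises(InvalidInputError):
                fn(-1.0)

    def test_full_record_roundtrip(self, schema):
        profile = ClinicalProfile(
            age_years=45, gender="Female", ethno_racial="Hispanic",
            education="College grad or above", fpl_ratio=2.5,
            employment="Employed, homemaker, or student", food_security="Full",
            insurance="Private", healthcare_site="Routine site - not ED",
            dash_accordant=True, physical_activity="Sufficient",
            alcohol_drinks_per_week=2.0, smoking="Never",
            bmi=23.0, fpg_mg_dl=90.0, sbp_mmHg=110.0, dbp_mmHg=70.0,
            ldl_mg_dl=100.0, hdl_mg_dl=60.0, tg_mg_dl=90.0,
        )
        rec = encode_record(profile, schema)
        assert rec["Age"] == "40–59"
        assert rec["Income"] == "200–399% FPL"
        assert rec["Diet"] == "DASH-accordant"
        assert rec["Alcohol use"] == "Light"
        assert rec["ABCD"] == "Stage 0"
        assert rec["CMBCD"] == "Stage 0"
        for name in schema.names:
            assert rec[name] in schema.levels(name)

    def test_missing_staging_input_propagates(self, schema):
        rec = encode_record(ClinicalProfile(age_years=50), schema)
        assert rec["ABCD"] is None and rec["CMBCD"] is None

    def test_invalid_level_rejected(self, schema):
        with pytest.raises(InvalidInputError):
            encode_record(ClinicalProfile(gender="Other"), schema)


class TestApplyExclusions:
    def _complete_record(self, schema, **overrides):
        rec = {name: schema.levels(name)[0] for name in schema.names}
        rec.update({"age_years": 45.0, "pregnant": False,
                    "type1_diabetes": False})
        rec.update(overrides)
        return rec

    def test_each_criterion_excludes(self, schema):
        records = pd.DataFrame(
            [
                self._complete_record(schema),
                self._complete_record(schema, Diet=None),
                self._complete_record(schema, age_years=19.0),
                self._complete_record(schema, pregnant=True),
                self._complete_record(schema, type1_diabetes=True),
            ]
        )
        clean, tally = apply_exclusions(records, schema)
        assert len(clean) == 1
        assert tally == {"missing": 1, "age_under_20": 1, "pregnant": 1,
                         "type1_diabetes": 1}
        assert list(tally) == ["missing", "age_under_20", "pregnant",
                               "type1_diabetes"]

    def test_output_is_complete_and_schema_only(self, schema):
        records = pd.DataFrame([self._complete_record(schema) for _ in range(5)])
        clean, _ = apply_exclusions(records, schema)
        assert list(clean.columns) == list(schema.names)
        assert not clean.isna().any().any()

    def test_records_without_metadata_only_checked_for_missingness(self, schema):
        rec = {name: schema.levels(name)[0] for name in schema.names}
        clean, tally = apply_exclusions(pd.DataFrame([rec]), schema)
        assert len(clean) == 1
        assert sum(tally.values()) == 0


class TestStagingRules:
    def test_yaml_roundtrip(self, tmp_path):
        rules = StagingRuleSet(bmi_obese=31.0)
        path = tmp_path / "rules.yaml"
        rules.to_yaml(path)
        assert StagingRuleSet.from_yaml(path) == rules

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("bmi_obese: 31\nnot_a_rule: 1\n")
        with pytest.raises(InvalidInputError):
            StagingRuleSet.from_yaml(path)

    def test_custom_cutoffs_change_staging(self):
        strict = StagingRuleSet(bmi_overweight=23.0)
        assert stage_driver(ClinicalProfile(bmi=24.0), "ABCD", strict) == 2
        assert stage_driver(ClinicalProfile(bmi=24.0), "ABCD") in (0, 1)
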