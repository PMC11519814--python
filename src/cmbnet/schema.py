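"""Variable schema, clinical staging, categorical encoding and exclusions.

The analysis operates on 18 categorical variables describing US adults:
socio-demographics, social determinants of health (SDOH), health behaviors,
the four secondary cardiometabolic drivers of the cardiometabolic-based
chronic disease (CMBCD) framework — adiposity (ABCD), dysglycemia (DBCD),
hypertension (HBCD) and lipids (LBCD), each staged 0 (no disease, no risk
factors) through 4 (pre-disease or disease with complications) — and the
overall CMBCD category anchored on cardiovascular-disease (CVD) history.

Variables are organised into six tiers, from non-modifiable demographics
down to the CMBCD outcome; the tiers drive the arc constraints used during
network learning (see :mod:`cmbnet.graphs`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DRIVERS = ("ABCD", "DBCD", "HBCD", "LBCD")

#: Metadata columns carried alongside the 18 model variables so that the
#: exclusion criteria can be applied on raw values.
META_COLUMNS = ("age_years", "pregnant", "type1_diabetes")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variable:
    """One categorical model variable: ordered levels plus a tier label.

    Tiers (descending): 1 non-modifiable socio-demographics, 2 modifiable
    socio-demographics, 3 SDOH, 4 behavioral factors, 5 cardiometabolic
    drivers, 6 CMBCD.
    """

    name: str
    levels: tuple[str, ...]
    tier: int

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise InvalidInputError(f"{self.name}: need >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise InvalidInputError(f"{self.name}: duplicate levels")
        if self.tier not in range(1, 7):
            raise InvalidInputError(f"{self.name}: tier must be 1..6")


@dataclass(frozen=True)
class VariableSchema:
    """Ordered collection of :class:`Variable` definitions."""

    variables: tuple[Variable, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise InvalidInputError("variable names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def levels(self, name: str) -> tuple[str, ...]:
        return self[name].levels

    def tier(self, name: str) -> int:
        return self[name].tier

    def drop(self, name: str) -> "VariableSchema":
        """Schema without one variable (used for stratified runs)."""
        if name not in self:
            raise KeyError(name)
        return VariableSchema(tuple(v for v in self.variables if v.name != name))


_STAGE_LEVELS = tuple(f"Stage {k}" for k in range(5))


def build_default_schema() -> VariableSchema:
    """The default 18-variable schema with verbatim level labels."""
    return VariableSchema(
        (
            Variable("Age", ("20–39", "40–59", "60+"), 1),
            Variable("Gender", ("Male", "Female"), 1),
            Variable(
                "Ethno-racial group",
                (
                    "Non-Hispanic White",
                    "Non-Hispanic Black",
                    "Hispanic",
                    "Other or Multiracial",
                ),
                1,
            ),
            Variable(
                "Education",
                (
                    "Less than high school",
                    "High school grad/GED",
                    "Some college or AA degree",
                    "College grad or above",
                ),
                2,
            ),
            Variable(
                "Income",
                ("<100% FPL", "100–199% FPL", "200–399% FPL", ">400% FPL"),
                2,
            ),
            Variable(
                "Employment status",
                (
                    "Employed, homemaker, or student",
                    "Retired",
                    "Unemployed or unable to work",
                ),
                2,
            ),
            Variable(
                "Household food security",
                ("Full", "Marginal", "Low", "Very low"),
                3,
            ),
            Variable(
                "Health insurance status",
                ("No health insurance", "Private", "Public - Medicare", "Public - other"),
                3,
            ),
            Variable(
                "Routine healthcare site",
                ("No routine healthcare site", "Routine site - ED", "Routine site - not ED"),
                3,
            ),
            Variable("Diet", ("Not DASH-accordant", "DASH-accordant"), 4),
            Variable("Physical activity", ("None", "Not sufficient", "Sufficient"), 4),
            Variable("Alcohol use", ("None", "Light", "Moderate", "Heavy"), 4),
            Variable("Smoking status", ("Never", "Former", "Current"), 4),
            Variable("ABCD", _STAGE_LEVELS, 5),
            Variable("DBCD", _STAGE_LEVELS, 5),
            Variable("HBCD", _STAGE_LEVELS, 5),
            Variable("LBCD", _STAGE_LEVELS, 5),
            Variable("CMBCD", ("Stage 0", "Stage 1", "Stage 2–4"), 6),
        )
    )


# ---------------------------------------------------------------------------
# Staging rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StagingRuleSet:
    """Numeric cut-offs used to stage the four cardiometabolic drivers.

    The stage *semantics* (0 no disease/no risk, 1 risk factors, 2
    predisease, 3 disease, 4 with complications) are fixed; the numeric
    thresholds are configurable so that alternative rule sets can be
    dropped in via :meth:`from_yaml`.  Defaults follow standard clinical
    categories (ADA glycemia, ACC/AHA blood pressure, NCEP lipids, WHO BMI).
    """

    bmi_overweight: float = 25.0
    bmi_obese: float = 30.0
    fpg_prediabetes: float = 100.0
    fpg_diabetes: float = 126.0
    hba1c_prediabetes: float = 5.7
    hba1c_diabetes: float = 6.5
    sbp_elevated: float = 120.0
    sbp_hypertension: float = 130.0
    dbp_hypertension: float = 80.0
    ldl_borderline: float = 130.0
    ldl_high: float = 160.0
    hdl_low: float = 40.0
    tg_borderline: float = 150.0
    tg_high: float = 200.0
    #: drinks/week band edges for alcohol use
    alcohol_light_max: float = 3.0
    alcohol_moderate_max: float = 14.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "StagingRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown staging-rule keys: {sorted(unknown)}")
        return cls(**raw)


DEFAULT_RULES = StagingRuleSet()


@dataclass
class ClinicalProfile:
    """Raw per-person inputs from which the 18 categorical variables derive.

    Numeric laboratory fields may be ``None`` (missing); a missing staging
    input makes the derived category missing, and the record is later
    dropped by :func:`apply_exclusions`.
    """

    age_years: float | None = None
    gender: str | None = None
    ethno_racial: str | None = None
    pregnant: bool = False
    type1_diabetes: bool = False
    # socio-economic / SDOH raw answers
    education: str | None = None
    fpl_ratio: float | None = None  # family income as a ratio to the FPL
    employment: str | None = None
    food_security: str | None = None
    insurance: str | None = None
    healthcare_site: str | None = None
    # behavioral
    dash_accordant: bool | None = None
    physical_activity: str | None = None
    alcohol_drinks_per_week: float | None = None
    smoking: str | None = None
    # clinical
    bmi: float | None = None
    waist_cm: float | None = None
    fpg_mg_dl: float | None = None
    hba1c_pct: float | None = None
    diabetes_dx: bool = False
    sbp_mmHg: float | None = None
    dbp_mmHg: float | None = None
    htn_dx_or_meds: bool = False
    ldl_mg_dl: float | None = None
    hdl_mg_dl: float | None = None
    tg_mg_dl: float | None = None
    lipid_dx_or_meds: bool = False
    #: driver-specific complication flags, e.g. {"adiposity", "dysglycemia"}
    complications: set[str] = field(default_factory=set)
    #: any of congestive heart failure, coronary artery disease, heart
    #: attack, or stroke
    cvd_history: bool = False

    def __post_init__(self) -> None:
        for name in (
            "age_years", "fpl_ratio", "alcohol_drinks_per_week", "bmi",
            "waist_cm", "fpg_mg_dl", "hba1c_pct", "sbp_mmHg", "dbp_mmHg",
            "ldl_mg_dl", "hdl_mg_dl", "tg_mg_dl",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidInputError(f"{name} must be non-negative, got {v}")


def _behavioral_risk(profile: ClinicalProfile, rules: StagingRuleSet) -> bool:
    """Any behavioral risk factor; missing answers count as absent."""
    if profile.smoking == "Current":
        return True
    if profile.physical_activity == "None":
        return True
    if profile.dash_accordant is False:
        return True
    drinks = profile.alcohol_drinks_per_week
    if drinks is not None and drinks > rules.alcohol_moderate_max:
        return True
    return False


def stage_driver(
    profile: ClinicalProfile,
    driver: str,
    rules: StagingRuleSet = DEFAULT_RULES,
) -> int | None:
    """Stage one cardiometabolic driver 0–4; ``None`` if inputs are missing.

    Stage 4 means pre-disease or disease *with* a complication relevant to
    the driver; a recorded CVD history always counts as such a
    complication.
    """
    if driver not in DRIVERS:
        raise InvalidInputError(f"unknown driver {driver!r}")
    p, r = profile, rules
    if driver == "ABCD":
        if p.bmi is None:
            return None
        complication = (
            "adiposity" in p.complications
            or p.cvd_history
            or p.diabetes_dx
            or p.htn_dx_or_meds
            or p.lipid_dx_or_meds
        )
        if p.bmi >= r.bmi_overweight and complication:
            return 4
        if p.bmi >= r.bmi_obese:
            return 3
        if p.bmi >= r.bmi_overweight:
            return 2
        return 1 if (_behavioral_risk(p, r) or "adiposity" in p.complications) else 0
    if driver == "DBCD":
        disease = p.diabetes_dx
        predisease = False
        measured = p.diabetes_dx
        if p.fpg_mg_dl is not None:
            measured = True
            disease = disease or p.fpg_mg_dl >= r.fpg_diabetes
            predisease = predisease or r.fpg_prediabetes <= p.fpg_mg_dl < r.fpg_diabetes
        if p.hba1c_pct is not None:
            measured = True
            disease = disease or p.hba1c_pct >= r.hba1c_diabetes
            predisease = predisease or r.hba1c_prediabetes <= p.hba1c_pct < r.hba1c_diabetes
        if not measured:
            return None
        complication = "dysglycemia" in p.complications or p.cvd_history
        if (disease or predisease) and complication:
            return 4
        if disease:
            return 3
        if predisease:
            return 2
        metabolic_risk = p.bmi is not None and p.bmi >= r.bmi_overweight
        return 1 if (_behavioral_risk(p, r) or metabolic_risk or complication) else 0
    if driver == "HBCD":
        if (p.sbp_mmHg is None or p.dbp_mmHg is None) and not p.htn_dx_or_meds:
            return None
        hypertension = p.htn_dx_or_meds
        elevated = False
        if p.sbp_mmHg is not None and p.dbp_mmHg is not None:
            hypertension = (
                hypertension
                or p.sbp_mmHg >= r.sbp_hypertension
                or p.dbp_mmHg >= r.dbp_hypertension
            )
            elevated = (
                r.sbp_elevated <= p.sbp_mmHg < r.sbp_hypertension
                and p.dbp_mmHg < r.dbp_hypertension
            )
        complication = "hypertension" in p.complications or p.cvd_history
        if (hypertension or elevated) and complication:
            return 4
        if hypertension:
            return 3
        if elevated:
            return 2
        metabolic_risk = p.bmi is not None and p.bmi >= r.bmi_overweight
        return 1 if (_behavioral_risk(p, r) or metabolic_risk or complication) else 0
    # LBCD
    have_lab = any(v is not None for v in (p.ldl_mg_dl, p.hdl_mg_dl, p.tg_mg_dl))
    if not have_lab and not p.lipid_dx_or_meds:
        return None
    disease = p.lipid_dx_or_meds
    borderline = False
    if p.ldl_mg_dl is not None:
        disease = disease or p.ldl_mg_dl >= r.ldl_high
        borderline = borderline or r.ldl_borderline <= p.ldl_mg_dl < r.ldl_high
    if p.tg_mg_dl is not None:
        disease = disease or p.tg_mg_dl >= r.tg_high
        borderline = borderline or r.tg_borderline <= p.tg_mg_dl < r.tg_high
    if p.hdl_mg_dl is not None:
        disease = disease or p.hdl_mg_dl < r.hdl_low
    complication = "lipids" in p.complications or p.cvd_history
    if (disease or borderline) and complication:
        return 4
    if disease:
        return 3
    if borderline:
        return 2
    metabolic_risk = p.bmi is not None and p.bmi >= r.bmi_overweight
    return 1 if (_behavioral_risk(p, r) or metabolic_risk or complication) else 0


def stage_cmbcd(cvd_history: bool, driver_stages: Sequence[int]) -> str:
    """Overall CMBCD category from CVD history and the four driver stages.

    Three-case rule: "Stage 0" = no CVD history and all drivers in stage 0;
    "Stage 1" = no CVD history and any driver in stage 1+; "Stage 2–4" =
    CVD history with any driver in stage 1+.  The combination (CVD history,
    all drivers stage 0) is not covered by the rule; it is classified as
    "Stage 2–4" — history of clinical CVD dominates — with a warning.
    """
    stages = tuple(driver_stages)
    if len(stages) != 4 or any(s not in range(5) for s in stages):
        raise InvalidInputError(f"need four stages in 0..4, got {stages!r}")
    any_active = any(s >= 1 for s in stages)
    if not cvd_history:
        return "Stage 1" if any_active else "Stage 0"
    if not any_active:
        warnings.warn(
            "CVD history with all drivers in stage 0 is outside the staging "
            "rule; classifying as 'Stage 2–4'",
            stacklevel=2,
        )
    return "Stage 2–4"


# ---------------------------------------------------------------------------
# Encoding continuous fields into bands
# ---------------------------------------------------------------------------


def age_band(age_years: float) -> str | None:
    """Closed-left age bands [20,40) [40,60) [60,inf); under 20 -> None."""
    if age_years < 0:
        raise InvalidInputError(f"age outside any band: {age_years}")
    if age_years < 20:
        return None  # below the adult domain; removed by apply_exclusions
    if age_years < 40:
        return "20–39"
    if age_years < 60:
        return "40–59"
    return "60+"


def income_band(fpl_ratio: float) -> str:
    if fpl_ratio < 0:
        raise InvalidInputError(f"FPL ratio outside any band: {fpl_ratio}")
    if fpl_ratio < 1:
        return "<100% FPL"
    if fpl_ratio < 2:
        return "100–199% FPL"
    if fpl_ratio < 4:
        return "200–399% FPL"
    return ">400% FPL"


def alcohol_band(drinks_per_week: float, rules: StagingRuleSet = DEFAULT_RULES) -> str:
    if drinks_per_week < 0:
        raise InvalidInputError(f"drinks/week outside any band: {drinks_per_week}")
    if drinks_per_week == 0:
        return "None"
    if drinks_per_week <= rules.alcohol_light_max:
        return "Light"
    if drinks_per_week <= rules.alcohol_moderate_max:
        return "Moderate"
    return "Heavy"


def _checked_level(value: str | None, variable: Variable) -> str | None:
    if value is None:
        return None
    if value not in variable.levels:
        raise InvalidInputError(
            f"{variable.name}: {value!r} is not one of {variable.levels}"
        )
    return value


def encode_record(
    profile: ClinicalProfile,
    schema: VariableSchema | None = None,
    rules: StagingRuleSet = DEFAULT_RULES,
) -> dict[str, object]:
    """Encode one clinical profile into an 18-variable categorical record.

    Returns a mapping from variable name to level label (``None`` for
    missing), plus the raw ``age_years``/``pregnant``/``type1_diabetes``
    metadata needed by :func:`apply_exclusions`.
    """
    schema = schema or build_default_schema()
    rec: dict[str, object] = {}
    rec["Age"] = None if profile.age_years is None else age_band(profile.age_years)
    rec["Gender"] = _checked_level(profile.gender, schema["Gender"])
    rec["Ethno-racial group"] = _checked_level(
        profile.ethno_racial, schema["Ethno-racial group"]
    )
    rec["Education"] = _checked_level(profile.education, schema["Education"])
    rec["Income"] = None if profile.fpl_ratio is None else income_band(profile.fpl_ratio)
    rec["Employment status"] = _checked_level(
        profile.employment, schema["Employment status"]
    )
    rec["Household food security"] = _checked_level(
        profile.food_security, schema["Household food security"]
    )
    rec["Health insurance status"] = _checked_level(
        profile.insurance, schema["Health insurance status"]
    )
    rec["Routine healthcare site"] = _checked_level(
        profile.healthcare_site, schema["Routine healthcare site"]
    )
    if profile.dash_accordant is None:
        rec["Diet"] = None
    else:
        rec["Diet"] = "DASH-accordant" if profile.dash_accordant else "Not DASH-accordant"
    rec["Physical activity"] = _checked_level(
        profile.physical_activity, schema["Physical activity"]
    )
    if profile.alcohol_drinks_per_week is None:
        rec["Alcohol use"] = None
    else:
        rec["Alcohol use"] = alcohol_band(profile.alcohol_drinks_per_week, rules)
    rec["Smoking status"] = _checked_level(profile.smoking, schema["Smoking status"])
    stages = {d: stage_driver(profile, d, rules) for d in DRIVERS}
    for d in DRIVERS:
        rec[d] = None if stages[d] is None else f"Stage {stages[d]}"
    if any(stages[d] is None for d in DRIVERS):
        rec["CMBCD"] = None
    else:
        rec["CMBCD"] = stage_cmbcd(profile.cvd_history, [stages[d] for d in DRIVERS])
    rec["age_years"] = profile.age_years
    rec["pregnant"] = profile.pregnant
    rec["type1_diabetes"] = profile.type1_diabetes
    return rec


def encode_profiles(
    profiles: Iterable[ClinicalProfile],
    schema: VariableSchema | None = None,
    rules: StagingRuleSet = DEFAULT_RULES,
) -> pd.DataFrame:
    schema = schema or build_default_schema()
    return pd.DataFrame.from_records([encode_record(p, schema, rules) for p in profiles])


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------


def apply_exclusions(
    records: pd.DataFrame, schema: VariableSchema | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records per the study's exclusion criteria.

    Criteria, in order: missing values for any model variable; age below
    20; pregnancy; type 1 diabetes.  Each removed record is tallied under
    the first criterion that applies.  Raw age/pregnancy/type-1 metadata
    columns are consulted when present and dropped from the output, which
    contains exactly the schema columns with zero missing cells.
    """
    schema = schema or build_default_schema()
    missing_cols = [c for c in schema.names if c not in records.columns]
    if missing_cols:
        raise InvalidInputError(f"records lack schema columns: {missing_cols}")
    model = records[list(schema.names)]
    missing_mask = model.isna().any(axis=1) | (model == "").any(axis=1)
    n = len(records)
    age_mask = pd.Series(False, index=records.index)
    if "age_years" in records.columns:
        age = pd.to_numeric(records["age_years"], errors="coerce")
        age_mask = age.isna() | (age < 20)
    preg_mask = (
        records["pregnant"].fillna(False).astype(bool)
        if "pregnant" in records.columns
        else pd.Series(False, index=records.index)
    )
    t1d_mask = (
        records["type1_diabetes"].fillna(False).astype(bool)
        if "type1_diabetes" in records.columns
        else pd.Series(False, index=records.index)
    )
    tally = {"missing": 0, "age_under_20": 0, "pregnant": 0, "type1_diabetes": 0}
    tally["missing"] = int(missing_mask.sum())
    remaining = ~missing_mask
    tally["age_under_20"] = int((remaining & age_mask).sum())
    remaining &= ~age_mask
    tally["pregnant"] = int((remaining & preg_mask).sum())
    remaining &= ~preg_mask
    tally["type1_diabetes"] = int((remaining & t1d_mask).sum())
    remaining &= ~t1d_mask
    kept = model[remaining].reset_index(drop=True)
    logger.info(
        "exclusions: kept %d of %d records (%s)", len(kept), n,
        ", ".join(f"{k}={v}" for k, v in tally.items()),
    )
    return kept, tally


# ---------------------------------------------------------------------------
# Dataset I/O and validation
# ---------------------------------------------------------------------------


def validate_dataset(
    data: pd.DataFrame, schema: VariableSchema, allow_missing: bool = False
) -> None:
    """Check a dataset conforms to the schema; raise with offenders listed."""
    problems = []
    for name in schema.names:
        if name not in data.columns:
            problems.append(f"missing column {name!r}")
            continue
        col = data[name].dropna()
        col = col[col != ""]
        bad = set(col.unique()) - set(schema.levels(name))
        if bad:
            problems.append(f"{name}: unknown levels {sorted(bad)!r}")
        if not allow_missing and (data[name].isna().any() or (data[name] == "").any()):
            problems.append(f"{name}: contains missing cells")
    if problems:
        raise InvalidInputError("dataset does not match schema: " + "; ".join(problems))


def read_dataset(path, schema: VariableSchema | None = None) -> pd.DataFrame:
    """Read a dataset CSV; empty cells become missing (NaN)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    if schema is not None:
        validate_dataset(df, schema, allow_missing=True)
    return df


def write_dataset(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False, na_rep="")
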