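"""Cohort schema and closed-form clinical derivations for canine MMVD studies.

This module defines the per-dog record used throughout the package —
demographics, clinical grades, raw echocardiographic measures, and the 13
morphometric body/thorax/head measurements — together with every derived
quantity that is a deterministic formula of a single record:

* allometric (Wesselowski) indexing of mitral valve and annulus measures
  to body weight, ``raw / weight**b`` with a measure-specific exponent;
* semiquantitative regurgitant-jet grading from the ARJ/LAA percentage;
* mitral valve prolapse grading from the P/T reference-line position;
* the age-weighted MMVD severity score ``(MVP + jet) * 5 / age``;
* the six morphometric body indexes (cephalic, craniofacial, thoracic,
  height-thorax, volume, body size);
* ACVIM stage-B1 eligibility (no atrial or ventricular enlargement) and
  the sphericity-index abnormality flag.

Units are fixed: centimetres (cm, cm^2) for lengths and areas, kilograms
for weight, years for age, degrees for the head stop angle.  Missing
numeric cells are permitted in the CSV interchange format (empty field)
and propagate as NaN; downstream analyses subset to complete cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "DomainError",
    "MorphometricProfile",
    "MorphometricIndexes",
    "DogRecord",
    "DerivedMeasures",
    "EXPOSURES",
    "WESSELOWSKI_EXPONENTS",
    "COHORT_COLUMNS",
    "COATS",
    "wesselowski_index",
    "index_measure",
    "grade_jet",
    "grade_mvp",
    "severity_score",
    "compute_indexes",
    "b1_filter",
    "sphericity_flag",
    "derive_measures",
    "read_cohort",
    "write_cohort",
    "cohort_frame",
]


class SchemaError(ValueError):
    """The cohort file does not match the expected column dictionary."""


class ValidationError(ValueError):
    """A record violates a range or type constraint."""


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of a formula."""


#: The 13 morphometric measurements treated as continuous exposures.
#: HNL (= HL + NL) and the composite indexes are excluded: HNL is a linear
#: sum of two exposures and the indexes are handled downstream via the
#: delta method.
EXPOSURES = [
    "wh", "bl", "cw", "th", "tw", "tl",
    "tc1", "tc2", "tc3", "hl", "nl", "hw", "ha",
]

#: Allometric scaling exponents for indexing valve/annulus measures to
#: body weight (Wesselowski method): indexed = raw / weight**b.
WESSELOWSKI_EXPONENTS = {
    "amvl": 0.37,
    "amvw": 0.41,
    "amva": 0.78,
    "mvad": 0.37,
    "mvas": 0.40,
}

COATS = ("blenheim", "black_and_tan", "ruby", "tricolor")

#: CSV interchange header, in order.
COHORT_COLUMNS = [
    "dog_id", "age_years", "sex", "neutered", "weight_kg", "coat", "bcs",
    "murmur_grade", "la_ao", "lviddn", "mvp_grade", "arj_laa_pct",
    "jet_all_systoles", "amvl_cm", "amvw_cm", "amva_cm2", "mvad_cm",
    "mvas_cm", "si", "wh_cm", "bl_cm", "cw_cm", "th_cm", "tw_cm", "tl_cm",
    "tc1_cm", "tc2_cm", "tc3_cm", "hl_cm", "nl_cm", "hw_cm", "ha_deg",
]

_MVP_POSITIONS = {"none": 0, "below_P": 1, "between_P_T": 2, "beyond_T": 3}


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class MorphometricProfile:
    """The 13 raw morphometric measurements of one dog (cm; HA in degrees).

    ``hnl`` (head + nose length) is exposed as a derived property so the
    identity HNL = HL + NL holds exactly by construction.
    """

    wh: float
    bl: float
    cw: float
    th: float
    tw: float
    tl: float
    tc1: float
    tc2: float
    tc3: float
    hl: float
    nl: float
    hw: float
    ha: float

    @property
    def hnl(self) -> float:
        return self.hl + self.nl

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in EXPOSURES}

    def validate(self, dog_id: str = "?") -> None:
        for k in EXPOSURES:
            v = getattr(self, k)
            if _isnan(v):
                continue
            if not math.isfinite(v):
                raise ValidationError(f"{dog_id}: {k} is not finite")
            if k == "ha":
                if not (0.0 < v < 180.0):
                    raise ValidationError(
                        f"{dog_id}: head stop angle {v} outside (0, 180) degrees"
                    )
            elif v <= 0:
                raise ValidationError(f"{dog_id}: {k} must be positive, got {v}")


@dataclass
class MorphometricIndexes:
    """The six composite body indexes (dimensionless)."""

    cephalic_index: float
    craniofacial_ratio: float
    thoracic_index: float
    height_thorax_index: float
    volume_index: float
    body_size: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class DogRecord:
    """One subject: demographics, clinical grades, echo measures, morphometry.

    Numeric fields may be NaN (missing); ordinal fields may be None.
    """

    dog_id: str
    age: float                      # years
    sex: str                        # "M" | "F"
    neutered: Optional[bool]
    weight: float                   # kg
    coat: str                       # one of COATS
    bcs: Optional[int]              # 1-9
    murmur_grade: Optional[int]     # 0-3
    la_ao: float
    lviddn: float
    mvp_grade: Optional[int]        # 0-3
    arj_laa_pct: float              # 0-100
    jet_all_systoles: Optional[bool]
    amvl: float                     # cm
    amvw: float                     # cm
    amva: float                     # cm^2
    mvad: float                     # cm
    mvas: float                     # cm
    si: float
    morpho: MorphometricProfile

    def validate(self) -> None:
        d = self.dog_id
        if self.sex not in ("M", "F"):
            raise ValidationError(f"{d}: sex must be M or F, got {self.sex!r}")
        if self.coat not in COATS:
            raise ValidationError(f"{d}: unknown coat {self.coat!r}")
        for name, lo, hi in (
            ("bcs", 1, 9),
            ("murmur_grade", 0, 3),
            ("mvp_grade", 0, 3),
        ):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValidationError(
                    f"{d}: {name}={v} outside ordinal range {lo}-{hi}"
                )
        for name in ("age", "weight"):
            v = getattr(self, name)
            if not _isnan(v) and (not math.isfinite(v) or v <= 0):
                raise ValidationError(f"{d}: {name} must be finite and > 0")
        for name in ("la_ao", "lviddn", "amvl", "amvw", "amva",
                     "mvad", "mvas", "si"):
            v = getattr(self, name)
            if not _isnan(v) and (not math.isfinite(v) or v <= 0):
                raise ValidationError(f"{d}: {name} must be finite and > 0")
        if not _isnan(self.arj_laa_pct) and not (0.0 <= self.arj_laa_pct <= 100.0):
            raise ValidationError(
                f"{d}: arj_laa_pct={self.arj_laa_pct} outside [0, 100]"
            )
        self.morpho.validate(d)


@dataclass
class DerivedMeasures:
    """Per-dog derived quantities: indexed measures, grades, flags, indexes."""

    amvl_i: float
    amvw_i: float
    amva_i: float
    mvad_i: float
    mvas_i: float
    severity: float
    jet_grade: Optional[int]
    spherical_flag: Optional[bool]
    b1_eligible: Optional[bool]
    indexes: MorphometricIndexes


def wesselowski_index(raw: float, weight: float, exponent: float) -> float:
    """Allometrically index a valve measure to body weight.

    Returns ``raw / weight**exponent``.  ``raw`` in cm or cm^2, ``weight``
    in kg; the exponent is measure-specific (see WESSELOWSKI_EXPONENTS).
    """
    if _isnan(raw) or _isnan(weight):
        return float("nan")
    if weight <= 0:
        raise DomainError(f"weight must be positive, got {weight}")
    if raw <= 0:
        raise DomainError(f"raw measure must be positive, got {raw}")
    return raw / weight ** exponent


def index_measure(name: str, raw: float, weight: float) -> float:
    """Index a named measure (amvl/amvw/amva/mvad/mvas) to body weight."""
    try:
        b = WESSELOWSKI_EXPONENTS[name]
    except KeyError:
        raise DomainError(f"no scaling exponent for measure {name!r}") from None
    return wesselowski_index(raw, weight, b)


def grade_jet(arj_laa_pct: float, all_systoles: bool) -> int:
    """Grade mitral regurgitation jet size on the 0-5 ordinal scale.

    0 = absent; 1 = trivial (< 10 % of left atrial area, not in all
    systoles); 2 = trace (< 10 %, all systoles); 3 = mild [10, 30);
    4 = moderate [30, 70); 5 = severe (>= 70).  Bins are lower-inclusive,
    upper-exclusive; when the jet is absent (0 %) the all-systoles flag is
    ignored.
    """
    p = arj_laa_pct
    if _isnan(p) or not (0.0 <= p <= 100.0):
        raise DomainError(f"arj_laa_pct={p} outside [0, 100]")
    if p == 0:
        return 0
    if p < 10:
        return 2 if all_systoles else 1
    if p < 30:
        return 3
    if p < 70:
        return 4
    return 5


def grade_mvp(position: str) -> int:
    """Grade mitral valve prolapse from leaflet position vs the P/T lines.

    none -> 0; below_P -> 1 (mild); between_P_T -> 2 (moderate);
    beyond_T -> 3 (severe).
    """
    try:
        return _MVP_POSITIONS[position]
    except KeyError:
        raise DomainError(
            f"unknown prolapse position {position!r}; "
            f"expected one of {sorted(_MVP_POSITIONS)}"
        ) from None


def severity_score(mvp_grade: float, jet_grade: float, age: float) -> float:
    """Age-weighted MMVD severity: ((MVP + jet) * 5) / age."""
    if _isnan(mvp_grade) or _isnan(jet_grade) or _isnan(age):
        return float("nan")
    if age <= 0:
        raise DomainError(f"age must be positive, got {age}")
    if mvp_grade < 0 or jet_grade < 0:
        raise DomainError("grades must be non-negative")
    return (mvp_grade + jet_grade) * 5.0 / age


def compute_indexes(profile: MorphometricProfile, weight: float) -> MorphometricIndexes:
    """Evaluate the six composite body indexes.

    cephalic = 100*HW/HNL; craniofacial = NL/HL; thoracic = 100*TW/TH;
    height-thorax = 100*TH/WH; volume = 100*weight/WH; body size = 100*WH/BL.
    """
    p = profile
    for name, den in (("hnl", p.hnl), ("hl", p.hl), ("th", p.th),
                      ("wh", p.wh), ("bl", p.bl)):
        if not _isnan(den) and den == 0:
            raise DomainError(f"zero denominator: {name}")
    def _nan_div(num, den):
        if _isnan(num) or _isnan(den):
            return float("nan")
        return num / den
    return MorphometricIndexes(
        cephalic_index=_nan_div(p.hw * 100.0, p.hnl),
        craniofacial_ratio=_nan_div(p.nl, p.hl),
        thoracic_index=_nan_div(p.tw * 100.0, p.th),
        height_thorax_index=_nan_div(p.th * 100.0, p.wh),
        volume_index=_nan_div(weight * 100.0, p.wh),
        body_size=_nan_div(p.wh * 100.0, p.bl),
    )


def b1_filter(la_ao: float, lviddn: float) -> bool:
    """ACVIM stage-B1 eligibility: no left atrial or ventricular enlargement.

    True iff LA/Ao < 1.6 and the normalized LV diastolic dimension < 1.7;
    either ratio at or above its threshold denotes enlargement.
    """
    if _isnan(la_ao) or _isnan(lviddn) or la_ao <= 0 or lviddn <= 0:
        raise DomainError("la_ao and lviddn must be positive")
    return la_ao < 1.6 and lviddn < 1.7


def sphericity_flag(si: float) -> bool:
    """True (abnormally spherical ventricle) iff the sphericity index < 1.65."""
    if _isnan(si) or si <= 0:
        raise DomainError(f"sphericity index must be positive, got {si}")
    return si < 1.65


def derive_measures(rec: DogRecord) -> DerivedMeasures:
    """All per-record derived quantities, NaN-propagating on missing inputs."""
    jet = None
    if not _isnan(rec.arj_laa_pct) and rec.jet_all_systoles is not None:
        jet = grade_jet(rec.arj_laa_pct, rec.jet_all_systoles)
    sev = severity_score(
        float("nan") if rec.mvp_grade is None else rec.mvp_grade,
        float("nan") if jet is None else jet,
        rec.age,
    )
    return DerivedMeasures(
        amvl_i=index_measure("amvl", rec.amvl, rec.weight),
        amvw_i=index_measure("amvw", rec.amvw, rec.weight),
        amva_i=index_measure("amva", rec.amva, rec.weight),
        mvad_i=index_measure("mvad", rec.mvad, rec.weight),
        mvas_i=index_measure("mvas", rec.mvas, rec.weight),
        severity=sev,
        jet_grade=jet,
        spherical_flag=None if _isnan(rec.si) else sphericity_flag(rec.si),
        b1_eligible=(None if (_isnan(rec.la_ao) or _isnan(rec.lviddn))
                     else b1_filter(rec.la_ao, rec.lviddn)),
        indexes=compute_indexes(rec.morpho, rec.weight),
    )


# ---------------------------------------------------------------------------
# CSV interchange


def _parse_float(v) -> float:
    if v is None or (isinstance(v, str) and v.strip() == "") or pd.isna(v):
        return float("nan")
    return float(v)


def _parse_int(v) -> Optional[int]:
    if v is None or (isinstance(v, str) and v.strip() == "") or pd.isna(v):
        return None
    f = float(v)
    if f != int(f):
        raise ValidationError(f"expected integer, got {v!r}")
    return int(f)


def _parse_bool(v) -> Optional[bool]:
    i = _parse_int(v)
    if i is None:
        return None
    if i not in (0, 1):
        raise ValidationError(f"expected 0/1 flag, got {v!r}")
    return bool(i)


def read_cohort(path) -> list[DogRecord]:
    """Read a cohort CSV (see COHORT_COLUMNS) into validated records.

    Raises SchemaError for a missing/unknown column and ValidationError
    (naming the dog) for out-of-range values.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype={"dog_id": str, "sex": str, "coat": str},
                     float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected column(s): {', '.join(extra)}")
    records = []
    for i, row in df.iterrows():
        dog_id = str(row["dog_id"])
        try:
            morpho = MorphometricProfile(
                **{k: _parse_float(row[f"{k}_cm" if k != "ha" else "ha_deg"])
                   for k in EXPOSURES}
            )
            rec = DogRecord(
                dog_id=dog_id,
                age=_parse_float(row["age_years"]),
                sex=str(row["sex"]).strip(),
                neutered=_parse_bool(row["neutered"]),
                weight=_parse_float(row["weight_kg"]),
                coat=str(row["coat"]).strip(),
                bcs=_parse_int(row["bcs"]),
                murmur_grade=_parse_int(row["murmur_grade"]),
                la_ao=_parse_float(row["la_ao"]),
                lviddn=_parse_float(row["lviddn"]),
                mvp_grade=_parse_int(row["mvp_grade"]),
                arj_laa_pct=_parse_float(row["arj_laa_pct"]),
                jet_all_systoles=_parse_bool(row["jet_all_systoles"]),
                amvl=_parse_float(row["amvl_cm"]),
                amvw=_parse_float(row["amvw_cm"]),
                amva=_parse_float(row["amva_cm2"]),
                mvad=_parse_float(row["mvad_cm"]),
                mvas=_parse_float(row["mvas_cm"]),
                si=_parse_float(row["si"]),
                morpho=morpho,
            )
            rec.validate()
        except ValidationError as e:
            raise ValidationError(f"row {i} ({dog_id}): {e}") from None
        records.append(rec)
    return records


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_cohort(records: Sequence[DogRecord], path) -> None:
    """Write records to the cohort CSV format (empty cell = missing)."""
    rows = []
    for r in records:
        m = r.morpho
        rows.append([
            r.dog_id, _fmt(r.age), r.sex, _fmt(r.neutered), _fmt(r.weight),
            r.coat, _fmt(r.bcs), _fmt(r.murmur_grade), _fmt(r.la_ao),
            _fmt(r.lviddn), _fmt(r.mvp_grade), _fmt(r.arj_laa_pct),
            _fmt(r.jet_all_systoles), _fmt(r.amvl), _fmt(r.amvw),
            _fmt(r.amva), _fmt(r.mvad), _fmt(r.mvas), _fmt(r.si),
            _fmt(m.wh), _fmt(m.bl), _fmt(m.cw), _fmt(m.th), _fmt(m.tw),
            _fmt(m.tl), _fmt(m.tc1), _fmt(m.tc2), _fmt(m.tc3), _fmt(m.hl),
            _fmt(m.nl), _fmt(m.hw), _fmt(m.ha),
        ])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(COHORT_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(str(x) for x in row) + "\n")


def cohort_frame(records: Sequence[DogRecord]) -> pd.DataFrame:
    """Flatten records into an analysis DataFrame.

    Columns: demographics (with sex_F / blenheim indicator coding —
    coat collapsed to Blenheim vs other), the 13 exposures, the raw echo
    measures, and the derived outcome columns (indexed valve measures,
    jet grade, severity, flags).
    """
    rows = []
    for r in records:
        d = derive_measures(r)
        row = {
            "dog_id": r.dog_id,
            "age": r.age,
            "sex_F": 1.0 if r.sex == "F" else 0.0,
            "neutered": np.nan if r.neutered is None else float(r.neutered),
            "weight": r.weight,
            "blenheim": 1.0 if r.coat == "blenheim" else 0.0,
            "bcs": np.nan if r.bcs is None else float(r.bcs),
            "murmur": np.nan if r.murmur_grade is None else float(r.murmur_grade),
            "la_ao": r.la_ao,
            "lviddn": r.lviddn,
            "mvp": np.nan if r.mvp_grade is None else float(r.mvp_grade),
            "arj_laa_pct": r.arj_laa_pct,
            "si": r.si,
        }
        row.update(r.morpho.as_dict())
        row.update({
            "amvl_i": d.amvl_i, "amvw_i": d.amvw_i, "amva_i": d.amva_i,
            "mvad_i": d.mvad_i, "mvas_i": d.mvas_i,
            "jet": np.nan if d.jet_grade is None else float(d.jet_grade),
            "severity": d.severity,
            "spherical": np.nan if d.spherical_flag is None else float(d.spherical_flag),
            "b1_eligible": np.nan if d.b1_eligible is None else float(d.b1_eligible),
        })
        row.update({f"idx_{k}": v for k, v in d.indexes.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)
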