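"""Participant-level cohort I/O, validation, and age/sex group assignment.

The canonical in-memory container is a :class:`pandas.DataFrame` holding one
row per participant with a fixed column schema (:data:`CANONICAL_COLUMNS`).
Clinical flags live in boolean columns prefixed ``flag_`` (``True`` = the
condition is present, ``pd.NA`` = not ascertained, which is distinct from
``False``).  Analyte columns use NaN for "not measured"; a value of zero is a
measurement, not missingness.

A row-level :class:`ParticipantRecord` dataclass is provided for callers who
prefer typed records; :func:`frame_to_records` / :func:`records_to_frame`
convert losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hbref")

FLAG_PREFIX = "flag_"

#: Canonical non-flag columns of a cohort frame, in storage order.
CANONICAL_COLUMNS = [
    "participant_id",
    "source_id",
    "age_years",
    "sex",
    "pregnant",
    "trimester",
    "haemoglobin_gL",
    "ferritin_ugL",
    "crp_mgL",
    "mcv_fL",
    "altitude_m",
    "stratum",
    "psu",
    "weight",
]

MANDATORY_COLUMNS = ["participant_id", "source_id", "age_years", "sex"]

_NUMERIC_COLUMNS = [
    "age_years",
    "haemoglobin_gL",
    "ferritin_ugL",
    "crp_mgL",
    "mcv_fL",
    "altitude_m",
    "weight",
]

_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "2": "female",
}

_BOOL_ALIASES = {
    "true": True, "t": True, "yes": True, "y": True, "1": True,
    "false": False, "f": False, "no": False, "n": False, "0": False,
}


class CohortValidationError(ValueError):
    """A cohort table violates a hard invariant (bad age, unknown sex, ...)."""


@dataclass
class ParticipantRecord:
    """One individual's demographics, analytes, clinical flags and design fields.

    ``clinical_flags`` maps flag name -> True/False/None, where None means the
    criterion was not ascertained for this person.
    """

    participant_id: str
    source_id: str
    age_years: float
    sex: str
    pregnant: Optional[bool] = None
    trimester: Optional[int] = None
    haemoglobin_gL: Optional[float] = None
    ferritin_ugL: Optional[float] = None
    crp_mgL: Optional[float] = None
    mcv_fL: Optional[float] = None
    altitude_m: Optional[float] = None
    clinical_flags: dict = field(default_factory=dict)
    stratum: Optional[str] = None
    psu: Optional[str] = None
    weight: Optional[float] = None


@dataclass(frozen=True)
class AgeSexGroup:
    """Half-open age interval [age_lo_years, age_hi_years) with sex/pregnancy restrictions.

    ``pregnancy_restriction`` is one of ``required_t1/required_t2/required_t3``
    (group is a pregnancy trimester), ``excluded`` (pregnant individuals do not
    belong; for female groups a *missing* pregnancy status is handled later, at
    the clinical-exclusion stage) or ``any``.
    """

    group_id: str
    age_lo_years: float
    age_hi_years: float
    sex_restriction: str = "any"          # male | female | any
    pregnancy_restriction: str = "any"    # required_t{1,2,3} | excluded | any

    def __post_init__(self):
        if not self.age_lo_years < self.age_hi_years:
            raise CohortValidationError(
                f"group {self.group_id}: age_lo must be < age_hi"
            )
        if self.sex_restriction == "any" and self.age_lo_years >= 12:
            raise CohortValidationError(
                f"group {self.group_id}: sex-shared groups only below age 12"
            )


#: Lifecycle groups used throughout: infants/young children (months converted
#: to fractional years), older children, adolescents and adults by sex, and
#: pregnancy by trimester.  Intervals are half-open, so a child exactly 24
#: months old belongs to c24_59m.
DEFAULT_GROUPS: tuple[AgeSexGroup, ...] = (
    AgeSexGroup("c6_23m", 6 / 12, 24 / 12, "any", "any"),
    AgeSexGroup("c24_59m", 24 / 12, 60 / 12, "any", "any"),
    AgeSexGroup("c5_11y", 5.0, 12.0, "any", "any"),
    AgeSexGroup("adol12_17_m", 12.0, 18.0, "male", "any"),
    AgeSexGroup("adol12_17_f", 12.0, 18.0, "female", "excluded"),
    AgeSexGroup("adult18_65_m", 18.0, 66.0, "male", "any"),
    AgeSexGroup("adult18_65_f_nonpreg", 18.0, 66.0, "female", "excluded"),
    AgeSexGroup("preg_t1", 18.0, 46.0, "female", "required_t1"),
    AgeSexGroup("preg_t2", 18.0, 46.0, "female", "required_t2"),
    AgeSexGroup("preg_t3", 18.0, 46.0, "female", "required_t3"),
)


# ---------------------------------------------------------------------------
# reading and validation
# ---------------------------------------------------------------------------

def _parse_bool_series(s: pd.Series) -> pd.Series:
    def parse(v):
        if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        key = str(v).strip().lower()
        if key in _BOOL_ALIASES:
            return _BOOL_ALIASES[key]
        return pd.NA

    return s.map(parse).astype("boolean")


def empty_cohort(flag_names: Sequence[str] = ()) -> pd.DataFrame:
    """An empty cohort frame with the canonical schema."""
    frame = pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_COLUMNS})
    for c in _NUMERIC_COLUMNS:
        frame[c] = frame[c].astype(float)
    frame["pregnant"] = frame["pregnant"].astype("boolean")
    frame["trimester"] = frame["trimester"].astype("Int64")
    for name in flag_names:
        frame[FLAG_PREFIX + name] = pd.Series(dtype="boolean")
    return frame


def flag_columns(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c.startswith(FLAG_PREFIX)]


def flag_names(frame: pd.DataFrame) -> list[str]:
    return [c[len(FLAG_PREFIX):] for c in flag_columns(frame)]


def validate_cohort(frame: pd.DataFrame) -> None:
    """Enforce hard invariants; raises :class:`CohortValidationError`.

    Checks: mandatory columns present and non-missing, age >= 0, sex binary,
    positive weights where present, and trimester => pregnant & female.
    """
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise CohortValidationError(f"missing mandatory column: {col}")
    age = pd.to_numeric(frame["age_years"], errors="coerce")
    bad = frame.index[age.isna() | (age < 0)]
    if len(bad):
        raise CohortValidationError(
            f"invalid age_years (missing or negative) at row(s) {list(bad[:5])}"
        )
    bad_sex = frame.index[~frame["sex"].isin(["male", "female"])]
    if len(bad_sex):
        raise CohortValidationError(f"invalid sex at row(s) {list(bad_sex[:5])}")
    if "weight" in frame.columns:
        w = pd.to_numeric(frame["weight"], errors="coerce")
        bad_w = frame.index[frame["weight"].notna() & ~(w > 0)]
        if len(bad_w):
            raise CohortValidationError(
                f"non-positive survey weight at row(s) {list(bad_w[:5])}"
            )
    if "trimester" in frame.columns:
        has_tri = frame["trimester"].notna()
        preg_true = (
            frame["pregnant"].astype("boolean").fillna(False).astype(bool)
            if "pregnant" in frame.columns else False
        )
        bad_t = frame.index[has_tri & ~(preg_true & (frame["sex"] == "female"))]
        if len(bad_t):
            raise CohortValidationError(
                f"trimester present without pregnant=true/female at row(s) {list(bad_t[:5])}"
            )


def read_cohort(
    path: str | Path,
    schema: Optional[Mapping[str, object]] = None,
) -> pd.DataFrame:
    """Read a participant-level CSV into the canonical cohort frame.

    Parameters
    ----------
    path
        CSV file (RFC 4180, UTF-8, header row).
    schema
        Optional column mapping ``{canonical_field: csv_column}``; the special
        key ``"clinical_flags"`` maps ``{flag_name: csv_column}``.  Without a
        schema, canonical column names are used directly and any CSV column
        prefixed ``flag_`` is read as a clinical flag.

    Unparseable analyte cells become missing; the number coerced is logged and
    stored in ``frame.attrs["n_unparseable"]``.  Row order is preserved.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)

    colmap: dict[str, str] = {}
    flagmap: dict[str, str] = {}
    if schema:
        for key, val in schema.items():
            if key == "clinical_flags":
                flagmap.update(val)  # type: ignore[arg-type]
            else:
                colmap[key] = str(val)
    for c in CANONICAL_COLUMNS:
        colmap.setdefault(c, c)
    if not flagmap:
        flagmap = {
            c[len(FLAG_PREFIX):]: c for c in raw.columns if c.startswith(FLAG_PREFIX)
        }

    for col in MANDATORY_COLUMNS:
        if colmap[col] not in raw.columns:
            raise CohortValidationError(
                f"missing mandatory column: {colmap[col]} (for {col})"
            )

    out = pd.DataFrame(index=raw.index)
    n_unparseable = 0
    for c in CANONICAL_COLUMNS:
        src = colmap[c]
        if src not in raw.columns:
            if c in _NUMERIC_COLUMNS:
                out[c] = np.nan
            elif c == "pregnant":
                out[c] = pd.Series(pd.NA, index=raw.index, dtype="boolean")
            elif c == "trimester":
                out[c] = pd.Series(pd.NA, index=raw.index, dtype="Int64")
            else:
                out[c] = None
            continue
        col = raw[src]
        if c in _NUMERIC_COLUMNS:
            parsed = pd.to_numeric(col, errors="coerce")
            n_unparseable += int((parsed.isna() & col.notna()).sum())
            out[c] = parsed.astype(float)
        elif c == "sex":
            out[c] = col.str.strip().str.lower().map(_SEX_ALIASES)
        elif c == "pregnant":
            out[c] = _parse_bool_series(col)
        elif c == "trimester":
            out[c] = pd.to_numeric(col, errors="coerce").astype("Int64")
        else:
            out[c] = col
    for name, src in flagmap.items():
        out[FLAG_PREFIX + name] = (
            _parse_bool_series(raw[src]) if src in raw.columns
            else pd.Series(pd.NA, index=raw.index, dtype="boolean")
        )
    # mandatory identifier/age completeness checked before dtype invariants
    for col in ("participant_id", "source_id"):
        if out[col].isna().any():
            bad = out.index[out[col].isna()]
            raise CohortValidationError(f"missing {col} at row(s) {list(bad[:5])}")
    if out["pregnant"].isna().all():
        pass
    validate_cohort(out)
    if n_unparseable:
        logger.warning("read_cohort(%s): %d unparseable analyte cells set to missing",
                       path.name, n_unparseable)
    out.attrs["n_unparseable"] = n_unparseable
    return out


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    names = sorted({n for r in records for n in r.clinical_flags})
    frame = empty_cohort(names)
    if not records:
        return frame
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        flags = d.pop("clinical_flags")
        for n in names:
            d[FLAG_PREFIX + n] = flags.get(n)
        rows.append(d)
    frame = pd.DataFrame(rows)
    frame["pregnant"] = frame["pregnant"].astype("boolean")
    frame["trimester"] = frame["trimester"].astype("Int64")
    for n in names:
        frame[FLAG_PREFIX + n] = frame[FLAG_PREFIX + n].astype("boolean")
    validate_cohort(frame)
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    names = flag_names(frame)
    out = []
    for _, row in frame.iterrows():
        def opt(v):
            return None if pd.isna(v) else v
        out.append(ParticipantRecord(
            participant_id=row["participant_id"],
            source_id=row["source_id"],
            age_years=float(row["age_years"]),
            sex=row["sex"],
            pregnant=opt(row.get("pregnant")),
            trimester=None if pd.isna(row.get("trimester")) else int(row["trimester"]),
            haemoglobin_gL=opt(row.get("haemoglobin_gL")),
            ferritin_ugL=opt(row.get("ferritin_ugL")),
            crp_mgL=opt(row.get("crp_mgL")),
            mcv_fL=opt(row.get("mcv_fL")),
            altitude_m=opt(row.get("altitude_m")),
            clinical_flags={n: opt(row.get(FLAG_PREFIX + n)) for n in names},
            stratum=opt(row.get("stratum")),
            psu=opt(row.get("psu")),
            weight=opt(row.get("weight")),
        ))
    return out


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

def _group_membership(frame: pd.DataFrame, g: AgeSexGroup) -> pd.Series:
    m = (frame["age_years"] >= g.age_lo_years) & (frame["age_years"] < g.age_hi_years)
    if g.sex_restriction != "any":
        m &= frame["sex"] == g.sex_restriction
    preg = frame["pregnant"] if "pregnant" in frame.columns else pd.Series(pd.NA, index=frame.index, dtype="boolean")
    tri = frame["trimester"] if "trimester" in frame.columns else pd.Series(pd.NA, index=frame.index, dtype="Int64")
    if g.pregnancy_restriction.startswith("required_t"):
        t = int(g.pregnancy_restriction[-1])
        m &= (preg == True).fillna(False) & (tri == t).fillna(False)  # noqa: E712
    elif g.pregnancy_restriction == "excluded":
        # explicitly pregnant people are not members; missing status is
        # resolved at the clinical-exclusion stage, not here
        m &= ~(preg == True).fillna(False)  # noqa: E712
    return m.fillna(False).astype(bool)


def assign_groups(
    frame: pd.DataFrame, groups: Sequence[AgeSexGroup] = DEFAULT_GROUPS
) -> pd.Series:
    """Vectorised group assignment: a string Series (``None`` = no group).

    Raises :class:`CohortValidationError` if two groups both claim a record
    (group definitions must be mutually exclusive after restrictions).
    """
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise CohortValidationError("duplicate group_id in group definitions")
    out = pd.Series([None] * len(frame), index=frame.index, dtype=object)
    claimed = pd.Series(False, index=frame.index)
    for g in groups:
        m = _group_membership(frame, g)
        overlap = m & claimed
        if overlap.any():
            other = out[overlap].iloc[0]
            raise CohortValidationError(
                f"overlapping group definitions: {other} and {g.group_id}"
            )
        out[m] = g.group_id
        claimed |= m
    return out


def assign_group(
    record: ParticipantRecord, groups: Sequence[AgeSexGroup] = DEFAULT_GROUPS
) -> Optional[str]:
    """Group id for a single record, or None if no group matches."""
    return assign_groups(records_to_frame([record]), groups).iloc[0]


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _to_frame(items, to_row) -> pd.DataFrame:
    return pd.DataFrame([to_row(x) for x in items])


def write_results(
    estimates,
    waterfalls,
    curves,
    out_dir: str | Path,
    metadata: Optional[Mapping] = None,
) -> dict:
    """Write estimates/waterfalls as CSV and curves + run metadata as JSON.

    Returns the manifest (also written as ``manifest.json``).  Output is
    deterministic: identical inputs produce byte-identical CSV bodies, and the
    manifest carries a content hash of each file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    est_rows = [e.to_row() if hasattr(e, "to_row") else dict(e) for e in estimates]
    est_path = out_dir / "estimates.csv"
    pd.DataFrame(est_rows).to_csv(est_path, index=False)
    files["estimates"] = est_path.name

    wf_rows = []
    for wf in waterfalls:
        wf_rows.extend(wf.to_rows() if hasattr(wf, "to_rows") else [dict(wf)])
    wf_path = out_dir / "waterfall.csv"
    pd.DataFrame(wf_rows).to_csv(wf_path, index=False)
    files["waterfall"] = wf_path.name

    curve_payload = [c.to_dict() if hasattr(c, "to_dict") else dict(c) for c in curves]
    if curve_payload:
        curves_path = out_dir / "curves.json"
        curves_path.write_text(json.dumps(curve_payload, indent=1, sort_keys=True))
        files["curves"] = curves_path.name

    manifest = {
        "files": files,
        "n_estimates": len(est_rows),
        "n_waterfalls": len(list(waterfalls)),
        "n_curves": len(curve_payload),
        "curves_present": bool(curve_payload),
        "metadata": dict(metadata or {}),
    }
    manifest["hashes"] = {
        name: hashlib.sha256((out_dir / fname).read_bytes()).hexdigest()
        for name, fname in files.items()
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_estimates(out_dir: str | Path) -> pd.DataFrame:
    """Re-read an estimates table written by :func:`write_results`."""
    return pd.read_csv(Path(out_dir) / "estimates.csv")
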