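"""Derivation of the apparently-healthy reference sample.

Exclusion logic mirrors posteriori reference-population construction for
haemoglobin thresholds: laboratory criteria are mandatory for everyone
(missing haemoglobin, ferritin or CRP excludes), iron deficiency is ferritin
below an age-specific floor, inflammation is CRP above a ceiling, elevated
ferritin excludes (possible inflammation or liver disease), and an optional
mean-cell-volume floor can be switched on for young children.  Clinical flags
exclude only when explicitly true — a missing flag never excludes, with one
exception: pregnancy status, which must be known (and false) for a female
"non-pregnant" group.  Residence above an altitude ceiling excludes; missing
altitude does not.  Finally Tukey's fences flag haemoglobin outliers among
the survivors.

Each excluded record is counted once, at its first failing step, in a fixed
documented order; the :class:`ExclusionWaterfall` accounts for every record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import DEFAULT_GROUPS, FLAG_PREFIX, AgeSexGroup, assign_groups


class InsufficientDataError(ValueError):
    """Raised when a computation is attempted on too small a sample."""


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds and flag lists governing reference-sample derivation.

    Sensitivity variants: ``sensitivity_ferritin_lo_ugL`` (15/30/45/100)
    replaces *both* age-specific iron-deficiency floors with a single value;
    ``sensitivity_crp_hi_mgL`` (1) lowers the inflammation ceiling;
    ``apply_mcv_floor`` switches on the per-group MCV restriction.
    """

    ferritin_lo_under5_ugL: float = 12.0
    ferritin_lo_other_ugL: float = 15.0
    ferritin_hi_male_ugL: float = 200.0
    ferritin_hi_female_ugL: float = 150.0
    ferritin_hi_child_ugL: float = 200.0
    crp_hi_mgL: float = 5.0
    mcv_lo_by_group: dict = field(
        default_factory=lambda: {"c6_23m": 73.0, "c24_59m": 75.0}
    )
    apply_mcv_floor: bool = False
    altitude_max_m: float = 750.0
    clinical_flag_names: tuple[str, ...] = (
        "chronic_illness",
        "recent_acute_illness",
        "recent_hospitalisation",
        "medication_use",
        "current_smoker",
        "alcohol_excess",
        "bmi_out_of_range",
    )
    sensitivity_ferritin_lo_ugL: Optional[float] = None
    sensitivity_crp_hi_mgL: Optional[float] = None

    def __post_init__(self):
        if self.sensitivity_ferritin_lo_ugL is not None:
            lo = self.sensitivity_ferritin_lo_ugL
        else:
            lo = max(self.ferritin_lo_under5_ugL, self.ferritin_lo_other_ugL)
        hi = min(self.ferritin_hi_male_ugL, self.ferritin_hi_female_ugL,
                 self.ferritin_hi_child_ugL)
        if lo >= hi:
            raise ValueError("ferritin lower threshold must be below upper thresholds")

    @property
    def effective_crp_hi(self) -> float:
        return (self.sensitivity_crp_hi_mgL
                if self.sensitivity_crp_hi_mgL is not None else self.crp_hi_mgL)

    def ferritin_lo(self, age_years: np.ndarray) -> np.ndarray:
        if self.sensitivity_ferritin_lo_ugL is not None:
            return np.full(np.shape(age_years), float(self.sensitivity_ferritin_lo_ugL))
        return np.where(np.asarray(age_years) < 5.0,
                        self.ferritin_lo_under5_ugL, self.ferritin_lo_other_ugL)

    def ferritin_hi(self, age_years: np.ndarray, sex: np.ndarray) -> np.ndarray:
        age = np.asarray(age_years)
        hi_adult = np.where(np.asarray(sex) == "male",
                            self.ferritin_hi_male_ugL, self.ferritin_hi_female_ugL)
        return np.where(age < 18.0, self.ferritin_hi_child_ugL, hi_adult)

    def with_sensitivity(self, *, ferritin_lo: Optional[float] = None,
                         crp_hi: Optional[float] = None,
                         mcv_floor: Optional[bool] = None) -> "ExclusionConfig":
        kw = {}
        if ferritin_lo is not None:
            kw["sensitivity_ferritin_lo_ugL"] = ferritin_lo
        if crp_hi is not None:
            kw["sensitivity_crp_hi_mgL"] = crp_hi
        if mcv_floor is not None:
            kw["apply_mcv_floor"] = mcv_floor
        return replace(self, **kw)


@dataclass
class ExclusionWaterfall:
    """Ordered, named exclusion steps with chained counts."""

    group_id: str = ""
    source_id: str = ""
    steps: list = field(default_factory=list)  # {step_name, n_before, n_excluded, n_after}

    def add(self, step_name: str, n_before: int, n_excluded: int) -> None:
        n_after = n_before - n_excluded
        if self.steps and self.steps[-1]["n_after"] != n_before:
            raise ValueError("waterfall steps must chain")
        if n_excluded < 0 or n_after < 0:
            raise ValueError("negative counts in waterfall")
        self.steps.append({
            "step_name": step_name,
            "n_before": int(n_before),
            "n_excluded": int(n_excluded),
            "n_after": int(n_after),
        })

    def extend(self, other: "ExclusionWaterfall") -> None:
        for s in other.steps:
            self.add(s["step_name"], s["n_before"], s["n_excluded"])

    @property
    def n_start(self) -> int:
        return self.steps[0]["n_before"] if self.steps else 0

    @property
    def n_reference(self) -> int:
        return self.steps[-1]["n_after"] if self.steps else 0

    @property
    def total_excluded(self) -> int:
        return sum(s["n_excluded"] for s in self.steps)

    def counts(self) -> dict:
        return {s["step_name"]: s["n_excluded"] for s in self.steps}

    def to_rows(self) -> list[dict]:
        return [
            {"group_id": self.group_id, "source_id": self.source_id, "step": i, **s}
            for i, s in enumerate(self.steps)
        ]


# ---------------------------------------------------------------------------
# exclusion steps
# ---------------------------------------------------------------------------

def apply_laboratory_exclusions(
    frame: pd.DataFrame,
    config: ExclusionConfig,
    *,
    group_id: str = "",
    source_id: str = "",
) -> tuple[pd.DataFrame, ExclusionWaterfall]:
    """Laboratory exclusions in fixed order, first failure wins.

    Order: missing Hb/ferritin/CRP -> iron deficiency (ferritin strictly below
    the age floor) -> inflammation (CRP strictly above the ceiling) ->
    elevated ferritin (strictly above the sex/age ceiling) -> MCV floor
    (only when active and MCV non-missing).
    """
    wf = ExclusionWaterfall(group_id=group_id, source_id=source_id)
    kept = frame

    missing = (
        kept["haemoglobin_gL"].isna()
        | kept["ferritin_ugL"].isna()
        | kept["crp_mgL"].isna()
    )
    wf.add("missing_laboratory", len(kept), int(missing.sum()))
    kept = kept[~missing]

    lo = config.ferritin_lo(kept["age_years"].to_numpy())
    iron_def = kept["ferritin_ugL"].to_numpy() < lo
    wf.add("iron_deficiency", len(kept), int(iron_def.sum()))
    kept = kept[~iron_def]

    inflamed = kept["crp_mgL"].to_numpy() > config.effective_crp_hi
    wf.add("inflammation", len(kept), int(inflamed.sum()))
    kept = kept[~inflamed]

    hi = config.ferritin_hi(kept["age_years"].to_numpy(), kept["sex"].to_numpy())
    elevated = kept["ferritin_ugL"].to_numpy() > hi
    wf.add("elevated_ferritin", len(kept), int(elevated.sum()))
    kept = kept[~elevated]

    mcv_floor = config.mcv_lo_by_group.get(group_id) if config.apply_mcv_floor else None
    if mcv_floor is not None:
        low_mcv = (kept["mcv_fL"] < mcv_floor).fillna(False).to_numpy(bool)
        wf.add("low_mcv", len(kept), int(low_mcv.sum()))
        kept = kept[~low_mcv]

    return kept, wf


def apply_clinical_exclusions(
    frame: pd.DataFrame,
    config: ExclusionConfig,
    *,
    group: Optional[AgeSexGroup] = None,
    group_id: str = "",
    source_id: str = "",
) -> tuple[pd.DataFrame, ExclusionWaterfall]:
    """Clinical-flag, pregnancy-status and altitude exclusions.

    A named flag excludes only when explicitly true; missing flags never
    exclude.  For a female group that excludes pregnancy, a *missing*
    pregnancy status excludes (pregnancy is the one clinical criterion that
    must be ascertained).  Altitude strictly above the ceiling excludes.
    """
    wf = ExclusionWaterfall(group_id=group_id or (group.group_id if group else ""),
                            source_id=source_id)
    kept = frame

    flagged = pd.Series(False, index=kept.index)
    for name in config.clinical_flag_names:
        col = FLAG_PREFIX + name
        if col in kept.columns:
            flagged |= (kept[col] == True).fillna(False).astype(bool)  # noqa: E712
    wf.add("clinical_flags", len(kept), int(flagged.sum()))
    kept = kept[~flagged]

    if group is not None and group.pregnancy_restriction == "excluded" \
            and group.sex_restriction == "female":
        unknown_preg = kept["pregnant"].isna() | (kept["pregnant"] == True)  # noqa: E712
        unknown_preg = unknown_preg.fillna(True).astype(bool)
        wf.add("pregnancy_status", len(kept), int(unknown_preg.sum()))
        kept = kept[~unknown_preg]

    high_alt = (kept["altitude_m"] > config.altitude_max_m).fillna(False).astype(bool)
    wf.add("high_altitude", len(kept), int(high_alt.sum()))
    kept = kept[~high_alt]

    return kept, wf


def tukey_outlier_mask(values) -> np.ndarray:
    """Boolean mask of values outside Tukey's inner fences.

    Fences are [Q1 - 1.5 IQR, Q3 + 1.5 IQR] with quartiles by the
    linear-interpolation convention; requires n >= 4.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < 4:
        raise InsufficientDataError("Tukey fences need at least 4 values")
    if np.isnan(x).any():
        raise ValueError("values must be non-missing")
    q1, q3 = np.percentile(x, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (x < lo) | (x > hi)


def derive_reference_sample(
    frame: pd.DataFrame,
    config: ExclusionConfig,
    group: AgeSexGroup | str,
    *,
    groups: Sequence[AgeSexGroup] = DEFAULT_GROUPS,
    source_id: str = "",
) -> tuple[pd.DataFrame, ExclusionWaterfall]:
    """Full reference-sample derivation for one age/sex group.

    Composition (fixed order): group assignment -> laboratory exclusions ->
    clinical/altitude exclusions -> Tukey outlier removal on haemoglobin of
    the survivors.  The waterfall starts at the records assigned to the group
    and accounts for every subsequent exclusion; an empty survivor set is
    returned with a complete waterfall.
    """
    if isinstance(group, str):
        matches = [g for g in groups if g.group_id == group]
        if not matches:
            raise ValueError(f"unknown group_id: {group}")
        group = matches[0]

    assigned = assign_groups(frame, groups)
    in_group = frame[assigned == group.group_id]

    kept, wf = apply_laboratory_exclusions(
        in_group, config, group_id=group.group_id, source_id=source_id
    )
    kept, wf_clin = apply_clinical_exclusions(
        kept, config, group=group, source_id=source_id
    )
    wf.extend(wf_clin)

    if len(kept) >= 4:
        outlier = tukey_outlier_mask(kept["haemoglobin_gL"].to_numpy())
        wf.add("tukey_outliers", len(kept), int(outlier.sum()))
        kept = kept[~outlier]
    else:
        wf.add("tukey_outliers", len(kept), 0)
    return kept, wf
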