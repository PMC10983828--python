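"""End-to-end orchestration: simulate/load -> filter -> estimate -> pool -> curve.

A :class:`RunConfig` fully determines a run (exactly one of cohort paths or a
simulation config; all seeds recorded), and :func:`run_pipeline` executes the
analysis per age/sex group and source, pools across sources, fits continuous
curves over pooled reference samples, and writes every artefact plus a
structured event log through :mod:`hbref.cohort_io`.  A stage failure aborts
only the affected group/source and is logged; other work proceeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort_io
from .cohort_io import DEFAULT_GROUPS, AgeSexGroup, assign_groups, read_cohort
from .discrete_centiles import (
    DEFAULT_MIN_N,
    SurveyDesign,
    parametric_centile,
    unweighted_sensitivity_centile,
    weighted_qr_centile,
)
from .pooling import pool_fixed, pool_random
from .continuous_centiles import fit_continuous_centile
from .reference_filter import (
    ExclusionConfig,
    InsufficientDataError,
    derive_reference_sample,
)
from .synthetic import SyntheticConfig, generate_cohort

#: Age spans (group-id sets) over which continuous curves are fitted, mirroring
#: the discrete category boundaries: young children, older children,
#: adolescents, adults.
DEFAULT_CURVE_SETS: dict[str, tuple[str, ...]] = {
    "c6_59m": ("c6_23m", "c24_59m"),
    "c5_11y": ("c5_11y",),
    "adol12_17": ("adol12_17_m", "adol12_17_f"),
    "adult18_65": ("adult18_65_m", "adult18_65_f_nonpreg"),
}

#: Current WHO anaemia cutoffs (g/L) per group, used as forest-plot reference
#: lines; config data, overridable.
DEFAULT_WHO_THRESHOLDS: dict[str, float] = {
    "c6_23m": 110.0, "c24_59m": 110.0, "c5_11y": 115.0,
    "adol12_17_m": 120.0, "adol12_17_f": 120.0,
    "adult18_65_m": 130.0, "adult18_65_f_nonpreg": 120.0,
    "preg_t1": 110.0, "preg_t2": 110.0, "preg_t3": 110.0,
}


@dataclass
class RunConfig:
    cohort_paths: Optional[list] = None
    simulation: Optional[SyntheticConfig] = None
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    groups: tuple[AgeSexGroup, ...] = DEFAULT_GROUPS
    group_ids: Optional[Sequence[str]] = None      # None = all with data
    centile_levels: tuple[float, ...] = (0.05, 0.025)
    ci_level: float = 0.90
    min_n: int = DEFAULT_MIN_N
    bootstrap_B: int = 1000
    seed: int = 0
    curve_sets: dict = field(default_factory=lambda: dict(DEFAULT_CURVE_SETS))
    curve_grid_step_years: float = 0.1
    fit_curves: bool = True
    who_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_WHO_THRESHOLDS))
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if (self.cohort_paths is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of cohort_paths or simulation must be supplied"
            )

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)
        payload = json.dumps(asdict_safe(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()


def asdict_safe(obj):
    try:
        return asdict(obj)
    except TypeError:
        return vars(obj)


@dataclass
class RunResult:
    manifest: dict
    estimates: list
    pooled: list
    waterfalls: list
    curves: list
    events: list
    reference_samples: dict   # (group_id, source_id) -> DataFrame
    truth: Optional[object] = None


def _has_survey_fields(frame: pd.DataFrame) -> bool:
    return (
        frame["weight"].notna().all()
        and frame["stratum"].notna().all()
        and frame["psu"].notna().all()
        and len(frame) > 0
    )


def _load_cohort(config: RunConfig):
    if config.simulation is not None:
        return generate_cohort(config.simulation, config.groups)
    frames = [read_cohort(p) for p in config.cohort_paths]
    return pd.concat(frames, ignore_index=True), None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured analysis; returns all artefacts and the manifest."""
    config.validate()
    events: list[dict] = []

    def log(event: str, **kw):
        events.append({"event": event, **kw})

    cohort, truth = _load_cohort(config)
    assigned = assign_groups(cohort, config.groups)
    log("cohort_loaded", n_records=len(cohort),
        n_assignable=int(assigned.notna().sum()))

    group_ids = list(config.group_ids) if config.group_ids else [
        g.group_id for g in config.groups
        if (assigned == g.group_id).any()
    ]

    estimates, pooled, waterfalls, curves = [], [], [], []
    reference_samples: dict = {}
    seed_counter = np.random.SeedSequence(config.seed)
    sub_seeds = iter(int(s) & 0x7FFFFFFF for s in seed_counter.generate_state(10_000))

    for gid in group_ids:
        group = next(g for g in config.groups if g.group_id == gid)
        per_source_primary: dict[float, list] = {p: [] for p in config.centile_levels}
        for sid, sub in cohort.groupby("source_id", sort=True):
            ref, wf = derive_reference_sample(
                sub, config.exclusions, group, groups=config.groups, source_id=sid
            )
            if wf.n_start == 0:
                continue
            waterfalls.append(wf)
            reference_samples[(gid, sid)] = ref
            log("waterfall", group_id=gid, source_id=sid,
                n_start=wf.n_start, n_reference=wf.n_reference)
            survey = _has_survey_fields(ref)
            for p in config.centile_levels:
                try:
                    if survey:
                        est = weighted_qr_centile(
                            ref, p,
                            SurveyDesign(B=config.bootstrap_B,
                                         seed=int(next(sub_seeds))),
                            config.ci_level, min_n=config.min_n,
                            source_id=sid, group_id=gid,
                        )
                        estimates.append(est)
                        estimates.append(unweighted_sensitivity_centile(
                            ref, p, config.ci_level, min_n=config.min_n,
                            source_id=sid, group_id=gid,
                        ))
                    else:
                        est = parametric_centile(
                            ref["haemoglobin_gL"].to_numpy(), p, config.ci_level,
                            min_n=config.min_n, source_id=sid, group_id=gid,
                        )
                        estimates.append(est)
                    per_source_primary[p].append(est)
                except InsufficientDataError as err:
                    log("insufficient_data", group_id=gid, source_id=sid,
                        p=p, reason=str(err))

        for p, ests in per_source_primary.items():
            if not ests:
                continue
            fixed = pool_fixed(ests, config.ci_level)
            pooled.append(fixed)
            log("pooled", group_id=gid, p=p, model="fixed",
                pooled_gL=fixed.pooled_gL, n_sources=len(ests))
            if len(ests) >= 2:
                pooled.append(pool_random(ests, config.ci_level))

    if config.fit_curves:
        for set_name, members in config.curve_sets.items():
            refs = [reference_samples[k] for k in reference_samples
                    if k[0] in members]
            if not refs:
                continue
            allref = pd.concat(refs, ignore_index=True)
            if len(allref) < config.min_n * 2:
                log("curve_skipped", curve_set=set_name, n=len(allref))
                continue
            sexes = allref["sex"].unique()
            sex = allref["sex"].to_numpy() if len(sexes) == 2 else None
            try:
                for p in config.centile_levels:
                    curve = fit_continuous_centile(
                        allref["age_years"].to_numpy(),
                        allref["haemoglobin_gL"].to_numpy(),
                        sex, p=p, B=config.bootstrap_B,
                        seed=int(next(sub_seeds)),
                        grid_step_years=config.curve_grid_step_years,
                        group_id=set_name, ci_level=config.ci_level,
                    )
                    curves.append(curve)
                    log("curve", curve_set=set_name, p=p,
                        fp_powers=list(curve.fp.powers),
                        sex_interaction=curve.fp.includes_sex_interaction,
                        n=len(allref))
            except Exception as err:  # a failing curve must not sink the run
                log("curve_failed", curve_set=set_name, reason=str(err))

    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "centile_levels": list(config.centile_levels),
        "ci_level": config.ci_level,
    }
    if config.out_dir:
        manifest = cohort_io.write_results(
            estimates + pooled, waterfalls, curves, config.out_dir,
            metadata=metadata,
        )
        log_path = Path(config.out_dir) / "log.jsonl"
        log_path.write_text("\n".join(json.dumps(e, default=str) for e in events))
    else:
        manifest = {"files": {}, "metadata": metadata,
                    "n_estimates": len(estimates) + len(pooled),
                    "n_waterfalls": len(waterfalls), "n_curves": len(curves)}
    return RunResult(
        manifest=manifest, estimates=estimates, pooled=pooled,
        waterfalls=waterfalls, curves=curves, events=events,
        reference_samples=reference_samples, truth=truth,
    )


def sensitivity_sweep(config: RunConfig, variants: Sequence[dict]) -> pd.DataFrame:
    """Re-run filtering/estimation/pooling under exclusion-threshold variants.

    Each variant is a dict with a ``name`` plus keyword overrides understood
    by :meth:`ExclusionConfig.with_sensitivity` (``ferritin_lo``, ``crp_hi``,
    ``mcv_floor``).  Returns a table of pooled estimates per variant per
    group and level, side by side with the base run and delta columns.
    """
    base_cfg = RunConfig(**{**vars(config), "fit_curves": False, "out_dir": None})
    base = run_pipeline(base_cfg)
    base_rows = {
        (pe.group_id, pe.p): pe for pe in base.pooled if pe.model == "fixed"
    }
    rows = []
    for pe in base.pooled:
        if pe.model != "fixed":
            continue
        rows.append({
            "variant": "base", "group_id": pe.group_id, "p": pe.p,
            "pooled_gL": pe.pooled_gL, "ci_lo_gL": pe.ci_lo_gL,
            "ci_hi_gL": pe.ci_hi_gL, "n_reference": pe.n_total,
            "delta_gL": 0.0, "status": "ok",
        })
    for variant in variants:
        v = dict(variant)
        name = v.pop("name")
        cfg = RunConfig(**{**vars(config),
                           "exclusions": config.exclusions.with_sensitivity(**v),
                           "fit_curves": False, "out_dir": None})
        res = run_pipeline(cfg)
        seen = set()
        for pe in res.pooled:
            if pe.model != "fixed":
                continue
            seen.add((pe.group_id, pe.p))
            ref = base_rows.get((pe.group_id, pe.p))
            rows.append({
                "variant": name, "group_id": pe.group_id, "p": pe.p,
                "pooled_gL": pe.pooled_gL, "ci_lo_gL": pe.ci_lo_gL,
                "ci_hi_gL": pe.ci_hi_gL, "n_reference": pe.n_total,
                "delta_gL": pe.pooled_gL - ref.pooled_gL if ref else np.nan,
                "status": "ok",
            })
        for key, ref in base_rows.items():
            if key not in seen:
                rows.append({
                    "variant": name, "group_id": key[0], "p": key[1],
                    "pooled_gL": np.nan, "ci_lo_gL": np.nan, "ci_hi_gL": np.nan,
                    "n_reference": 0, "delta_gL": np.nan,
                    "status": "insufficient",
                })
    return pd.DataFrame(rows)
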