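"""Age-continuous centile curves via the two-stage approach:

1. select the best-fitting fractional-polynomial (FP) *mean* model for
   haemoglobin against age by the Royston function-selection closed test
   (null -> linear -> best FP1 -> best FP2, Gaussian deviance differences
   referred to chi-square), with a sex main effect always included when sex
   is supplied, followed by a likelihood-ratio test for a sex-by-age(FP)
   interaction at alpha = 0.05;
2. refit the selected transform by (unweighted) quantile regression at the
   target level, predict on a uniform age grid, and band the predictions
   with bootstrap-percentile 90% intervals from case-resampling replicates.

FP powers come from the standard set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, power 0
meaning ln(x), and a repeated power p contributing x^p and x^p ln(x).  Ages
are preconditioned by their geometric mean (recorded as ``age_scale``) so
predictions are invariant to the age unit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
import statsmodels.api as sm

FP_POWER_SET = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_DEV_FLOOR = 1e-12  # RSS floor guarding log of a perfect fit


class QuantRegConvergenceError(RuntimeError):
    """Too many bootstrap replicates failed to converge."""


@dataclass
class FPModel:
    degree: int                      # 0 (null), 1, or 2
    powers: tuple[float, ...]        # multiset, len == degree
    coefficients: np.ndarray         # intercept + per-term (+ sex) OLS coefs
    includes_sex_main: bool
    includes_sex_interaction: bool
    deviance: float
    age_scale: float
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "degree": self.degree, "powers": list(self.powers),
            "coefficients": np.asarray(self.coefficients).tolist(),
            "includes_sex_main": self.includes_sex_main,
            "includes_sex_interaction": self.includes_sex_interaction,
            "deviance": self.deviance, "age_scale": self.age_scale, "n": self.n,
        }


def fp_transform(age, powers, age_scale: float = 1.0) -> np.ndarray:
    """Design columns for an FP term multiset on scaled age x = age/age_scale.

    Power 0 yields ln(x); a repeated power p yields x^p then x^p ln(x)
    (recursively, so (0, 0) yields ln(x), (ln x)^2).  Column count equals the
    number of powers; ages must be positive after scaling.
    """
    x = np.asarray(age, dtype=float) / age_scale
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("ages must be positive and finite after scaling")
    cols = []
    prev_power: Optional[float] = None
    for p in sorted(powers):
        if prev_power is not None and p == prev_power:
            term = cols[-1] * np.log(x)
        else:
            term = np.log(x) if p == 0 else x ** p
        cols.append(term)
        prev_power = p
    if not cols:
        return np.empty((x.size, 0))
    return np.column_stack(cols)


def _ols_deviance(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Gaussian -2 log likelihood (up to constant): n ln(RSS/n)."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = max(float(resid @ resid), _DEV_FLOOR)
    n = y.size
    return n * np.log(rss / n), coef


def _candidate_powers(degree: int) -> list[tuple[float, ...]]:
    if degree == 1:
        return [(p,) for p in FP_POWER_SET]
    return [tuple(c) for c in itertools.combinations_with_replacement(FP_POWER_SET, 2)]


def _sex_indicator(sex) -> np.ndarray:
    s = np.asarray(sex)
    ind = np.where(s == "male", 1.0, 0.0)
    if not set(np.unique(s)) <= {"male", "female"}:
        raise ValueError("sex must be 'male'/'female'")
    return ind


def select_fp_mean_model(age, hb, sex=None, alpha: float = 0.05) -> FPModel:
    """Royston function-selection (closed test) for the haemoglobin mean.

    Exhaustive least-squares search over the 8 FP1 and 36 FP2 power multisets;
    then (1) best FP2 vs null on 4 df, (2) vs linear on 3 df, (3) vs best FP1
    on 2 df.  The first non-significant comparison stops the test and returns
    the simpler model.  A sex main effect is always included when supplied.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(hb, dtype=float)
    n = y.size
    base_cols = [np.ones(n)]
    includes_sex = sex is not None
    if includes_sex:
        base_cols.append(_sex_indicator(sex))
    base = np.column_stack(base_cols)
    n_par_max = base.shape[1] + 2
    if n < 10 * n_par_max:
        raise ValueError(f"need n >= {10 * n_par_max} for FP selection, got {n}")

    age_scale = float(np.exp(np.mean(np.log(age))))

    def fit(powers: tuple[float, ...]):
        X = np.column_stack([base, fp_transform(age, powers, age_scale)]) \
            if powers else base
        return _ols_deviance(X, y)

    dev_null, coef_null = fit(())
    dev_lin, coef_lin = fit((1.0,))

    best1: tuple[float, tuple, np.ndarray] = (np.inf, (), np.empty(0))
    for pw in _candidate_powers(1):
        d, c = fit(pw)
        if d < best1[0]:
            best1 = (d, pw, c)
    best2: tuple[float, tuple, np.ndarray] = (np.inf, (), np.empty(0))
    for pw in _candidate_powers(2):
        d, c = fit(pw)
        if d < best2[0]:
            best2 = (d, pw, c)

    def make(degree, powers, dev, coef):
        return FPModel(
            degree=degree, powers=tuple(powers), coefficients=np.asarray(coef),
            includes_sex_main=includes_sex, includes_sex_interaction=False,
            deviance=float(dev), age_scale=age_scale, n=n,
        )

    crit = lambda df: stats.chi2.ppf(1.0 - alpha, df)
    if dev_null - best2[0] <= crit(4):
        return make(0, (), dev_null, coef_null)
    if dev_lin - best2[0] <= crit(3):
        return make(1, (1.0,), dev_lin, coef_lin)
    if best1[0] - best2[0] <= crit(2):
        return make(1, best1[1], best1[0], best1[2])
    return make(2, best2[1], best2[0], best2[2])


def test_sex_interaction(age, hb, sex, fp: FPModel, alpha: float = 0.05) -> dict:
    """LRT for a sex-by-FP(age) interaction in the mean model.

    Compares {FP(age) + sex} against {FP(age) + sex + sex x FP(age)}; df
    equals the number of FP terms.  Returns lrt_stat, df, p_value and
    ``retain`` (p < alpha).
    """
    if fp.degree == 0:
        raise ValueError("selected mean model has no age terms to interact with")
    age = np.asarray(age, dtype=float)
    y = np.asarray(hb, dtype=float)
    ind = _sex_indicator(sex)
    for s in (0.0, 1.0):
        if (ind == s).sum() < 30:
            raise ValueError("both sexes must be present with n >= 30 each")
    F = fp_transform(age, fp.powers, fp.age_scale)
    X0 = np.column_stack([np.ones(y.size), F, ind])
    X1 = np.column_stack([X0, F * ind[:, None]])
    dev0, _ = _ols_deviance(X0, y)
    dev1, _ = _ols_deviance(X1, y)
    lrt = max(0.0, dev0 - dev1)
    df = len(fp.powers)
    p = float(stats.chi2.sf(lrt, df))
    return {"lrt_stat": float(lrt), "df": df, "p_value": p, "retain": bool(p < alpha)}


@dataclass
class ContinuousCentileCurve:
    group_id: str
    p: float
    age_grid_years: np.ndarray
    predicted_gL: dict            # sex (or "all") -> vector
    band_lo_gL: dict
    band_hi_gL: dict
    B: int
    seed: int
    fp: FPModel
    n_redrawn: int = 0
    ci_level: float = 0.90

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id, "p": self.p,
            "age_grid_years": np.asarray(self.age_grid_years).tolist(),
            "predicted_gL": {k: np.asarray(v).tolist() for k, v in self.predicted_gL.items()},
            "band_lo_gL": {k: np.asarray(v).tolist() for k, v in self.band_lo_gL.items()},
            "band_hi_gL": {k: np.asarray(v).tolist() for k, v in self.band_hi_gL.items()},
            "B": self.B, "seed": self.seed, "n_redrawn": self.n_redrawn,
            "ci_level": self.ci_level, "fp_model": self.fp.to_dict(),
        }


def _qr_design(age, sex_ind, fp: FPModel, with_interaction: bool) -> np.ndarray:
    n = np.asarray(age, dtype=float).size
    F = fp_transform(age, fp.powers, fp.age_scale) if fp.degree else np.empty((n, 0))
    parts = [np.ones((n, 1))]
    if F.shape[1]:
        parts.append(F)
    if sex_ind is not None:
        parts.append(np.reshape(sex_ind, (-1, 1)))
        if with_interaction and F.shape[1]:
            parts.append(F * np.reshape(sex_ind, (-1, 1)))
    return np.hstack(parts)


def _fit_qr(X: np.ndarray, y: np.ndarray, p: float) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(y, X).fit(q=p, max_iter=2000)
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise RuntimeError("quantile regression produced non-finite coefficients")
    return params


def fit_continuous_centile(
    age,
    hb,
    sex=None,
    fp: Optional[FPModel] = None,
    p: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    grid_step_years: float = 0.1,
    *,
    include_sex_interaction: Optional[bool] = None,
    group_id: str = "",
    ci_level: float = 0.90,
    alpha: float = 0.05,
) -> ContinuousCentileCurve:
    """Quantile-regression centile curve on the selected FP transform.

    If ``fp`` is None the mean-model selection (and, when both sexes are
    present, the interaction LRT) is run first.  Predictions cover a uniform
    grid within the observed age range; bands are bootstrap-percentile
    intervals at ``ci_level`` from ``B`` case-resampling replicates.  A
    replicate whose quantile regression fails is redrawn (capped at 5% of B).
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(hb, dtype=float)
    sex_arr = None if sex is None else np.asarray(sex)

    if fp is None:
        fp = select_fp_mean_model(age, y, sex_arr, alpha=alpha)
    if include_sex_interaction is None:
        if sex_arr is not None and fp.degree > 0 \
                and len(np.unique(sex_arr)) == 2:
            include_sex_interaction = test_sex_interaction(
                age, y, sex_arr, fp, alpha=alpha
            )["retain"]
        else:
            include_sex_interaction = False
    fp.includes_sex_interaction = bool(include_sex_interaction)

    grid = np.arange(age.min(), age.max() + 0.5 * grid_step_years, grid_step_years)
    grid = grid[grid <= age.max() + 1e-12]
    sexes = ["all"] if sex_arr is None else ["male", "female"]

    def grid_design(sex_label):
        si = None
        if sex_arr is not None:
            si = np.full(grid.size, 1.0 if sex_label == "male" else 0.0)
        return _qr_design(grid, si, fp, include_sex_interaction)

    if np.ptp(y) == 0:
        # degenerate constant response: flat curve, zero-width bands
        flat = np.full(grid.size, float(y[0]))
        return ContinuousCentileCurve(
            group_id=group_id, p=p, age_grid_years=grid,
            predicted_gL={s: flat.copy() for s in sexes},
            band_lo_gL={s: flat.copy() for s in sexes},
            band_hi_gL={s: flat.copy() for s in sexes},
            B=B, seed=seed, fp=fp, ci_level=ci_level,
        )

    sex_ind = None if sex_arr is None else _sex_indicator(sex_arr)
    X = _qr_design(age, sex_ind, fp, include_sex_interaction)
    params = _fit_qr(X, y, p)
    preds = {s: grid_design(s) @ params for s in sexes}

    rng = np.random.default_rng(seed)
    n = y.size
    boot_preds = {s: np.empty((B, grid.size)) for s in sexes}
    max_redraws = int(np.ceil(0.05 * B))
    n_redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(n, size=n)
        try:
            bp = _fit_qr(X[idx], y[idx], p)
        except (RuntimeError, np.linalg.LinAlgError):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise QuantRegConvergenceError(
                    f"more than {max_redraws} bootstrap replicates failed to converge"
                )
            continue
        for s in sexes:
            boot_preds[s][b] = grid_design(s) @ bp
        b += 1

    a = 0.5 * (1.0 - ci_level)
    lo = {s: np.percentile(boot_preds[s], 100 * a, axis=0) for s in sexes}
    hi = {s: np.percentile(boot_preds[s], 100 * (1 - a), axis=0) for s in sexes}
    # the point estimate is kept inside its band (pointwise containment)
    lo = {s: np.minimum(lo[s], preds[s]) for s in sexes}
    hi = {s: np.maximum(hi[s], preds[s]) for s in sexes}
    return ContinuousCentileCurve(
        group_id=group_id, p=p, age_grid_years=grid,
        predicted_gL=preds, band_lo_gL=lo, band_hi_gL=hi,
        B=B, seed=seed, fp=fp, n_redrawn=n_redrawn, ci_level=ci_level,
    )
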