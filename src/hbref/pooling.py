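"""Meta-analytic pooling of per-source centile estimates.

Fixed-effects inverse-variance pooling is the primary model; a
DerSimonian–Laird random-effects fit serves as the sensitivity analysis.
Cochran's Q and I^2 are always reported so heterogeneity can be judged even
under the fixed model.  :func:`forest_table` emits a plot-ready table (one
row per source plus the pooled row and the current WHO reference threshold);
no graphics are produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discrete_centiles import CentileEstimate


@dataclass
class PooledEstimate:
    group_id: str
    model: str                   # fixed | random
    p: float
    pooled_gL: float
    se_gL: float
    ci_lo_gL: float
    ci_hi_gL: float
    ci_level: float
    n_total: int
    weights: dict = field(default_factory=dict)  # source -> relative weight
    Q: float = 0.0
    df: int = 0
    I2: float = 0.0
    tau2: float = 0.0

    def to_row(self) -> dict:
        return {
            "group_id": self.group_id, "source_id": "POOLED",
            "p": self.p, "method": f"pooled_{self.model}", "n": self.n_total,
            "estimate_gL": self.pooled_gL, "se_gL": self.se_gL,
            "ci_lo_gL": self.ci_lo_gL, "ci_hi_gL": self.ci_hi_gL,
            "ci_level": self.ci_level, "Q": self.Q, "df": self.df,
            "I2": self.I2, "tau2": self.tau2,
        }


def _validate(estimates: Sequence[CentileEstimate]) -> None:
    if not estimates:
        raise ValueError("at least one estimate required")
    if len({e.group_id for e in estimates}) > 1:
        raise ValueError("estimates must share a group")
    if len({e.p for e in estimates}) > 1:
        raise ValueError("estimates must share a centile level")
    if any(e.se_gL <= 0 for e in estimates):
        raise ValueError("degenerate weight: every SE must be positive")


def _pool(estimates: Sequence[CentileEstimate], tau2: float,
          ci_level: float, model: str) -> PooledEstimate:
    y = np.array([e.estimate_gL for e in estimates])
    v = np.array([e.se_gL ** 2 for e in estimates])

    w_fixed = 1.0 / v
    mu_fixed = float(np.sum(w_fixed * y) / np.sum(w_fixed))
    Q = float(np.sum(w_fixed * (y - mu_fixed) ** 2))
    df = len(estimates) - 1
    I2 = max(0.0, (Q - df) / Q) if (df >= 1 and Q > 0) else 0.0

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    zc = stats.norm.ppf(0.5 * (1.0 + ci_level))
    rel = w / np.sum(w)
    return PooledEstimate(
        group_id=estimates[0].group_id, model=model, p=estimates[0].p,
        pooled_gL=mu, se_gL=se, ci_lo_gL=mu - zc * se, ci_hi_gL=mu + zc * se,
        ci_level=ci_level, n_total=int(sum(e.n for e in estimates)),
        weights={e.source_id: float(r) for e, r in zip(estimates, rel)},
        Q=Q, df=df, I2=float(I2), tau2=float(tau2),
    )


def pool_fixed(estimates: Sequence[CentileEstimate],
               ci_level: float = 0.90) -> PooledEstimate:
    """Inverse-variance fixed-effects pooled centile with Q and I^2."""
    _validate(estimates)
    return _pool(estimates, tau2=0.0, ci_level=ci_level, model="fixed")


def pool_random(estimates: Sequence[CentileEstimate],
                ci_level: float = 0.90) -> PooledEstimate:
    """DerSimonian–Laird random-effects pooled centile (sensitivity model).

    tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w); when the
    inputs are homogeneous (Q <= df) the result collapses to the fixed model.
    """
    _validate(estimates)
    if len(estimates) < 2:
        raise ValueError("random-effects pooling needs at least two estimates")
    y = np.array([e.estimate_gL for e in estimates])
    v = np.array([e.se_gL ** 2 for e in estimates])
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    Q = np.sum(w * (y - mu) ** 2)
    df = len(estimates) - 1
    C = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    return _pool(estimates, tau2=float(tau2), ci_level=ci_level, model="random")


def forest_table(
    pooled: PooledEstimate,
    estimates: Sequence[CentileEstimate],
    who_threshold_gL: Optional[float] = None,
) -> pd.DataFrame:
    """Forest-plot-ready table: per-source rows, the pooled row, and the
    current WHO threshold for the group as the reference-line column."""
    _validate(estimates)
    if any(e.group_id != pooled.group_id for e in estimates):
        raise ValueError("estimates and pooled result must share a group")
    rows = []
    for e in estimates:
        rows.append({
            "group_id": e.group_id, "source_id": e.source_id, "row": "source",
            "estimate_gL": e.estimate_gL, "ci_lo_gL": e.ci_lo_gL,
            "ci_hi_gL": e.ci_hi_gL, "n": e.n,
            "rel_weight": pooled.weights.get(e.source_id, np.nan),
            "who_threshold_gL": who_threshold_gL,
        })
    rows.append({
        "group_id": pooled.group_id, "source_id": "POOLED",
        "row": f"pooled_{pooled.model}",
        "estimate_gL": pooled.pooled_gL, "ci_lo_gL": pooled.ci_lo_gL,
        "ci_hi_gL": pooled.ci_hi_gL, "n": pooled.n_total,
        "rel_weight": 1.0, "who_threshold_gL": who_threshold_gL,
    })
    return pd.DataFrame(rows)
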