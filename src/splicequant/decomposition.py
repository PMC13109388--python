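"""Weighted additive decomposition of combined-perturbation splicing effects.

Given per-event inclusion-level differences for two single perturbations
(ID_A, ID_B, each relative to the same control) and for the combined
perturbation, the combined effect is modelled as the weighted mean

    ID_combined ≈ ID_A * (1 - w) + ID_B * w,      w in [0, 1].

The weight is recovered by sweeping a grid of w values and maximising the
Pearson correlation between predicted and observed combined differences,
pooled over events and separately per event type. Weights are represented
as integer grid fractions k/N so that swapping the two inputs mirrors the
correlation profile bitwise exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectVector",
    "WeightProfile",
    "DecompositionResult",
    "predict_combined",
    "sweep_weights",
    "fit_linear_summary",
    "LinearFit",
]


@dataclass
class EffectVector:
    """Per-event inclusion-level differences, indexed by event id."""

    values: pd.Series  # float, NaN = missing
    label: str = ""

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)

    @classmethod
    def from_comparisons(cls, comparisons: pd.DataFrame, label: str = "") -> "EffectVector":
        series = comparisons.set_index("event_id")["delta_inclusion"]
        return cls(values=series, label=label or f"{comparisons['condition_b'].iloc[0]}")

    @property
    def event_ids(self) -> pd.Index:
        return self.values.index


def _aligned(a: EffectVector, b: EffectVector) -> tuple[pd.Series, pd.Series]:
    if a.values.index.equals(b.values.index):
        return a.values, b.values
    if set(a.values.index) != set(b.values.index):
        raise ValueError("effect vectors cover different event sets")
    return a.values, b.values.reindex(a.values.index)


def predict_combined(a: EffectVector, b: EffectVector, w: float) -> EffectVector:
    """Elementwise (1−w)·a + w·b; missing in either input stays missing."""
    if not 0 <= w <= 1:
        raise ValueError(f"weight must lie in [0, 1], got {w}")
    va, vb = _aligned(a, b)
    return EffectVector(values=va * (1.0 - w) + vb * w, label=f"(1-{w})*{a.label}+{w}*{b.label}")


@dataclass
class WeightProfile:
    """Correlation profile of one event set over the weight grid."""

    grid: np.ndarray
    r: np.ndarray
    r2: np.ndarray
    best_weight: float
    n: int


@dataclass
class DecompositionResult:
    pooled: WeightProfile
    per_type: dict[str, WeightProfile] = field(default_factory=dict)

    @property
    def best_weight(self) -> float:
        return self.pooled.best_weight

    def to_frame(self) -> pd.DataFrame:
        """Long profile table: (as_type, w, r, r2), 'pooled' first."""
        frames = [
            pd.DataFrame(
                {"as_type": name, "w": prof.grid, "r": prof.r, "r2": prof.r2, "n_events": prof.n}
            )
            for name, prof in [("pooled", self.pooled), *sorted(self.per_type.items())]
        ]
        return pd.concat(frames, ignore_index=True)


def _profile(a: np.ndarray, b: np.ndarray, obs: np.ndarray, n_steps: int) -> WeightProfile:
    ks = np.arange(n_steps + 1)
    grid = ks / n_steps
    # integer-scaled weights: (N-k)/N and k/N sum to 1 exactly and the
    # sweep is bitwise symmetric under swapping a and b
    preds = ((n_steps - ks)[:, None] * a[None, :] + ks[:, None] * b[None, :]) / n_steps
    centred = preds - preds.mean(axis=1, keepdims=True)
    o = obs - obs.mean()
    sso = float(o @ o)
    ssp = np.einsum("ij,ij->i", centred, centred)
    # einsum (not BLAS matmul) keeps each row's reduction order independent
    # of its row index, so mirrored sweeps agree bitwise
    cross = np.einsum("ij,j->i", centred, o)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((ssp > 0) & (sso > 0), cross / np.sqrt(ssp * sso), np.nan)
    if np.all(np.isnan(r)):
        raise ValueError("correlation undefined at every grid point (zero variance)")
    best = float(grid[np.nanargmax(r)])  # first max = smallest w on ties
    return WeightProfile(grid=grid, r=r, r2=r * r, best_weight=best, n=a.size)


def sweep_weights(
    effect_a: EffectVector,
    effect_b: EffectVector,
    observed_combined: EffectVector,
    grid_step: float = 0.01,
    as_types: Optional[pd.Series] = None,
    min_events: int = 3,
) -> DecompositionResult:
    """Correlation of predicted vs observed combined effects over a weight grid.

    Only complete cases (all three values present) enter; grid points where
    prediction or observation has zero variance yield NaN and are excluded
    from the argmax. ``as_types`` (event_id -> type) adds per-type
    profiles for every type with at least ``min_events`` complete events.
    """
    va, vb = _aligned(effect_a, effect_b)
    obs = observed_combined.values.reindex(va.index)
    if set(observed_combined.values.index) != set(va.index):
        raise ValueError("observed combined effects cover a different event set")
    n_steps = round(1.0 / grid_step)
    if n_steps < 1 or abs(n_steps * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid step {grid_step} does not evenly divide [0, 1]")
    complete = va.notna() & vb.notna() & obs.notna()
    if int(complete.sum()) < min_events:
        raise ValueError(f"need at least {min_events} complete events, have {int(complete.sum())}")
    a = va[complete].to_numpy()
    b = vb[complete].to_numpy()
    o = obs[complete].to_numpy()
    pooled = _profile(a, b, o, n_steps)
    per_type: dict[str, WeightProfile] = {}
    if as_types is not None:
        types = as_types.reindex(va.index)[complete]
        for name in types.dropna().unique():
            mask = (types == name).to_numpy()
            if mask.sum() >= min_events:
                try:
                    per_type[str(name)] = _profile(a[mask], b[mask], o[mask], n_steps)
                except ValueError:
                    continue
    return DecompositionResult(pooled=pooled, per_type=per_type)


@dataclass
class LinearFit:
    """OLS line of observed on predicted with a pointwise CI band."""

    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    slope_se: float
    intercept_se: float
    resid_sd: float
    x_mean: float
    sxx: float

    def ci_band(self, x, level: float = 0.95):
        """Fitted line and pointwise confidence band at the given level."""
        x = np.asarray(x, dtype=float)
        fit = self.intercept + self.slope * x
        tcrit = stats.t.ppf(0.5 + level / 2, self.n - 2)
        se = self.resid_sd * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        return fit, fit - tcrit * se, fit + tcrit * se


def fit_linear_summary(predicted: EffectVector, observed: EffectVector) -> LinearFit:
    """Least-squares line of observed on predicted combined effects."""
    vp, vo = _aligned(predicted, observed)
    mask = vp.notna() & vo.notna()
    x = vp[mask].to_numpy()
    y = vo[mask].to_numpy()
    if x.size < 3:
        raise ValueError("need at least 3 complete events for a linear summary")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: predicted or observed effects are constant")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = x.size - 2
    resid_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else float("nan")
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        n=int(x.size),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        resid_sd=resid_sd,
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
    )
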