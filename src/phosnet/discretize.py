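"""Median-centering, ternary delta events, and 3-level discretization.

Network inference works on two discrete views of each site's time course
within one condition:

* **delta events** — for each pair of consecutive time points the change
  of the replicate-mean profile is classed +1 (up), -1 (down) or 0
  (unchanged).  A change counts only if it clears two gates: its absolute
  value must exceed the c-quantile (default 10%) of all absolute changes
  pooled over the condition's network sites, and it must amount to at
  least a (default 25%) of the previous level's magnitude.  Absent
  profile entries are set to 0 on the median-centered scale.
* **3-level states** — per replicate and time point, the centered value
  is LOW (at or below the condition median), HIGH (above it) or ABSENT
  (masked).  These feed the Bayesian score, which counts replicate-level
  data vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import NormalizedMatrix

LOW, HIGH, ABSENT_LEVEL = 0, 1, 2
N_LEVELS = 3


@dataclass(frozen=True)
class DeltaConfig:
    """Thresholds of the delta-event rule.

    ``a``/``b`` are the relative up/down thresholds (fraction of the
    previous level's magnitude); ``c`` is the quantile of pooled absolute
    changes below which a change is "unchanged".
    """

    a: float = 0.25
    b: float = 0.25
    c: float = 0.10

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("relative thresholds a, b must be positive")
        if not 0 <= self.c < 1:
            raise ValueError("quantile c must lie in [0, 1)")


def median_center(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Subtract, per condition, the median of that condition's unmasked values."""
    values = matrix.values.copy()
    for cond, samples in matrix.design.groupby("condition").groups.items():
        cols = [s for s in samples]
        block = values[cols]
        med = np.nanmedian(block.to_numpy(dtype=float))
        if np.isnan(med):
            raise ValueError(f"condition {cond!r} has no unmasked values")
        values[cols] = block - med
    return NormalizedMatrix(values, matrix.mask.copy(), matrix.design)


def condition_profiles(matrix: NormalizedMatrix, condition) -> pd.DataFrame:
    """Replicate-mean profile per site over time for one condition.

    Cells with no detected replicate value (absent) are set to 0, which
    on the centered scale is the condition median.
    """
    design = matrix.design
    sel = design[design["condition"] == condition]
    times = sorted(sel["time_min"].unique())
    cols = {}
    for t in times:
        samples = sel.index[sel["time_min"] == t]
        block = matrix.values[list(samples)].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(block, axis=1)
        cols[t] = np.where(np.isnan(mean), 0.0, mean)
    return pd.DataFrame(cols, index=matrix.values.index)


def pooled_abs_deltas(profiles: pd.DataFrame) -> np.ndarray:
    """All |p(t) - p(t-1)| over every site of one condition, pooled."""
    arr = profiles.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    return np.abs(np.diff(arr, axis=1)).ravel()


def delta_events(
    profile: np.ndarray,
    pooled_deltas: np.ndarray,
    cfg: DeltaConfig = DeltaConfig(),
) -> np.ndarray:
    """Ternary change events of one profile (length T -> length T-1).

    Gate order: the pooled-quantile gate first, then up (+1) if the
    change exceeds a times the previous magnitude, then down (-1), else
    0.  The baseline uses |p(t-1)| so the thresholds keep their sign on
    the centered scale; from a baseline of exactly 0 any change passing
    the quantile gate takes its sign.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("profile needs at least 2 time points")
    gate = float(np.quantile(np.asarray(pooled_deltas, dtype=float), cfg.c))
    d = np.diff(p)
    base = np.abs(p[:-1])
    out = np.zeros(d.size, dtype=np.int8)
    active = np.abs(d) >= gate
    out[active & (d > cfg.a * base)] = 1
    out[active & (d < -cfg.b * base) & (out == 0)] = -1
    return out


def delta_series(
    profiles: pd.DataFrame, cfg: DeltaConfig = DeltaConfig()
) -> pd.DataFrame:
    """Delta events for every site of one condition (site x transition)."""
    pooled = pooled_abs_deltas(profiles)
    rows = np.vstack(
        [delta_events(profiles.loc[s].to_numpy(), pooled, cfg) for s in profiles.index]
    ) if len(profiles) else np.empty((0, profiles.shape[1] - 1), dtype=np.int8)
    return pd.DataFrame(
        rows, index=profiles.index, columns=list(profiles.columns[1:])
    )


def discretize_levels(matrix: NormalizedMatrix) -> pd.DataFrame:
    """3-level states per entry: LOW(0) / HIGH(1) / ABSENT(2).

    The split point is each condition's median of unmasked centered
    values (ties go LOW); masked entries are ABSENT, a countable level of
    its own rather than missing data.
    """
    values = matrix.values
    out = np.full(values.shape, ABSENT_LEVEL, dtype=np.int8)
    arr = values.to_numpy(dtype=float)
    for cond, samples in matrix.design.groupby("condition").groups.items():
        cols = [values.columns.get_loc(s) for s in samples]
        block = arr[:, cols]
        med = np.nanmedian(block)
        with np.errstate(invalid="ignore"):
            high = block > med
            low = block <= med
        sub = out[:, cols]
        sub[low] = LOW
        sub[high] = HIGH
        out[:, cols] = sub
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def level_array(
    levels: pd.DataFrame, design: pd.DataFrame, condition
) -> tuple[np.ndarray, list, list]:
    """Reshape one condition's levels to (site, replicate, time) order.

    Returns the int8 array plus the replicate and time orderings used.
    """
    sel = design[design["condition"] == condition]
    reps = sorted(sel["replicate"].unique())
    times = sorted(sel["time_min"].unique())
    arr = np.empty((len(levels), len(reps), len(times)), dtype=np.int8)
    for ri, r in enumerate(reps):
        for ti, t in enumerate(times):
            sample = sel.index[(sel["replicate"] == r) & (sel["time_min"] == t)]
            if len(sample) != 1:
                raise ValueError(
                    f"design must have exactly one sample per (condition, time, replicate); "
                    f"got {len(sample)} for {condition!r}, t={t}, rep={r!r}"
                )
            arr[:, ri, ti] = levels[sample[0]].to_numpy()
    return arr, reps, times
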