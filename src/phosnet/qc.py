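"""Missing-value classification and normalization.

Label-free phosphoproteomics mixes two kinds of missingness: values
missing completely at random (MCAR, technical dropouts) and values
missing not at random (MNAR, abundance below the detection limit).  MNAR
zeros are biologically informative — a site switched off in one condition
— so sites are split by a valid-value rule applied per
(condition, time point) cell across replicates:

* a cell is VALID when at least ``min_valid`` replicates detected the
  site, ABSENT when at least ``min_valid`` replicates report 0, and
  AMBIGUOUS otherwise (e.g. 2 valid + 2 zeros out of 4);
* a site with any AMBIGUOUS cell (or no VALID cell at all) is DISCARDED;
* a site VALID in every cell is QUANTIFIED and enters the statistical
  analysis;
* otherwise — ABSENT somewhere, VALID somewhere, never AMBIGUOUS — the
  site is kept as an ABSENCE_PRESENCE site, excluded from the per-site
  model but eligible for network inference.

Normalization is variance-stabilizing (vsn): a per-sample affine
calibration followed by a generalized-log (arsinh) transform, fitted by a
robust maximum-likelihood criterion under the assumption that most sites
do not change between samples.  Output is divided by ln 2 so that at high
intensities it behaves like log2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import PhosphoTable

logger = logging.getLogger(__name__)

QUANTIFIED = "QUANTIFIED"
ABSENCE_PRESENCE = "ABSENCE_PRESENCE"
DISCARDED = "DISCARDED"

VALID = "VALID"
ABSENT = "ABSENT"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class ValidityClassification:
    """Per-site class and per-(condition, time) cell status.

    ``site_class`` maps each site key to QUANTIFIED / ABSENCE_PRESENCE /
    DISCARDED; ``cell_status`` is a site x (condition, time) frame of
    VALID / ABSENT / AMBIGUOUS; ``min_valid`` is the threshold used.
    """

    site_class: pd.Series
    cell_status: pd.DataFrame
    min_valid: int

    def sites(self, cls: str) -> pd.Index:
        return self.site_class.index[self.site_class == cls]

    def counts(self) -> dict[str, int]:
        c = self.site_class.value_counts()
        return {k: int(c.get(k, 0)) for k in (QUANTIFIED, ABSENCE_PRESENCE, DISCARDED)}


@dataclass
class NormalizedMatrix:
    """Log2-scale normalized intensities with an absence mask.

    ``values`` holds finite numbers where detected and NaN where absent;
    ``mask`` is True exactly where absent.  Absent entries are never
    imputed.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        m = self.mask.to_numpy(dtype=bool)
        if m.any() and not np.isnan(vals[m]).all():
            raise ValueError("masked entries must be NaN")
        if not np.isfinite(vals[~m]).all():
            raise ValueError("unmasked entries must be finite")

    def subset(self, sites: pd.Index) -> "NormalizedMatrix":
        sites = self.values.index.intersection(sites)
        return NormalizedMatrix(
            self.values.loc[sites].copy(), self.mask.loc[sites].copy(), self.design
        )


def default_min_valid(n_replicates: int) -> int:
    """3-of-4 rule generalized: ceil(0.75 x replicates)."""
    return math.ceil(0.75 * n_replicates)


def classify_missingness(
    table: PhosphoTable, min_valid: int | None = None
) -> ValidityClassification:
    """Apply the valid-value rules cell by cell and classify each site."""
    design = table.design
    if min_valid is None:
        min_valid = default_min_valid(len(table.replicates))
    cells = list(
        design.groupby(["condition", "time_min"], sort=True).groups.items()
    )
    X = table.intensities
    status = {}
    for (cond, t), samples in cells:
        block = X[list(samples)].to_numpy(dtype=float)
        valid = (block > 0).sum(axis=1)
        zero = block.shape[1] - valid
        st = np.where(
            valid >= min_valid, VALID, np.where(zero >= min_valid, ABSENT, AMBIGUOUS)
        )
        status[(cond, t)] = st
    cell_status = pd.DataFrame(status, index=X.index)
    cell_status.columns = pd.MultiIndex.from_tuples(
        cell_status.columns, names=["condition", "time_min"]
    )
    arr = cell_status.to_numpy()
    any_ambiguous = (arr == AMBIGUOUS).any(axis=1)
    any_valid = (arr == VALID).any(axis=1)
    all_valid = (arr == VALID).all(axis=1)
    site_class = np.where(
        any_ambiguous | ~any_valid,
        DISCARDED,
        np.where(all_valid, QUANTIFIED, ABSENCE_PRESENCE),
    )
    return ValidityClassification(
        pd.Series(site_class, index=X.index, name="site_class"),
        cell_status,
        int(min_valid),
    )


def split_subsets(
    matrix: NormalizedMatrix, cls: ValidityClassification
) -> tuple[NormalizedMatrix, NormalizedMatrix]:
    """Partition a normalized matrix into (quantified, absence/presence)."""
    return matrix.subset(cls.sites(QUANTIFIED)), matrix.subset(cls.sites(ABSENCE_PRESENCE))


# ---------------------------------------------------------------------------
# vsn

def _fit_vsn(
    X_raw: np.ndarray,
    trim: float = 0.9,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> np.ndarray:
    """Variance-stabilizing calibration + generalized log.

    Each sample s gets an affine calibration x -> (x - alpha_s)/beta_s
    fitted by iteratively reweighted least squares against a robust
    reference profile (the row median of the calibrated data), under the
    assumption that most sites are unchanged between samples: weights
    are the inverse variances of the additive + multiplicative error
    model, var ~ x0^2 + ref^2, and a least-trimmed-squares style
    influence set keeps the ``trim`` fraction of rows with the smallest
    weighted residuals.  The glog offset x0 is re-estimated each
    iteration from the residual spread of the low-intensity rows, so
    with a real additive noise floor the transform linearizes there,
    and with purely multiplicative noise it degenerates to a plain log.

    Output is arsinh(calibrated/x0)/ln 2 — log2-like at high intensity.
    Iterates until parameters change by less than ``tol`` (relative) or
    ``max_iter`` rounds.
    """
    n, S = X_raw.shape
    for s in range(S):
        if np.isfinite(X_raw[:, s]).sum() < 2:
            raise ValueError(f"sample column {s} has fewer than 2 detected values")
    med = np.nanmedian(X_raw, axis=0)
    med = np.where(med > 0, med, 1.0)
    scale0 = float(np.exp(np.mean(np.log(med))))
    alpha = np.zeros(S)
    beta = med / scale0
    x0 = 1e-3 * scale0
    n_keep = max(2, int(math.floor(trim * n)))
    obs = np.isfinite(X_raw)

    for _ in range(max_iter):
        C = (X_raw - alpha) / beta
        ref = np.nanmedian(C, axis=1)
        resid = C - ref[:, None]
        w_row = 1.0 / (x0**2 + np.square(ref))
        with np.errstate(invalid="ignore"):
            row_score = np.nanmean(np.square(resid), axis=1) * w_row
        row_score = np.where(np.isfinite(row_score), row_score, np.inf)
        influence = np.zeros(n, dtype=bool)
        influence[np.argsort(row_score, kind="stable")[:n_keep]] = True

        alpha_new = np.empty(S)
        beta_new = np.empty(S)
        for s in range(S):
            rows = influence & obs[:, s] & np.isfinite(ref)
            x = X_raw[rows, s]
            r = ref[rows]
            w = w_row[rows] * np.square(beta[s])  # weights in raw units
            # pseudo-observation at the origin: integrated MS1 intensities
            # are baseline-subtracted, so the affine offset is shrunk hard
            # toward zero -- estimating it freely would extrapolate far
            # below the measured range and destabilize the lowest sites
            x = np.append(x, 0.0)
            r = np.append(r, 0.0)
            w = np.append(w, 100.0 * w.sum())
            sw = w.sum()
            mx, mr = (w * x).sum() / sw, (w * r).sum() / sw
            cov = (w * (x - mx) * (r - mr)).sum()
            var = (w * np.square(r - mr)).sum()
            if var <= 0:
                raise ValueError(f"sample column {s}: reference profile is constant")
            b_s = cov / var
            if b_s <= 0:
                raise ValueError(f"sample column {s}: non-positive calibration slope")
            beta_new[s] = b_s
            alpha_new[s] = mx - b_s * mr

        # glog offset = additive component of the error model, separated
        # from the multiplicative one by regressing per-row residual
        # variance on ref^2 (var ~ sigma_add^2 + sigma_mult^2 ref^2)
        fin_ref = np.isfinite(ref)
        rows = influence & fin_ref
        with np.errstate(invalid="ignore"):
            row_scale = 1.4826 * np.nanmedian(np.abs(resid[rows]), axis=1)
        u = np.square(row_scale)
        z = np.square(ref[rows])
        good = np.isfinite(u) & np.isfinite(z) & (z > 0)
        u, z = u[good], z[good]
        if u.size >= 4:
            # slope (multiplicative variance) from the top of the
            # intensity range, intercept (additive variance) from the
            # bottom -- a plain fit is dominated by the largest rows
            order = np.argsort(z, kind="stable")
            top = order[-max(2, u.size // 4):]
            bottom = order[: max(2, u.size // 4)]
            B = float(np.median(u[top] / z[top]))
            excess = u[bottom] - B * z[bottom]
            A = float(np.median(excess))
            # keep the additive term only when it clears its sampling
            # noise AND carries a substantial share of the variance at
            # low intensity; otherwise the offset would land inside the
            # intensity bulk and linearize genuinely log-scale data
            spread = 1.4826 * float(np.median(np.abs(excess - A)))
            floor_stat = 2.0 * spread / math.sqrt(len(excess))
            floor_rel = 0.25 * B * float(np.median(z[bottom]))
            if A <= max(floor_stat, floor_rel):
                A = 0.0
            sigma_add = math.sqrt(max(A, 0.0))
        else:
            sigma_add = 0.0
        ref_med = max(float(np.nanmedian(ref[fin_ref])), 1e-300)
        x0_new = max(float(sigma_add), 1e-6 * ref_med)

        delta = max(
            np.max(np.abs(alpha_new - alpha)) / (1.0 + np.max(np.abs(alpha_new))),
            np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new))),
            abs(x0_new - x0) / (1.0 + abs(x0_new)),
        )
        alpha, beta, x0 = alpha_new, beta_new, x0_new
        if delta < tol:
            break

    return np.arcsinh(((X_raw - alpha) / beta) / x0) / math.log(2)


def normalize(table: PhosphoTable, method: str = "vsn") -> NormalizedMatrix:
    """Normalize raw intensities onto a log2-comparable scale.

    ``method="vsn"`` fits the variance-stabilizing calibration (see
    module docstring); ``method="log2-median"`` is the plain fallback:
    log2 transform followed by per-sample median subtraction.  Zeros are
    masked as absent before either transform and stay masked.
    """
    X = table.intensities.to_numpy(dtype=float).copy()
    mask = ~(X > 0)
    X[mask] = np.nan
    if method == "vsn":
        H = _fit_vsn(X)
    elif method == "log2-median":
        for s in range(X.shape[1]):
            if np.isfinite(X[:, s]).sum() < 2:
                raise ValueError(f"sample column {s} has fewer than 2 detected values")
        H = np.log2(X)
        H = H - np.nanmedian(H, axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    values = pd.DataFrame(H, index=table.intensities.index, columns=table.intensities.columns)
    mask_df = pd.DataFrame(
        mask, index=table.intensities.index, columns=table.intensities.columns
    )
    values = values.where(~mask_df)
    return NormalizedMatrix(values, mask_df, table.design.copy())
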