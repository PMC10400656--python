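"""Per-site mixed models, q-values, and selection of network sites.

Each QUANTIFIED phosphosite is modelled with a linear mixed model chosen
from the experimental design::

    Y = mu + beta_j           + gamma_k + eps        (1 condition, >1 time)
    Y = mu + alpha_i          + gamma_k + eps        (>1 condition, 1 time)
    Y = mu + alpha_i + beta_j + (alpha beta)_ij + gamma_k + eps   (both)

with fixed condition (alpha) and time (beta) effects, a random intercept
gamma_k per replicate (plants grown together are correlated) and residual
eps.  The tested effect is the condition when present, else time: the
condition main effect and the condition x time interaction are dropped
jointly from the full model.

The random-intercept likelihood is profiled analytically: for a grouped
covariance V = sigma^2 (I + rho Z Z') the GLS fit reduces to ordinary
least squares on within-group shrunken data, leaving a one-dimensional
optimization over rho.  The default p-value references the nested-model
statistic against an F distribution with denominator degrees of freedom
that discount the replicate blocks — in the balanced crossed design the
tested contrasts are orthogonal to the blocks and the F reference is
exact, where the chi-square limit of the raw likelihood ratio is badly
anticonservative at these sample sizes.  ``statistic="lrt"`` gives the
asymptotic chi-square version.  Variance components are reported from
REML at the full model.

Multiple testing is handled with Storey q-values (pi0 estimated on a
lambda grid with a cubic smoother).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .qc import ABSENT, VALID, ValidityClassification

logger = logging.getLogger(__name__)

TIME_ONLY = "TIME_ONLY"
CONDITION_ONLY = "CONDITION_ONLY"
FULL = "FULL"


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects enter the model and which one is tested."""

    variant: str
    tested_effect: str  # "condition" or "time"


@dataclass
class SiteTestResult:
    site: object
    p_value: float
    statistic: float
    df_test: int
    method: str
    var_replicate: float
    var_residual: float
    q_value: float | None = None
    significant: bool | None = None


def select_design(n_conditions: int, n_times: int) -> ModelSpec:
    """Pick the model variant from the design shape.

    One condition with a time course tests the time effect; several
    conditions at a single time point test the condition effect; a full
    two-way design tests the condition main effect together with the
    condition x time interaction.
    """
    if n_conditions < 1 or n_times < 1:
        raise ValueError("design counts must be >= 1")
    if n_conditions == 1 and n_times == 1:
        raise ValueError("degenerate design: a single condition x time cell tests nothing")
    if n_conditions == 1:
        return ModelSpec(TIME_ONLY, "time")
    if n_times == 1:
        return ModelSpec(CONDITION_ONLY, "condition")
    return ModelSpec(FULL, "condition")


# ---------------------------------------------------------------------------
# Random-intercept ML/REML engine


def _whiten(y, X, groups, rho):
    yw = y.copy()
    Xw = X.copy()
    logdet = 0.0
    for idx in groups:
        n_k = len(idx)
        theta = 1.0 - 1.0 / np.sqrt(1.0 + rho * n_k)
        yw[idx] -= theta * yw[idx].mean()
        Xw[idx] -= theta * Xw[idx].mean(axis=0)
        logdet += np.log1p(rho * n_k)
    return yw, Xw, logdet


def _gls_at_rho(y, X, groups, rho):
    yw, Xw, logdet = _whiten(y, X, groups, rho)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    return beta, rss, logdet, Xw, rank


def _neg2ll(y, X, groups, rho, reml: bool):
    n, p = X.shape
    beta, rss, logdet, Xw, _ = _gls_at_rho(y, X, groups, rho)
    if reml:
        dof = n - p
        sigma2 = max(rss / dof, 1e-300)
        sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        return (
            dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdet + logdet_xx,
            sigma2,
        )
    sigma2 = max(rss / n, 1e-300)
    return n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet, sigma2


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool = False
):
    """Profile-fit Y = X beta + (group intercept) + eps.

    Returns ``(loglik, rho, sigma2, beta, rss_whitened)`` where ``rho`` is
    the ratio of replicate to residual variance.  The search is over
    log rho with the boundary rho = 0 checked explicitly.
    """
    labels = pd.unique(groups)
    idxs = [np.flatnonzero(groups == g) for g in labels]

    def obj(log_rho):
        return _neg2ll(y, X, idxs, np.exp(log_rho), reml)[0]

    best = optimize.minimize_scalar(
        obj, bounds=(-14.0, 14.0), method="bounded", options={"xatol": 1e-10}
    )
    cand = [(best.fun, float(np.exp(best.x)))]
    cand.append((_neg2ll(y, X, idxs, 0.0, reml)[0], 0.0))
    fun, rho = min(cand, key=lambda c: c[0])
    beta, rss, _, _, _ = _gls_at_rho(y, X, idxs, rho)
    _, sigma2 = _neg2ll(y, X, idxs, rho, reml)
    return -0.5 * fun, rho, sigma2, beta, rss


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _dummies(values) -> np.ndarray:
    """Treatment-coded indicator columns (first level dropped)."""
    levels = pd.unique(values)
    levels = np.sort(levels)
    return np.column_stack([(values == lv).astype(float) for lv in levels[1:]]) if len(
        levels
    ) > 1 else np.empty((len(values), 0))


def _model_matrices(design: pd.DataFrame, spec: ModelSpec):
    n = len(design)
    one = np.ones((n, 1))
    cond = _dummies(design["condition"].to_numpy())
    time = _dummies(design["time_min"].to_numpy())
    if spec.variant == TIME_ONLY:
        return np.hstack([one, time]), one
    if spec.variant == CONDITION_ONLY:
        return np.hstack([one, cond]), one
    inter = np.hstack(
        [cond[:, [i]] * time[:, [j]] for i in range(cond.shape[1]) for j in range(time.shape[1])]
    ) if cond.shape[1] and time.shape[1] else np.empty((n, 0))
    full = np.hstack([one, cond, time, inter])
    reduced = np.hstack([one, time])  # drop condition main effect + interaction
    return full, reduced


def fit_site_model(
    values: pd.Series,
    design: pd.DataFrame,
    spec: ModelSpec,
    statistic: str = "f",
    site=None,
) -> SiteTestResult:
    """Fit one site's mixed model and test the design effect.

    ``values`` is indexed by sample name (NaN marks absent entries, which
    are dropped); ``design`` supplies condition / time_min / replicate per
    sample.  ``statistic`` is ``"f"`` (default; nested F at the REML
    variance ratio, exact for balanced designs) or ``"lrt"``
    (chi-square likelihood ratio of nested ML fits).
    """
    common = values.index.intersection(design.index)
    v = values.loc[common]
    keep = v.notna()
    v = v[keep]
    d = design.loc[v.index]
    y = v.to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite intensity values")
    X_full, X_red = _model_matrices(d, spec)
    groups = d["replicate"].to_numpy()
    n, p_full = X_full.shape
    q = p_full - X_red.shape[1]
    n_groups = len(pd.unique(groups))
    ddf = n - p_full - (n_groups - 1)
    if ddf < 1:
        raise ValueError(
            f"insufficient residual degrees of freedom ({ddf}) for {n} observations"
        )

    method = "mixed"
    try:
        ll_full_reml, rho, sigma2_reml, _, _ = fit_random_intercept(
            y, X_full, groups, reml=True
        )
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        rho, sigma2_reml = 0.0, np.nan
        method = "ols-fallback"
        logger.warning("REML fit failed for site %r; using fixed-effects fall-back", site)
    if method == "ols-fallback" or rho == 0.0:
        if rho == 0.0 and method == "mixed":
            method = "ols"  # replicate variance estimated at zero

    if statistic == "f":
        # Exact within-block F: replicate intercepts absorbed as fixed
        # blocks in both nested models.  With treatments crossed with
        # replicates this conditions on the random intercepts, so the F
        # reference is exact under the mixed model -- no variance-ratio
        # estimate enters the test.
        blocks = _dummies(groups)
        Xf = np.hstack([X_full, blocks])
        Xr = np.hstack([X_red, blocks])
        rss_full = _ols_rss(y, Xf)
        rss_red = _ols_rss(y, Xr)
        num = max(rss_red - rss_full, 0.0) / q
        den = rss_full / ddf
        # effects below the numerical precision of the input scale are
        # indistinguishable from zero (exactly constant data has RSS 0)
        eps = 1e-9 * max(1.0, float(np.mean(np.square(y))))
        if num <= eps:
            stat, p = 0.0, 1.0
        elif den <= eps:
            stat, p = np.inf, 0.0
        else:
            stat = num / den
            p = float(stats.f.sf(stat, q, ddf))
        method += "-f"
    elif statistic == "lrt":
        ll_full, *_ = fit_random_intercept(y, X_full, groups, reml=False)
        ll_red, *_ = fit_random_intercept(y, X_red, groups, reml=False)
        stat = max(2.0 * (ll_full - ll_red), 0.0)
        p = float(stats.chi2.sf(stat, q)) if stat > 0 else 1.0
        method += "-lrt"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    var_res = sigma2_reml
    var_rep = rho * sigma2_reml
    return SiteTestResult(
        site=site,
        p_value=float(min(max(p, 0.0), 1.0)),
        statistic=float(stat),
        df_test=int(q),
        method=method,
        var_replicate=float(var_rep),
        var_residual=float(var_res),
    )


# ---------------------------------------------------------------------------
# Storey q-values


def estimate_pi0(p_values: np.ndarray) -> float:
    """Estimate the null proportion pi0 on the 0.05..0.95 lambda grid.

    The raw estimates pi0(lambda) = #{p > lambda} / (m (1 - lambda)) are
    smoothed with a cubic polynomial and read off at lambda = 0.95, then
    clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    lam = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = pi0_lam[-1]
    else:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, 0.95))
    return float(min(max(pi0, 1.0 / m if m else 1.0), 1.0)) if m else 1.0


def estimate_qvalues(p_values) -> np.ndarray:
    """Storey q-values, returned in the input order.

    q(p_(i)) = min_{j >= i} pi0 m p_(j) / j over the sorted p-values, so
    q is monotone in p and bounded by pi0.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def attach_qvalues(results: list[SiteTestResult], q_cutoff: float = 0.05,
                   p_cutoff: float = 0.05) -> list[SiteTestResult]:
    qs = estimate_qvalues([r.p_value for r in results])
    for r, qv in zip(results, qs):
        r.q_value = float(qv)
        r.significant = bool(r.p_value < p_cutoff and r.q_value <= q_cutoff)
    return results


def results_frame(results: list[SiteTestResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "statistic": [r.statistic for r in results],
            "method": [r.method for r in results],
            "var_replicate": [r.var_replicate for r in results],
            "var_residual": [r.var_residual for r in results],
            "significant": [r.significant for r in results],
        },
        index=pd.MultiIndex.from_tuples([r.site for r in results])
        if results and isinstance(results[0].site, tuple)
        else [r.site for r in results],
    )
    return df


def select_network_sites(
    results: pd.DataFrame,
    cls: ValidityClassification,
    q_cutoff: float = 0.05,
    p_cutoff: float = 0.05,
) -> pd.Index:
    """Sites entering network inference.

    Union of (a) quantified sites significant for the tested effect
    (p < p_cutoff and q <= q_cutoff) and (b) absence/presence sites with
    at least one time point where one condition's cell is VALID while
    another condition's cell is ABSENT.
    """
    sig = results.index[
        (results["p_value"] < p_cutoff) & (results["q_value"] <= q_cutoff)
    ]
    ap_sites = cls.sites("ABSENCE_PRESENCE")
    chosen = []
    if len(ap_sites):
        cell = cls.cell_status.loc[ap_sites]
        times = cell.columns.get_level_values("time_min").unique()
        for t in times:
            block = cell.xs(t, axis=1, level="time_min")
            has_valid = (block == VALID).any(axis=1)
            has_absent = (block == ABSENT).any(axis=1)
            chosen.append(has_valid & has_absent)
        ap_mask = pd.concat(chosen, axis=1).any(axis=1)
        ap_selected = ap_sites[ap_mask.loc[ap_sites]]
    else:
        ap_selected = ap_sites
    return sig.union(ap_selected)
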