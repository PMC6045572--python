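"""Stage-gradient trend analysis of model fits.

Quantifies how RSA model fit varies across the ordered processing stages
within each region: restricted-cubic-spline (RCS) trend curves with
data-driven knot counts, a shape classification (decreasing / peaked /
increasing), and a permutation test of the region x stage interaction
(whether regions follow different stage curves).

The estimation strategy is a two-stage summary-statistics approximation
to a mixed-effects model: subjects enter as strata (fixed intercepts in
the pooled fits, per-subject coefficients in the curve summaries) and
inference is by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StageCurve",
    "InteractionResult",
    "rcs_basis",
    "rcs_knots",
    "fit_stage_curve",
    "region_stage_interaction",
]

#: standard Harrell knot placement quantiles by knot count
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def rcs_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knot locations at the standard quantiles of ``x``."""
    if n_knots not in KNOT_QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(KNOT_QUANTILES)}")
    return np.quantile(np.asarray(x, dtype=float), KNOT_QUANTILES[n_knots])


def rcs_basis(x: np.ndarray, n_knots: int, knots: np.ndarray | None = None) -> np.ndarray:
    """Restricted cubic spline basis (Harrell parameterisation).

    Returns an (n, n_knots - 1) matrix: the linear term followed by
    n_knots - 2 nonlinear terms.  The implied curve is continuous with
    continuous first and second derivatives and is linear beyond the
    boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if len(np.unique(x)) < n_knots:
            raise ValueError("too few distinct x values for the requested knots")
        knots = rcs_knots(x, n_knots)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    norm = (t[-1] - t[0]) ** 2

    def cube(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class StageCurve:
    """Fitted stage-trend for one region."""

    region: str
    n_knots: int | None       # None: linear model preferred
    knots: np.ndarray | None
    coef: np.ndarray          # group-mean coefficients incl. intercept
    stages: np.ndarray
    fitted: np.ndarray        # fitted mean rho per stage
    shape: str                # decreasing | peaked | increasing | flat

    @staticmethod
    def classify(fitted: np.ndarray, rel_tol: float = 0.02) -> str:
        """Shape of a fitted stage curve.

        A curve counts as *peaked* only when its interior maximum exceeds
        the value at both endpoints by more than ``rel_tol`` of the fitted
        range — small interior bumps (spline wiggle on plateaus) do not
        make a trend peaked.  Otherwise the endpoint comparison decides
        increasing vs decreasing; a numerically constant curve is flat.
        """
        f = np.asarray(fitted, dtype=float)
        rng = f.max() - f.min()
        if rng < 1e-10:
            return "flat"
        tol = rel_tol * rng
        peak = int(np.argmax(f))
        if 0 < peak < len(f) - 1 and f[peak] > f[0] + tol and f[peak] > f[-1] + tol:
            return "peaked"
        return "increasing" if f[-1] > f[0] else "decreasing"


def _check_fit_table(fit_table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "region", "stage_index", "rho"}
    missing = required - set(fit_table.columns)
    if missing:
        raise ValueError(f"fit table is missing columns: {sorted(missing)}")
    counts = fit_table.groupby(["subject", "region"])["stage_index"].nunique()
    if counts.nunique() > 1:
        raise ValueError("unbalanced fit table: stage coverage differs across cells")
    return fit_table


def _design(x, n_knots, knots=None):
    if n_knots is None:  # plain linear trend
        return np.column_stack([np.asarray(x, dtype=float)])
    return rcs_basis(x, n_knots, knots=knots)


def _pooled_rss(sub: pd.DataFrame, basis: np.ndarray) -> tuple[float, int]:
    """RSS of a pooled OLS with subject strata (fixed intercepts)."""
    subjects = pd.Categorical(sub["subject"])
    S = pd.get_dummies(subjects).to_numpy(dtype=float)
    X = np.column_stack([S, basis])
    y = sub["rho"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), X.shape[1]


def fit_stage_curve(
    fit_table: pd.DataFrame,
    region: str,
    knot_candidates: tuple[int, ...] = (3, 4, 5),
    alpha_in: float = 0.05,
) -> StageCurve:
    """Fit the stage-trend curve for one region with data-driven knots.

    Candidate models of increasing complexity (linear, then RCS with each
    knot count in ``knot_candidates``) are compared on a pooled fit with
    subject strata; a more complex model is retained while its extra terms
    significantly reduce the residual sum of squares (partial F test at
    ``alpha_in``).  The returned curve averages per-subject least-squares
    coefficients of the selected basis.
    """
    from scipy import stats

    fit_table = _check_fit_table(fit_table)
    sub = fit_table[fit_table["region"] == region]
    if sub.empty:
        raise ValueError(f"region {region} not present in the fit table")
    if sub["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    x = sub["stage_index"].to_numpy(dtype=float)
    n = len(sub)

    chosen: int | None = None
    rss_prev, df_prev = _pooled_rss(sub, _design(x, None))
    for k in sorted(knot_candidates):
        basis = _design(x, k)
        rss_k, df_k = _pooled_rss(sub, basis)
        d_df = df_k - df_prev
        df_res = n - df_k
        if d_df <= 0 or df_res <= 0 or rss_k <= 0:
            break
        F = ((rss_prev - rss_k) / d_df) / (rss_k / df_res)
        p = stats.f.sf(F, d_df, df_res)
        if p < alpha_in:
            chosen, rss_prev, df_prev = k, rss_k, df_k
        else:
            break

    knots = rcs_knots(x, chosen) if chosen is not None else None
    stage_grid = np.unique(x)
    coefs = []
    for _, grp in sub.groupby("subject"):
        xs = grp["stage_index"].to_numpy(dtype=float)
        B = np.column_stack([np.ones(len(grp)), _design(xs, chosen, knots)])
        beta, *_ = np.linalg.lstsq(B, grp["rho"].to_numpy(dtype=float), rcond=None)
        coefs.append(beta)
    coef = np.mean(coefs, axis=0)
    Bg = np.column_stack([np.ones(len(stage_grid)), _design(stage_grid, chosen, knots)])
    fitted = Bg @ coef
    return StageCurve(
        region=region,
        n_knots=chosen,
        knots=knots,
        coef=coef,
        stages=stage_grid,
        fitted=fitted,
        shape=StageCurve.classify(fitted),
    )


@dataclass
class InteractionResult:
    """Region x stage interaction test."""

    F: float
    p: float
    n_perm: int
    n_knots: int


def _interaction_F(
    y: np.ndarray,
    S: np.ndarray,
    basis: np.ndarray,
    region_codes: np.ndarray,
    n_regions: int,
) -> float:
    """F-type statistic: region-specific stage curves vs a shared curve."""
    R = np.zeros((len(y), n_regions - 1))
    for r in range(1, n_regions):
        R[region_codes == r, r - 1] = 1.0
    inter = np.concatenate(
        [basis * R[:, [r]] for r in range(n_regions - 1)], axis=1
    )
    X0 = np.column_stack([S, R, basis])
    X1 = np.column_stack([X0, inter])
    b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ b0) ** 2))
    rss1 = float(np.sum((y - X1 @ b1) ** 2))
    d_df = inter.shape[1]
    df_res = len(y) - X1.shape[1]
    if df_res <= 0 or rss1 <= 0:
        return np.inf
    return ((rss0 - rss1) / d_df) / (rss1 / df_res)


def region_stage_interaction(
    fit_table: pd.DataFrame,
    n_perm: int = 2000,
    n_knots: int = 3,
    seed=0,
) -> InteractionResult:
    """Permutation test of the region x stage interaction.

    Compares a model with region-specific stage curves against one with a
    shared curve (subjects as strata); the null distribution permutes the
    region labels of each subject's region series independently within
    subject, preserving the stage structure.
    """
    fit_table = _check_fit_table(fit_table)
    regions = sorted(fit_table["region"].unique())
    if len(regions) < 2:
        raise ValueError("interaction test requires at least 2 regions")
    df = fit_table.sort_values(["subject", "region", "stage_index"], kind="stable")
    y = df["rho"].to_numpy(dtype=float)
    x = df["stage_index"].to_numpy(dtype=float)
    S = pd.get_dummies(pd.Categorical(df["subject"])).to_numpy(dtype=float)
    basis = rcs_basis(x, n_knots)
    codes = pd.Categorical(df["region"], categories=regions).codes.astype(int)
    n_regions = len(regions)

    F_obs = _interaction_F(y, S, basis, codes, n_regions)
    rng = np.random.default_rng(seed)
    subjects = df["subject"].to_numpy()
    subj_ids = pd.unique(subjects)
    exceed = 0
    for _ in range(n_perm):
        perm_codes = codes.copy()
        for sid in subj_ids:
            m = subjects == sid
            relabel = rng.permutation(n_regions)
            perm_codes[m] = relabel[codes[m]]
        if _interaction_F(y, S, basis, perm_codes, n_regions) >= F_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return InteractionResult(F=float(F_obs), p=float(p), n_perm=n_perm, n_knots=n_knots)
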