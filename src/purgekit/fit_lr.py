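"""Linear-regression (LR) estimation of the purging coefficient.

The intercept b0 = E[ln W0] is fixed in a first step as the mean
log-fitness of the noninbred reference set (F = Fa = 0), or supplied by
the user.  For each candidate d, Y_i = ln(W_i) - b0 is regressed through
the origin on the purged inbreeding g_i(d) (plus optional covariates);
the d minimizing the residual sum of squares over the grid
0 <= d <= 0.5, step 0.01, is refined by golden-section search in a
+/- 0.01 bracket.  The fit at d = 0 (no purging) is always reported
alongside for comparison.

Fixing b0 separately matters: estimating it jointly with b1 and d lets
the model overfit (too low an intercept compensated by too shallow a
slope and too small a d), which destroys the predictive value of the
estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .coefficients import inbreeding_F, ancestral_Fa, purged_inbreeding_grid
from .pedigree import Pedigree, PedigreeError, noninbred_reference_set

__all__ = [
    "IPFitResult",
    "estimate_intercept_lr",
    "lr_fit_given_d",
    "lr_search_d",
    "aicc",
]

log = logging.getLogger(__name__)

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0  # 0.618...


def aicc(rss: float, n: int, k_reg: int, d_estimated: bool) -> float:
    """Corrected Akaike information criterion for a least-squares fit.

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1), where k counts all
    regression coefficients, the error variance, and the purging
    coefficient d when it was estimated (the parameter count covers the
    whole two-stage procedure, not just the final regression).
    """
    k = k_reg + 1 + (1 if d_estimated else 0)
    if n <= k + 1:
        return np.inf
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass
class IPFitResult:
    """One row of an IP analysis (plus the d = 0 comparison fit)."""

    d_hat: float
    b: np.ndarray  # coefficient on g first, then covariates
    se_b: np.ndarray
    p_t: np.ndarray
    intercept: float  # lnW0 (LR) or W0 (NNLR)
    intercept_sd: float
    rss: float
    p_F: float | None
    aR2: float | None
    aicc: float
    n_used: int
    n_dropped: int = 0
    predictor_names: tuple[str, ...] = ("g",)
    comparison_d0: "IPFitResult | None" = None
    rss_spread: float | None = None  # NNLR restart spread

    @property
    def b_g(self) -> float:
        return float(self.b[0])


def estimate_intercept_lr(
    p: Pedigree, F: np.ndarray | None = None, Fa: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean and SD of log-fitness over the noninbred reference set.

    The reference set is every individual with F = Fa = 0 and recorded
    fitness.  Zero fitness cannot be log-transformed: that is an error
    here (the NNLR method handles zeros).
    """
    if F is None:
        F = inbreeding_F(p)
    if Fa is None:
        Fa = ancestral_Fa(p, F)
    ids = noninbred_reference_set(p, F, Fa)
    w = np.array([p.fitness[p.index[i]] for i in sorted(ids)])
    if np.any(w <= 0):
        raise PedigreeError(
            "reference set contains zero fitness values; log-fitness is undefined "
            "-- use the NNLR method or supply the intercept"
        )
    lw = np.log(w)
    sd = float(np.std(lw, ddof=1)) if len(lw) > 1 else 0.0
    return float(np.mean(lw)), sd


def _design(
    p: Pedigree,
    g: np.ndarray,
    use_covariates: bool,
    maternal_g: bool,
    g_all: np.ndarray | None = None,
):
    """Build (mask, X, names) for the through-origin regression.

    Records with missing or nonpositive fitness are dropped (logged).
    ``maternal_g`` appends the dam's purged inbreeding at the same d
    (requires ``g_all``, g for every individual).
    """
    mask = np.isfinite(p.fitness) & (p.fitness > 0)
    n_dropped = int(np.isfinite(p.fitness).sum() - mask.sum())
    if n_dropped:
        log.info("dropped %d records with nonpositive fitness from LR", n_dropped)
    cols = [g[mask]]
    names = ["g"]
    if use_covariates and p.covariates.shape[1]:
        for j in range(p.covariates.shape[1]):
            cols.append(p.covariates[mask, j])
            names.append(f"cov{j + 1}")
    if maternal_g:
        if g_all is None:
            g_all = g
        gm = np.where(p.dam_idx >= 0, g_all[np.clip(p.dam_idx, 0, None)], 0.0)
        cols.append(gm[mask])
        names.append("g_dam")
    X = np.column_stack(cols)
    return mask, n_dropped, X, tuple(names)


def lr_fit_given_d(
    p: Pedigree,
    d: float,
    lnW0: float,
    lnW0_sd: float = np.nan,
    g: np.ndarray | None = None,
    use_covariates: bool = True,
    maternal_g: bool = False,
    d_estimated: bool = False,
) -> IPFitResult:
    """Through-origin OLS of Y = ln(W) - lnW0 on g(d) (+ covariates).

    Standard errors, t and F tests assume normal, independent residuals;
    the adjusted R^2 uses the uncentered total sum of squares (the
    standard definition when the intercept is suppressed).
    """
    if g is None:
        g = purged_inbreeding_grid(p, [d])[:, 0]
    mask, n_dropped, X, names = _design(p, g, use_covariates, maternal_g, g)
    n = int(mask.sum())
    k = X.shape[1]
    if n < k + 1:
        raise PedigreeError(
            f"only {n} usable records for {k} predictors; cannot fit"
        )
    if np.linalg.matrix_rank(X) < k:
        raise PedigreeError(
            "singular design matrix (e.g. no inbreeding variation: all g equal zero)"
        )
    y = np.log(p.fitness[mask]) - lnW0
    res = sm.OLS(y, X).fit()
    return IPFitResult(
        d_hat=float(d),
        b=np.asarray(res.params),
        se_b=np.asarray(res.bse),
        p_t=np.asarray(res.pvalues),
        intercept=float(lnW0),
        intercept_sd=float(lnW0_sd),
        rss=float(res.ssr),
        p_F=float(res.f_pvalue),
        aR2=float(res.rsquared_adj),
        aicc=aicc(float(res.ssr), n, k, d_estimated),
        n_used=n,
        n_dropped=n_dropped,
        predictor_names=names,
    )


def _rss_at(p, d, lnW0, use_covariates, maternal_g) -> float:
    fit = lr_fit_given_d(
        p, d, lnW0, g=None, use_covariates=use_covariates, maternal_g=maternal_g
    )
    return fit.rss


def _golden_section(fun, lo: float, hi: float, tol: float) -> float:
    """Minimize a unimodal scalar function on [lo, hi] to bracket width tol."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d_ = a + _GOLDEN * (b - a)
    fc, fd = fun(c), fun(d_)
    while b - a > tol:
        if fc < fd:
            b, d_, fd = d_, c, fc
            c = b - _GOLDEN * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d_, fd
            d_ = a + _GOLDEN * (b - a)
            fd = fun(d_)
    return (a + b) / 2.0


def lr_search_d(
    p: Pedigree,
    lnW0: float | None = None,
    precision: str = "gss",
    grid_step: float = 0.01,
    gss_tol: float = 1e-4,
    use_covariates: bool = True,
    maternal_g: bool = False,
) -> IPFitResult:
    """LR estimate of d: RSS grid search on [0, 0.5] plus GSS refinement.

    ``precision`` is ``"grid"`` (step ``grid_step``) or ``"gss"`` (grid
    then golden-section search within +/- grid_step, clipped to [0, 0.5],
    to ``gss_tol`` in d).  If ``lnW0`` is None it is estimated from the
    noninbred reference set.  The returned result carries the fit
    conditional on d = 0 in ``comparison_d0``.
    """
    if precision not in ("grid", "gss"):
        raise ValueError("precision must be 'grid' or 'gss'")
    if lnW0 is None:
        lnW0, lnW0_sd = estimate_intercept_lr(p)
    else:
        lnW0_sd = np.nan

    F = inbreeding_F(p)
    grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    grid = np.clip(grid, 0.0, 0.5)
    G = purged_inbreeding_grid(p, grid, F=F)
    rss = np.empty(len(grid))
    for k, d in enumerate(grid):
        rss[k] = lr_fit_given_d(
            p, d, lnW0, g=G[:, k], use_covariates=use_covariates,
            maternal_g=maternal_g,
        ).rss
    k_best = int(np.argmin(rss))
    d_best = float(grid[k_best])

    if precision == "gss":
        lo = max(0.0, d_best - grid_step)
        hi = min(0.5, d_best + grid_step)
        d_ref = _golden_section(
            lambda d: _rss_at(p, d, lnW0, use_covariates, maternal_g),
            lo, hi, gss_tol,
        )
        # never accept a refinement worse than the grid optimum
        if _rss_at(p, d_ref, lnW0, use_covariates, maternal_g) <= rss[k_best]:
            d_best = d_ref

    fit = lr_fit_given_d(
        p, d_best, lnW0, lnW0_sd=lnW0_sd, use_covariates=use_covariates,
        maternal_g=maternal_g, d_estimated=True,
    )
    fit.comparison_d0 = lr_fit_given_d(
        p, 0.0, lnW0, lnW0_sd=lnW0_sd, g=G[:, 0],
        use_covariates=use_covariates, maternal_g=maternal_g, d_estimated=False,
    )
    return fit
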