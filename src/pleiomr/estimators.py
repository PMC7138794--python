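"""Causal-effect estimators and pleiotropy tests for two-sample MR.

Each SNP j provides a Wald ratio beta_zy_j / beta_zx_j.  The inverse-variance
weighted (IVW) estimate is the weighted mean of those ratios with first-order
weights w_j = beta_zx_j^2 / se_zy_j^2, equivalent to a zero-intercept weighted
regression of outcome on exposure effects.  The sensitivity battery trades
efficiency for robustness to invalid instruments:

* MR-Egger frees the intercept; the intercept estimates average directional
  pleiotropy (valid under InSIDE) and its SIMEX correction counters the
  regression dilution caused by noise in the SNP-exposure effects.
* The weighted median is consistent when at least half the weight comes from
  valid SNPs; the weighted mode when the largest cluster of ratios does.
* Multivariable IVW regresses outcome effects jointly on several exposures'
  effects, giving each exposure's direct effect holding the others fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (CollinearityError, ConfigurationError, DivisionError,
                     InsufficientSnpsError)
from .summary_io import Z95, HarmonizedSet, MvHarmonizedSet


@dataclass
class MrEstimate:
    """One estimator's causal-effect result.

    ``beta`` is per SD of exposure (per unit genetic liability for binary
    exposures); for binary outcomes it is a log odds ratio.  Intercept fields
    are populated only by the Egger family.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    exposure_id: str = ""
    outcome_id: str = ""
    outcome_type: str = "continuous"
    ci_low: float = field(default=None)
    ci_high: float = field(default=None)
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci_low is None:
            self.ci_low = self.beta - Z95 * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _check_nonzero_bzx(bzx: np.ndarray, rsids: Sequence[str] | None) -> None:
    zero = np.flatnonzero(bzx == 0.0)
    if zero.size:
        name = rsids[zero[0]] if rsids is not None else f"index {zero[0]}"
        raise DivisionError(f"SNP-exposure effect is zero for {name}")


# ---------------------------------------------------------------------------
# array-level fits (fast paths shared by the public API and the simulation
# studies; the public functions below wrap them with bookkeeping)

def ivw_weights(bzx: np.ndarray, se_zy: np.ndarray) -> np.ndarray:
    """First-order weights beta_zx^2 / se_zy^2 (outcome-variance only)."""
    return bzx ** 2 / se_zy ** 2


def fit_ivw(bzx: np.ndarray, bzy: np.ndarray, se_zy: np.ndarray,
            model: str = "multiplicative_random") -> tuple[float, float, float]:
    """IVW estimate; returns (beta, se, cochran_q)."""
    w = ivw_weights(bzx, se_zy)
    ratios = bzy / bzx
    sw = w.sum()
    beta = float((w * ratios).sum() / sw)
    q = float((w * (ratios - beta) ** 2).sum())
    se = 1.0 / np.sqrt(sw)
    k = len(bzx)
    if model == "multiplicative_random" and k > 1:
        se *= np.sqrt(max(1.0, q / (k - 1)))
    elif model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown IVW model {model!r}")
    return beta, float(se), q


def fit_egger(bzx: np.ndarray, bzy: np.ndarray,
              se_zy: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted regression with intercept on orientation-flipped effects.

    Rows with beta_zx < 0 are flipped (both betas negated) so every
    SNP-exposure effect is non-negative.  Returns (coef, se, sigma2) with
    coef = [intercept, slope]; SEs carry multiplicative residual scaling
    floored at 1.
    """
    flip = bzx < 0
    bx = np.where(flip, -bzx, bzx)
    by = np.where(flip, -bzy, bzy)
    w = 1.0 / se_zy ** 2
    k = len(bx)
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    sigma2 = float((w * resid ** 2).sum() / (k - 2))
    cov = np.linalg.inv(A) * max(1.0, sigma2)
    return coef, np.sqrt(np.diag(cov)), sigma2


def fit_weighted_median(bzx: np.ndarray, bzy: np.ndarray,
                        se_zy: np.ndarray) -> float:
    """Weight-0.5 quantile of the ordered Wald ratios (linear interpolation)."""
    ratios = bzy / bzx
    w = ivw_weights(bzx, se_zy)
    order = np.argsort(ratios, kind="stable")
    r, wn = ratios[order], w[order] / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    k = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if k > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    return phi * 0.9 * min(sd, iqr / 1.349) * k ** (-0.2)


def fit_weighted_mode(bzx: np.ndarray, bzy: np.ndarray, se_zy: np.ndarray,
                      phi: float = 1.0, grid_size: int = 2048) -> float:
    """Argmax of a weighted normal-kernel density over the Wald ratios."""
    ratios = bzy / bzx
    w = ivw_weights(bzx, se_zy)
    h = _mode_bandwidth(ratios, phi)
    if h <= 0.0:  # all ratios identical (or k too small to spread)
        return float(ratios[0])
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = (np.exp(-0.5 * z ** 2) * (w / w.sum())[None, :]).sum(axis=1)
    return float(grid[np.argmax(dens)])


def fit_mv_ivw(BZX: np.ndarray, bzy: np.ndarray,
               se_zy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-intercept weighted multivariate regression; returns (coef, se)."""
    w = 1.0 / se_zy ** 2
    k, K = BZX.shape
    XtW = BZX.T * w
    A = XtW @ BZX
    if np.linalg.cond(A) > 1e10:
        corr = np.corrcoef(BZX, rowvar=False)
        pairs = [(i, j) for i in range(K) for j in range(i + 1, K)
                 if abs(corr[i, j]) > 0.999]
        raise CollinearityError(
            f"exposure effect matrix is rank deficient (near-duplicate "
            f"column pairs: {pairs or 'degenerate scaling'})")
    coef = np.linalg.solve(A, XtW @ bzy)
    resid = bzy - BZX @ coef
    sigma2 = float((w * resid ** 2).sum() / (k - K))
    cov = np.linalg.inv(A) * max(1.0, sigma2)
    return coef, np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------
# public API on harmonized sets

def wald_ratio(beta_zx: float, se_zx: float, beta_zy: float, se_zy: float,
               exposure_id: str = "", outcome_id: str = "",
               outcome_type: str = "continuous") -> MrEstimate:
    """Single-SNP causal estimate with first-order delta-method SE."""
    if beta_zx == 0:
        raise DivisionError("SNP-exposure effect is zero")
    beta = beta_zy / beta_zx
    se = se_zy / abs(beta_zx)
    return MrEstimate(method="wald_ratio", beta=float(beta), se=float(se),
                      pval=_norm_p(beta / se), n_snps=1,
                      exposure_id=exposure_id, outcome_id=outcome_id,
                      outcome_type=outcome_type)


def _ids(h: HarmonizedSet) -> dict:
    return dict(exposure_id=h.exposure_id, outcome_id=h.outcome_id,
                outcome_type=h.outcome_type)


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``multiplicative_random`` (default) scales the fixed-effects SE by
    sqrt(max(1, Q/(k-1))); a single SNP delegates to the Wald ratio.
    """
    _check_nonzero_bzx(h.beta_zx, h.rsids)
    if h.k == 1:
        est = wald_ratio(h.beta_zx[0], h.se_zx[0], h.beta_zy[0], h.se_zy[0],
                         **_ids(h))
        return est
    beta, se, q = fit_ivw(h.beta_zx, h.beta_zy, h.se_zy, model=model)
    return MrEstimate(method="ivw", beta=beta, se=se,
                      pval=_norm_p(beta / se), n_snps=h.k, **_ids(h),
                      info={"q": q, "model": model})


def _i2_gx(bzx: np.ndarray, se_zx: np.ndarray) -> float:
    """Regression-dilution statistic for the oriented SNP-exposure effects."""
    if np.any(se_zx <= 0) or len(bzx) < 2:
        return float("nan")
    bx = np.abs(bzx)
    w = 1.0 / se_zx ** 2
    mean = (w * bx).sum() / w.sum()
    q_gx = float((w * (bx - mean) ** 2).sum())
    k = len(bx)
    return max(0.0, (q_gx - (k - 1)) / q_gx) if q_gx > 0 else 0.0


def egger(h: HarmonizedSet) -> MrEstimate:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy; inference on t with k-2 df."""
    if h.k < 3:
        raise InsufficientSnpsError(f"MR-Egger needs >= 3 SNPs, have {h.k}")
    coef, se, _ = fit_egger(h.beta_zx, h.beta_zy, h.se_zy)
    df = h.k - 2
    t_p = lambda est, s: float(2.0 * stats.t.sf(abs(est / s), df))
    return MrEstimate(
        method="egger", beta=float(coef[1]), se=float(se[1]),
        pval=t_p(coef[1], se[1]), n_snps=h.k, **_ids(h),
        intercept=float(coef[0]), intercept_se=float(se[0]),
        intercept_pval=t_p(coef[0], se[0]),
        info={"i2_gx": _i2_gx(h.beta_zx, h.se_zx)})


DEFAULT_LAMBDA_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)


def simex_egger(h: HarmonizedSet, lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                b_reps: int = 1000, seed: int = 0,
                extrapolation: str = "quadratic") -> MrEstimate:
    """Simulation-extrapolation correction of the MR-Egger fit.

    For each lambda > 0 the SNP-exposure effects are perturbed with noise of
    variance lambda * se_zx^2 over ``b_reps`` replicates; the mean fit as a
    function of total error variance (1 + lambda) is extrapolated
    quadratically back to the error-free state lambda = -1.  Variances use
    the Stefanski-Cook difference method (model variance minus simulation
    variance, extrapolated on the same grid, falling back to the plain Egger
    variance if the extrapolation turns non-positive).
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if len(np.unique(lam)) < 3 or lam[0] != 0.0 or np.any(np.diff(lam) <= 0):
        raise ConfigurationError(
            "lambda grid must start at 0, ascend, and hold >= 3 distinct values")
    if extrapolation != "quadratic":
        raise ConfigurationError(f"unsupported extrapolation {extrapolation!r}")
    if h.k < 3:
        raise InsufficientSnpsError(f"SIMEX-Egger needs >= 3 SNPs, have {h.k}")
    base = egger(h)
    if np.all(h.se_zx == 0.0):
        # no measurement error: nothing to simulate, extrapolation is exact
        return MrEstimate(method="egger_simex", beta=base.beta, se=base.se,
                          pval=base.pval, n_snps=h.k, **_ids(h),
                          intercept=base.intercept,
                          intercept_se=base.intercept_se,
                          intercept_pval=base.intercept_pval,
                          info={"lambda_grid": tuple(lam), "b_reps": 0})
    rng = np.random.default_rng(seed)
    bzx, bzy, se_zx, se_zy = h.beta_zx, h.beta_zy, h.se_zx, h.se_zy
    coef0, se0, _ = fit_egger(bzx, bzy, se_zy)
    means = [coef0]                    # lambda = 0: unperturbed fit
    tau2 = [se0 ** 2]
    for lmb in lam[1:]:
        ests = np.empty((b_reps, 2))
        mvar = np.empty((b_reps, 2))
        scale = np.sqrt(lmb) * se_zx
        for b in range(b_reps):
            bx = bzx + rng.normal(0.0, 1.0, bzx.shape) * scale
            c, s, _ = fit_egger(bx, bzy, se_zy)
            ests[b] = c
            mvar[b] = s ** 2
        means.append(ests.mean(axis=0))
        tau2.append(mvar.mean(axis=0) - ests.var(axis=0, ddof=1))
    means = np.asarray(means)
    tau2 = np.asarray(tau2)
    out = {}
    for j, name in enumerate(("intercept", "slope")):
        pf = np.polyfit(lam, means[:, j], 2)
        est = float(np.polyval(pf, -1.0))
        pv = np.polyfit(lam, tau2[:, j], 2)
        var = float(np.polyval(pv, -1.0))
        if var <= 0.0:
            var = float(se0[j] ** 2)
        out[name] = (est, np.sqrt(var))
    df = h.k - 2
    t_p = lambda est, s: float(2.0 * stats.t.sf(abs(est / s), df))
    b, bs = out["slope"]
    a, as_ = out["intercept"]
    return MrEstimate(method="egger_simex", beta=b, se=bs, pval=t_p(b, bs),
                      n_snps=h.k, **_ids(h), intercept=a, intercept_se=as_,
                      intercept_pval=t_p(a, as_),
                      info={"lambda_grid": tuple(lam), "b_reps": b_reps,
                            "lambda_means": means[:, 1].tolist()})


def _parametric_boot(h: HarmonizedSet, stat, n_boot: int, seed: int) -> float:
    """SD of ``stat`` over parametric resamples of the summary estimates."""
    rng = np.random.default_rng(seed)
    bzx, bzy = h.beta_zx, h.beta_zy
    se_zx, se_zy = h.se_zx, h.se_zy
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(bzx, se_zx)
        by = rng.normal(bzy, se_zy)
        reps[b] = stat(bx, by, se_zy)
    return float(np.std(reps, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted median of the Wald ratios; SE by parametric bootstrap."""
    if h.k < 3:
        raise InsufficientSnpsError(f"weighted median needs >= 3 SNPs, have {h.k}")
    _check_nonzero_bzx(h.beta_zx, h.rsids)
    beta = fit_weighted_median(h.beta_zx, h.beta_zy, h.se_zy)
    se = _parametric_boot(h, fit_weighted_median, n_boot, seed)
    return MrEstimate(method="weighted_median", beta=beta, se=se,
                      pval=_norm_p(beta / se), n_snps=h.k, **_ids(h))


def weighted_mode(h: HarmonizedSet, bandwidth_phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Mode of the weighted kernel density of ratios; bootstrap SE."""
    if h.k < 3:
        raise InsufficientSnpsError(f"weighted mode needs >= 3 SNPs, have {h.k}")
    if bandwidth_phi <= 0:
        raise ConfigurationError("bandwidth multiplier must be positive")
    _check_nonzero_bzx(h.beta_zx, h.rsids)
    beta = fit_weighted_mode(h.beta_zx, h.beta_zy, h.se_zy, phi=bandwidth_phi)
    se = _parametric_boot(
        h, lambda bx, by, sy: fit_weighted_mode(bx, by, sy, phi=bandwidth_phi),
        n_boot, seed)
    return MrEstimate(method="weighted_mode", beta=beta, se=se,
                      pval=_norm_p(beta / se), n_snps=h.k, **_ids(h))


def mv_ivw(m: MvHarmonizedSet) -> list[MrEstimate]:
    """Multivariable IVW: each exposure's direct effect on the outcome."""
    K = m.n_exposures
    if m.k < K + 2:
        raise InsufficientSnpsError(
            f"multivariable IVW needs >= {K + 2} SNPs for {K} exposures, "
            f"have {m.k}")
    coef, se = fit_mv_ivw(m.beta_zx, m.beta_zy, m.se_zy)
    return [MrEstimate(method="mv_ivw", beta=float(coef[i]), se=float(se[i]),
                       pval=_norm_p(coef[i] / se[i]), n_snps=m.k,
                       exposure_id=m.exposure_ids[i], outcome_id=m.outcome_id,
                       outcome_type=m.outcome_type,
                       info={"adjusted_for": [e for j, e in
                                              enumerate(m.exposure_ids) if j != i]})
            for i in range(K)]
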