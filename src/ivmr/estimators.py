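"""Causal-effect estimators for two-sample summary-data Mendelian randomization.

Given L harmonized instruments with exposure effects ``beta_x_j`` (SE
``se_x_j``) and outcome effects ``beta_y_j`` (SE ``se_y_j``), the estimators
implemented here are:

* the per-SNP Wald ratio ``beta_y_j / beta_x_j``,
* the inverse-variance weighted (IVW) pooled estimate — equivalently a
  weighted regression of outcome on exposure effects through the origin with
  weights ``se_y_j**-2`` — with fixed-effect or multiplicative random-effects
  standard errors,
* MR-Egger regression (the same weighted regression with an unconstrained
  intercept; the intercept estimates average directional pleiotropy and the
  slope a pleiotropy-adjusted causal effect under the InSIDE assumption), and
* the weighted median of the ratio estimates, consistent when valid
  instruments carry more than half the total weight, with a parametric
  bootstrap standard error.

All causal estimates are returned per standard deviation of the exposure
(the per-log-unit estimate multiplied by the set's ``sd_scale``); the Egger
intercept, an average per-instrument direct effect on the outcome, is not
rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

from .summary_data import HarmonizedInstrument, InstrumentSet, rescale_per_sd

__all__ = [
    "CausalEstimate",
    "UndefinedRatioError",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "to_odds_ratio",
]

Z_95 = float(stats.norm.ppf(0.975))


class UndefinedRatioError(ValueError):
    """A Wald ratio is undefined because the exposure effect is zero."""


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclass(frozen=True)
class CausalEstimate:
    """A causal-effect estimate with its uncertainty and method metadata.

    ``beta`` is on the log-odds-per-SD-of-exposure scale unless ``scale`` says
    ``odds-ratio`` (after :func:`to_odds_ratio`).  Egger fits additionally
    carry the intercept triple; the weighted median carries its bootstrap
    settings.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    scale: str = "log-odds"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        """JSON-ready representation, including OR-scale point and CI."""
        d = {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "scale": self.scale,
        }
        if self.scale == "log-odds":
            d.update(
                {
                    "or": float(np.exp(self.beta)),
                    "ci_low_or": float(np.exp(self.ci_low)),
                    "ci_high_or": float(np.exp(self.ci_high)),
                }
            )
        if self.intercept is not None:
            d.update(
                {
                    "intercept": self.intercept,
                    "intercept_se": self.intercept_se,
                    "intercept_p": self.intercept_p,
                }
            )
        if self.n_boot is not None:
            d.update({"n_boot": self.n_boot, "seed": self.seed})
        return d


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratio(inst: HarmonizedInstrument, sd_scale: float = 1.0) -> CausalEstimate:
    """Per-SNP causal estimate: outcome effect divided by exposure effect.

    The SE is the first-order (leading-term) approximation
    ``se_y / |beta_x|``, which ignores the sampling error in ``beta_x``.
    """
    if inst.beta_x == 0:
        raise UndefinedRatioError(f"{inst.rsid}: exposure effect is zero, Wald ratio undefined")
    theta = inst.beta_y / inst.beta_x
    se = inst.se_y / abs(inst.beta_x)
    est = CausalEstimate(
        method="wald",
        beta=theta,
        se=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        p=_two_sided_normal_p(theta / se),
        n_snps=1,
    )
    return rescale_per_sd(est, sd_scale) if sd_scale != 1.0 else est


def _check_nonzero_bx(instruments: InstrumentSet) -> None:
    for inst in instruments:
        if inst.beta_x == 0:
            raise UndefinedRatioError(f"{inst.rsid}: exposure effect is zero, Wald ratio undefined")


def ivw(instruments: InstrumentSet, model: Literal["fixed", "random"] = "random") -> CausalEstimate:
    """Inverse-variance weighted pooled causal estimate.

    Point estimate ``sum(bx*by/sy^2) / sum(bx^2/sy^2)``: the weighted mean of
    the Wald ratios with weights ``(bx/sy)^2``, or equivalently the weighted
    regression of ``by`` on ``bx`` through the origin.  Under ``model
    ="random"`` (multiplicative random effects) the fixed-effect SE is
    inflated by ``max(1, sqrt(Q/(L-1)))`` with Q the Cochran heterogeneity
    statistic of the ratio estimates, so the CI never narrows versus the
    fixed-effect fit.
    """
    from .diagnostics import cochran_q  # deferred: diagnostics imports this module

    _check_nonzero_bx(instruments)
    L = instruments.L
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if model == "random" and L < 2:
        raise InsufficientInstrumentsError("random-effects IVW requires at least 2 instruments")

    bx, by, sy = instruments.beta_x, instruments.beta_y, instruments.se_y
    w = sy**-2.0
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    if model == "random":
        q, _ = cochran_q(instruments, theta)
        se *= max(1.0, np.sqrt(q / (L - 1)))

    est = CausalEstimate(
        method=f"ivw-{model}",
        beta=theta,
        se=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        p=_two_sided_normal_p(theta / se),
        n_snps=L,
    )
    return rescale_per_sd(est, instruments.sd_scale)


def _oriented(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exposure/outcome effects with each instrument oriented so beta_x > 0."""
    bx, by, sy = instruments.beta_x, instruments.beta_y, instruments.se_y
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign, sy


def egger(instruments: InstrumentSet) -> CausalEstimate:
    """MR-Egger weighted regression with an unconstrained intercept.

    Instruments are first oriented so every exposure effect is positive (a
    joint sign flip of ``(beta_x, beta_y)``, to which the slope is invariant
    but the intercept is not).  The fit is weighted least squares of outcome
    on exposure effects with weights ``se_y**-2``; the slope is the causal
    estimate (per SD after rescaling) and the intercept the average direct
    (pleiotropic) effect per instrument, left unrescaled.  SEs carry a
    multiplicative random-effects factor ``max(1, sqrt(RSS_w/(L-2)))`` and
    inference uses the t distribution with L-2 degrees of freedom.
    """
    _check_nonzero_bx(instruments)
    L = instruments.L
    if L < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires at least 3 instruments, got {L}")

    bx, by, sy = _oriented(instruments)
    if np.ptp(bx) == 0:
        raise ValueError("all exposure effects identical after orientation; Egger fit is collinear")

    w = sy**-2.0
    s_w = np.sum(w)
    s_x = np.sum(w * bx)
    s_xx = np.sum(w * bx**2)
    s_y = np.sum(w * by)
    s_xy = np.sum(w * bx * by)
    det = s_w * s_xx - s_x**2
    slope = float((s_w * s_xy - s_x * s_y) / det)
    intercept = float((s_xx * s_y - s_x * s_xy) / det)

    resid = by - intercept - slope * bx
    overdispersion = max(1.0, float(np.sum(w * resid**2)) / (L - 2))
    se_slope = float(np.sqrt(overdispersion * s_w / det))
    se_intercept = float(np.sqrt(overdispersion * s_xx / det))

    tdist = stats.t(df=L - 2)
    tcrit = float(tdist.ppf(0.975))
    p_slope = float(min(1.0, 2.0 * tdist.sf(abs(slope / se_slope))))
    p_intercept = float(min(1.0, 2.0 * tdist.sf(abs(intercept / se_intercept))))

    est = CausalEstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tcrit * se_slope,
        ci_high=slope + tcrit * se_slope,
        p=p_slope,
        n_snps=L,
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_p=p_intercept,
    )
    return rescale_per_sd(est, instruments.sd_scale)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` with normalized ``weights``."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> CausalEstimate:
    """Weighted median of the per-SNP ratio estimates.

    Ratio estimates are weighted by their approximate inverse variances
    ``(beta_x/se_y)^2`` (normalized), sorted, and the estimate is the linear
    interpolation of the ratio against the cumulative weight midpoint at 50%.
    The SE is a parametric bootstrap: exposure and outcome effects are
    resampled from normal distributions centred at the observed values with
    SDs ``(se_x, se_y)``, the weighted median recomputed, and the SE taken as
    the standard deviation across replicates.  A seed is required so the
    report is reproducible.
    """
    _check_nonzero_bx(instruments)
    L = instruments.L
    if L < 3:
        raise InsufficientInstrumentsError(f"weighted median requires at least 3 instruments, got {L}")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for the bootstrap")

    bx, by = instruments.beta_x, instruments.beta_y
    sx, sy = instruments.se_x, instruments.se_y
    theta = _weighted_median(by / bx, (bx / sy) ** 2)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, L))
    by_b = rng.normal(by, sy, size=(n_boot, L))
    ratios_b = by_b / bx_b
    weights_b = (bx_b / sy) ** 2
    order = np.argsort(ratios_b, axis=1)
    r_sorted = np.take_along_axis(ratios_b, order, axis=1)
    w_sorted = np.take_along_axis(weights_b, order, axis=1)
    w_sorted /= w_sorted.sum(axis=1, keepdims=True)
    s = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    boots = np.array([np.interp(0.5, s[b], r_sorted[b]) for b in range(n_boot)])
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")

    est = CausalEstimate(
        method="weighted-median",
        beta=theta,
        se=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        p=_two_sided_normal_p(theta / se) if np.isfinite(se) and se > 0 else 1.0,
        n_snps=L,
        n_boot=n_boot,
        seed=seed,
    )
    return rescale_per_sd(est, instruments.sd_scale)


def to_odds_ratio(est: CausalEstimate) -> CausalEstimate:
    """Exponentiate a log-odds estimate and its CI bounds onto the OR scale.

    The SE is retained on the log scale (the conventional reporting form).
    """
    if est.scale != "log-odds":
        raise ValueError(f"estimate is on scale {est.scale!r}, expected log-odds")
    return replace(
        est,
        beta=float(np.exp(est.beta)),
        ci_low=float(np.exp(est.ci_low)),
        ci_high=float(np.exp(est.ci_high)),
        scale="odds-ratio",
    )
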