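"""Instrument-strength and pleiotropy diagnostics.

Covers the standard checks run alongside a two-sample MR analysis: per-SNP
F-statistics and variance explained (instrument strength), Cochran's Q over
the ratio estimates (heterogeneity, also feeding the random-effects IVW SE),
the I2_GX statistic assessing the NO-Measurement-Error (NOME) assumption
behind MR-Egger, a Bonferroni screen of the per-SNP outcome associations, and
funnel/forest plot data exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import CausalEstimate, ivw, to_odds_ratio, wald_ratio
from .summary_data import HarmonizedInstrument, InstrumentSet

__all__ = [
    "InstrumentDiagnostics",
    "f_statistic",
    "variance_explained",
    "cochran_q",
    "i2_gx",
    "funnel_data",
    "forest_data",
    "outcome_screen",
    "compute_diagnostics",
]

logger = logging.getLogger(__name__)


def f_statistic(inst: HarmonizedInstrument) -> float:
    """Instrument-strength F-statistic: the squared exposure z-statistic ``(beta_x/se_x)^2``."""
    return (inst.beta_x / inst.se_x) ** 2


def variance_explained(
    inst: HarmonizedInstrument,
    n: float | None = None,
    var_exposure: float = 1.0,
) -> float | None:
    """Exposure variance explained by one instrument.

    Uses the allele-frequency formula ``2*eaf*(1-eaf)*beta_x^2 / var_exposure``
    when the effect-allele frequency is available (``var_exposure`` is the
    exposure variance in the units of ``beta_x``; for an exposure whose SD is
    ``sd_scale`` log-units this is ``sd_scale**2``).  Falls back to
    ``F / (n - 2 + F)`` when only the exposure sample size is known, and
    returns None (with a warning) when neither route is possible.
    """
    if inst.eaf is not None:
        return 2.0 * inst.eaf * (1.0 - inst.eaf) * inst.beta_x**2 / var_exposure
    if n is not None and n > 2:
        f = f_statistic(inst)
        return f / (n - 2 + f)
    logger.warning("%s: no eaf and no usable sample size; variance explained skipped", inst.rsid)
    return None


def cochran_q(instruments: InstrumentSet, theta: float) -> tuple[float, float]:
    """Cochran's Q for heterogeneity of the ratio estimates about ``theta``.

    ``Q = sum_j w_j (theta_j - theta)^2`` with ratio estimates
    ``theta_j = beta_y/beta_x`` and weights ``w_j = (beta_x/se_y)^2``; the
    p-value is from chi-squared with L-1 degrees of freedom.  ``theta`` should
    be the pooled (fixed-effect IVW) estimate on the same, pre-rescaling scale.
    """
    L = instruments.L
    if L < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    bx, by, sy = instruments.beta_x, instruments.beta_y, instruments.se_y
    ratios = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (ratios - theta) ** 2))
    p = float(stats.chi2.sf(q, df=L - 1))
    return q, p


def i2_gx(instruments: InstrumentSet) -> float:
    """I2_GX: relative measurement error in the instrument-exposure effects.

    Computed as an I-squared over the (positively oriented) exposure effects
    with precision weights ``se_x**-2``: values near 1 mean the spread of the
    effects dwarfs their sampling error, so MR-Egger suffers little
    regression-dilution (NOME) bias; values near 0 mean the Egger slope is
    badly attenuated.  Floored at 0.
    """
    L = instruments.L
    if L < 2:
        raise ValueError("I2_GX requires at least 2 instruments")
    bx = np.abs(instruments.beta_x)  # orientation: beta_x > 0, as in the Egger fit
    w = instruments.se_x**-2.0
    m = float(np.sum(w * bx) / np.sum(w))
    q_gx = float(np.sum(w * (bx - m) ** 2))
    if q_gx == 0.0:
        logger.warning("I2_GX: zero dispersion in exposure effects; returning 0")
        return 0.0
    return max(0.0, (q_gx - (L - 1)) / q_gx)


def funnel_data(instruments: InstrumentSet, y_axis: str = "precision") -> pd.DataFrame:
    """Per-instrument funnel-plot coordinates.

    x is the per-SNP causal estimate (per SD of exposure).  With ``y_axis
    ="precision"`` (default) y is the reciprocal SE of that estimate; with
    ``y_axis="instrument-strength"`` y is the absolute exposure effect — both
    conventions appear in published funnel plots.
    """
    if y_axis not in ("precision", "instrument-strength"):
        raise ValueError(f"unknown funnel y_axis {y_axis!r}")
    rows = []
    for inst in instruments:
        w = wald_ratio(inst, sd_scale=instruments.sd_scale)
        y = 1.0 / w.se if y_axis == "precision" else abs(inst.beta_x)
        rows.append({"rsid": inst.rsid, "estimate": w.beta, y_axis.replace("-", "_"): y})
    return pd.DataFrame(rows)


def forest_data(instruments: InstrumentSet, pooled: CausalEstimate) -> pd.DataFrame:
    """Forest-plot rows: per-SNP OR (per SD) with 95% CI, then the pooled row."""
    rows = []
    for inst in instruments:
        w = to_odds_ratio(wald_ratio(inst, sd_scale=instruments.sd_scale))
        rows.append({"rsid": inst.rsid, "or": w.beta, "ci_low": w.ci_low, "ci_high": w.ci_high})
    pooled_or = to_odds_ratio(pooled) if pooled.scale == "log-odds" else pooled
    rows.append(
        {
            "rsid": f"pooled ({pooled.method})",
            "or": pooled_or.beta,
            "ci_low": pooled_or.ci_low,
            "ci_high": pooled_or.ci_high,
        }
    )
    return pd.DataFrame(rows)


def outcome_screen(instruments: InstrumentSet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP outcome-association screen with a Bonferroni adjustment.

    Reports each instrument's outcome z-test p-value, raw significance at
    ``alpha``, and significance at the Bonferroni level ``alpha / L``.
    """
    L = instruments.L
    z = instruments.beta_y / instruments.se_y
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "rsid": instruments.rsids,
            "p": p,
            "significant_raw": p < alpha,
            "significant_bonferroni": p < alpha / L,
        }
    )


@dataclass
class InstrumentDiagnostics:
    """Bundle of instrument diagnostics for one harmonized set."""

    per_snp_f: np.ndarray
    mean_f: float
    min_f: float
    max_f: float
    per_snp_r2: np.ndarray | None
    total_r2: float | None
    q: float
    q_p: float
    i2_gx: float
    funnel: pd.DataFrame
    forest: pd.DataFrame
    outcome_screen: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "per_snp_f": [float(f) for f in self.per_snp_f],
            "mean_f": self.mean_f,
            "min_f": self.min_f,
            "max_f": self.max_f,
            "per_snp_r2": None if self.per_snp_r2 is None else [float(r) for r in self.per_snp_r2],
            "total_r2": self.total_r2,
            "cochran_q": self.q,
            "cochran_q_p": self.q_p,
            "i2_gx": self.i2_gx,
            "n_outcome_significant_raw": int(self.outcome_screen["significant_raw"].sum()),
            "n_outcome_significant_bonferroni": int(self.outcome_screen["significant_bonferroni"].sum()),
        }


def compute_diagnostics(
    instruments: InstrumentSet,
    pooled: CausalEstimate | None = None,
    n_exposure: float | None = None,
    funnel_y: str = "precision",
) -> InstrumentDiagnostics:
    """Assemble the full diagnostic bundle for an instrument set.

    ``pooled`` is the estimate shown on the forest plot's bottom row (defaults
    to the random-effects IVW fit of the same set).  ``n_exposure`` enables
    the F-based fallback for variance explained when allele frequencies are
    missing.
    """
    per_f = np.array([f_statistic(i) for i in instruments])

    var_exposure = instruments.sd_scale**2
    r2_list = [variance_explained(i, n=n_exposure, var_exposure=var_exposure) for i in instruments]
    if any(r is None for r in r2_list):
        per_r2, total_r2 = None, None
    else:
        per_r2 = np.array(r2_list, dtype=float)
        total_r2 = float(per_r2.sum())

    theta_fixed = ivw(instruments, model="fixed").beta / instruments.sd_scale
    q, q_p = cochran_q(instruments, theta_fixed)

    if pooled is None:
        pooled = ivw(instruments, model="random")

    return InstrumentDiagnostics(
        per_snp_f=per_f,
        mean_f=float(per_f.mean()),
        min_f=float(per_f.min()),
        max_f=float(per_f.max()),
        per_snp_r2=per_r2,
        total_r2=total_r2,
        q=q,
        q_p=q_p,
        i2_gx=i2_gx(instruments) if instruments.L >= 2 else 0.0,
        funnel=funnel_data(instruments, y_axis=funnel_y),
        forest=forest_data(instruments, pooled),
        outcome_screen=outcome_screen(instruments),
    )
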