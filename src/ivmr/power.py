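"""Analytic power for two-sample Mendelian randomization with a binary outcome.

Uses the non-centrality approximation for an instrumental-variable test of a
causal odds ratio in a case-control outcome study: the log-linear causal
effect is attenuated onto the risk-difference scale, converted into a
non-centrality parameter proportional to the outcome sample size and the
exposure variance explained by the instruments, and compared against the
two-sided normal critical value.

With case fraction K and true odds ratio OR per SD of exposure:

    b   = K * (OR / (1 + K*(OR - 1)) - 1)
    v   = K*(1 - K) - b^2
    NCP = N * R2 * b^2 / v
    power = Phi(sqrt(NCP) - z_{1-alpha/2})

where R2 is the proportion of exposure variance explained by the instruments.
An optional ``adjust_r2`` flag divides the NCP by (1 - R2), a refinement some
calculators apply; it is off by default and immaterial at the small R2
typical of MR.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerInputs", "PowerResult", "binary_power", "minimum_detectable_or"]


@dataclass(frozen=True)
class PowerInputs:
    """Inputs for the binary-outcome MR power calculation.

    n_total: outcome-study sample size (cases + controls).
    case_fraction: proportion of cases K, in (0, 1).
    r2: exposure variance explained by the instruments, in (0, 1).
    or_alt: true odds ratio per SD of exposure under the alternative.
    alpha: two-sided significance level.
    """

    n_total: float
    case_fraction: float
    r2: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.n_total > 0:
            raise ValueError("n_total must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must lie in (0, 1)")
        if not self.or_alt > 0:
            raise ValueError("or_alt must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Power plus the intermediate quantities, retained for audit."""

    power: float
    b: float
    v: float
    ncp: float
    inputs: PowerInputs

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "b": self.b,
            "v": self.v,
            "ncp": self.ncp,
            "n_total": self.inputs.n_total,
            "case_fraction": self.inputs.case_fraction,
            "r2": self.inputs.r2,
            "or_alt": self.inputs.or_alt,
            "alpha": self.inputs.alpha,
        }


def binary_power(inp: PowerInputs, adjust_r2: bool = False) -> PowerResult:
    """Power to detect ``inp.or_alt`` at two-sided level ``inp.alpha``."""
    k, orr = inp.case_fraction, inp.or_alt
    b = k * (orr / (1.0 + k * (orr - 1.0)) - 1.0)
    v = k * (1.0 - k) - b * b
    if v <= 0:
        raise ValueError(f"variance term non-positive (v={v:.4g}); OR/case-fraction combination too extreme")
    ncp = inp.n_total * inp.r2 * b * b / v
    if adjust_r2:
        ncp /= 1.0 - inp.r2
    z_crit = stats.norm.ppf(1.0 - inp.alpha / 2.0)
    power = float(stats.norm.cdf(ncp**0.5 - z_crit))
    return PowerResult(power=power, b=b, v=v, ncp=ncp, inputs=inp)


def minimum_detectable_or(
    n_total: float,
    case_fraction: float,
    r2: float,
    target_power: float,
    alpha: float = 0.05,
    adjust_r2: bool = False,
    or_max: float = 10.0,
    tol: float = 1e-6,
) -> float:
    """Smallest odds ratio above 1 detectable with ``target_power``.

    Bisects on OR over (1, ``or_max``], exploiting that power is strictly
    increasing in OR on that range, to a tolerance of ``tol`` in power.

    Raises
    ------
    ValueError
        If ``target_power`` is not attainable even at ``or_max``.
    """
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie strictly between alpha and 1")

    def power_at(orr: float) -> float:
        return binary_power(
            PowerInputs(n_total=n_total, case_fraction=case_fraction, r2=r2, or_alt=orr, alpha=alpha),
            adjust_r2=adjust_r2,
        ).power

    # For case fractions below 1/2 the attenuation formula leaves its validity
    # region (v <= 0) at large OR; shrink the upper bracket back inside it.
    hi = or_max
    while hi > 1.0 + 1e-9:
        try:
            p_hi = power_at(hi)
            break
        except ValueError:
            hi = 1.0 + 0.9 * (hi - 1.0)
    else:
        raise ValueError("no valid OR bracket for the power formula")
    if p_hi < target_power:
        raise ValueError(f"target power {target_power} unattainable at OR <= {or_max}")

    lo = 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = power_at(mid)
        if abs(p - target_power) <= tol:
            return mid
        if p < target_power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
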