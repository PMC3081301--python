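"""Exact power, PFP and expected-false-positive arithmetic for the study design.

Power of the two-sided pooled-variance two-sample t-test comes from the
noncentral t distribution; the proportion of false positives (PFP, equal to
the marginal FDR) follows from the mixture identity

    PFP = pi0 * alpha / (pi0 * alpha + (1 - pi0) * power)

for a homogeneous effect d, and the expected number of false positives among
M tests is pi0 * alpha * M regardless of the correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerResult",
    "compute_power",
    "compute_pfp",
    "expected_false_positives",
    "power_table",
]


@dataclass(frozen=True)
class PowerResult:
    n1: int
    n2: int
    alpha: float
    d: float
    sigma: float
    power: float
    pi0: float
    pfp: float


def compute_power(n1: int, n2: int, alpha: float, d: float,
                  sigma: float = 1.0) -> float:
    """Power of the two-sided equal-variance two-sample t-test.

    With df = n1 + n2 - 2, critical value t* the upper alpha/2 quantile of
    the central t, and noncentrality delta = d / (sigma * sqrt(1/n1 + 1/n2)),
    power = P(T' > t*) + P(T' < -t*) for T' ~ noncentral t(df, delta).
    At d = 0 this reduces to the test size alpha.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must be >= 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not (sigma > 0):
        raise ValueError("sigma must be > 0")
    df = n1 + n2 - 2
    delta = d / (sigma * np.sqrt(1.0 / n1 + 1.0 / n2))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta))


def compute_pfp(pi0: float, alpha: float, power: float) -> float:
    """Proportion of false positives (marginal FDR) at threshold alpha.

    pi0*alpha of the tests are false positives in expectation and
    (1-pi0)*power are true positives; PFP is the false share of all
    positives.
    """
    for name, v in (("pi0", pi0), ("alpha", alpha), ("power", power)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    denom = pi0 * alpha + (1.0 - pi0) * power
    if denom == 0.0:
        raise ZeroDivisionError("no expected positives: pi0*alpha + (1-pi0)*power = 0")
    return float(pi0 * alpha / denom)


def expected_false_positives(M: int, pi0: float, alpha: float) -> float:
    """Expected count of false positives, pi0 * alpha * M.

    Holds for any correlation structure among the M test statistics, since
    each null p-value is marginally uniform.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not (0.0 <= pi0 <= 1.0 and 0.0 <= alpha <= 1.0):
        raise ValueError("pi0 and alpha must be in [0, 1]")
    return float(pi0 * alpha * M)


def power_table(n_values=range(3, 16), alpha: float = 0.01, d: float = 2.0,
                sigma: float = 1.0, pi0: float = 0.8) -> pd.DataFrame:
    """Power and PFP for balanced designs n1 = n2 = n (the design-choice table)."""
    rows = []
    for n in n_values:
        pw = compute_power(n, n, alpha, d, sigma)
        rows.append({
            "n1": n, "n2": n, "alpha": alpha, "d": d,
            "power": pw, "pi0": pi0, "pfp": compute_pfp(pi0, alpha, pw),
        })
    return pd.DataFrame(rows)
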