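"""Approximate power for two-sample MR with a binary outcome.

Under the standard noncentrality approximation, the IVW z statistic for a
true log odds ratio theta per SD of exposure has noncentrality

    ncp = |theta| * sqrt(n * r2 * K * (1 - K))

where n is the total outcome sample size, K the case fraction and r2 the
share of exposure variance explained by the instrument.  Two-sided power at
level alpha is approximately Phi(ncp - z_{1-alpha/2}) (the far-tail rejection
mass is negligible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = ["PowerSpec", "mr_power_binary", "power_table"]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a binary-outcome two-sample MR power estimate."""

    n_outcome: float  # total outcome sample size (cases + controls)
    case_fraction: float  # K, in (0, 1)
    r2: float  # instrument variance explained, in [0, 1)
    theta: float  # true log OR per SD of exposure
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.n_outcome > 0:
            raise ValueError("n_outcome must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0.0 <= self.r2 < 1.0:
            raise ValueError("r2 must lie in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def mr_power_binary(spec: PowerSpec) -> float:
    """Power of the two-sided IVW test under ``spec``; in [0, 1]."""
    if spec.r2 == 0.0 and spec.theta != 0.0:
        warnings.warn(
            "instrument explains no variance; power equals the alpha level",
            stacklevel=2,
        )
    z = _stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(spec.theta) * np.sqrt(
        spec.n_outcome * spec.r2 * spec.case_fraction * (1.0 - spec.case_fraction)
    )
    return float(_stats.norm.cdf(ncp - z))


def power_table(
    n_outcome: float,
    case_fraction: float,
    r2: float,
    odds_ratios,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power over a grid of odds ratios (per SD), as a tidy DataFrame."""
    rows = []
    for odds in np.atleast_1d(np.asarray(odds_ratios, dtype=float)):
        spec = PowerSpec(n_outcome, case_fraction, r2, float(np.log(odds)), alpha)
        rows.append(
            {
                "OR_per_SD": float(odds),
                "theta": spec.theta,
                "power": mr_power_binary(spec),
            }
        )
    return pd.DataFrame(rows)
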