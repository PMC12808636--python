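"""Analytic power of a two-sample MR test with a continuous outcome.

Normal-approximation formulation with standardized variables: the MR Wald
z-statistic is approximately Normal(sqrt(NCP), 1) with non-centrality
NCP = n_outcome * R^2_exposure * beta^2, where R^2 is the variance in the
exposure explained by the instrument and beta the causal effect in
SD-outcome per SD-exposure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerInput:
    n_outcome: int
    r2_exposure: float  # variance in exposure explained by the instrument
    beta: float  # hypothesized causal effect (SD/SD)
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_outcome <= 0:
            raise ValueError("n_outcome must be positive")
        if not (0 < self.r2_exposure < 1):
            raise ValueError("r2_exposure must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def mr_power(inp: PowerInput) -> float:
    """Two-sided power: 1 - Phi(z_{1-a/2} - sqrt(NCP)) + Phi(-z_{1-a/2} - sqrt(NCP))."""
    ncp = inp.n_outcome * inp.r2_exposure * inp.beta**2
    z_crit = stats.norm.isf(inp.alpha / 2)
    s = np.sqrt(ncp)
    return float(stats.norm.sf(z_crit - s) + stats.norm.cdf(-z_crit - s))
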