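"""Two-step network MR mediation: exposure -> mediator -> outcome.

The indirect effect is the product of the step-1 (exposure on mediator,
``a``) and step-2 (mediator on outcome, ``b``) MR estimates; its standard
error comes from the Sobel formula and the test is two-sided normal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .estimators import MREstimate


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    a: float
    se_a: float
    b: float
    se_b: float
    indirect: float  # a * b
    se_indirect: float  # Sobel SE
    z: float
    pval: float
    proportion_mediated: float | None = None


def sobel_se(a: float, se_a: float, b: float, se_b: float,
             exact: bool = False) -> float:
    """Sobel standard error of the product a*b.

    First-order: sqrt(a^2 se_b^2 + b^2 se_a^2); ``exact=True`` adds the
    second-order se_a^2 se_b^2 term.
    """
    var = a**2 * se_b**2 + b**2 * se_a**2
    if exact:
        var += se_a**2 * se_b**2
    return float(np.sqrt(var))


def two_step_mediation(step1: MREstimate, step2: MREstimate,
                       exact_se: bool = False,
                       total: MREstimate | None = None) -> MediationResult:
    """Combine the two MR steps into an indirect-effect estimate.

    ``step1`` estimates exposure -> mediator, ``step2`` mediator -> outcome;
    their mediator ids must agree.  The proportion mediated (indirect/total)
    is reported only when a total-effect estimate is supplied and |total|
    exceeds its SE.
    """
    if step1.outcome_id != step2.exposure_id:
        raise ConfigurationError(
            f"mediator mismatch: step1 outcome {step1.outcome_id!r} != "
            f"step2 exposure {step2.exposure_id!r}")
    a, se_a = step1.beta, step1.se
    b, se_b = step2.beta, step2.se
    indirect = a * b
    se_ind = sobel_se(a, se_a, b, se_b, exact=exact_se)
    z = indirect / se_ind if se_ind > 0 else 0.0
    pval = float(2 * stats.norm.sf(abs(z)))
    prop = None
    if total is not None and abs(total.beta) > total.se:
        prop = indirect / total.beta
    return MediationResult(
        exposure_id=step1.exposure_id, mediator_id=step1.outcome_id,
        outcome_id=step2.outcome_id, a=a, se_a=se_a, b=b, se_b=se_b,
        indirect=indirect, se_indirect=se_ind, z=z, pval=pval,
        proportion_mediated=prop)
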