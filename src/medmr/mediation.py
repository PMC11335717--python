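"""Two-step MR mediation arithmetic with delta-method confidence intervals.

Given the three IVW estimates of one mediation path —

* ``beta_a``: exposure -> mediator,
* ``beta_b``: mediator -> outcome,
* ``beta_c``: total exposure -> outcome effect,

the indirect effect is the product ``beta_a*beta_b``, the direct effect is
``beta_c' = beta_c - beta_a*beta_b`` (so the decomposition
``direct + indirect = beta_c`` is exact by construction), and the
proportion mediated is ``beta_a*beta_b/beta_c``.  Standard errors use the
first-order delta method treating the three estimates as independent: they
come from three distinct GWAS pairings, although beta_a and beta_c do share
exposure instruments — a documented approximation.  The proportion's p is a
Wald z-test on P.

Following common reporting practice, the proportion is only flagged for
reporting when the direct and indirect effects point the same way
(otherwise it is not interpretable as a fraction of the total effect,
though its value is still computed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedProportionError, ValidationError

_TINY_P = 5e-324


@dataclass
class MediationResult:
    """One exposure -> mediator -> outcome decomposition."""

    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    beta_c: float
    se_c: float
    indirect: float
    se_indirect: float
    direct: float
    se_direct: float
    proportion: float
    se_proportion: float
    proportion_ci: tuple
    proportion_pval: float
    same_direction: bool
    proportion_reported: bool
    alpha: float = 0.05

    def __post_init__(self):
        # direct is defined as beta_c - indirect, so the decomposition holds
        # by construction; re-adding may differ by one rounding ulp.
        import math

        if not math.isclose(
            self.direct + self.indirect, self.beta_c, rel_tol=1e-12, abs_tol=1e-300
        ):
            raise ValidationError("direct + indirect must equal beta_c")
        if self.proportion_reported and not self.same_direction:
            raise ValidationError("proportion reported despite opposite-sign effects")


def product_effect(
    beta_a: float, se_a: float, beta_b: float, se_b: float
) -> tuple[float, float]:
    """Indirect effect ``beta_a*beta_b`` with first-order delta-method SE.

    ``se = sqrt(beta_a^2*se_b^2 + beta_b^2*se_a^2)``, assuming the two
    estimates are independent.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValidationError("standard errors must be > 0")
    estimate = beta_a * beta_b
    se = float(np.sqrt(beta_a**2 * se_b**2 + beta_b**2 * se_a**2))
    return float(estimate), se


def mediate(
    beta_a: float,
    se_a: float,
    beta_b: float,
    se_b: float,
    beta_c: float,
    se_c: float,
    alpha: float = 0.05,
    direction_rule: str = "direct",
) -> MediationResult:
    """Full mediation decomposition for one path.

    The proportion mediated ``P = beta_a*beta_b/beta_c`` gets a first-order
    delta-method variance

    ``Var(P) = (beta_b/beta_c)^2 se_a^2 + (beta_a/beta_c)^2 se_b^2
               + (beta_a*beta_b/beta_c^2)^2 se_c^2``

    and a two-sided ``(1-alpha)`` normal CI.  ``direction_rule`` selects
    which pair must agree in sign for the proportion to be flagged
    reportable: ``"direct"`` (direct vs indirect, the default) or
    ``"total"`` (total vs indirect).
    """
    if beta_c == 0:
        raise UndefinedProportionError("total effect is zero; proportion undefined")
    if min(se_a, se_b, se_c) <= 0:
        raise ValidationError("standard errors must be > 0")
    if direction_rule not in ("direct", "total"):
        raise ValidationError(f"unknown direction_rule {direction_rule!r}")

    indirect, se_ind = product_effect(beta_a, se_a, beta_b, se_b)
    direct = beta_c - indirect
    se_dir = float(np.sqrt(se_c**2 + se_ind**2))

    prop = indirect / beta_c
    var_p = (
        (beta_b / beta_c) ** 2 * se_a**2
        + (beta_a / beta_c) ** 2 * se_b**2
        + (beta_a * beta_b / beta_c**2) ** 2 * se_c**2
    )
    se_p = float(np.sqrt(var_p))
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (prop - z * se_p, prop + z * se_p)
    pval = max(2.0 * stats.norm.sf(abs(prop / se_p)), _TINY_P) if se_p > 0 else _TINY_P

    reference = direct if direction_rule == "direct" else beta_c
    same_direction = bool(np.sign(reference) == np.sign(indirect))
    return MediationResult(
        beta_a=beta_a,
        se_a=se_a,
        beta_b=beta_b,
        se_b=se_b,
        beta_c=beta_c,
        se_c=se_c,
        indirect=indirect,
        se_indirect=se_ind,
        direct=direct,
        se_direct=se_dir,
        proportion=float(prop),
        se_proportion=se_p,
        proportion_ci=ci,
        proportion_pval=float(pval),
        same_direction=same_direction,
        proportion_reported=same_direction,
        alpha=alpha,
    )
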