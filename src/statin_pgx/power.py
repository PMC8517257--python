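"""Post hoc minimum-detectable-difference (MDD) calculations.

For a genotype-group contrast on a continuous outcome (two-sample z
approximation), the smallest true mean difference detectable at a given
sample size, outcome SD, two-sided alpha and power is

    MDD = (z_{1-alpha/2} + z_{power}) * sd * sqrt(1/n1 + 1/n2)

where the group sizes follow from Hardy-Weinberg proportions at the
variant's minor-allele frequency: the exposed fraction is maf**2 under a
recessive model and 1 - (1-maf)**2 under a dominant model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    """A single detectability question.

    total_n    -- cohort size available for the contrast
    maf        -- minor-allele frequency of the variant, in (0, 1)
    genetic_model -- "recessive" or "dominant" (sets the exposed fraction)
    outcome_sd -- SD of the continuous outcome (mmol/L for non-HDL-C change)
    alpha      -- two-sided type-I error rate
    power      -- target power, in (0, 1)
    """

    total_n: int
    maf: float
    genetic_model: str = "recessive"
    outcome_sd: float = 1.04
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.total_n < 4:
            raise ValueError("total_n must be at least 4")
        if self.outcome_sd <= 0:
            raise ValueError("outcome_sd must be positive")
        if self.genetic_model not in ("recessive", "dominant"):
            raise ValueError("genetic_model must be 'recessive' or 'dominant'")

    @property
    def exposed_fraction(self) -> float:
        if self.genetic_model == "recessive":
            return self.maf ** 2
        return 1.0 - (1.0 - self.maf) ** 2


class InfeasibleGroupError(ValueError):
    """The expected size of a genotype group is too small to form a contrast."""


def minimum_detectable_difference(query: PowerQuery) -> float:
    """Closed-form MDD in outcome units (mmol/L) for the genotype contrast."""
    f = query.exposed_fraction
    n1 = f * query.total_n
    n2 = (1.0 - f) * query.total_n
    if n1 < 2 or n2 < 2:
        raise InfeasibleGroupError(
            f"expected group sizes {n1:.1f}/{n2:.1f} too small for a two-group contrast"
        )
    z_alpha = stats.norm.ppf(1.0 - query.alpha / 2.0)
    z_power = stats.norm.ppf(query.power)
    return float((z_alpha + z_power) * query.outcome_sd * np.sqrt(1.0 / n1 + 1.0 / n2))


def detectable_at(query: PowerQuery, effect: float) -> bool:
    """True when `effect` (mmol/L) is at or above the minimum detectable
    difference for this query; the boundary counts as detectable."""
    return effect >= minimum_detectable_difference(query)


def empirical_power(query: PowerQuery, effect: float, n_replicates: int = 2000,
                    seed: int = 0) -> float:
    """Monte-Carlo power of the two-sample z test at a given true effect.

    Simulation cross-check for the closed form: draws normal outcomes for
    the two HWE genotype groups and counts two-sided rejections at
    `query.alpha`.
    """
    rng = np.random.default_rng(seed)
    f = query.exposed_fraction
    n1 = max(int(round(f * query.total_n)), 2)
    n2 = max(query.total_n - n1, 2)
    sd = query.outcome_sd
    x1 = rng.normal(effect, sd, size=(n_replicates, n1))
    x2 = rng.normal(0.0, sd, size=(n_replicates, n2))
    se = np.sqrt(x1.var(axis=1, ddof=1) / n1 + x2.var(axis=1, ddof=1) / n2)
    z = (x1.mean(axis=1) - x2.mean(axis=1)) / se
    crit = stats.norm.ppf(1.0 - query.alpha / 2.0)
    return float(np.mean(np.abs(z) > crit))
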