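"""Instrument strength and statistical power for binary-outcome MR.

Variance explained per variant, the joint F-statistic, and the minimal
detectable odds ratio per exposure SD at a given two-sided level and
power for a case-control outcome GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_associations import VariantAssociation


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-variant and total variance explained plus the joint F-statistic."""

    r2_per_variant: tuple[float, ...]
    r2_total: float
    f_statistic: float
    n: int
    k: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the binary-outcome MR power approximation."""

    n_cases: int
    n_controls: int
    r2: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")


def variance_explained(assoc: VariantAssociation, method: str = "se_based") -> float:
    """Proportion of exposure variance explained by one variant.

    ``se_based`` uses beta^2 / (beta^2 + n * SE^2), requiring the GWAS
    sample size; ``eaf_based`` uses 2 p (1-p) beta^2, valid when beta is
    in trait-SD units.
    """
    if method == "se_based":
        if assoc.sample_size is None:
            raise ValueError(
                f"{assoc.variant_id}: sample_size required for method 'se_based'"
            )
        b2 = assoc.beta**2
        return b2 / (b2 + assoc.sample_size * assoc.se**2)
    if method == "eaf_based":
        p = assoc.effect_allele_freq
        return 2.0 * p * (1.0 - p) * assoc.beta**2
    raise ValueError(f"unknown method {method!r}")


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Joint instrument F-statistic ((n-k-1)/k) * (R^2/(1-R^2))."""
    if not 0 <= r2_total < 1:
        raise ValueError(f"r2_total must be in [0, 1), got {r2_total}")
    if n <= k + 1 or k < 1:
        raise ValueError("need n > k+1 >= 2")
    return ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))


def instrument_strength(
    assocs: Sequence[VariantAssociation], n: int | None = None, method: str = "se_based"
) -> InstrumentStrength:
    """Summarize variance explained and F over a set of exposure associations."""
    if n is not None:
        assocs = [
            a if a.sample_size is not None else _with_n(a, n) for a in assocs
        ]
    r2s = tuple(variance_explained(a, method=method) for a in assocs)
    r2_total = float(sum(r2s))
    k = len(assocs)
    n_eff = n if n is not None else assocs[0].sample_size
    return InstrumentStrength(
        r2_per_variant=r2s,
        r2_total=r2_total,
        f_statistic=f_statistic(r2_total, n_eff, k),
        n=n_eff,
        k=k,
    )


def _with_n(assoc: VariantAssociation, n: int) -> VariantAssociation:
    from dataclasses import replace

    return replace(assoc, sample_size=n)


def minimal_detectable_or(spec: PowerSpec) -> float:
    """Smallest detectable OR per exposure SD at the spec's alpha and power.

    log-OR_min = (z_{1-alpha/2} + z_{power}) / sqrt(N phi (1-phi) R^2)
    with N the total sample and phi the case fraction.
    """
    if not 0 < spec.r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    n_total = spec.n_cases + spec.n_controls
    phi = spec.n_cases / n_total
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    log_or = (z_a + z_b) / np.sqrt(n_total * phi * (1 - phi) * spec.r2)
    return float(np.exp(log_or))


def power_at_or(spec: PowerSpec, odds_ratio: float) -> float:
    """Power to detect a candidate OR per exposure SD (inverse of the above)."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0 < spec.r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    n_total = spec.n_cases + spec.n_controls
    phi = spec.n_cases / n_total
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    return float(
        stats.norm.cdf(np.log(odds_ratio) * np.sqrt(n_total * phi * (1 - phi) * spec.r2) - z_a)
    )
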