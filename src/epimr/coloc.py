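"""Bayesian enumeration colocalization for two traits over a genomic region.

Each variant's association evidence is summarized by a Wakefield
approximate Bayes factor computed from its estimated effect, standard
error, and a prior effect variance W. Assuming at most one causal variant
per trait in the region, five hypotheses are enumerated:

- H0: no association with either trait
- H1 / H2: association with trait 1 / trait 2 only
- H3: both traits associated, distinct causal variants
- H4: both traits associated, one shared causal variant

Posterior probabilities follow from the per-variant Bayes factors and the
per-variant priors p1, p2, p12. All arithmetic is in log-space so that no
per-variant Bayes factor can overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .summary_associations import VariantAssociation

#: default prior effect SDs (sqrt of W): trait-SD units for quantitative
#: traits, log-odds for binary traits
PRIOR_SD_QUANTITATIVE = 0.2
PRIOR_SD_BINARY = 0.15

#: per-variant prior that a variant is causal for one trait
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
#: "standard" and "relaxed" presets for the shared-causal-variant prior
P12_STANDARD = 1e-5
P12_RELAXED = 1e-4


def _default_w(trait_type: str) -> float:
    if trait_type == "quantitative":
        return PRIOR_SD_QUANTITATIVE**2
    if trait_type == "binary":
        return PRIOR_SD_BINARY**2
    raise ValueError(f"unknown trait type {trait_type!r}")


@dataclass
class RegionalDataset:
    """Aligned two-trait summary statistics for one genomic region."""

    variant_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait1_type: str = "quantitative"
    trait2_type: str = "binary"
    w1: float | None = None
    w2: float | None = None

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.se1 = np.asarray(self.se1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.se2 = np.asarray(self.se2, dtype=float)
        m = len(self.variant_ids)
        if m < 1:
            raise ValueError("region must contain at least one variant")
        for name, arr in (("beta1", self.beta1), ("se1", self.se1),
                          ("beta2", self.beta2), ("se2", self.se2)):
            if arr.shape != (m,):
                raise ValueError(f"{name} length {arr.shape} does not match {m} variants")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0):
            raise ValueError("all standard errors must be positive")
        if self.w1 is None:
            self.w1 = _default_w(self.trait1_type)
        if self.w2 is None:
            self.w2 = _default_w(self.trait2_type)
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("prior effect variances must be positive")

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five enumeration hypotheses."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    p1: float
    p2: float
    p12: float
    log_abf1: np.ndarray
    log_abf2: np.ndarray

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def log_abf(beta, se, w) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor (association vs null).

    With V = se^2, z = beta/se and r = w/(w+V):
    log ABF = 0.5 log(1-r) + z^2 r / 2. Vectorized over inputs.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any(np.asarray(w) <= 0):
        raise ValueError("prior variance w must be positive")
    v = se**2
    r = w / (w + v)
    z = beta / se
    out = 0.5 * np.log1p(-r) + z**2 * r / 2.0
    return float(out) if out.ndim == 0 else out


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_enumerate(
    region: RegionalDataset,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = P12_STANDARD,
) -> ColocResult:
    """Enumerate H0-H4 posterior probabilities for a region.

    Unnormalized hypothesis weights from per-variant Bayes factors B1_i,
    B2_i: H0 = 1, H1 = p1 sum B1_i, H2 = p2 sum B2_i,
    H3 = p1 p2 sum_{i != j} B1_i B2_j, H4 = p12 sum B1_i B2_i.
    """
    if min(p1, p2, p12) <= 0:
        raise ValueError("priors must be positive")
    m = len(region)
    if (p1 + p2 + p12) * m > 0.1:
        warnings.warn(
            f"priors sum to {(p1 + p2 + p12) * m:.3g} over {m} variants; "
            "the single-causal-variant enumeration assumes this is well below 1",
            stacklevel=2,
        )
    l1 = log_abf(region.beta1, region.se1, region.w1)
    l2 = log_abf(region.beta2, region.se2, region.w2)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    log_h = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + _logdiffexp(s1 + s2, s12),
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(log_h - logsumexp(log_h))
    pp /= pp.sum()
    return ColocResult(
        pp0=float(pp[0]),
        pp1=float(pp[1]),
        pp2=float(pp[2]),
        pp3=float(pp[3]),
        pp4=float(pp[4]),
        p1=p1,
        p2=p2,
        p12=p12,
        log_abf1=np.asarray(l1),
        log_abf2=np.asarray(l2),
    )


def regional_dataset(
    trait1: Sequence[VariantAssociation],
    trait2: Sequence[VariantAssociation],
    trait1_type: str = "quantitative",
    trait2_type: str = "binary",
    w1: float | None = None,
    w2: float | None = None,
) -> RegionalDataset:
    """Align two per-variant association collections into a RegionalDataset.

    Variants present in both traits are kept, in trait-1 order. Raises if
    the traits share no variant.
    """
    by_id = {r.variant_id: r for r in trait2}
    ids, b1, s1, b2, s2 = [], [], [], [], []
    for r in trait1:
        other = by_id.get(r.variant_id)
        if other is None:
            continue
        ids.append(r.variant_id)
        b1.append(r.beta)
        s1.append(r.se)
        b2.append(other.beta)
        s2.append(other.se)
    if not ids:
        raise ValueError("no shared variants between the two traits")
    return RegionalDataset(
        variant_ids=ids,
        beta1=np.array(b1),
        se1=np.array(s1),
        beta2=np.array(b2),
        se2=np.array(s2),
        trait1_type=trait1_type,
        trait2_type=trait2_type,
        w1=w1,
        w2=w2,
    )
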