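"""GWAS summary-association records: reading, harmonization, region subsetting.

Summary-statistic MR works from per-variant association tables for an
exposure (here a circulating protein, effects in trait-SD units) and a
binary outcome (effects in log-odds). Before any estimator can combine the
two traits, their effect sizes must refer to the same effect allele at each
variant; :func:`harmonize` performs that alignment and records which
outcome rows were reoriented.

The declared TSV dialect is tab-separated with '.' decimals, "NA" for
missing values, required columns ``snp chr pos effect_allele other_allele
eaf beta se`` and optional ``pval n``.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("snp", "chr", "pos", "effect_allele", "other_allele", "eaf", "beta", "se")
OPTIONAL_COLUMNS = ("pval", "n")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GwasTableError(ValueError):
    """Raised for malformed GWAS summary tables."""


class HarmonizationError(ValueError):
    """Raised when exposure and outcome tables cannot be aligned."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-trait summary association record.

    ``beta`` is the per-effect-allele effect: trait-SD units for a
    quantitative exposure, log-odds for a binary outcome.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    effect_allele_freq: float
    beta: float
    se: float
    p_value: float | None = None
    sample_size: int | None = None
    trait_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_allele_freq <= 1.0:
            raise ValueError(
                f"{self.variant_id}: effect_allele_freq {self.effect_allele_freq} outside [0, 1]"
            )
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1 (1-based)")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Allele-aligned exposure/outcome pair for one genetic instrument."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if not self.se_exposure > 0:
            raise ValueError(f"{self.variant_id}: se_exposure must be positive")
        if not self.se_outcome > 0:
            raise ValueError(f"{self.variant_id}: se_outcome must be positive")


@dataclass
class InstrumentSet:
    """Ordered harmonized instruments, optionally with a genotype correlation matrix."""

    instruments: list[HarmonizedInstrument]
    correlation: np.ndarray | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.correlation is not None:
            rho = np.asarray(self.correlation, dtype=float)
            k = len(self.instruments)
            if rho.shape != (k, k):
                raise ValueError(f"correlation matrix shape {rho.shape} does not match {k} instruments")
            if not np.allclose(rho, rho.T, atol=1e-10):
                raise ValueError("correlation matrix is not symmetric")
            if not np.allclose(np.diag(rho), 1.0, atol=1e-10):
                raise ValueError("correlation matrix diagonal is not unity")
            if np.linalg.eigvalsh(rho).min() <= 0:
                raise ValueError("correlation matrix is not positive definite")
            self.correlation = rho

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([i.beta_exposure for i in self.instruments])

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([i.beta_outcome for i in self.instruments])

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([i.se_outcome for i in self.instruments])

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([i.se_exposure for i in self.instruments])


def read_gwas_table(path, trait_label: str = "") -> list[VariantAssociation]:
    """Read a GWAS summary TSV into :class:`VariantAssociation` records.

    Raises :class:`GwasTableError` naming the offending column (if a
    required column is missing) or row and field (if a value fails to
    parse).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise GwasTableError(f"missing required column '{col}' in {path}")

    records: list[VariantAssociation] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = row._asdict()
        parsed: dict[str, object] = {}
        for name, caster in (
            ("pos", int),
            ("eaf", float),
            ("beta", float),
            ("se", float),
        ):
            try:
                parsed[name] = caster(rec[name])
            except (TypeError, ValueError) as exc:
                raise GwasTableError(
                    f"row {row_number}: cannot parse field '{name}' value {rec[name]!r}"
                ) from exc
        p_value = None
        if "pval" in rec and rec["pval"] not in (None, "") and not pd.isna(rec["pval"]):
            try:
                p_value = float(rec["pval"])
            except ValueError as exc:
                raise GwasTableError(f"row {row_number}: cannot parse field 'pval'") from exc
        sample_size = None
        if "n" in rec and rec["n"] not in (None, "") and not pd.isna(rec["n"]):
            try:
                sample_size = int(float(rec["n"]))
            except ValueError as exc:
                raise GwasTableError(f"row {row_number}: cannot parse field 'n'") from exc
        try:
            records.append(
                VariantAssociation(
                    variant_id=str(rec["snp"]),
                    chromosome=str(rec["chr"]),
                    position=parsed["pos"],
                    effect_allele=str(rec["effect_allele"]).upper(),
                    other_allele=str(rec["other_allele"]).upper(),
                    effect_allele_freq=parsed["eaf"],
                    beta=parsed["beta"],
                    se=parsed["se"],
                    p_value=p_value,
                    sample_size=sample_size,
                    trait_label=trait_label,
                )
            )
        except ValueError as exc:
            raise GwasTableError(f"row {row_number}: {exc}") from exc
    return records


def write_gwas_table(records: Iterable[VariantAssociation], path) -> None:
    """Write records back to the declared TSV dialect (round-trip safe)."""
    rows = []
    for r in records:
        rows.append(
            {
                "snp": r.variant_id,
                "chr": r.chromosome,
                "pos": r.position,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": repr(r.effect_allele_freq),
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pval": "NA" if r.p_value is None else repr(r.p_value),
                "n": "NA" if r.sample_size is None else r.sample_size,
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def _alleles_match(exp: VariantAssociation, out: VariantAssociation) -> str | None:
    """Classify outcome allele orientation relative to exposure.

    Returns "same", "swapped", "same_complement", "swapped_complement",
    or None for incompatible alleles. Forward strand is assumed;
    complement matching is attempted before giving up.
    """
    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele
    if (o1, o2) == (e1, e2):
        return "same"
    if (o1, o2) == (e2, e1):
        return "swapped"
    c1, c2 = _COMPLEMENT.get(o1), _COMPLEMENT.get(o2)
    if (c1, c2) == (e1, e2):
        return "same_complement"
    if (c1, c2) == (e2, e1):
        return "swapped_complement"
    return None


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_policy: str = "drop",
    ambiguity_threshold: float = 0.42,
    correlation: np.ndarray | None = None,
) -> InstrumentSet:
    """Align outcome effects to the exposure effect allele per variant.

    Outcome betas are sign-flipped (and the EAF complemented) when the
    outcome row lists the alleles in swapped order. Palindromic (A/T, G/C)
    variants cannot be oriented by allele labels alone:

    - policy ``"drop"`` excludes them when min(EAF, 1-EAF) exceeds
      ``ambiguity_threshold`` (orientation genuinely ambiguous) and
      otherwise resolves the orientation by comparing allele frequencies;
    - policy ``"eaf_infer"`` always resolves by frequency comparison.

    Variants with incompatible alleles are dropped and logged. Raises
    :class:`HarmonizationError` if no variant overlaps.
    """
    if palindrome_policy not in ("drop", "eaf_infer"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    out_by_id = {r.variant_id: r for r in outcome}
    instruments: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            continue
        if exp.is_palindromic:
            maf = min(exp.effect_allele_freq, 1.0 - exp.effect_allele_freq)
            if palindrome_policy == "drop" and maf > ambiguity_threshold:
                reason = f"palindromic with ambiguous EAF {exp.effect_allele_freq:.3f}"
                logger.info("dropping %s: %s", exp.variant_id, reason)
                dropped.append((exp.variant_id, reason))
                continue
            # frequency-based orientation: effect alleles agree if EAFs sit
            # on the same side of 0.5
            same_side = (exp.effect_allele_freq - 0.5) * (out.effect_allele_freq - 0.5) >= 0
            flipped = not same_side
        else:
            match = _alleles_match(exp, out)
            if match is None:
                reason = (
                    f"incompatible alleles {out.effect_allele}/{out.other_allele} "
                    f"vs {exp.effect_allele}/{exp.other_allele}"
                )
                logger.info("dropping %s: %s", exp.variant_id, reason)
                dropped.append((exp.variant_id, reason))
                continue
            flipped = match in ("swapped", "swapped_complement")
        instruments.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=-out.beta if flipped else out.beta,
                se_outcome=out.se,
                eaf_exposure=exp.effect_allele_freq,
                flipped=flipped,
            )
        )
    if not instruments:
        raise HarmonizationError("no overlapping variants between exposure and outcome")
    return InstrumentSet(instruments=instruments, correlation=correlation, dropped=dropped)


def select_region(
    assocs: Sequence[VariantAssociation],
    center_position: int,
    window: int,
    chromosome: str | None = None,
) -> list[VariantAssociation]:
    """Keep records within ``window`` base pairs of ``center_position`` (closed interval).

    If ``chromosome`` is given, only records on that chromosome are
    considered; otherwise all records are filtered by position alone.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    kept = []
    for r in assocs:
        if chromosome is not None and str(r.chromosome) != str(chromosome):
            continue
        if abs(r.position - center_position) <= window:
            kept.append(r)
    return kept


def load_fabp4_instruments() -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Load the packaged three-SNP FABP-4 instrument fixture.

    Returns (exposure records, outcome records): the published
    SNP-FABP-4 associations (per-SD units, discovery n = 20,436) and the
    SNP-colorectal-cancer associations (log-odds) for rs2012444,
    rs77878271 (the cis variant near *FABP4*) and rs79389622.
    """
    ref = importlib.resources.files("epimr.data").joinpath("fabp4_instruments.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    exposure, outcome = [], []
    for _, row in df.iterrows():
        common = dict(
            variant_id=row["snp"],
            chromosome=str(row["chr"]),
            position=int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
        )
        exposure.append(
            VariantAssociation(
                **common,
                effect_allele_freq=float(row["eaf_exposure"]),
                beta=float(row["beta_exposure"]),
                se=float(row["se_exposure"]),
                sample_size=int(row["n_exposure"]),
                trait_label="FABP-4 (SD units)",
            )
        )
        outcome.append(
            VariantAssociation(
                **common,
                effect_allele_freq=float(row["eaf_outcome"]),
                beta=float(row["beta_outcome"]),
                se=float(row["se_outcome"]),
                trait_label="colorectal cancer (log-odds)",
            )
        )
    return exposure, outcome
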