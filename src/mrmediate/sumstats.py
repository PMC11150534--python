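"""Reading, validating, and writing GWAS summary-statistic tables.

The canonical on-disk format is tab-separated text with a header row and
columns ``SNP CHR POS EA OA EAF BETA SE P N``.  ``BETA`` is the marginal
per-effect-allele association: a log odds ratio for binary traits and an
effect in standard-deviation units for (inverse-normal transformed)
continuous traits.  ``EAF`` may be ``NA``; every other field is mandatory.
Other header conventions are supported through a per-file column map
(:class:`Dialect`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "Dialect",
    "RowError",
    "SumstatsFormatError",
    "SumstatsValidationError",
    "SumstatsTable",
    "VariantAssociation",
    "read_sumstats",
    "write_results_table",
    "write_sumstats",
]

#: Canonical column order of the on-disk dialect.
CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N")

_NA_STRINGS = frozenset({"", "NA", "NaN", "nan", "na", "."})
_VALID_BASES = frozenset("ACGT")


class SumstatsFormatError(ValueError):
    """The file structure (header, delimiter) does not match the dialect."""


class SumstatsValidationError(ValueError):
    """The file parsed but violates a table-level invariant."""


@dataclass(frozen=True)
class Dialect:
    """Column-name map from canonical names to the names used in a file."""

    columns: Mapping[str, str] = field(default_factory=lambda: {c: c for c in CANONICAL_COLUMNS})
    sep: str = "\t"

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class RowError:
    """Diagnostic for one rejected input row (1-based data-row numbering)."""

    row: int
    variant_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row} ({self.variant_id}): {self.field}: {self.message}"


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association in one GWAS."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: int

    def problems(self) -> list[tuple[str, str]]:
        """Return (field, message) pairs for every violated invariant."""
        out: list[tuple[str, str]] = []
        if not self.variant_id:
            out.append(("variant_id", "empty variant identifier"))
        if not self.chrom:
            out.append(("chrom", "empty chromosome"))
        if self.pos < 1:
            out.append(("pos", f"position must be >= 1, got {self.pos}"))
        ea, oa = self.effect_allele, self.other_allele
        for name, allele in (("effect_allele", ea), ("other_allele", oa)):
            if not allele or not set(allele) <= _VALID_BASES:
                out.append((name, f"allele {allele!r} is not a non-empty A/C/G/T string"))
        if ea == oa:
            out.append(("other_allele", "effect and other allele are identical"))
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append(("eaf", f"eaf {self.eaf} outside [0, 1]"))
        if not math.isfinite(self.beta):
            out.append(("beta", f"non-finite beta {self.beta}"))
        if not (math.isfinite(self.se) and self.se > 0):
            out.append(("se", f"se must be a finite positive number, got {self.se}"))
        if not (0.0 < self.pvalue <= 1.0):
            out.append(("pvalue", f"p-value {self.pvalue} outside (0, 1]"))
        if self.n < 1:
            out.append(("n", f"sample size must be positive, got {self.n}"))
        return out

    def is_valid(self) -> bool:
        return not self.problems()


@dataclass
class SumstatsTable:
    """An ordered, validated collection of per-variant associations.

    ``trait_type`` is ``"binary"`` (betas are log odds ratios) or
    ``"continuous"`` (betas in SD units).  ``rejects`` records rows that were
    dropped at load time, so no input row ever vanishes silently.
    """

    trait_id: str
    trait_type: str
    records: tuple[VariantAssociation, ...]
    rejects: tuple[RowError, ...] = ()

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise SumstatsValidationError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        seen: set[str] = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise SumstatsValidationError(
                    f"duplicate variant_id {rec.variant_id!r} in table {self.trait_id!r}"
                )
            seen.add(rec.variant_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(r.variant_id for r in self.records)

    def get(self, variant_id: str) -> VariantAssociation:
        for rec in self.records:
            if rec.variant_id == variant_id:
                return rec
        raise KeyError(variant_id)

    def subset(self, variant_ids: Iterable[str]) -> "SumstatsTable":
        """New table with the listed variants, original order preserved."""
        keep = set(variant_ids)
        return replace(
            self, records=tuple(r for r in self.records if r.variant_id in keep), rejects=()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": [r.variant_id for r in self.records],
                "CHR": [r.chrom for r in self.records],
                "POS": [r.pos for r in self.records],
                "EA": [r.effect_allele for r in self.records],
                "OA": [r.other_allele for r in self.records],
                "EAF": [np.nan if r.eaf is None else r.eaf for r in self.records],
                "BETA": [r.beta for r in self.records],
                "SE": [r.se for r in self.records],
                "P": [r.pvalue for r in self.records],
                "N": [r.n for r in self.records],
            }
        )


def _parse_float(raw: str, allow_missing: bool = False) -> Optional[float]:
    if raw.strip() in _NA_STRINGS:
        if allow_missing:
            return None
        raise ValueError("missing value")
    return float(raw)


def _parse_int(raw: str) -> int:
    # tolerate "3340.0"-style sample sizes produced by some exporters
    value = float(raw)
    if not value.is_integer():
        raise ValueError(f"expected an integer, got {raw!r}")
    return int(value)


def read_sumstats(
    path: Union[str, Path],
    dialect: Dialect = DEFAULT_DIALECT,
    *,
    trait_id: Optional[str] = None,
    trait_type: str = "continuous",
) -> SumstatsTable:
    """Load a summary-statistic file into a validated :class:`SumstatsTable`.

    Rows violating per-variant invariants are rejected (not fatal) and
    reported with 1-based data-row numbers in ``table.rejects``.  Structural
    problems — a missing mandatory column or a duplicated variant ID among
    accepted rows — raise instead.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    file_cols = {canon: dialect.file_column(canon) for canon in CANONICAL_COLUMNS}
    missing = [fc for fc in file_cols.values() if fc not in raw.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path.name}: missing mandatory column(s) {missing}; found {list(raw.columns)}"
        )

    records: list[VariantAssociation] = []
    rejects: list[RowError] = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        values = {canon: getattr(row, fc) for canon, fc in file_cols.items()}
        snp = str(values["SNP"]).strip()
        rec = None
        try:
            rec = VariantAssociation(
                variant_id=snp,
                chrom=str(values["CHR"]).strip(),
                pos=_parse_int(values["POS"]),
                effect_allele=str(values["EA"]).strip().upper(),
                other_allele=str(values["OA"]).strip().upper(),
                eaf=_parse_float(values["EAF"], allow_missing=True),
                beta=float(values["BETA"]),
                se=float(values["SE"]),
                pvalue=float(values["P"]),
                n=_parse_int(values["N"]),
            )
        except ValueError as exc:
            # identify the first offending field for the diagnostic
            bad_field = "row"
            for fname in ("POS", "EAF", "BETA", "SE", "P", "N"):
                try:
                    if fname == "EAF":
                        _parse_float(values[fname], allow_missing=True)
                    elif fname in ("POS", "N"):
                        _parse_int(values[fname])
                    else:
                        float(values[fname])
                except ValueError:
                    bad_field = fname.lower()
                    break
            rejects.append(RowError(i, snp, bad_field, str(exc)))
        if rec is not None:
            problems = rec.problems()
            if problems:
                fname, msg = problems[0]
                rejects.append(RowError(i, snp, fname, msg))
            else:
                records.append(rec)

    return SumstatsTable(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        records=tuple(records),
        rejects=tuple(rejects),
    )


def write_sumstats(table: SumstatsTable, path: Union[str, Path]) -> Path:
    """Write a table in the canonical TSV dialect; round-trips exactly."""
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for r in table.records:
        eaf = "NA" if r.eaf is None else repr(r.eaf)
        lines.append(
            "\t".join(
                [
                    r.variant_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    eaf,
                    repr(r.beta),
                    repr(r.se),
                    repr(r.pvalue),
                    str(r.n),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _is_mr_estimate(row: object) -> bool:
    return hasattr(row, "method") and hasattr(row, "n_snp")


def _is_mediation_result(row: object) -> bool:
    return hasattr(row, "indirect") and hasattr(row, "proportion")


def write_results_table(rows: Sequence[object], path: Union[str, Path]) -> Path:
    """Write a homogeneous collection of MR estimates or mediation results.

    MR estimates gain an odds-ratio column (``exp(beta)``) when the outcome
    is binary; mediation results are written with the proportion mediated as
    a percentage.  Mixing the two row types is a usage error.
    """
    path = Path(path)
    if not rows:
        raise ValueError("no rows to write")
    kinds = {(_is_mr_estimate(r), _is_mediation_result(r)) for r in rows}
    if len(kinds) > 1:
        raise TypeError("mixed row types: all rows must be MREstimate or all MediationResult")

    if _is_mediation_result(rows[0]):
        frame = pd.DataFrame([r.to_row() for r in rows])
    elif _is_mr_estimate(rows[0]):
        out = []
        for r in rows:
            rec = {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "method": r.method,
                "n_snp": r.n_snp,
                "beta": r.beta,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "OR": math.exp(r.beta) if r.outcome_binary else np.nan,
                "OR_ci_low": math.exp(r.ci_low) if r.outcome_binary else np.nan,
                "OR_ci_high": math.exp(r.ci_high) if r.outcome_binary else np.nan,
                "p": r.pvalue,
            }
            if r.intercept is not None:
                rec.update(
                    intercept=r.intercept,
                    intercept_se=r.intercept_se,
                    intercept_p=r.intercept_p,
                )
            out.append(rec)
        frame = pd.DataFrame(out)
    else:
        raise TypeError(f"unsupported row type {type(rows[0]).__name__}")

    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
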