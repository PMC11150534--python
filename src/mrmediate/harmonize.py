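"""Instrument selection and exposure/outcome harmonization.

Stage 1 of the pipeline: keep genome-wide significant variants, prune them
to near-independence by greedy LD clumping (r² < 0.001 within 10,000 kb by
default), align the outcome associations onto the exposure's effect-allele
orientation, and drop weak instruments (F < 10).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Union

import pandas as pd

from .sumstats import SumstatsTable, VariantAssociation

__all__ = [
    "AttritionStep",
    "HarmonizationResult",
    "HarmonizedInstrument",
    "LDInfo",
    "SelectionConfig",
    "SelectionError",
    "SelectionResult",
    "clump",
    "compute_f_stat",
    "filter_by_pvalue",
    "harmonize",
    "select_instruments",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SelectionError(ValueError):
    """Instrument selection exhausted the candidate set (or bad inputs)."""


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT[b] for b in allele)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _complement(ea) == oa


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One variant's exposure and outcome effects on a common orientation."""

    variant_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.variant_id}: standard errors must be positive")

    @property
    def f_stat(self) -> float:
        return compute_f_stat(self.beta_exp, self.se_exp)

    @property
    def ratio(self) -> float:
        """Wald ratio beta_out / beta_exp."""
        return self.beta_out / self.beta_exp

    @property
    def ratio_se(self) -> float:
        """First-order standard error of the Wald ratio, se_out / |beta_exp|."""
        return self.se_out / abs(self.beta_exp)


class LDInfo:
    """Sparse symmetric table of pairwise r² values; absent pairs mean r² = 0."""

    def __init__(self, pairs: Optional[Mapping[tuple[str, str], float]] = None) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r² must lie in [0, 1], got {r2} for ({a}, {b})")
        if a != b:
            self._r2[self._key(a, b)] = r2

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self._r2.items())

    @classmethod
    def read(cls, path: Union[str, Path]) -> "LDInfo":
        frame = pd.read_csv(path, sep="\t")
        for col in ("ID_A", "ID_B", "R2"):
            if col not in frame.columns:
                raise ValueError(f"LD table must have columns ID_A, ID_B, R2; missing {col}")
        info = cls()
        for row in frame.itertuples(index=False):
            info.set(str(row.ID_A), str(row.ID_B), float(row.R2))
        return info

    def write(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        rows = [{"ID_A": a, "ID_B": b, "R2": r2} for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["ID_A", "ID_B", "R2"]).to_csv(path, sep="\t", index=False)
        return path


EMPTY_LD = LDInfo()


@dataclass(frozen=True)
class SelectionConfig:
    """Tuning of the four-step instrument-selection procedure."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10000.0
    palindrome_eaf_margin: float = 0.08
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError(f"p_threshold must lie in (0, 1), got {self.p_threshold}")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must lie in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if not 0.0 <= self.palindrome_eaf_margin < 0.5:
            raise ValueError("palindrome_eaf_margin must lie in [0, 0.5)")


def filter_by_pvalue(table: SumstatsTable, threshold: float) -> SumstatsTable:
    """Keep rows with p strictly below ``threshold``, order preserved."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    kept = tuple(r for r in table.records if r.pvalue < threshold)
    return replace(table, records=kept, rejects=())


def compute_f_stat(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F statistic, (beta / se)²."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def clump(
    table: SumstatsTable,
    ld: LDInfo = EMPTY_LD,
    r2_threshold: float = 0.001,
    window_kb: float = 10000.0,
) -> SumstatsTable:
    """Greedy LD clumping: repeatedly take the smallest-p remaining variant
    as an index and discard same-chromosome variants within ``window_kb``
    whose r² with it is >= ``r2_threshold``.  The surviving indices are
    returned sorted by p-value."""
    for rec in table.records:
        if rec.pos < 1 or not rec.chrom:
            raise ValueError(f"variant {rec.variant_id!r} is missing chromosome/position")
    window_bp = window_kb * 1000.0
    remaining = sorted(table.records, key=lambda r: (r.pvalue, r.variant_id))
    survivors: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        survivors.append(index)
        remaining = [
            r
            for r in remaining
            if not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_bp
                and ld.get(index.variant_id, r.variant_id) >= r2_threshold
            )
        ]
    return replace(table, records=tuple(survivors), rejects=())


@dataclass
class HarmonizationResult:
    """Harmonized instruments plus a log of variants dropped with reasons."""

    instruments: tuple[HarmonizedInstrument, ...]
    dropped: tuple[tuple[str, str], ...] = ()  # (variant_id, reason)

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)


def _orient_outcome(
    exp: VariantAssociation,
    out: VariantAssociation,
    margin: float,
) -> Union[tuple[float, Optional[float]], str]:
    """Return (sign, eaf_out aligned to the exposure effect allele) or a
    drop reason string."""
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if _is_palindromic(e_ea, e_oa):
        # allele labels cannot distinguish strand from swap; use frequencies
        if (o_ea, o_oa) == (e_ea, e_oa):
            sign, eaf_out = 1.0, out.eaf
        elif (o_ea, o_oa) == (e_oa, e_ea):
            sign, eaf_out = -1.0, None if out.eaf is None else 1.0 - out.eaf
        else:
            return "incompatible alleles"
        if exp.eaf is None or eaf_out is None:
            return "ambiguous palindrome"
        lo, hi = 0.5 - margin, 0.5 + margin
        if lo <= exp.eaf <= hi or lo <= eaf_out <= hi:
            return "ambiguous palindrome"
        if (exp.eaf < 0.5) != (eaf_out < 0.5):
            # frequencies disagree: the outcome is on the other strand, which
            # for a palindrome is equivalent to a swap
            sign, eaf_out = -sign, 1.0 - eaf_out
        return sign, eaf_out

    candidates = {
        (o_ea, o_oa): (1.0, out.eaf),
        (o_oa, o_ea): (-1.0, None if out.eaf is None else 1.0 - out.eaf),
    }
    try:
        flipped = (_complement(o_ea), _complement(o_oa))
    except KeyError:
        return "incompatible alleles"
    candidates.setdefault(flipped, (1.0, out.eaf))
    candidates.setdefault(
        (flipped[1], flipped[0]), (-1.0, None if out.eaf is None else 1.0 - out.eaf)
    )
    if (e_ea, e_oa) in candidates:
        return candidates[(e_ea, e_oa)]
    return "incompatible alleles"


def harmonize(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    palindrome_eaf_margin: float = 0.08,
) -> HarmonizationResult:
    """Align outcome effects onto the exposure's effect-allele orientation.

    Swapped alleles negate the outcome beta (and reflect its frequency);
    strand flips are recognised by complementing; palindromic (A/T, C/G)
    variants are resolved by allele frequency only when both frequencies lie
    outside ``0.5 ± margin``, and dropped as ambiguous otherwise.
    """
    out_by_id = {r.variant_id: r for r in outcome.records}
    shared = [r for r in exposure.records if r.variant_id in out_by_id]
    if not shared:
        raise SelectionError(
            f"no shared instruments between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )
    instruments: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    for exp in shared:
        out = out_by_id[exp.variant_id]
        oriented = _orient_outcome(exp, out, palindrome_eaf_margin)
        if isinstance(oriented, str):
            dropped.append((exp.variant_id, oriented))
            continue
        sign, eaf_out = oriented
        instruments.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                effect_allele=exp.effect_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=sign * out.beta,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
            )
        )
    return HarmonizationResult(tuple(instruments), tuple(dropped))


@dataclass(frozen=True)
class AttritionStep:
    step: str
    n_in: int
    n_out: int


@dataclass
class SelectionResult:
    """Instruments surviving the full selection chain, with attrition log."""

    instruments: tuple[HarmonizedInstrument, ...]
    attrition: tuple[AttritionStep, ...]
    dropped: tuple[tuple[str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)


def select_instruments(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LDInfo = EMPTY_LD,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """p-filter -> clump -> harmonize -> F-filter, with per-step attrition.

    Raises :class:`SelectionError` naming the step that exhausted the
    candidate set when no instrument survives.
    """
    attrition: list[AttritionStep] = []

    n0 = len(exposure)
    significant = filter_by_pvalue(exposure, config.p_threshold)
    attrition.append(AttritionStep("p_filter", n0, len(significant)))
    if not len(significant):
        raise SelectionError(
            f"no variant passes p < {config.p_threshold:g} (p_filter step, {n0} candidates)"
        )

    clumped = clump(significant, ld, config.clump_r2, config.clump_window_kb)
    attrition.append(AttritionStep("clump", len(significant), len(clumped)))

    harm = harmonize(clumped, outcome, config.palindrome_eaf_margin)
    attrition.append(AttritionStep("harmonize", len(clumped), len(harm)))
    if not len(harm):
        raise SelectionError("all instruments lost at the harmonize step")

    strong = tuple(i for i in harm if not i.f_stat < config.f_min)
    attrition.append(AttritionStep("f_filter", len(harm), len(strong)))
    if not strong:
        raise SelectionError(f"all instruments removed by the F >= {config.f_min:g} filter")

    return SelectionResult(strong, tuple(attrition), harm.dropped)
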