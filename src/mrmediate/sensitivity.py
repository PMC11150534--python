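"""Sensitivity battery for two-sample MR.

Heterogeneity (Cochran's Q with the fixed/random model decision it drives),
directional pleiotropy (the MR-Egger intercept), leave-one-out stability,
and the Steiger directionality test.  The pleiotropy test flags; it never
drops instruments — re-running with an explicit exclusion list is the
caller's decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .estimators import EstimationError, MREstimate, egger, ivw, _q_statistic, _ratios_weights
from .harmonize import HarmonizedInstrument

__all__ = [
    "HeterogeneityResult",
    "LeaveOneOutResult",
    "SteigerResult",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "steiger",
    "write_sensitivity_report",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    q_stat: float
    df: int
    pvalue: float
    model_selected: str  # "fixed" or "random"

    def __post_init__(self) -> None:
        if self.q_stat < 0 or self.df < 1 or not 0 < self.pvalue <= 1:
            raise ValueError("invalid heterogeneity result")


@dataclass(frozen=True)
class LeaveOneOutRow:
    variant_id: str
    estimate: MREstimate


@dataclass(frozen=True)
class LeaveOneOutResult:
    """One IVW re-estimate per omitted instrument.

    ``stable`` is true when every leave-one-out confidence interval reaches
    the same sign conclusion as the full-set estimate (all on the same side
    of zero, or all spanning zero together).  ``flagged`` lists the variants
    whose omission changes that conclusion.
    """

    full: MREstimate
    rows: tuple[LeaveOneOutRow, ...]
    stable: bool
    flagged: tuple[str, ...] = ()


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_true: bool
    pvalue: float

    def __post_init__(self) -> None:
        for r2 in (self.r2_exposure, self.r2_outcome):
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r² {r2} outside [0, 1]")


def cochran_q(insts: Sequence[HarmonizedInstrument]) -> HeterogeneityResult:
    """Cochran's Q over Wald ratios around the fixed-effect IVW mean.

    p is the upper chi-square tail with J−1 df; the result also records the
    fixed/random model the p-value selects (random iff p < 0.05).
    """
    if len(insts) < 2:
        raise EstimationError("Cochran's Q requires at least 2 instruments")
    ratios, weights = _ratios_weights(insts)
    q, p = _q_statistic(ratios, weights)
    return HeterogeneityResult(
        q_stat=q,
        df=len(insts) - 1,
        pvalue=p,
        model_selected="random" if p < 0.05 else "fixed",
    )


def egger_intercept_test(
    insts: Sequence[HarmonizedInstrument],
) -> tuple[float, float, float]:
    """MR-Egger intercept, SE, and p; p < 0.05 flags directional pleiotropy."""
    est = egger(insts)
    assert est.intercept is not None
    return est.intercept, est.intercept_se, est.intercept_p


def leave_one_out(
    insts: Sequence[HarmonizedInstrument], model: str = "auto"
) -> LeaveOneOutResult:
    """Re-fit IVW omitting each instrument in turn.

    All re-fits use the model flavor (fixed/random) selected by the full
    fit, so differences reflect the omitted SNP rather than a model switch.
    """
    if len(insts) < 3:
        raise EstimationError("leave-one-out requires at least 3 instruments")
    full = ivw(insts, model=model)
    flavor = "random" if full.method.endswith("random") else "fixed"

    def conclusion(e: MREstimate) -> int:
        if e.ci_low > 0:
            return 1
        if e.ci_high < 0:
            return -1
        return 0

    target = conclusion(full)
    rows = []
    flagged = []
    for j in range(len(insts)):
        subset = list(insts[:j]) + list(insts[j + 1 :])
        est = ivw(subset, model=flavor)
        rows.append(LeaveOneOutRow(insts[j].variant_id, est))
        if conclusion(est) != target:
            flagged.append(insts[j].variant_id)
    return LeaveOneOutResult(
        full=full, rows=tuple(rows), stable=not flagged, flagged=tuple(flagged)
    )


def _r2_from_t(t: np.ndarray, n: int) -> np.ndarray:
    return t**2 / (t**2 + n - 2)


def steiger(
    insts: Sequence[HarmonizedInstrument], n_exp: int, n_out: int
) -> SteigerResult:
    """Directionality check: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-SNP r² is recovered from the marginal t statistic,
    r² = t² / (t² + n − 2), summed over instruments for each trait.  The
    p-value compares the two summed r² through Fisher's z transform of
    r = sqrt(r²).
    """
    if n_exp <= 2 or n_out <= 2:
        raise ValueError("sample sizes must exceed 2")
    if not insts:
        raise EstimationError("Steiger test requires at least one instrument")
    t_exp = np.array([i.beta_exp / i.se_exp for i in insts])
    t_out = np.array([i.beta_out / i.se_out for i in insts])
    r2_exp = float(np.sum(_r2_from_t(t_exp, n_exp)))
    r2_out = float(np.sum(_r2_from_t(t_out, n_out)))
    if r2_exp > 1 or r2_out > 1:
        raise ValueError("summed r² exceeds 1: inputs are not a valid instrument set")
    z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / math.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    pvalue = 2.0 * float(stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction_true=r2_exp > r2_out,
        pvalue=pvalue,
    )


def write_sensitivity_report(
    path: Union[str, Path],
    heterogeneity: Optional[HeterogeneityResult] = None,
    pleiotropy: Optional[tuple[float, float, float]] = None,
    steiger_result: Optional[SteigerResult] = None,
    loo: Optional[LeaveOneOutResult] = None,
) -> Path:
    """Write one TSV combining the sensitivity battery for a single analysis."""
    path = Path(path)
    lines: list[str] = ["test\tstatistic\tvalue"]
    if heterogeneity is not None:
        lines += [
            f"cochran_q\tQ\t{heterogeneity.q_stat!r}",
            f"cochran_q\tdf\t{heterogeneity.df}",
            f"cochran_q\tp\t{heterogeneity.pvalue!r}",
            f"cochran_q\tmodel_selected\t{heterogeneity.model_selected}",
        ]
    if pleiotropy is not None:
        intercept, se, p = pleiotropy
        lines += [
            f"egger_intercept\tintercept\t{intercept!r}",
            f"egger_intercept\tse\t{se!r}",
            f"egger_intercept\tp\t{p!r}",
        ]
    if steiger_result is not None:
        lines += [
            f"steiger\tr2_exposure\t{steiger_result.r2_exposure!r}",
            f"steiger\tr2_outcome\t{steiger_result.r2_outcome!r}",
            f"steiger\tdirection_true\t{steiger_result.direction_true}",
            f"steiger\tp\t{steiger_result.pvalue!r}",
        ]
    if loo is not None:
        lines.append(f"leave_one_out\tstable\t{loo.stable}")
        if loo.flagged:
            lines.append(f"leave_one_out\tflagged\t{','.join(loo.flagged)}")
        lines.append("")
        lines.append("omitted_snp\tbeta\tse\tci_low\tci_high\tp")
        for row in loo.rows:
            e = row.estimate
            lines.append(
                f"{row.variant_id}\t{e.beta!r}\t{e.se!r}\t{e.ci_low!r}\t{e.ci_high!r}\t{e.pvalue!r}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path
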