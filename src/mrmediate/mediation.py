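"""Two-step mediation MR with the coefficient-product method.

The exposure→mediator effect (β1) and the mediator→outcome effect (β2) are
each estimated by univariable two-sample MR; their product β1·β2 is the
indirect (mediated) effect, with a first-order delta-method SE.  Dividing
by the directly re-estimated total exposure→outcome effect (β3) gives the
proportion mediated.  All arithmetic is on the log-odds / SD scale; odds
ratios are exponentiated only at reporting time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .estimators import MREstimate, ivw
from .harmonize import LDInfo, EMPTY_LD, SelectionConfig, SelectionError, select_instruments
from .sensitivity import (
    HeterogeneityResult,
    LeaveOneOutResult,
    SteigerResult,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    steiger,
)
from .sumstats import SumstatsTable

__all__ = [
    "InconsistentMediationWarning",
    "LegResult",
    "MediationConfig",
    "MediationResult",
    "product_of_coefficients",
    "proportion_mediated",
    "two_step_mediation",
]

_Z95 = 1.96


class InconsistentMediationWarning(UserWarning):
    """Indirect and total effects disagree in sign, or |proportion| > 1."""


def product_of_coefficients(
    beta1: float, se1: float, beta2: float, se2: float
) -> tuple[float, float, tuple[float, float], float]:
    """Indirect effect β1·β2 with first-order delta-method SE.

    Returns ``(indirect, se, (ci_low, ci_high), p)`` where
    se = sqrt(β2²·se1² + β1²·se2²) and p comes from the normal z-test.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    indirect = beta1 * beta2
    se = math.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2)
    ci = (indirect - _Z95 * se, indirect + _Z95 * se)
    p = 2.0 * float(stats.norm.sf(abs(indirect / se))) if se > 0 else 1.0
    return indirect, se, ci, p


def proportion_mediated(indirect: float, beta3: float) -> float:
    """Proportion of the total effect carried by the mediated path,
    indirect / β3 (a fraction; multiply by 100 for reporting).

    Warns on inconsistent mediation (opposite signs, or |proportion| > 1);
    raises when the total effect is exactly zero.
    """
    if beta3 == 0:
        raise ValueError("total effect is zero: proportion mediated undefined")
    proportion = indirect / beta3
    if proportion < 0:
        warnings.warn(
            "indirect and total effects have opposite signs (inconsistent mediation)",
            InconsistentMediationWarning,
            stacklevel=2,
        )
    elif abs(proportion) > 1:
        warnings.warn(
            f"|proportion mediated| = {abs(proportion):.3g} exceeds 1",
            InconsistentMediationWarning,
            stacklevel=2,
        )
    return proportion


@dataclass
class LegResult:
    """One MR leg: its IVW estimate plus the sensitivity battery."""

    name: str
    estimate: MREstimate
    heterogeneity: Optional[HeterogeneityResult] = None
    pleiotropy: Optional[tuple[float, float, float]] = None
    steiger: Optional[SteigerResult] = None
    leave_one_out: Optional[LeaveOneOutResult] = None
    attrition: tuple = ()


@dataclass
class MediationResult:
    """Coefficient-product mediation decomposition on the log scale."""

    exposure: str
    mediator: str
    outcome: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float
    indirect: float
    indirect_se: float
    indirect_ci_low: float
    indirect_ci_high: float
    indirect_p: float
    proportion: float
    direct: float
    legs: dict[str, LegResult] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.indirect != self.beta1 * self.beta2:
            raise ValueError("indirect effect must equal beta1 * beta2 exactly")
        if self.direct != self.beta3 - self.indirect:
            raise ValueError("direct effect must equal beta3 - indirect exactly")

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "beta3": self.beta3,
            "se3": self.se3,
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "indirect_ci_low": self.indirect_ci_low,
            "indirect_ci_high": self.indirect_ci_high,
            "indirect_p": self.indirect_p,
            "direct": self.direct,
            "proportion_pct": 100.0 * self.proportion,
            "n_snp_leg1": self.legs["exposure_mediator"].estimate.n_snp
            if "exposure_mediator" in self.legs
            else None,
            "n_snp_leg2": self.legs["mediator_outcome"].estimate.n_snp
            if "mediator_outcome" in self.legs
            else None,
            "n_snp_leg3": self.legs["exposure_outcome"].estimate.n_snp
            if "exposure_outcome" in self.legs
            else None,
            "warnings": ";".join(self.warnings),
        }


@dataclass(frozen=True)
class MediationConfig:
    """Per-leg selection thresholds and shared clumping/strength settings.

    Nutrient-style exposures use genome-wide significance (5e−08); the
    mediator-as-exposure leg uses the relaxed 5e−06 threshold so immune-type
    mediators retain enough instruments.
    """

    exposure_p_threshold: float = 5e-8
    mediator_p_threshold: float = 5e-6
    clump_r2: float = 0.001
    clump_window_kb: float = 10000.0
    palindrome_eaf_margin: float = 0.08
    f_min: float = 10.0
    ivw_model: str = "auto"

    def selection(self, p_threshold: float) -> SelectionConfig:
        return SelectionConfig(
            p_threshold=p_threshold,
            clump_r2=self.clump_r2,
            clump_window_kb=self.clump_window_kb,
            palindrome_eaf_margin=self.palindrome_eaf_margin,
            f_min=self.f_min,
        )


def _median_n(table: SumstatsTable) -> int:
    ns = sorted(r.n for r in table.records)
    return ns[len(ns) // 2]


def _run_leg(
    name: str,
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LDInfo,
    selection: SelectionConfig,
    ivw_model: str,
) -> LegResult:
    try:
        selected = select_instruments(exposure, outcome, ld, selection)
    except SelectionError as exc:
        raise SelectionError(f"leg {name!r} ({exposure.trait_id} -> {outcome.trait_id}): {exc}")
    insts = selected.instruments
    estimate = ivw(
        insts,
        model=ivw_model,
        exposure=exposure.trait_id,
        outcome=outcome.trait_id,
        outcome_binary=outcome.trait_type == "binary",
    )
    het = cochran_q(insts) if len(insts) >= 2 else None
    pleio = egger_intercept_test(insts) if len(insts) >= 3 else None
    loo = leave_one_out(insts, model=ivw_model) if len(insts) >= 3 else None
    st = steiger(insts, _median_n(exposure), _median_n(outcome))
    return LegResult(
        name=name,
        estimate=estimate,
        heterogeneity=het,
        pleiotropy=pleio,
        steiger=st,
        leave_one_out=loo,
        attrition=selected.attrition,
    )


def two_step_mediation(
    exposure: SumstatsTable,
    mediator: SumstatsTable,
    outcome: SumstatsTable,
    ld: LDInfo = EMPTY_LD,
    config: MediationConfig = MediationConfig(),
) -> MediationResult:
    """Run the three MR legs and assemble the mediation decomposition.

    Leg 1 (exposure→mediator, β1) and leg 3 (exposure→outcome, β3) select
    instruments at the exposure threshold; leg 2 (mediator→outcome, β2)
    treats the mediator as the exposure at its own, typically relaxed,
    threshold.  β3 is re-estimated directly, never reconstructed, so
    direct + indirect = β3 holds by construction.
    """
    leg1 = _run_leg(
        "exposure_mediator",
        exposure,
        mediator,
        ld,
        config.selection(config.exposure_p_threshold),
        config.ivw_model,
    )
    leg2 = _run_leg(
        "mediator_outcome",
        mediator,
        outcome,
        ld,
        config.selection(config.mediator_p_threshold),
        config.ivw_model,
    )
    leg3 = _run_leg(
        "exposure_outcome",
        exposure,
        outcome,
        ld,
        config.selection(config.exposure_p_threshold),
        config.ivw_model,
    )

    beta1, se1 = leg1.estimate.beta, leg1.estimate.se
    beta2, se2 = leg2.estimate.beta, leg2.estimate.se
    beta3, se3 = leg3.estimate.beta, leg3.estimate.se
    indirect, indirect_se, (ci_low, ci_high), indirect_p = product_of_coefficients(
        beta1, se1, beta2, se2
    )
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", InconsistentMediationWarning)
        proportion = proportion_mediated(indirect, beta3)
        notes.extend(str(w.message) for w in caught)

    return MediationResult(
        exposure=exposure.trait_id,
        mediator=mediator.trait_id,
        outcome=outcome.trait_id,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta3=beta3,
        se3=se3,
        indirect=indirect,
        indirect_se=indirect_se,
        indirect_ci_low=ci_low,
        indirect_ci_high=ci_high,
        indirect_p=indirect_p,
        proportion=proportion,
        direct=beta3 - indirect,
        legs={"exposure_mediator": leg1, "mediator_outcome": leg2, "exposure_outcome": leg3},
        warnings=tuple(notes),
    )
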