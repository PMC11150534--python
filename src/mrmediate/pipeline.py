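"""Orchestration of the full analysis flow.

``run_total_effects`` screens every exposure × outcome pair with the
configured estimators and the sensitivity battery; ``run_mediation_screen``
admits mediators whose exposure→mediator and mediator→outcome IVW legs are
both significant and assembles the coefficient-product decomposition for
each.  Failures in one pair are logged, never fatal — a wide phenotype
screen must tolerate pairs with no usable instruments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .estimators import EstimationError, MREstimate, egger, ivw, weighted_median, weighted_mode
from .harmonize import EMPTY_LD, LDInfo, SelectionConfig, SelectionError, select_instruments
from .mediation import MediationConfig, MediationResult, two_step_mediation
from .sensitivity import cochran_q, egger_intercept_test, leave_one_out, steiger
from .sumstats import SumstatsTable

logger = logging.getLogger("mrmediate")

__all__ = [
    "AnalysisConfig",
    "MediationScreenResult",
    "TotalEffectsResult",
    "run_mediation_screen",
    "run_total_effects",
    "write_manifest",
]

_ALL_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-level settings shared by the screens and the CLI."""

    p_threshold_exposure: float = 5e-8
    p_threshold_mediator: float = 5e-6
    clump_r2: float = 0.001
    clump_window_kb: float = 10000.0
    palindrome_eaf_margin: float = 0.08
    f_min: float = 10.0
    methods: tuple[str, ...] = _ALL_METHODS
    ivw_model: str = "auto"
    n_boot: int = 1000
    seed: int = 0
    leg_alpha: float = 0.05
    multiple_testing: str = "none"  # none | bonferroni | fdr_bh

    def __post_init__(self) -> None:
        for thr in (self.p_threshold_exposure, self.p_threshold_mediator):
            if not 0.0 < thr < 1.0:
                raise ValueError(f"p-threshold must lie in (0, 1), got {thr}")
        unknown = set(self.methods) - set(_ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.multiple_testing not in ("none", "bonferroni", "fdr_bh"):
            raise ValueError(f"unknown multiple_testing mode {self.multiple_testing!r}")

    def selection(self, p_threshold: Optional[float] = None) -> SelectionConfig:
        return SelectionConfig(
            p_threshold=self.p_threshold_exposure if p_threshold is None else p_threshold,
            clump_r2=self.clump_r2,
            clump_window_kb=self.clump_window_kb,
            palindrome_eaf_margin=self.palindrome_eaf_margin,
            f_min=self.f_min,
        )

    def mediation(self) -> MediationConfig:
        return MediationConfig(
            exposure_p_threshold=self.p_threshold_exposure,
            mediator_p_threshold=self.p_threshold_mediator,
            clump_r2=self.clump_r2,
            clump_window_kb=self.clump_window_kb,
            palindrome_eaf_margin=self.palindrome_eaf_margin,
            f_min=self.f_min,
            ivw_model=self.ivw_model,
        )


@dataclass
class PairFailure:
    exposure: str
    outcome: str
    stage: str
    message: str


@dataclass
class TotalEffectsResult:
    estimates: list[MREstimate]
    sensitivity: dict[tuple[str, str], dict]
    attrition: dict[tuple[str, str], tuple]
    failures: list[PairFailure] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            rows.append(
                {
                    "exposure": e.exposure,
                    "outcome": e.outcome,
                    "method": e.method,
                    "n_snp": e.n_snp,
                    "beta": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.pvalue,
                }
            )
        return pd.DataFrame(rows)


def _estimate_all_methods(
    insts, config: AnalysisConfig, seed: int, **meta
) -> list[MREstimate]:
    out: list[MREstimate] = []
    for i, method in enumerate(config.methods):
        try:
            if method == "ivw":
                out.append(ivw(insts, model=config.ivw_model, **meta))
            elif method == "egger":
                out.append(egger(insts, **meta))
            elif method == "weighted_median":
                out.append(
                    weighted_median(insts, n_boot=config.n_boot, seed=seed + i, **meta)
                )
            elif method == "weighted_mode":
                out.append(weighted_mode(insts, n_boot=config.n_boot, seed=seed + i, **meta))
        except EstimationError as exc:
            logger.info("method %s skipped for %s: %s", method, meta, exc)
    return out


def run_total_effects(
    exposures: Sequence[SumstatsTable],
    outcomes: Sequence[SumstatsTable],
    config: AnalysisConfig = AnalysisConfig(),
    ld: LDInfo = EMPTY_LD,
) -> TotalEffectsResult:
    """Estimate every exposure × outcome pair with all configured methods.

    Pairs that fail instrument selection are recorded in ``failures`` and
    skipped.  Raises only when *every* pair fails.
    """
    if not exposures or not outcomes:
        raise ValueError("need at least one exposure and one outcome")
    result = TotalEffectsResult(estimates=[], sensitivity={}, attrition={})
    for exposure in exposures:
        for outcome in outcomes:
            key = (exposure.trait_id, outcome.trait_id)
            try:
                selected = select_instruments(exposure, outcome, ld, config.selection())
            except SelectionError as exc:
                result.failures.append(PairFailure(*key, "selection", str(exc)))
                logger.warning("pair %s: %s", key, exc)
                continue
            insts = selected.instruments
            result.attrition[key] = selected.attrition
            meta = {
                "exposure": exposure.trait_id,
                "outcome": outcome.trait_id,
                "outcome_binary": outcome.trait_type == "binary",
            }
            result.estimates.extend(
                _estimate_all_methods(insts, config, config.seed, **meta)
            )
            sens: dict = {}
            if len(insts) >= 2:
                sens["heterogeneity"] = cochran_q(insts)
            if len(insts) >= 3:
                try:
                    sens["pleiotropy"] = egger_intercept_test(insts)
                except EstimationError:
                    pass
                sens["leave_one_out"] = leave_one_out(insts, model=config.ivw_model)
            n_exp = sorted(r.n for r in exposure.records)[len(exposure) // 2]
            n_out = sorted(r.n for r in outcome.records)[len(outcome) // 2]
            sens["steiger"] = steiger(insts, n_exp, n_out)
            result.sensitivity[key] = sens
    if not result.estimates:
        raise SelectionError(
            f"all {len(result.failures)} exposure-outcome pairs failed instrument selection"
        )
    return result


@dataclass
class ScreenedOut:
    mediator: str
    failing_leg: str
    pvalue: Optional[float]


@dataclass
class MediationScreenResult:
    total: MREstimate
    rows: list[MediationResult]
    screened_out: list[ScreenedOut] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.rows])


def _adjusted(pvalues: list[float], mode: str) -> list[float]:
    if not pvalues or mode == "none":
        return pvalues
    return list(multipletests(pvalues, method=mode)[1])


def run_mediation_screen(
    exposure: SumstatsTable,
    mediators: Sequence[SumstatsTable],
    outcome: SumstatsTable,
    config: AnalysisConfig = AnalysisConfig(),
    ld: LDInfo = EMPTY_LD,
) -> MediationScreenResult:
    """Two-step screen: a mediator earns a mediation row when both of its
    legs (exposure→mediator and mediator→outcome) are IVW-significant at
    ``leg_alpha`` (raw p by default; Bonferroni/FDR optional)."""
    total = ivw(
        select_instruments(exposure, outcome, ld, config.selection()).instruments,
        model=config.ivw_model,
        exposure=exposure.trait_id,
        outcome=outcome.trait_id,
        outcome_binary=outcome.trait_type == "binary",
    )

    candidates = []
    screened: list[ScreenedOut] = []
    for mediator in mediators:
        if mediator.trait_id == outcome.trait_id:
            screened.append(ScreenedOut(mediator.trait_id, "degenerate_self_mediation", None))
            logger.warning("mediator %r is the outcome itself: skipped", mediator.trait_id)
            continue
        try:
            leg1 = ivw(
                select_instruments(exposure, mediator, ld, config.selection()).instruments,
                model=config.ivw_model,
            )
            leg2 = ivw(
                select_instruments(
                    mediator, outcome, ld, config.selection(config.p_threshold_mediator)
                ).instruments,
                model=config.ivw_model,
            )
        except SelectionError as exc:
            screened.append(ScreenedOut(mediator.trait_id, "selection", None))
            logger.warning("mediator %r: %s", mediator.trait_id, exc)
            continue
        candidates.append((mediator, leg1.pvalue, leg2.pvalue))

    p1_adj = _adjusted([c[1] for c in candidates], config.multiple_testing)
    p2_adj = _adjusted([c[2] for c in candidates], config.multiple_testing)

    rows: list[MediationResult] = []
    for (mediator, _, _), p1, p2 in zip(candidates, p1_adj, p2_adj):
        if p1 >= config.leg_alpha:
            screened.append(ScreenedOut(mediator.trait_id, "exposure_mediator", p1))
            continue
        if p2 >= config.leg_alpha:
            screened.append(ScreenedOut(mediator.trait_id, "mediator_outcome", p2))
            continue
        rows.append(two_step_mediation(exposure, mediator, outcome, ld, config.mediation()))
    return MediationScreenResult(total=total, rows=rows, screened_out=screened)


def write_manifest(
    path: Union[str, Path],
    config,
    seed: int,
    counts: Optional[dict] = None,
    inputs: Optional[dict] = None,
) -> Path:
    """Write a JSON manifest sufficient to re-run the analysis bit-identically."""
    path = Path(path)
    payload = {
        "software": "mrmediate",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config),
        "counts": counts or {},
        "inputs": inputs or {},
    }
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
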