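"""Causal-effect estimators for two-sample MR on harmonized instruments.

Implements the Wald ratio, inverse-variance-weighted (IVW) meta-analysis
with a fixed/random switch driven by Cochran's Q, MR-Egger regression with
a free intercept, and the weighted median and weighted mode estimators.
All confidence intervals are normal-theory (beta ± 1.96 se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

__all__ = [
    "EstimationError",
    "MREstimate",
    "egger",
    "ivw",
    "wald_ratio",
    "weighted_median",
    "weighted_mode",
]

_Z95 = 1.96


class EstimationError(ValueError):
    """Estimator preconditions violated (too few or degenerate instruments)."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from one method.

    ``beta`` is on the log-odds scale for binary outcomes and in SD units
    otherwise.  The intercept triple is populated only for MR-Egger.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    exposure: str = ""
    outcome: str = ""
    outcome_binary: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence interval does not bracket the estimate")
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")


def _estimate(method: str, beta: float, se: float, n_snp: int, pvalue=None, **meta) -> MREstimate:
    if pvalue is None:
        pvalue = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else 1.0
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pvalue=float(pvalue),
        n_snp=n_snp,
        **meta,
    )


def wald_ratio(inst: HarmonizedInstrument, **meta) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order SE."""
    if inst.beta_exp == 0:
        raise EstimationError(f"{inst.variant_id}: beta_exp is zero, Wald ratio undefined")
    return _estimate("wald", inst.ratio, inst.ratio_se, 1, **meta)


def _ratios_weights(insts: Sequence[HarmonizedInstrument]) -> tuple[np.ndarray, np.ndarray]:
    if any(i.beta_exp == 0 for i in insts):
        raise EstimationError("instrument with beta_exp = 0 cannot contribute a Wald ratio")
    ratios = np.array([i.ratio for i in insts])
    weights = np.array([1.0 / i.ratio_se**2 for i in insts])
    return ratios, weights


def _q_statistic(ratios: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Cochran's Q around the fixed-effect IVW mean, and its chi² p-value."""
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    q = float(np.sum(weights * (ratios - beta) ** 2))
    df = len(ratios) - 1
    p = float(stats.chi2.sf(q, df)) if df >= 1 else 1.0
    return q, p


def ivw(insts: Sequence[HarmonizedInstrument], model: str = "auto", **meta) -> MREstimate:
    """Inverse-variance-weighted estimate over Wald ratios.

    ``model`` is ``"fixed"``, ``"random"`` (multiplicative overdispersion,
    floored so the random SE is never narrower than the fixed SE), or
    ``"auto"``, which picks random effects when Cochran's Q has p < 0.05 and
    fixed effects otherwise.  A single instrument degenerates to the Wald
    ratio.
    """
    if model not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if len(insts) == 0:
        raise EstimationError("IVW requires at least one instrument")
    if len(insts) == 1:
        return wald_ratio(insts[0], **meta)

    ratios, weights = _ratios_weights(insts)
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    se_fixed = float(np.sum(weights) ** -0.5)
    q, q_p = _q_statistic(ratios, weights)
    if model == "auto":
        model = "random" if q_p < 0.05 else "fixed"
    if model == "random":
        inflation = max(1.0, math.sqrt(q / (len(insts) - 1)))
        se = se_fixed * inflation
    else:
        se = se_fixed
    return _estimate(f"ivw_{model}", beta, se, len(insts), **meta)


def egger(insts: Sequence[HarmonizedInstrument], **meta) -> MREstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Instruments are first oriented so every beta_exp > 0.  Weights are
    1/se_out²; standard errors use multiplicative overdispersion floored at
    1; p-values use the t distribution with J−2 degrees of freedom.  The
    intercept triple feeds the directional-pleiotropy test.
    """
    if len(insts) < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    if any(i.beta_exp == 0 for i in insts):
        raise EstimationError("instrument with beta_exp = 0 cannot be oriented")
    sign = np.array([1.0 if i.beta_exp > 0 else -1.0 for i in insts])
    x = sign * np.array([i.beta_exp for i in insts])
    y = sign * np.array([i.beta_out for i in insts])
    w = np.array([1.0 / i.se_out**2 for i in insts])
    if np.ptp(x) == 0:
        raise EstimationError("zero spread in exposure effects: Egger fit is singular")

    # closed-form weighted least squares with intercept
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    df = len(insts) - 2
    scale = float(np.sum(w * resid**2) / df)  # overdispersion factor
    phi = max(1.0, scale)
    slope_se = math.sqrt(phi / sxx)
    intercept_se = math.sqrt(phi * (1.0 / sw + xbar**2 / sxx))
    slope_p = 2.0 * float(stats.t.sf(abs(slope / slope_se), df))
    intercept_p = 2.0 * float(stats.t.sf(abs(intercept / intercept_se), df))
    return _estimate(
        "egger",
        slope,
        slope_se,
        len(insts),
        pvalue=slope_p,
        intercept=intercept,
        intercept_se=intercept_se,
        intercept_p=intercept_p,
        **meta,
    )


def _interpolated_weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w  # cumulative midpoint positions
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _parametric_bootstrap_se(
    insts: Sequence[HarmonizedInstrument],
    statistic,
    n_boot: int,
    seed: Optional[int],
) -> float:
    """SE of ``statistic(ratios, weights)`` under per-instrument normal
    resampling of beta_exp and beta_out around their observed values."""
    rng = np.random.default_rng(seed)
    be = np.array([i.beta_exp for i in insts])
    se_e = np.array([i.se_exp for i in insts])
    bo = np.array([i.beta_out for i in insts])
    se_o = np.array([i.se_out for i in insts])
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bexp = rng.normal(be, se_e)
        bout = rng.normal(bo, se_o)
        bexp[bexp == 0] = 1e-12
        ratios = bout / bexp
        weights = (np.abs(bexp) / se_o) ** 2
        draws[b] = statistic(ratios, weights)
    return float(np.std(draws, ddof=1))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    **meta,
) -> MREstimate:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    The estimate interpolates the IVW-weight cumulative distribution of the
    sorted ratios at probability 0.5; it is consistent when instruments
    carrying at least half the weight are valid.
    """
    if len(insts) < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ratios, weights = _ratios_weights(insts)
    beta = _interpolated_weighted_median(ratios, weights)
    se = _parametric_bootstrap_se(insts, _interpolated_weighted_median, n_boot, seed)
    return _estimate("weighted_median", beta, se, len(insts), **meta)


def _kernel_bandwidth(ratios: np.ndarray, bandwidth_factor: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return bandwidth_factor * 0.9 * spread * len(ratios) ** (-1 / 5)


def _weighted_mode_point(ratios, weights, bandwidth_factor=1.0, n_grid=2048):
    h = _kernel_bandwidth(np.asarray(ratios), bandwidth_factor)
    if h == 0:  # all ratios identical
        return float(ratios[0])
    w = np.asarray(weights) / np.sum(weights)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    dens = np.sum(w * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2), axis=1)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    insts: Sequence[HarmonizedInstrument],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    **meta,
) -> MREstimate:
    """Weighted mode: argmax of a weighted Gaussian kernel density of the
    Wald ratios (Silverman-style bandwidth scaled by ``bandwidth_factor``),
    with the same parametric-bootstrap SE as the weighted median.
    """
    if len(insts) < 3:
        raise EstimationError("weighted mode requires at least 3 instruments")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    ratios, weights = _ratios_weights(insts)
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)
    se = _parametric_bootstrap_se(
        insts,
        lambda r, w: _weighted_mode_point(r, w, bandwidth_factor),
        n_boot,
        seed,
    )
    return _estimate("weighted_mode", beta, se, len(insts), **meta)
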