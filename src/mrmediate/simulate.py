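"""Synthetic GWAS summary-statistic triples with known causal structure.

The generator draws individual-level genotypes for three non-overlapping
cohorts (honoring the two-sample design) and produces marginal per-SNP
summary statistics for an exposure X, a mediator M, and an outcome Y under
the structural model

    X = sum_j a_j G_j + e_x
    M = beta1 * X + sum_j b_j G_j + e_m
    Y = direct * X + beta2 * M + sum_j q_j G_j + e_y

where the a_j are the exposure's instruments, the b_j give the mediator its
own instruments (without them the mediator→outcome leg would have nothing
to select), and q_j ~ Normal(pleiotropy_mean, pleiotropy_sd) are direct
SNP→outcome pleiotropic effects (zero by default).  Continuous traits are
scaled to approximately unit variance and analysed by per-SNP least
squares; a binary outcome is generated by thresholding the liability
``direct*X + beta2*M + sum q_j G_j + logistic noise`` at the configured
prevalence, and analysed by per-SNP logistic regression, so its betas are
log odds ratios.

A fast direct-summary mode (:func:`simulate_summary`,
:func:`simulate_instruments`) samples the marginal estimates straight from
their sampling distribution; it is used for large calibration suites where
individual-level realism is not needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument, LDInfo
from .sumstats import SumstatsTable, VariantAssociation

__all__ = [
    "LDBlocks",
    "SimTriple",
    "SimulationConfig",
    "simulate_instruments",
    "simulate_ld",
    "simulate_summary",
    "simulate_triple",
]

# effect/other allele pairs that are never strand-ambiguous
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T"))


@dataclass(frozen=True)
class LDBlocks:
    """Block-diagonal LD: ``n_blocks`` groups with constant within-block r²."""

    n_blocks: int
    r2: float

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.r2 < 1.0:
            raise ValueError("within-block r² must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic triple.

    Defaults describe a well-powered continuous-outcome study: 20 exposure
    instruments and 20 mediator instruments with per-allele effects strong
    enough to pass genome-wide selection at n = 20,000 per cohort, a
    protective exposure→mediator path (β1 = −0.15), a harmful
    mediator→outcome path (β2 = 0.17), a direct effect of −0.14, and no
    pleiotropy.  ``outcome_binary`` switches to a liability-threshold
    disease outcome at ``prevalence``.
    """

    n_snp_instrument: int = 20
    n_snp_instrument_mediator: int = 20
    n_snp_null: int = 60
    maf_range: tuple[float, float] = (0.15, 0.5)
    instrument_effect_range: tuple[float, float] = (0.12, 0.20)
    beta1: float = -0.15
    beta2: float = 0.17
    direct_effect: float = -0.14
    mediator_pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exp: int = 20000
    n_med: int = 20000
    n_out: int = 20000
    outcome_binary: bool = False
    prevalence: float = 0.063
    ld_blocks: Optional[LDBlocks] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp_instrument < 0 or self.n_snp_instrument_mediator < 0 or self.n_snp_null < 0:
            raise ValueError("SNP counts must be non-negative")
        if self.n_snp_instrument + self.n_snp_instrument_mediator + self.n_snp_null < 1:
            raise ValueError("at least one variant is required")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if min(self.n_exp, self.n_med, self.n_out) < 100:
            raise ValueError("cohort sizes must be >= 100")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.instrument_effect_range[0] < 0 or (
            self.instrument_effect_range[0] > self.instrument_effect_range[1]
        ):
            raise ValueError("instrument_effect_range must be ordered and non-negative")

    @property
    def n_snp_total(self) -> int:
        return self.n_snp_instrument + self.n_snp_instrument_mediator + self.n_snp_null

    @property
    def beta3(self) -> float:
        """Implied total exposure→outcome effect, direct + β1·β2."""
        return self.direct_effect + self.beta1 * self.beta2


@dataclass
class SimTriple:
    exposure: SumstatsTable
    mediator: SumstatsTable
    outcome: SumstatsTable
    ld: LDInfo
    truth: dict


# ---------------------------------------------------------------------------
# variant layout


@dataclass(frozen=True)
class _Layout:
    ids: tuple[str, ...]
    chrom: tuple[str, ...]
    pos: tuple[int, ...]
    maf: np.ndarray
    block: np.ndarray  # block index per SNP, -1 when unlinked
    ea: tuple[str, ...]
    oa: tuple[str, ...]


def _layout(config: SimulationConfig, rng: np.random.Generator) -> _Layout:
    m = config.n_snp_total
    ids = tuple(f"rs{1000 + i}" for i in range(m))
    maf = rng.uniform(*config.maf_range, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = tuple(_ALLELE_PAIRS[i][0] for i in pair_idx)
    oa = tuple(_ALLELE_PAIRS[i][1] for i in pair_idx)

    chrom: list[str] = []
    pos: list[int] = []
    block = np.full(m, -1, dtype=int)
    if config.ld_blocks is None:
        # spread variants far apart (one per 25 Mb, cycling chromosomes)
        for i in range(m):
            chrom.append(str(1 + i % 22))
            pos.append(1_000_000 + 25_000_000 * (i // 22))
    else:
        nb = config.ld_blocks.n_blocks
        per = math.ceil(m / nb)
        for i in range(m):
            b = i // per
            within = i % per
            block[i] = b
            chrom.append(str(1 + b % 22))
            # blocks 50 Mb apart, members 10 kb apart (inside the clump window)
            pos.append(1_000_000 + 50_000_000 * (b // 22) + 10_000 * within)
        # members of a block share a frequency so the copy construction below
        # yields the configured r²
        for b in range(nb):
            maf[block == b] = maf[block == b][0]
    return _Layout(ids, tuple(chrom), tuple(pos), maf, block, ea, oa)


def simulate_ld(config: SimulationConfig) -> LDInfo:
    """LD table implied by the configured block structure (empty when none)."""
    rng = np.random.default_rng(config.seed)
    layout = _layout(config, rng)
    info = LDInfo()
    if config.ld_blocks is None:
        return info
    for b in range(config.ld_blocks.n_blocks):
        members = [layout.ids[i] for i in np.flatnonzero(layout.block == b)]
        for i, a in enumerate(members):
            for c in members[i + 1 :]:
                info.set(a, c, config.ld_blocks.r2)
    return info


# ---------------------------------------------------------------------------
# genotypes and marginal regressions


def _draw_genotypes(
    n: int, layout: _Layout, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    m = len(layout.ids)
    if config.ld_blocks is None or config.ld_blocks.r2 == 0:
        geno = rng.binomial(2, layout.maf, size=(n, m)).astype(np.float64)
    else:
        # haplotype copy construction: each SNP copies a block tag allele
        # with probability tau, giving pairwise allelic correlation tau² and
        # genotype r² ≈ tau⁴ = configured r²
        tau = config.ld_blocks.r2**0.25
        geno = np.empty((n, m))
        copy = rng.random(size=(2, n, m)) < tau
        indep = rng.random(size=(2, n, m)) < layout.maf
        nb = config.ld_blocks.n_blocks
        for b in range(nb):
            members = np.flatnonzero(layout.block == b)
            f = layout.maf[members[0]]
            tag = rng.random(size=(2, n, 1)) < f
            hap = np.where(copy[:, :, members], tag, indep[:, :, members])
            geno[:, members] = hap.sum(axis=0)
        unlinked = np.flatnonzero(layout.block < 0)
        if unlinked.size:
            geno[:, unlinked] = (
                indep[0][:, unlinked].astype(np.float64) + indep[1][:, unlinked]
            )
    # avoid monomorphic columns, which have no defined marginal regression
    mono = np.flatnonzero(np.ptp(geno, axis=0) == 0)
    for j in mono:
        geno[rng.integers(0, n), j] = 1.0
    return geno


def _linear_marginal(
    geno: np.ndarray, trait: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple linear regression (slope, SE, two-sided p)."""
    n = trait.shape[0]
    gc = geno - geno.mean(axis=0)
    yc = trait - trait.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    beta = sxy / sxx
    rss = np.dot(yc, yc) - beta * sxy
    sigma2 = np.maximum(rss, 1e-300) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return beta, se, np.clip(p, 1e-300, 1.0)


def _logistic_marginal(
    geno: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression (intercept + allele count) by vectorised
    Newton–Raphson across SNPs; returns (log-OR, SE, two-sided p)."""
    n, m = geno.shape
    ybar = y.mean()
    b0 = np.full(m, math.log(ybar / (1 - ybar)))
    b1 = np.zeros(m)
    yv = y[:, None]
    s00 = s01 = s11 = None
    for _ in range(max_iter):
        eta = b0[None, :] + geno * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = yv - mu
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", geno, r)
        s00 = w.sum(axis=0)
        s01 = np.einsum("ij,ij->j", geno, w)
        s11 = np.einsum("ij,ij->j", geno * geno, w)
        det = s00 * s11 - s01**2
        db0 = (s11 * g0 - s01 * g1) / det
        db1 = (-s01 * g0 + s00 * g1) / det
        b0 += db0
        b1 += db1
        if max(np.abs(db0).max(), np.abs(db1).max()) < tol:
            break
    se = np.sqrt(s00 / det)
    z = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return b1, se, np.clip(p, 1e-300, 1.0)


def _build_table(
    trait_id: str,
    trait_type: str,
    layout: _Layout,
    beta: np.ndarray,
    se: np.ndarray,
    p: np.ndarray,
    eaf: np.ndarray,
    n: int,
) -> SumstatsTable:
    records = tuple(
        VariantAssociation(
            variant_id=layout.ids[j],
            chrom=layout.chrom[j],
            pos=layout.pos[j],
            effect_allele=layout.ea[j],
            other_allele=layout.oa[j],
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(p[j]),
            n=n,
        )
        for j in range(len(layout.ids))
    )
    return SumstatsTable(trait_id=trait_id, trait_type=trait_type, records=records)


def _structural_effects(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP effect vectors (a on X, b on M, p_med on M, q on Y)."""
    m = config.n_snp_total
    k_exp = config.n_snp_instrument
    k_med = config.n_snp_instrument_mediator
    lo, hi = config.instrument_effect_range

    a = np.zeros(m)
    a[:k_exp] = rng.uniform(lo, hi, size=k_exp) * rng.choice([-1.0, 1.0], size=k_exp)
    b = np.zeros(m)
    b[k_exp : k_exp + k_med] = rng.uniform(lo, hi, size=k_med) * rng.choice(
        [-1.0, 1.0], size=k_med
    )
    p_med = np.zeros(m)
    if config.mediator_pleiotropy_sd > 0:
        p_med[:k_exp] = rng.normal(0.0, config.mediator_pleiotropy_sd, size=k_exp)
    q = np.zeros(m)
    if config.pleiotropy_mean != 0 or config.pleiotropy_sd > 0:
        # directional pleiotropy is defined relative to the exposure-raising
        # allele (the orientation MR-Egger uses), not the arbitrary coding
        q[:k_exp] = np.sign(a[:k_exp]) * rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=k_exp
        )
    return a, b, p_med, q


def _genetic_variance(effects: np.ndarray, maf: np.ndarray) -> float:
    return float(np.sum(effects**2 * 2.0 * maf * (1.0 - maf)))


def simulate_triple(config: SimulationConfig) -> SimTriple:
    """Generate (exposure, mediator, outcome) GWAS tables, LD, and truth.

    Same seed ⇒ byte-identical output.  The truth record carries the
    structural coefficients, the per-SNP effects, and the implied total
    effect β3 = direct + β1·β2.
    """
    rng = np.random.default_rng(config.seed)
    layout = _layout(config, rng)
    a, b, p_med, q = _structural_effects(config, rng)
    maf = layout.maf

    var_gx = _genetic_variance(a, maf)
    sd_ex = math.sqrt(max(0.05, 1.0 - var_gx))
    var_gm = _genetic_variance(b, maf) + _genetic_variance(p_med, maf)
    sd_em = math.sqrt(max(0.05, 1.0 - config.beta1**2 - var_gm))
    var_y_struct = (
        config.direct_effect**2
        + config.beta2**2
        + 2.0 * config.direct_effect * config.beta2 * config.beta1
        + _genetic_variance(q, maf)
    )
    sd_ey = math.sqrt(max(0.05, 1.0 - var_y_struct))

    def make_x(geno: np.ndarray, n: int) -> np.ndarray:
        return geno @ a + rng.normal(0.0, sd_ex, size=n)

    def make_m(geno: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
        return config.beta1 * x + geno @ (b + p_med) + rng.normal(0.0, sd_em, size=n)

    # cohort 1: exposure GWAS
    g1 = _draw_genotypes(config.n_exp, layout, config, rng)
    x1 = make_x(g1, config.n_exp)
    beta_x, se_x, p_x = _linear_marginal(g1, x1)
    exposure = _build_table(
        "exposure", "continuous", layout, beta_x, se_x, p_x, g1.mean(axis=0) / 2.0, config.n_exp
    )

    # cohort 2: mediator GWAS
    g2 = _draw_genotypes(config.n_med, layout, config, rng)
    x2 = make_x(g2, config.n_med)
    m2 = make_m(g2, x2, config.n_med)
    beta_m, se_m, p_m = _linear_marginal(g2, m2)
    mediator = _build_table(
        "mediator", "continuous", layout, beta_m, se_m, p_m, g2.mean(axis=0) / 2.0, config.n_med
    )

    # cohort 3: outcome GWAS
    g3 = _draw_genotypes(config.n_out, layout, config, rng)
    x3 = make_x(g3, config.n_out)
    m3 = make_m(g3, x3, config.n_out)
    eta = config.direct_effect * x3 + config.beta2 * m3 + g3 @ q
    if config.outcome_binary:
        # logistic liability noise makes the per-SNP logistic fits estimate
        # the structural coefficients on the log-odds scale
        liability = eta + rng.logistic(0.0, 1.0, size=config.n_out)
        threshold = np.quantile(liability, 1.0 - config.prevalence)
        y3 = (liability > threshold).astype(np.float64)
        beta_y, se_y, p_y = _logistic_marginal(g3, y3)
        trait_type = "binary"
    else:
        y3 = eta + rng.normal(0.0, sd_ey, size=config.n_out)
        beta_y, se_y, p_y = _linear_marginal(g3, y3)
        trait_type = "continuous"
    outcome = _build_table(
        "outcome", trait_type, layout, beta_y, se_y, p_y, g3.mean(axis=0) / 2.0, config.n_out
    )

    truth = {
        "beta1": config.beta1,
        "beta2": config.beta2,
        "direct_effect": config.direct_effect,
        "beta3": config.beta3,
        "proportion_mediated": (config.beta1 * config.beta2) / config.beta3
        if config.beta3 != 0
        else None,
        "exposure_instruments": list(layout.ids[: config.n_snp_instrument]),
        "mediator_instruments": list(
            layout.ids[
                config.n_snp_instrument : config.n_snp_instrument
                + config.n_snp_instrument_mediator
            ]
        ),
        "a": a.tolist(),
        "b": b.tolist(),
        "pleiotropy_outcome": q.tolist(),
        "maf": maf.tolist(),
        "config": _config_dict(config),
    }
    return SimTriple(exposure, mediator, outcome, simulate_ld(config), truth)


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["maf_range"] = list(config.maf_range)
    d["instrument_effect_range"] = list(config.instrument_effect_range)
    if config.ld_blocks is not None:
        d["ld_blocks"] = {"n_blocks": config.ld_blocks.n_blocks, "r2": config.ld_blocks.r2}
    return d


# ---------------------------------------------------------------------------
# fast direct-summary mode


def _marginal_se(maf: np.ndarray, n: int) -> np.ndarray:
    """SE of the marginal slope for a unit-variance trait."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_summary(config: SimulationConfig) -> SimTriple:
    """Direct-summary mode: draw beta_hat ~ Normal(truth, se) per variant.

    Orders of magnitude faster than :func:`simulate_triple`; intended for
    large calibration suites.  Binary outcomes are not modelled here — the
    outcome is always emitted as a continuous trait.
    """
    rng = np.random.default_rng(config.seed)
    layout = _layout(config, rng)
    a, b, p_med, q = _structural_effects(config, rng)

    true_x = a
    true_m = config.beta1 * a + b + p_med
    true_y = config.beta3 * a + config.beta2 * b + q

    tables = {}
    for trait_id, true_beta, n in (
        ("exposure", true_x, config.n_exp),
        ("mediator", true_m, config.n_med),
        ("outcome", true_y, config.n_out),
    ):
        se = _marginal_se(layout.maf, n)
        beta_hat = rng.normal(true_beta, se)
        z = beta_hat / se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        eaf = np.clip(
            rng.normal(layout.maf, np.sqrt(layout.maf * (1 - layout.maf) / (2 * n))),
            1e-6,
            1 - 1e-6,
        )
        tables[trait_id] = _build_table(
            trait_id, "continuous", layout, beta_hat, se, p, eaf, n
        )

    truth = {
        "beta1": config.beta1,
        "beta2": config.beta2,
        "direct_effect": config.direct_effect,
        "beta3": config.beta3,
        "a": a.tolist(),
        "b": b.tolist(),
        "config": _config_dict(config),
    }
    return SimTriple(
        tables["exposure"], tables["mediator"], tables["outcome"], simulate_ld(config), truth
    )


def simulate_instruments(
    n_instruments: int,
    true_effect: float,
    n_exp: int,
    n_out: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.15, 0.5),
    effect_range: tuple[float, float] = (0.12, 0.20),
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
) -> list[HarmonizedInstrument]:
    """Draw one already-harmonized instrument set under a known causal effect.

    Exposure effects a_j are drawn from ``effect_range``; the observed
    associations are a_j + noise and true_effect*a_j + pleiotropy_j + noise
    with the standard errors implied by allele frequency and sample size.
    This is the instrument-level direct-summary generator used by the
    calibration suites (heterogeneity type-I error, CI coverage, pleiotropy
    power).
    """
    maf = rng.uniform(*maf_range, size=n_instruments)
    a = rng.uniform(*effect_range, size=n_instruments) * rng.choice(
        [-1.0, 1.0], size=n_instruments
    )
    se_exp = _marginal_se(maf, n_exp)
    se_out = _marginal_se(maf, n_out)
    # directional relative to the exposure-raising allele, as MR-Egger assumes
    pleio = (
        np.sign(a) * rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_instruments)
        if (pleiotropy_mean != 0 or pleiotropy_sd > 0)
        else np.zeros(n_instruments)
    )
    beta_exp = rng.normal(a, se_exp)
    beta_out = rng.normal(true_effect * a + pleio, se_out)
    beta_exp[beta_exp == 0] = 1e-12
    return [
        HarmonizedInstrument(
            variant_id=f"rs{1000 + j}",
            effect_allele="A",
            beta_exp=float(beta_exp[j]),
            se_exp=float(se_exp[j]),
            beta_out=float(beta_out[j]),
            se_out=float(se_out[j]),
            eaf_exp=float(maf[j]),
            eaf_out=float(maf[j]),
        )
        for j in range(n_instruments)
    ]
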