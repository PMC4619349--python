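"""Analytic power machinery for 1-df interaction tests.

Under the alternative, the Wald interaction statistic is non-central
chi-square with 1 df and non-centrality

    NCP = N * v * rho2_tag,

where ``v`` is the fraction of outcome variance explained by the true
interaction term (rho^2(Y, G1*G2)) and ``rho2_tag`` the squared tagging
correlation between the true product term and the observable one (1 for
sequence data, rho_GC^2 for best-tag GWAS SNPs, rho_LC^2 for
local-ancestry dosages).  Power at a corrected level alpha is the
upper-tail non-central chi-square mass beyond the central 1-alpha
quantile; everything else — required sample sizes, Bonferroni accounting
over pair counts, break-even tagging correlations, cost-adjusted designs
— follows by inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Conventional design presets: number of testable variants per design.
DESIGN_PRESETS = {
    "sequence": 20_000_000,   # whole-genome sequence variants
    "gwas": 1_000_000,        # genotyped GWAS chip SNPs
    "gwas_imputed": 10_000_000,  # common imputed SNPs
    "ancestry": 1_000,        # local-ancestry segments in recent two-way admixture
}


@dataclass
class DesignSpec:
    """A study design: how many predictors, hence how many pair tests."""

    n_variants: int
    alpha_nominal: float = 0.05
    cost_fold: int = 1

    @classmethod
    def preset(cls, name: str, alpha_nominal: float = 0.05, cost_fold: int = 1) -> "DesignSpec":
        if name not in DESIGN_PRESETS:
            raise ValueError(f"unknown preset {name!r}; use one of {sorted(DESIGN_PRESETS)}")
        return cls(DESIGN_PRESETS[name], alpha_nominal, cost_fold)

    @property
    def n_tests(self) -> int:
        return self.n_variants * (self.n_variants - 1) // 2

    @property
    def alpha_corrected(self) -> float:
        return bonferroni_alpha(self.alpha_nominal, self.n_variants)


@dataclass
class PowerQuery:
    """Inputs of one analytic power evaluation."""

    N: int
    v: float
    rho2_tag: float
    design: DesignSpec


@dataclass
class PowerResult:
    ncp: float
    alpha_corrected: float
    power: float


@dataclass
class PowerEstimate:
    """Empirical power with an exact binomial confidence interval."""

    power: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_significant: int


def ncp(N: float, v: float, rho2_tag: float = 1.0) -> float:
    """Non-centrality of the interaction Wald statistic: N * v * rho2_tag."""
    if N < 0:
        raise ValueError("N must be non-negative")
    for name, x in (("v", v), ("rho2_tag", rho2_tag)):
        if not (0 <= x <= 1):
            raise ValueError(f"{name} must lie in [0, 1], got {x!r}")
    return float(N) * v * rho2_tag


def analytic_power(ncp_value: float, alpha: float) -> float:
    """Upper-tail non-central chi-square(1, ncp) mass beyond the null quantile."""
    if ncp_value < 0:
        raise ValueError("non-centrality must be non-negative")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if ncp_value == 0:
        return alpha
    q = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(q, df=1, nc=ncp_value))


def required_ncp(alpha: float, power: float) -> float:
    """Non-centrality at which the 1-df test attains the target power.

    Solves analytic_power(lambda, alpha) = power by bracketed root
    finding (Brent) to relative tolerance 1e-8, auto-expanding the upper
    bracket as needed.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if not (alpha < power < 1):
        if power == alpha:
            return 0.0
        raise ValueError("power must lie in (alpha, 1)")
    hi = 100.0
    while analytic_power(hi, alpha) < power:
        hi *= 2
        if hi > 1e9:
            raise RuntimeError("failed to bracket the required non-centrality")
    return float(
        optimize.brentq(lambda lam: analytic_power(lam, alpha) - power, 0.0, hi,
                        rtol=1e-10, xtol=1e-12)
    )


def required_sample_size(
    v: float, rho2_tag: float, alpha_corrected: float, power: float = 0.8
) -> float:
    """Smallest N reaching the target power: ceil(required_ncp / (v * rho2_tag)).

    A zero effective effect (v * rho2_tag == 0) is unattainable and is
    reported as ``math.inf`` rather than raising.
    """
    for name, x in (("v", v), ("rho2_tag", rho2_tag)):
        if not (0 <= x <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    eff = v * rho2_tag
    if eff == 0:
        return math.inf
    return float(math.ceil(required_ncp(alpha_corrected, power) / eff))


def bonferroni_alpha(alpha_nominal: float, n_variants: int) -> float:
    """Family-wise level divided by the pairwise test count C(n_variants, 2)."""
    if n_variants < 2:
        raise ValueError("need at least 2 variants for a pairwise test")
    if not (0 < alpha_nominal < 1):
        raise ValueError("alpha_nominal must lie in (0, 1)")
    return alpha_nominal / (n_variants * (n_variants - 1) / 2)


def breakeven_rho(alpha_a: float, alpha_b: float, power: float = 0.8) -> float:
    """Tagging correlation at which design a matches fully-tagged design b.

    Design a tests fewer pairs (larger corrected alpha) but tags the true
    interaction imperfectly; at rho = sqrt(NCP_a / NCP_b) the two designs
    require the same sample size for the target power.
    """
    la = required_ncp(alpha_a, power)
    lb = required_ncp(alpha_b, power)
    return float(np.sqrt(la / lb))


def cost_adjusted_N(N_base: int, fold: float) -> int:
    """Sample size affordable at a fixed budget when per-sample cost drops ``fold``-fold."""
    if fold < 1:
        raise ValueError("fold must be at least 1")
    return int(round(N_base * fold))


def detectable_variance(
    N: int, alpha_corrected: float, power: float = 0.8, rho2_tag: float = 1.0
) -> float:
    """Smallest interaction-variance fraction detectable at sample size N."""
    if N <= 0 or not (0 < rho2_tag <= 1):
        raise ValueError("need N > 0 and rho2_tag in (0, 1]")
    return required_ncp(alpha_corrected, power) / (N * rho2_tag)


def empirical_power(
    p_values: np.ndarray, alpha_corrected: float, confidence: float = 0.95
) -> PowerEstimate:
    """Fraction of replicates significant at the corrected level, with exact CI."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    k = int(np.sum(p < alpha_corrected))
    n = p.size
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return PowerEstimate(
        power=k / n, ci_low=float(ci.low), ci_high=float(ci.high),
        n_replicates=n, n_significant=k,
    )


def power_for_query(query: PowerQuery) -> PowerResult:
    """Analytic power for a fully specified design query."""
    n_eff = cost_adjusted_N(query.N, query.design.cost_fold)
    lam = ncp(n_eff, query.v, query.rho2_tag)
    alpha_c = query.design.alpha_corrected
    return PowerResult(ncp=lam, alpha_corrected=alpha_c, power=analytic_power(lam, alpha_c))


def power_table(
    designs: dict[str, DesignSpec],
    N_grid: np.ndarray,
    v_grid: np.ndarray,
    rho_grid: np.ndarray,
    power_target: float = 0.8,
) -> pd.DataFrame:
    """Tabulate analytic power and required N over a design/parameter grid."""
    rows = []
    for name, design in designs.items():
        alpha_c = design.alpha_corrected
        for v in v_grid:
            for rho in rho_grid:
                req_n = required_sample_size(v, rho**2, alpha_c, power_target)
                for N in N_grid:
                    res = power_for_query(PowerQuery(int(N), float(v), float(rho**2), design))
                    rows.append(dict(
                        design=name, n_variants=design.n_variants,
                        cost_fold=design.cost_fold, alpha_corrected=alpha_c,
                        N=int(N), v=float(v), rho_tag=float(rho),
                        ncp=res.ncp, power=res.power,
                        required_N=req_n,
                    ))
    return pd.DataFrame(rows)
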