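"""Latent-variable quantitative-trait simulation with gene-gene interaction.

Two distant loci each drive an unmeasured latent variable

    Z_i = sum_k G_ik * beta_ik,

where ``G_ik`` is the standardized genotype of causal SNP ``k`` at locus
``i``.  The outcome is

    Y = theta1*Z1 + theta2*Z2 + theta12*Z1*Z2 + eps,

with ``eps`` normal and its variance scaled so the interaction term
explains a chosen fraction of var(Y) (1% by default, in line with effect
sizes typical for common complex traits).  Causal SNPs are selected by
their differentiation between the ancestral populations, operationalized
as the correlation between genotype dosage and local-ancestry dosage, and
effect sizes come from either a symmetric normal or a left-truncated
(half-)normal, the latter making locus effects directionally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .admixture import AdmixedCohort
from .founders import _as_rng

_FAMILIES = ("normal", "left-truncated-normal")


@dataclass
class EffectSpec:
    """Distribution of per-SNP causal effects within a locus."""

    K: int
    family: str = "left-truncated-normal"
    parent_mean: float = 0.0
    parent_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown effect family {self.family!r}; use one of {_FAMILIES}")
        if self.parent_variance <= 0:
            raise ValueError("parent_variance must be positive")


@dataclass
class TraitModel:
    """Latent-interaction trait architecture.

    ``target_interaction_variance`` is the fraction of var(Y) explained by
    the interaction term theta12*Z1*Z2.  ``snp_main_effects`` additionally
    gives every causal SNP a main effect of the same magnitude as the
    interaction effect (the two-step screening scenario).
    """

    theta1: float = 0.0
    theta2: float = 0.0
    theta12: float = 1.0
    target_interaction_variance: float = 0.01
    snp_main_effects: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.target_interaction_variance < 1):
            raise ValueError("target_interaction_variance must lie in (0, 1)")


@dataclass
class CausalSelection:
    """Causal SNPs chosen for one locus, with allele orientation."""

    segment: int
    indices: np.ndarray
    flip: np.ndarray  # True where the coded allele is 2 - dosage
    ancestry_corr: np.ndarray
    n_eligible: int


@dataclass
class LatentTrait:
    """One locus' latent variable and its ingredients."""

    locus: int
    causal_indices: np.ndarray
    beta: np.ndarray
    Z: np.ndarray
    genotypes_std: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.beta) != len(self.causal_indices):
            raise ValueError("beta and causal_indices must have equal length")


@dataclass
class PhenotypeSet:
    """Simulated outcomes and the variance bookkeeping behind them."""

    Y: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    epsilon_variance: float
    realized_interaction_variance: float


@dataclass
class CausalEligibility:
    """Per-segment SNP eligibility for causal selection.

    ``snp_idx`` holds the global indices of all SNPs in the segment;
    ``eligible`` marks those passing the MAF and differentiation filters;
    ``flip`` marks SNPs whose coded allele must be recoded (2 - dosage)
    so the coded allele is minor in the designated population.
    """

    segment: int
    snp_idx: np.ndarray
    eligible: np.ndarray
    ancestry_corr: np.ndarray
    flip: np.ndarray

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())


def causal_eligibility(
    cohort: AdmixedCohort,
    segment: int,
    differentiation_threshold: float = 0.0,
    maf_min: float = 0.10,
    designated_pop: int = 2,
) -> CausalEligibility:
    """Score every SNP in a segment for causal eligibility.

    Eligible SNPs have cohort minor-allele frequency above ``maf_min`` and
    absolute correlation between genotype dosage and the segment's
    local-ancestry dosage above ``differentiation_threshold`` (the
    operational measure of between-population differentiation).
    """
    snp_idx = cohort.snps_in_segment(segment)
    if len(snp_idx) == 0:
        raise ValueError(f"segment {segment} contains no SNPs")
    G = cohort.genotypes[:, snp_idx].astype(float)
    L = cohort.local_ancestry[:, segment].astype(float)
    if L.std() == 0:
        raise ValueError(f"ancestry dosage constant in segment {segment}")

    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    sd = G.std(axis=0)
    corr = np.zeros(len(snp_idx))
    ok = sd > 0
    Gc = G[:, ok] - G[:, ok].mean(axis=0)
    Lc = L - L.mean()
    corr[ok] = (Gc.T @ Lc) / (len(L) * sd[ok] * L.std())

    eligible = (maf > maf_min) & (np.abs(corr) > differentiation_threshold)

    if cohort.model_frequencies is not None:
        pop_freq = cohort.model_frequencies.frequencies(designated_pop)[snp_idx]
    else:
        pop_freq = freq  # fall back to cohort frequency
    flip = pop_freq > 0.5

    return CausalEligibility(
        segment=segment, snp_idx=snp_idx, eligible=eligible,
        ancestry_corr=corr, flip=flip,
    )


def select_causals(
    cohort: AdmixedCohort,
    segment: int,
    K: int,
    differentiation_threshold: float = 0.0,
    maf_min: float = 0.10,
    seed: int | np.random.Generator = 0,
    designated_pop: int = 2,
) -> CausalSelection:
    """Select K causal SNPs in a segment by ancestry differentiation.

    K SNPs are drawn uniformly without replacement from the set passing
    the MAF and differentiation filters (see :func:`causal_eligibility`).
    The coded allele of each causal is oriented to the allele that is
    minor in the designated population (population 2, the majority
    ancestry, by default) so that effects act in a consistent direction
    there.
    """
    elig = causal_eligibility(
        cohort, segment, differentiation_threshold, maf_min, designated_pop
    )
    if elig.n_eligible < K:
        raise ValueError(
            f"segment {segment}: only {elig.n_eligible} SNPs pass "
            f"MAF > {maf_min} and |corr with ancestry| > {differentiation_threshold}; "
            f"{K} required"
        )
    rng = _as_rng(seed)
    pick = rng.choice(np.nonzero(elig.eligible)[0], size=K, replace=False)
    pick.sort()
    return CausalSelection(
        segment=segment,
        indices=elig.snp_idx[pick],
        flip=elig.flip[pick],
        ancestry_corr=elig.ancestry_corr[pick],
        n_eligible=elig.n_eligible,
    )


def draw_effects(spec: EffectSpec, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw the K per-SNP effects of one locus.

    ``normal`` draws i.i.d. from N(parent_mean, parent_variance);
    ``left-truncated-normal`` conditions the same parent on being >= 0
    (half-normal for the default standard parent, mean sqrt(2/pi)).
    """
    rng = _as_rng(seed)
    sd = np.sqrt(spec.parent_variance)
    if spec.family == "normal":
        return spec.parent_mean + sd * rng.standard_normal(spec.K)
    a = (0.0 - spec.parent_mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=spec.parent_mean, scale=sd, size=spec.K, random_state=rng
    )


def standardize_genotypes(G: np.ndarray) -> np.ndarray:
    """Center and scale genotype dosage columns to mean 0, variance 1."""
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    sd = G.std(axis=0)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0].tolist()
        raise ValueError(f"monomorphic genotype column(s) at {bad}: zero variance")
    return (G - G.mean(axis=0)) / sd


def build_latent(
    cohort: AdmixedCohort,
    causal_indices: np.ndarray,
    beta: np.ndarray,
    flip: np.ndarray | None = None,
    locus: int = 0,
) -> LatentTrait:
    """Build a locus' latent variable Z from standardized causal genotypes."""
    causal_indices = np.asarray(causal_indices)
    beta = np.asarray(beta, dtype=float)
    if len(beta) != len(causal_indices):
        raise ValueError("beta and causal_indices must have equal length")
    G = cohort.genotypes[:, causal_indices].astype(float)
    if flip is not None:
        G[:, np.asarray(flip, dtype=bool)] = 2.0 - G[:, np.asarray(flip, dtype=bool)]
    Gs = standardize_genotypes(G)
    return LatentTrait(
        locus=locus,
        causal_indices=causal_indices,
        beta=beta,
        Z=Gs @ beta,
        genotypes_std=Gs,
    )


def simulate_phenotype(
    Z1: np.ndarray,
    Z2: np.ndarray,
    model: TraitModel,
    seed: int | np.random.Generator = 0,
    causal_genotypes: tuple[np.ndarray, np.ndarray] | None = None,
) -> PhenotypeSet:
    """Simulate outcomes Y = theta1*Z1 + theta2*Z2 + theta12*Z1*Z2 + eps.

    The residual variance is solved from the empirical variance of the
    product term so that the interaction explains exactly
    ``model.target_interaction_variance`` of var(Y) in expectation:
    with v the target and g the genetic part,
    sigma^2 = theta12^2 var(Z1 Z2)/v - var(g).  With
    ``model.snp_main_effects`` the standardized causal genotypes (pass
    them via ``causal_genotypes``) each get a main effect equal to
    ``theta12``.
    """
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    if Z1.shape != Z2.shape:
        raise ValueError("Z1 and Z2 must have the same length")
    prod = Z1 * Z2
    var_prod = prod.var()
    if var_prod == 0:
        raise ValueError("degenerate product term Z1*Z2 (zero variance)")

    g = model.theta1 * Z1 + model.theta2 * Z2 + model.theta12 * prod
    if model.snp_main_effects:
        if causal_genotypes is None:
            raise ValueError("snp_main_effects requires causal_genotypes")
        for Gs in causal_genotypes:
            g = g + model.theta12 * np.asarray(Gs, dtype=float).sum(axis=1)

    v = model.target_interaction_variance
    var_int = model.theta12**2 * var_prod
    eps_var = var_int / v - g.var()
    if eps_var < 0:
        raise ValueError(
            "target interaction variance unattainable: main effects already "
            "dominate the outcome variance"
        )
    rng = _as_rng(seed)
    Y = g + rng.normal(0.0, np.sqrt(eps_var), size=len(g))
    realized = float(np.corrcoef(Y, prod)[0, 1] ** 2)
    return PhenotypeSet(
        Y=Y, Z1=Z1, Z2=Z2, epsilon_variance=float(eps_var),
        realized_interaction_variance=realized,
    )


def rho_latent_ancestry(Z: np.ndarray, L: np.ndarray) -> float:
    """Pearson correlation between a latent variable and local ancestry.

    This is the quantity that bounds the power of the ancestry-based
    interaction test: it is null on average under symmetric effect
    distributions and grows with the number of causal SNPs when effects
    are directionally consistent.
    """
    Z = np.asarray(Z, dtype=float)
    L = np.asarray(L, dtype=float)
    if Z.std() == 0 or L.std() == 0:
        raise ValueError("zero-variance input to rho_latent_ancestry")
    return float(np.corrcoef(Z, L)[0, 1])
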