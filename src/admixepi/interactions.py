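"""1-df Wald interaction tests on SNP pairs and ancestry-segment pairs.

The workhorse is an ordinary-least-squares fit of

    y ~ intercept + a + b + a*b

with the squared z statistic of the product coefficient referred to a
chi-square distribution on 1 degree of freedom.  The same machinery serves
the three study designs: sequence data (the causal SNPs themselves),
GWAS-chip data (best tag SNPs), and local-ancestry dosages.  Helpers
compute the best combined tag of a multi-SNP latent locus, the tagging
correlations between the true and observable product terms, exhaustive
pair scans, and the two-step marginal prescreen that shrinks the
multiple-testing burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

_MODEL_KINDS = ("sequence", "gwas", "ancestry")


@dataclass
class InteractionResult:
    """Result of one 1-df interaction test."""

    id_a: object
    id_b: object
    beta_int: float
    se: float
    wald: float
    p_value: float
    model_kind: str = "sequence"
    n_used: int = 0


@dataclass
class TagSelection:
    """Best combined tag SNP for a multi-causal locus."""

    locus: int
    tag_index: int
    score: float
    scores: np.ndarray


@dataclass
class TagCorrelations:
    """Correlations between the true product term and its observable tags."""

    rho_GC: float
    rho_LC: float


def fit_interaction(
    y: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    model_kind: str = "sequence",
    id_a: object = "a",
    id_b: object = "b",
) -> InteractionResult:
    """OLS fit of ``y ~ 1 + a + b + a*b`` with a Wald test on the product.

    Returns the product-term estimate, its standard error, the 1-df Wald
    statistic ``(beta/se)^2`` and the upper-tail chi-square(1) p-value
    (the asymptotic reference the power theory is built on).
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("y, a, b must have equal length")
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 observations for a 4-parameter fit")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("predictors must be non-constant")
    if model_kind not in _MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {_MODEL_KINDS}")

    X = np.column_stack([np.ones(n), a, b, a * b])
    # rank check with named columns so collinearity is diagnosable
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * diag.max()
    if np.any(diag < tol):
        names = ["intercept", "a", "b", "a*b"]
        bad = names[int(np.argmin(diag))]
        raise np.linalg.LinAlgError(
            f"design matrix rank-deficient: column '{bad}' is collinear"
        )
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ coef
    dof = n - 4
    sigma2 = float(resid @ resid) / dof
    Rinv = np.linalg.inv(R)
    cov = sigma2 * (Rinv @ Rinv.T)
    beta_int = float(coef[3])
    se = float(np.sqrt(cov[3, 3]))
    wald = (beta_int / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))
    return InteractionResult(
        id_a=id_a, id_b=id_b, beta_int=beta_int, se=se, wald=wald,
        p_value=p, model_kind=model_kind, n_used=n,
    )


def best_tag(
    locus_genotypes: np.ndarray,
    beta: np.ndarray,
    causal_indices: np.ndarray,
    candidate_indices: np.ndarray,
) -> TagSelection:
    """Best combined tag: the SNP j maximizing |sum_k beta_k * corr(G_j, G_k)|.

    Correlations are computed on standardized genotypes.  The combined
    score sums signed correlations over the K causal SNPs, so opposing
    causal effects can cancel; the absolute value is maximized because a
    tag SNP's own allele coding is arbitrary (flipping the tag flips the
    score's sign but leaves the interaction Wald statistic unchanged).
    Pass causal genotype columns already oriented to the coded allele.
    Ties are broken by the lowest SNP index; monomorphic candidates are
    excluded.
    """
    beta = np.asarray(beta, dtype=float)
    causal_indices = np.asarray(causal_indices)
    candidate_indices = np.sort(np.asarray(candidate_indices))
    if len(candidate_indices) == 0:
        raise ValueError("candidate set is empty")
    G = np.asarray(locus_genotypes, dtype=float)
    n = G.shape[0]

    sd = G.std(axis=0)
    poly = sd[candidate_indices] > 0
    candidates = candidate_indices[poly]
    if len(candidates) == 0:
        raise ValueError("all candidate SNPs are monomorphic")
    if np.any(sd[causal_indices] == 0):
        raise ValueError("monomorphic causal SNP")

    Zc = (G[:, candidates] - G[:, candidates].mean(axis=0)) / sd[candidates]
    Zk = (G[:, causal_indices] - G[:, causal_indices].mean(axis=0)) / sd[causal_indices]
    corr = (Zc.T @ Zk) / n  # (candidates, K)
    scores = np.abs(corr @ beta)
    best = int(np.argmax(scores))  # argmax returns the first (lowest) index on ties
    return TagSelection(
        locus=0, tag_index=int(candidates[best]), score=float(scores[best]),
        scores=scores,
    )


def product_correlation(
    a1: np.ndarray, a2: np.ndarray, b1: np.ndarray, b2: np.ndarray
) -> float:
    """Pearson correlation of the elementwise products a1*a2 and b1*b2.

    With (a1, a2) the true causal variables and (b1, b2) their tags —
    either best tag SNPs or local-ancestry dosages — this is the tagging
    correlation (rho_GC or rho_LC) that attenuates the interaction NCP.
    """
    pa = np.asarray(a1, dtype=float) * np.asarray(a2, dtype=float)
    pb = np.asarray(b1, dtype=float) * np.asarray(b2, dtype=float)
    if pa.std() == 0 or pb.std() == 0:
        raise ValueError("zero-variance product term")
    return float(np.corrcoef(pa, pb)[0, 1])


def scan_pairs(
    y: np.ndarray,
    predictors: np.ndarray,
    pair_set: list[tuple[int, int]] | None = None,
    alpha_corrected: float = 0.05,
    model_kind: str = "sequence",
) -> pd.DataFrame:
    """Fit the interaction test for every predictor pair in ``pair_set``.

    ``pair_set=None`` enumerates all pairs lexicographically by (i, j),
    i < j.  Per-pair rank failures are reported as flagged rows (``error``
    column) rather than aborting the scan.
    """
    predictors = np.asarray(predictors, dtype=float)
    p = predictors.shape[1]
    if pair_set is None:
        pair_set = list(combinations(range(p), 2))
    rows = []
    for i, j in pair_set:
        if not (0 <= i < p and 0 <= j < p):
            raise IndexError(f"pair ({i}, {j}) outside predictor matrix")
        try:
            r = fit_interaction(
                y, predictors[:, i], predictors[:, j],
                model_kind=model_kind, id_a=i, id_b=j,
            )
            rows.append(
                dict(i=i, j=j, beta_int=r.beta_int, se=r.se, wald=r.wald,
                     p_value=r.p_value, significant=r.p_value < alpha_corrected,
                     error=""))
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append(
                dict(i=i, j=j, beta_int=np.nan, se=np.nan, wald=np.nan,
                     p_value=np.nan, significant=False, error=str(exc)))
    return pd.DataFrame(rows)


def two_step_screen(
    y: np.ndarray,
    predictors: np.ndarray,
    t: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Two-step prescreen: keep predictors with marginal p below ``t``.

    Step 1 fits ``y ~ 1 + x`` for every predictor and keeps those with
    p < t.  Assuming most predictors carry no interaction, the step-2
    test count is approximated by C(n*t, 2) = n*t*(n*t - 1)/2, the
    quantity to use for the step-2 Bonferroni budget.  Returns the
    selected column indices and that approximation.
    """
    if not (0 < t <= 1):
        raise ValueError("threshold t must lie in (0, 1]")
    y = np.asarray(y, dtype=float)
    X = np.asarray(predictors, dtype=float)
    n, m = X.shape
    if n != len(y):
        raise ValueError("y and predictors disagree on sample size")
    sd = X.std(axis=0)
    yc = y - y.mean()
    r = np.zeros(m)
    ok = sd > 0
    r[ok] = ((X[:, ok] - X[:, ok].mean(axis=0)).T @ yc) / (n * sd[ok] * y.std())
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    pvals = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    pvals[~ok] = 1.0
    selected = np.nonzero(pvals < t)[0] if t < 1 else np.arange(m)
    x = m * t
    approx = x * (x - 1) / 2 if x > 1 else 0.0
    return selected, float(approx)
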