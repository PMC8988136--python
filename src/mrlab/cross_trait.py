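"""Shared-genetics analyses: cross-phenotype meta-analysis (SHet),
LD-score-regression genetic correlation, colocalization posteriors and
the TWAS association statistic.

SHet is the heterogeneity-tolerant cross-phenotype statistic: with
sample-size weights w_i = sqrt(n_i) and trait-correlation matrix R, each
nonempty trait subset T contributes

    S(T) = (w_T' R_T^{-1} z_T)^2 / (w_T' R_T^{-1} w_T)

with z sign-aligned within the subset, and S_Het is the maximum over
subsets (exhaustive enumeration; exact for small trait counts).  Because
the maximum is not chi-square distributed, the p-value comes from a
Monte-Carlo null (z ~ MVN(0, R)); an analytic union (Bonferroni) upper
bound over the subset chi-square tails covers tail claims beyond MC
resolution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import LDPanel
from .sumstats import SumStats
from .instruments import ClumpResult, clump


# ---------------------------------------------------------------------------
# SHet cross-phenotype statistic


def _subset_stat(z: np.ndarray, w: np.ndarray, Rinv: np.ndarray) -> float:
    """S(T) with z sign-aligned to the subset's first trait.

    Aligning every z to the first trait's direction maps z -> sign(z_1)*|z|,
    so the quadratic form depends only on |z|.
    """
    num = float(w @ Rinv @ np.abs(z)) ** 2
    den = float(w @ Rinv @ w)
    return num / den


def _subset_machinery(n: np.ndarray, R: np.ndarray):
    """Precompute (index array, Rinv @ w_T, w'Rinv w) for every subset."""
    K = len(n)
    w = np.sqrt(n)
    out = []
    for size in range(1, K + 1):
        for subset in itertools.combinations(range(K), size):
            idx = np.array(subset)
            Rinv = np.linalg.inv(R[np.ix_(idx, idx)])
            coefs = Rinv @ w[idx]
            out.append((idx, coefs, float(w[idx] @ coefs)))
    return out


def _shet_batch(Z: np.ndarray, machinery) -> np.ndarray:
    """S_Het for each row of Z (rows are independent variant draws)."""
    A = np.abs(Z)
    best = np.full(Z.shape[0], -np.inf)
    for idx, coefs, den in machinery:
        s = (A[:, idx] @ coefs) ** 2 / den
        np.maximum(best, s, out=best)
    return best


def shet_statistic(z: np.ndarray, n: np.ndarray, R: np.ndarray) -> float:
    """Max of S(T) over all nonempty trait subsets."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    R = np.asarray(R, dtype=float)
    K = len(z)
    if not (len(n) == K and R.shape == (K, K)):
        raise ValueError("dimension mismatch")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("trait correlation matrix must be positive definite") from exc
    w = np.sqrt(n)
    best = -np.inf
    for size in range(1, K + 1):
        for subset in itertools.combinations(range(K), size):
            idx = list(subset)
            Rinv = np.linalg.inv(R[np.ix_(idx, idx)])
            best = max(best, _subset_stat(z[idx], w[idx], Rinv))
    return best


def shet_p_upper(s_het: float, n: np.ndarray, R: np.ndarray) -> float:
    """Analytic union bound on P(S_Het >= s) under the MVN(0, R) null.

    Each subset statistic is marginally chi-square(1) (quadratic form in
    one linear combination of z), so the union bound sums the chi-square
    tail over all 2^K - 1 subsets.  Conservative but sharp enough for
    genome-wide tail claims that Monte Carlo cannot resolve.
    """
    K = len(n)
    n_subsets = 2**K - 1
    return float(min(1.0, n_subsets * stats.chi2.sf(s_het, 1)))


def shet(
    z: np.ndarray,
    n: np.ndarray,
    R: np.ndarray | None = None,
    n_mc: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """SHet statistic and Monte-Carlo p-value.

    p = (1 + #{max* >= S_Het}) / (n_mc + 1) with null draws
    z* ~ MVN(0, R).  When the MC resolution floor 1/(n_mc+1) is hit, the
    analytic union bound is substituted if smaller.  R defaults to the
    identity (non-overlapping cohorts).
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    K = len(z)
    if R is None:
        R = np.eye(K)
    R = np.asarray(R, dtype=float)
    s_obs = shet_statistic(z, n, R)
    if n_mc <= 0:
        return s_obs, shet_p_upper(s_obs, n, R)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    machinery = _subset_machinery(n, R)
    exceed = 0
    chunk = 50_000
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        z_null = rng.standard_normal((m, K)) @ L.T
        exceed += int(np.sum(_shet_batch(z_null, machinery) >= s_obs))
        done += m
    p = (1 + exceed) / (n_mc + 1)
    if exceed == 0:
        p = min(p, shet_p_upper(s_obs, n, R))
    return s_obs, float(p)


def cross_trait_scan(
    a: SumStats,
    b: SumStats,
    panel: LDPanel,
    R: np.ndarray | None = None,
    p_meta_threshold: float = 2.5e-8,
    p_single_threshold: float = 1e-5,
    clump_params: dict | None = None,
) -> tuple[pd.DataFrame, ClumpResult]:
    """Per-variant SHet scan over shared variants, filter, and meta-clump.

    Survivors need meta p below the cross-trait genome-wide level
    (2.5e-8, i.e. 5e-8 halved for two meta-analyses) AND both
    single-trait p below 1e-5; they are then clumped with the
    meta-analysis parameters (p1=2.5e-8, p2=1e-5, r2=0.4, kb=500) to
    yield index loci.  The analytic tail bound is used for p_meta, so the
    scan is deterministic and conservative at genome-wide stringency.
    """
    ta = a.indexed()
    tb = b.indexed()
    shared = ta.index.intersection(tb.index)
    if len(shared) < 1:
        raise ValueError("no shared variants between traits")
    za = ta.loc[shared, "z"].to_numpy()
    zb = tb.loc[shared, "z"].to_numpy()
    na = ta.loc[shared, "n"].to_numpy(dtype=float)
    nb = tb.loc[shared, "n"].to_numpy(dtype=float)
    if R is None:
        R = np.eye(2)

    Z = np.column_stack([za, zb])
    s_het = np.empty(len(shared))
    for n1, n2 in {(x, y) for x, y in zip(na, nb)}:
        sel = (na == n1) & (nb == n2)
        machinery = _subset_machinery(np.array([n1, n2]), R)
        s_het[sel] = _shet_batch(Z[sel], machinery)
    n_subsets = 2 ** Z.shape[1] - 1
    p_meta = np.minimum(1.0, n_subsets * stats.chi2.sf(s_het, 1))
    meta = pd.DataFrame(
        {"variant_id": shared, "s_het": s_het, "p_meta": p_meta}
    )
    meta["p_a"] = ta.loc[shared, "pvalue"].to_numpy()
    meta["p_b"] = tb.loc[shared, "pvalue"].to_numpy()
    meta["chrom"] = ta.loc[shared, "chrom"].to_numpy()
    meta["pos"] = ta.loc[shared, "pos"].to_numpy()

    keep = (
        (meta["p_meta"] < p_meta_threshold)
        & (meta["p_a"] < p_single_threshold)
        & (meta["p_b"] < p_single_threshold)
    )
    survivors = meta.loc[keep].copy()
    survivors["pvalue"] = survivors["p_meta"]
    params = dict(p1=p_meta_threshold, p2=p_single_threshold, r2=0.4, kb=500)
    if clump_params:
        params.update(clump_params)
    result = clump(
        survivors[["variant_id", "chrom", "pos", "pvalue"]],
        panel,
        **params,
    )
    return meta, result


# ---------------------------------------------------------------------------
# LD-score-regression genetic correlation


@dataclass
class RgEstimate:
    rg: float
    se: float
    pvalue: float
    h2_a: float
    h2_a_se: float
    h2_b: float
    h2_b_se: float
    intercept_a: float
    intercept_b: float
    intercept_cov: float
    n_blocks: int
    defined: bool = True
    diagnostics: dict = field(default_factory=dict)


def _ldsc_regression(y: np.ndarray, x: np.ndarray, weights: np.ndarray):
    """WLS of y on [1, x]; returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(x), x])
    WX = X * weights[:, None]
    coef = np.linalg.solve(X.T @ WX, WX.T @ y)
    return coef


def ldsc_rg(
    a: SumStats,
    b: SumStats,
    panel: LDPanel,
    n_blocks: int = 200,
) -> RgEstimate:
    """Genetic correlation by LD-score regression with a block jackknife.

    Per trait, h^2 comes from regressing z^2 on n*l/M with a free
    intercept; the genetic covariance from regressing z_a*z_b on
    sqrt(n_a*n_b)*l/M.  rg = cov/sqrt(h2_a*h2_b).  The SE is a
    delete-one-block jackknife over contiguous variant blocks, the
    p-value a normal approximation.  Weights follow the standard
    heteroskedasticity form 1/(l*(1 + n*h2*l/M)^2) from a first OLS pass.
    """
    ta = a.indexed()
    tb = b.indexed()
    shared = ta.index.intersection(tb.index)
    if len(shared) < 200:
        raise ValueError("need >= 200 shared variants for LD-score regression")
    idx = panel.index_of(shared)
    ell = panel.ld_scores[idx]
    M = panel.M
    za = ta.loc[shared, "z"].to_numpy()
    zb = tb.loc[shared, "z"].to_numpy()
    na = ta.loc[shared, "n"].to_numpy(dtype=float)
    nb = tb.loc[shared, "n"].to_numpy(dtype=float)

    xa = na * ell / M
    xb = nb * ell / M
    xab = np.sqrt(na * nb) * ell / M

    def weights(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        coef0 = _ldsc_regression(y, x, np.ones_like(x))
        fitted = np.maximum(coef0[0] + coef0[1] * x, 0.1)
        return 1.0 / (ell * fitted**2)

    wa = weights(xa, za**2)
    wb = weights(xb, zb**2)
    wab = np.sqrt(wa * wb)

    n_blocks = min(n_blocks, len(shared) // 2)
    edges = np.linspace(0, len(shared), n_blocks + 1).astype(int)

    def fit(mask: np.ndarray) -> tuple[float, float, float, float, float, float]:
        ia, sa = _ldsc_regression(za[mask] ** 2, xa[mask], wa[mask])
        ib, sb = _ldsc_regression(zb[mask] ** 2, xb[mask], wb[mask])
        iab, sab = _ldsc_regression((za * zb)[mask], xab[mask], wab[mask])
        return sa, sb, sab, ia, ib, iab

    full_mask = np.ones(len(shared), dtype=bool)
    h2a, h2b, cov, int_a, int_b, int_ab = fit(full_mask)

    def rg_of(sa: float, sb: float, sab: float) -> float:
        if sa <= 0 or sb <= 0:
            return np.nan
        return sab / np.sqrt(sa * sb)

    rg_full = rg_of(h2a, h2b, cov)
    jk = []
    jk_h2a, jk_h2b = [], []
    for k in range(n_blocks):
        mask = full_mask.copy()
        mask[edges[k] : edges[k + 1]] = False
        sa, sb, sab, *_ = fit(mask)
        jk.append(rg_of(sa, sb, sab))
        jk_h2a.append(sa)
        jk_h2b.append(sb)

    jk = np.asarray(jk, dtype=float)
    usable = np.isfinite(jk)
    g = int(usable.sum())
    if not np.isfinite(rg_full) or g < 2:
        return RgEstimate(
            rg=np.nan, se=np.nan, pvalue=np.nan,
            h2_a=h2a, h2_a_se=np.nan, h2_b=h2b, h2_b_se=np.nan,
            intercept_a=int_a, intercept_b=int_b, intercept_cov=int_ab,
            n_blocks=n_blocks, defined=False,
            diagnostics={"reason": "nonpositive heritability estimate"},
        )
    se = float(np.sqrt((g - 1) / g * np.sum((jk[usable] - jk[usable].mean()) ** 2)))
    h2a_se = float(np.sqrt((g - 1) / g * np.sum((np.asarray(jk_h2a) - np.mean(jk_h2a)) ** 2)))
    h2b_se = float(np.sqrt((g - 1) / g * np.sum((np.asarray(jk_h2b) - np.mean(jk_h2b)) ** 2)))
    p = float(2.0 * stats.norm.sf(abs(rg_full) / se)) if se > 0 else np.nan
    return RgEstimate(
        rg=float(rg_full), se=se, pvalue=p,
        h2_a=float(h2a), h2_a_se=h2a_se, h2_b=float(h2b), h2_b_se=h2b_se,
        intercept_a=float(int_a), intercept_b=float(int_b), intercept_cov=float(int_ab),
        n_blocks=n_blocks,
    )


# ---------------------------------------------------------------------------
# colocalization posteriors


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    log_abf_a: np.ndarray
    log_abf_b: np.ndarray
    priors: tuple[float, float, float]

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def as_dict(self) -> dict:
        return {f"PP{i}": float(self.pp[i]) for i in range(5)}


def _log_abf(z: np.ndarray, se: np.ndarray, sd_prior: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant."""
    V = se**2
    W = sd_prior**2
    return 0.5 * (np.log(V / (V + W)) + W * z**2 / (V + W))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(x - m))))


def coloc_abf(
    region_a: pd.DataFrame,
    region_b: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    sd_prior_a: float = 0.15,
    sd_prior_b: float = 0.15,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    ``region_a``/``region_b`` are variant tables (columns variant_id,
    beta, se) over the *same* variant set.  Hypotheses: H0 no
    association; H1/H2 association with one trait only; H3 two distinct
    causal variants; H4 one shared causal variant — the colocalization
    hypothesis, declared at PP4 > 0.9 by convention.  Sums over causal
    configurations use log-sum-exp throughout.
    """
    ids_a = list(region_a["variant_id"])
    ids_b = list(region_b["variant_id"])
    if ids_a != ids_b:
        raise ValueError("regions must cover the same variants in the same order")
    if len(ids_a) < 2:
        raise ValueError("need >= 2 variants for colocalization")

    za = (region_a["beta"] / region_a["se"]).to_numpy(dtype=float)
    zb = (region_b["beta"] / region_b["se"]).to_numpy(dtype=float)
    la = _log_abf(za, region_a["se"].to_numpy(dtype=float), sd_prior_a)
    lb = _log_abf(zb, region_b["se"].to_numpy(dtype=float), sd_prior_b)

    s1 = _logsumexp(la)
    s2 = _logsumexp(lb)
    s12 = _logsumexp(la + lb)
    # H3 sums ABF_a[i]*ABF_b[j] over i != j, i.e. exp(s1+s2) - exp(s12),
    # evaluated stably in log space
    both = s1 + s2
    if both <= s12:
        s3 = -np.inf
    else:
        s3 = both + np.log1p(-np.exp(s12 - both))

    lp = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + s3,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lp - _logsumexp(lp))
    pp /= pp.sum()
    return ColocResult(pp=pp, log_abf_a=la, log_abf_b=lb, priors=(p1, p2, p12))


# ---------------------------------------------------------------------------
# TWAS association


@dataclass
class TwasResult:
    gene: str
    tissue: str
    z_twas: float
    pvalue: float
    bonferroni_significant: bool


def twas_assoc(
    weights: np.ndarray,
    z: np.ndarray,
    sigma: np.ndarray,
    gene: str = "",
    tissue: str = "",
    n_tests: int = 1,
    alpha: float = 0.05,
) -> TwasResult:
    """Weighted-burden TWAS statistic z = (w'z)/sqrt(w' Sigma w).

    ``weights`` is the gene's expression weight vector over the region's
    variants, ``z`` the trait's marginal z-scores and ``sigma`` the LD
    sub-matrix.  Bonferroni significance is declared at alpha/n_tests
    over the gene-tissue pairs tested.
    """
    w = np.asarray(weights, dtype=float)
    z = np.asarray(z, dtype=float)
    denom2 = float(w @ sigma @ w)
    if denom2 <= 0:
        raise ValueError("w' Sigma w must be positive")
    z_t = float(w @ z / np.sqrt(denom2))
    p = float(2.0 * stats.norm.sf(abs(z_t)))
    return TwasResult(
        gene=gene,
        tissue=tissue,
        z_twas=z_t,
        pvalue=p,
        bonferroni_significant=p < alpha / max(1, n_tests),
    )
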