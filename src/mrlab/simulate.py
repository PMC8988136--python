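"""Synthetic LD panels and two-sample GWAS summary statistics.

The generator emulates the data situation of a two-sample MR /
cross-trait study: two (or three) non-overlapping European-style cohorts,
block-structured linkage disequilibrium, a polygenic architecture with
controlled per-trait heritability and cross-trait genetic correlation,
and an exposure -> mediator -> outcome structural model with a binary
(liability-threshold) outcome.

Genotypes are simulated at the individual level (dosages 0/1/2 from two
latent-Gaussian haplotypes) so that the marginal per-variant regressions
— effect, standard error, p — are produced exactly the way a GWAS
produces them.  A fast z-score-only mode draws marginal z directly from
``z ~ MVN(sqrt(n)·Σβ, Σ)`` for LD-score-regression and meta-analysis
calibration at larger variant counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStats, COMPLEMENT

_BASES = np.array(list("ACGT"))
#: ordered non-identical allele pairs that are not strand-ambiguous
_NONPALINDROMIC_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b and COMPLEMENT[a] != b
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _detect_blocks(r: np.ndarray) -> list[slice]:
    """Contiguous diagonal blocks of a block-diagonal correlation matrix."""
    M = r.shape[0]
    blocks: list[slice] = []
    start = 0
    end = 0  # inclusive index of furthest coupling seen so far
    for j in range(M):
        nz = np.nonzero(r[j])[0]
        if len(nz):
            end = max(end, int(nz[-1]))
        if j >= end:
            blocks.append(slice(start, j + 1))
            start = j + 1
            end = j + 1
    return blocks


@dataclass
class LDPanel:
    """LD reference: variant map, correlation matrix and LD scores.

    ``variants`` columns: variant_id, chrom, pos, effect_allele,
    other_allele, maf.  ``r`` is the M x M correlation matrix (block
    diagonal for simulated panels); ``ld_scores[j] = sum_k r[j,k]**2``.
    """

    variants: pd.DataFrame
    r: np.ndarray
    ld_scores: np.ndarray
    blocks: list[slice] = field(default_factory=list)

    def __post_init__(self) -> None:
        M = len(self.variants)
        if self.r.shape != (M, M):
            raise ValueError("correlation matrix does not match variant map")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(self.ld_scores < 1.0 - 1e-8):
            raise ValueError("LD scores must be >= 1")
        if not self.blocks:
            self.blocks = _detect_blocks(self.r)

    @property
    def M(self) -> int:
        return len(self.variants)

    def index_of(self, variant_ids) -> np.ndarray:
        lookup = pd.Index(self.variants["variant_id"])
        idx = lookup.get_indexer(variant_ids)
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise KeyError(f"variants not in panel: {missing[:5]}")
        return idx

    def r2(self, id_a: str, id_b: str) -> float:
        i, j = self.index_of([id_a, id_b])
        return float(self.r[i, j] ** 2)


@dataclass
class SimConfig:
    """Generator design: cohort sizes, architecture and mediation DAG.

    Defaults are the study conditions used throughout: 2000 variants in
    100 LD blocks with heterogeneous within-block decay (rho_b ~
    Uniform(0, 0.95)); heritabilities 0.13 and 0.05 with genetic
    correlation 0.26 (the TV-watching / breakfast-skipping tier of trait
    pairs); desk-scale cohorts of 20 000; mediation coefficients a=0.3,
    b=0.6, c'=0.4 and a binary outcome with case fraction 26676/159208
    (the T2D case load).
    """

    n_blocks: int = 100
    block_size: int = 20
    rho: float | None = None
    rho_max: float = 0.95
    h2_x: float = 0.13
    h2_y: float = 0.05
    rg: float = 0.26
    n_x: int = 20_000
    n_y: int = 20_000
    causal_fraction: float = 0.2
    a: float = 0.3
    b: float = 0.6
    c_prime: float = 0.4
    h2_m: float = 0.15
    case_fraction: float = 26676 / 159208
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindrome_fraction: float = 1.0 / 6.0
    binary_outcome: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho is not None and not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0.0 <= self.rho_max < 1.0):
            raise ValueError("rho_max must be in [0, 1)")
        if self.block_size < 1 or self.n_blocks < 1:
            raise ValueError("block sizes must be >= 1")
        for h2 in (self.h2_x, self.h2_y, self.h2_m):
            if not (0.0 <= h2 <= 1.0):
                raise ValueError("heritability must be in [0, 1]")
        if abs(self.rg) > 1.0:
            raise ValueError("|rg| must be <= 1")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case fraction must be in (0, 1)")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal fraction must be in (0, 1]")

    @property
    def M(self) -> int:
        return self.n_blocks * self.block_size


@dataclass
class TruthRecord:
    """Ground truth stored alongside every simulated dataset."""

    beta_true: dict[str, np.ndarray]
    h2_realized: dict[str, float]
    rg_realized: float | None = None
    causal_index: dict[str, np.ndarray] = field(default_factory=dict)
    total_effect: float | None = None
    indirect_effect: float | None = None
    direct_effect: float | None = None
    observed_scale_factor: float = 1.0
    cohorts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def total_effect_observed(self) -> float | None:
        if self.total_effect is None:
            return None
        return self.total_effect * self.observed_scale_factor

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["beta_true"] = {k: v.tolist() for k, v in self.beta_true.items()}
        payload["causal_index"] = {k: v.tolist() for k, v in self.causal_index.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# LD panel


def make_ld_panel(config: SimConfig) -> LDPanel:
    """Block-diagonal AR(1) LD panel: r[j,k] = rho_b^|j-k| within block b.

    By default each block draws its own decay rho_b ~ Uniform(0,
    rho_max), emulating the wide genome-wide spread of LD scores between
    recombination hotspots and cold spots (a fixed ``rho`` yields nearly
    constant LD scores, which leaves LD-score regression without
    leverage).  Blocks are placed 1 Mb apart along chromosomes 1..22
    with 5 kb between adjacent variants, so distance-based clumping
    windows behave realistically.  Allele pairs are drawn at random with
    a configurable fraction of strand-ambiguous (A/T, C/G) pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    M = config.M
    B = config.block_size

    dist = np.abs(np.subtract.outer(np.arange(B), np.arange(B)))
    if config.rho is not None:
        rhos = np.full(config.n_blocks, config.rho)
    else:
        rhos = rng.uniform(0.0, config.rho_max, size=config.n_blocks)
    r = np.zeros((M, M))
    blocks = []
    for b in range(config.n_blocks):
        sl = slice(b * B, (b + 1) * B)
        r[sl, sl] = rhos[b] ** dist
        blocks.append(sl)
    ld_scores = (r**2).sum(axis=1)

    chrom = np.array([str(1 + (b % 22)) for b in range(config.n_blocks)]).repeat(B)
    block_start = (1 + np.arange(config.n_blocks) // 22) * 1_000_000
    pos = np.repeat(block_start, B) + np.tile(5_000 * np.arange(B), config.n_blocks)

    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=M)
    pal = rng.random(M) < config.palindrome_fraction
    pairs = np.empty((M, 2), dtype=object)
    if pal.any():
        pairs[pal] = [
            _PALINDROMIC_PAIRS[i]
            for i in rng.integers(0, len(_PALINDROMIC_PAIRS), pal.sum())
        ]
    if (~pal).any():
        pairs[~pal] = [
            _NONPALINDROMIC_PAIRS[i]
            for i in rng.integers(0, len(_NONPALINDROMIC_PAIRS), (~pal).sum())
        ]

    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1:06d}" for j in range(M)],
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "effect_allele": pairs[:, 0],
            "other_allele": pairs[:, 1],
            "maf": maf,
        }
    )
    return LDPanel(variants=variants, r=r, ld_scores=ld_scores, blocks=blocks)


def write_ld_panel(panel: LDPanel, directory) -> None:
    """Write a panel as variant-map TSV + dense correlation-matrix TSV."""
    import os

    os.makedirs(directory, exist_ok=True)
    panel.variants.to_csv(
        os.path.join(directory, "variants.tsv"), sep="\t", index=False,
        float_format="%.17g",
    )
    np.savetxt(os.path.join(directory, "ld_matrix.tsv"), panel.r, delimiter="\t")


def read_ld_panel(directory) -> LDPanel:
    import os

    variants = pd.read_csv(
        os.path.join(directory, "variants.tsv"), sep="\t", dtype={"chrom": str}
    )
    r = np.loadtxt(os.path.join(directory, "ld_matrix.tsv"), delimiter="\t")
    r = np.atleast_2d(r)
    return LDPanel(variants=variants, r=r, ld_scores=(r**2).sum(axis=1))


# ---------------------------------------------------------------------------
# genotypes and marginal GWAS


def _simulate_dosages(panel: LDPanel, n: int, rng: np.random.Generator) -> np.ndarray:
    """n x M dosage matrix: two latent-Gaussian haplotypes per individual.

    Within each block the latent haplotype values follow the block's
    correlation; an allele is carried when the latent value falls below
    the maf quantile, so per-variant frequencies match the panel maf in
    expectation (LD on the dosage scale is slightly attenuated relative
    to the latent scale, as for real tetrachoric correlations).
    """
    maf = panel.variants["maf"].to_numpy()
    thresh = stats.norm.ppf(maf)
    G = np.empty((n, panel.M), dtype=np.float64)
    for sl in panel.blocks:
        C = panel.r[sl, sl]
        L = np.linalg.cholesky(C + 1e-10 * np.eye(C.shape[0]))
        for hap in range(2):
            latent = rng.standard_normal((n, C.shape[0])) @ L.T
            carried = (latent < thresh[sl]).astype(np.float64)
            if hap == 0:
                G[:, sl] = carried
            else:
                G[:, sl] += carried
    return G


def _marginal_gwas(G: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-variant simple linear regression of y on raw dosage."""
    n = len(y)
    gbar = G.mean(axis=0)
    yc = y - y.mean()
    gc = G - gbar
    gg = (gc**2).sum(axis=0)
    gg = np.where(gg == 0, np.nan, gg)
    beta = (gc * yc[:, None]).sum(axis=0) / gg
    rss = (yc**2).sum() - beta**2 * gg
    se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / gg)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"beta": beta, "se": se, "pvalue": p, "eaf": gbar / 2.0})


def _as_sumstats(panel: LDPanel, gwas: pd.DataFrame, label: str, n: int) -> SumStats:
    table = panel.variants[
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    ].copy()
    table["eaf"] = gwas["eaf"].to_numpy()
    table["beta"] = gwas["beta"].to_numpy()
    table["se"] = gwas["se"].to_numpy()
    table["pvalue"] = gwas["pvalue"].to_numpy()
    table["n"] = n
    ok = np.isfinite(table["beta"]) & (table["se"] > 0)
    return SumStats(trait_label=label, table=table.loc[ok].reset_index(drop=True))


def _scaled_effects(
    raw: np.ndarray, causal: np.ndarray, h2: float, r: np.ndarray
) -> np.ndarray:
    """Scale standardized-genotype effects so beta' Sigma beta = h2 exactly."""
    if h2 == 0:
        return np.zeros(r.shape[0])
    beta = np.zeros(r.shape[0])
    beta[causal] = raw
    var = float(beta @ r @ beta)
    if var <= 0:
        raise ValueError("degenerate causal-effect draw")
    return beta * np.sqrt(h2 / var)


def _standardize(G: np.ndarray) -> np.ndarray:
    sd = G.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (G - G.mean(axis=0)) / sd


def _effect_correlation(bx: np.ndarray, by: np.ndarray) -> float:
    if len(bx) < 2 or bx.std() == 0 or by.std() == 0:
        return np.nan
    return float(np.corrcoef(bx, by)[0, 1])


# ---------------------------------------------------------------------------
# bivariate trait pair


def simulate_pair_sumstats(
    panel: LDPanel, config: SimConfig
) -> tuple[SumStats, SumStats, TruthRecord]:
    """Two genetically correlated quantitative traits in disjoint cohorts.

    Causal effects for a shared causal set of size ``causal_fraction*M``
    are drawn from a bivariate normal with per-trait variance h2/M_c and
    covariance rg*sqrt(h2_x*h2_y)/M_c, then rescaled so the realized
    genetic variance equals h2 exactly against the panel LD.  Each trait
    is measured by marginal regressions in its own cohort of size n_x /
    n_y; no individual is shared between cohorts.
    """
    if min(config.n_x, config.n_y) < 50:
        raise ValueError("cohort size < 50: marginal regressions unstable")
    ss = np.random.SeedSequence([config.seed, 1])
    rng_eff, rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))

    M = panel.M
    Mc = max(1, int(round(config.causal_fraction * M)))
    causal = np.sort(rng_eff.choice(M, size=Mc, replace=False))
    u = rng_eff.standard_normal(Mc)
    w = rng_eff.standard_normal(Mc)
    v = config.rg * u + np.sqrt(max(0.0, 1 - config.rg**2)) * w
    beta_x = _scaled_effects(u, causal, config.h2_x, panel.r)
    beta_y = _scaled_effects(v, causal, config.h2_y, panel.r)
    rg_real = _effect_correlation(beta_x[causal], beta_y[causal])

    Gx = _simulate_dosages(panel, config.n_x, rng_x)
    Gy = _simulate_dosages(panel, config.n_y, rng_y)
    x = _standardize(Gx) @ beta_x + rng_x.standard_normal(config.n_x) * np.sqrt(
        max(0.0, 1 - config.h2_x)
    )
    y = _standardize(Gy) @ beta_y + rng_y.standard_normal(config.n_y) * np.sqrt(
        max(0.0, 1 - config.h2_y)
    )

    sa = _as_sumstats(panel, _marginal_gwas(Gx, x), "trait_x", config.n_x)
    sb = _as_sumstats(panel, _marginal_gwas(Gy, y), "trait_y", config.n_y)
    truth = TruthRecord(
        beta_true={"trait_x": beta_x, "trait_y": beta_y},
        h2_realized={"trait_x": config.h2_x, "trait_y": config.h2_y},
        rg_realized=rg_real,
        causal_index={"shared": causal},
        cohorts={"trait_x": (0, config.n_x), "trait_y": (config.n_x, config.n_x + config.n_y)},
    )
    return sa, sb, truth


# ---------------------------------------------------------------------------
# mediation DAG


def simulate_mediation_sumstats(
    panel: LDPanel, config: SimConfig
) -> tuple[SumStats, SumStats, SumStats, TruthRecord]:
    """Exposure -> mediator -> outcome summary statistics, three cohorts.

    Structural model on standardized genotypes G::

        X    = G·gamma + e_x                       (Var_g = h2_x)
        Mdtr = a·X + G·delta + e_m                 (direct Var_g = h2_m)
        L    = c'·X + b·Mdtr + e_y,  Y = 1[L > t]  (case fraction K)

    gamma and delta are supported on disjoint causal sets, so mediator
    instruments tag the mediator's own biology rather than the exposure
    pathway.  Marginal GWAS are run in three disjoint cohorts (exposure,
    mediator, outcome).  The binary outcome GWAS is a linear-probability
    regression rescaled by 1/(K(1-K)) to an approximate logistic scale;
    the truth record carries the analytic liability->observed scale
    factor so structural effects can be compared on the analysis scale.
    """
    if not (0.0 < config.case_fraction < 1.0):
        raise ValueError("case fraction must be in (0, 1)")
    for v in (config.a, config.b, config.c_prime):
        if not np.isfinite(v):
            raise ValueError("mediation coefficients must be finite")
    if min(config.n_x, config.n_y) < 50:
        raise ValueError("cohort size < 50: marginal regressions unstable")

    ss = np.random.SeedSequence([config.seed, 2])
    rng_eff, *cohort_rngs = (np.random.default_rng(s) for s in ss.spawn(4))

    M = panel.M
    Mc = max(2, int(round(config.causal_fraction * M)))
    all_causal = np.sort(rng_eff.choice(M, size=Mc, replace=False))
    half = Mc // 2
    causal_x, causal_m = all_causal[:half], all_causal[half:]
    gamma = _scaled_effects(rng_eff.standard_normal(half), causal_x, config.h2_x, panel.r)
    delta = _scaled_effects(
        rng_eff.standard_normal(Mc - half), causal_m, config.h2_m, panel.r
    )

    a, b, cp, K = config.a, config.b, config.c_prime, config.case_fraction

    def draw_cohort(n: int, rng: np.random.Generator):
        G = _simulate_dosages(panel, n, rng)
        Gs = _standardize(G)
        x = Gs @ gamma + rng.standard_normal(n) * np.sqrt(max(0.0, 1 - config.h2_x))
        m = a * x + Gs @ delta + rng.standard_normal(n) * np.sqrt(max(0.0, 1 - config.h2_m))
        liab = cp * x + b * m + rng.standard_normal(n)
        return G, x, m, liab

    n_out = config.n_y
    G1, x1, _, _ = draw_cohort(config.n_x, cohort_rngs[0])
    G2, _, m2, _ = draw_cohort(config.n_x, cohort_rngs[1])
    G3, _, _, l3 = draw_cohort(n_out, cohort_rngs[2])

    t = np.quantile(l3, 1.0 - K)
    y3 = (l3 > t).astype(float)
    k_real = float(y3.mean())

    exp_ss = _as_sumstats(panel, _marginal_gwas(G1, x1), "exposure", config.n_x)
    med_ss = _as_sumstats(panel, _marginal_gwas(G2, m2), "mediator", config.n_x)
    out_gwas = _marginal_gwas(G3, y3)
    scale = k_real * (1.0 - k_real)
    out_gwas["beta"] /= scale
    out_gwas["se"] /= scale
    out_ss = _as_sumstats(panel, out_gwas, "outcome", n_out)
    out_ss.table["n_case"] = int(y3.sum())
    out_ss.table["n_control"] = int(n_out - y3.sum())

    sd_l = float(l3.std())
    obs_factor = float(stats.norm.pdf((t - l3.mean()) / sd_l) / (sd_l * scale))
    if not config.binary_outcome:
        out_gwas2 = _marginal_gwas(G3, l3)
        out_ss = _as_sumstats(panel, out_gwas2, "outcome", n_out)
        obs_factor = 1.0

    truth = TruthRecord(
        beta_true={"exposure": gamma, "mediator_direct": delta},
        h2_realized={"exposure": config.h2_x, "mediator_direct": config.h2_m},
        causal_index={"exposure": causal_x, "mediator": causal_m},
        total_effect=cp + a * b,
        indirect_effect=a * b,
        direct_effect=cp,
        observed_scale_factor=obs_factor,
        cohorts={
            "exposure": (0, config.n_x),
            "mediator": (config.n_x, 2 * config.n_x),
            "outcome": (2 * config.n_x, 2 * config.n_x + n_out),
        },
    )
    return exp_ss, med_ss, out_ss, truth


# ---------------------------------------------------------------------------
# fast z-score mode


def simulate_zscores(
    panel: LDPanel, config: SimConfig
) -> tuple[SumStats, SumStats, TruthRecord]:
    """Marginal z-scores drawn directly as ``z ~ MVN(sqrt(n)·Σβ, Σ)``.

    Skips individual-level genotypes; intended for LD-score-regression
    and cross-phenotype meta-analysis calibration where only marginal z
    and LD scores matter.  Effects are reported on the standardized
    scale (beta = z/sqrt(n), se = 1/sqrt(n)); eaf is the panel maf.
    """
    ss = np.random.SeedSequence([config.seed, 3])
    rng_eff, rng_z = (np.random.default_rng(s) for s in ss.spawn(2))

    M = panel.M
    Mc = max(1, int(round(config.causal_fraction * M)))
    causal = np.sort(rng_eff.choice(M, size=Mc, replace=False))
    u = rng_eff.standard_normal(Mc)
    w = rng_eff.standard_normal(Mc)
    v = config.rg * u + np.sqrt(max(0.0, 1 - config.rg**2)) * w
    beta_x = _scaled_effects(u, causal, config.h2_x, panel.r)
    beta_y = _scaled_effects(v, causal, config.h2_y, panel.r)

    def draw_z(beta: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        z = np.empty(M)
        for sl in panel.blocks:
            C = panel.r[sl, sl]
            L = np.linalg.cholesky(C + 1e-10 * np.eye(C.shape[0]))
            mean = np.sqrt(n) * (C @ beta[sl])
            z[sl] = mean + L @ rng.standard_normal(C.shape[0])
        return z

    z_x = draw_z(beta_x, config.n_x, rng_z)
    z_y = draw_z(beta_y, config.n_y, rng_z)

    def to_ss(z: np.ndarray, n: int, label: str) -> SumStats:
        table = panel.variants[
            ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
        ].copy()
        table["eaf"] = panel.variants["maf"].to_numpy()
        table["beta"] = z / np.sqrt(n)
        table["se"] = 1.0 / np.sqrt(n)
        table["pvalue"] = np.clip(
            2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0
        )
        table["n"] = n
        return SumStats(trait_label=label, table=table)

    rg_real = _effect_correlation(beta_x[causal], beta_y[causal])
    truth = TruthRecord(
        beta_true={"trait_x": beta_x, "trait_y": beta_y},
        h2_realized={"trait_x": config.h2_x, "trait_y": config.h2_y},
        rg_realized=rg_real,
        causal_index={"shared": causal},
    )
    return to_ss(z_x, config.n_x, "trait_x"), to_ss(z_y, config.n_y, "trait_y"), truth


# ---------------------------------------------------------------------------
# instrument-level generator for estimator calibration


def simulate_mr_instruments(
    theta: float,
    n_instruments: int = 127,
    n_exp: int = 422_218,
    n_out: int = 159_208,
    h2_instruments: float = 0.041,
    pleiotropy_sd: float = 0.0,
    directional_pleiotropy: float = 0.0,
    outlier_index: int | None = None,
    outlier_offset_se: float = 0.0,
    seed: int = 0,
):
    """Summary-level instrument pairs under a known causal effect.

    Draws true per-variant exposure effects for ``n_instruments``
    independent instruments that jointly explain ``h2_instruments`` of
    the exposure, then observed effects ``beta_exp ~ N(beta, se_exp^2)``
    and ``beta_out ~ N(theta*beta + alpha_j, se_out^2)`` with per-variant
    pleiotropy ``alpha_j ~ N(directional_pleiotropy, pleiotropy_sd^2)``.
    Optionally plants one gross outlier offset (in units of its SE).
    Returns a :class:`~mrlab.sumstats.HarmonizedSet`.

    Defaults mirror the TV-watching -> T2D instrument design: 127
    instruments explaining 4.1% of the exposure in a 422 218-person
    exposure GWAS against a 159 208-person outcome GWAS (mean
    per-instrument F ~ 140, so weak-instrument dilution is negligible).
    """
    from .sumstats import HarmonizedSet

    rng = np.random.default_rng(seed)
    J = n_instruments
    beta = rng.normal(0.0, np.sqrt(h2_instruments / J), size=J)
    se_exp = np.full(J, 1.0 / np.sqrt(n_exp))
    se_out = np.full(J, 1.0 / np.sqrt(n_out))
    alpha = rng.normal(directional_pleiotropy, pleiotropy_sd, size=J)
    beta_exp = beta + rng.standard_normal(J) * se_exp
    beta_out = theta * beta + alpha + rng.standard_normal(J) * se_out
    if outlier_index is not None:
        beta_out[outlier_index] += outlier_offset_se * se_out[outlier_index]

    f = rng.uniform(0.05, 0.5, size=J)
    table = pd.DataFrame(
        {
            "variant_id": [f"iv{j + 1:04d}" for j in range(J)],
            "beta_exp": beta_exp, "se_exp": se_exp, "f_exp": f,
            "beta_out": beta_out, "se_out": se_out, "f_out": f,
            "n_exp": n_exp, "n_out": n_out,
            "z_exp": beta_exp / se_exp, "z_out": beta_out / se_out,
            "flipped": False,
        }
    )
    return HarmonizedSet(
        table=table, exclusions=pd.DataFrame(columns=["variant_id", "reason"])
    )
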