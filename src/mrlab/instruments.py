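"""Instrument selection: LD clumping, strength statistics, confounder filter.

Clumping follows the PLINK greedy rule: repeatedly take the smallest-p
unassigned variant below the index threshold ``p1`` as an index, then
assign every unassigned variant with p < p2, LD r^2 >= r2 with the index
and within ``kb`` kilobases on the same chromosome to that clump.  MR
instruments are the index variants of a strict clump (p1 = p2 = 5e-8,
r^2 >= 0.001 prunes).

Instrument strength uses the summary-data variance-explained formula

    r^2 = sum_j  beta_j^2 * 2 f_j (1-f_j)
               / [beta_j^2 * 2 f_j (1-f_j) + se_j^2 * 2 n_j f_j (1-f_j)]

and F = ((n - k - 1) / k) * r^2 / (1 - r^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import LDPanel
from .sumstats import SumStats


@dataclass
class Clump:
    index_variant: str
    members: list[str]


@dataclass
class ClumpResult:
    clumps: list[Clump]
    params: dict
    skipped: list[str] = field(default_factory=list)

    @property
    def index_variants(self) -> list[str]:
        return [c.index_variant for c in self.clumps]

    def __len__(self) -> int:
        return len(self.clumps)


@dataclass
class InstrumentSet:
    """Independent instruments with per-variant and total strength."""

    variant_ids: list[str]
    r2_per_variant: pd.Series
    n: float

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    @property
    def r2_total(self) -> float:
        return float(self.r2_per_variant.sum())

    @property
    def F(self) -> float:
        return f_statistic(self.n, self.k, self.r2_total)


def clump(
    s, panel: LDPanel, p1: float, p2: float, r2: float, kb: float
) -> ClumpResult:
    """Greedy PLINK-style clumping of an association table.

    ``s`` is a :class:`SumStats` or any DataFrame with columns
    variant_id, chrom, pos, pvalue.  Variants not covered by the panel
    are skipped (logged in ``ClumpResult.skipped``).  Ties in p are
    broken by (chrom, pos) ascending, making the result deterministic.
    """
    if kb <= 0:
        raise ValueError("kb window must be positive")
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("r2 threshold must be in [0, 1]")
    df = s.table if isinstance(s, SumStats) else s
    df = df[["variant_id", "chrom", "pos", "pvalue"]].copy()

    covered = pd.Index(panel.variants["variant_id"])
    in_panel = df["variant_id"].isin(covered)
    skipped = df.loc[~in_panel, "variant_id"].tolist()
    df = df.loc[in_panel].reset_index(drop=True)
    if df.empty:
        return ClumpResult(clumps=[], params=dict(p1=p1, p2=p2, r2=r2, kb=kb), skipped=skipped)

    idx = panel.index_of(df["variant_id"])
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pval = df["pvalue"].to_numpy()
    # deterministic processing order: p ascending, ties by (chrom, pos)
    order = np.lexsort((pos, chrom, pval))

    assigned = np.zeros(len(df), dtype=bool)
    clumps: list[Clump] = []
    r2mat = panel.r ** 2
    for i in order:
        if assigned[i] or pval[i] >= p1:
            continue
        assigned[i] = True
        member_mask = (
            ~assigned
            & (pval < p2)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= kb * 1000.0)
            & (r2mat[idx[i], idx] >= r2)
        )
        assigned |= member_mask
        members = df.loc[member_mask, "variant_id"].tolist()
        clumps.append(Clump(index_variant=df.loc[i, "variant_id"], members=members))
    return ClumpResult(clumps=clumps, params=dict(p1=p1, p2=p2, r2=r2, kb=kb), skipped=skipped)


def select_instruments(
    s: SumStats,
    panel: LDPanel,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    kb: float = 10_000,
) -> InstrumentSet:
    """Independent instruments at p < 5e-8 with pairwise LD r^2 < 0.001.

    Implemented as a strict clump (p1 = p2 = p_threshold, prune at
    r^2 >= r2_threshold) whose index variants become the instruments.
    The 10 Mb window makes LD, not distance, the effective criterion.
    """
    res = clump(s, panel, p1=p_threshold, p2=p_threshold, r2=r2_threshold, kb=kb)
    if not res.clumps:
        near = int((s.table["pvalue"] < p_threshold * 100).sum())
        raise ValueError(
            f"no instruments at p < {p_threshold:g} "
            f"({near} near-misses below {p_threshold * 100:g})"
        )
    ids = res.index_variants
    sub = s.indexed().loc[ids]
    return InstrumentSet(
        variant_ids=ids,
        r2_per_variant=variance_explained_terms(sub),
        n=float(sub["n"].median()),
    )


def variance_explained_terms(ivs: pd.DataFrame) -> pd.Series:
    """Per-variant variance-explained terms of the summary-data formula.

    Each term is beta^2*2f(1-f) / (beta^2*2f(1-f) + se^2*2n*f(1-f)).
    Variants with f in {0, 1} (or missing) carry zero genotype variance
    and are skipped with a warning.
    """
    f = ivs["eaf"].to_numpy(dtype=float)
    beta = ivs["beta"].to_numpy(dtype=float)
    se = ivs["se"].to_numpy(dtype=float)
    n = ivs["n"].to_numpy(dtype=float)
    het = 2.0 * f * (1.0 - f)
    bad = ~np.isfinite(het) | (het <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} variant(s) with zero/missing allele-frequency "
            "variance skipped in r^2",
            stacklevel=2,
        )
    num = beta**2 * het
    den = num + se**2 * 2.0 * n * f * (1.0 - f)
    terms = np.where(bad, 0.0, num / np.where(den == 0, np.nan, den))
    return pd.Series(np.nan_to_num(terms), index=ivs.index, name="r2_term")


def variance_explained(ivs: pd.DataFrame) -> float:
    """Total instrument r^2 (sum of per-variant terms)."""
    return float(variance_explained_terms(ivs).sum())


def f_statistic(n: float, k: int, r2: float) -> float:
    """Instrument-strength F = ((n-k-1)/k) * r2/(1-r2)."""
    if r2 >= 1.0:
        raise ValueError("r2 must be < 1")
    if r2 < 0.0:
        raise ValueError("r2 must be >= 0")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return (n - k - 1) / k * r2 / (1.0 - r2)


def exclude_confounder_snps(
    ivs: InstrumentSet,
    annotation: pd.DataFrame,
    blocklist: list[str],
    p_threshold: float = 5e-8,
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Drop instruments associated with blocklisted (confounder) traits.

    ``annotation`` has columns variant_id, trait, pvalue — a user-supplied
    stand-in for a GWAS-catalog query.  An instrument is removed when it
    is annotated to any blocklisted trait at p < 5e-8.  Returns the
    filtered set and the removal log.
    """
    if annotation.empty or not blocklist:
        return ivs, pd.DataFrame(columns=["variant_id", "trait", "pvalue"])
    hits = annotation[
        annotation["trait"].isin(blocklist)
        & (annotation["pvalue"] < p_threshold)
        & annotation["variant_id"].isin(ivs.variant_ids)
    ]
    removed = set(hits["variant_id"])
    kept = [v for v in ivs.variant_ids if v not in removed]
    return (
        InstrumentSet(
            variant_ids=kept,
            r2_per_variant=ivs.r2_per_variant.loc[kept],
            n=ivs.n,
        ),
        hits.reset_index(drop=True),
    )
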