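"""GWAS summary-statistics containers, validation and two-sample harmonization.

Summary statistics are exchanged as tab-delimited tables (one row per
variant) with the columns ``variant_id, chrom, pos, effect_allele,
other_allele, eaf, beta, se, pvalue, n`` and optionally ``n_case,
n_control``.  All positions refer to GRCh37.  Harmonization aligns an
outcome GWAS to the effect allele of an exposure GWAS, excluding
palindromic (A/T, C/G) variants outright because their strand cannot be
resolved from alleles and frequencies alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for the on-disk TSV dialect
CORE_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]
OPTIONAL_COLUMNS = ["n_case", "n_control"]

#: |z(beta/se) - z(p)| above which a consistency warning is raised
Z_CONSISTENCY_TOL = 0.05

#: aligned |f_exp - f_out| above which a frequency-sanity warning is raised
FREQ_SANITY_THRESHOLD = 0.2


class SumStatsError(ValueError):
    """Raised for structurally invalid summary-statistics input."""


def _zscore_from_p(pvalue: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Two-sided p and effect sign -> signed z via the normal inverse tail."""
    z = -stats.norm.ppf(np.asarray(pvalue, dtype=float) / 2.0)
    return np.sign(np.where(beta == 0, 1.0, beta)) * z


@dataclass
class SumStats:
    """One trait's GWAS summary statistics.

    ``table`` holds one row per variant (unique ``variant_id``), in input
    order, with a derived ``z = beta / se`` column.  ``exclusions`` logs
    rows dropped during validation as (variant_id, reason) pairs.
    """

    trait_label: str
    table: pd.DataFrame
    genome_build: str = "GRCh37"
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.table["variant_id"].duplicated().any():
            dup = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise SumStatsError(f"duplicate variant_id {dup!r} in {self.trait_label}")
        if (self.table["pos"] < 0).any():
            raise SumStatsError("negative positions present")
        if not self.genome_build:
            raise SumStatsError("genome build label required")
        if "z" not in self.table.columns:
            self.table = self.table.assign(z=self.table["beta"] / self.table["se"])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.table["variant_id"])

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("variant_id", drop=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to the exposure's effect allele.

    ``table`` columns: variant_id, beta_exp, se_exp, f_exp, beta_out,
    se_out, f_out, n_exp, n_out, z_exp, z_out, flipped.  ``exclusions``
    maps dropped variants to one of ``palindromic | allele_mismatch |
    missing``.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_snp(self) -> int:
        return len(self.table)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-wise invariant checks; returns (kept, exclusion log)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & (reasons == "")
        reasons[new] = reason

    flag(~df["effect_allele"].isin(VALID_BASES) | ~df["other_allele"].isin(VALID_BASES),
         "invalid_allele")
    flag(df["effect_allele"] == df["other_allele"], "identical_alleles")
    flag(~(df["se"] > 0), "nonpositive_se")
    flag(df["eaf"].notna() & ~df["eaf"].between(0.0, 1.0), "eaf_out_of_range")
    flag(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue_out_of_range")
    flag(~(df["n"] > 0), "nonpositive_n")

    bad = reasons != ""
    log = pd.DataFrame(
        {"variant_id": df.loc[bad, "variant_id"].to_numpy(), "reason": reasons[bad].to_numpy()}
    )
    return df.loc[~bad].copy(), log


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_label: str | None = None,
) -> SumStats:
    """Read a tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    column_map
        Optional mapping from the file's column names to the canonical
        names (e.g. ``{"SNP": "variant_id", "A1": "effect_allele"}``),
        absorbing consortium dialects.
    trait_label
        Label for the trait; defaults to the file stem.

    Rows violating per-variant invariants (nonpositive SE, out-of-range
    frequency or p, invalid alleles) are dropped and logged in
    ``SumStats.exclusions``; row order is preserved.  A warning is raised
    when the stored p-value and beta/se disagree (|Δz| > 0.05).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        raise SumStatsError(f"empty summary-statistics file: {path}")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CORE_COLUMNS if c not in df.columns and c != "eaf"]
    if missing:
        raise SumStatsError(f"missing mandatory column(s): {', '.join(missing)}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)

    kept, log = _validate_rows(df)
    kept = kept.assign(z=kept["beta"] / kept["se"])

    # p-value vs beta/se consistency (validation warning, not exclusion)
    z_p = _zscore_from_p(kept["pvalue"].to_numpy(), kept["beta"].to_numpy())
    finite = np.isfinite(z_p)
    bad_z = finite & (np.abs(kept["z"].to_numpy() - z_p) > Z_CONSISTENCY_TOL)
    if bad_z.any():
        warnings.warn(
            f"{int(bad_z.sum())} variant(s) with |z(beta/se) - z(p)| > "
            f"{Z_CONSISTENCY_TOL}; p-values and effects may be inconsistent",
            stacklevel=2,
        )

    label = trait_label if trait_label is not None else _stem(path)
    return SumStats(trait_label=label, table=kept.reset_index(drop=True), exclusions=log)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_sumstats(s: SumStats, path) -> None:
    """Write the canonical TSV dialect (round-trips through read_sumstats)."""
    cols = [c for c in CORE_COLUMNS + OPTIONAL_COLUMNS if c in s.table.columns]
    s.table.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.17g")


def write_exclusion_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False, columns=["variant_id", "reason"])


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is complementary ({A,T} or {C,G})."""
    return COMPLEMENT.get(effect_allele) == other_allele


def detect_palindromes(s: SumStats) -> dict[str, bool]:
    """Map variant_id -> whether its allele pair is strand-ambiguous."""
    ea = s.table["effect_allele"].to_numpy()
    oa = s.table["other_allele"].to_numpy()
    flags = np.array([is_palindromic(a, b) for a, b in zip(ea, oa)])
    return dict(zip(s.table["variant_id"], (bool(f) for f in flags)))


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    iv_ids: list[str] | None = None,
    freq_warning_threshold: float = FREQ_SANITY_THRESHOLD,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele.

    For each instrument: palindromic variants are excluded; variants
    absent from the outcome are logged as missing; when the outcome's
    effect allele equals the exposure's *other* allele, the outcome beta
    is negated and its frequency replaced by 1 - f; variants whose allele
    sets do not match are excluded.  Retained + excluded = input.
    """
    exp = exposure.indexed()
    out = outcome.indexed()
    ids = list(iv_ids) if iv_ids is not None else list(exp.index)
    unknown = [i for i in ids if i not in exp.index]
    if unknown:
        raise SumStatsError(f"iv_ids not present in exposure: {unknown[:5]}")

    rows = []
    excl: list[tuple[str, str]] = []
    for vid in ids:
        e = exp.loc[vid]
        if vid not in out.index:
            excl.append((vid, "missing"))
            continue
        o = out.loc[vid]
        if is_palindromic(e["effect_allele"], e["other_allele"]) or is_palindromic(
            o["effect_allele"], o["other_allele"]
        ):
            excl.append((vid, "palindromic"))
            continue
        if (o["effect_allele"], o["other_allele"]) == (e["effect_allele"], e["other_allele"]):
            flipped = False
            beta_out, f_out = o["beta"], o["eaf"]
        elif (o["effect_allele"], o["other_allele"]) == (e["other_allele"], e["effect_allele"]):
            flipped = True
            beta_out = -o["beta"]
            f_out = 1.0 - o["eaf"] if pd.notna(o["eaf"]) else np.nan
        else:
            # includes strand-coded mismatches (e.g. A/G vs T/C): excluded,
            # not strand-flipped, since the strand cannot be confirmed
            excl.append((vid, "allele_mismatch"))
            continue
        rows.append(
            dict(
                variant_id=vid,
                beta_exp=e["beta"], se_exp=e["se"], f_exp=e["eaf"],
                beta_out=beta_out, se_out=o["se"], f_out=f_out,
                n_exp=e["n"], n_out=o["n"],
                z_exp=e["beta"] / e["se"], z_out=beta_out / o["se"],
                flipped=flipped,
            )
        )

    if not rows and not excl:
        raise SumStatsError("no overlapping instruments")
    table = pd.DataFrame(
        rows,
        columns=["variant_id", "beta_exp", "se_exp", "f_exp", "beta_out",
                 "se_out", "f_out", "n_exp", "n_out", "z_exp", "z_out", "flipped"],
    )
    if table.empty and excl:
        raise SumStatsError("no overlapping instruments after harmonization")

    if len(table):
        d = (table["f_exp"] - table["f_out"]).abs()
        n_warn = int((d > freq_warning_threshold).sum())
        if n_warn:
            warnings.warn(
                f"{n_warn} variant(s) with aligned allele-frequency difference "
                f"> {freq_warning_threshold}; check strand/build consistency",
                stacklevel=2,
            )

    log = pd.DataFrame(excl, columns=["variant_id", "reason"])
    return HarmonizedSet(table=table.reset_index(drop=True), exclusions=log)
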