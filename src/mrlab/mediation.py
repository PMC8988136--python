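"""Two-step MR mediation: product-of-coefficients decomposition.

For a candidate mediator, two MR estimates are combined: ``a``
(exposure -> mediator) and ``b`` (mediator -> outcome).  The indirect
effect is a*b, the direct effect c' = c - a*b where c is the total
exposure -> outcome effect, and the proportion mediated is (a*b)/c.
A mediator counts as significant only when both steps individually pass
the Bonferroni gate (0.05/11 for the eleven candidate mediators);
non-significant mediators never contribute to a combined decomposition.

Two proportion conventions are exposed: ``proportion`` uses the
unrounded indirect effect; ``proportion_table`` first rounds the
indirect effect to 3 decimals and then divides by the total — the
convention used when quoting proportions next to 3-decimal tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mr import MREstimate

#: Bonferroni gate for eleven candidate mediators
ALPHA_MEDIATION = 0.05 / 11


@dataclass
class MediationResult:
    """One mediator's two-step decomposition."""

    mediator: str
    a: float
    a_pvalue: float
    b: float
    b_pvalue: float
    total: float
    a_egger_intercept_p: float | None = None
    b_egger_intercept_p: float | None = None
    alpha: float = ALPHA_MEDIATION

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def direct(self) -> float:
        return self.total - self.indirect

    @property
    def adjusted_or(self) -> float:
        return float(np.exp(self.direct))

    @property
    def proportion(self) -> float:
        return self.indirect / self.total

    @property
    def proportion_table(self) -> float:
        """Proportion computed from the 3-dp-rounded indirect effect."""
        return round(self.indirect, 3) / self.total

    @property
    def significant(self) -> bool:
        return self.a_pvalue < self.alpha and self.b_pvalue < self.alpha


@dataclass
class CombinedMediation:
    """Joint decomposition over the significant mediators."""

    members: list[MediationResult]
    total: float

    @property
    def indirect(self) -> float:
        return float(sum(m.indirect for m in self.members))

    @property
    def direct(self) -> float:
        return self.total - self.indirect

    @property
    def adjusted_or(self) -> float:
        return float(np.exp(self.direct))

    @property
    def proportion(self) -> float:
        return self.indirect / self.total

    @property
    def proportion_table(self) -> float:
        return round(self.indirect, 3) / self.total

    def __len__(self) -> int:
        return len(self.members)


def two_step_mediation(
    est_xm: MREstimate,
    est_my: MREstimate,
    total_c: float,
    mediator: str = "",
    alpha_bonf: float = ALPHA_MEDIATION,
) -> MediationResult:
    """Assemble a mediation decomposition from the two MR step estimates.

    ``est_xm`` estimates the exposure -> mediator effect (a), ``est_my``
    the mediator -> outcome effect (b); ``total_c`` is the total
    exposure -> outcome effect from the primary MR.  The identity
    indirect + direct = total holds exactly by construction.
    """
    if not np.isfinite(total_c):
        raise ValueError("total effect must be finite")
    return MediationResult(
        mediator=mediator,
        a=est_xm.beta_hat,
        a_pvalue=est_xm.pvalue,
        b=est_my.beta_hat,
        b_pvalue=est_my.pvalue,
        total=total_c,
        a_egger_intercept_p=est_xm.egger_intercept_p,
        b_egger_intercept_p=est_my.egger_intercept_p,
        alpha=alpha_bonf,
    )


def combine_mediators(
    results: list[MediationResult], total_c: float
) -> CombinedMediation:
    """Combined decomposition summing unrounded indirect effects over the
    significant mediators (empty, not an error, when none qualify)."""
    members = [r for r in results if r.significant]
    return CombinedMediation(members=members, total=total_c)


def mediation_table(results: list[MediationResult], total_c: float):
    """3-decimal summary table plus the combined row."""
    import pandas as pd

    rows = []
    for r in results:
        sig = r.significant
        rows.append(
            dict(
                mediator=r.mediator,
                a=round(r.a, 3),
                a_pvalue=r.a_pvalue,
                b=round(r.b, 3),
                b_pvalue=r.b_pvalue,
                indirect=round(r.indirect, 3) if sig else np.nan,
                direct=round(r.direct, 3) if sig else np.nan,
                adjusted_or=round(r.adjusted_or, 2) if sig else np.nan,
                proportion_pct=round(100 * r.proportion_table, 2) if sig else np.nan,
                significant=sig,
            )
        )
    combined = combine_mediators(results, total_c)
    if len(combined):
        rows.append(
            dict(
                mediator="ALL",
                a=np.nan,
                a_pvalue=np.nan,
                b=np.nan,
                b_pvalue=np.nan,
                indirect=round(combined.indirect, 3),
                direct=round(combined.direct, 3),
                adjusted_or=round(combined.adjusted_or, 2),
                proportion_pct=round(100 * combined.proportion_table, 2),
                significant=True,
            )
        )
    return pd.DataFrame(rows)
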