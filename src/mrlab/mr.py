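"""Two-sample Mendelian randomization estimators and diagnostics.

All estimators consume a :class:`~mrlab.sumstats.HarmonizedSet` of
aligned per-variant effect pairs (beta_exp, se_exp, beta_out, se_out).
The per-variant building block is the Wald ratio theta_j =
beta_out_j / beta_exp_j with first-order (delta-method) standard error
se_out_j / |beta_exp_j| and inverse-variance weight w_j = 1/se_j^2.

The battery:

* :func:`ivw` — multiplicative random-effects inverse-variance weighting
  (the primary estimator), with Cochran's Q heterogeneity test;
* :func:`weighted_median` — consistent when up to half the weight is on
  invalid instruments;
* :func:`egger` — weighted regression with an intercept probing
  directional pleiotropy;
* :func:`raps` — robust adjusted profile score, tolerant of many weak
  instruments and overdispersed pleiotropy;
* :func:`presso` — residual-sum-of-squares outlier search with an
  outlier-corrected re-estimate;
* :func:`steiger` — directionality check from instrument-explained
  variance in exposure versus outcome;
* :func:`leave_one_out` — influence diagnostics;
* :func:`mr_power_binary` — analytic power for a binary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sumstats import HarmonizedSet

Z975 = stats.norm.ppf(0.975)

#: Bonferroni significance gate used for the six primary MR analyses
ALPHA_MR = 0.05 / 6


@dataclass
class MREstimate:
    """One estimator's causal-effect result with uncertainty/diagnostics."""

    method: str
    beta_hat: float
    se: float
    pvalue: float
    n_snp: int
    q_stat: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    tau2: float | None = None
    global_p: float | None = None
    outliers: list[str] = field(default_factory=list)
    steiger_direction: bool | None = None
    steiger_p: float | None = None
    raw_beta: float | None = None
    raw_se: float | None = None
    raw_pvalue: float | None = None

    @property
    def ci_low(self) -> float:
        return self.beta_hat - Z975 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta_hat + Z975 * self.se

    @property
    def or_hat(self) -> float:
        return float(np.exp(self.beta_hat))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def significant(self, alpha: float = ALPHA_MR) -> bool:
        return self.pvalue < alpha


def _ratios(h: HarmonizedSet):
    t = h.table
    bx = t["beta_exp"].to_numpy(dtype=float)
    by = t["beta_out"].to_numpy(dtype=float)
    sx = t["se_exp"].to_numpy(dtype=float)
    sy = t["se_out"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ValueError("ratio undefined: beta_exp = 0 for some instrument")
    theta = by / bx
    se = sy / np.abs(bx)
    return theta, se, bx, by, sx, sy


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(h: HarmonizedSet) -> MREstimate:
    """Single-instrument Wald ratio with delta-method SE."""
    if len(h) != 1:
        raise ValueError("wald_ratio expects exactly one instrument")
    theta, se, *_ = _ratios(h)
    return MREstimate(
        method="Wald ratio",
        beta_hat=float(theta[0]),
        se=float(se[0]),
        pvalue=_two_sided_p(theta[0] / se[0]),
        n_snp=1,
    )


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    beta_hat = sum(w*theta)/sum(w) with w = 1/se_theta^2; the fixed
    SE (sum w)^(-1/2) is inflated by max(1, sqrt(Q/(J-1))) where Q is
    Cochran's heterogeneity statistic, chi-square with J-1 df.
    """
    if len(h) < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio")
    theta, se, *_ = _ratios(h)
    w = 1.0 / se**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    J = len(theta)
    q_p = float(stats.chi2.sf(q, J - 1))
    scale = max(1.0, np.sqrt(q / (J - 1))) if random_effects else 1.0
    se_hat = se_fixed * scale
    return MREstimate(
        method="IVW",
        beta_hat=beta,
        se=se_hat,
        pvalue=_two_sided_p(beta / se_hat),
        n_snp=J,
        q_stat=q,
        q_pvalue=q_p,
    )


def weighted_median(h: HarmonizedSet, boot_reps: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the ratio estimates.

    The estimate interpolates the weighted empirical CDF of ordered
    theta_j at probability 0.5 using standardized cumulative weights
    s_j = (cumsum(w)_j - w_j/2)/sum(w).  SE comes from a parametric
    bootstrap resampling theta_j ~ N(theta_j, se_j^2).
    """
    if len(h) < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    if boot_reps < 100:
        import warnings

        warnings.warn("fewer than 100 bootstrap reps: SE will be noisy", stacklevel=2)
    theta, se, *_ = _ratios(h)
    w = 1.0 / se**2

    def wmedian(th: np.ndarray) -> float:
        order = np.argsort(th)
        th_s, w_s = th[order], w[order]
        s = (np.cumsum(w_s) - 0.5 * w_s) / np.sum(w_s)
        return float(np.interp(0.5, s, th_s))

    est = wmedian(theta)
    rng = np.random.default_rng(seed)
    boots = np.empty(boot_reps)
    for r in range(boot_reps):
        boots[r] = wmedian(theta + rng.standard_normal(len(theta)) * se)
    se_hat = float(boots.std(ddof=1))
    return MREstimate(
        method="Weighted median",
        beta_hat=est,
        se=se_hat,
        pvalue=_two_sided_p(est / se_hat),
        n_snp=len(theta),
    )


def egger(h: HarmonizedSet, t_dist: bool = False) -> MREstimate:
    """MR-Egger regression: slope is the causal effect, intercept probes
    directional pleiotropy.

    Instruments are oriented so beta_exp >= 0 (flipping both effects;
    allele-coding invariant).  Weighted least squares with weights
    1/se_out^2; both SEs are inflated by max(1, sqrt(RSS_w/(J-2))).
    Normal p-values by default (t with J-2 df behind ``t_dist``).
    """
    if len(h) < 3:
        raise ValueError("Egger regression needs >= 3 instruments")
    _, _, bx, by, sx, sy = _ratios(h)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all beta_exp identical")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ y)
    resid = y - X @ coef
    J = len(x)
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (J - 2)))
    cov = np.linalg.inv(xtx) * scale**2
    se_int, se_slope = np.sqrt(np.diag(cov))
    if t_dist:
        pfun = lambda z: float(2.0 * stats.t.sf(abs(z), J - 2))  # noqa: E731
    else:
        pfun = _two_sided_p
    return MREstimate(
        method="MR-Egger",
        beta_hat=float(coef[1]),
        se=float(se_slope),
        pvalue=pfun(coef[1] / se_slope),
        n_snp=J,
        q_stat=rss_w,
        q_pvalue=float(stats.chi2.sf(rss_w, J - 2)),
        egger_intercept=float(coef[0]),
        egger_intercept_p=pfun(coef[0] / se_int),
    )


def _raps_objective(theta, bx, by, sx, sy, tau2, loss, delta=1.345):
    t = (by - theta * bx) / np.sqrt(sy**2 + theta**2 * sx**2 + tau2)
    if loss == "plain":
        return 0.5 * np.sum(t**2)
    a = np.abs(t)
    return float(np.sum(np.where(a <= delta, 0.5 * t**2, delta * a - 0.5 * delta**2)))


def raps(
    h: HarmonizedSet,
    loss: str = "plain",
    overdispersion: bool = False,
    max_iter: int = 50,
) -> MREstimate:
    """Robust adjusted profile score estimator.

    Minimizes sum rho(t_j) over theta where t_j = (beta_out_j -
    theta*beta_exp_j)/sqrt(se_out_j^2 + theta^2 se_exp_j^2 + tau^2), rho
    the squared (``plain``) or Huber (delta=1.345) loss.  With
    ``overdispersion`` the pleiotropy variance tau^2 is profiled by a
    moment condition (mean t^2 = 1), floored at 0.  Bounded scalar
    optimization from three starts; sandwich SE.
    """
    if len(h) < 3:
        raise ValueError("RAPS needs >= 3 instruments")
    if loss not in ("plain", "huber"):
        raise ValueError("loss must be 'plain' or 'huber'")
    theta0, se0, bx, by, sx, sy = _ratios(h)

    span = max(1.0, 3.0 * np.nanmax(np.abs(theta0)))
    bounds = (-span, span)

    def solve_theta(tau2: float) -> float:
        starts = [np.median(theta0), 0.0, np.average(theta0, weights=1 / se0**2)]
        best, best_val = None, np.inf
        for s0 in starts:
            res = optimize.minimize_scalar(
                _raps_objective,
                bounds=bounds,
                args=(bx, by, sx, sy, tau2, loss),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        if best is None:
            raise RuntimeError("RAPS failed to converge")
        return float(best)

    tau2 = 0.0
    theta = solve_theta(tau2)
    if overdispersion:
        for _ in range(max_iter):
            def moment(t2: float) -> float:
                t = (by - theta * bx) / np.sqrt(sy**2 + theta**2 * sx**2 + t2)
                return float(np.mean(t**2) - 1.0)

            if moment(0.0) <= 0:
                tau2_new = 0.0
            else:
                hi = np.var(by - theta * bx) + 1e-12
                while moment(hi) > 0:
                    hi *= 4.0
                tau2_new = float(optimize.brentq(moment, 0.0, hi, xtol=1e-14))
            theta_new = solve_theta(tau2_new)
            if abs(theta_new - theta) < 1e-10 and abs(tau2_new - tau2) < 1e-12:
                theta, tau2 = theta_new, tau2_new
                break
            theta, tau2 = theta_new, tau2_new

    # sandwich SE: score per instrument, numerical derivative of total score
    def total_score(th: float) -> np.ndarray:
        sig = np.sqrt(sy**2 + th**2 * sx**2 + tau2)
        t = (by - th * bx) / sig
        dt = -(bx / sig) - t * th * sx**2 / sig**2
        if loss == "plain":
            psi = t
        else:
            psi = np.clip(t, -1.345, 1.345)
        return psi * dt

    g = total_score(theta)
    eps = 1e-6 * max(1.0, abs(theta))
    dg = (total_score(theta + eps).sum() - total_score(theta - eps).sum()) / (2 * eps)
    var = float(np.sum(g**2) / dg**2)
    se_hat = np.sqrt(var)
    return MREstimate(
        method="MR-RAPS",
        beta_hat=theta,
        se=se_hat,
        pvalue=_two_sided_p(theta / se_hat),
        n_snp=len(bx),
        tau2=tau2 if overdispersion else None,
    )


def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant leave-one-out IVW estimates (influence diagnostics).

    Returns one row per excluded variant with the re-estimated effect,
    SE, p, and a flag when that row's 95% CI excludes the full-set
    estimate (i.e. the full result hinges on a single SNP).
    """
    if len(h) < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    theta, se, *_ = _ratios(h)
    w = 1.0 / se**2
    J = len(theta)
    full = ivw(h)
    rows = []
    for j in range(J):
        mask = np.ones(J, dtype=bool)
        mask[j] = False
        wj, tj = w[mask], theta[mask]
        beta = float(np.sum(wj * tj) / np.sum(wj))
        se_fixed = float(np.sum(wj) ** -0.5)
        q = float(np.sum(wj * (tj - beta) ** 2))
        se_hat = se_fixed * max(1.0, np.sqrt(q / (J - 2))) if J > 2 else se_fixed
        rows.append(
            dict(
                variant_id=h.table["variant_id"].iloc[j],
                beta_hat=beta,
                se=se_hat,
                pvalue=_two_sided_p(beta / se_hat),
                ci_excludes_full=abs(beta - full.beta_hat) > Z975 * se_hat,
            )
        )
    return pd.DataFrame(rows)


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha_outlier: float = 0.05,
) -> MREstimate:
    """Pleiotropy residual-sum-and-outlier (PRESSO-style) test.

    Observed RSS uses leave-one-out IVW predictions: RSS =
    sum_j (beta_out_j - theta_(-j)*beta_exp_j)^2.  The null distribution
    simulates effect pairs from normals centred on the fitted means with
    the observed SEs.  The global p is the MC exceedance probability;
    per-variant outlier p-values are Bonferroni-corrected over J.  The
    returned estimate is IVW on the non-outlier instruments (the raw
    IVW is recoverable by re-running :func:`ivw` on the input).
    """
    if len(h) < 4:
        raise ValueError("PRESSO needs >= 4 instruments")
    if n_sim < 500:
        raise ValueError("n_sim must be >= 500")
    theta, se_th, bx, by, sx, sy = _ratios(h)
    w = 1.0 / se_th**2
    J = len(theta)
    S1, S0 = np.sum(w * theta), np.sum(w)
    theta_loo = (S1 - w * theta) / (S0 - w)  # per-j IVW excluding j

    resid_obs = by - theta_loo * bx
    rss_obs = float(np.sum(resid_obs**2))
    rss_j_obs = resid_obs**2

    rng = np.random.default_rng(seed)
    exceed = 0
    exceed_j = np.zeros(J)
    for _ in range(n_sim):
        bx_s = bx + rng.standard_normal(J) * sx
        by_s = theta_loo * bx + rng.standard_normal(J) * sy
        th_s = by_s / bx_s
        se_s = sy / np.abs(bx_s)
        w_s = 1.0 / se_s**2
        S1_s, S0_s = np.sum(w_s * th_s), np.sum(w_s)
        loo_s = (S1_s - w_s * th_s) / (S0_s - w_s)
        r_s = by_s - loo_s * bx_s
        rj = r_s**2
        if rj.sum() >= rss_obs:
            exceed += 1
        exceed_j += rj >= rss_j_obs
    global_p = (1 + exceed) / (n_sim + 1)
    p_j = np.minimum(1.0, (1 + exceed_j) / (n_sim + 1) * J)  # Bonferroni
    outlier_mask = p_j < alpha_outlier
    if outlier_mask.all():
        raise ValueError("all instruments flagged as outliers")
    outlier_ids = h.table["variant_id"].to_numpy()[outlier_mask].tolist()

    keep = ~outlier_mask
    sub = HarmonizedSet(
        table=h.table.loc[keep].reset_index(drop=True), exclusions=h.exclusions
    )
    corrected = ivw(sub)
    raw = ivw(h)
    return MREstimate(
        method="MR-PRESSO (outlier-corrected)",
        beta_hat=corrected.beta_hat,
        se=corrected.se,
        pvalue=corrected.pvalue,
        n_snp=corrected.n_snp,
        q_stat=corrected.q_stat,
        q_pvalue=corrected.q_pvalue,
        global_p=float(global_p),
        outliers=outlier_ids,
        raw_beta=raw.beta_hat,
        raw_se=raw.se,
        raw_pvalue=raw.pvalue,
    )


def steiger(h: HarmonizedSet) -> tuple[bool, float]:
    """Directionality test: does the instrument set explain more variance
    in the exposure than in the outcome?

    Per trait, r^2 = sum_j z_j^2/(z_j^2 + n - 2) over instruments.
    Direction is True iff r2_exp > r2_out (tie -> False); the p-value
    compares Fisher-transformed sqrt(r^2) between the two independent
    samples.
    """
    t = h.table
    if t["n_exp"].isna().any() or t["n_out"].isna().any():
        raise ValueError("sample sizes required for the Steiger test")
    z_exp = t["z_exp"].to_numpy(dtype=float)
    z_out = t["z_out"].to_numpy(dtype=float)
    n_exp = float(t["n_exp"].median())
    n_out = float(t["n_out"].median())
    r2_exp = float(np.sum(z_exp**2 / (z_exp**2 + n_exp - 2)))
    r2_out = float(np.sum(z_out**2 / (z_out**2 + n_out - 2)))
    r2_exp, r2_out = min(r2_exp, 1 - 1e-12), min(r2_out, 1 - 1e-12)
    direction = r2_exp > r2_out
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    return direction, _two_sided_p(z)


def mr_power_binary(
    n_total: float, case_fraction: float, r2: float, odds_ratio: float, alpha: float = 0.05
) -> float:
    """Analytic power of two-sample MR with a binary outcome.

    power = Phi( |log OR| * sqrt(N * r2 * K * (1-K)) - z_{1-alpha/2} )
          + Phi( -|log OR| * sqrt(...) - z_{1-alpha/2} )

    where K is the case fraction and r2 the exposure variance explained
    by the instruments.  At OR = 1 this returns alpha (two-sided test).
    """
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case fraction must be in (0, 1)")
    if not (0.0 < r2 < 1.0):
        raise ValueError("r2 must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    ncp = abs(np.log(odds_ratio)) * np.sqrt(
        n_total * r2 * case_fraction * (1.0 - case_fraction)
    )
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(ncp - zc) + stats.norm.cdf(-ncp - zc))


def mr_battery(
    h: HarmonizedSet,
    methods: tuple[str, ...] = ("ivw", "wm", "egger", "raps", "presso"),
    seed: int = 0,
) -> pd.DataFrame:
    """Run the estimator battery and return a table of results.

    Single-instrument sets fall back to the Wald ratio.  The Steiger
    direction and p are attached to every row.
    """
    runners = {
        "ivw": lambda: ivw(h),
        "wm": lambda: weighted_median(h, seed=seed),
        "egger": lambda: egger(h),
        "raps": lambda: raps(h, overdispersion=True),
        "presso": lambda: presso(h, seed=seed),
    }
    if len(h) == 1:
        results = [wald_ratio(h)]
    else:
        results = []
        for m in methods:
            if m not in runners:
                raise ValueError(f"unknown method {m!r}")
            try:
                results.append(runners[m]())
            except ValueError:
                continue  # too few instruments for this method
    direction, p_steiger = steiger(h)
    rows = []
    for r in results:
        rows.append(
            dict(
                method=r.method,
                n_snp=r.n_snp,
                beta=r.beta_hat,
                or_=r.or_hat,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                se=r.se,
                pvalue=r.pvalue,
                q_pvalue=r.q_pvalue,
                egger_intercept_p=r.egger_intercept_p,
                steiger_direction=direction,
                steiger_p=p_steiger,
                significant=r.significant(),
            )
        )
    table = pd.DataFrame(rows)
    for col in ("q_pvalue", "egger_intercept_p"):
        table[col] = table[col].astype(float)
    return table
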