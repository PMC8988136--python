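"""Study-flow orchestration: instruments -> harmonization -> MR battery
-> reverse MR -> mediation -> cross-trait stages, from a YAML/dict config.

Every filter step logs (input count, output count, reason histogram);
the resolved configuration and master seed are embedded in the JSON
summary for provenance, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import cross_trait, instruments, mediation, mr, simulate, sumstats

log = logging.getLogger("mrlab")

DEFAULT_THRESHOLDS = dict(
    p_iv=5e-8,
    ld_r2=0.001,
    p_meta=2.5e-8,
    p_single=1e-5,
    alpha_mr=0.05 / 6,
    alpha_mediation=0.05 / 11,
)


@dataclass
class PipelineConfig:
    exposure: str
    outcome: str
    panel: str | None = None
    mediators: dict[str, str] = field(default_factory=dict)
    annotation: str | None = None
    confounder_traits: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    run_reverse: bool = True
    run_mediation: bool = True
    run_cross_trait: bool = True
    seed: int = 0
    out_dir: str = "mrlab_out"

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _count_log(stage: str, n_in: int, n_out: int, reasons: dict) -> dict:
    entry = dict(stage=stage, n_in=int(n_in), n_out=int(n_out), reasons=reasons)
    log.info("%s: %d -> %d %s", stage, n_in, n_out, reasons or "")
    return entry


def _mr_direction(
    exposure: sumstats.SumStats,
    outcome: sumstats.SumStats,
    panel: simulate.LDPanel | None,
    cfg: PipelineConfig,
    counts: list[dict],
    annotation: pd.DataFrame | None,
) -> tuple[pd.DataFrame, sumstats.HarmonizedSet]:
    th = cfg.thresholds
    if panel is not None:
        ivset = instruments.select_instruments(
            exposure, panel, p_threshold=th["p_iv"], r2_threshold=th["ld_r2"]
        )
        iv_ids = ivset.variant_ids
    else:
        iv_ids = exposure.table.loc[
            exposure.table["pvalue"] < th["p_iv"], "variant_id"
        ].tolist()
        ivset = None
    n_candidates = int((exposure.table["pvalue"] < th["p_iv"]).sum())
    counts.append(
        _count_log(
            f"select_instruments[{exposure.trait_label}]",
            n_candidates,
            len(iv_ids),
            {"ld_pruned": n_candidates - len(iv_ids)},
        )
    )

    if ivset is not None and annotation is not None and cfg.confounder_traits:
        before = ivset.k
        ivset, removed = instruments.exclude_confounder_snps(
            ivset, annotation, cfg.confounder_traits
        )
        iv_ids = ivset.variant_ids
        counts.append(
            _count_log(
                f"exclude_confounders[{exposure.trait_label}]",
                before,
                ivset.k,
                {"confounder_associated": before - ivset.k},
            )
        )

    h = sumstats.harmonize(exposure, outcome, iv_ids)
    reasons = h.exclusions["reason"].value_counts().to_dict()
    counts.append(
        _count_log(
            f"harmonize[{exposure.trait_label}->{outcome.trait_label}]",
            len(iv_ids),
            len(h),
            reasons,
        )
    )
    battery = mr.mr_battery(h, seed=cfg.seed)
    battery.insert(0, "exposure", exposure.trait_label)
    battery.insert(1, "outcome", outcome.trait_label)
    return battery, h


def run_pipeline(config: PipelineConfig | str | dict) -> dict:
    """Execute the configured stages; returns the machine-readable summary.

    Writes per-stage TSVs (MR battery, leave-one-out, mediation table,
    cross-trait loci, genetic correlation), a run log, and
    ``summary.json`` under ``config.out_dir``.
    """
    if isinstance(config, str):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig(**config)
    else:
        cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    counts: list[dict] = []
    summary: dict = {"config": asdict(cfg), "seed": cfg.seed, "counts": counts}
    stage = "load"
    try:
        exposure = sumstats.read_sumstats(cfg.exposure)
        outcome = sumstats.read_sumstats(cfg.outcome)
        panel = simulate.read_ld_panel(cfg.panel) if cfg.panel else None
        annotation = (
            pd.read_csv(cfg.annotation, sep="\t") if cfg.annotation else None
        )

        stage = "mr_forward"
        fwd, h_fwd = _mr_direction(exposure, outcome, panel, cfg, counts, annotation)
        tables = [fwd]
        loo = mr.leave_one_out(h_fwd) if len(h_fwd) >= 3 else None
        if loo is not None:
            loo.to_csv(os.path.join(cfg.out_dir, "leave_one_out.tsv"), sep="\t", index=False)

        if cfg.run_reverse:
            stage = "mr_reverse"
            rev, _ = _mr_direction(outcome, exposure, panel, cfg, counts, None)
            tables.append(rev)
        battery = pd.concat(tables, ignore_index=True)
        battery.to_csv(os.path.join(cfg.out_dir, "mr_battery.tsv"), sep="\t", index=False)
        ivw_row = fwd.loc[fwd["method"].isin(["IVW", "Wald ratio"])].iloc[0]
        total_c = float(ivw_row["beta"])
        summary["mr"] = {
            "total_effect": total_c,
            "or": float(ivw_row["or_"]),
            "pvalue": float(ivw_row["pvalue"]),
            "n_snp": int(ivw_row["n_snp"]),
        }

        if cfg.run_mediation and cfg.mediators:
            stage = "mediation"
            results = []
            for name, path in cfg.mediators.items():
                med = sumstats.read_sumstats(path, trait_label=name)
                step1, _ = _mr_direction(exposure, med, panel, cfg, counts, None)
                step2, _ = _mr_direction(med, outcome, panel, cfg, counts, None)
                e1 = _primary_estimate(step1)
                e2 = _primary_estimate(step2)
                results.append(
                    mediation.two_step_mediation(
                        e1, e2, total_c, mediator=name,
                        alpha_bonf=cfg.thresholds["alpha_mediation"],
                    )
                )
            med_table = mediation.mediation_table(results, total_c)
            med_table.to_csv(
                os.path.join(cfg.out_dir, "mediation.tsv"), sep="\t", index=False
            )
            summary["mediation"] = med_table.to_dict(orient="records")

        if cfg.run_cross_trait and panel is not None:
            stage = "cross_trait"
            meta, loci = cross_trait.cross_trait_scan(
                exposure, outcome, panel,
                p_meta_threshold=cfg.thresholds["p_meta"],
                p_single_threshold=cfg.thresholds["p_single"],
            )
            idx = meta.set_index("variant_id").loc[loci.index_variants].reset_index()
            idx.to_csv(os.path.join(cfg.out_dir, "cross_trait_loci.tsv"), sep="\t", index=False)
            summary["cross_trait"] = {
                "n_index_loci": len(loci),
                "index_variants": loci.index_variants,
            }
            try:
                rg = cross_trait.ldsc_rg(exposure, outcome, panel)
                summary["rg"] = {
                    "rg": None if not rg.defined else rg.rg,
                    "se": rg.se if rg.defined else None,
                    "pvalue": rg.pvalue if rg.defined else None,
                    "h2_a": rg.h2_a,
                    "h2_b": rg.h2_b,
                }
            except ValueError as exc:
                summary["rg"] = {"error": str(exc)}
    except Exception as exc:
        summary["error"] = {"stage": stage, "message": str(exc)}
        _write_summary(summary, cfg.out_dir)
        log.removeHandler(handler)
        raise
    _write_summary(summary, cfg.out_dir)
    log.removeHandler(handler)
    return summary


def _primary_estimate(battery: pd.DataFrame) -> mr.MREstimate:
    row = battery.loc[battery["method"].isin(["IVW", "Wald ratio"])].iloc[0]
    egger_rows = battery.loc[battery["method"] == "MR-Egger"]
    egger_p = (
        float(egger_rows["egger_intercept_p"].iloc[0]) if len(egger_rows) else None
    )
    return mr.MREstimate(
        method=str(row["method"]),
        beta_hat=float(row["beta"]),
        se=float(row["se"]),
        pvalue=float(row["pvalue"]),
        n_snp=int(row["n_snp"]),
        egger_intercept_p=egger_p,
    )


def _write_summary(summary: dict, out_dir: str) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=default)
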