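"""Orchestration of the full bidirectional MR screen.

`analyze_direction` runs one exposure -> outcome direction end to end
(harmonize, clump, proxy substitution, shared-significant removal,
estimator battery, MR-PRESSO, Steiger-filtered IVW, F statistics).
`run_pair` runs both directions of one trait pair, pools the IVW p-values
for FDR, applies the sensitivity criteria, runs the sharing-vs-causal
comparison for directions passing the sensitivity gate and classifies the
evidence.  `run_screen` does the same for an index trait against a screened
panel of candidate traits, with the FDR pooled over every IVW test run and
the Bonferroni divisor equal to the number of model comparisons actually
performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mrscreen import cause as cause_mod
from mrscreen._rng import child_seeds
from mrscreen.decisions import (
    DecisionRecord,
    bh_fdr,
    bonferroni_threshold,
    build_report,
    classify_pair,
    evaluate_sensitivity,
    mark_bidirectional,
)
from mrscreen.estimators import (
    MRInput,
    egger,
    ivw_mre,
    leave_one_out,
    simex_egger,
    weighted_median,
    weighted_mode,
)
from mrscreen.instruments import (
    InstrumentSet,
    LDReference,
    build_instrument_set,
    clump,
    f_statistics,
    remove_shared_significant,
    steiger_filter,
    substitute_proxies,
)
from mrscreen.presso import presso_outliers_and_correct
from mrscreen.sumstats import SumStatsTable, TraitMeta, harmonize, read_sumstats, screen_traits

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every analysis threshold, with the screen's defaults."""

    instrument_p: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_r2_min: float = 0.8
    palindrome_maf_limit: float = 0.42
    cause_p: float = 1e-3
    cause_clump_r2: float = 0.01
    cause_window_kb: float = 250.0
    fdr_alpha: float = 0.05
    sensitivity_alpha: float = 0.05
    f_min: float = 10.0
    i2gx_low: float = 0.6
    i2gx_high: float = 0.9
    bonferroni_alpha: float = 0.05
    presso_n_sim: int = 1000
    boot_B: int = 1000
    lenient_disregard: bool = False


@dataclass
class PipelineConfig:
    index_path: str | None = None
    index_trait_type: str = "binary"
    metadata_path: str | None = None
    ld_pairs_path: str | None = None
    out_dir: str = "mrscreen_out"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    cause_grids: cause_mod.CauseGrids = field(default_factory=cause_mod.CauseGrids)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        grids = cause_mod.CauseGrids(**raw.pop("cause_grids", {}))
        return cls(thresholds=thr, cause_grids=grids, **raw)


@dataclass
class DirectionResult:
    """Everything computed for one exposure -> outcome direction."""

    exposure_id: str
    outcome_id: str
    direction: str
    instruments: InstrumentSet | None = None
    mr_input: MRInput | None = None
    results: dict = field(default_factory=dict)
    presso: object = None
    steiger_ivw: object = None
    f_stats: tuple | None = None
    loo: list = field(default_factory=list)
    exposure_type: str = "continuous"
    error: str | None = None
    cause: dict = field(default_factory=dict)

    @property
    def ivw(self):
        return self.results.get("ivw_mre")


def analyze_direction(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    ld: LDReference | None,
    thresholds: Thresholds | None = None,
    direction: str = "forward",
    seed: int = 0,
) -> DirectionResult:
    """One direction of the screen: instruments, then the estimator battery."""
    thr = thresholds or Thresholds()
    out = DirectionResult(exposure.trait_id, outcome.trait_id, direction,
                          exposure_type=exposure.trait_type)
    pair = harmonize(exposure, outcome, thr.palindrome_maf_limit)
    selected = clump(exposure, ld, thr.clump_r2, thr.clump_window_kb, thr.instrument_p)
    if not selected:
        out.error = "no genome-wide significant instrument"
        return out
    usable_ids = set(pair.usable()["variant_id"])
    missing = [v for v in selected if v not in usable_ids]
    proxies = []
    if missing and ld is not None:
        for orig, proxy in substitute_proxies(missing, outcome, ld, thr.proxy_r2_min):
            if proxy in usable_ids and proxy not in selected:
                selected[selected.index(orig)] = proxy
                proxies.append((proxy, orig))
    pair = remove_shared_significant(pair, thr.instrument_p)
    inst = build_instrument_set(
        pair, selected, exposure, outcome, direction=direction, proxies=proxies
    )
    out.instruments = inst
    if len(inst) == 0:
        out.error = "no instrument survived harmonization and filtering"
        return out
    mri = MRInput.from_instrument_set(inst)
    out.mr_input = mri

    s_med, s_mode, s_simex, s_presso = child_seeds(seed, 4)
    ivw, het = ivw_mre(mri)
    ivw.extra.update(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
                     direction=direction)
    out.results["ivw_mre"] = ivw
    out.results["heterogeneity"] = het
    out.results["weighted_median"] = weighted_median(mri, boot_B=thr.boot_B, seed=s_med)
    out.results["weighted_mode"] = weighted_mode(mri, boot_B=thr.boot_B, seed=s_mode)
    egg = egger(mri)
    out.results["mr_egger"] = egg
    i2gx = egg.extra.get("i2gx", np.nan)
    if egg.applicable and thr.i2gx_low < i2gx <= thr.i2gx_high:
        out.results["simex_egger"] = simex_egger(mri, seed=s_simex)
    out.presso = presso_outliers_and_correct(
        mri, n_sim=thr.presso_n_sim, seed=s_presso, alpha=thr.sensitivity_alpha
    )
    steiger_set = steiger_filter(inst)
    if len(steiger_set) >= 2:
        out.steiger_ivw, _ = ivw_mre(MRInput.from_instrument_set(steiger_set))
        out.steiger_ivw.method = "ivw_steiger"
    if exposure.trait_type in ("continuous", "ordered-categorical"):
        n_exp = int(np.nanmedian(exposure.records["n"]))
        out.f_stats = f_statistics(inst, n_exp)
    out.loo = leave_one_out(mri)
    return out


def run_cause(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    ld: LDReference | None,
    thresholds: Thresholds | None = None,
    grids: cause_mod.CauseGrids | None = None,
    seed: int = 0,
) -> dict:
    """Sharing-vs-causal comparison for one direction."""
    thr = thresholds or Thresholds()
    pair = harmonize(exposure, outcome, thr.palindrome_maf_limit)
    vset = cause_mod.select_cause_variants(
        exposure, ld, thr.cause_clump_r2, thr.cause_window_kb, thr.cause_p, pair=pair
    )
    if len(vset) < 2:
        return {"error": "too few variants for the model comparison"}
    prior = cause_mod.fit_effect_prior(vset)
    sharing, causal = cause_mod.fit_cause_models(vset, prior, grids, seed=seed)
    comp = cause_mod.elpd_compare(sharing, causal)
    return {
        "variant_set": vset,
        "prior": prior,
        "sharing": sharing,
        "causal": causal,
        "comparison": comp,
    }


def _decision_from_direction(dr: DirectionResult, fdr_p: float, thr: Thresholds) -> DecisionRecord:
    rec = evaluate_sensitivity(
        ivw=dr.ivw,
        fdr_p=fdr_p,
        battery={k: v for k, v in dr.results.items()
                 if k in ("weighted_median", "weighted_mode", "simex_egger")},
        presso=dr.presso,
        steiger_ivw=dr.steiger_ivw,
        egger_info=dr.results.get("mr_egger"),
        f_stats=dr.f_stats,
        exposure_type=dr.exposure_type,
        alpha=thr.sensitivity_alpha,
        i2gx_low=thr.i2gx_low,
        i2gx_high=thr.i2gx_high,
        f_min=thr.f_min,
        lenient_disregard=thr.lenient_disregard,
    )
    return rec


def _attach_cause(rec: DecisionRecord, cause_bundle: dict) -> None:
    if "error" in cause_bundle:
        return
    comp = cause_bundle["comparison"]
    gsum = cause_bundle["causal"].summaries["gamma"]
    rec.cause_p = comp.p_one_sided
    rec.cause_gamma = gsum["median"]
    rec.cause_gamma_ci = (gsum["ci_low"], gsum["ci_high"])
    rec.cause_delta_elpd = comp.delta_elpd
    rec.cause_se_delta = comp.se_delta


def run_pair(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    ld: LDReference | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Both directions for one trait pair, with FDR over the two IVW tests."""
    cfg = config or PipelineConfig()
    thr = cfg.thresholds
    seeds = child_seeds(cfg.seed, 4)
    directions = {
        "forward": analyze_direction(exposure, outcome, ld, thr, "forward", seeds[0]),
        "reverse": analyze_direction(outcome, exposure, ld, thr, "reverse", seeds[1]),
    }
    pvals, keys = [], []
    for key, dr in directions.items():
        if dr.error is None and dr.ivw is not None and dr.ivw.applicable:
            pvals.append(dr.ivw.pval)
            keys.append(key)
    fdr = dict(zip(keys, bh_fdr(pvals)))
    records: dict[str, DecisionRecord] = {}
    cause_runs = 0
    for i, (key, dr) in enumerate(directions.items()):
        if key not in fdr:
            rec = DecisionRecord(dr.exposure_id, dr.outcome_id, key)
            records[key] = rec
            continue
        rec = _decision_from_direction(dr, fdr[key], thr)
        rec.direction = key
        if rec.meets_sensitivity:
            exp_t, out_t = (exposure, outcome) if key == "forward" else (outcome, exposure)
            dr.cause = run_cause(exp_t, out_t, ld, thr, cfg.cause_grids, seeds[2 + i])
            _attach_cause(rec, dr.cause)
            if rec.cause_p is not None:
                cause_runs += 1
        records[key] = rec
    m = max(cause_runs, 1)
    thresh = bonferroni_threshold(thr.bonferroni_alpha, m)
    for rec in records.values():
        classify_pair(rec, thresh, thr.fdr_alpha)
    mark_bidirectional(list(records.values()))
    return {"directions": directions, "records": records, "bonferroni_m": m}


def run_screen(
    index: SumStatsTable,
    traits: dict[str, SumStatsTable],
    metas: list[TraitMeta],
    ld: LDReference | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Screen the index trait against every candidate passing the filters.

    Stages: metadata screen; both-direction MR for each kept trait (failures
    are quarantined, not fatal); BH-FDR pooled over every IVW test run;
    sensitivity criteria; model comparison for the passers with a Bonferroni
    divisor equal to the number of comparisons run; report assembly.
    """
    cfg = config or PipelineConfig()
    thr = cfg.thresholds
    kept, excluded = screen_traits(metas)
    meta_by_id = {m.trait_id: m for m in metas}
    pair_seeds = child_seeds(cfg.seed, 2 * len(kept) + 2)

    directions: list[DirectionResult] = []
    quarantined: list[tuple[str, str]] = []
    for i, meta in enumerate(kept):
        trait = traits.get(meta.trait_id)
        if trait is None:
            quarantined.append((meta.trait_id, "summary statistics unavailable"))
            continue
        for j, (exp_t, out_t, label) in enumerate(
            ((index, trait, "index->trait"), (trait, index, "trait->index"))
        ):
            try:
                directions.append(
                    analyze_direction(exp_t, out_t, ld, thr, label, pair_seeds[2 * i + j])
                )
            except Exception as exc:  # pragma: no cover - quarantine path
                logger.exception("direction failed for %s", meta.trait_id)
                quarantined.append((meta.trait_id, str(exc)))

    valid = [d for d in directions if d.error is None and d.ivw is not None
             and d.ivw.applicable]
    fdr_adj = bh_fdr([d.ivw.pval for d in valid])
    records: list[DecisionRecord] = []
    cause_jobs = []
    for d, p_adj in zip(valid, fdr_adj):
        rec = _decision_from_direction(d, p_adj, thr)
        rec.direction = d.direction
        trait_id = d.outcome_id if d.direction == "index->trait" else d.exposure_id
        rec.category = getattr(meta_by_id.get(trait_id), "category", "")
        records.append(rec)
        if rec.meets_sensitivity:
            cause_jobs.append((d, rec))
    for d in directions:
        if d not in valid:
            rec = DecisionRecord(d.exposure_id, d.outcome_id, d.direction)
            trait_id = d.outcome_id if d.direction == "index->trait" else d.exposure_id
            rec.category = getattr(meta_by_id.get(trait_id), "category", "")
            records.append(rec)

    cause_seed_pool = child_seeds(cfg.seed + 1, max(len(cause_jobs), 1))
    m = 0
    for (d, rec), s in zip(cause_jobs, cause_seed_pool):
        exp_t = index if d.direction == "index->trait" else traits[d.exposure_id]
        out_t = traits[d.outcome_id] if d.direction == "index->trait" else index
        d.cause = run_cause(exp_t, out_t, ld, thr, cfg.cause_grids, s)
        _attach_cause(rec, d.cause)
        if rec.cause_p is not None:
            m += 1
    thresh = bonferroni_threshold(thr.bonferroni_alpha, max(m, 1))
    for rec in records:
        classify_pair(rec, thresh, thr.fdr_alpha)
    mark_bidirectional(records)
    mr_table, cause_table, summary = build_report(records)
    return {
        "kept": kept,
        "excluded": excluded,
        "directions": directions,
        "records": records,
        "quarantined": quarantined,
        "bonferroni_m": max(m, 1),
        "mr_table": mr_table,
        "cause_table": cause_table,
        "stage_summary": summary,
    }


def results_table(directions: list[DirectionResult]) -> pd.DataFrame:
    """Tidy one-row-per-method results table across directions."""
    rows = []
    for d in directions:
        for name, res in d.results.items():
            if name == "heterogeneity":
                continue
            rows.append({
                "exposure": d.exposure_id, "outcome": d.outcome_id,
                "direction": d.direction, "method": res.method,
                "estimate": res.estimate, "se": res.se,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "pval": res.pval, "L_used": res.L_used,
                **{k: v for k, v in res.extra.items()
                   if isinstance(v, (int, float, bool))},
            })
        if d.presso is not None and d.presso.applicable:
            rows.append({
                "exposure": d.exposure_id, "outcome": d.outcome_id,
                "direction": d.direction, "method": "mr_presso_global",
                "pval": d.presso.global_p, "L_used": len(d.mr_input.b_X),
            })
        if d.steiger_ivw is not None:
            res = d.steiger_ivw
            rows.append({
                "exposure": d.exposure_id, "outcome": d.outcome_id,
                "direction": d.direction, "method": res.method,
                "estimate": res.estimate, "se": res.se,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "pval": res.pval, "L_used": res.L_used,
            })
    return pd.DataFrame(rows)


def write_outputs(out_dir, screen_result: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    screen_result["mr_table"].to_csv(out / "mr_results.tsv", sep="\t", index=False)
    screen_result["cause_table"].to_csv(out / "cause_results.tsv", sep="\t", index=False)
    screen_result["stage_summary"].to_csv(out / "stage_summary.tsv", sep="\t", index=False)
    results_table(screen_result["directions"]).to_csv(
        out / "method_results.tsv", sep="\t", index=False
    )
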