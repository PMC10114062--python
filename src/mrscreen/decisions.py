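"""Multiple-testing control and evidence classification.

A trait pair (per direction) advances through three gates:

1. **MR main** — the IVW FDR-adjusted p-value is below 0.05 (BH over the
   pooled set of all IVW tests run in the screen).
2. **MR sensitivity** — every required member of the sensitivity battery
   (weighted median, weighted mode, MR-PRESSO, IVW after Steiger filtering,
   and — only when the Egger intercept signals pleiotropy — MR-Egger or its
   SIMEX correction depending on I2GX) agrees in direction with IVW with
   p < 0.05, and the mean F statistic exceeds 10 for continuous exposures.
3. **CAUSE** — the sharing-vs-causal ELPD comparison is significant at a
   Bonferroni threshold over the number of comparisons actually run.

A pair is *bidirectional* when both directions reach at least the
sensitivity gate with the same final class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from mrscreen.estimators import MRResult
from mrscreen.presso import PressoResult

FINAL_CLASSES = ["none", "mr_main", "mr_sensitivity", "cause_confirmed"]


@dataclass
class DecisionRecord:
    exposure_id: str
    outcome_id: str
    direction: str
    ivw_p_raw: float = np.nan
    ivw_p_fdr: float = np.nan
    ivw_estimate: float = np.nan
    ivw_ci: tuple = (np.nan, np.nan)
    n_snps: int = 0
    sensitivity_checks: dict = field(default_factory=dict)
    f_ok: bool | None = None  # None = not applicable (binary exposure)
    meets_sensitivity: bool = False
    cause_p: float | None = None
    cause_gamma: float | None = None
    cause_gamma_ci: tuple | None = None
    cause_delta_elpd: float | None = None
    cause_se_delta: float | None = None
    cause_bonferroni_pass: bool | None = None
    final_class: str = "none"
    bidirectional: bool = False
    category: str = ""

    def __post_init__(self):
        if self.final_class not in FINAL_CLASSES:
            raise ValueError(f"unknown final class {self.final_class!r}")


def bh_fdr(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    pvals = list(pvals)
    if not pvals:
        return []
    arr = np.asarray(pvals, float)
    if np.any((arr <= 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return [float(p) for p in adj]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m controlling family-wise error over m tests."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


def evaluate_sensitivity(
    ivw: MRResult,
    fdr_p: float,
    battery: dict[str, MRResult],
    presso: PressoResult | None,
    steiger_ivw: MRResult | None,
    egger_info: MRResult | None,
    f_stats: tuple | None,
    exposure_type: str,
    alpha: float = 0.05,
    i2gx_low: float = 0.6,
    i2gx_high: float = 0.9,
    f_min: float = 10.0,
    lenient_disregard: bool = False,
) -> DecisionRecord:
    """Apply the three evidence criteria to one direction of one pair.

    (i) IVW FDR p < ``alpha``; (ii) weighted median, weighted mode,
    MR-PRESSO (outlier-corrected IVW) and Steiger-filtered IVW all estimate
    the same direction as IVW with p < ``alpha``; when the Egger intercept
    shows pleiotropy (p < alpha), MR-Egger additionally must agree if
    I2GX > ``i2gx_high``, or SIMEX-corrected Egger if
    ``i2gx_low`` < I2GX <= ``i2gx_high``; with I2GX <= ``i2gx_low`` the
    Egger family is unusable ("disregarded") and the pair conservatively
    fails unless ``lenient_disregard``; (iii) mean F > ``f_min`` for continuous
    exposures.

    ``battery`` must contain ``weighted_median`` and ``weighted_mode``;
    ``egger_info`` carries the intercept test and I2GX in ``extra``;
    ``f_stats`` is the (per_snp, mean_F, aggregate_F) triple.  Missing
    required components raise rather than silently pass.
    """
    if not ivw.applicable:
        raise ValueError("IVW result required")
    for key in ("weighted_median", "weighted_mode"):
        if key not in battery:
            raise ValueError(f"sensitivity battery is missing {key}")
    ivw_sign = np.sign(ivw.estimate)
    checks: dict[str, str] = {}
    checks["weighted_median"] = _req(battery["weighted_median"], ivw_sign, alpha)
    checks["weighted_mode"] = _req(battery["weighted_mode"], ivw_sign, alpha)

    if presso is None or not presso.applicable:
        checks["mr_presso"] = "not-required"
    elif presso.corrected is None:
        checks["mr_presso"] = "fail"  # all instruments flagged: no usable estimate
    else:
        checks["mr_presso"] = _req(presso.corrected, ivw_sign, alpha)

    if steiger_ivw is None or not steiger_ivw.applicable:
        checks["ivw_steiger"] = "fail"
    else:
        checks["ivw_steiger"] = _req(steiger_ivw, ivw_sign, alpha)

    checks["egger_or_simex"] = _egger_check(
        egger_info, battery.get("simex_egger"), ivw_sign, alpha,
        i2gx_low, i2gx_high, lenient_disregard,
    )

    if exposure_type in ("continuous", "ordered-categorical"):
        if f_stats is None:
            raise ValueError("F statistics required for a continuous exposure")
        f_ok = f_stats[1] > f_min
    else:
        f_ok = None

    required_ok = all(v in ("pass", "not-required") for v in checks.values())
    meets = (fdr_p < alpha) and required_ok and (f_ok is not False)
    return DecisionRecord(
        exposure_id=ivw.extra.get("exposure_id", ""),
        outcome_id=ivw.extra.get("outcome_id", ""),
        direction=ivw.extra.get("direction", ""),
        ivw_p_raw=ivw.pval,
        ivw_p_fdr=fdr_p,
        ivw_estimate=ivw.estimate,
        ivw_ci=(ivw.ci_low, ivw.ci_high),
        n_snps=ivw.L_used,
        sensitivity_checks=checks,
        f_ok=f_ok,
        meets_sensitivity=bool(meets),
    )


def _req(res: MRResult, ivw_sign: float, alpha: float) -> str:
    if not res.applicable:
        return "fail"
    same_dir = np.sign(res.estimate) == ivw_sign
    ok = same_dir and np.isfinite(res.pval) and res.pval < alpha
    return "pass" if ok else "fail"


def _egger_check(
    egger_info, simex, ivw_sign, alpha, i2gx_low, i2gx_high, lenient
) -> str:
    if egger_info is None or not egger_info.applicable:
        return "not-required"
    intercept_p = egger_info.extra.get("egger_intercept_p", np.nan)
    if not (np.isfinite(intercept_p) and intercept_p < alpha):
        return "not-required"  # no evidence of directional pleiotropy
    i2gx = egger_info.extra.get("i2gx", np.nan)
    if not np.isfinite(i2gx) or i2gx <= i2gx_low:
        return "not-required" if lenient else "disregarded"
    if i2gx > i2gx_high:
        return _req(egger_info, ivw_sign, alpha)
    if simex is None or not simex.applicable:
        raise ValueError("SIMEX result required when 0.6 < I2GX <= 0.9 with pleiotropy")
    return _req(simex, ivw_sign, alpha)


def classify_pair(
    record: DecisionRecord,
    cause_alpha_bonf: float | None = None,
    fdr_alpha: float = 0.05,
) -> DecisionRecord:
    """Assign the final evidence class from the staged gates.

    ``cause_confirmed`` requires a CAUSE p-value below the Bonferroni
    threshold over the comparisons actually run; the chain is monotone:
    cause_confirmed implies mr_sensitivity implies mr_main.
    """
    if not record.ivw_p_fdr < fdr_alpha:
        record.final_class = "none"
        return record
    if not record.meets_sensitivity:
        record.final_class = "mr_main"
        return record
    record.final_class = "mr_sensitivity"
    if record.cause_p is not None and cause_alpha_bonf is not None:
        record.cause_bonferroni_pass = record.cause_p < cause_alpha_bonf
        if record.cause_bonferroni_pass:
            record.final_class = "cause_confirmed"
    return record


def mark_bidirectional(records: list[DecisionRecord]) -> None:
    """Flag pairs whose two directions reach the same class >= sensitivity."""
    by_pair: dict[frozenset, list[DecisionRecord]] = {}
    for r in records:
        by_pair.setdefault(frozenset((r.exposure_id, r.outcome_id)), []).append(r)
    for group in by_pair.values():
        if len(group) < 2:
            continue
        classes = {r.final_class for r in group}
        if len(classes) == 1 and FINAL_CLASSES.index(group[0].final_class) >= 2:
            for r in group:
                r.bidirectional = True


def build_report(
    records: list[DecisionRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assemble the MR table, the CAUSE table and the stage-count summary.

    The MR table mirrors the per-direction layout of the main results
    (number of SNPs, effect, 95% CI, FDR p, meets-sensitivity); the CAUSE
    table reports the causal-model posterior (gamma, 95% CrI) with the ELPD
    comparison; the summary counts records passing each gate per category
    and direction.
    """
    mr_cols = ["exposure", "outcome", "direction", "n_snps", "effect",
               "ci_low", "ci_high", "fdr_p", "meets_sensitivity", "final_class"]
    cause_cols = ["exposure", "outcome", "direction", "gamma", "cri_low",
                  "cri_high", "delta_elpd", "se_delta", "elpd_p", "bonferroni_pass"]
    mr_rows, cause_rows = [], []
    for r in records:
        mr_rows.append({
            "exposure": r.exposure_id, "outcome": r.outcome_id,
            "direction": r.direction, "n_snps": r.n_snps,
            "effect": r.ivw_estimate, "ci_low": r.ivw_ci[0], "ci_high": r.ivw_ci[1],
            "fdr_p": r.ivw_p_fdr,
            "meets_sensitivity": r.meets_sensitivity,
            "final_class": r.final_class,
        })
        if r.cause_p is not None:
            cause_rows.append({
                "exposure": r.exposure_id, "outcome": r.outcome_id,
                "direction": r.direction, "gamma": r.cause_gamma,
                "cri_low": (r.cause_gamma_ci or (np.nan, np.nan))[0],
                "cri_high": (r.cause_gamma_ci or (np.nan, np.nan))[1],
                "delta_elpd": r.cause_delta_elpd, "se_delta": r.cause_se_delta,
                "elpd_p": r.cause_p, "bonferroni_pass": r.cause_bonferroni_pass,
            })
    mr_table = pd.DataFrame(mr_rows, columns=mr_cols)
    cause_table = pd.DataFrame(cause_rows, columns=cause_cols)

    stage_rows = []
    for (category, direction), group in _group(records):
        counts = {
            "all": len(group),
            "mr_main": sum(FINAL_CLASSES.index(r.final_class) >= 1 for r in group),
            "mr_sens": sum(FINAL_CLASSES.index(r.final_class) >= 2 for r in group),
            "cause": sum(FINAL_CLASSES.index(r.final_class) >= 3 for r in group),
        }
        stage_rows.append({"category": category, "direction": direction, **counts})
    summary = pd.DataFrame(
        stage_rows, columns=["category", "direction", "all", "mr_main", "mr_sens", "cause"]
    )
    return mr_table, cause_table, summary


def _group(records):
    keys = sorted({(r.category, r.direction) for r in records})
    for key in keys:
        yield key, [r for r in records if (r.category, r.direction) == key]
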