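"""Genetic-instrument selection for two-sample MR.

Implements greedy LD clumping (r2 < 0.001 or distance > 10 000 kb at
p < 5e-8 by default), proxy substitution (r2 >= 0.8), removal of variants
genome-wide significant in both traits, per-variant variance explained on
the observed and liability scales, Steiger directionality filtering, and
instrument-strength F statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.sumstats import HarmonizedPair, SumStatsTable

logger = logging.getLogger(__name__)


class LDReference:
    """Sparse pairwise LD (r2) lookup with per-variant positions.

    Pairs are symmetric; an absent pair means r2 = 0; r2(v, v) = 1.
    """

    def __init__(self, pairs: pd.DataFrame | None = None, positions: pd.DataFrame | None = None):
        """``pairs``: columns variant_a, variant_b, r2.  ``positions``:
        columns variant_id, chrom, pos (needed only for window logic when the
        summary-stats table lacks positions)."""
        self._r2: dict[tuple[str, str], float] = {}
        if pairs is not None:
            for a, b, r2 in pairs[["variant_a", "variant_b", "r2"]].itertuples(index=False):
                if not 0.0 <= r2 <= 1.0:
                    raise ValueError(f"r2 out of range for pair ({a}, {b}): {r2}")
                key = (a, b) if a <= b else (b, a)
                self._r2[key] = float(r2)
        self.positions = positions

    @classmethod
    def from_file(cls, pairs_path, positions_path=None, sep: str = "\t") -> "LDReference":
        pairs = pd.read_csv(pairs_path, sep=sep)
        pos = pd.read_csv(positions_path, sep=sep) if positions_path else None
        return cls(pairs, pos)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._r2.get(key, 0.0)

    def partners(self, v: str) -> dict[str, float]:
        """All variants with recorded nonzero r2 to ``v``."""
        out = {}
        for (a, b), r2 in self._r2.items():
            if a == v:
                out[b] = r2
            elif b == v:
                out[a] = r2
        return out


@dataclass
class Instrument:
    variant_id: str
    b_X: float
    se_X: float
    p_X: float
    b_Y: float
    se_Y: float
    r2_exposure: float = np.nan
    r2_outcome: float = np.nan
    proxy_of: str | None = None


@dataclass
class InstrumentSet:
    """Selected, harmonized instruments for one exposure->outcome direction."""

    exposure_id: str
    outcome_id: str
    direction: str
    instruments: list[Instrument]
    selection_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)

    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]


def clump(
    table: SumStatsTable,
    ld: LDReference | None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
    p_max: float = 5e-8,
) -> list[str]:
    """Greedy LD clumping: keep the best (lowest-p) variant of each LD clump.

    Candidates with p < ``p_max`` are ranked by ascending p (ties broken by
    variant id for determinism); a candidate is accepted iff its r2 with every
    already-accepted variant within ``window_kb`` on the same chromosome is
    below ``r2_max``.  Variants outside the window are independent by
    construction.  Without an LD reference only the distance rule applies,
    with a warning.
    """
    if ld is None:
        logger.warning("no LD reference supplied; clumping on distance only")
    df = table.records
    cand = df[df["pval"] < p_max]
    if cand.empty:
        return []
    cand = cand.sort_values(["pval", "variant_id"], kind="mergesort")
    kept: list[tuple[str, str, float]] = []  # (id, chrom, pos)
    window_bp = window_kb * 1000.0
    for vid, chrom, pos in cand[["variant_id", "chrom", "pos"]].itertuples(index=False):
        ok = True
        for kid, kchrom, kpos in kept:
            if str(chrom) != str(kchrom):
                continue
            in_window = (
                pd.notna(pos) and pd.notna(kpos) and abs(float(pos) - float(kpos)) <= window_bp
            )
            if not in_window:
                continue
            if ld is None or ld.r2(vid, kid) >= r2_max:
                ok = False
                break
        if ok:
            kept.append((vid, chrom, pos))
    return [k[0] for k in kept]


def substitute_proxies(
    missing: list[str],
    outcome: SumStatsTable,
    ld: LDReference,
    r2_min: float = 0.8,
) -> list[tuple[str, str]]:
    """For each missing exposure instrument, the best outcome-present proxy.

    Returns (original, proxy) pairs for proxies with r2 >= ``r2_min``; a
    missing variant with no qualifying proxy is simply absent from the
    result.  Proxies are chosen by highest r2, ties broken by variant id.
    """
    present = set(outcome.records["variant_id"])
    out = []
    for vid in missing:
        partners = [
            (r2, pid)
            for pid, r2 in ld.partners(vid).items()
            if pid in present and r2 >= r2_min
        ]
        if partners:
            r2_best, proxy = max(partners, key=lambda t: (t[0], t[1]))
            out.append((vid, proxy))
    return out


def remove_shared_significant(pair: HarmonizedPair, p_thresh: float = 5e-8) -> HarmonizedPair:
    """Drop variants genome-wide significant in both exposure and outcome.

    Such variants are plausibly primary signals of both traits and violate
    the exclusion-restriction assumption most flagrantly.
    """
    rows = pair.rows
    shared = (rows["p_X"] < p_thresh) & (rows["p_Y"] < p_thresh)
    n_removed = int(shared.sum())
    out = HarmonizedPair(
        pair.exposure_id,
        pair.outcome_id,
        rows[~shared].reset_index(drop=True),
        dict(pair.log),
    )
    out.log["shared-significant-removed"] = n_removed
    return out


def r2_continuous(beta: float, se: float, n: int) -> float:
    """Variance of a continuous trait explained by one variant, t2/(t2+n-2)."""
    if n <= 2:
        raise ValueError("n must exceed 2")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def _lee_scale_factors(prevalence: float, case_prop: float) -> tuple[float, float]:
    """C and theta of the observed-to-liability R2 transformation.

    C rescales an observed-scale (0/1 regression) R2 from an ascertained
    case-control sample to the latent liability scale; theta corrects for
    ascertainment-induced nonlinearity.  K is the population prevalence, P
    the sample case proportion, t the liability threshold and z the normal
    density at t.
    """
    K, P = prevalence, case_prop
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    m = z / K  # mean liability of cases
    C = (K * (1 - K)) ** 2 / (z**2 * P * (1 - P))
    d = m * (P - K) / (K * (1 - K))
    theta = d * (d - t)
    return C, theta


def r2_binary_liability(
    log_or: float,
    eaf: float,
    n_case: int,
    n_control: int,
    prevalence: float | None = None,
) -> float:
    """Liability-scale variance explained by one variant of a binary trait.

    The per-allele log odds ratio is first converted to an observed-scale
    (0/1 linear regression) R2 via the logistic-derivative approximation
    R2_obs = 2 p (1-p) b^2 P(1-P) with p the effect-allele frequency and P
    the sample case proportion, then mapped to the latent liability scale
    with the case-control ascertainment transformation
    R2_l = C R2_obs / (1 + C theta R2_obs).

    When no population prevalence is supplied the sample case proportion is
    used, which biases the conversion for strongly ascertained studies; the
    substitution is logged.
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError("eaf must be strictly inside (0, 1)")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    P = n_case / (n_case + n_control)
    if prevalence is None:
        prevalence = P
        logger.info(
            "no population prevalence supplied; using case proportion %.4g "
            "(biases liability-scale r2 for ascertained samples)",
            P,
        )
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be strictly inside (0, 1)")
    r2_obs = 2.0 * eaf * (1.0 - eaf) * log_or**2 * P * (1.0 - P)
    C, theta = _lee_scale_factors(prevalence, P)
    r2_l = C * r2_obs / (1.0 + C * theta * r2_obs)
    return float(min(r2_l, 1.0 - 1e-12))


def steiger_filter(inst_set: InstrumentSet) -> InstrumentSet:
    """Drop instruments that do not explain more variance in the exposure.

    Guards against reverse causation: a variant whose primary effect is on
    the outcome explains more outcome than exposure variance and would
    otherwise contaminate the causal estimate.  Keeps instruments with
    r2_exposure > r2_outcome (strict); idempotent.
    """
    survivors, removed = [], 0
    for ins in inst_set.instruments:
        if np.isnan(ins.r2_exposure) or np.isnan(ins.r2_outcome):
            raise ValueError(f"instrument {ins.variant_id} lacks variance-explained fields")
        if ins.r2_exposure > ins.r2_outcome:
            survivors.append(ins)
        else:
            removed += 1
    log = dict(inst_set.selection_log)
    log["steiger-removed"] = removed
    return InstrumentSet(
        inst_set.exposure_id, inst_set.outcome_id, inst_set.direction, survivors, log
    )


def f_statistics(
    inst_set: InstrumentSet, n_exposure: int
) -> tuple[list[float], float, float]:
    """Instrument-strength F statistics for a continuous exposure.

    Returns per-SNP F_j = (b_Xj/se_Xj)^2, their mean, and the aggregate
    F = ((n - L - 1)/L) * R2/(1 - R2) with R2 the summed per-SNP variance
    explained.  The rule of thumb is F > 10 for strong instruments.
    """
    L = len(inst_set.instruments)
    if L == 0:
        raise ValueError("instrument set is empty")
    per_snp = [float((i.b_X / i.se_X) ** 2) for i in inst_set.instruments]
    mean_f = float(np.mean(per_snp))
    r2_total = float(np.nansum([i.r2_exposure for i in inst_set.instruments]))
    r2_total = min(r2_total, 1.0 - 1e-12)
    aggregate = (n_exposure - L - 1) / L * r2_total / (1.0 - r2_total)
    return per_snp, mean_f, float(aggregate)


def build_instrument_set(
    pair: HarmonizedPair,
    selected: list[str],
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    direction: str = "forward",
    prevalence_exposure: float | None = None,
    prevalence_outcome: float | None = None,
    proxies: list[tuple[str, str]] | None = None,
) -> InstrumentSet:
    """Assemble instruments from a harmonized pair restricted to ``selected``.

    Populates per-variant variance explained on the appropriate scale for
    each trait (liability for binary traits, observed for continuous), which
    Steiger filtering and the aggregate F statistic require.
    """
    proxies = dict(proxies or [])
    usable = pair.usable().set_index("variant_id")
    exp_n = _sizes(exposure)
    out_n = _sizes(outcome)
    instruments = []
    for vid in selected:
        if vid not in usable.index:
            continue
        row = usable.loc[vid]
        r2x = _variance_explained(exposure, row["b_X"], row["se_X"], row["eaf_X"], exp_n,
                                  prevalence_exposure)
        r2y = _variance_explained(outcome, row["b_Y"], row["se_Y"], row["eaf_Y"], out_n,
                                  prevalence_outcome)
        instruments.append(
            Instrument(
                variant_id=vid,
                b_X=float(row["b_X"]),
                se_X=float(row["se_X"]),
                p_X=float(row["p_X"]),
                b_Y=float(row["b_Y"]),
                se_Y=float(row["se_Y"]),
                r2_exposure=r2x,
                r2_outcome=r2y,
                proxy_of=proxies.get(vid),
            )
        )
    return InstrumentSet(
        pair.exposure_id, pair.outcome_id, direction, instruments, dict(pair.log)
    )


def _sizes(table: SumStatsTable) -> tuple[float, float | None, float | None]:
    rec = table.records
    n = float(np.nanmedian(rec["n"])) if rec["n"].notna().any() else np.nan
    nc = float(np.nanmedian(rec["n_case"])) if rec["n_case"].notna().any() else None
    nk = float(np.nanmedian(rec["n_control"])) if rec["n_control"].notna().any() else None
    return n, nc, nk


def _variance_explained(table, beta, se, eaf, sizes, prevalence) -> float:
    n, nc, nk = sizes
    if table.is_binary and nc and nk:
        if pd.isna(eaf):
            return np.nan
        return r2_binary_liability(beta, eaf, int(nc), int(nk), prevalence)
    if np.isnan(n):
        return np.nan
    return r2_continuous(beta, se, int(n))
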