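"""Synthetic two-sample GWAS summary statistics.

The generator mirrors the structural model the analysis assumes: per-variant
true exposure effects are drawn from a zero-mean normal mixture; the true
outcome effect of a forward variant is

    beta_Y = gamma * beta_X + eta * Z * beta_X + theta

with Z ~ Bernoulli(q) flagging variants acting through a shared heritable
factor (correlated pleiotropy) and theta an independent uncorrelated-
pleiotropy term.  A configurable fraction of variants is "reverse": their
primary effect is on the outcome and the exposure sees only a damped echo,
so Steiger filtering has something real to remove.  Observed effects add
independent exposure- and outcome-panel sampling error with the asymptotic
standard error se = 1/sqrt(2 maf (1-maf) n) for standardized continuous
traits (inflated by 1/sqrt(P(1-P)) on the log-OR scale for binary traits).

All randomness flows through per-variant counter-based streams keyed by
variant id, so identical configurations reproduce byte-identical tables
regardless of row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen._rng import variant_rng
from mrscreen.instruments import LDReference, _lee_scale_factors
from mrscreen.sumstats import COLUMNS, SumStatsTable

# allele pairs used for non-palindromic variants
_SAFE_ALLELES = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMES = [("A", "T"), ("C", "G")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Study conditions for one simulated exposure/outcome pair."""

    L_total: int = 100
    n_exp: int = 100_000
    n_out: int = 100_000
    exposure_type: str = "continuous"
    outcome_type: str = "continuous"
    case_frac_exp: float = 0.5
    case_frac_out: float = 0.5
    prevalence: float = 0.05  # population prevalence for liability conversions
    gamma: float = 0.0  # true causal effect of exposure on outcome
    eta: float = 0.0  # shared-factor (correlated pleiotropy) effect
    q: float = 0.0  # fraction of variants acting through the shared factor
    pi_uncorr: float = 0.0  # fraction with uncorrelated pleiotropy
    uncorr_sd: float = 0.05  # sd of the uncorrelated pleiotropy term
    effect_prior: tuple = ((1.0, 0.05),)  # (weight, sd) mixture over beta_X
    maf_range: tuple = (0.05, 0.5)
    ld_blocks: tuple | None = None  # (n_blocks, block_size, within_r2)
    reverse_fraction: float = 0.0  # variants whose primary effect is on the outcome
    reverse_effect: float = 0.3  # damping of the reverse echo on the exposure
    swap_fraction: float = 0.2  # outcome rows emitted with swapped alleles
    palindromic_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("q", "pi_uncorr", "reverse_fraction", "swap_fraction",
                     "palindromic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.L_total < 1 or self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("L_total and sample sizes must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        w = sum(p[0] for p in self.effect_prior)
        if not np.isclose(w, 1.0):
            raise ValueError("effect prior weights must sum to 1")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for t in (self.exposure_type, self.outcome_type):
            if t not in ("continuous", "binary"):
                raise ValueError(f"trait type must be continuous or binary, got {t}")


@dataclass
class SimTruth:
    """Per-variant generative decomposition of the simulated pair."""

    table: pd.DataFrame  # variant_id, beta_X, beta_Y, causal, shared, uncorr,
    #                      reverse, Z, is_reverse, block
    config: SimConfig = field(repr=False, default=None)


def _se(maf: np.ndarray, n: float, trait_type: str, case_frac: float) -> np.ndarray:
    base = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    if trait_type == "binary":
        return base / np.sqrt(case_frac * (1.0 - case_frac))
    return base


def simulate_pair(
    cfg: SimConfig,
) -> tuple[SumStatsTable, SumStatsTable, LDReference, SimTruth]:
    """Draw one exposure/outcome summary-statistics pair under ``cfg``."""
    cfg.validate()
    L = cfg.L_total
    ids = [f"v{i:05d}" for i in range(L)]

    weights = np.array([p[0] for p in cfg.effect_prior])
    sds = np.array([p[1] for p in cfg.effect_prior])

    if cfg.ld_blocks is not None:
        n_blocks, block_size, within_r2 = cfg.ld_blocks
        blocks = np.arange(L) // block_size
        # blocks sit 1 Mb apart; members span < 100 kb so windows bind in-block
        pos = blocks * 1_000_000 + (np.arange(L) % block_size) * 2_000 + 1
    else:
        blocks = np.arange(L)
        pos = np.arange(L) * 1_000_000 + 1
    chrom = np.full(L, "1")

    rows_exp, rows_out, truth_rows = [], [], []
    for j, vid in enumerate(ids):
        rng = variant_rng(cfg.seed, vid, salt="sim:")
        maf = rng.uniform(*cfg.maf_range)
        eaf = maf if rng.random() < 0.5 else 1.0 - maf
        if rng.random() < cfg.palindromic_fraction:
            ea, oa = _PALINDROMES[rng.integers(len(_PALINDROMES))]
        else:
            ea, oa = _SAFE_ALLELES[rng.integers(len(_SAFE_ALLELES))]

        comp = rng.choice(len(weights), p=weights)
        primary = rng.normal(0.0, sds[comp]) if sds[comp] > 0 else 0.0
        is_reverse = rng.random() < cfg.reverse_fraction
        Z = rng.random() < cfg.q
        theta = rng.normal(0.0, cfg.uncorr_sd) if rng.random() < cfg.pi_uncorr else 0.0
        if is_reverse:
            beta_x = cfg.reverse_effect * primary
            rev = primary
            causal = cfg.gamma * beta_x
            shared = 0.0
            theta = 0.0
            beta_y = rev + causal
        else:
            beta_x = primary
            rev = 0.0
            causal = cfg.gamma * beta_x
            shared = cfg.eta * beta_x if Z else 0.0
            beta_y = causal + shared + theta

        se_x = float(_se(np.array(maf), cfg.n_exp, cfg.exposure_type, cfg.case_frac_exp))
        se_y = float(_se(np.array(maf), cfg.n_out, cfg.outcome_type, cfg.case_frac_out))
        b_x = rng.normal(beta_x, se_x)
        b_y = rng.normal(beta_y, se_y)

        # a fraction of outcome rows is emitted in the swapped-allele
        # representation so harmonization logic is exercised end to end
        swap = rng.random() < cfg.swap_fraction
        out_ea, out_oa = (oa, ea) if swap else (ea, oa)
        out_eaf = 1.0 - eaf if swap else eaf
        out_b = -b_y if swap else b_y

        n_exp_rec = cfg.n_exp
        n_out_rec = cfg.n_out
        rows_exp.append(dict(
            variant_id=vid, chrom=chrom[j], pos=int(pos[j]), effect_allele=ea,
            other_allele=oa, eaf=eaf, beta=b_x, se=se_x,
            pval=float(2 * stats.norm.sf(abs(b_x / se_x))), n=n_exp_rec,
            n_case=int(cfg.case_frac_exp * n_exp_rec) if cfg.exposure_type == "binary" else np.nan,
            n_control=int((1 - cfg.case_frac_exp) * n_exp_rec) if cfg.exposure_type == "binary" else np.nan,
        ))
        rows_out.append(dict(
            variant_id=vid, chrom=chrom[j], pos=int(pos[j]), effect_allele=out_ea,
            other_allele=out_oa, eaf=out_eaf, beta=out_b, se=se_y,
            pval=float(2 * stats.norm.sf(abs(b_y / se_y))), n=n_out_rec,
            n_case=int(cfg.case_frac_out * n_out_rec) if cfg.outcome_type == "binary" else np.nan,
            n_control=int((1 - cfg.case_frac_out) * n_out_rec) if cfg.outcome_type == "binary" else np.nan,
        ))
        truth_rows.append(dict(
            variant_id=vid, beta_X=beta_x, beta_Y=beta_y, causal=causal,
            shared=shared, uncorr=theta, reverse=rev, Z=int(Z),
            is_reverse=int(is_reverse), block=int(blocks[j]),
        ))

    exp_df = pd.DataFrame(rows_exp, columns=COLUMNS)
    out_df = pd.DataFrame(rows_out, columns=COLUMNS)
    exposure = SumStatsTable("sim_exposure", cfg.exposure_type, exp_df,
                             "log-OR" if cfg.exposure_type == "binary" else "SD")
    outcome = SumStatsTable("sim_outcome", cfg.outcome_type, out_df,
                            "log-OR" if cfg.outcome_type == "binary" else "SD")

    ld = _ld_reference(ids, blocks, chrom, pos, cfg)
    truth = SimTruth(pd.DataFrame(truth_rows), cfg)
    return exposure, outcome, ld, truth


def _ld_reference(ids, blocks, chrom, pos, cfg: SimConfig) -> LDReference:
    pairs = []
    if cfg.ld_blocks is not None:
        within_r2 = cfg.ld_blocks[2]
        for b in np.unique(blocks):
            members = [ids[i] for i in np.flatnonzero(blocks == b)]
            for i in range(len(members)):
                for k in range(i + 1, len(members)):
                    pairs.append((members[i], members[k], within_r2))
    pairs_df = pd.DataFrame(pairs, columns=["variant_a", "variant_b", "r2"]) if pairs else None
    positions = pd.DataFrame({"variant_id": ids, "chrom": chrom, "pos": pos})
    return LDReference(pairs_df, positions)


def simulate_binary_margins(cfg: SimConfig) -> pd.DataFrame:
    """Per-variant (log_or, se) for a binary trait under a liability model.

    Liability-scale per-allele effects are drawn from the configured effect
    prior; each is converted to the expected log odds ratio by inverting the
    same observed-to-liability variance mapping used for Steiger filtering,
    so converting the emitted log-ORs back to liability R2 round-trips
    exactly in expectation.
    """
    cfg.validate()
    P = cfg.case_frac_out
    K = cfg.prevalence
    C, theta = _lee_scale_factors(K, P)
    weights = np.array([p[0] for p in cfg.effect_prior])
    sds = np.array([p[1] for p in cfg.effect_prior])
    rows = []
    for j in range(cfg.L_total):
        vid = f"v{j:05d}"
        rng = variant_rng(cfg.seed, vid, salt="liab:")
        maf = rng.uniform(*cfg.maf_range)
        comp = rng.choice(len(weights), p=weights)
        beta_liab = rng.normal(0.0, sds[comp]) if sds[comp] > 0 else 0.0
        # the ascertainment map saturates at 1/theta on the liability scale;
        # clamp below the ceiling so the inverse stays defined
        r2_cap = 0.9 / theta if theta > 0 else 0.95
        r2_liab = min(2.0 * maf * (1.0 - maf) * beta_liab**2, r2_cap)
        denom = C * (1.0 - theta * r2_liab)
        r2_obs = r2_liab / denom
        log_or = np.sign(beta_liab) * np.sqrt(
            r2_obs / (2.0 * maf * (1.0 - maf) * P * (1.0 - P))
        )
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_out * P * (1.0 - P))
        rows.append(dict(variant_id=vid, maf=maf, beta_liability=beta_liab,
                         r2_liability=r2_liab, log_or=float(log_or), se=float(se)))
    return pd.DataFrame(rows)


#: deterministic fixture scenarios used by the tests and the documentation
FIXTURE_SCENARIOS: dict[str, SimConfig] = {
    "null": SimConfig(L_total=50, seed=101),
    "causal": SimConfig(L_total=50, gamma=0.3, seed=102),
    "correlated_pleiotropy": SimConfig(L_total=100, eta=0.3, q=0.3, seed=103),
    # reverse primary effects are outcome-GWAS-grade hits and their exposure
    # echo is strong enough to pass instrument selection, so Steiger
    # filtering has true reverse instruments to remove
    "reverse_causation": SimConfig(
        L_total=100, gamma=0.2, reverse_fraction=0.3, reverse_effect=0.6,
        effect_prior=((1.0, 0.08),), seed=104
    ),
    "ld_blocks": SimConfig(L_total=50, gamma=0.2, ld_blocks=(5, 10, 0.8), seed=105),
}


def make_fixture_suite(out_dir) -> list[Path]:
    """Write the five standard scenario fixtures as delimited text files.

    Each scenario directory holds exposure/outcome summary statistics in the
    default column dialect, the LD pair table and the generative truth.
    Deterministic: repeated runs produce identical bytes.
    """
    from mrscreen.sumstats import DEFAULT_DIALECT

    out_dir = Path(out_dir)
    written = []
    for name, cfg in FIXTURE_SCENARIOS.items():
        d = out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        exposure, outcome, ld, truth = simulate_pair(replace(cfg))
        for label, table in (("exposure", exposure), ("outcome", outcome)):
            df = table.records.rename(columns=DEFAULT_DIALECT)
            p = d / f"{label}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.10g")
            written.append(p)
        pairs = pd.DataFrame(
            [(a, b, r2) for (a, b), r2 in sorted(ld._r2.items())],
            columns=["variant_a", "variant_b", "r2"],
        )
        p = d / "ld_pairs.tsv"
        pairs.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
        p = d / "truth.tsv"
        truth.table.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
    return written
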