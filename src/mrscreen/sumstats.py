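"""Reading, validation, harmonization and trait screening for GWAS summary statistics.

A :class:`SumStatsTable` holds one trait's per-variant association records
(effect sizes in SD units for continuous traits, log odds ratios for binary
traits).  :func:`harmonize` aligns an exposure and an outcome table to a
common effect allele, the first step of any two-sample MR analysis.
:func:`screen_traits` applies study-level inclusion filters to trait metadata:
effective sample size above 5000, more than 450 000 variants, European
ancestry, non-sex-specific, more than three independent genome-wide
significant signals, heritability Z score above 4 and index-trait genetic
correlation Z score above 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names used internally
COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_case",
    "n_control",
]

#: default dialect matching a generic MR-Base-style export
DEFAULT_DIALECT = {
    "variant_id": "SNP",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
    "n_case": "ncase",
    "n_control": "ncontrol",
}

MANDATORY = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval"]


class SumStatsFormatError(ValueError):
    """Raised when a summary-statistics file cannot be interpreted."""


@dataclass
class SumStatsTable:
    """Per-variant association records for one trait.

    ``records`` is a DataFrame with the canonical :data:`COLUMNS`; variant ids
    are unique.  ``trait_type`` is one of ``continuous``, ``binary`` or
    ``ordered-categorical`` (the latter analysed exactly as continuous, with
    the unit note carrying the reporting convention).
    """

    trait_id: str
    trait_type: str
    records: pd.DataFrame
    unit_note: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary", "ordered-categorical"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.records["variant_id"].duplicated().any():
            dups = self.records["variant_id"][self.records["variant_id"].duplicated()]
            raise ValueError(f"duplicated variant ids: {sorted(set(dups))[:5]}")
        if self.trait_type == "binary":
            if self.records["n_case"].isna().all() or self.records["n_control"].isna().all():
                raise ValueError("binary trait requires n_case and n_control")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_binary(self) -> bool:
        return self.trait_type == "binary"


@dataclass
class TraitMeta:
    """Study-level metadata for one trait, consumed by :func:`screen_traits`."""

    trait_id: str
    n: float | None = None
    n_case: float | None = None
    n_control: float | None = None
    n_variants: int | None = None
    ancestry: str | None = None
    sex_specific: bool | None = None
    n_gws_signals: int | None = None
    h2_Z: float | None = None
    rg_with_index_Z: float | None = None
    category: str = ""


@dataclass
class HarmonizedPair:
    """Exposure/outcome effects aligned to a common effect allele.

    ``rows`` has one row per exposure variant with columns
    ``variant_id, chrom, pos, b_X, se_X, p_X, b_Y, se_Y, p_Y, eaf_X, eaf_Y,
    action`` where action is one of ``kept``, ``sign-flipped``,
    ``palindromic-dropped``, ``missing-dropped`` or ``proxy-substituted``.
    Dropped rows carry NaN outcome effects and are excluded by
    :meth:`usable`.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame
    log: dict = field(default_factory=dict)

    def usable(self) -> pd.DataFrame:
        """Rows retained for analysis (outcome effect present and aligned)."""
        keep = self.rows["action"].isin(["kept", "sign-flipped", "proxy-substituted"])
        return self.rows[keep]


def effective_sample_size(n_case: float, n_control: float) -> float:
    """Effective sample size of a case-control study, 4*nc*nk/(nc+nk).

    Equals the total sample size for a balanced design and is strictly
    smaller otherwise.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 * n_case * n_control / (n_case + n_control)


def read_sumstats(
    path,
    dialect: dict | None = None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    sep: str | None = None,
    unit_note: str = "",
) -> SumStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``dialect`` maps canonical column names to the file's column names;
    unmapped optional columns become missing.  Rows failing validation
    (non-positive SE, missing beta/se, non-biallelic allele strings, p
    outside (0,1]) are dropped with a logged count.  A p-value grossly
    inconsistent with |beta/se| triggers a warning only: public summary
    statistics routinely carry rounded p-values.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    missing = [c for c in MANDATORY if dialect.get(c) not in raw.columns]
    if missing:
        raise SumStatsFormatError(
            f"missing mandatory columns {missing} (dialect maps them to "
            f"{[dialect.get(c) for c in missing]})"
        )
    df = pd.DataFrame(index=raw.index)
    for canon in COLUMNS:
        src = dialect.get(canon)
        df[canon] = raw[src] if src in raw.columns else np.nan
    df["variant_id"] = df["variant_id"].astype(str)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()
    for c in ("eaf", "beta", "se", "pval", "n", "n_case", "n_control"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    n0 = len(df)
    ok = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    ok &= df["effect_allele"].isin(_BASES) & df["other_allele"].isin(_BASES)
    ok &= df["effect_allele"] != df["other_allele"]
    ok &= df["pval"].notna() & (df["pval"] > 0) & (df["pval"] <= 1)
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d/%d invalid rows", trait_id or path, dropped, n0)
    df = df[ok].reset_index(drop=True)

    # warn-only consistency check between p and |beta/se|
    with np.errstate(divide="ignore"):
        z = np.abs(df["beta"] / df["se"])
        implied = 2 * stats.norm.sf(z)
    bad = (implied > 0) & (np.abs(np.log(df["pval"] / np.maximum(implied, 1e-300))) > np.log(10))
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} rows have p-values inconsistent with beta/se "
            "by more than a factor of 10 (kept; check the column mapping)",
            stacklevel=2,
        )
    return SumStatsTable(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        records=df,
        unit_note=unit_note,
    )


# trait-screening rules, applied in order; the first failure is reported
_SCREEN_DEFAULTS = {
    "min_sample_size": 5000.0,
    "min_n_variants": 450_000,
    "ancestry": "European",
    "min_gws_signals": 3,
    "min_h2_z": 4.0,
    "min_rg_z": 2.0,
}


def screen_traits(
    metas: list[TraitMeta], cfg: dict | None = None
) -> tuple[list[TraitMeta], list[tuple[TraitMeta, str]]]:
    """Partition traits into kept and excluded per the inclusion criteria.

    Rules, in order of evaluation (an exclusion carries the first failing
    rule): (effective) sample size > 5000; > 450 000 variants; European
    ancestry; non-sex-specific; > 3 independent genome-wide significant
    signals; heritability Z > 4; genetic correlation Z with the index trait
    > 2.  Missing required fields exclude a trait with reason ``incomplete``.
    """
    cfg = {**_SCREEN_DEFAULTS, **(cfg or {})}
    kept: list[TraitMeta] = []
    excluded: list[tuple[TraitMeta, str]] = []
    for m in metas:
        reason = _first_failure(m, cfg)
        if reason is None:
            kept.append(m)
        else:
            excluded.append((m, reason))
    return kept, excluded


def _first_failure(m: TraitMeta, cfg: dict) -> str | None:
    if m.n_case is not None and m.n_control is not None:
        if m.n_case <= 0 or m.n_control <= 0:
            return "incomplete"
        size = effective_sample_size(m.n_case, m.n_control)
    elif m.n is not None:
        size = m.n
    else:
        return "incomplete"
    if not size > cfg["min_sample_size"]:
        return "sample-size"
    if m.n_variants is None:
        return "incomplete"
    if not m.n_variants > cfg["min_n_variants"]:
        return "variant-count"
    if m.ancestry is None:
        return "incomplete"
    if m.ancestry != cfg["ancestry"]:
        return "ancestry"
    if m.sex_specific is None:
        return "incomplete"
    if m.sex_specific:
        return "sex-specific"
    if m.n_gws_signals is None:
        return "incomplete"
    if not m.n_gws_signals > cfg["min_gws_signals"]:
        return "gws-signals"
    if m.h2_Z is None or not np.isfinite(m.h2_Z):
        return "incomplete"
    if not m.h2_Z > cfg["min_h2_z"]:
        return "heritability-z"
    if m.rg_with_index_Z is None or not np.isfinite(m.rg_with_index_Z):
        return "incomplete"
    if not m.rg_with_index_Z > cfg["min_rg_z"]:
        return "genetic-correlation-z"
    return None


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindrome_maf_limit: float = 0.42,
) -> HarmonizedPair:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Matching handles direct allele matches, effect/other swaps (outcome beta
    sign flipped, eaf complemented) and strand flips (allele complements).
    Palindromic variants (A/T or C/G) are kept only when both frequencies are
    present, informative (minor allele frequency below
    ``palindrome_maf_limit``) and agree on orientation; otherwise they are
    dropped as unresolvable.  Exposure variants absent from the outcome are
    flagged ``missing-dropped`` so the instruments module can attempt proxy
    substitution.
    """
    exp = exposure.records
    out = outcome.records.set_index("variant_id")
    rows = []
    for rec in exp.itertuples(index=False):
        row = {
            "variant_id": rec.variant_id,
            "chrom": rec.chrom,
            "pos": rec.pos,
            "b_X": rec.beta,
            "se_X": rec.se,
            "p_X": rec.pval,
            "eaf_X": rec.eaf,
            "b_Y": np.nan,
            "se_Y": np.nan,
            "p_Y": np.nan,
            "eaf_Y": np.nan,
        }
        if rec.variant_id not in out.index:
            row["action"] = "missing-dropped"
            rows.append(row)
            continue
        o = out.loc[rec.variant_id]
        action = _align(rec, o, palindrome_maf_limit)
        if action in ("palindromic-dropped", "missing-dropped"):
            row["action"] = action
            rows.append(row)
            continue
        flip = action == "sign-flipped"
        row.update(
            b_Y=-o["beta"] if flip else o["beta"],
            se_Y=o["se"],
            p_Y=o["pval"],
            eaf_Y=(1 - o["eaf"]) if flip and pd.notna(o["eaf"]) else o["eaf"],
            action=action,
        )
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "b_X", "se_X", "p_X",
            "b_Y", "se_Y", "p_Y", "eaf_X", "eaf_Y", "action",
        ],
    )
    log = df["action"].value_counts().to_dict() if len(df) else {}
    return HarmonizedPair(exposure.trait_id, outcome.trait_id, df, log)


def _align(exp_rec, out_row, palindrome_maf_limit: float) -> str:
    """Decide the harmonization action for one exposure/outcome variant pair."""
    ea, oa = exp_rec.effect_allele, exp_rec.other_allele
    oea, ooa = out_row["effect_allele"], out_row["other_allele"]
    if _is_palindromic(ea, oa):
        # strand is unknowable from alleles; use frequencies if informative
        eaf_x, eaf_y = exp_rec.eaf, out_row["eaf"]
        if {oea, ooa} != {ea, oa}:
            return "palindromic-dropped"
        if pd.isna(eaf_x) or pd.isna(eaf_y):
            return "palindromic-dropped"
        if min(eaf_x, 1 - eaf_x) > palindrome_maf_limit or min(eaf_y, 1 - eaf_y) > palindrome_maf_limit:
            return "palindromic-dropped"
        same_allele = oea == ea
        same_side = (eaf_x < 0.5) == ((eaf_y if same_allele else 1 - eaf_y) < 0.5)
        if same_allele:
            return "kept" if same_side else "sign-flipped"
        return "sign-flipped" if same_side else "kept"
    if (oea, ooa) == (ea, oa):
        return "kept"
    if (oea, ooa) == (oa, ea):
        return "sign-flipped"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (oea, ooa) == (cea, coa):
        return "kept"
    if (oea, ooa) == (coa, cea):
        return "sign-flipped"
    return "missing-dropped"  # irreconcilable alleles; no usable outcome record


def write_harmonization_log(pair: HarmonizedPair, path) -> None:
    """Write the per-variant harmonization audit (one row per variant)."""
    pair.rows[["variant_id", "action"]].to_csv(path, sep="\t", index=False)
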