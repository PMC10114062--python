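"""Two-sample MR estimators and diagnostics.

All estimators consume an :class:`MRInput` (per-instrument exposure and
outcome effects with standard errors, harmonized to a common effect allele)
and return an :class:`MRResult`.  The main analysis is the multiplicative
random-effects inverse-variance-weighted (IVW) estimator; the battery adds
MR-Egger (with the I2GX regression-dilution diagnostic and a SIMEX
correction), the weighted median, the weighted mode, leave-one-out IVW and
tidy data frames for scatter, funnel and forest plots.

Conventions: standard errors are scaled by max(1, sqrt(Q/df)) so the
random-effects model never shrinks below fixed-effects; p-values use the
normal reference distribution.  Both are switchable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MRInput:
    """Harmonized per-instrument effect vectors for one direction."""

    b_X: np.ndarray
    se_X: np.ndarray
    b_Y: np.ndarray
    se_Y: np.ndarray
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    direction: str = "forward"
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.b_X = np.asarray(self.b_X, dtype=float)
        self.se_X = np.asarray(self.se_X, dtype=float)
        self.b_Y = np.asarray(self.b_Y, dtype=float)
        self.se_Y = np.asarray(self.se_Y, dtype=float)
        L = len(self.b_X)
        if not (len(self.se_X) == len(self.b_Y) == len(self.se_Y) == L):
            raise ValueError("effect vectors must have equal length")
        if L < 1:
            raise ValueError("at least one instrument required")
        if np.any(self.se_X <= 0) or np.any(self.se_Y <= 0):
            raise ValueError("standard errors must be positive")
        if self.variant_ids is None:
            self.variant_ids = [f"v{i}" for i in range(L)]

    @property
    def L(self) -> int:
        return len(self.b_X)

    def subset(self, mask: np.ndarray) -> "MRInput":
        ids = [v for v, m in zip(self.variant_ids, mask) if m]
        return MRInput(
            self.b_X[mask], self.se_X[mask], self.b_Y[mask], self.se_Y[mask],
            self.exposure_id, self.outcome_id, self.direction, ids,
        )

    @classmethod
    def from_instrument_set(cls, inst_set) -> "MRInput":
        ins = inst_set.instruments
        return cls(
            b_X=np.array([i.b_X for i in ins]),
            se_X=np.array([i.se_X for i in ins]),
            b_Y=np.array([i.b_Y for i in ins]),
            se_Y=np.array([i.se_Y for i in ins]),
            exposure_id=inst_set.exposure_id,
            outcome_id=inst_set.outcome_id,
            direction=inst_set.direction,
            variant_ids=[i.variant_id for i in ins],
        )


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    L_used: int
    extra: dict = field(default_factory=dict)

    @property
    def applicable(self) -> bool:
        return np.isfinite(self.estimate)


@dataclass
class HeterogeneityStats:
    Q: float
    df: int
    q_pval: float
    i2_percent: float


def not_applicable(method: str, reason: str) -> MRResult:
    """Explicit method-not-applicable result (too few instruments etc.)."""
    return MRResult(method, np.nan, np.nan, np.nan, np.nan, np.nan, 0, {"reason": reason})


def _finish(method, estimate, se, L, extra=None, use_t=False, df=None):
    if se > 0 and np.isfinite(se):
        if use_t and df and df > 0:
            crit = stats.t.ppf(0.975, df)
            pval = 2 * stats.t.sf(abs(estimate / se), df)
        else:
            crit = stats.norm.ppf(0.975)
            pval = 2 * stats.norm.sf(abs(estimate / se))
        pval = max(float(pval), np.finfo(float).tiny)
    else:
        crit, pval = np.nan, np.nan
    return MRResult(
        method, float(estimate), float(se),
        float(estimate - crit * se), float(estimate + crit * se),
        pval, int(L), extra or {},
    )


def wald_ratios(mr_input: MRInput) -> list[tuple[float, float]]:
    """Per-variant causal ratios b_Y/b_X with first-order delta SEs.

    Instruments with a zero exposure effect are excluded (their ratio is
    undefined); the returned list is aligned to the surviving instruments.
    """
    ratios = []
    for bx, by, sy in zip(mr_input.b_X, mr_input.b_Y, mr_input.se_Y):
        if bx == 0:
            continue
        ratios.append((by / bx, sy / abs(bx)))
    return ratios


def _ratio_arrays(mr_input: MRInput) -> tuple[np.ndarray, np.ndarray]:
    keep = mr_input.b_X != 0
    bx, by, sy = mr_input.b_X[keep], mr_input.b_Y[keep], mr_input.se_Y[keep]
    return by / bx, sy / np.abs(bx)


def ivw_mre(
    mr_input: MRInput, se_floor: bool = True, use_t: bool = False
) -> tuple[MRResult, HeterogeneityStats]:
    """Multiplicative random-effects IVW: regression through the origin.

    estimate = sum(w b_X b_Y)/sum(w b_X^2) with w = 1/se_Y^2; Cochran's
    Q = sum(w (b_Y - est*b_X)^2) on L-1 df; the SE is the fixed-effects SE
    scaled by sqrt(Q/df), floored at 1 unless ``se_floor`` is False.
    """
    if mr_input.L < 2:
        het = HeterogeneityStats(np.nan, 0, np.nan, np.nan)
        return not_applicable("ivw_mre", "fewer than 2 instruments"), het
    bx, by, sy = mr_input.b_X, mr_input.b_Y, mr_input.se_Y
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    est = np.sum(w * bx * by) / denom
    Q = float(np.sum(w * (by - est * bx) ** 2))
    df = mr_input.L - 1
    scale = np.sqrt(Q / df)
    if se_floor:
        scale = max(1.0, scale)
    se = np.sqrt(1.0 / denom) * scale
    het = heterogeneity(Q, df)
    res = _finish("ivw_mre", est, se, mr_input.L, use_t=use_t, df=df)
    res.extra.update(Q=Q, q_df=df, q_pval=het.q_pval, i2_percent=het.i2_percent)
    return res, het


def heterogeneity(Q: float, df: int) -> HeterogeneityStats:
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    q_p = float(stats.chi2.sf(Q, df)) if df > 0 else np.nan
    return HeterogeneityStats(float(Q), int(df), q_p, float(i2))


def i2_gx(b_X: np.ndarray, se_X: np.ndarray) -> float:
    """Regression-dilution diagnostic for MR-Egger (NOME assumption).

    I2GX = max(0, (Q_GX - (L-1))/Q_GX) with Q_GX the precision-weighted
    dispersion of the exposure effects relative to their standard errors.
    Values near 1 mean exposure effects are measured essentially without
    error; below 0.9 the Egger slope is attenuated, below 0.6 it is
    conventionally disregarded.
    """
    w = 1.0 / se_X**2
    bbar = np.sum(w * b_X) / np.sum(w)
    q_gx = float(np.sum((b_X - bbar) ** 2 / se_X**2))
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (len(b_X) - 1)) / q_gx)


def _egger_fit(bx: np.ndarray, by: np.ndarray, w: np.ndarray):
    """Weighted straight-line fit; returns (intercept, slope, cov matrix)."""
    sw = np.sum(w)
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    slope = np.sum(w * (bx - mx) * (by - my)) / sxx
    intercept = my - slope * mx
    var_slope = 1.0 / sxx
    var_intercept = 1.0 / sw + mx**2 / sxx
    return intercept, slope, var_intercept, var_slope


def egger(mr_input: MRInput, se_floor: bool = True, use_t: bool = False) -> MRResult:
    """MR-Egger regression: weighted fit of b_Y on b_X with an intercept.

    Instruments are oriented so all b_X > 0 before fitting (the intercept is
    only interpretable under a fixed exposure-effect orientation).  The
    intercept estimates the average directional pleiotropy and its test is
    reported as ``egger_intercept_p``; the I2GX diagnostic is attached.
    """
    if mr_input.L < 3:
        return not_applicable("mr_egger", "fewer than 3 instruments")
    flip = np.sign(mr_input.b_X)
    flip[flip == 0] = 1.0
    bx = mr_input.b_X * flip
    by = mr_input.b_Y * flip
    w = 1.0 / mr_input.se_Y**2
    if np.allclose(bx, bx[0]):
        return not_applicable("mr_egger", "no spread in exposure effects")
    intercept, slope, var_i, var_s = _egger_fit(bx, by, w)
    resid = by - intercept - slope * bx
    Q = float(np.sum(w * resid**2))
    df = mr_input.L - 2
    scale = np.sqrt(Q / df) if df > 0 else 1.0
    if se_floor:
        scale = max(1.0, scale)
    se_slope = np.sqrt(var_s) * scale
    se_int = np.sqrt(var_i) * scale
    if use_t and df > 0:
        int_p = 2 * stats.t.sf(abs(intercept / se_int), df)
    else:
        int_p = 2 * stats.norm.sf(abs(intercept / se_int))
    res = _finish("mr_egger", slope, se_slope, mr_input.L, use_t=use_t, df=df)
    res.extra.update(
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_p=float(int_p),
        i2gx=i2_gx(mr_input.b_X, mr_input.se_X),
        Q=Q,
        q_df=df,
    )
    return res


def simex_egger(
    mr_input: MRInput,
    lambda_grid: list[float] | None = None,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    n_batches: int = 20,
) -> MRResult:
    """Simulation-extrapolation correction of the MR-Egger slope.

    When exposure effects carry non-negligible measurement error
    (0.6 < I2GX <= 0.9) the naive Egger slope is attenuated towards zero.
    SIMEX adds further synthetic error of variance lambda * se_X^2 for each
    lambda on the grid, averages the refitted slope over ``B`` replicates,
    fits a quadratic in lambda and extrapolates to lambda = -1 (no error).
    The SE comes from a jackknife over simulation batches combined with the
    naive Egger sampling variance.
    """
    if mr_input.L < 3:
        return not_applicable("simex_egger", "fewer than 3 instruments")
    grid = np.asarray(lambda_grid if lambda_grid is not None else [0.0, 0.5, 1.0, 1.5, 2.0])
    if len(grid) < 3:
        raise ValueError("lambda grid must have at least 3 points for quadratic extrapolation")
    if B < n_batches:
        n_batches = max(2, B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flip = np.sign(mr_input.b_X)
    flip[flip == 0] = 1.0
    bx = mr_input.b_X * flip
    by = mr_input.b_Y * flip
    sx = mr_input.se_X
    w = 1.0 / mr_input.se_Y**2

    # slopes[g, b]: Egger slope at grid point g, replicate b (vectorized fit)
    slopes = np.empty((len(grid), B))
    for g, lam in enumerate(grid):
        if lam == 0:
            _, s0, _, _ = _egger_fit(bx, by, w)
            slopes[g, :] = s0
            continue
        # perturb the covariate only: orientation was fixed once on the
        # observed effects, re-flipping would skew the added noise
        noise = rng.normal(0.0, 1.0, size=(B, mr_input.L)) * np.sqrt(lam) * sx
        bxs = bx[None, :] + noise
        sw = np.sum(w)
        mx = bxs @ w / sw
        my = np.sum(w * by) / sw
        dx = bxs - mx[:, None]
        sxx = np.sum(w * dx**2, axis=1)
        slopes[g, :] = np.sum(w * dx * (by - my)[None, :], axis=1) / sxx

    def extrapolate(mean_slopes: np.ndarray) -> float:
        coef = np.polyfit(grid, mean_slopes, 2)
        return float(np.polyval(coef, -1.0))

    est = extrapolate(slopes.mean(axis=1))
    # jackknife over batches captures simulation noise in the extrapolation
    batches = np.array_split(np.arange(B), n_batches)
    jk = np.array([
        extrapolate(np.delete(slopes, idx, axis=1).mean(axis=1)) for idx in batches
    ])
    var_sim = (n_batches - 1) / n_batches * np.sum((jk - jk.mean()) ** 2)
    naive = egger(mr_input)
    se = float(np.sqrt(var_sim + naive.se**2))
    res = _finish("simex_egger", est, se, mr_input.L)
    res.extra.update(
        naive_egger=naive.estimate,
        egger_intercept_p=naive.extra.get("egger_intercept_p"),
        i2gx=naive.extra.get("i2gx"),
        simex_applied=True,
    )
    return res


def _weighted_median_core(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    k = np.searchsorted(s, 0.5) - 1
    frac = (0.5 - s[k]) / (s[k + 1] - s[k])
    return float(r[k] + frac * (r[k + 1] - r[k]))


def weighted_median(
    mr_input: MRInput, boot_B: int = 1000, seed: int | np.random.Generator = 0
) -> MRResult:
    """Weighted-median estimator: consistent if >=50% of weight is valid.

    The estimate interpolates the inverse-variance-weighted empirical
    distribution of per-variant ratios at probability 1/2.  The SE is a
    parametric bootstrap (resampling b_X and b_Y from their sampling
    normals); pass ``boot_B=0`` for the point estimate alone.
    """
    if mr_input.L < 3:
        return not_applicable("weighted_median", "fewer than 3 instruments")
    ratios, ratio_se = _ratio_arrays(mr_input)
    weights = 1.0 / ratio_se**2
    est = _weighted_median_core(ratios, weights)
    se = _bootstrap_se(mr_input, _weighted_median_core, boot_B, seed)
    return _finish("weighted_median", est, se, mr_input.L)


def _weighted_mode_core(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float = 1.0,
    grid_size: int = 512,
) -> float:
    w = weights / np.sum(weights)
    mu = np.sum(w * ratios)
    sd = np.sqrt(np.sum(w * (ratios - mu) ** 2))
    med = _weighted_median_core(ratios, weights)
    mad = 1.4826 * _weighted_median_core(np.abs(ratios - med), weights)
    s = min(sd, mad) if mad > 0 else sd
    if s <= 0:
        return float(ratios[0])  # all ratios identical
    h = bandwidth_factor * 0.9 * s * len(ratios) ** (-1 / 5)

    def density(x):
        return np.sum(
            w[None, :] * np.exp(-0.5 * ((x[:, None] - ratios[None, :]) / h) ** 2),
            axis=1,
        )

    # the global mode lies within ~h of a data point; locate the best point
    # first, then refine on a local grid — a single uniform grid over the
    # full ratio range can miss narrow kernels entirely when outlier ratios
    # stretch the range far beyond the bandwidth
    at_points = density(ratios)
    anchor = ratios[int(np.argmax(at_points))]
    local = np.linspace(anchor - 2 * h, anchor + 2 * h, grid_size)
    dens = density(local)
    return float(local[np.argmax(dens)])


def weighted_mode(
    mr_input: MRInput,
    bandwidth_factor: float = 1.0,
    boot_B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MRResult:
    """Weighted-mode estimator: consistent if the largest group of
    instruments sharing a ratio is valid.

    The mode of the weighted normal-kernel density over per-variant ratios,
    with a modified Silverman bandwidth on the weighted data scaled by
    ``bandwidth_factor``.  SE by parametric bootstrap (``boot_B=0`` skips it).
    """
    if mr_input.L < 3:
        return not_applicable("weighted_mode", "fewer than 3 instruments")
    ratios, ratio_se = _ratio_arrays(mr_input)
    weights = 1.0 / ratio_se**2
    est = _weighted_mode_core(ratios, weights, bandwidth_factor)
    se = _bootstrap_se(
        mr_input, lambda r, w: _weighted_mode_core(r, w, bandwidth_factor), boot_B, seed
    )
    return _finish("weighted_mode", est, se, mr_input.L)


def _bootstrap_se(mr_input: MRInput, core, B: int, seed) -> float:
    if B <= 0:
        return np.nan
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = mr_input.L
    bx = rng.normal(mr_input.b_X, mr_input.se_X, size=(B, L))
    by = rng.normal(mr_input.b_Y, mr_input.se_Y, size=(B, L))
    bx[bx == 0] = np.finfo(float).eps
    ratios = by / bx
    ratio_se = mr_input.se_Y[None, :] / np.abs(bx)
    ests = np.array([core(ratios[b], 1.0 / ratio_se[b] ** 2) for b in range(B)])
    return float(np.std(ests, ddof=1))


def leave_one_out(mr_input: MRInput) -> list[tuple[str, MRResult]]:
    """IVW-MRE refit omitting each instrument in turn."""
    if mr_input.L < 3:
        return []
    out = []
    for i in range(mr_input.L):
        mask = np.ones(mr_input.L, dtype=bool)
        mask[i] = False
        res, _ = ivw_mre(mr_input.subset(mask))
        out.append((mr_input.variant_ids[i], res))
    return out


def plot_frames(
    mr_input: MRInput, results: list[MRResult]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tidy data frames backing scatter, funnel and forest plots."""
    ratios, ratio_se = _ratio_arrays(mr_input)
    scatter = pd.DataFrame({
        "variant_id": mr_input.variant_ids,
        "b_X": mr_input.b_X,
        "se_X": mr_input.se_X,
        "b_Y": mr_input.b_Y,
        "se_Y": mr_input.se_Y,
    })
    for r in results:
        if r.applicable:
            scatter[f"fit_{r.method}"] = (
                r.extra.get("egger_intercept", 0.0) + r.estimate * mr_input.b_X
            )
    funnel = pd.DataFrame({
        "variant_id": [v for v, bx in zip(mr_input.variant_ids, mr_input.b_X) if bx != 0],
        "ratio": ratios,
        "precision": 1.0 / ratio_se,
    })
    z = stats.norm.ppf(0.975)
    forest_rows = [
        {
            "label": v,
            "estimate": r,
            "ci_low": r - z * s,
            "ci_high": r + z * s,
            "kind": "snp",
        }
        for v, r, s in zip(funnel["variant_id"], ratios, ratio_se)
    ]
    for res in results:
        forest_rows.append({
            "label": res.method,
            "estimate": res.estimate,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "kind": "pooled",
        })
    return scatter, funnel, pd.DataFrame(forest_rows)
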