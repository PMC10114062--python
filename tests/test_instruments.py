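import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrscreen.estimators import MRInput, ivw_mre
from mrscreen.instruments import (
    Instrument,
    InstrumentSet,
    LDReference,
    build_instrument_set,
    clump,
    f_statistics,
    r2_binary_liability,
    r2_continuous,
    remove_shared_significant,
    steiger_filter,
    substitute_proxies,
)
from mrscreen.simulate import SimConfig, simulate_pair
from mrscreen.sumstats import harmonize

from conftest import table_from_records


def _ld(pairs):
    return LDReference(pd.DataFrame(pairs, columns=["variant_a", "variant_b", "r2"]))


class TestClump:
    def test_greedy_keeps_best_of_correlated_pair(self):
        t = table_from_records([
            {"beta": 0.1, "se": 0.01, "pval": 1e-10, "pos": 1000},
            {"beta": 0.1, "se": 0.01, "pval": 1e-9, "pos": 6000},
        ])
        kept = clump(t, _ld([("rs0", "rs1", 0.9)]))
        assert kept == ["rs0"]

    def test_different_chromosomes_both_kept(self):
        t = table_from_records([
            {"beta": 0.1, "se": 0.01, "pval": 1e-9, "chrom": "1"},
            {"beta": 0.1, "se": 0.01, "pval": 1e-9, "chrom": "2"},
        ])
        assert len(clump(t, _ld([]))) == 2

    def test_ld_blocks_yield_one_hit_each(self):
        cfg = SimConfig(L_total=50, gamma=0.4, effect_prior=((1.0, 0.12),),
                        ld_blocks=(5, 10, 0.8), seed=21)
        exposure, _, ld, truth = simulate_pair(cfg)
        kept = clump(exposure, ld)
        blocks = truth.table.set_index("variant_id")["block"]
        assert len(kept) == len({blocks[v] for v in kept})
        rec = exposure.records.set_index("variant_id")
        for v in kept:
            members = blocks[blocks == blocks[v]].index
            sig = rec.loc[members].query("pval < 5e-8")
            assert rec.loc[v, "pval"] == sig["pval"].min()

    def test_no_significant_variant_returns_empty(self):
        t = table_from_records([{"beta": 0.01, "se": 0.01, "pval": 0.3}])
        assert clump(t, _ld([])) == []

    def test_row_order_invariance_and_greedy_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            L = int(rng.integers(10, 60))
            pvals = 10 ** rng.uniform(-30, -5, L)
            pos = rng.integers(0, 50_000, L)
            rows = [{"beta": 1.0, "se": 0.1, "pval": float(pvals[i]),
                     "pos": int(pos[i])} for i in range(L)]
            t = table_from_records(rows)
            ids = list(t.records["variant_id"])
            pairs = []
            for a, b in itertools.combinations(range(L), 2):
                if rng.random() < 0.3:
                    pairs.append((ids[a], ids[b], float(rng.uniform(0, 1))))
            ld = _ld(pairs)
            kept = clump(t, ld, r2_max=0.1, window_kb=20.0, p_max=5e-8)

            shuffled = t.records.sample(frac=1, random_state=trial).reset_index(drop=True)
            t2 = type(t)(t.trait_id, t.trait_type, shuffled)
            assert clump(t2, ld, r2_max=0.1, window_kb=20.0, p_max=5e-8) == kept

            # brute-force greedy oracle over the explicit p-ranked order
            rec = t.records.sort_values(["pval", "variant_id"])
            oracle = []
            for vid, p, po in rec[["variant_id", "pval", "pos"]].itertuples(index=False):
                if p >= 5e-8:
                    continue
                if all(
                    ld.r2(vid, k) < 0.1 or abs(po - kp) > 20_000
                    for k, kp in oracle_pos(oracle, rec)
                ):
                    oracle.append(vid)
            assert kept == oracle


def oracle_pos(chosen, rec):
    lookup = rec.set_index("variant_id")["pos"]
    return [(k, lookup[k]) for k in chosen]


class TestProxies:
    def _outcome(self):
        return table_from_records(
            [{"beta": 0.1, "se": 0.01, "pval": 0.01} for _ in range(3)], trait_id="out"
        )

    def test_highest_r2_proxy_chosen(self):
        ld = _ld([("missing", "rs0", 0.95), ("missing", "rs1", 0.85)])
        assert substitute_proxies(["missing"], self._outcome(), ld) == [("missing", "rs0")]

    def test_below_threshold_not_substituted(self):
        ld = _ld([("missing", "rs0", 0.7)])
        assert substitute_proxies(["missing"], self._outcome(), ld) == []

    def test_empty_input(self):
        assert substitute_proxies([], self._outcome(), _ld([])) == []


class TestRemoveSharedSignificant:
    def _pair(self, p_x, p_y):
        e = table_from_records([{"beta": 0.1, "se": 0.01, "pval": p_x}])
        o = table_from_records([{"beta": 0.1, "se": 0.01, "pval": p_y}])
        return harmonize(e, o)

    def test_both_significant_removed(self):
        out = remove_shared_significant(self._pair(1e-10, 1e-9))
        assert len(out.rows) == 0
        assert out.log["shared-significant-removed"] == 1

    def test_one_sided_failure_kept(self):
        out = remove_shared_significant(self._pair(1e-10, 1e-3))
        assert len(out.rows) == 1

    def test_empty_pair_passthrough(self):
        e = table_from_records([])
        out = remove_shared_significant(harmonize(e, e))
        assert len(out.rows) == 0


class TestVarianceExplained:
    def test_null_effect_is_zero(self):
        assert r2_continuous(0.0, 0.1, 1000) == 0.0
        assert r2_binary_liability(0.0, 0.3, 5000, 5000, 0.1) == 0.0

    def test_continuous_closed_form(self):
        # t = 10, n = 10002 -> 100/10100
        assert r2_continuous(0.1, 0.01, 10002) == pytest.approx(100 / 10100)

    def test_continuous_decreases_with_n(self):
        vals = [r2_continuous(0.1, 0.01, n) for n in (100, 1000, 10_000)]
        assert vals == sorted(vals, reverse=True)

    def test_continuous_requires_n_above_two(self):
        with pytest.raises(ValueError):
            r2_continuous(0.1, 0.01, 2)

    def test_binary_sign_symmetric(self):
        a = r2_binary_liability(0.25, 0.3, 20_000, 30_000, 0.08)
        b = r2_binary_liability(-0.25, 0.3, 20_000, 30_000, 0.08)
        assert a == pytest.approx(b)

    def test_binary_matches_independent_rederivation(self):
        # independent step-by-step liability-conversion oracle: observed-scale
        # R2 from the logistic derivative, then the case-control-to-liability
        # rescaling C/(1 + C*theta*R2) with threshold-model constants
        log_or, eaf, nc, nk, K = 0.2, 0.25, 20_000, 30_000, 0.05
        P = nc / (nc + nk)
        r2_obs = 2 * eaf * (1 - eaf) * log_or**2 * P * (1 - P)
        t = stats.norm.ppf(1 - K)
        z = stats.norm.pdf(t)
        i = z / K
        C = K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2)
        lam = i * (P - K) / (K * (1 - K))
        theta = lam * (lam - t)
        expected = C * r2_obs / (1 + C * theta * r2_obs)
        assert r2_binary_liability(log_or, eaf, nc, nk, K) == pytest.approx(expected, rel=1e-12)

    def test_outputs_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            v = r2_binary_liability(
                rng.normal(0, 1.0), rng.uniform(0.01, 0.99),
                1000, 3000, rng.uniform(0.01, 0.5),
            )
            assert 0.0 <= v < 1.0
            w = r2_continuous(rng.normal(0, 0.2), 0.01, 1000)
            assert 0.0 <= w < 1.0

    def test_binary_boundary_inputs_rejected(self):
        with pytest.raises(ValueError):
            r2_binary_liability(0.1, 0.0, 100, 100, 0.1)
        with pytest.raises(ValueError):
            r2_binary_liability(0.1, 0.3, 100, 100, 1.0)


def _inst(vid, r2_exp, r2_out, b=0.1):
    return Instrument(vid, b, 0.01, 1e-9, 0.05, 0.01, r2_exp, r2_out)


class TestSteigerFilter:
    def test_keeps_correct_direction_removes_reverse(self):
        s = InstrumentSet("e", "o", "forward", [
            _inst("a", 0.010, 0.001), _inst("b", 0.001, 0.010)
        ])
        out = steiger_filter(s)
        assert out.variant_ids() == ["a"]
        assert out.selection_log["steiger-removed"] == 1

    def test_idempotent_and_survivors_positive_gap(self):
        s = InstrumentSet("e", "o", "forward", [
            _inst("a", 0.01, 0.001), _inst("b", 0.004, 0.002), _inst("c", 0.001, 0.02)
        ])
        once = steiger_filter(s)
        twice = steiger_filter(once)
        assert once.variant_ids() == twice.variant_ids()
        assert all(i.r2_exposure > i.r2_outcome for i in once.instruments)

    def test_removes_planted_reverse_instruments(self):
        cfg = SimConfig(L_total=100, gamma=0.2, reverse_fraction=0.3,
                        reverse_effect=0.6, effect_prior=((1.0, 0.08),), seed=104)
        exposure, outcome, ld, truth = simulate_pair(cfg)
        pair = harmonize(exposure, outcome)
        selected = clump(exposure, ld)
        inst = build_instrument_set(pair, selected, exposure, outcome)
        reverse = set(truth.table.variant_id[truth.table.is_reverse == 1])
        planted = set(inst.variant_ids()) & reverse
        assert planted, "fixture must place reverse variants among instruments"
        survivors = set(steiger_filter(inst).variant_ids())
        removed = len(planted - survivors) / len(planted)
        assert removed >= 0.9


class TestFStatistics:
    def test_single_snp_f_is_squared_z(self):
        s = InstrumentSet("e", "o", "f", [_inst("a", 0.01, 0.001, b=0.1)])
        per_snp, mean_f, agg = f_statistics(s, 10_000)
        assert per_snp[0] == pytest.approx(100.0)
        assert mean_f == pytest.approx(100.0)

    def test_zero_effects_zero_f(self):
        s = InstrumentSet("e", "o", "f", [_inst("a", 0.0, 0.0, b=0.0),
                                          _inst("b", 0.0, 0.0, b=0.0)])
        assert f_statistics(s, 10_000)[1] == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            f_statistics(InstrumentSet("e", "o", "f", []), 1000)

    def test_mean_f_matches_noncentral_chi2_expectation(self):
        # observed z ~ N(true_z, 1) so F = z^2 ~ chi2_1(ncp=true_z^2),
        # E[F] = true_z^2 + 1 = 65 for true_z = 8
        rng = np.random.default_rng(7)
        true_z = 8.0
        means = []
        for _ in range(500):
            z = rng.normal(true_z, 1.0, size=10)
            means.append(np.mean(z**2))
        grand = np.mean(means)
        # MC standard error of the grand mean ~ sqrt(2(1+2*64)/10/500) ~ 0.23
        assert grand == pytest.approx(65.0, abs=1.0)

    def test_aggregate_f_formula(self):
        s = InstrumentSet("e", "o", "f", [_inst("a", 0.001, 0.0), _inst("b", 0.002, 0.0)])
        _, _, agg = f_statistics(s, 10_000)
        r2 = 0.003
        assert agg == pytest.approx((10_000 - 2 - 1) / 2 * r2 / (1 - r2))


class TestBuildInstrumentSet:
    def test_variance_explained_populated_and_ivw_ready(self, causal_pair):
        exposure, outcome, ld, _ = causal_pair
        pair = harmonize(exposure, outcome)
        selected = clump(exposure, ld)
        inst = build_instrument_set(pair, selected, exposure, outcome)
        assert len(inst) > 0
        assert all(np.isfinite(i.r2_exposure) for i in inst.instruments)
        res, _ = ivw_mre(MRInput.from_instrument_set(inst))
        assert np.isfinite(res.estimate)
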