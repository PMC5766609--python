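"""Generative biopanning simulator: sampling fidelity, the additive
potency model, round dynamics and scheme-level enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from dopedlib import DopedDesign, GLUCAGON, mutation_class_fraction
from dopedlib.simulate import (ActivityModelParams, PanningParams,
                               PoolExtinctError, PoolState, Variant,
                               assign_potencies, panning_round, pool_summary,
                               run_scheme, sample_library, scheme_order,
                               simulate_readout)


def _design(positions=tuple(range(1, 10)), p_wt=0.45, a=18):
    return DopedDesign(parent=GLUCAGON, randomized_positions=positions,
                       p_wt=p_wt, n_alternatives=a)


def _toy_pool(potencies):
    """Pool of single-mutation variants with hand-set log10 EC50 pairs."""
    variants, counts = {}, {}
    for i, (log_a, log_b, count) in enumerate(potencies):
        key = ((i + 1, "A"),)
        variants[key] = Variant(mutations=key, log_ec50=(log_a, log_b))
        counts[key] = count
    return PoolState(round_index=0, variants=variants, counts=counts)


class TestSampleLibrary:
    def test_mutation_class_frequencies(self):
        design = _design()
        N = 100_000
        pool = sample_library(design, N=N, seed=1)
        k3 = sum(c for key, c in pool.counts.items() if len(key) == 3)
        p = mutation_class_fraction(design, 3)  # 11.60%
        se = math.sqrt(p * (1 - p) / N)
        assert abs(k3 / N - p) < 3 * se

    def test_undoped_library_all_parent(self):
        pool = sample_library(_design(p_wt=1.0), N=1000, seed=0)
        assert pool.counts == {(): 1000}

    def test_unique_variant_count_matches_occupancy(self):
        # m=2, a=2: 9 possible variants; per-variant occupancy expectation
        design = _design(positions=(1, 2), p_wt=0.45, a=2)
        N = 10
        reps = [sample_library(design, N=N, seed=s).n_unique
                for s in range(200)]
        expected = 0.0
        for k in range(3):
            D_k = math.comb(2, k) * 2 ** k
            q = mutation_class_fraction(design, k) / D_k
            expected += D_k * (1.0 - (1.0 - q) ** N)
        se = np.std(reps, ddof=1) / math.sqrt(len(reps))
        assert abs(np.mean(reps) - expected) < 3 * max(se, 0.05)

    def test_seed_determinism(self):
        a = sample_library(_design(), N=2000, seed=5)
        b = sample_library(_design(), N=2000, seed=5)
        assert a.counts == b.counts

    def test_mutations_confined_to_randomized_positions(self):
        design = _design(positions=(3, 7, 12))
        pool = sample_library(design, N=5000, seed=2)
        for key in pool.counts:
            assert {p for p, _ in key} <= {3, 7, 12}


class TestAssignPotencies:
    def test_wild_type_gets_anchor_potencies(self):
        pool = sample_library(_design(), N=1000, seed=3)
        params = ActivityModelParams(seed=9)
        pool = assign_potencies(pool, params)
        assert pool.variants[()].log_ec50 == pytest.approx(
            params.wt_log_ec50)

    def test_single_mutation_shifts_log_potency(self):
        params = ActivityModelParams(seed=9)
        key = ((5, "W"),)
        pool = PoolState(round_index=0,
                         variants={key: Variant(mutations=key),
                                   (): Variant(mutations=())},
                         counts={key: 1, (): 1})
        pool = assign_potencies(pool, params)
        wt = np.asarray(params.wt_log_ec50)
        eff = np.asarray(pool.variants[key].log_ec50) - wt
        assert np.all(np.isfinite(eff)) and np.any(eff != 0)

    def test_shared_mutation_contributes_identically(self):
        params = ActivityModelParams(seed=4)
        k1 = ((5, "W"),)
        k2 = ((5, "W"), (8, "K"))
        k3 = ((8, "K"),)
        pool = PoolState(
            round_index=0,
            variants={k: Variant(mutations=k) for k in (k1, k2, k3, ())},
            counts={k: 1 for k in (k1, k2, k3, ())})
        pool = assign_potencies(pool, params)
        wt = np.asarray(params.wt_log_ec50)
        e1 = np.asarray(pool.variants[k1].log_ec50) - wt
        e3 = np.asarray(pool.variants[k3].log_ec50) - wt
        e13 = np.asarray(pool.variants[k2].log_ec50) - wt
        assert e13 == pytest.approx(e1 + e3, abs=1e-12)

    def test_deterministic_across_pools_and_orders(self):
        params = ActivityModelParams(seed=11)
        p1 = assign_potencies(sample_library(_design(), 500, seed=0), params)
        p2 = assign_potencies(sample_library(_design(), 800, seed=99), params)
        common = set(p1.variants) & set(p2.variants)
        assert common
        for k in common:
            assert p1.variants[k].log_ec50 == p2.variants[k].log_ec50


class TestPanningRound:
    def test_idealized_round_keeps_only_binders(self):
        # near-step capture: strong binder vs hopeless non-binder
        pool = _toy_pool([(-2.0, 0.0, 500), (6.0, 0.0, 500)])
        params = PanningParams(depletion_efficiency=0.0, carryover=0.0,
                               wash_binder=1.0, wash_nonbinder=0.0,
                               capture_midpoint=0.0, capture_width=0.01,
                               amplification_size=1000)
        out = panning_round(pool, "GCGR", params, seed=0)
        assert set(out.counts) == {((1, "A"),)}  # only the 10 pM binder

    def test_two_variant_enrichment_matches_binomial_expectation(self):
        # capture probabilities 0.8 and 0.2 via the logistic: b = +-ln(4)*w
        w = 0.5
        b = math.log(4) * w
        pool = _toy_pool([(-b, 0.0, 100_000), (b, 0.0, 100_000)])
        params = PanningParams(depletion_efficiency=0.0, carryover=0.0,
                               wash_binder=1.0, wash_nonbinder=0.0,
                               capture_midpoint=0.0, capture_width=w,
                               amplification_size=200_000)
        out = panning_round(pool, "GCGR", params, seed=1)
        k1, k2 = ((1, "A"),), ((2, "A"),)
        ratio = out.counts[k1] / out.counts[k2]
        # survivors ~ Bin(1e5, .8) vs Bin(1e5, .2): ratio 4 with small SE
        se_ratio = 4 * math.sqrt(0.2 / (100_000 * 0.8) +
                                 0.8 / (100_000 * 0.2))
        assert abs(ratio - 4.0) < 3 * (se_ratio + 0.02)

    def test_full_carryover_preserves_composition_in_expectation(self):
        pool = _toy_pool([(-2.0, 0.0, 90_000), (6.0, 0.0, 10_000)])
        params = PanningParams(depletion_efficiency=0.0, carryover=1.0,
                               wash_binder=0.0, wash_nonbinder=0.0,
                               amplification_size=100_000)
        out = panning_round(pool, "GCGR", params, seed=2)
        f = out.counts[((1, "A"),)] / out.total
        assert abs(f - 0.9) < 3 * math.sqrt(0.9 * 0.1 / 100_000) + 0.001

    def test_extinction_signalled(self):
        pool = _toy_pool([(6.0, 6.0, 10)])
        params = PanningParams(depletion_efficiency=0.0, carryover=0.0,
                               wash_binder=1.0, wash_nonbinder=0.0,
                               capture_width=0.01)
        with pytest.raises(PoolExtinctError):
            panning_round(pool, "GCGR", params, seed=3)

    def test_missing_potencies_rejected(self):
        key = ((1, "A"),)
        pool = PoolState(round_index=0,
                         variants={key: Variant(mutations=key)},
                         counts={key: 5})
        with pytest.raises(ValueError):
            panning_round(pool, "GCGR", PanningParams(), seed=0)

    def test_amplification_conserves_target_size(self):
        pool = _toy_pool([(-2.0, 0.0, 1000), (0.0, 0.0, 1000)])
        params = PanningParams(amplification_size=4321)
        out = panning_round(pool, "GCGR", params, seed=4)
        assert out.total == 4321


class TestRunScheme:
    def test_scheme_orders(self):
        assert scheme_order(1, 4) == ["GCGR", "GLP1R", "GCGR", "GLP1R"]
        assert scheme_order(2, 4) == ["GLP1R", "GCGR", "GLP1R", "GCGR"]

    def test_zero_rounds_returns_initial_sample(self):
        design = _design(positions=(1, 2, 3))
        model = ActivityModelParams(seed=0)
        panning = PanningParams(rounds=0, amplification_size=1000)
        pools, summaries = run_scheme(design, model, panning, N=1000, seed=0)
        assert len(pools) == 1 and pools[0].round_index == 0
        assert pools[0].total == 1000

    def test_determinism(self):
        design = _design()
        model = ActivityModelParams(seed=1)
        panning = PanningParams(rounds=2, amplification_size=5000)
        a = run_scheme(design, model, panning, N=5000, seed=42)
        b = run_scheme(design, model, panning, N=5000, seed=42)
        assert a[0][-1].counts == b[0][-1].counts

    def test_alternating_selection_enriches_dual_potent(self):
        design = _design()
        model = ActivityModelParams(seed=0)
        panning = PanningParams(rounds=2, amplification_size=20_000)
        wins = 0
        for seed in range(10):
            pools, summaries = run_scheme(design, model, panning,
                                          scheme=1, N=20_000, seed=seed)
            if summaries[2]["dual_potent"] > summaries[0]["dual_potent"]:
                wins += 1
        assert wins >= 8

    def test_binder_only_burden_can_erode_activity(self):
        # when most mutations bind without activating, the activating
        # fraction declines over many rounds
        design = _design()
        model = ActivityModelParams(binder_only_fraction=0.8, seed=2)
        panning = PanningParams(rounds=4, amplification_size=20_000)
        pools, summaries = run_scheme(design, model, panning, scheme=1,
                                      N=20_000, seed=3)
        activating = [s["dual_potent"] + s["single_potent"]
                      for s in summaries]
        assert summaries[-1]["binder_only"] > summaries[0]["binder_only"]
        assert activating[-1] < max(activating)


class TestReadout:
    def test_binder_only_gives_no_signal(self):
        key = ((1, "A"),)
        pool = PoolState(
            round_index=0,
            variants={key: Variant(mutations=key, log_ec50=(-3.0, -3.0),
                                   binder_only=True)},
            counts={key: 10})
        sig = simulate_readout(pool, "GCGR", seed=0)
        assert sig[key] == 0.0

    def test_potent_variant_outsignals_weak(self):
        k1, k2 = ((1, "A"),), ((2, "A"),)
        pool = PoolState(
            round_index=0,
            variants={k1: Variant(mutations=k1, log_ec50=(-3.0, 0.0)),
                      k2: Variant(mutations=k2, log_ec50=(3.0, 0.0))},
            counts={k1: 1, k2: 1})
        sig = simulate_readout(pool, "GCGR", noise_sd=0.0, seed=0)
        assert sig[k1] > sig[k2]


class TestPoolSummary:
    def test_fractions_partition_pool(self):
        pool = sample_library(_design(), N=2000, seed=8)
        pool = assign_potencies(pool, ActivityModelParams(seed=8))
        s = pool_summary(pool)
        total = (s["dual_potent"] + s["single_potent"] + s["binder_only"]
                 + s["inert"])
        assert total == pytest.approx(1.0, abs=1e-9)
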