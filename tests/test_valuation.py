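"""Cost model: each operation against an independent oracle, plus invariants."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifemarket.exceptions import EnumerationCapError, LifemarketError
from lifemarket.records import BiomedicalRecord, Dataset, RecordTypeSpec, UserProfile, ValuationConfig
from lifemarket.valuation import (
    ValuationResult,
    attribute_payments,
    combination_cost,
    dataset_cost,
    group_cost,
    group_growth,
    marginal_cost,
    quality_aggregate,
    single_record_cost,
    time_value,
    user_cost,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def grid_time_value(records, config, valuation_time, step=1e-4, zooms=3):
    """Grid-search oracle for the max-min time value.

    Vectorized first-principles evaluation of min_m w_m on a uniform grid
    (step 1e-4 years), then zoomed 100x around the best grid point a few
    times so the reported optimum is accurate well below 1e-6.
    """
    specs = [config.spec_for(t) for t, _ in records]
    times = np.array([tm for _, tm in records])

    def envelope(grid):
        best = np.full(grid.shape, np.inf)
        for spec, tm in zip(specs, times):
            if math.isinf(spec.half_life):
                vals = np.ones_like(grid)
            else:
                u = (grid - tm - spec.kernel_offset) / spec.half_life
                vals = 2.0 ** (-np.abs(u))
            best = np.minimum(best, vals)
        return best

    lo, hi = float(times.min()), float(valuation_time)
    for _ in range(zooms):
        grid = np.arange(lo, hi + step, step)
        vals = envelope(grid)
        t_best = float(grid[int(vals.argmax())])
        lo, hi = max(lo, t_best - step), min(hi, t_best + step)
        step /= 100.0
    return float(envelope(np.arange(lo, hi + step, step)).max())


def brute_force_user_cost(user, records, config, valuation_time, lam=0.0):
    """Exhaustive subset enumeration computing every f_k from first principles."""
    total = 0.0
    for k in range(1, config.max_combination_order + 1):
        for subset in combinations(records, k):
            if k == 1:
                rec = subset[0]
                spec = config.type_registry[rec.type]
                u = 0.0 if math.isinf(spec.half_life) else (
                    (valuation_time - rec.time) / spec.half_life
                )
                tv = 1.0 if math.isinf(spec.half_life) else 2.0 ** (-abs(u))
                total += spec.base_value * user.base_value_modifier * rec.quality * tv
            else:
                psi = config.synergy_table.get(tuple(sorted(r.type for r in subset)), 0.0)
                if psi == 0.0:
                    continue
                if any(r.quality == 0 for r in subset):
                    continue
                v = 1.0 / sum(1.0 / r.quality for r in subset)
                tv = grid_time_value([(r.type, r.time) for r in subset], config,
                                     valuation_time)
                total += psi * user.base_value_modifier * v * tv
    scale = (1.0 + lam) if config.relationship_regularization else 1.0
    return total * scale


# ---------------------------------------------------------------------------
# time value
# ---------------------------------------------------------------------------

class TestTimeValue:
    def test_perfect_overlap_is_one(self, config):
        assert time_value([("blood_test", 30.0), ("blood_test", 30.0)], config, 30.0) == 1.0

    def test_two_half_lives_apart_is_half(self, config):
        # T = 1 yr records sampled 2 yrs apart: optimum at the midpoint, each 2^-1
        tv = time_value([("transcriptome", 30.0), ("transcriptome", 32.0)], config, 40.0)
        assert tv == 0.5

    def test_static_record_never_decays(self, config):
        for age in (0.0, 5.0, 90.0):
            assert time_value([("genome", 0.0)], config, age) == 1.0

    def test_single_record_decays_to_valuation_date(self, config):
        # cholesterol panel, half-life 5: exactly 1/2 five years after sampling
        assert time_value([("cholesterol_panel", 30.0)], config, 35.0) == pytest.approx(0.5)

    def test_future_record_rejected(self, config):
        with pytest.raises(ValueError, match="precedes"):
            time_value([("blood_test", 50.0)], config, 40.0)

    def test_all_static_combination_is_one(self, config):
        assert time_value([("genome", 1.0), ("genome", 70.0)], config, 80.0) == 1.0

    def test_matches_grid_oracle_on_random_pairs(self, config):
        rng = np.random.default_rng(42)
        types = ["blood_test", "transcriptome", "mri", "cholesterol_panel", "genome"]
        for _ in range(50):
            recs = [
                (types[int(rng.integers(0, len(types)))], float(rng.uniform(0, 50)))
                for _ in range(int(rng.integers(2, 4)))
            ]
            vt = max(t for _, t in recs) + float(rng.uniform(0, 10))
            got = time_value(recs, config, vt)
            want = grid_time_value(recs, config, vt)
            assert got == pytest.approx(want, abs=1e-6)
            assert 0.0 <= got <= 1.0

    def test_mixed_kernels_match_grid_oracle(self):
        cfg = ValuationConfig(
            type_registry={
                "rect": RecordTypeSpec("rect", 1.0, half_life=2.0, kernel="rectangular"),
                "exp": RecordTypeSpec("exp", 1.0, half_life=1.0),
            }
        )
        got = time_value([("rect", 10.0), ("exp", 13.0)], cfg, 20.0)
        want = grid_time_value_mixed(cfg, [("rect", 10.0), ("exp", 13.0)], 20.0)
        assert got == pytest.approx(want, abs=1e-6)

    def test_never_exceeds_any_single_kernel_peak(self, config):
        # the overlap value is bounded by the best common relevance achievable
        tv = time_value([("blood_test", 10.0), ("blood_test", 20.0)], config, 30.0)
        assert tv < 0.01  # 10 yrs apart at T = 0.5: essentially no overlap


def grid_time_value_mixed(config, records, vt, step=1e-4, zooms=3):
    from lifemarket.valuation import kernel_value

    def envelope(grid):
        best = np.inf * np.ones_like(grid)
        for (tk, tm) in records:
            spec = config.spec_for(tk)
            vals = np.array([kernel_value(spec, t, tm) for t in grid])
            best = np.minimum(best, vals)
        return best

    lo, hi = min(t for _, t in records), vt
    for _ in range(zooms):
        grid = np.arange(lo, hi + step, step)
        vals = envelope(grid)
        t_best = float(grid[int(vals.argmax())])
        lo, hi = max(lo, t_best - step), min(hi, t_best + step)
        step /= 100.0
    return float(envelope(np.arange(lo, hi + step, step)).max())


# ---------------------------------------------------------------------------
# quality aggregation
# ---------------------------------------------------------------------------

class TestQualityAggregate:
    def test_printed_examples(self, config):
        assert quality_aggregate([1.0, 1.0], config) == 0.5
        assert quality_aggregate([2.0, 2.0, 2.0], config) == pytest.approx(2.0 / 3.0)

    def test_any_zero_gives_zero(self, config):
        assert quality_aggregate([1.0, 0.0, 3.0], config) == 0.0

    def test_empty_rejected(self, config):
        with pytest.raises(ValueError):
            quality_aggregate([], config)

    @given(
        qs=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=6),
        bump=st.integers(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_argument(self, qs, bump):
        from lifemarket.synthetic import default_config

        cfg = default_config()
        idx = bump % len(qs)
        raised = list(qs)
        raised[idx] *= 2.0
        assert quality_aggregate(raised, cfg) >= quality_aggregate(qs, cfg)


# ---------------------------------------------------------------------------
# single / combination / user costs
# ---------------------------------------------------------------------------

class TestPerUserCosts:
    def test_zero_quality_record_is_free(self, config, user):
        rec = BiomedicalRecord("r", "u1", "genome", 10.0, 0.0)
        assert single_record_cost(rec, user, config, 20.0) == 0.0

    def test_fresh_unit_record_costs_base_value(self, plain_config, user):
        rec = BiomedicalRecord("r", "u1", "unit", 30.0, 1.0)
        assert single_record_cost(rec, user, plain_config, 30.0) == 1.0

    def test_cholesterol_half_value_after_half_life(self, config, user):
        rec = BiomedicalRecord("r", "u1", "cholesterol_panel", 30.0, 1.0)
        assert single_record_cost(rec, user, config, 35.0) == pytest.approx(0.5)

    def test_undeclared_pair_has_no_synergy(self, config, user):
        recs = [
            BiomedicalRecord("a", "u1", "mri", 30.0, 1.0),
            BiomedicalRecord("b", "u1", "blood_test", 30.0, 1.0),
        ]
        assert combination_cost(recs, user, config, 30.0) == 0.0

    def test_declared_pair_term_by_term(self, config, user):
        # synergy 2 x v2(1,1) = 1/2 x co-sampled time value 1
        recs = [
            BiomedicalRecord("a", "u1", "blood_test", 30.0, 1.0),
            BiomedicalRecord("b", "u1", "transcriptome", 30.0, 1.0),
        ]
        assert combination_cost(recs, user, config, 30.0) == pytest.approx(1.0)

    def test_zero_quality_member_kills_combination(self, config, user):
        recs = [
            BiomedicalRecord("a", "u1", "blood_test", 30.0, 0.0),
            BiomedicalRecord("b", "u1", "transcriptome", 30.0, 1.0),
        ]
        assert combination_cost(recs, user, config, 30.0) == 0.0

    def test_single_record_user_cost_reduces_to_single_cost(self, config, user):
        rec = BiomedicalRecord("r", "u1", "transcriptome", 40.0, 1.3)
        assert user_cost(user, [rec], config, 41.0) == pytest.approx(
            single_record_cost(rec, user, config, 41.0)
        )

    def test_twin_lambda_doubles_user_cost(self, config, user):
        # one enrolled monozygotic twin: lambda = 1, multiplier (1 + 1) = 2
        recs = [
            BiomedicalRecord("a", "u1", "blood_test", 30.0, 1.0),
            BiomedicalRecord("b", "u1", "transcriptome", 30.5, 0.7),
        ]
        base = user_cost(user, recs, config, 31.0, cohort_lambda=0.0)
        with_twin = user_cost(user, recs, config, 31.0, cohort_lambda=1.0)
        assert with_twin == pytest.approx(2.0 * base)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_enumeration(self, config, seed):
        rng = np.random.default_rng(seed)
        user = UserProfile(user_id="u", current_age=90.0)
        types = sorted(config.type_registry)
        recs = [
            BiomedicalRecord(
                f"r{i}", "u", types[int(rng.integers(0, len(types)))],
                float(rng.uniform(0, 60)),
                0.0 if rng.random() < 0.15 else float(rng.uniform(0.2, 2.0)),
            )
            for i in range(10)
        ]
        got = user_cost(user, recs, config, 65.0)
        want = brute_force_user_cost(user, recs, config, 65.0)
        assert got == pytest.approx(want, rel=1e-5)

    def test_cap_raises_instead_of_truncating(self, config, user):
        recs = [
            BiomedicalRecord(f"r{i}", "u1", "blood_test", 1.0, 1.0) for i in range(70)
        ]
        with pytest.raises(EnumerationCapError, match="enumeration cap"):
            user_cost(user, recs, config, 2.0)


# ---------------------------------------------------------------------------
# group terms
# ---------------------------------------------------------------------------

class TestGroupCost:
    def test_lone_user_has_no_group_bonus(self, config):
        assert group_cost("blood_test", [1.0], config) == 0.0

    def test_closed_form_k4(self, config):
        assert group_cost("blood_test", [1.0] * 4, config) == pytest.approx(4 * math.log(4))

    def test_zero_quality_users_do_not_count(self, config):
        assert group_cost("blood_test", [1.0, 0.0, 1.0], config) == pytest.approx(
            group_cost("blood_test", [1.0, 1.0], config)
        )

    @pytest.mark.parametrize("form", ["k_log_k", "k_pow_3_2"])
    def test_doubling_group_more_than_doubles_value(self, config, form):
        config.group_growth_form = form
        for k in range(2, 65):
            assert group_cost("mri", [1.0] * 2 * k, config) > 2 * group_cost(
                "mri", [1.0] * k, config
            )


# ---------------------------------------------------------------------------
# dataset level
# ---------------------------------------------------------------------------

class TestDatasetCost:
    def test_empty_dataset_is_free(self, config):
        res = dataset_cost(Dataset(), {}, config, 0.0)
        assert res.total_cost == 0.0 and res.per_user_terms == {}

    def test_two_users_same_type_term_by_term(self, config):
        users = {u: UserProfile(user_id=u, current_age=40.0) for u in ("u1", "u2")}
        ds = Dataset([
            BiomedicalRecord("a", "u1", "mri", 30.0, 1.0),
            BiomedicalRecord("b", "u2", "mri", 30.0, 0.5),
        ])
        res = dataset_cost(ds, users, config, 30.0)
        singles = 3.0 * 1.0 + 3.0 * 0.5
        group = 1.0 * 2 * math.log(2) * (1.0 + 0.5) / 2
        assert res.total_cost == pytest.approx(singles + group)
        kinds = {kind for _, kind, _ in res.per_term_breakdown}
        assert kinds == {"single", "group"}

    def test_all_zero_qualities_cost_nothing(self, config, random_dataset_factory):
        ds, users = random_dataset_factory(7)
        zeroed = Dataset(
            BiomedicalRecord(r.record_id, r.owner_id, r.type, r.time, 0.0) for r in ds
        )
        assert dataset_cost(zeroed, users, config, 80.0).total_cost == 0.0

    def test_breakdown_sums_to_total(self, config, random_dataset_factory):
        for seed in range(5):
            ds, users = random_dataset_factory(seed)
            res = dataset_cost(ds, users, config, 80.0)
            assert res.total_cost == pytest.approx(sum(res.per_user_terms.values()), abs=1e-9)
            assert all(v >= 0 for _, _, v in res.per_term_breakdown)

    def test_zero_quality_addition_never_changes_cost(self, config, random_dataset_factory):
        for seed in range(50):
            ds, users = random_dataset_factory(seed, n_users=3, max_records=2)
            before = dataset_cost(ds, users, config, 80.0).total_cost
            ds.add(BiomedicalRecord("extra", "u0", "transcriptome", 33.0, 0.0))
            after = dataset_cost(ds, users, config, 80.0).total_cost
            assert abs(after - before) < 1e-12

    def test_monotone_in_quality_and_base_value(self, config, random_dataset_factory):
        ds, users = random_dataset_factory(9, zero_quality_prob=0.0)
        base = dataset_cost(ds, users, config, 80.0).total_cost
        richer = Dataset(
            BiomedicalRecord(r.record_id, r.owner_id, r.type, r.time, r.quality * 1.5)
            for r in ds
        )
        assert dataset_cost(richer, users, config, 80.0).total_cost >= base
        for spec in config.type_registry.values():
            object.__setattr__(spec, "base_value", spec.base_value * 2)
        assert dataset_cost(ds, users, config, 80.0).total_cost >= base


class TestMarginalCost:
    def test_owned_superset_costs_nothing(self, config, random_dataset_factory):
        ds, users = random_dataset_factory(1)
        assert marginal_cost(ds, ds, users, config, 80.0) == pytest.approx(0.0, abs=1e-9)

    def test_empty_history_pays_full_price(self, config, random_dataset_factory):
        ds, users = random_dataset_factory(2)
        assert marginal_cost(ds, Dataset(), users, config, 80.0) == pytest.approx(
            dataset_cost(ds, users, config, 80.0).total_cost
        )

    def test_split_purchases_sum_to_full_price(self, config, random_dataset_factory):
        rng = np.random.default_rng(123)
        for seed in range(30):
            ds, users = random_dataset_factory(seed)
            ids = sorted(ds.record_ids)
            cut = int(rng.integers(0, len(ids) + 1))
            first = ds.subset(ids[:cut])
            second = ds.subset(ids[cut:])
            paid = marginal_cost(first, Dataset(), users, config, 80.0) + marginal_cost(
                second, first, users, config, 80.0
            )
            full = dataset_cost(ds, users, config, 80.0).total_cost
            assert paid == pytest.approx(full, abs=1e-9)

    def test_marginal_cost_is_nonnegative(self, config, random_dataset_factory):
        for seed in range(20):
            ds, users = random_dataset_factory(seed)
            ids = sorted(ds.record_ids)
            owned = ds.subset(ids[: len(ids) // 2])
            assert marginal_cost(ds, owned, users, config, 80.0) >= 0.0


# ---------------------------------------------------------------------------
# payment attribution
# ---------------------------------------------------------------------------

class TestAttributePayments:
    def _result(self, terms):
        res = ValuationResult(total_cost=sum(terms.values()), per_user_terms=dict(terms))
        return res

    def test_single_submitter_no_dv_gets_everything(self):
        payouts = attribute_payments(self._result({"u1": 5.0}), 10.0, 0.0)
        assert payouts == {"u1": 10.0}

    def test_three_to_one_split_with_dv(self):
        payouts = attribute_payments(
            self._result({"a": 3.0, "b": 1.0}), 100.0, 0.2, dv_account="dv"
        )
        assert payouts["dv"] == pytest.approx(20.0)
        assert payouts["a"] == pytest.approx(60.0)
        assert payouts["b"] == pytest.approx(20.0)

    def test_conservation_over_random_cases(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            terms = {f"u{i}": float(rng.uniform(0.01, 10)) for i in range(n)}
            amount = float(rng.uniform(0, 100))
            share = float(rng.uniform(0, 0.9))
            payouts = attribute_payments(self._result(terms), amount, share, "dv")
            assert sum(payouts.values()) == pytest.approx(amount, abs=1e-9)

    def test_zero_value_result_cannot_be_paid(self):
        with pytest.raises(LifemarketError):
            attribute_payments(self._result({}), 1.0, 0.0)
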