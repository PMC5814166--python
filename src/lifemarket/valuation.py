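"""The cost model for personal biomedical data.

The worth of a dataset is a sum of two families of terms:

* **per-user terms** — for each user, over every combination of k of their
  records (k = 1 .. ``max_combination_order``),

      f_k = Psi_k(types) * v_k(qualities) * tau(times, types)

  where Psi_1 is the record type's base value (scaled by the user's
  modifier), Psi_k for k >= 2 comes from the synergy table (zero when the
  type multiset is undeclared), v_k is a monotone quality aggregator that
  vanishes whenever any member quality is zero, and tau is the *time value*
  — a max–min construction over decay kernels that rewards records whose
  validity windows overlap;

* **group terms** — for each record type, with K distinct users holding a
  positive-quality record of that type, gamma(K) times the mean of their
  best qualities, where gamma grows superlinearly in K (C*K*ln K by
  default, or C*K^(3/2)).

If relationship regularization is enabled, a user's terms are scaled by
(1 + lambda), where lambda sums that user's coefficients of relationship
with the other enrolled users (see :mod:`lifemarket.pedigree`): data from
close relatives is worth more, and an enrolled monozygotic twin exactly
doubles a user's contribution.

Purchases are priced marginally: a customer who already owns part of a
dataset pays Cost(union) - Cost(owned), so no record is ever paid for
twice and any purchase order of the same records costs the same in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .exceptions import EnumerationCapError, LifemarketError
from .records import BiomedicalRecord, Dataset, RecordTypeSpec, UserProfile, ValuationConfig

__all__ = [
    "ValuationResult",
    "PurchaseLedgerEntry",
    "kernel_value",
    "time_value",
    "quality_aggregate",
    "single_record_cost",
    "combination_cost",
    "user_cost",
    "group_cost",
    "group_growth",
    "dataset_cost",
    "marginal_cost",
    "marginal_valuation",
    "attribute_payments",
]

@dataclass
class ValuationResult:
    """Priced dataset with the additive breakdown needed for payouts.

    ``per_user_terms`` attributes every LifePound of ``total_cost`` to a
    user: single and combination terms to the record owner, each group
    term split across the contributing users proportionally to their best
    quality for that type.
    """

    total_cost: float = 0.0
    per_user_terms: dict[str, float] = field(default_factory=dict)
    per_term_breakdown: list[tuple[frozenset[str], str, float]] = field(default_factory=list)
    valuation_time: float = 0.0

    def _add_user(self, user_id: str, value: float) -> None:
        self.per_user_terms[user_id] = self.per_user_terms.get(user_id, 0.0) + value


@dataclass
class PurchaseLedgerEntry:
    """One customer's purchase history: what they own and what they paid."""

    customer_id: str
    previously_bought: set[str] = field(default_factory=set)
    amount_paid: float = 0.0

    def __post_init__(self) -> None:
        if self.amount_paid < 0:
            raise ValueError("amount_paid must be >= 0")


# ---------------------------------------------------------------------------
# time value
# ---------------------------------------------------------------------------

def kernel_value(spec: RecordTypeSpec, t: float, sample_time: float) -> float:
    """Decay kernel of one record evaluated at reference time ``t``.

    The kernel argument is u = (t - sample_time - kernel_offset) / half_life.
    The default ``half_life_exp`` kernel is w(u) = 2^(-|u|), so the value is
    exactly 1/2 one half-life away from the sampling age; ``one_sided_exp``
    decays only forward in time and is zero before sampling;
    ``rectangular`` is a hard validity window of one half-life either side.
    Infinite half-life means the record never decays (w = 1).
    """
    if math.isinf(spec.half_life):
        return 1.0
    u = (t - sample_time - spec.kernel_offset) / spec.half_life
    if spec.kernel == "half_life_exp":
        return 2.0 ** (-abs(u))
    if spec.kernel == "one_sided_exp":
        return 2.0 ** (-u) if u >= 0 else 0.0
    if spec.kernel == "rectangular":
        return 1.0 if abs(u) <= 1.0 else 0.0
    raise LifemarketError(f"unknown kernel {spec.kernel!r}")


def _overlap_objective(specs: Sequence[RecordTypeSpec], times: Sequence[float]):
    def objective(t: float) -> float:
        return min(kernel_value(s, t, tm) for s, tm in zip(specs, times))

    return objective


def _optimum_candidates(
    specs: Sequence[RecordTypeSpec], times: Sequence[float], lo: float, hi: float
) -> list[float]:
    """Breakpoint candidates for the max-min overlap optimum.

    In log space every kernel is piecewise linear in t (slopes 0 or
    +-1/T_m, with hard cut-offs for the rectangular and one-sided
    shapes), so the lower envelope's maximum sits at a kernel breakpoint,
    an interval end, or a crossing of two legs.  Enumerating all of these
    and taking the best makes the search exact — no iterative optimizer.
    """
    cands = [lo, hi]
    finite: list[tuple[float, float]] = []  # (center, half_life)
    for spec, tm in zip(specs, times):
        if math.isinf(spec.half_life):
            continue
        center = tm + spec.kernel_offset
        cands.append(center)
        if spec.kernel == "rectangular":
            cands += [center - spec.half_life, center + spec.half_life]
        finite.append((center, spec.half_life))
    for (a, ta), (b, tb) in combinations(finite, 2):
        # opposite-sign legs meet at the half-life-weighted midpoint
        cands.append((a * tb + b * ta) / (ta + tb))
        if ta != tb:
            # same-sign legs of kernels with different decay rates
            cands.append((a * tb - b * ta) / (tb - ta))
    return [t for t in cands if lo <= t <= hi]


def time_value(
    records: Sequence[tuple[str, float]],
    config: ValuationConfig,
    valuation_time: float,
) -> float:
    """Time value in [0, 1] of a set of ``(type_key, sampling_age)`` pairs.

    For a single record this is the record's own kernel evaluated at the
    valuation date. For k >= 2 it is the max over a common reference age t
    in [min sampling age, valuation_time] of the minimum kernel value — the
    best simultaneous relevance the combination achieves, so co-sampled
    records score 1 and records far apart relative to their half-lives
    score near 0.
    """
    if not records:
        raise ValueError("time_value needs at least one record")
    specs = [config.spec_for(tk) for tk, _ in records]
    times = [tm for _, tm in records]
    if max(times) > valuation_time:
        raise ValueError(
            f"valuation_time {valuation_time} precedes a sampling age {max(times)}"
        )

    if len(records) == 1:
        return kernel_value(specs[0], valuation_time, times[0])

    if all(math.isinf(s.half_life) for s in specs):
        return 1.0

    lo, hi = min(times), valuation_time
    objective = _overlap_objective(specs, times)
    if lo == hi:
        return objective(lo)
    return max(objective(t) for t in _optimum_candidates(specs, times, lo, hi))


# ---------------------------------------------------------------------------
# quality aggregation
# ---------------------------------------------------------------------------

def quality_aggregate(qualities: Sequence[float], config: ValuationConfig) -> float:
    """Combined quality v_k of a record combination.

    Monotone nondecreasing in every argument and zero as soon as any
    member quality is zero, so worthless records never raise a cost.
    The default is the reciprocal sum (sum 1/q_m)^-1 — the harmonic mean
    divided by k — which reduces to q itself for a single record.
    """
    if len(qualities) == 0:
        raise ValueError("quality_aggregate needs at least one quality")
    if any(q < 0 for q in qualities):
        raise ValueError("qualities must be >= 0")
    if any(q == 0 for q in qualities):
        return 0.0
    if config.quality_aggregator == "reciprocal_sum":
        return 1.0 / sum(1.0 / q for q in qualities)
    if config.quality_aggregator == "min":
        return min(qualities)
    raise LifemarketError(f"unknown aggregator {config.quality_aggregator!r}")


# ---------------------------------------------------------------------------
# per-user terms
# ---------------------------------------------------------------------------

def single_record_cost(
    record: BiomedicalRecord,
    user: UserProfile,
    config: ValuationConfig,
    valuation_time: float,
) -> float:
    """f_1 = base_value(type) * user modifier * quality * time value."""
    spec = config.spec_for(record.type)
    if record.quality == 0:
        return 0.0
    tv = time_value([(record.type, record.time)], config, valuation_time)
    return spec.base_value * user.base_value_modifier * record.quality * tv


def combination_cost(
    records: Sequence[BiomedicalRecord],
    user: UserProfile,
    config: ValuationConfig,
    valuation_time: float,
) -> float:
    """f_k for k >= 2: synergy base value * v_k * time value.

    Zero when the type multiset carries no declared synergy; the synergy
    value is scaled by the owner's base-value modifier like any base value.
    """
    if len(records) < 2:
        raise ValueError("combination_cost needs k >= 2 records")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record in combination")
    if any(r.owner_id != user.user_id for r in records):
        raise ValueError("all records in a combination must belong to the same user")
    psi_k = config.synergy_value(r.type for r in records)
    if psi_k == 0.0:
        return 0.0
    v_k = quality_aggregate([r.quality for r in records], config)
    if v_k == 0.0:
        return 0.0
    tv = time_value([(r.type, r.time) for r in records], config, valuation_time)
    return psi_k * user.base_value_modifier * v_k * tv


def _synergy_subsets(
    records: Sequence[BiomedicalRecord], config: ValuationConfig
) -> Iterable[tuple[BiomedicalRecord, ...]]:
    """Record subsets whose type multiset is declared in the synergy table.

    Enumerated per synergy key rather than over all 2^n subsets, so a
    sparse table keeps user_cost cheap; an exhaustive oracle checks
    equivalence in the test suite.
    """
    by_type: dict[str, list[BiomedicalRecord]] = {}
    for r in records:
        by_type.setdefault(r.type, []).append(r)
    for key in config.synergy_table:
        if len(key) > config.max_combination_order:
            continue
        counts: dict[str, int] = {}
        for t in key:
            counts[t] = counts.get(t, 0) + 1
        if any(len(by_type.get(t, ())) < c for t, c in counts.items()):
            continue
        pools = [combinations(by_type[t], c) for t, c in sorted(counts.items())]

        def product(pool_idx: int, chosen: tuple) -> Iterable[tuple]:
            if pool_idx == len(pools):
                yield chosen
                return
            for combo in pools[pool_idx]:
                yield from product(pool_idx + 1, chosen + combo)

        pools = [list(p) for p in pools]
        yield from product(0, ())


def user_cost(
    user: UserProfile,
    records: Sequence[BiomedicalRecord],
    config: ValuationConfig,
    valuation_time: float,
    cohort_lambda: float = 0.0,
    result: ValuationResult | None = None,
) -> float:
    """Sum of f_k over all record combinations of one user.

    Exact enumeration over subsets of size 1..max_combination_order;
    record sets above ``config.enumeration_cap`` raise rather than
    silently truncating. With relationship regularization on, the sum is
    scaled by (1 + cohort_lambda). When ``result`` is given, each term is
    appended to its breakdown (values include the lambda scaling so the
    breakdown stays additive).
    """
    if any(r.owner_id != user.user_id for r in records):
        raise ValueError("user_cost received records not owned by the user")
    if len(records) > config.enumeration_cap:
        raise EnumerationCapError(
            f"user {user.user_id} has {len(records)} records, above the exact "
            f"enumeration cap {config.enumeration_cap}; raise config.enumeration_cap "
            "to value this user"
        )
    scale = (1.0 + cohort_lambda) if config.relationship_regularization else 1.0
    total = 0.0
    for rec in records:
        v = single_record_cost(rec, user, config, valuation_time) * scale
        total += v
        if result is not None and v != 0.0:
            result.per_term_breakdown.append((frozenset([rec.record_id]), "single", v))
            result._add_user(user.user_id, v)
    for subset in _synergy_subsets(records, config):
        v = combination_cost(subset, user, config, valuation_time) * scale
        total += v
        if result is not None and v != 0.0:
            result.per_term_breakdown.append(
                (frozenset(r.record_id for r in subset), "combination", v)
            )
            result._add_user(user.user_id, v)
    return total


# ---------------------------------------------------------------------------
# group terms
# ---------------------------------------------------------------------------

def group_growth(k: int, config: ValuationConfig) -> float:
    """Superlinear growth factor gamma(K) of the group term."""
    if k < 1:
        raise ValueError("group size must be >= 1")
    c = config.group_growth_c
    if config.group_growth_form == "k_log_k":
        return c * k * math.log(k)
    if config.group_growth_form == "k_pow_3_2":
        return c * k ** 1.5
    raise LifemarketError(f"unknown group growth form {config.group_growth_form!r}")


def group_cost(
    type_key: str, best_quality_per_user: Sequence[float], config: ValuationConfig
) -> float:
    """Group term for one record type: gamma(K) * mean of best qualities.

    One entry per distinct user (that user's best quality for the type).
    Zero-quality entries are dropped before K is counted, so worthless
    records never create or inflate a group.
    """
    if len(best_quality_per_user) == 0:
        raise ValueError("group_cost needs at least one quality")
    config.spec_for(type_key)  # fail fast on unregistered types
    qualities = [q for q in best_quality_per_user if q > 0]
    if not qualities:
        return 0.0
    k = len(qualities)
    return group_growth(k, config) * (sum(qualities) / k)


def _best_qualities(dataset: Dataset) -> dict[str, dict[str, float]]:
    """type -> user -> best positive quality of that user's records of the type."""
    best: dict[str, dict[str, float]] = {}
    for rec in dataset:
        if rec.quality <= 0:
            continue
        per_user = best.setdefault(rec.type, {})
        if rec.quality > per_user.get(rec.owner_id, 0.0):
            per_user[rec.owner_id] = rec.quality
    return best


# ---------------------------------------------------------------------------
# dataset level
# ---------------------------------------------------------------------------

def dataset_cost(
    dataset: Dataset,
    users: Mapping[str, UserProfile],
    config: ValuationConfig,
    valuation_time: float | None = None,
    lambdas: Mapping[str, float] | None = None,
) -> ValuationResult:
    """Full price of a dataset: per-user terms plus per-type group terms.

    ``lambdas`` maps user_id to the relationship regularization
    coefficient (sum of r with enrolled relatives); missing users default
    to 0. ``valuation_time`` defaults to the latest sampling age present.
    """
    if valuation_time is None:
        valuation_time = dataset.max_time()
    lambdas = lambdas or {}
    result = ValuationResult(valuation_time=valuation_time)
    for owner_id, recs in sorted(dataset.by_owner().items()):
        user = users[owner_id]
        user_cost(user, recs, config, valuation_time, lambdas.get(owner_id, 0.0), result)

    best = _best_qualities(dataset)
    for type_key in sorted(best):
        per_user = best[type_key]
        value = group_cost(type_key, list(per_user.values()), config)
        if value == 0.0:
            continue
        total_q = sum(per_user.values())
        members = frozenset(
            rec.record_id
            for rec in dataset
            if rec.type == type_key and rec.quality == per_user.get(rec.owner_id)
        )
        result.per_term_breakdown.append((members, "group", value))
        for uid, q in per_user.items():
            result._add_user(uid, value * q / total_q)

    result.total_cost = sum(result.per_user_terms.values())
    return result


def marginal_valuation(
    dataset: Dataset,
    already_bought: Dataset,
    users: Mapping[str, UserProfile],
    config: ValuationConfig,
    valuation_time: float | None = None,
    lambdas: Mapping[str, float] | None = None,
) -> ValuationResult:
    """Valuation of what is *new* in ``dataset`` given ``already_bought``.

    per_user_terms are the differences between the union's and the owned
    set's attributions, so payments reward only newly paid-for value.
    """
    union = dataset.union(already_bought)
    if valuation_time is None:
        valuation_time = union.max_time()
    full = dataset_cost(union, users, config, valuation_time, lambdas)
    owned = dataset_cost(already_bought, users, config, valuation_time, lambdas)
    out = ValuationResult(valuation_time=valuation_time)
    for uid, v in full.per_user_terms.items():
        delta = v - owned.per_user_terms.get(uid, 0.0)
        if delta > 1e-12:
            out.per_user_terms[uid] = delta
    out.total_cost = full.total_cost - owned.total_cost
    if out.total_cost < 0 and out.total_cost > -1e-9:
        out.total_cost = 0.0
    return out


def marginal_cost(
    dataset: Dataset,
    already_bought: Dataset,
    users: Mapping[str, UserProfile],
    config: ValuationConfig,
    valuation_time: float | None = None,
    lambdas: Mapping[str, float] | None = None,
) -> float:
    """Cost(dataset | owned) = Cost(dataset U owned) - Cost(owned), >= 0."""
    return marginal_valuation(
        dataset, already_bought, users, config, valuation_time, lambdas
    ).total_cost


# ---------------------------------------------------------------------------
# payment distribution
# ---------------------------------------------------------------------------

def attribute_payments(
    result: ValuationResult,
    amount_paid: float,
    dv_share: float,
    dv_account: str | None = None,
) -> dict[str, float]:
    """Split a payment among submitters (and optionally a data validator).

    The validator receives ``dv_share * amount_paid``; the remainder is
    split proportionally to ``result.per_user_terms``. Payouts sum to
    ``amount_paid`` exactly: the largest share absorbs the floating-point
    residual (ties broken by account id).
    """
    if not 0 <= dv_share < 1:
        raise ValueError("dv_share must be in [0, 1)")
    if amount_paid < 0:
        raise ValueError("amount_paid must be >= 0")
    if amount_paid == 0:
        return {}
    total = sum(result.per_user_terms.values())
    if total <= 0:
        raise LifemarketError("cannot attribute a positive payment to a zero-value result")
    if dv_share > 0 and dv_account is None:
        raise ValueError("dv_share > 0 requires a dv_account")

    payouts: dict[str, float] = {}
    dv_cut = dv_share * amount_paid
    pool = amount_paid - dv_cut
    shares = sorted(result.per_user_terms.items(), key=lambda kv: (-kv[1], kv[0]))
    largest = shares[0][0]
    for uid, term in shares[1:]:
        payouts[uid] = pool * term / total
    payouts[largest] = amount_paid - dv_cut - math.fsum(payouts.values())
    if dv_cut > 0:
        payouts[dv_account] = payouts.get(dv_account, 0.0) + dv_cut
    return payouts
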