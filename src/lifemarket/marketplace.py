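"""Discrete-event simulator of the token-based health-data marketplace.

Three workflows move LifePounds (the marketplace's unit of account) and
data through the system:

* **upload** — a user encrypts a record payload with a fresh symmetric
  key, splits the key into N Shamir shares held by key keepers (any K
  reconstruct, with the Byzantine-style admissibility bound
  K > round(N/3)), stores the ciphertext in mock cloud storage, and
  registers the upload on the ledger;

* **validation** — a data validator (DV) locks the valuation-model price
  of a batch of unvalidated records in an escrow contract, obtains the
  keys from the keepers, and returns a boolean verdict per record before
  a deadline.  The escrow pays submitters for valid records (the DV then
  earns a share of the records' future sales), refunds the DV for invalid
  ones, and defaults to all-valid on timeout;

* **purchase** — a customer pays the marginal price of a batch of listed
  records given their purchase history (re-buying is free), the payment
  splitting dv_share to the validators and the rest to submitters
  proportionally to their newly paid valuation terms.

Every state transition is a ledger transaction with explicit balance
deltas, so the chain audits itself: with minting disabled the total token
supply is invariant, and a (seed, config) pair replays to a bit-identical
chain.  "Encryption" is a keyed XOR-stream stand-in — the simulation's
claims concern protocol logic (thresholds, escrow, conservation, audit),
not cipher strength.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ThresholdError, WorkflowError
from .ledger import Chain, Transaction, append_block, sha256_hex
from .records import BiomedicalRecord, Dataset, UserProfile, ValuationConfig
from .valuation import attribute_payments, dataset_cost, marginal_valuation

__all__ = [
    "SHAMIR_PRIME",
    "ShamirScheme",
    "Share",
    "min_threshold",
    "split_secret",
    "reconstruct_secret",
    "encrypt_payload",
    "decrypt_payload",
    "Actor",
    "CatalogEntry",
    "EscrowContract",
    "MarketplaceState",
    "ScenarioConfig",
    "ScenarioReport",
    "submit_upload",
    "start_validation",
    "finish_validation",
    "purchase",
    "run_scenario",
]

# 2^61 - 1, a Mersenne prime: secrets are elements of GF(p)
SHAMIR_PRIME = 2305843009213693951


def min_threshold(n_keepers: int) -> int:
    """Smallest admissible K for N keepers: the least K with K > round(N/3)."""
    return round(n_keepers / 3) + 1


@dataclass(frozen=True)
class ShamirScheme:
    """(N, K) threshold sharing over GF(prime): any K of N shares decrypt."""

    n_keepers: int
    threshold: int
    prime: int = SHAMIR_PRIME

    def __post_init__(self) -> None:
        n, k = self.n_keepers, self.threshold
        if n < 1 or not 1 <= k <= n:
            raise ThresholdError(f"need 1 <= K <= N, got N={n}, K={k}")
        if k <= round(n / 3):
            raise ThresholdError(
                f"K={k} violates the Byzantine bound K > round(N/3) = {round(n / 3)} "
                f"for N={n}"
            )


@dataclass(frozen=True)
class Share:
    """One keeper's point (x, y) on the sharing polynomial, tagged by split."""

    x: int
    y: int
    split_id: str


def split_secret(secret: int, scheme: ShamirScheme, rng: np.random.Generator) -> list[Share]:
    """Shamir split: sample a degree-(K-1) polynomial with f(0) = secret.

    Shares are f(1)..f(N); the split id tags all shares from one split so
    accidental mixing across splits is detected at reconstruction.
    """
    p = scheme.prime
    if not 0 <= secret < p:
        raise ThresholdError(f"secret must be in [0, {p})")
    coeffs = [secret] + [int(rng.integers(0, p)) for _ in range(scheme.threshold - 1)]
    split_id = sha256_hex(b"split" + b"".join(c.to_bytes(32, "big") for c in coeffs))[:16]
    shares = []
    for x in range(1, scheme.n_keepers + 1):
        y = 0
        for c in reversed(coeffs):  # Horner
            y = (y * x + c) % p
        shares.append(Share(x=x, y=y, split_id=split_id))
    return shares


def reconstruct_secret(shares: Sequence[Share], scheme: ShamirScheme) -> int:
    """Lagrange interpolation at 0; refuses fewer than K shares or mixed splits."""
    if len(shares) < scheme.threshold:
        raise ThresholdError(
            f"{len(shares)} shares given, threshold is {scheme.threshold}"
        )
    if len({s.split_id for s in shares}) != 1:
        raise ThresholdError("shares come from different splits")
    if len({s.x for s in shares}) != len(shares):
        raise ThresholdError("duplicate share x coordinates")
    p = scheme.prime
    shares = shares[: scheme.threshold]
    secret = 0
    for i, si in enumerate(shares):
        num, den = 1, 1
        for j, sj in enumerate(shares):
            if i == j:
                continue
            num = num * (-sj.x) % p
            den = den * (si.x - sj.x) % p
        secret = (secret + si.y * num * pow(den, -1, p)) % p
    return secret


def _keystream(key: int, length: int) -> bytes:
    out = b""
    counter = 0
    while len(out) < length:
        out += hashlib.sha256(key.to_bytes(32, "big") + counter.to_bytes(8, "big")).digest()
        counter += 1
    return out[:length]


def encrypt_payload(payload: bytes, key: int) -> bytes:
    """Keyed reversible XOR-stream transform (cipher stand-in, not real crypto)."""
    ks = _keystream(key, len(payload))
    return bytes(a ^ b for a, b in zip(payload, ks))


decrypt_payload = encrypt_payload  # XOR stream is an involution


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

ROLES = ("user", "data_validator", "customer", "key_keeper", "auditor")


@dataclass
class Actor:
    actor_id: str
    role: str
    balance: float = 0.0
    online: bool = True  # keepers can be taken offline to model outages

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise WorkflowError(f"unknown role {self.role!r}")
        if self.balance < 0:
            raise WorkflowError("balances cannot be negative")


@dataclass
class CatalogEntry:
    """Off-chain catalog row for one uploaded record (metadata stays off-chain)."""

    record: BiomedicalRecord
    status: str = "unvalidated"  # unvalidated | in_validation | listed | invalid
    ciphertext: bytes = b""
    payload_hash: str = ""
    shares: dict[str, Share] = field(default_factory=dict)  # keeper id -> share
    validator_id: str | None = None


@dataclass
class EscrowContract:
    contract_id: str
    dv_id: str
    batch: tuple[str, ...]
    locked_amount: float
    deadline: int
    status: str = "open"  # open | settled_valid | settled_invalid | timed_out
    disbursed: float = 0.0
    refunded: float = 0.0
    decryptable: bool = True


class MarketplaceState:
    """All mutable simulator state plus its ledger."""

    def __init__(self, config: ValuationConfig,
                 lambdas: Mapping[str, float] | None = None) -> None:
        self.config = config
        self.scheme = ShamirScheme(
            n_keepers=config.marketplace.n_keepers,
            threshold=config.marketplace.threshold,
        )
        self.actors: dict[str, Actor] = {}
        self.users: dict[str, UserProfile] = {}
        self.lambdas: dict[str, float] = dict(lambdas or {})
        self.catalog: dict[str, CatalogEntry] = {}
        self.escrows: dict[str, EscrowContract] = {}
        self.purchase_history: dict[str, set[str]] = {}
        self.chain = Chain()
        self.time: int = 0
        self.events: list[dict] = []
        self._contract_seq = 0

    # -- actors -------------------------------------------------------------

    def register_actor(self, actor: Actor, profile: UserProfile | None = None) -> None:
        if actor.actor_id in self.actors:
            raise WorkflowError(f"actor {actor.actor_id!r} already registered")
        if actor.balance and self.chain.blocks:
            raise WorkflowError(
                "funded actors must be registered before the first block: their "
                "opening balance is part of the chain's genesis state"
            )
        self.actors[actor.actor_id] = actor
        if profile is not None:
            self.users[profile.user_id] = profile
        if actor.balance:
            self.chain.genesis_state[actor.actor_id] = actor.balance

    def keepers(self) -> list[Actor]:
        return [a for a in self.actors.values() if a.role == "key_keeper"]

    def total_supply(self) -> float:
        return sum(a.balance for a in self.actors.values())

    # -- bookkeeping ---------------------------------------------------------

    def _balances(self) -> dict[str, float]:
        # mirrors the ledger's replay rule exactly: zero balances are absent
        return {a.actor_id: a.balance for a in self.actors.values() if a.balance != 0}

    def _apply_deltas(self, deltas: Mapping[str, float]) -> None:
        for actor_id, delta in deltas.items():
            actor = self.actors[actor_id]
            new_balance = actor.balance + delta
            if new_balance < -1e-9:
                raise WorkflowError(f"balance of {actor_id!r} would go negative")
            actor.balance = new_balance

    def _commit(self, kind: str, signer: str, payload: dict,
                deltas: Mapping[str, float] | None = None) -> Transaction:
        deltas = {k: v for k, v in (deltas or {}).items() if v != 0}
        if deltas:
            self._apply_deltas(deltas)
        tx = Transaction(
            kind=kind, payload=payload, signer=signer,
            timestamp=self.time, balance_deltas=deltas,
        )
        append_block(self.chain, [tx], self._balances(), timestamp=self.time)
        return tx

    def _event(self, kind: str, **fields) -> None:
        self.events.append({"time": self.time, "event": kind, **fields})

    def listed_dataset(self, record_ids: Iterable[str]) -> Dataset:
        return Dataset(self.catalog[rid].record for rid in record_ids)


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

def submit_upload(
    state: MarketplaceState,
    user_id: str,
    record: BiomedicalRecord,
    payload: bytes,
    rng: np.random.Generator,
) -> Transaction:
    """Upload workflow: encrypt, share the key with keepers, register on chain.

    The chain payload carries only identifiers and digests (owner, type
    key, storage link hash) — never the record's sampling age or quality.
    """
    if user_id not in state.actors or state.actors[user_id].role != "user":
        raise WorkflowError(f"{user_id!r} is not a registered user")
    if record.record_id in state.catalog:
        raise WorkflowError(f"duplicate record_id {record.record_id!r}")
    state.config.spec_for(record.type)  # reject unregistered types up front

    key = int(rng.integers(0, SHAMIR_PRIME))
    shares = split_secret(key, state.scheme, rng)
    ciphertext = encrypt_payload(payload, key)
    entry = CatalogEntry(
        record=record,
        ciphertext=ciphertext,
        payload_hash=sha256_hex(payload),
        shares={k.actor_id: s for k, s in zip(state.keepers(), shares)},
    )
    state.catalog[record.record_id] = entry

    deltas: dict[str, float] = {}
    mp = state.config.marketplace
    if mp.mint_on_upload and mp.mint_amount > 0:
        deltas[user_id] = mp.mint_amount
        state._event("mint", account=user_id, amount=mp.mint_amount)
    tx = state._commit(
        "upload", user_id,
        payload={
            "record_id": record.record_id,
            "owner": user_id,
            "data_type": record.type,
            "storage_link": sha256_hex(ciphertext),
            "payload_hash": entry.payload_hash,
        },
        deltas=deltas,
    )
    state._event("upload", record_id=record.record_id, user=user_id)
    return tx


def _deliver_shares(state: MarketplaceState, record_id: str) -> list[Share]:
    entry = state.catalog[record_id]
    return [
        entry.shares[k.actor_id]
        for k in state.keepers()
        if k.online and k.actor_id in entry.shares
    ]


def start_validation(
    state: MarketplaceState, dv_id: str, batch: Sequence[str]
) -> EscrowContract | None:
    """DV workflow, steps 1-5: fund the escrow and collect key shares.

    The escrow locks the valuation-model price of the batch.  A DV that
    cannot afford the batch simply fails to start (no state change).  If
    keeper outages leave fewer than K shares for any record, decryption
    is blocked and the contract can only run to timeout.
    """
    dv = state.actors.get(dv_id)
    if dv is None or dv.role != "data_validator":
        raise WorkflowError(f"{dv_id!r} is not a data validator")
    for rid in batch:
        if rid not in state.catalog:
            raise WorkflowError(f"unknown record {rid!r}")
        if state.catalog[rid].status != "unvalidated":
            raise WorkflowError(f"record {rid!r} is not awaiting validation")

    ds = state.listed_dataset(batch)
    price = dataset_cost(ds, state.users, state.config,
                         lambdas=state.lambdas).total_cost
    if dv.balance < price:
        state._event("validation_unaffordable", dv=dv_id, price=price)
        return None

    state._contract_seq += 1
    contract = EscrowContract(
        contract_id=f"escrow-{state._contract_seq}",
        dv_id=dv_id,
        batch=tuple(batch),
        locked_amount=price,
        deadline=state.time + state.config.marketplace.validation_timeout,
    )
    decryptable = all(
        len(_deliver_shares(state, rid)) >= state.scheme.threshold for rid in batch
    )
    contract.decryptable = decryptable
    state.escrows[contract.contract_id] = contract
    for rid in batch:
        state.catalog[rid].status = "in_validation"
    state._commit(
        "validate", dv_id,
        payload={
            "contract_id": contract.contract_id,
            "phase": "open",
            "batch": sorted(batch),
            "locked": price,
            "deadline": contract.deadline,
        },
        deltas={dv_id: -price} if price else {},
    )
    state._event("escrow_open", contract=contract.contract_id, dv=dv_id,
                 locked=price, decryptable=decryptable)
    return contract


def finish_validation(
    state: MarketplaceState,
    contract: EscrowContract,
    verdicts: Sequence[bool] | None,
) -> dict[str, float]:
    """DV workflow, steps 7-8: settle the escrow on verdicts or timeout.

    ``verdicts=None`` means the deadline passed without a verdict; the
    contract then deems the whole batch valid.  The escrow portion of the
    valid records (their dataset cost) is distributed to submitters via
    the payment-attribution rule; the rest is refunded to the DV.  Valid
    records are listed with the DV as their revenue-share beneficiary.
    """
    if contract.status != "open":
        raise WorkflowError(f"contract {contract.contract_id} is not open")
    timed_out = verdicts is None
    if timed_out:
        verdicts = [True] * len(contract.batch)
    elif contract.decryptable is False:
        raise WorkflowError(
            f"contract {contract.contract_id}: fewer than K key shares were "
            "delivered; the DV cannot decrypt, only timeout can settle"
        )
    if len(verdicts) != len(contract.batch):
        raise WorkflowError(
            f"verdict vector length {len(verdicts)} != batch size {len(contract.batch)}"
        )

    valid_ids = [rid for rid, ok in zip(contract.batch, verdicts) if ok]
    payouts: dict[str, float] = {}
    if valid_ids:
        valid_ds = state.listed_dataset(valid_ids)
        valuation = dataset_cost(valid_ds, state.users, state.config,
                                 lambdas=state.lambdas)
        valid_amount = min(valuation.total_cost, contract.locked_amount)
        if valid_amount > 0:
            payouts = attribute_payments(valuation, valid_amount, dv_share=0.0)
    disbursed = sum(payouts.values())
    refund = contract.locked_amount - disbursed

    deltas = dict(payouts)
    if refund:
        deltas[contract.dv_id] = deltas.get(contract.dv_id, 0.0) + refund
    for rid, ok in zip(contract.batch, verdicts):
        entry = state.catalog[rid]
        if ok:
            entry.status = "listed"
            entry.validator_id = contract.dv_id
        else:
            entry.status = "invalid"

    contract.status = "timed_out" if timed_out else (
        "settled_valid" if all(verdicts) else "settled_invalid"
    )
    contract.disbursed = disbursed
    contract.refunded = refund
    state._commit(
        "validate", contract.dv_id,
        payload={
            "contract_id": contract.contract_id,
            "phase": "settle",
            "verdicts": [bool(v) for v in verdicts],
            "timed_out": timed_out,
        },
        deltas=deltas,
    )
    state._event("escrow_settle", contract=contract.contract_id,
                 status=contract.status, disbursed=disbursed, refunded=refund)
    return payouts


def purchase(
    state: MarketplaceState, customer_id: str, batch: Sequence[str]
) -> dict[str, float]:
    """Customer workflow: pay the marginal price, split it, release the keys.

    Atomic: an unaffordable batch changes nothing.  The price is marginal
    against the customer's purchase history, so an identical re-purchase
    is free; dv_share of the payment goes to the batch's validators
    (proportionally to the records each validated), the remainder to
    submitters by their newly paid valuation terms.
    """
    customer = state.actors.get(customer_id)
    if customer is None or customer.role != "customer":
        raise WorkflowError(f"{customer_id!r} is not a customer")
    for rid in batch:
        if rid not in state.catalog or state.catalog[rid].status != "listed":
            raise WorkflowError(f"record {rid!r} is not listed for sale")

    history = state.purchase_history.setdefault(customer_id, set())
    owned = state.listed_dataset(history)
    wanted = state.listed_dataset(batch)
    valuation = marginal_valuation(wanted, owned, state.users, state.config,
                                   lambdas=state.lambdas)
    price = valuation.total_cost
    if price < 1e-9 or not valuation.per_user_terms:
        price = 0.0
    if customer.balance < price:
        state._event("purchase_unaffordable", customer=customer_id, price=price)
        return {}

    deltas: dict[str, float] = {customer_id: -price}
    dv_share = state.config.marketplace.dv_share
    payouts: dict[str, float] = {}
    if price > 0:
        new_ids = set(batch) - history
        validator_weight: dict[str, int] = {}
        for rid in new_ids:
            vid = state.catalog[rid].validator_id
            validator_weight[vid] = validator_weight.get(vid, 0) + 1
        dv_pool = dv_share * price
        submitter_pool = price - dv_pool
        payouts = attribute_payments(valuation, submitter_pool, dv_share=0.0)
        total_w = sum(validator_weight.values())
        for vid, w in sorted(validator_weight.items()):
            payouts[vid] = payouts.get(vid, 0.0) + dv_pool * w / total_w
        for account, amount in payouts.items():
            deltas[account] = deltas.get(account, 0.0) + amount

    history.update(batch)
    released = all(
        len(_deliver_shares(state, rid)) >= state.scheme.threshold for rid in batch
    )
    state._commit(
        "purchase", customer_id,
        payload={
            "batch": sorted(batch),
            "price": price,
            "keys_released": released,
        },
        deltas=deltas,
    )
    state._event("purchase", customer=customer_id, price=price,
                 n_records=len(batch), keys_released=released)
    return payouts


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Shape of one simulated run; the seed fully determines the outcome."""

    n_users: int = 10
    n_validators: int = 2
    n_customers: int = 2
    records_per_user: int = 2
    invalid_fraction: float = 0.0
    timeout_fraction: float = 0.0
    validator_funds: float = 1000.0
    customer_funds: float = 1000.0
    purchase_rounds: int = 2
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.invalid_fraction <= 1:
            raise WorkflowError("invalid_fraction must be in [0, 1]")


@dataclass
class ScenarioReport:
    events: list[dict]
    balances: dict[str, float]
    chain: Chain
    initial_supply: float
    final_supply: float
    minted: float
    n_listed: int
    n_purchases: int


def run_scenario(
    scenario: ScenarioConfig,
    config: ValuationConfig,
    users: Mapping[str, UserProfile] | None = None,
    dataset: Dataset | None = None,
    lambdas: Mapping[str, float] | None = None,
) -> ScenarioReport:
    """Run upload -> validation (with injected invalids and timeouts) -> purchases.

    When ``users``/``dataset`` are not supplied, a simple synthetic
    population is drawn from the scenario seed via
    :func:`lifemarket.synthetic.gen_records`.
    """
    rng = np.random.default_rng(scenario.seed)
    state = MarketplaceState(config, lambdas=lambdas)

    if users is None or dataset is None:
        from .synthetic import GeneratorSpec, gen_records, gen_users

        spec = GeneratorSpec(n_users=scenario.n_users, seed=scenario.seed)
        users = gen_users(spec)
        dataset = gen_records(spec, users, config)

    for uid in sorted(users):
        state.register_actor(Actor(uid, "user"), users[uid])
    validators = [f"dv{i}" for i in range(scenario.n_validators)]
    for vid in validators:
        state.register_actor(Actor(vid, "data_validator", scenario.validator_funds))
    customers = [f"cust{i}" for i in range(scenario.n_customers)]
    for cid in customers:
        state.register_actor(Actor(cid, "customer", scenario.customer_funds))
    for i in range(config.marketplace.n_keepers):
        state.register_actor(Actor(f"keeper{i}", "key_keeper"))
    initial_supply = state.total_supply()

    # uploads
    for rec in sorted(dataset, key=lambda r: r.record_id):
        payload = f"payload:{rec.record_id}".encode()
        submit_upload(state, rec.owner_id, rec, payload, rng)
        state.time += 1

    # validation in batches, round-robin over DVs
    pending = sorted(state.catalog)
    minted = state.total_supply() - initial_supply
    batches = [
        pending[i: i + scenario.batch_size]
        for i in range(0, len(pending), scenario.batch_size)
    ]
    for b, batch in enumerate(batches):
        dv = validators[b % len(validators)]
        contract = start_validation(state, dv, batch)
        state.time += 1
        if contract is None:
            continue
        if rng.random() < scenario.timeout_fraction:
            state.time = contract.deadline + 1
            finish_validation(state, contract, None)
        else:
            verdicts = [rng.random() >= scenario.invalid_fraction for _ in batch]
            finish_validation(state, contract, verdicts)
        state.time += 1

    # purchases
    listed = sorted(rid for rid, e in state.catalog.items() if e.status == "listed")
    n_purchases = 0
    for round_i in range(scenario.purchase_rounds):
        for cid in customers:
            if not listed:
                break
            take = rng.choice(len(listed), size=min(scenario.batch_size, len(listed)),
                              replace=False)
            batch = [listed[i] for i in sorted(take)]
            if purchase(state, cid, batch):
                n_purchases += 1
            state.time += 1

    return ScenarioReport(
        events=state.events,
        balances={a.actor_id: a.balance for a in state.actors.values()},
        chain=state.chain,
        initial_supply=initial_supply,
        final_supply=state.total_supply(),
        minted=minted,
        n_listed=sum(1 for e in state.catalog.values() if e.status == "listed"),
        n_purchases=n_purchases,
    )
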