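"""A minimal permissioned ledger: hash-linked blocks and Merkle proofs.

Desk-scale rendering of the storage side of a blockchain marketplace:
transactions are canonically serialized and SHA-256 hashed; each block
commits to its transactions (Merkle root) and to the balance map after
applying them (sorted-leaf Merkle root); blocks are hash-linked so any
alteration of history invalidates every later block.  Sorted state leaves
give logarithmic proofs of both presence and absence of a key, verified
purely against a trusted root.  An append-only anchor log records state
digests externally so chain rollbacks are detectable later.

Consensus, networking and real signatures are out of scope: the simulator
is the single block producer and a "signature" is an (actor id, payload
digest) record, sufficient for the protocol-logic checks modelled here.

Serialization dialect: canonical JSON (sorted keys, compact separators,
UTF-8).  Merkle dialect: leaf hash = SHA-256(0x00 || leaf bytes), node
hash = SHA-256(0x01 || left || right); an odd node at the end of a level
is promoted unchanged to the next level.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .exceptions import LedgerError

__all__ = [
    "canonical_bytes",
    "sha256_hex",
    "EMPTY_ROOT",
    "ZERO_DIGEST",
    "MerkleTree",
    "MerkleProof",
    "Transaction",
    "Block",
    "Chain",
    "append_block",
    "verify_chain",
    "prove_inclusion",
    "prove_absence",
    "verify_proof",
    "state_root",
    "state_leaves",
    "anchor_digest",
    "verify_anchors",
    "export_chain",
    "import_chain",
]

TX_KINDS = ("upload", "validate", "purchase", "transfer", "mint")

ZERO_DIGEST = "0" * 64


def canonical_bytes(obj) -> bytes:
    """Canonical serialization: sorted-key compact JSON, UTF-8."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":")).encode("utf-8")


def sha256_hex(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _leaf_hash(leaf: bytes) -> str:
    return sha256_hex(b"\x00" + leaf)


def _node_hash(left: str, right: str) -> str:
    return sha256_hex(b"\x01" + bytes.fromhex(left) + bytes.fromhex(right))


EMPTY_ROOT = sha256_hex(b"\x02empty")


# ---------------------------------------------------------------------------
# Merkle tree
# ---------------------------------------------------------------------------

@dataclass
class MerkleProof:
    """Audit path binding one leaf (or an adjacent pair, for absence) to a root.

    ``path`` lists (sibling digest, side) pairs bottom-up, side being the
    sibling's position; ``leaf_index``/``n_leaves`` pin the leaf position so
    verification reconstructs exactly the builder's (promoting) tree shape.
    For absence proofs ``kind`` is "absence" and ``neighbor`` carries the
    second inclusion proof of the adjacent-leaf pair.
    """

    kind: str  # "inclusion" | "absence"
    leaf: bytes
    leaf_index: int
    n_leaves: int
    path: list[tuple[str, str]]
    root: str
    key: str | None = None
    neighbor: "MerkleProof | None" = None
    position: str = "inner"  # absence proofs: "before_first" | "after_last" | "between"


class MerkleTree:
    """Binary Merkle tree over an ordered list of leaf byte strings."""

    def __init__(self, leaves: Sequence[bytes]) -> None:
        self.leaves = list(leaves)
        self.levels: list[list[str]] = [[_leaf_hash(l) for l in self.leaves]]
        level = self.levels[0]
        while len(level) > 1:
            nxt = []
            for i in range(0, len(level) - 1, 2):
                nxt.append(_node_hash(level[i], level[i + 1]))
            if len(level) % 2 == 1:
                nxt.append(level[-1])  # promote the odd tail node
            self.levels.append(nxt)
            level = nxt

    @property
    def root(self) -> str:
        if not self.leaves:
            return EMPTY_ROOT
        return self.levels[-1][0]

    def prove(self, index: int) -> MerkleProof:
        if not 0 <= index < len(self.leaves):
            raise LedgerError(f"leaf index {index} out of range")
        path: list[tuple[str, str]] = []
        idx = index
        for level in self.levels[:-1]:
            if idx % 2 == 0:
                if idx + 1 < len(level):
                    path.append((level[idx + 1], "R"))
                # else: promoted node, no sibling at this level
            else:
                path.append((level[idx - 1], "L"))
            idx //= 2
        return MerkleProof(
            kind="inclusion",
            leaf=self.leaves[index],
            leaf_index=index,
            n_leaves=len(self.leaves),
            path=path,
            root=self.root,
        )


def _recompute_root(leaf: bytes, leaf_index: int, n_leaves: int,
                    path: Sequence[tuple[str, str]]) -> str | None:
    """Replay the builder's promotion rule; None on malformed paths."""
    if n_leaves <= 0 or not 0 <= leaf_index < n_leaves:
        return None
    digest = _leaf_hash(leaf)
    idx, size, step = leaf_index, n_leaves, 0
    while size > 1:
        if idx % 2 == 0 and idx + 1 == size:
            pass  # promoted: consumes no sibling
        else:
            if step >= len(path):
                return None
            sibling, side = path[step]
            expected_side = "R" if idx % 2 == 0 else "L"
            if side != expected_side:
                return None
            digest = _node_hash(digest, sibling) if side == "R" else _node_hash(sibling, digest)
            step += 1
        idx //= 2
        size = (size + 1) // 2
    if step != len(path):
        return None
    return digest


def verify_proof(proof: MerkleProof, root: str) -> bool:
    """Pure verification of an inclusion or absence proof against a trusted root."""
    if proof.kind == "inclusion":
        if proof.root != root:
            return False
        return _recompute_root(proof.leaf, proof.leaf_index, proof.n_leaves, proof.path) == root
    if proof.kind == "absence":
        return _verify_absence(proof, root)
    return False


# ---------------------------------------------------------------------------
# sorted-key state commitment with absence proofs
# ---------------------------------------------------------------------------

def state_leaves(state: Mapping[str, object]) -> tuple[list[str], list[bytes]]:
    keys = sorted(state)
    leaves = [canonical_bytes({"key": k, "value": state[k]}) for k in keys]
    return keys, leaves


def state_root(state: Mapping[str, object]) -> str:
    return MerkleTree(state_leaves(state)[1]).root


def _leaf_key(leaf: bytes) -> str:
    return json.loads(leaf.decode("utf-8"))["key"]


def prove_inclusion_state(state: Mapping[str, object], key: str) -> MerkleProof:
    """Inclusion proof for a key in the sorted-leaf state commitment."""
    keys, leaves = state_leaves(state)
    if key not in state:
        raise LedgerError(f"key {key!r} not present in state")
    proof = MerkleTree(leaves).prove(keys.index(key))
    proof.key = key
    return proof


def prove_absence(state: Mapping[str, object], key: str) -> MerkleProof:
    """Absence proof: the adjacent sorted leaves bracketing the missing key."""
    if key in state:
        raise LedgerError(f"key {key!r} is present; cannot prove absence")
    keys, leaves = state_leaves(state)
    tree = MerkleTree(leaves)
    if not keys:
        return MerkleProof(
            kind="absence", leaf=b"", leaf_index=0, n_leaves=0, path=[],
            root=tree.root, key=key, position="empty",
        )
    import bisect

    i = bisect.bisect_left(keys, key)
    if i == 0:
        proof = tree.prove(0)
        proof.kind, proof.key, proof.position = "absence", key, "before_first"
        return proof
    if i == len(keys):
        proof = tree.prove(len(keys) - 1)
        proof.kind, proof.key, proof.position = "absence", key, "after_last"
        return proof
    left = tree.prove(i - 1)
    right = tree.prove(i)
    left.kind, left.key, left.position = "absence", key, "between"
    left.neighbor = right
    return left


def _verify_absence(proof: MerkleProof, root: str) -> bool:
    if proof.key is None or proof.root != root:
        return False
    if proof.position == "empty":
        return root == EMPTY_ROOT and proof.n_leaves == 0
    if _recompute_root(proof.leaf, proof.leaf_index, proof.n_leaves, proof.path) != root:
        return False
    try:
        leaf_key = _leaf_key(proof.leaf)
    except (ValueError, KeyError):
        return False
    if proof.position == "before_first":
        return proof.leaf_index == 0 and proof.key < leaf_key
    if proof.position == "after_last":
        return proof.leaf_index == proof.n_leaves - 1 and proof.key > leaf_key
    if proof.position == "between":
        nb = proof.neighbor
        if nb is None or nb.root != root or nb.n_leaves != proof.n_leaves:
            return False
        if nb.leaf_index != proof.leaf_index + 1:
            return False
        if _recompute_root(nb.leaf, nb.leaf_index, nb.n_leaves, nb.path) != root:
            return False
        try:
            right_key = _leaf_key(nb.leaf)
        except (ValueError, KeyError):
            return False
        return leaf_key < proof.key < right_key
    return False


# ---------------------------------------------------------------------------
# transactions, blocks, chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transaction:
    """One ledger entry; ``tx_id`` is the hash of the canonical body.

    ``payload`` must contain only identifiers, digests and public
    parameters — never sensitive record metadata.  ``balance_deltas``
    makes the state transition explicit so any auditor can replay the
    chain and recompute every state root.
    """

    kind: str
    payload: dict
    signer: str
    timestamp: int
    balance_deltas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TX_KINDS:
            raise LedgerError(f"unknown transaction kind {self.kind!r}")

    def body(self) -> dict:
        return {
            "kind": self.kind,
            "payload": self.payload,
            "signer": self.signer,
            "timestamp": self.timestamp,
            "balance_deltas": self.balance_deltas,
        }

    @property
    def tx_id(self) -> str:
        return sha256_hex(canonical_bytes(self.body()))

    @property
    def signature(self) -> tuple[str, str]:
        """Signature stand-in: (signer id, digest of the signed body)."""
        return (self.signer, self.tx_id)


@dataclass(frozen=True)
class Block:
    height: int
    prev_hash: str
    tx_root: str
    state_root: str
    timestamp: int
    transactions: tuple[Transaction, ...] = ()

    def header(self) -> dict:
        return {
            "height": self.height,
            "prev_hash": self.prev_hash,
            "tx_root": self.tx_root,
            "state_root": self.state_root,
            "timestamp": self.timestamp,
        }

    @property
    def block_hash(self) -> str:
        return sha256_hex(canonical_bytes(self.header()))


def _tx_tree(transactions: Sequence[Transaction]) -> MerkleTree:
    return MerkleTree([canonical_bytes(tx.body()) for tx in transactions])


class Chain:
    """Append-only block list rooted at an implicit zero-digest genesis parent."""

    def __init__(self, genesis_state: Mapping[str, float] | None = None) -> None:
        self.blocks: list[Block] = []
        self.genesis_state: dict[str, float] = dict(genesis_state or {})

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def tip_hash(self) -> str:
        return self.blocks[-1].block_hash if self.blocks else ZERO_DIGEST


def append_block(
    chain: Chain,
    transactions: Sequence[Transaction],
    state_after: Mapping[str, float],
    timestamp: int,
) -> Block:
    """Commit a batch of transactions and the resulting state as one block.

    The batch is atomic: any malformed transaction rejects the whole call
    and leaves the chain unchanged.
    """
    txs = tuple(transactions)
    for tx in txs:
        if not isinstance(tx, Transaction):
            raise LedgerError("batch contains a non-transaction entry")
    block = Block(
        height=len(chain.blocks),
        prev_hash=chain.tip_hash,
        tx_root=_tx_tree(txs).root,
        state_root=state_root(state_after),
        timestamp=timestamp,
        transactions=txs,
    )
    chain.blocks.append(block)
    return block


def _apply_deltas(state: dict[str, float], tx: Transaction) -> None:
    for account, delta in tx.balance_deltas.items():
        state[account] = state.get(account, 0.0) + delta
        if state[account] == 0:
            del state[account]  # committed states omit exactly-zero balances


def verify_chain(
    chain: Chain,
    replay: Callable[[dict[str, float], Transaction], None] = _apply_deltas,
) -> int | None:
    """Audit the whole chain; return None if sound, else the first bad height.

    Checks hash links and heights, recomputes every tx root from the
    stored transactions, and replays all balance deltas from the genesis
    state to recompute every state root.
    """
    prev = ZERO_DIGEST
    state = dict(chain.genesis_state)
    for expected_height, block in enumerate(chain.blocks):
        if block.height != expected_height or block.prev_hash != prev:
            return expected_height
        if _tx_tree(block.transactions).root != block.tx_root:
            return expected_height
        for tx in block.transactions:
            replay(state, tx)
        if state_root(state) != block.state_root:
            return expected_height
        prev = block.block_hash
    return None


def prove_inclusion(block: Block, tx_id: str) -> MerkleProof:
    """Merkle proof that a transaction is committed in a finalized block."""
    for i, tx in enumerate(block.transactions):
        if tx.tx_id == tx_id:
            proof = _tx_tree(block.transactions).prove(i)
            proof.key = tx_id
            return proof
    raise LedgerError(f"transaction {tx_id!r} not in block {block.height}")


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def anchor_digest(chain: Chain, anchor_log: list[dict] | None = None,
                  path: str | Path | None = None) -> dict:
    """Record the tip's commitments in an external append-only anchor log.

    The anchor pins height, block hash and state root; replaying the log
    against a chain later exposes rollbacks and rewrites even though the
    log holds no chain data itself. A digest stub for an external
    timestamping service — no network activity.
    """
    if not chain.blocks:
        raise LedgerError("cannot anchor an empty chain")
    tip = chain.blocks[-1]
    record = {
        "height": tip.height,
        "block_hash": tip.block_hash,
        "state_root": tip.state_root,
    }
    if anchor_log is not None:
        anchor_log.append(record)
    if path is not None:
        with open(path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    return record


def verify_anchors(chain: Chain, anchor_log: Iterable[dict]) -> bool:
    """Check every anchored height still matches the chain (detects rollback)."""
    for record in anchor_log:
        h = record["height"]
        if h >= len(chain.blocks):
            return False  # chain tip rolled back below an anchored height
        block = chain.blocks[h]
        if block.block_hash != record["block_hash"]:
            return False
        if block.state_root != record["state_root"]:
            return False
    return True


# ---------------------------------------------------------------------------
# JSON Lines export/import
# ---------------------------------------------------------------------------

def export_chain(chain: Chain, path: str | Path) -> None:
    """One JSON object per line: genesis state first, then each block."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"genesis_state": chain.genesis_state}, sort_keys=True) + "\n")
        for block in chain.blocks:
            fh.write(json.dumps(
                {
                    "header": block.header(),
                    "transactions": [tx.body() for tx in block.transactions],
                },
                sort_keys=True,
            ) + "\n")


def import_chain(path: str | Path) -> Chain:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    if not lines or "genesis_state" not in lines[0]:
        raise LedgerError(f"{path}: missing genesis line")
    chain = Chain(genesis_state=lines[0]["genesis_state"])
    for entry in lines[1:]:
        header = entry["header"]
        txs = tuple(
            Transaction(
                kind=b["kind"], payload=b["payload"], signer=b["signer"],
                timestamp=b["timestamp"], balance_deltas=b["balance_deltas"],
            )
            for b in entry["transactions"]
        )
        chain.blocks.append(
            Block(
                height=header["height"], prev_hash=header["prev_hash"],
                tx_root=header["tx_root"], state_root=header["state_root"],
                timestamp=header["timestamp"], transactions=txs,
            )
        )
    return chain
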