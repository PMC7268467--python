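"""Minimal hash-linked, single-sealer ledger with gas-metered contract
storage.

The ledger models the parts of a permissioned Ethereum-style chain that
matter for storage/query semantics and nothing else: transactions are batched
into blocks by a single deterministic sealer (proof of authority with one
authority), each block commits to the previous block's hash, and contract
state lives in flat key-value mappings whose every read and write is charged
to a :class:`GasMeter`.

Storage semantics follow contract-storage conventions:

* reads of absent keys return the zero value and are still charged one SLOAD;
* a write is classified SSTORE_NEW iff the slot previously held the zero
  value, otherwise SSTORE_UPDATE;
* dynamic arrays occupy a length slot plus one slot per element, so reading
  an array of length L costs 1+L SLOADs and appending costs one SLOAD (the
  length) plus two SSTOREs (new element, length update).

Consensus, networking, transaction pools and fee markets are out of scope;
query calls are metered but not recorded as transactions because reads do not
change state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Optional

# --------------------------------------------------------------------------
# Digests.  Keccak-256 is used when a provider is importable (Ethereum
# fidelity); otherwise SHA-256, which satisfies the same tamper-evidence
# contract.  The algorithm in force is recorded in the genesis block.

def _load_digests() -> dict[str, Callable[[bytes], str]]:
    digests: dict[str, Callable[[bytes], str]] = {
        "sha256": lambda data: hashlib.sha256(data).hexdigest()
    }
    try:  # pragma: no cover - provider not present in the default stack
        from Crypto.Hash import keccak

        digests["keccak256"] = lambda data: keccak.new(
            data=data, digest_bits=256
        ).hexdigest()
    except ImportError:
        pass
    return digests


DIGESTS = _load_digests()
DEFAULT_DIGEST = "keccak256" if "keccak256" in DIGESTS else "sha256"
ZERO_HASH = "0" * 64


def _canonical(obj: Any) -> bytes:
    return json.dumps(obj, sort_keys=True, separators=(",", ":")).encode("utf-8")


# --------------------------------------------------------------------------
# Gas accounting.

@dataclass(frozen=True)
class GasSchedule:
    """Gas charged per storage operation (configurable; Ethereum-fee-schedule
    defaults).  All scaling properties of the package hold for any positive
    constants."""

    sload: int = 200
    sstore_new: int = 20000
    sstore_update: int = 5000

    def __post_init__(self):
        if min(self.sload, self.sstore_new, self.sstore_update) <= 0:
            raise ValueError("gas costs must be positive")


@dataclass(frozen=True)
class GasUsage:
    """Immutable snapshot / difference of gas-meter counters."""

    sload_count: int = 0
    sstore_new_count: int = 0
    sstore_update_count: int = 0
    total_gas: int = 0

    def __sub__(self, other: "GasUsage") -> "GasUsage":
        return GasUsage(
            self.sload_count - other.sload_count,
            self.sstore_new_count - other.sstore_new_count,
            self.sstore_update_count - other.sstore_update_count,
            self.total_gas - other.total_gas,
        )

    def __add__(self, other: "GasUsage") -> "GasUsage":
        return GasUsage(
            self.sload_count + other.sload_count,
            self.sstore_new_count + other.sstore_new_count,
            self.sstore_update_count + other.sstore_update_count,
            self.total_gas + other.total_gas,
        )


class GasMeter:
    """Counts charged storage reads/writes; total gas derives from the
    schedule.  Counters never decrease."""

    def __init__(self, schedule: GasSchedule | None = None):
        self.schedule = schedule or GasSchedule()
        self.sload_count = 0
        self.sstore_new_count = 0
        self.sstore_update_count = 0

    @property
    def total_gas(self) -> int:
        s = self.schedule
        return (
            s.sload * self.sload_count
            + s.sstore_new * self.sstore_new_count
            + s.sstore_update * self.sstore_update_count
        )

    def charge_sload(self) -> None:
        self.sload_count += 1

    def charge_sstore(self, is_new: bool) -> None:
        if is_new:
            self.sstore_new_count += 1
        else:
            self.sstore_update_count += 1

    def snapshot(self) -> GasUsage:
        return GasUsage(
            self.sload_count,
            self.sstore_new_count,
            self.sstore_update_count,
            self.total_gas,
        )

    def since(self, before: GasUsage) -> GasUsage:
        return self.snapshot() - before


# --------------------------------------------------------------------------
# Contract storage.

def _is_zero(value: Any) -> bool:
    return value == 0 or value == "" or (isinstance(value, bytes) and not value.strip(b"\x00"))


class ContractStorage:
    """Flat key-value persistence for one contract, routed through a meter.

    Slots are addressed by (mapping name, key).  Absent slots read as the
    caller-supplied zero value (0 by default) and the read is still charged.
    """

    def __init__(self, meter: GasMeter | None = None):
        self.meter = meter or GasMeter()
        self._slots: dict[tuple, Any] = {}

    # -- scalar slots -------------------------------------------------------
    def load(self, mapping: str, key: Any, zero: Any = 0) -> Any:
        self.meter.charge_sload()
        return self._slots.get((mapping, key), zero)

    def store(self, mapping: str, key: Any, value: Any) -> None:
        slot = (mapping, key)
        prev = self._slots.get(slot, 0)
        self.meter.charge_sstore(is_new=_is_zero(prev))
        self._slots[slot] = value

    # -- dynamic arrays (length slot + element slots) -----------------------
    def array_length(self, name: str, key: Any) -> int:
        return self.load((name, "len"), key)

    def array_append(self, name: str, key: Any, value: Any) -> None:
        n = self.array_length(name, key)
        self.store((name, "elem"), (key, n), value)
        self.store((name, "len"), key, n + 1)

    def array_read(self, name: str, key: Any) -> list:
        n = self.array_length(name, key)
        return [self.load((name, "elem"), (key, i)) for i in range(n)]

    # -- unmetered inspection (tests/diagnostics only) ----------------------
    def peek(self, mapping: str, key: Any, zero: Any = 0) -> Any:
        return self._slots.get((mapping, key), zero)

    @property
    def slot_count(self) -> int:
        """Number of occupied (non-zero) storage slots."""
        return sum(1 for v in self._slots.values() if not _is_zero(v))

    def fingerprint(self) -> int:
        """Order-independent hash of the full slot contents (used to assert
        that queries are read-only)."""
        digest = hashlib.sha256()
        for slot in sorted(map(repr, self._slots.items())):
            digest.update(slot.encode())
        return int.from_bytes(digest.digest()[:8], "big")


# --------------------------------------------------------------------------
# Transactions and blocks.

@dataclass(frozen=True)
class Transaction:
    """One contract call recorded on-chain (an insert, in practice)."""

    tx_index: int
    submitter: str
    payload: str
    gas_used: int

    def to_dict(self) -> dict:
        return {
            "tx_index": self.tx_index,
            "submitter": self.submitter,
            "payload": self.payload,
            "gas_used": self.gas_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Transaction":
        return cls(d["tx_index"], d["submitter"], d["payload"], d["gas_used"])


@dataclass
class Block:
    """Hash-linked batch of transactions.

    Deliberately a plain mutable record: tamper-evidence comes from
    :meth:`Ledger.verify_chain` recomputing every digest, not from Python
    immutability.
    """

    block_number: int
    timestamp: int
    prev_hash: str
    payload_hash: str
    block_hash: str
    transactions: tuple[Transaction, ...]

    def to_dict(self) -> dict:
        return {
            "block_number": self.block_number,
            "timestamp": self.timestamp,
            "prev_hash": self.prev_hash,
            "payload_hash": self.payload_hash,
            "block_hash": self.block_hash,
            "transactions": [t.to_dict() for t in self.transactions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Block":
        return cls(
            block_number=d["block_number"],
            timestamp=d["timestamp"],
            prev_hash=d["prev_hash"],
            payload_hash=d["payload_hash"],
            block_hash=d["block_hash"],
            transactions=tuple(Transaction.from_dict(t) for t in d["transactions"]),
        )


@dataclass(frozen=True)
class VerificationReport:
    valid: bool
    first_invalid_block: Optional[int] = None


LEDGER_FORMAT = "pgxchain-ledger"
LEDGER_VERSION = 1


class Ledger:
    """Append-only chain of blocks sealed by a single deterministic authority.

    The genesis block records the digest algorithm in force (as a pseudo
    transaction) so an imported ledger can be re-verified with the right
    hash.  Timestamps come from an injectable ``clock``; the default is a
    constant, making identical transaction sequences produce bit-identical
    ledgers.
    """

    def __init__(
        self,
        digest: str | None = None,
        clock: Callable[[], int] | None = None,
        _blocks: list[Block] | None = None,
    ):
        self.digest_name = digest or DEFAULT_DIGEST
        if self.digest_name not in DIGESTS:
            raise ValueError(f"unknown digest {self.digest_name!r}")
        self._digest = DIGESTS[self.digest_name]
        self.clock = clock or (lambda: 0)
        if _blocks is not None:
            self.blocks = _blocks
        else:
            self.blocks = [self._make_genesis()]

    # -- hashing ------------------------------------------------------------
    def _payload_hash(self, transactions: Iterable[Transaction]) -> str:
        return self._digest(_canonical([t.to_dict() for t in transactions]))

    def _block_hash(
        self, block_number: int, timestamp: int, prev_hash: str, payload_hash: str
    ) -> str:
        return self._digest(
            _canonical(
                {
                    "block_number": block_number,
                    "timestamp": timestamp,
                    "prev_hash": prev_hash,
                    "payload_hash": payload_hash,
                }
            )
        )

    def _make_genesis(self) -> Block:
        genesis_tx = Transaction(
            tx_index=0,
            submitter="genesis",
            payload=json.dumps({"digest": self.digest_name}, sort_keys=True),
            gas_used=0,
        )
        return self._seal(0, ZERO_HASH, (genesis_tx,))

    def _seal(
        self, number: int, prev_hash: str, transactions: tuple[Transaction, ...]
    ) -> Block:
        timestamp = self.clock()
        payload_hash = self._payload_hash(transactions)
        return Block(
            block_number=number,
            timestamp=timestamp,
            prev_hash=prev_hash,
            payload_hash=payload_hash,
            block_hash=self._block_hash(number, timestamp, prev_hash, payload_hash),
            transactions=transactions,
        )

    # -- public API ---------------------------------------------------------
    @property
    def head(self) -> Block:
        return self.blocks[-1]

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def next_tx_index(self) -> int:
        return 1 + max(
            (t.tx_index for b in self.blocks for t in b.transactions), default=-1
        )

    def append_block(self, transactions: Iterable[Transaction]) -> Block:
        """Seal *transactions* into a new block linked to the current head."""
        txs = tuple(transactions)
        if not txs:
            raise ValueError("cannot seal an empty block")
        block = self._seal(len(self.blocks), self.head.block_hash, txs)
        self.blocks.append(block)
        return block

    def verify_chain(self) -> VerificationReport:
        """Recompute every digest and linkage; report the lowest inconsistent
        block if any.  Corruption is a report, never an exception."""
        for i, block in enumerate(self.blocks):
            expected_prev = ZERO_HASH if i == 0 else self.blocks[i - 1].block_hash
            if (
                block.block_number != i
                or block.prev_hash != expected_prev
                or block.payload_hash != self._payload_hash(block.transactions)
                or block.block_hash
                != self._block_hash(
                    block.block_number,
                    block.timestamp,
                    block.prev_hash,
                    block.payload_hash,
                )
            ):
                return VerificationReport(valid=False, first_invalid_block=i)
        return VerificationReport(valid=True)

    def iter_transactions(self) -> Iterable[Transaction]:
        """All non-genesis transactions in chain order."""
        for block in self.blocks[1:]:
            yield from block.transactions

    # -- export / import ----------------------------------------------------
    def export(self, path) -> None:
        """Line-delimited canonical block records; header names the digest."""
        with open(path, "w", encoding="utf-8") as fh:
            header = {
                "format": LEDGER_FORMAT,
                "version": LEDGER_VERSION,
                "digest": self.digest_name,
            }
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for block in self.blocks:
                fh.write(json.dumps(block.to_dict(), sort_keys=True) + "\n")

    @classmethod
    def load(cls, path, clock: Callable[[], int] | None = None) -> "Ledger":
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            if header.get("format") != LEDGER_FORMAT:
                raise ValueError(f"not a {LEDGER_FORMAT} file: {path}")
            blocks = [Block.from_dict(json.loads(line)) for line in fh if line.strip()]
        if not blocks:
            raise ValueError("ledger file contains no blocks")
        return cls(digest=header["digest"], clock=clock, _blocks=blocks)

    def copy(self) -> "Ledger":
        """Deep-enough copy for tamper experiments (blocks are duplicated)."""
        blocks = [replace(b, transactions=tuple(b.transactions)) for b in self.blocks]
        return Ledger(digest=self.digest_name, clock=self.clock, _blocks=blocks)
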