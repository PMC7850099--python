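"""Secret-sharing primitives for two-party computation over Z_2^l.

Two sharing schemes are supported:

* **Arithmetic sharing** — a vector of l-bit values ``x`` is split into two
  random summands ``s0 + s1 ≡ x (mod 2^l)``.  Addition (and subtraction, and
  addition of public constants) is local: no communication between the two
  parties is needed.

* **Boolean (XOR) sharing** — a vector of bit strings is split into two
  strings whose XOR is the secret.  XOR is local; AND needs interaction
  (see :mod:`genoshare.engine`).

The module also implements the *local zero-value conversion*: an arithmetic
sharing of a secret can be reinterpreted as a Boolean sharing whose XOR
reconstruction is the all-zero string exactly at the positions where the
secret is zero.  Party 0 keeps the binary representation of its share;
party 1 takes the additive inverse of its share.  Then

    x = 0  ⟺  s0 ≡ -s1 (mod 2^l)  ⟺  bits(s0) = bits(2^l - s1)

so the XOR of the two bit strings is 0...0 iff the secret is zero (at
non-zero positions the reconstruction is some unspecified non-zero string).
This makes equality-to-zero tests possible without the expensive general
arithmetic-to-Boolean conversion.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "ProtocolConfig",
    "ArithShareVector",
    "BoolShareVector",
    "arith_share",
    "arith_reconstruct",
    "arith_add_local",
    "zero_convert",
    "bool_share",
    "bool_reconstruct",
    "write_share_file",
    "read_share_file",
]

_U64 = np.uint64
SHARE_MAGIC = b"MPCSHARE"
SHARE_VERSION = 1

TRANSPORTS = ("in-process", "socket")


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol-wide parameters.

    Parameters
    ----------
    l:
        Bit length of ring elements; all arithmetic is modulo ``2**l``.
        The deployment default is 32; tiny rings (l=4) are supported for
        exhaustive testing.
    rng_seed:
        Seed for the deterministic test-mode generator.  ``None`` selects
        fresh OS entropy (deployment mode).
    transport:
        ``"in-process"`` (both parties in one process, paired queues) or
        ``"socket"`` (each party in its own process, TCP framing).
    """

    l: int = 32
    rng_seed: Optional[int] = None
    transport: str = "in-process"

    def __post_init__(self) -> None:
        if not (2 <= self.l <= 64):
            raise ValueError(f"bit length l must be in [2, 64], got {self.l}")
        if self.transport not in TRANSPORTS:
            raise ValueError(f"unknown transport {self.transport!r}")

    @property
    def mask(self) -> np.uint64:
        """Bit mask selecting the low ``l`` bits of a 64-bit word."""
        if self.l == 64:
            return _U64(0xFFFFFFFFFFFFFFFF)
        return _U64((1 << self.l) - 1)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def ring_mask(l: int) -> np.uint64:
    if l == 64:
        return _U64(0xFFFFFFFFFFFFFFFF)
    return _U64((1 << l) - 1)


def as_ring_vector(values: Union[Sequence[int], np.ndarray], l: int) -> np.ndarray:
    """Validate and coerce a plaintext vector into the ring Z_2^l."""
    arr = np.asarray(values, dtype=_U64)
    if arr.ndim != 1:
        arr = arr.reshape(-1)
    if l < 64 and np.any(arr >= _U64(1 << l)):
        bad = int(arr[arr >= _U64(1 << l)][0])
        raise ValueError(f"element {bad} outside ring Z_2^{l}")
    return arr


@dataclass
class ArithShareVector:
    """One party's additive share of a secret vector over Z_2^l."""

    party_id: int
    values: np.ndarray
    l: int

    def __post_init__(self) -> None:
        if self.party_id not in (0, 1):
            raise ValueError("party_id must be 0 or 1")
        self.values = as_ring_vector(self.values, self.l)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BoolShareVector:
    """One party's XOR share of a vector of ``width``-bit strings.

    ``width`` is 1 for indicator vectors and l for full ring elements;
    each element is stored packed in a uint64 word.
    """

    party_id: int
    bits: np.ndarray
    width: int

    def __post_init__(self) -> None:
        if self.party_id not in (0, 1):
            raise ValueError("party_id must be 0 or 1")
        if not (1 <= self.width <= 64):
            raise ValueError("width must be in [1, 64]")
        self.bits = np.asarray(self.bits, dtype=_U64) & ring_mask(self.width)

    def __len__(self) -> int:
        return len(self.bits)


def _uniform_words(rng: np.random.Generator, n: int, l: int) -> np.ndarray:
    """n words uniform over [0, 2^l)."""
    if l == 64:
        return rng.integers(0, 1 << 64, size=n, dtype=_U64)
    return rng.integers(0, 1 << l, size=n, dtype=_U64)


def arith_share(
    x: Union[Sequence[int], np.ndarray], l: int, rng: np.random.Generator
) -> Tuple[ArithShareVector, ArithShareVector]:
    """Additively share ``x`` over Z_2^l.

    Party 1 receives a uniform random mask; party 0 receives value minus
    mask, mirroring the outsourcing convention where the data owner sends
    the mask R to server S1 and (V - R) to server S0.
    """
    vec = as_ring_vector(x, l)
    s1 = _uniform_words(rng, len(vec), l)
    s0 = (vec - s1) & ring_mask(l)
    return (
        ArithShareVector(0, s0, l),
        ArithShareVector(1, s1, l),
    )


def arith_reconstruct(s0: ArithShareVector, s1: ArithShareVector) -> np.ndarray:
    """Elementwise ``(s0 + s1) mod 2^l``."""
    if {s0.party_id, s1.party_id} != {0, 1}:
        raise ValueError("need one share from each party")
    if len(s0) != len(s1) or s0.l != s1.l:
        raise ValueError("share vectors do not match")
    return (s0.values + s1.values) & ring_mask(s0.l)


def arith_add_local(
    a: ArithShareVector,
    b: Union[ArithShareVector, Sequence[int], np.ndarray],
    sign: int = 1,
) -> ArithShareVector:
    """Local addition/subtraction of shares, or of a public constant.

    When ``b`` is another share it must belong to the same party.  When
    ``b`` is a public vector, only party 0 incorporates it (party 1's
    share is returned unchanged), so the sharing of the sum stays valid.
    Requires no communication.
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    m = ring_mask(a.l)
    if isinstance(b, ArithShareVector):
        if b.party_id != a.party_id:
            raise ValueError("cannot mix shares of different parties")
        if b.l != a.l or len(b) != len(a):
            raise ValueError("share vectors do not match")
        other = b.values
    else:
        other = as_ring_vector(b, a.l)
        if len(other) != len(a):
            raise ValueError("length mismatch with public vector")
        if a.party_id == 1:
            return ArithShareVector(a.party_id, a.values.copy(), a.l)
    if sign == 1:
        out = (a.values + other) & m
    else:
        out = (a.values - other) & m
    return ArithShareVector(a.party_id, out, a.l)


def zero_convert(a: ArithShareVector) -> BoolShareVector:
    """Local conversion of an arithmetic share for zero-equality testing.

    Party 0 reinterprets its share's binary representation as its Boolean
    share; party 1 outputs the binary representation of the additive
    inverse of its share.  XOR-reconstruction is all-zero exactly where
    the arithmetic secret is zero; elsewhere it is some non-zero string.
    No communication is needed.
    """
    if a.party_id == 0:
        bits = a.values.copy()
    else:
        bits = (-a.values) & ring_mask(a.l)
    return BoolShareVector(a.party_id, bits, a.l)


def bool_share(
    x: Union[Sequence[int], np.ndarray], width: int, rng: np.random.Generator
) -> Tuple[BoolShareVector, BoolShareVector]:
    """XOR-share a vector of ``width``-bit strings; party 1 gets the mask."""
    vec = np.asarray(x, dtype=_U64)
    if width < 64 and np.any(vec >= _U64(1 << width)):
        raise ValueError(f"element wider than {width} bits")
    b1 = _uniform_words(rng, len(vec), width)
    b0 = vec ^ b1
    return (
        BoolShareVector(0, b0, width),
        BoolShareVector(1, b1, width),
    )


def bool_reconstruct(b0: BoolShareVector, b1: BoolShareVector) -> np.ndarray:
    if {b0.party_id, b1.party_id} != {0, 1}:
        raise ValueError("need one share from each party")
    if b0.width != b1.width or len(b0) != len(b1):
        raise ValueError("share vectors do not match")
    return b0.bits ^ b1.bits


# ---------------------------------------------------------------------------
# Share file format: "MPCSHARE", version byte, party_id byte, l byte,
# element count as 8-byte little-endian, payload as ceil(l/8)-byte
# little-endian words.  Bit-exact so independently written parties
# interoperate.
# ---------------------------------------------------------------------------


def write_share_file(path, share: ArithShareVector) -> None:
    nbytes = (share.l + 7) // 8
    with open(path, "wb") as fh:
        fh.write(SHARE_MAGIC)
        fh.write(struct.pack("<BBB", SHARE_VERSION, share.party_id, share.l))
        fh.write(struct.pack("<Q", len(share)))
        le = np.frombuffer(share.values.astype("<u8").tobytes(), dtype=np.uint8)
        payload = le.reshape(-1, 8)[:, :nbytes]  # low bytes of each LE word
        fh.write(np.ascontiguousarray(payload).tobytes())


def read_share_file(path) -> ArithShareVector:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != SHARE_MAGIC:
            raise ValueError(f"{path}: not a share file (bad magic)")
        version, party_id, l = struct.unpack("<BBB", fh.read(3))
        if version != SHARE_VERSION:
            raise ValueError(f"{path}: unsupported share-file version {version}")
        (count,) = struct.unpack("<Q", fh.read(8))
        nbytes = (l + 7) // 8
        payload = fh.read(nbytes * count)
        if len(payload) != nbytes * count:
            raise ValueError(f"{path}: truncated payload")
        words = np.zeros((count, 8), dtype=np.uint8)
        words[:, :nbytes] = np.frombuffer(payload, dtype=np.uint8).reshape(count, nbytes)
        values = np.frombuffer(words.tobytes(), dtype="<u8").astype(_U64)
    return ArithShareVector(party_id, values, l)
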