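"""Two-party GMW-style evaluation of Boolean gates over XOR shares.

Linear gates (XOR, INV) are local.  Non-linear gates (AND, and everything
built from it: OR, equality-to-zero, unsigned greater-than, multiplexer,
full arithmetic-to-Boolean conversion) consume pre-dealt Boolean
multiplication triples and one communication round each, exchanging the
masked openings d = x⊕a and e = y⊕b.

Triples come from a trusted dealer (:func:`deal_bool_triples`).  The dealer
is a distinct component so that an OT-based offline phase could be swapped
in without touching the online protocol; dealing happens before any private
input is touched (offline phase).

Gate counting follows SIMD semantics: one counter tick per *vectorized*
gate invocation regardless of vector length, and composite gates (EQ, GT,
MUX, OR, A2B) count as a single unit gate even though they consume several
internal AND layers.
"""

from __future__ import annotations

import queue
import socket as _socket
import struct
import threading
from dataclasses import dataclass, field, asdict
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .sharing import (
    ArithShareVector,
    BoolShareVector,
    ProtocolConfig,
    arith_add_local,
    ring_mask,
    zero_convert as _zero_convert_local,
)

__all__ = [
    "GateStats",
    "TripleExhaustedError",
    "BooleanTripleStore",
    "deal_bool_triples",
    "PartyRuntime",
    "QueueEndpoint",
    "SocketEndpoint",
    "make_queue_pair",
    "run_two_party",
]

_U64 = np.uint64


class TripleExhaustedError(RuntimeError):
    """Raised when the offline material (Beaver triples) is used up."""


@dataclass
class GateStats:
    """Per-run counters of vector-level gate and conversion invocations.

    One tick per SIMD invocation, independent of vector length; internal
    AND layers of composite gates are not counted separately.
    """

    bool_and: int = 0
    bool_or: int = 0
    bool_inv: int = 0
    bool_eq: int = 0
    bool_mux: int = 0
    bool_gt: int = 0
    arith_add: int = 0
    zero_conversions: int = 0
    full_a2b_conversions: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


class BooleanTripleStore:
    """One party's stream of correlated random bit-triples.

    Triples are stored as 64-bit words; a vectorized AND on ``n`` elements
    consumes ``n`` words (high bits beyond the gate width are simply
    ignored).  Each word is consumed at most once.
    """

    def __init__(self, a: np.ndarray, b: np.ndarray, c: np.ndarray):
        self.a = a
        self.b = b
        self.c = c
        self.cursor = 0

    def __len__(self) -> int:
        return len(self.a)

    @property
    def remaining(self) -> int:
        return len(self.a) - self.cursor

    def take(self, n: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.cursor + n > len(self.a):
            raise TripleExhaustedError(
                f"offline material exhausted: need {n} triples, "
                f"{self.remaining} left"
            )
        sl = slice(self.cursor, self.cursor + n)
        self.cursor += n
        return self.a[sl], self.b[sl], self.c[sl]


def deal_bool_triples(
    count: int, rng: np.random.Generator, width: int = 64
) -> Tuple[BooleanTripleStore, BooleanTripleStore]:
    """Trusted-dealer generation of ``count`` Boolean triple words.

    Returns the two parties' stores.  For every word,
    ``(a0^a1) & (b0^b1) == c0^c1`` bitwise; dealer randomness is drawn
    before and independently of any private input.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    m = ring_mask(width)
    a = rng.integers(0, 1 << 64, size=count, dtype=_U64) & m
    b = rng.integers(0, 1 << 64, size=count, dtype=_U64) & m
    c = a & b
    a0 = rng.integers(0, 1 << 64, size=count, dtype=_U64) & m
    b0 = rng.integers(0, 1 << 64, size=count, dtype=_U64) & m
    c0 = rng.integers(0, 1 << 64, size=count, dtype=_U64) & m
    s0 = BooleanTripleStore(a0, b0, c0)
    s1 = BooleanTripleStore(a ^ a0, b ^ b0, c ^ c0)
    assert np.all(((s0.a ^ s1.a) & (s0.b ^ s1.b)) == (s0.c ^ s1.c))
    return s0, s1


# ---------------------------------------------------------------------------
# Transport endpoints.  Wire format: 4-byte LE payload length, 4-byte LE
# gate sequence number, payload.  Identical framing for both transports so
# transcripts are bit-exact across them.
# ---------------------------------------------------------------------------

_HEADER = struct.Struct("<II")


class QueueEndpoint:
    """In-process endpoint backed by a pair of thread-safe queues."""

    def __init__(self, inbox: "queue.Queue[bytes]", outbox: "queue.Queue[bytes]",
                 timeout: float = 120.0):
        self._inbox = inbox
        self._outbox = outbox
        self._timeout = timeout
        self.bytes_sent = 0
        self.messages_sent = 0

    def send(self, frame: bytes) -> None:
        self.bytes_sent += len(frame)
        self.messages_sent += 1
        self._outbox.put(frame)

    def recv(self) -> bytes:
        try:
            return self._inbox.get(timeout=self._timeout)
        except queue.Empty:
            raise RuntimeError("peer did not respond (protocol desync?)")


def make_queue_pair(timeout: float = 120.0) -> Tuple[QueueEndpoint, QueueEndpoint]:
    q01: "queue.Queue[bytes]" = queue.Queue()
    q10: "queue.Queue[bytes]" = queue.Queue()
    return QueueEndpoint(q10, q01, timeout), QueueEndpoint(q01, q10, timeout)


class SocketEndpoint:
    """TCP endpoint speaking the same length-prefixed frame format."""

    def __init__(self, sock: _socket.socket):
        self._sock = sock
        self.bytes_sent = 0
        self.messages_sent = 0

    def send(self, frame: bytes) -> None:
        self.bytes_sent += len(frame)
        self.messages_sent += 1
        self._sock.sendall(frame)

    def _read_exact(self, n: int) -> bytes:
        buf = bytearray()
        while len(buf) < n:
            chunk = self._sock.recv(n - len(buf))
            if not chunk:
                raise RuntimeError("peer closed connection mid-protocol")
            buf.extend(chunk)
        return bytes(buf)

    def recv(self) -> bytes:
        header = self._read_exact(_HEADER.size)
        (length, _seq) = _HEADER.unpack(header)
        return header + self._read_exact(length)


def _next_pow2(x: int) -> int:
    p = 1
    while p < x:
        p *= 2
    return p


class PartyRuntime:
    """One party's view of the two-party engine.

    All gate methods operate on this party's *local* halves of shared
    vectors; the peer runs the same program on its halves, and the two
    exchange masked openings through the endpoint in lock-step.
    """

    def __init__(
        self,
        party_id: int,
        endpoint,
        triples: BooleanTripleStore,
        config: ProtocolConfig,
    ):
        if party_id not in (0, 1):
            raise ValueError("party_id must be 0 or 1")
        self.party_id = party_id
        self.endpoint = endpoint
        self.triples = triples
        self.config = config
        self.stats = GateStats()
        self.rounds = 0
        self._seq = 0

    # -- transport ---------------------------------------------------------

    def _exchange(self, payload: bytes) -> bytes:
        """One communication round: send our frame, receive the peer's."""
        frame = _HEADER.pack(len(payload), self._seq) + payload
        self.endpoint.send(frame)
        reply = self.endpoint.recv()
        (length, seq) = _HEADER.unpack(reply[: _HEADER.size])
        if seq != self._seq:
            raise RuntimeError(
                f"gate sequence mismatch: expected {self._seq}, got {seq}"
            )
        self._seq += 1
        self.rounds += 1
        return reply[_HEADER.size : _HEADER.size + length]

    # -- share constructors ------------------------------------------------

    def const_bool(self, values: np.ndarray, width: int) -> BoolShareVector:
        """Share of a public constant: party 0 holds it, party 1 holds zero."""
        vals = np.asarray(values, dtype=_U64)
        if self.party_id == 0:
            return BoolShareVector(0, vals, width)
        return BoolShareVector(1, np.zeros(len(vals), dtype=_U64), width)

    def zero_arith(self, n: int, l: Optional[int] = None) -> ArithShareVector:
        """Canonical arithmetic sharing of the all-zero vector (0, 0)."""
        return ArithShareVector(self.party_id, np.zeros(n, dtype=_U64), l or self.config.l)

    # -- arithmetic (local, counted) ---------------------------------------

    def arith_add(self, a: ArithShareVector, b, sign: int = 1) -> ArithShareVector:
        """One counted vector-level arithmetic add/subtract (local)."""
        self.stats.arith_add += 1
        return arith_add_local(a, b, sign)

    def zero_convert(self, a: ArithShareVector) -> BoolShareVector:
        """Counted local conversion of arithmetic-shared zeros (no comms)."""
        self.stats.zero_conversions += 1
        return _zero_convert_local(a)

    # -- raw AND kernel ----------------------------------------------------

    def _and_words(self, x: np.ndarray, y: np.ndarray, width: int) -> np.ndarray:
        """Beaver-triple AND on packed words; one communication round."""
        n = len(x)
        a, b, c = self.triples.take(n)
        m = ring_mask(width)
        a = a & m
        b = b & m
        c = c & m
        d_i = (x & m) ^ a
        e_i = (y & m) ^ b
        payload = d_i.astype("<u8").tobytes() + e_i.astype("<u8").tobytes()
        reply = self._exchange(payload)
        peer = np.frombuffer(reply, dtype="<u8").astype(_U64)
        d = d_i ^ peer[:n]
        e = e_i ^ peer[n:]
        z = (d & b) ^ (e & a) ^ c
        if self.party_id == 0:
            z = z ^ (d & e)
        return z

    # -- gates -------------------------------------------------------------

    def xor_gate(self, x: BoolShareVector, y: BoolShareVector) -> BoolShareVector:
        if x.width != y.width or len(x) != len(y):
            raise ValueError("width/length mismatch in XOR")
        return BoolShareVector(self.party_id, x.bits ^ y.bits, x.width)

    def inv_gate(self, x: BoolShareVector) -> BoolShareVector:
        """Bitwise NOT: XOR with public all-ones, applied by party 0 only."""
        self.stats.bool_inv += 1
        return self._inv_raw(x)

    def _inv_raw(self, x: BoolShareVector) -> BoolShareVector:
        if self.party_id == 0:
            return BoolShareVector(0, x.bits ^ ring_mask(x.width), x.width)
        return BoolShareVector(1, x.bits.copy(), x.width)

    def and_gate(self, x: BoolShareVector, y: BoolShareVector) -> BoolShareVector:
        if x.width != y.width or len(x) != len(y):
            raise ValueError("width/length mismatch in AND")
        self.stats.bool_and += 1
        return BoolShareVector(self.party_id, self._and_words(x.bits, y.bits, x.width), x.width)

    def or_gate(self, x: BoolShareVector, y: BoolShareVector) -> BoolShareVector:
        """OR via x ⊕ y ⊕ (x ∧ y); costs one AND's worth of triples."""
        if x.width != y.width or len(x) != len(y):
            raise ValueError("width/length mismatch in OR")
        self.stats.bool_or += 1
        z = self._and_words(x.bits, y.bits, x.width)
        return BoolShareVector(self.party_id, x.bits ^ y.bits ^ z, x.width)

    def eq_zero_gate(self, x: BoolShareVector) -> BoolShareVector:
        """Indicator (width 1): 1 iff the reconstructed element is zero.

        AND-tree over the inverted bits, padded to a power of two with
        shared constant ones; counted as one unit EQ gate.
        """
        self.stats.bool_eq += 1
        l = x.width
        t = self._inv_raw(x).bits
        p = _next_pow2(l)
        if p > l and self.party_id == 0:
            # pad bits are public ones so they are AND-neutral
            t = t | (ring_mask(p) ^ ring_mask(l))
        w = p
        while w > 1:
            half = w // 2
            lo = t & ring_mask(half)
            hi = t >> _U64(half)
            t = self._and_words(lo, hi, half)
            w = half
        return BoolShareVector(self.party_id, t & _U64(1), 1)

    def _carry_chain(
        self, abits: List[np.ndarray], bbits: List[np.ndarray],
        c0: np.ndarray, upto: int,
    ) -> List[np.ndarray]:
        """Ripple carries c_1..c_upto of a+b with initial carry c0.

        Uses c_{i+1} = ((a_i ⊕ c_i) ∧ (b_i ⊕ c_i)) ⊕ c_i — one AND per bit.
        All arrays are width-1 packed words.
        """
        carries = []
        c = c0
        for i in range(upto):
            t = self._and_words(abits[i] ^ c, bbits[i] ^ c, 1)
            c = t ^ c
            carries.append(c)
        return carries

    @staticmethod
    def _bits_of(words: np.ndarray, l: int) -> List[np.ndarray]:
        return [(words >> _U64(i)) & _U64(1) for i in range(l)]

    def gt_gate(self, x: BoolShareVector, y: BoolShareVector) -> BoolShareVector:
        """Indicator (width 1): 1 iff x > y as unsigned l-bit integers.

        x > y ⟺ NOT carry-out of (y + ~x + 1); the carry chain reuses the
        same adder kernel as the full conversion.  One unit GT gate.
        """
        if x.width != y.width or len(x) != len(y):
            raise ValueError("width/length mismatch in GT")
        self.stats.bool_gt += 1
        l = x.width
        n = len(x)
        ybits = self._bits_of(y.bits, l)
        nx = self._inv_raw(x)
        nxbits = self._bits_of(nx.bits, l)
        one = np.ones(n, dtype=_U64) if self.party_id == 0 else np.zeros(n, dtype=_U64)
        carries = self._carry_chain(ybits, nxbits, one, l)
        out = carries[-1]
        if self.party_id == 0:
            out = out ^ _U64(1)
        return BoolShareVector(self.party_id, out, 1)

    def mux_gate(
        self,
        s: BoolShareVector,
        x: BoolShareVector,
        y: BoolShareVector,
    ) -> BoolShareVector:
        """Select x where s=1 else y: y ⊕ (s ∧ (x⊕y)); one unit MUX."""
        self.stats.bool_mux += 1
        return self._mux_raw(s, x, y)

    def mux_pair_gate(
        self,
        s: BoolShareVector,
        x: Sequence[BoolShareVector],
        y: Sequence[BoolShareVector],
    ) -> List[BoolShareVector]:
        """Mux several lanes on one selector, counted as a single MUX
        invocation (the extra lanes ride on the same selector)."""
        self.stats.bool_mux += 1
        return [self._mux_raw(s, xi, yi) for xi, yi in zip(x, y)]

    def _mux_raw(self, s, x, y):
        if s.width != 1:
            raise ValueError("selector must be width 1")
        if x.width != y.width or len(x) != len(y) or len(s) != len(x):
            raise ValueError("width/length mismatch in MUX")
        sexp = (np.zeros(len(s), dtype=_U64) - (s.bits & _U64(1))) & ring_mask(x.width)
        z = self._and_words(sexp, x.bits ^ y.bits, x.width)
        return BoolShareVector(self.party_id, y.bits ^ z, x.width)

    def full_a2b(self, a: ArithShareVector) -> BoolShareVector:
        """Full (interactive) arithmetic-to-Boolean conversion.

        Each party Boolean-shares its own arithmetic share locally, then
        the two jointly evaluate an l-bit ripple adder under Boolean
        sharing; reconstruction equals the binary representation of
        (s0+s1) mod 2^l.  Counted as one conversion.
        """
        self.stats.full_a2b_conversions += 1
        l = a.l
        n = len(a)
        zero = np.zeros(n, dtype=_U64)
        # shared addend u = s0: party 0 holds the bits; shared addend v = s1.
        u = a.values if self.party_id == 0 else zero
        v = a.values if self.party_id == 1 else zero
        ubits = self._bits_of(u, l)
        vbits = self._bits_of(v, l)
        carries = self._carry_chain(ubits, vbits, zero, l - 1)
        out = ubits[0] ^ vbits[0]
        for i in range(1, l):
            out = out | ((ubits[i] ^ vbits[i] ^ carries[i - 1]) << _U64(i))
        return BoolShareVector(self.party_id, out, l)


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------


def run_two_party(
    program: Callable,
    inputs0,
    inputs1,
    *,
    config: ProtocolConfig,
    triple_words: int,
    dealer_seed: Optional[int] = None,
    timeout: float = 120.0,
):
    """Run ``program(runtime, inputs)`` for both parties in lock-step.

    The dealer issues ``triple_words`` Boolean triple words before the
    program touches any input (offline phase).  Returns
    ``(out0, out1, runtime0, runtime1)``.
    """
    rng = np.random.default_rng(dealer_seed if dealer_seed is not None else config.rng_seed)
    st0, st1 = deal_bool_triples(triple_words, rng)
    e0, e1 = make_queue_pair(timeout)
    rt0 = PartyRuntime(0, e0, st0, config)
    rt1 = PartyRuntime(1, e1, st1, config)

    results: List = [None, None]
    errors: List = [None, None]

    def _worker(i, rt, inputs):
        try:
            results[i] = program(rt, inputs)
        except BaseException as exc:  # propagate to driver
            errors[i] = exc

    t0 = threading.Thread(target=_worker, args=(0, rt0, inputs0))
    t1 = threading.Thread(target=_worker, args=(1, rt1, inputs1))
    t0.start()
    t1.start()
    t0.join()
    t1.join()
    for err in errors:
        if err is not None:
            raise err
    return results[0], results[1], rt0, rt1
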