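"""End-to-end phases across two proxy servers.

Phase 0 (offline) deals Boolean triples before any share file is read;
Phase 1 outsources a patient's three vectors as one arithmetic share file
per server (a single server never holds both shares of anything); Phase 2
is the researcher query (ids, operation, pedigree roles); Phase 3 runs the
secure operation between the servers; Phase 4 XOR-combines the two output
shares at the researcher and decodes them against the public catalog.

Two transports execute Phase 3: both parties in one process (lock-step
threads), or party 1 in a separate ``serve`` process reached over TCP with
bit-identical framing.
"""

from __future__ import annotations

import json
import socket as _socket
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .encoding import IndividualEncoding, VariantCatalog, decode_candidates
from .engine import (
    BooleanTripleStore,
    PartyRuntime,
    SocketEndpoint,
    deal_bool_triples,
)
from .protocols import (
    AnalysisResult,
    CohortSpec,
    Role,
    _comphet_program,
    _dominant_program,
    _intersection_program,
    _max_program,
    _recessive_program,
    _setdiff_program,
    comphet_pairs,
    estimate_triple_words,
    protection_quotient,
    run_secure_operation,
)
from .sharing import (
    ArithShareVector,
    ProtocolConfig,
    arith_share,
    read_share_file,
    write_share_file,
)

__all__ = [
    "ServerState",
    "ResearcherQuery",
    "outsource",
    "run_analysis",
    "serve_analysis",
    "run_remote_analysis",
]

TAGS = ("H", "E", "G")

_PROGRAMS = {
    "recessive": _recessive_program,
    "dominant": _dominant_program,
    "comphet": _comphet_program,
    "setdiff": _setdiff_program,
    "intersection": _intersection_program,
    "max": _max_program,
}


class ServerState:
    """One proxy server's on-disk state: share files, catalog, allow-list."""

    def __init__(self, root, party_id: int):
        if party_id not in (0, 1):
            raise ValueError("party_id must be 0 or 1")
        self.root = Path(root)
        self.party_id = party_id
        self.root.mkdir(parents=True, exist_ok=True)

    def share_path(self, patient_id: str, tag: str) -> Path:
        return self.root / f"{patient_id}.{tag}.share"

    def has_patient(self, patient_id: str) -> bool:
        return all(self.share_path(patient_id, t).exists() for t in TAGS)

    def store_share(self, patient_id: str, tag: str, share: ArithShareVector,
                    overwrite: bool = False) -> None:
        if share.party_id != self.party_id:
            raise ValueError("share belongs to the other server")
        path = self.share_path(patient_id, tag)
        if path.exists() and not overwrite:
            raise FileExistsError(
                f"patient {patient_id!r} already outsourced to server {self.party_id}"
            )
        write_share_file(path, share)

    def load_share(self, patient_id: str, tag: str) -> ArithShareVector:
        path = self.share_path(patient_id, tag)
        if not path.exists():
            raise FileNotFoundError(f"no {tag} share for patient {patient_id!r}")
        share = read_share_file(path)
        if share.party_id != self.party_id:
            raise ValueError(f"{path}: share file belongs to the other server")
        return share

    def load_patient(self, patient_id: str) -> Dict[str, ArithShareVector]:
        return {t: self.load_share(patient_id, t) for t in TAGS}

    # -- catalog (public metadata) -----------------------------------------

    @property
    def catalog_path(self) -> Path:
        return self.root / "catalog.tsv"

    def store_catalog(self, catalog: VariantCatalog) -> None:
        catalog.to_tsv(self.catalog_path)

    def load_catalog(self) -> VariantCatalog:
        if not self.catalog_path.exists():
            raise FileNotFoundError(f"server {self.party_id} has no catalog")
        return VariantCatalog.from_tsv(self.catalog_path)

    # -- researcher authorization ------------------------------------------

    @property
    def allowlist_path(self) -> Path:
        return self.root / "allowlist.txt"

    def authorized(self, patient_ids: List[str]) -> bool:
        """Allow-list file (one patient id per line); absent file = allow all."""
        if not self.allowlist_path.exists():
            return True
        allowed = {
            line.strip()
            for line in self.allowlist_path.read_text().splitlines()
            if line.strip()
        }
        return all(p in allowed for p in patient_ids)


@dataclass
class ResearcherQuery:
    """Phase 2 payload: who, which analysis, which roles."""

    operation: str
    members: List[Tuple[str, Role]]
    k: int = 1

    @property
    def cohort(self) -> CohortSpec:
        return CohortSpec(list(self.members))

    def to_json(self) -> str:
        return json.dumps({
            "operation": self.operation,
            "members": [[m, r.value] for m, r in self.members],
            "k": self.k,
        })

    @classmethod
    def from_json(cls, text: str) -> "ResearcherQuery":
        obj = json.loads(text)
        return cls(
            operation=obj["operation"],
            members=[(m, Role(r)) for m, r in obj["members"]],
            k=obj.get("k", 1),
        )


def outsource(
    encoding: IndividualEncoding,
    server0: ServerState,
    server1: ServerState,
    l: int,
    rng: np.random.Generator,
    overwrite: bool = False,
) -> None:
    """Phase 1: split a patient's three vectors into arithmetic shares and
    store one share file per vector on each server.  Plaintext is never
    persisted server-side; re-outsourcing requires ``overwrite``."""
    pid = encoding.id
    if not overwrite and (server0.has_patient(pid) or server1.has_patient(pid)):
        raise FileExistsError(f"patient {pid!r} already outsourced")
    for tag, vec in (("H", encoding.v_hom), ("E", encoding.v_het), ("G", encoding.v_gene)):
        s0, s1 = arith_share(vec.astype(np.uint64), l, rng)
        server0.store_share(pid, tag, s0, overwrite=overwrite)
        server1.store_share(pid, tag, s1, overwrite=overwrite)


def _load_query_shares(query: ResearcherQuery, server: ServerState) -> Dict:
    return {m: server.load_patient(m) for m, _ in query.members}


def _disclosure_counts(
    op: str,
    result: AnalysisResult,
    query: ResearcherQuery,
    shares0: Dict,
    shares1: Dict,
    l: int,
) -> Tuple[int, int]:
    """Revealed/total observation counts for the protection quotient.

    Conventions: variant operations count each member's rare variants in
    the total; RECESSIVE/DOMINANT/COMPHET/INTERSECTION reveal the output
    positions once per contributing member, SETDIFF reveals them for the
    proband only, and MAX reveals k genes per patient out of each
    patient's rare-gene entries.
    """
    mask = (1 << l) - 1
    members = [m for m, _ in query.members]

    def _member_count(tag: str) -> Dict[str, int]:
        out = {}
        for m in members:
            h = (shares0[m]["H"].values + shares1[m]["H"].values) & mask
            e = (shares0[m]["E"].values + shares1[m]["E"].values) & mask
            if tag == "HE":
                out[m] = int(np.count_nonzero(h | e))
            else:
                g = (shares0[m]["G"].values + shares1[m]["G"].values) & mask
                out[m] = int(np.count_nonzero(g))
        return out

    if op == "max":
        totals = _member_count("G")
        revealed = len(result.output["top"]) * len(members)
        return revealed, sum(totals.values())
    totals = _member_count("HE")
    total = sum(totals.values())
    if op == "comphet":
        out_bits = result.output["maternal"] | result.output["paternal"]
    else:
        out_bits = result.output["candidates"]
    n_out = int(np.count_nonzero(out_bits))
    if op == "setdiff":
        revealed = n_out  # proband only
    else:
        revealed = n_out * len(members)
    return revealed, total


def run_analysis(
    query: ResearcherQuery,
    server0: ServerState,
    server1: ServerState,
    config: ProtocolConfig,
    dealer_seed: Optional[int] = None,
) -> Tuple[AnalysisResult, Dict]:
    """Phases 0–4 with both servers in this process.

    Returns the analysis result plus a JSON-serializable run report
    (candidates, gate counters, communication, protection quotient).
    """
    ids = [m for m, _ in query.members]
    for srv in (server0, server1):
        if not srv.authorized(ids):
            raise PermissionError("researcher not authorized for all patients")
        missing = [m for m in ids if not srv.has_patient(m)]
        if missing:
            raise FileNotFoundError(f"server {srv.party_id} lacks shares for {missing}")
    catalog = server0.load_catalog()
    shares0 = _load_query_shares(query, server0)
    shares1 = _load_query_shares(query, server1)
    cohort = query.cohort
    result = run_secure_operation(
        query.operation, shares0, shares1, cohort, config,
        catalog=catalog, k=query.k, dealer_seed=dealer_seed,
    )
    revealed, total = _disclosure_counts(
        query.operation.lower(), result, query, shares0, shares1, config.l
    )
    result.revealed_count = revealed
    result.total_count = total
    report = build_report(result, catalog)
    return result, report


def build_report(result: AnalysisResult, catalog: VariantCatalog) -> Dict:
    op = result.operation
    report: Dict = {
        "operation": op,
        "gate_stats": result.stats.as_dict(),
        "rounds": result.rounds,
        "bytes_sent": result.bytes_sent,
        "revealed": result.revealed_count,
        "total": result.total_count,
        "protection_quotient": result.protection_quotient,
    }
    if op == "max":
        report["top"] = [
            {"gene": catalog.genes[idx], "count": val}
            for val, idx in result.output["top"]
        ]
    elif op == "comphet":
        report["maternal_candidates"] = [
            ":".join(map(str, v))
            for v in decode_candidates(result.output["maternal"], catalog)
        ]
        report["paternal_candidates"] = [
            ":".join(map(str, v))
            for v in decode_candidates(result.output["paternal"], catalog)
        ]
        report["gene_pairs"] = {
            g: pairs for g, pairs in result.output["pairs"].items()
        }
    else:
        report["candidates"] = [
            ":".join(map(str, v))
            for v in decode_candidates(result.output["candidates"], catalog)
        ]
    return report


# ---------------------------------------------------------------------------
# Socket transport: party 1 as a server process
# ---------------------------------------------------------------------------

_BLOB = struct.Struct("<Q")


def _send_blob(sock: _socket.socket, data: bytes) -> None:
    sock.sendall(_BLOB.pack(len(data)) + data)


def _recv_blob(sock: _socket.socket) -> bytes:
    header = b""
    while len(header) < _BLOB.size:
        chunk = sock.recv(_BLOB.size - len(header))
        if not chunk:
            raise RuntimeError("connection closed during handshake")
        header += chunk
    (length,) = _BLOB.unpack(header)
    buf = bytearray()
    while len(buf) < length:
        chunk = sock.recv(min(1 << 20, length - len(buf)))
        if not chunk:
            raise RuntimeError("connection closed mid-blob")
        buf.extend(chunk)
    return bytes(buf)


def _program_inputs(op, shares, cohort, catalog, k):
    if op == "comphet":
        return (shares, cohort, catalog.gene_members(), catalog.gene_of)
    if op == "max":
        return (shares, cohort, k)
    return (shares, cohort)


def _pack_output(op, out) -> bytes:
    if op == "comphet":
        return json.dumps({
            "m": out[0].bits.tolist(), "f": out[1].bits.tolist(),
        }).encode()
    if op == "max":
        return json.dumps({"winners": out}).encode()
    return json.dumps({"bits": out.bits.tolist()}).encode()


def serve_analysis(server: ServerState, port: int, config: ProtocolConfig,
                   host: str = "127.0.0.1", ready=None) -> None:
    """Run party 1 for a single researcher-driven analysis over TCP.

    Handshake: query JSON blob, then this party's triple stream (a, b, c
    word arrays from the dealer), then gate frames, then the final output
    share and counters travel back as a JSON blob.
    """
    if server.party_id != 1:
        raise ValueError("serve_analysis hosts party 1")
    with _socket.socket() as lsock:
        lsock.setsockopt(_socket.SOL_SOCKET, _socket.SO_REUSEADDR, 1)
        lsock.bind((host, port))
        lsock.listen(1)
        if ready is not None:
            ready.set()
        conn, _addr = lsock.accept()
        with conn:
            query = ResearcherQuery.from_json(_recv_blob(conn).decode())
            ids = [m for m, _ in query.members]
            if not server.authorized(ids):
                raise PermissionError("researcher not authorized")
            triple_raw = _recv_blob(conn)
            words = np.frombuffer(triple_raw, dtype="<u8").astype(np.uint64)
            a, b, c = np.split(words, 3)
            triples = BooleanTripleStore(a, b, c)
            catalog = server.load_catalog()
            shares = _load_query_shares(query, server)
            cohort = query.cohort
            op = query.operation.lower()
            rt = PartyRuntime(1, SocketEndpoint(conn), triples, config)
            out = _PROGRAMS[op](rt, _program_inputs(op, shares, cohort, catalog, query.k))
            _send_blob(conn, _pack_output(op, out))
            _send_blob(conn, json.dumps(rt.stats.as_dict()).encode())


def run_remote_analysis(
    query: ResearcherQuery,
    server0: ServerState,
    host: str,
    port: int,
    config: ProtocolConfig,
    dealer_seed: Optional[int] = None,
) -> Tuple[AnalysisResult, Dict]:
    """Phases 0–4 with party 0 local and party 1 reached over TCP."""
    ids = [m for m, _ in query.members]
    if not server0.authorized(ids):
        raise PermissionError("researcher not authorized for all patients")
    catalog = server0.load_catalog()
    shares0 = _load_query_shares(query, server0)
    cohort = query.cohort
    op = query.operation.lower()
    cohort.validate_for(op, config.l)
    some = ids[0]
    n_var = len(shares0[some]["H"])
    n_gen = len(shares0[some]["G"])
    words = estimate_triple_words(op, n_var, n_gen, config.l, query.k)
    rng = np.random.default_rng(dealer_seed if dealer_seed is not None else config.rng_seed)
    st0, st1 = deal_bool_triples(words, rng)

    with _socket.socket() as sock:
        sock.connect((host, port))
        _send_blob(sock, query.to_json().encode())
        stream = np.concatenate([st1.a, st1.b, st1.c]).astype("<u8").tobytes()
        _send_blob(sock, stream)
        rt0 = PartyRuntime(0, SocketEndpoint(sock), st0, config)
        out0 = _PROGRAMS[op](rt0, _program_inputs(op, shares0, cohort, catalog, query.k))
        peer = json.loads(_recv_blob(sock).decode())
        peer_stats = json.loads(_recv_blob(sock).decode())

    if peer_stats != rt0.stats.as_dict():
        raise RuntimeError("per-party gate counters diverged")
    if op == "comphet":
        m_bits = (out0[0].bits ^ np.asarray(peer["m"], dtype=np.uint64)).astype(np.uint8)
        f_bits = (out0[1].bits ^ np.asarray(peer["f"], dtype=np.uint64)).astype(np.uint8)
        output = {"maternal": m_bits, "paternal": f_bits,
                  "pairs": comphet_pairs(m_bits, f_bits, catalog)}
    elif op == "max":
        winners = [tuple(w) for w in peer["winners"]]
        if winners != out0:
            raise RuntimeError("parties disagree on opened MAX output")
        output = {"top": out0, "max_count": out0[0][0], "argmax_gene": out0[0][1]}
    else:
        output = {
            "candidates": (out0.bits ^ np.asarray(peer["bits"], dtype=np.uint64)).astype(np.uint8)
        }
    result = AnalysisResult(
        operation=op,
        output=output,
        stats=rt0.stats,
        rounds=rt0.rounds,
        bytes_sent=rt0.endpoint.bytes_sent,
        cohort=cohort,
    )
    report = build_report(result, catalog)
    return result, report
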