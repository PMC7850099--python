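"""The six secure operations over secret-shared genotype encodings.

Each operation follows the same mixed-protocol recipe:

1. *Local arithmetic phase* — sum the relevant shared bit vectors and
   subtract the public count that marks the sought pattern, so that the
   positions of interest hold an arithmetic-shared **zero**.  All of this
   is communication-free.
2. *Local zero conversion* — reinterpret the arithmetic shares as Boolean
   shares (party 1 negates); zeros stay zeros, non-zeros stay non-zero.
3. *Boolean phase* — a GMW equality-to-zero per converted vector turns
   zeros into indicator ones, and a handful of AND/OR/INV/MUX gates
   combine the indicators into the final candidate vector.

Because counts of carriers are summed in Z_2^l, the no-wraparound
precondition (fewer than 2^l vectors summed) must hold; it is validated
up front.

Every operation has a plaintext oracle implementing the same Boolean
semantics directly; secure and plaintext paths must agree bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .encoding import IndividualEncoding, VariantCatalog
from .engine import GateStats, PartyRuntime, run_two_party
from .sharing import ArithShareVector, BoolShareVector, ProtocolConfig, arith_share

__all__ = [
    "Role",
    "CohortSpec",
    "AnalysisResult",
    "share_cohort",
    "run_secure_operation",
    "secure_recessive",
    "secure_dominant",
    "secure_comphet",
    "secure_setdiff",
    "secure_intersection",
    "secure_max",
    "plaintext_oracle",
    "protection_quotient",
    "estimate_triple_words",
]

_U64 = np.uint64

OPERATIONS = ("recessive", "dominant", "comphet", "setdiff", "intersection", "max")


class Role(str, Enum):
    MOTHER = "mother"
    FATHER = "father"
    AFFECTED_SIB = "affected_sib"
    UNAFFECTED_SIB = "unaffected_sib"
    OTHER = "other"


@dataclass
class CohortSpec:
    """Pedigree roles partitioning the participants of one operation."""

    members: List[Tuple[str, Role]]

    def _ids(self, role: Role) -> List[str]:
        return [m for m, r in self.members if r == role]

    @property
    def mother(self) -> Optional[str]:
        ids = self._ids(Role.MOTHER)
        return ids[0] if ids else None

    @property
    def father(self) -> Optional[str]:
        ids = self._ids(Role.FATHER)
        return ids[0] if ids else None

    @property
    def affected(self) -> List[str]:
        return self._ids(Role.AFFECTED_SIB)

    @property
    def unaffected(self) -> List[str]:
        return self._ids(Role.UNAFFECTED_SIB)

    @property
    def others(self) -> List[str]:
        return self._ids(Role.OTHER)

    @property
    def p(self) -> int:
        return len(self.affected)

    @property
    def r(self) -> int:
        return len(self.unaffected)

    @property
    def s(self) -> int:
        return len(self.others)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def all_ids(self) -> List[str]:
        return [m for m, _ in self.members]

    def validate_for(self, op: str, l: int = 32) -> None:
        op = op.lower()
        if op not in OPERATIONS:
            raise ValueError(f"unknown operation {op!r}")
        ids = self.all_ids
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate member ids in cohort")
        if op in ("recessive", "dominant", "comphet"):
            if len(self._ids(Role.MOTHER)) != 1 or len(self._ids(Role.FATHER)) != 1:
                raise ValueError(f"{op} needs exactly one mother and one father")
            if self.p < 1:
                raise ValueError(f"{op} needs at least one affected sibling")
        elif op == "setdiff":
            if self.p < 1:
                raise ValueError("setdiff needs a nonempty case (affected) group")
            if self.n - self.p < 1:
                raise ValueError("setdiff needs a nonempty control group")
        else:  # intersection, max
            if self.n < 2:
                raise ValueError(f"{op} needs at least two participants")
        # counts are summed in Z_2^l; no modular wraparound allowed
        if 2 * self.n + 2 >= (1 << l):
            raise ValueError(
                f"cohort of {self.n} too large for ring Z_2^{l} (wraparound)"
            )


@dataclass
class AnalysisResult:
    """Outcome of one secure operation run."""

    operation: str
    output: Dict
    stats: GateStats
    rounds: int
    bytes_sent: int
    cohort: CohortSpec
    output_shares: Optional[Tuple] = None
    revealed_count: Optional[int] = None
    total_count: Optional[int] = None

    @property
    def protection_quotient(self) -> Optional[float]:
        if self.revealed_count is None or self.total_count is None:
            return None
        return protection_quotient(self.revealed_count, self.total_count)


# ---------------------------------------------------------------------------
# Sharing a cohort
# ---------------------------------------------------------------------------


def share_cohort(
    encodings: Dict[str, IndividualEncoding],
    l: int,
    rng: np.random.Generator,
) -> Tuple[Dict, Dict]:
    """Arithmetic-share every member's three vectors; returns per-party dicts."""
    shares0: Dict[str, Dict[str, ArithShareVector]] = {}
    shares1: Dict[str, Dict[str, ArithShareVector]] = {}
    for ind_id, enc in encodings.items():
        s0, s1 = {}, {}
        for tag, vec in (("H", enc.v_hom), ("E", enc.v_het), ("G", enc.v_gene)):
            a0, a1 = arith_share(vec.astype(np.uint64), l, rng)
            s0[tag] = a0
            s1[tag] = a1
        shares0[ind_id] = s0
        shares1[ind_id] = s1
    return shares0, shares1


# ---------------------------------------------------------------------------
# Shared helpers for the per-party programs
# ---------------------------------------------------------------------------


def _arith_sum(rt: PartyRuntime, vectors: List[ArithShareVector],
               n: int) -> ArithShareVector:
    """Counted left-fold sum; an empty list yields the canonical (0,0) sharing."""
    if not vectors:
        return rt.zero_arith(n)
    acc = vectors[0]
    for v in vectors[1:]:
        acc = rt.arith_add(acc, v)
    return acc


def _sub_const(rt: PartyRuntime, a: ArithShareVector, k: int) -> ArithShareVector:
    const = np.full(len(a), k, dtype=_U64)
    return rt.arith_add(a, const, sign=-1)


def _segmented_or(rt: PartyRuntime, bits: BoolShareVector,
                  members: List[np.ndarray]) -> BoolShareVector:
    """Per-gene OR-reduction of a width-1 variant vector to a gene vector.

    Balanced pairwise tree over each gene's (public) member indices; all
    genes advance one level per communication flush.  Counted as one
    vector-level OR.
    """
    rt.stats.bool_or += 1
    vals = bits.bits
    segs = [m.copy() for m in members]
    out = np.zeros(len(members), dtype=_U64)
    # current value per active slot, per gene, indexes into a flat work array
    work = vals
    positions = segs  # positions into `work` per gene
    while True:
        lefts, rights, keeps = [], [], []
        new_positions = []
        cursor = 0
        any_pair = False
        for pos in positions:
            npos = []
            i = 0
            while i + 1 < len(pos):
                lefts.append(pos[i])
                rights.append(pos[i + 1])
                npos.append(cursor)
                cursor += 1
                i += 2
                any_pair = True
            if i < len(pos):
                keeps.append((cursor, pos[i]))
                npos.append(cursor)
                cursor += 1
            new_positions.append(np.asarray(npos, dtype=np.int64))
        if not any_pair:
            break
        li = np.asarray(lefts, dtype=np.int64)
        ri = np.asarray(rights, dtype=np.int64)
        x = work[li]
        y = work[ri]
        z = x ^ y ^ rt._and_words(x, y, 1)
        nwork = np.zeros(cursor, dtype=_U64)
        nwork[: len(z)] = 0  # placeholder; fill by position below
        # paired results occupy their assigned slots in order of creation
        pair_slots = []
        kslots = {slot: src for slot, src in keeps}
        pi = 0
        for slot in range(cursor):
            if slot in kslots:
                nwork[slot] = work[kslots[slot]]
            else:
                nwork[slot] = z[pi]
                pi += 1
        work = nwork
        positions = new_positions
    for g, pos in enumerate(positions):
        if len(pos) == 1:
            out[g] = work[pos[0]]
        elif len(pos) == 0:
            out[g] = 0  # empty gene: OR of nothing is 0 (party-symmetric)
    return BoolShareVector(rt.party_id, out, 1)


# ---------------------------------------------------------------------------
# Per-party protocol programs
# ---------------------------------------------------------------------------


def _presence(rt: PartyRuntime, member: Dict[str, ArithShareVector]) -> List[ArithShareVector]:
    return [member["H"], member["E"]]


def _recessive_program(rt: PartyRuntime, inputs):
    shares, cohort = inputs
    p = cohort.p
    n = len(shares[cohort.affected[0]]["H"])
    aff = [shares[m]["H"] for m in cohort.affected]
    acc = _arith_sum(rt, aff, n)
    acc = rt.arith_add(acc, shares[cohort.mother]["E"])
    acc = rt.arith_add(acc, shares[cohort.father]["E"])
    a_vec = _sub_const(rt, acc, p + 2)
    o_terms = [shares[m]["H"] for m in cohort.unaffected]
    for m in cohort.others:
        o_terms.extend(_presence(rt, shares[m]))
    o_vec = _arith_sum(rt, o_terms, n)
    aB = rt.zero_convert(a_vec)
    oB = rt.zero_convert(o_vec)
    aZ = rt.eq_zero_gate(aB)
    oZ = rt.eq_zero_gate(oB)
    return rt.and_gate(aZ, oZ)


def _dominant_program(rt: PartyRuntime, inputs):
    shares, cohort = inputs
    p = cohort.p
    n = len(shares[cohort.affected[0]]["E"])
    acc = _arith_sum(rt, [shares[m]["E"] for m in cohort.affected], n)
    a_vec = _sub_const(rt, acc, p)
    o_terms: List[ArithShareVector] = []
    for m in cohort.unaffected + cohort.others:
        o_terms.extend(_presence(rt, shares[m]))
    o_vec = _arith_sum(rt, o_terms, n)
    aB = rt.zero_convert(a_vec)
    oB = rt.zero_convert(o_vec)
    aZ = rt.eq_zero_gate(aB)
    oZ = rt.eq_zero_gate(oB)
    return rt.and_gate(aZ, oZ)


def _comphet_program(rt: PartyRuntime, inputs):
    shares, cohort, gene_members, gene_of = inputs
    p = cohort.p
    n = len(shares[cohort.affected[0]]["E"])
    S = _arith_sum(rt, [shares[m]["E"] for m in cohort.affected], n)
    m_vec = _sub_const(rt, rt.arith_add(S, shares[cohort.mother]["E"]), p + 1)
    f_vec = _sub_const(rt, rt.arith_add(S, shares[cohort.father]["E"]), p + 1)
    o_terms = [shares[m]["E"] for m in cohort.unaffected + cohort.others]
    o_vec = _arith_sum(rt, o_terms, n)
    mB = rt.zero_convert(m_vec)
    fB = rt.zero_convert(f_vec)
    oB = rt.zero_convert(o_vec)
    mZ = rt.eq_zero_gate(mB)
    fZ = rt.eq_zero_gate(fB)
    oZ = rt.eq_zero_gate(oB)
    nfZ = rt.inv_gate(fZ)
    nmZ = rt.inv_gate(mZ)
    m_cand = rt.and_gate(rt.and_gate(mZ, nfZ), oZ)
    f_cand = rt.and_gate(rt.and_gate(fZ, nmZ), oZ)
    or_m = _segmented_or(rt, m_cand, gene_members)
    or_f = _segmented_or(rt, f_cand, gene_members)
    pass_g = rt.and_gate(or_m, or_f)
    pass_var = BoolShareVector(rt.party_id, pass_g.bits[gene_of], 1)
    m_out = rt.and_gate(m_cand, pass_var)
    f_out = rt.and_gate(f_cand, pass_var)
    return m_out, f_out


def _setdiff_program(rt: PartyRuntime, inputs):
    shares, cohort = inputs
    cases = cohort.affected
    controls = [m for m in cohort.all_ids if m not in cases]
    n = len(shares[cases[0]]["H"])
    a_terms: List[ArithShareVector] = []
    for m in cases:
        a_terms.extend(_presence(rt, shares[m]))
    a_vec = _sub_const(rt, _arith_sum(rt, a_terms, n), len(cases))
    o_terms: List[ArithShareVector] = []
    for m in controls:
        o_terms.extend(_presence(rt, shares[m]))
    o_vec = _arith_sum(rt, o_terms, n)
    aB = rt.zero_convert(a_vec)
    oB = rt.zero_convert(o_vec)
    aZ = rt.eq_zero_gate(aB)
    oZ = rt.eq_zero_gate(oB)
    return rt.and_gate(aZ, oZ)


def _intersection_program(rt: PartyRuntime, inputs):
    shares, cohort = inputs
    ids = cohort.all_ids
    n = len(shares[ids[0]]["H"])
    terms: List[ArithShareVector] = []
    for m in ids:
        terms.extend(_presence(rt, shares[m]))
    t_vec = _sub_const(rt, _arith_sum(rt, terms, n), len(ids))
    tB = rt.zero_convert(t_vec)
    return rt.eq_zero_gate(tB)


def _max_program(rt: PartyRuntime, inputs):
    shares, cohort, k = inputs
    ids = cohort.all_ids
    g = len(shares[ids[0]]["G"])
    l = rt.config.l
    counts = _arith_sum(rt, [shares[m]["G"] for m in ids], g)
    winners: List[Tuple[int, int]] = []
    count_vals = counts.values.copy()
    for _round in range(k):
        cshare = ArithShareVector(rt.party_id, count_vals.copy(), l)
        cb = rt.full_a2b(cshare)
        best_val = BoolShareVector(rt.party_id, cb.bits[:1].copy(), l)
        best_idx = rt.const_bool(np.zeros(1, dtype=_U64), l)
        for j in range(1, g):
            cand_val = BoolShareVector(rt.party_id, cb.bits[j : j + 1].copy(), l)
            cand_idx = rt.const_bool(np.full(1, j, dtype=_U64), l)
            is_gt = rt.gt_gate(cand_val, best_val)
            best_val, best_idx = rt.mux_pair_gate(
                is_gt, (cand_val, cand_idx), (best_val, best_idx)
            )
        # open this round's (value, index) pair so the next round can mask
        # the winner's count; for k rounds this is exactly the disclosed
        # top-k output.
        payload = best_val.bits.astype("<u8").tobytes() + best_idx.bits.astype("<u8").tobytes()
        peer = np.frombuffer(rt._exchange(payload), dtype="<u8").astype(_U64)
        val = int(best_val.bits[0] ^ peer[0])
        idx = int(best_idx.bits[0] ^ peer[1])
        winners.append((val, idx))
        count_vals[idx] = 0  # both parties zero their share: count becomes 0
    return winners


# ---------------------------------------------------------------------------
# Triple sizing (offline phase)
# ---------------------------------------------------------------------------


def _eq_levels(l: int) -> int:
    p, lv = 1, 0
    while p < l:
        p *= 2
        lv += 1
    return lv


def estimate_triple_words(op: str, n_variants: int, n_genes: int,
                          l: int, k: int = 1) -> int:
    """Upper bound on triple words an operation will consume."""
    eq = _eq_levels(l)
    if op in ("recessive", "dominant", "setdiff"):
        need = (2 * eq + 1) * n_variants
    elif op == "intersection":
        need = eq * n_variants
    elif op == "comphet":
        need = (3 * eq + 8) * n_variants + 2 * n_genes
    elif op == "max":
        need = k * ((l - 1) * n_genes + (n_genes - 1) * (l + 2) + 4)
    else:
        raise ValueError(f"unknown operation {op!r}")
    return int(need * 1.25) + 64


# ---------------------------------------------------------------------------
# Public drivers
# ---------------------------------------------------------------------------


def run_secure_operation(
    op: str,
    shares0: Dict,
    shares1: Dict,
    cohort: CohortSpec,
    config: ProtocolConfig,
    catalog: Optional[VariantCatalog] = None,
    k: int = 1,
    dealer_seed: Optional[int] = None,
) -> AnalysisResult:
    """Execute one secure operation end to end (both parties, in lock-step).

    ``shares0``/``shares1`` map member id to that party's arithmetic
    shares of the member's H/E/G vectors.  Returns the reconstructed
    plaintext output, the gate/conversion counters and the communication
    totals.
    """
    op = op.lower()
    cohort.validate_for(op, config.l)
    for m in cohort.all_ids:
        if m not in shares0 or m not in shares1:
            raise KeyError(f"missing shares for member {m!r}")
    some = cohort.all_ids[0]
    n_var = len(shares0[some]["H"])
    n_gen = len(shares0[some]["G"])
    words = estimate_triple_words(op, n_var, n_gen, config.l, k)

    if op in ("recessive", "dominant", "setdiff", "intersection"):
        program = {
            "recessive": _recessive_program,
            "dominant": _dominant_program,
            "setdiff": _setdiff_program,
            "intersection": _intersection_program,
        }[op]
        out0, out1, rt0, rt1 = run_two_party(
            program, (shares0, cohort), (shares1, cohort),
            config=config, triple_words=words, dealer_seed=dealer_seed,
        )
        bits = (out0.bits ^ out1.bits).astype(np.uint8)
        output = {"candidates": bits}
        output_shares = (out0, out1)
    elif op == "comphet":
        if catalog is None:
            raise ValueError("comphet requires the public catalog (gene ranges)")
        gene_members = catalog.gene_members()
        gene_of = catalog.gene_of
        out0, out1, rt0, rt1 = run_two_party(
            _comphet_program,
            (shares0, cohort, gene_members, gene_of),
            (shares1, cohort, gene_members, gene_of),
            config=config, triple_words=words, dealer_seed=dealer_seed,
        )
        m_bits = (out0[0].bits ^ out1[0].bits).astype(np.uint8)
        f_bits = (out0[1].bits ^ out1[1].bits).astype(np.uint8)
        pairs = comphet_pairs(m_bits, f_bits, catalog)
        output = {"maternal": m_bits, "paternal": f_bits, "pairs": pairs}
        output_shares = (out0, out1)
    else:  # max
        out0, out1, rt0, rt1 = run_two_party(
            _max_program, (shares0, cohort, k), (shares1, cohort, k),
            config=config, triple_words=words, dealer_seed=dealer_seed,
        )
        if out0 != out1:
            raise RuntimeError("parties disagree on opened MAX output")
        output = {
            "top": out0,
            "max_count": out0[0][0],
            "argmax_gene": out0[0][1],
        }
        output_shares = None
    if rt0.stats != rt1.stats:
        raise RuntimeError("per-party gate counters diverged")
    bytes_sent = rt0.endpoint.bytes_sent + rt1.endpoint.bytes_sent
    return AnalysisResult(
        operation=op,
        output=output,
        stats=rt0.stats,
        rounds=rt0.rounds,
        bytes_sent=bytes_sent,
        cohort=cohort,
        output_shares=output_shares,
    )


def secure_recessive(shares0, shares1, cohort, config, **kw) -> AnalysisResult:
    return run_secure_operation("recessive", shares0, shares1, cohort, config, **kw)


def secure_dominant(shares0, shares1, cohort, config, **kw) -> AnalysisResult:
    return run_secure_operation("dominant", shares0, shares1, cohort, config, **kw)


def secure_comphet(shares0, shares1, cohort, config, catalog, **kw) -> AnalysisResult:
    return run_secure_operation("comphet", shares0, shares1, cohort, config,
                                catalog=catalog, **kw)


def secure_setdiff(shares0, shares1, cohort, config, **kw) -> AnalysisResult:
    return run_secure_operation("setdiff", shares0, shares1, cohort, config, **kw)


def secure_intersection(shares0, shares1, cohort, config, **kw) -> AnalysisResult:
    return run_secure_operation("intersection", shares0, shares1, cohort, config, **kw)


def secure_max(shares0, shares1, cohort, config, k: int = 1, **kw) -> AnalysisResult:
    return run_secure_operation("max", shares0, shares1, cohort, config, k=k, **kw)


# ---------------------------------------------------------------------------
# Plaintext oracles
# ---------------------------------------------------------------------------


def comphet_pairs(m_bits: np.ndarray, f_bits: np.ndarray,
                  catalog: VariantCatalog) -> Dict[str, List[Tuple[int, int]]]:
    """Per passing gene, the Cartesian product of maternal × paternal
    candidate variant indices."""
    pairs: Dict[str, List[Tuple[int, int]]] = {}
    for g, members in enumerate(catalog.gene_members()):
        m_idx = [int(i) for i in members if m_bits[i]]
        f_idx = [int(i) for i in members if f_bits[i]]
        if m_idx and f_idx:
            pairs[catalog.genes[g]] = [(a, b) for a in m_idx for b in f_idx]
    return pairs


def _all_and(vectors: List[np.ndarray], n: int) -> np.ndarray:
    acc = np.ones(n, dtype=bool)
    for v in vectors:
        acc &= v.astype(bool)
    return acc


def oracle_recessive(enc: Dict[str, IndividualEncoding], cohort: CohortSpec) -> np.ndarray:
    n = len(enc[cohort.affected[0]].v_hom)
    out = _all_and([enc[m].v_hom for m in cohort.affected], n)
    out &= enc[cohort.mother].v_het.astype(bool)
    out &= enc[cohort.father].v_het.astype(bool)
    for m in cohort.unaffected:
        out &= ~enc[m].v_hom.astype(bool)
    for m in cohort.others:
        out &= ~(enc[m].v_hom | enc[m].v_het).astype(bool)
    return out.astype(np.uint8)


def oracle_dominant(enc, cohort: CohortSpec) -> np.ndarray:
    n = len(enc[cohort.affected[0]].v_het)
    out = _all_and([enc[m].v_het for m in cohort.affected], n)
    for m in cohort.unaffected + cohort.others:
        out &= ~(enc[m].v_hom | enc[m].v_het).astype(bool)
    return out.astype(np.uint8)


def oracle_comphet(enc, cohort: CohortSpec, catalog: VariantCatalog):
    n = len(enc[cohort.affected[0]].v_het)
    aff_het = _all_and([enc[m].v_het for m in cohort.affected], n)
    mz = aff_het & enc[cohort.mother].v_het.astype(bool)
    fz = aff_het & enc[cohort.father].v_het.astype(bool)
    oz = np.ones(n, dtype=bool)
    for m in cohort.unaffected + cohort.others:
        oz &= ~enc[m].v_het.astype(bool)
    m_cand = mz & ~fz & oz
    f_cand = fz & ~mz & oz
    passing = np.zeros(catalog.n_genes, dtype=bool)
    for g, members in enumerate(catalog.gene_members()):
        if m_cand[members].any() and f_cand[members].any():
            passing[g] = True
    pass_var = passing[catalog.gene_of]
    m_out = (m_cand & pass_var).astype(np.uint8)
    f_out = (f_cand & pass_var).astype(np.uint8)
    return m_out, f_out, comphet_pairs(m_out, f_out, catalog)


def oracle_setdiff(enc, cohort: CohortSpec) -> np.ndarray:
    cases = cohort.affected
    controls = [m for m in cohort.all_ids if m not in cases]
    n = len(enc[cases[0]].v_hom)
    out = _all_and([(enc[m].v_hom | enc[m].v_het) for m in cases], n)
    for m in controls:
        out &= ~(enc[m].v_hom | enc[m].v_het).astype(bool)
    return out.astype(np.uint8)


def oracle_intersection(enc, cohort: CohortSpec) -> np.ndarray:
    ids = cohort.all_ids
    n = len(enc[ids[0]].v_hom)
    return _all_and([(enc[m].v_hom | enc[m].v_het) for m in ids], n).astype(np.uint8)


def oracle_max(enc, cohort: CohortSpec, k: int = 1):
    counts = np.zeros(len(enc[cohort.all_ids[0]].v_gene), dtype=np.int64)
    for m in cohort.all_ids:
        counts += enc[m].v_gene
    work = counts.copy()
    winners = []
    for _ in range(k):
        idx = int(np.argmax(work))  # np.argmax takes the lowest index on ties
        winners.append((int(work[idx]), idx))
        work[idx] = 0
    return winners


def plaintext_oracle(op: str, enc: Dict[str, IndividualEncoding],
                     cohort: CohortSpec, catalog: Optional[VariantCatalog] = None,
                     k: int = 1):
    """Direct evaluation of an operation's declared semantics, no sharing."""
    op = op.lower()
    cohort.validate_for(op, l=64)
    if op == "recessive":
        return oracle_recessive(enc, cohort)
    if op == "dominant":
        return oracle_dominant(enc, cohort)
    if op == "comphet":
        if catalog is None:
            raise ValueError("comphet oracle requires the catalog")
        return oracle_comphet(enc, cohort, catalog)
    if op == "setdiff":
        return oracle_setdiff(enc, cohort)
    if op == "intersection":
        return oracle_intersection(enc, cohort)
    if op == "max":
        return oracle_max(enc, cohort, k)
    raise ValueError(f"unknown operation {op!r}")


# ---------------------------------------------------------------------------
# Protection quotient
# ---------------------------------------------------------------------------


def protection_quotient(revealed: int, total: int) -> float:
    """Percentage of variant/gene observations kept private.

    100 × (1 − revealed/total), truncated toward zero at one decimal place
    (exact integer arithmetic, so printed values are reproducible).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= revealed <= total):
        raise ValueError("revealed must be in [0, total]")
    tenths = (1000 * (total - revealed)) // total
    return tenths / 10.0
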