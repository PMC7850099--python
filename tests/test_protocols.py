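"""The six secure operations: worked examples, equivalence with the
plaintext oracles, gate-counter conformance, monotonicity, and the
protection quotient."""

import numpy as np
import pytest

from genoshare.encoding import IndividualEncoding, VariantCatalog
from genoshare.protocols import (
    CohortSpec,
    Role,
    oracle_comphet,
    oracle_intersection,
    oracle_max,
    oracle_recessive,
    plaintext_oracle,
    protection_quotient,
    run_secure_operation,
    share_cohort,
)
from genoshare.sharing import ProtocolConfig
from genoshare.synth import SyntheticCohortSpec, generate_cohort


def _enc(ind_id, v_hom, v_het, catalog):
    return IndividualEncoding.from_genotypes(ind_id, v_hom, v_het, catalog)


@pytest.fixture
def cat4():
    return VariantCatalog(
        [("chr1", 1, "A", "T"), ("chr1", 2, "A", "T"),
         ("chr1", 3, "A", "T"), ("chr1", 4, "A", "T")],
        ["G0", "G1"], [0, 0, 1, 1],
    )


def _run(op, enc, cohort, catalog, l=32, seed=5, k=1):
    cfg = ProtocolConfig(l=l, rng_seed=seed)
    s0, s1 = share_cohort(enc, l, np.random.default_rng(seed))
    return run_secure_operation(op, s0, s1, cohort, cfg, catalog=catalog,
                                k=k, dealer_seed=seed + 1)


class TestRecessive:
    def test_trio_worked_example(self, cat4):
        enc = {
            "p": _enc("p", [1, 0, 1, 0], [0, 0, 0, 0], cat4),
            "m": _enc("m", [0, 0, 0, 0], [1, 0, 1, 1], cat4),
            "f": _enc("f", [0, 0, 0, 0], [1, 0, 0, 1], cat4),
        }
        cohort = CohortSpec([("m", Role.MOTHER), ("f", Role.FATHER),
                             ("p", Role.AFFECTED_SIB)])
        assert oracle_recessive(enc, cohort).tolist() == [1, 0, 0, 0]
        res = _run("recessive", enc, cohort, cat4)
        assert res.output["candidates"].tolist() == [1, 0, 0, 0]

    def test_all_zero_genotypes(self, cat4):
        z = np.zeros(4, dtype=np.uint8)
        enc = {m: _enc(m, z, z, cat4) for m in ("m", "f", "p")}
        cohort = CohortSpec([("m", Role.MOTHER), ("f", Role.FATHER),
                             ("p", Role.AFFECTED_SIB)])
        res = _run("recessive", enc, cohort, cat4)
        assert not res.output["candidates"].any()

    def test_conversion_and_gate_counts(self, cat4):
        enc = {
            "p": _enc("p", [1, 0, 0, 0], [0, 0, 0, 0], cat4),
            "m": _enc("m", [0, 0, 0, 0], [1, 0, 0, 0], cat4),
            "f": _enc("f", [0, 0, 0, 0], [1, 0, 0, 0], cat4),
            "u": _enc("u", [0, 0, 0, 0], [0, 0, 0, 0], cat4),
            "o": _enc("o", [0, 0, 0, 0], [0, 0, 0, 0], cat4),
        }
        cohort = CohortSpec([("m", Role.MOTHER), ("f", Role.FATHER),
                             ("p", Role.AFFECTED_SIB), ("u", Role.UNAFFECTED_SIB),
                             ("o", Role.OTHER)])
        res = _run("recessive", enc, cohort, cat4)
        s = res.stats
        # p=1, r=1, s=1: adds p+r+2s+1
        assert (s.zero_conversions, s.bool_eq, s.bool_and) == (2, 2, 1)
        assert s.arith_add == 1 + 1 + 2 * 1 + 1


class TestDominant:
    def test_worked_example(self):
        cat = VariantCatalog([("chr1", 1, "A", "T"), ("chr1", 2, "A", "T")],
                             ["G0"], [0, 0])
        z = np.zeros(2, dtype=np.uint8)
        enc = {
            "a1": _enc("a1", z, [1, 1], cat),
            "a2": _enc("a2", z, [1, 0], cat),
            "m": _enc("m", z, z, cat),
            "f": _enc("f", z, z, cat),
            "o": _enc("o", z, z, cat),
        }
        cohort = CohortSpec([("m", Role.MOTHER), ("f", Role.FATHER),
                             ("a1", Role.AFFECTED_SIB), ("a2", Role.AFFECTED_SIB),
                             ("o", Role.OTHER)])
        res = _run("dominant", enc, cohort, cat)
        assert res.output["candidates"].tolist() == [1, 0]
        assert res.stats.zero_conversions == 2
        # p=2, r=0, s=1: adds p+2r+2s-1
        assert res.stats.arith_add == 2 + 0 + 2 - 1

    def test_het_unaffected_excludes(self):
        cat = VariantCatalog([("chr1", 1, "A", "T")], ["G0"], [0])
        z = np.zeros(1, dtype=np.uint8)
        enc = {
            "a": _enc("a", z, [1], cat),
            "u": _enc("u", z, [1], cat),
            "m": _enc("m", z, z, cat),
            "f": _enc("f", z, z, cat),
        }
        cohort = CohortSpec([("m", Role.MOTHER), ("f", Role.FATHER),
                             ("a", Role.AFFECTED_SIB), ("u", Role.UNAFFECTED_SIB)])
        res = _run("dominant", enc, cohort, cat)
        assert res.output["candidates"].tolist() == [0]


class TestComphet:
    def test_worked_example(self, cat4):
        z = np.zeros(4, dtype=np.uint8)
        enc = {
            "m": _enc("m", z, [1, 0, 0, 1], cat4),
            "f": _enc("f", z, [0, 1, 1, 0], cat4),
            "a": _enc("a", z, [1, 1, 0, 0], cat4),
        }
        cohort = CohortSpec([("m", Role.MOTHER), ("f", Role.FATHER),
                             ("a", Role.AFFECTED_SIB)])
        m_out, f_out, pairs = oracle_comphet(enc, cohort, cat4)
        assert m_out.tolist() == [1, 0, 0, 0]
        assert f_out.tolist() == [0, 1, 0, 0]
        assert pairs == {"G0": [(0, 1)]}
        res = _run("comphet", enc, cohort, cat4)
        assert res.output["maternal"].tolist() == [1, 0, 0, 0]
        assert res.output["paternal"].tolist() == [0, 1, 0, 0]
        assert res.output["pairs"] == {"G0": [(0, 1)]}
        s = res.stats
        assert (s.zero_conversions, s.bool_eq, s.bool_inv, s.bool_or) == (3, 3, 2, 2)
        # p=1 and no unaffected/others: the exclusion sum is the canonical
        # zero sharing (no add), so adds = p + 3; with r+s >= 1 the count
        # is p+r+s+2 (checked in test_counter_conformance below)
        assert s.arith_add == 1 + 3

    def test_counter_conformance_with_exclusion_group(self, cat4):
        z = np.zeros(4, dtype=np.uint8)
        enc = {
            "m": _enc("m", z, [1, 0, 0, 1], cat4),
            "f": _enc("f", z, [0, 1, 1, 0], cat4),
            "a": _enc("a", z, [1, 1, 0, 0], cat4),
            "u": _enc("u", z, z, cat4),
            "o": _enc("o", z, z, cat4),
        }
        cohort = CohortSpec([("m", Role.MOTHER), ("f", Role.FATHER),
                             ("a", Role.AFFECTED_SIB), ("u", Role.UNAFFECTED_SIB),
                             ("o", Role.OTHER)])
        res = _run("comphet", enc, cohort, cat4)
        s = res.stats
        assert (s.zero_conversions, s.bool_eq, s.bool_inv, s.bool_or) == (3, 3, 2, 2)
        assert s.arith_add == 1 + 1 + 1 + 2  # p+r+s+2

    def test_biparental_het_excluded(self, cat4):
        """A variant het in both parents is exclusive to neither."""
        z = np.zeros(4, dtype=np.uint8)
        enc = {
            "m": _enc("m", z, [1, 1, 0, 0], cat4),
            "f": _enc("f", z, [1, 1, 0, 0], cat4),
            "a": _enc("a", z, [1, 1, 0, 0], cat4),
        }
        cohort = CohortSpec([("m", Role.MOTHER), ("f", Role.FATHER),
                             ("a", Role.AFFECTED_SIB)])
        res = _run("comphet", enc, cohort, cat4)
        assert not res.output["maternal"].any()
        assert not res.output["paternal"].any()


class TestSetdiffIntersection:
    def test_setdiff_example(self):
        cat = VariantCatalog([("chr1", i, "A", "T") for i in (1, 2, 3)],
                             ["G0"], [0, 0, 0])
        enc = {
            "case": _enc("case", [0, 0, 0], [1, 1, 0], cat),
            "ctrl": _enc("ctrl", [0, 1, 0], [0, 0, 0], cat),
        }
        cohort = CohortSpec([("case", Role.AFFECTED_SIB), ("ctrl", Role.OTHER)])
        res = _run("setdiff", enc, cohort, cat)
        assert res.output["candidates"].tolist() == [1, 0, 0]
        assert res.stats.zero_conversions == 2

    def test_setdiff_identical_groups_empty(self):
        cat = VariantCatalog([("chr1", 1, "A", "T")], ["G0"], [0])
        enc = {
            "case": _enc("case", [0], [1], cat),
            "ctrl": _enc("ctrl", [0], [1], cat),
        }
        cohort = CohortSpec([("case", Role.AFFECTED_SIB), ("ctrl", Role.OTHER)])
        res = _run("setdiff", enc, cohort, cat)
        assert res.output["candidates"].tolist() == [0]

    def test_intersection_example(self):
        cat = VariantCatalog([("chr1", i, "A", "T") for i in (1, 2, 3)],
                             ["G0"], [0, 0, 0])
        enc = {
            "x": _enc("x", [0, 0, 0], [1, 1, 0], cat),
            "y": _enc("y", [1, 0, 0], [0, 0, 1], cat),
        }
        cohort = CohortSpec([("x", Role.OTHER), ("y", Role.OTHER)])
        assert oracle_intersection(enc, cohort).tolist() == [1, 0, 0]
        res = _run("intersection", enc, cohort, cat)
        assert res.output["candidates"].tolist() == [1, 0, 0]
        assert res.stats.zero_conversions == 1
        assert res.stats.bool_eq == 1
        assert res.stats.bool_and == 0
        assert res.stats.arith_add == 2 * 2  # 2n


class TestMax:
    def test_counts_and_argmax(self):
        cat = VariantCatalog([("chr1", i, "A", "T") for i in (1, 2, 3)],
                             ["G0", "G1", "G2"], [0, 1, 2])
        vecs = [[1, 0, 1], [1, 1, 0], [1, 0, 0]]
        enc = {}
        for i, v in enumerate(vecs):
            enc[f"x{i}"] = IndividualEncoding(f"x{i}", np.zeros(3, np.uint8),
                                              np.array(v, np.uint8),
                                              np.array(v, np.uint8))
        cohort = CohortSpec([(f"x{i}", Role.OTHER) for i in range(3)])
        assert oracle_max(enc, cohort) == [(3, 0)]
        res = _run("max", enc, cohort, cat)
        assert res.output["max_count"] == 3
        assert res.output["argmax_gene"] == 0
        g, n = 3, 3
        assert res.stats.bool_gt == g - 1
        assert res.stats.bool_mux == g - 1
        assert res.stats.full_a2b_conversions == 1
        assert res.stats.arith_add == n - 1

    def test_tie_breaks_to_lowest_index(self):
        cat = VariantCatalog([("chr1", 1, "A", "T"), ("chr1", 2, "A", "T")],
                             ["G0", "G1"], [0, 1])
        enc = {
            "x": IndividualEncoding("x", np.zeros(2, np.uint8),
                                    np.array([1, 1], np.uint8),
                                    np.array([1, 1], np.uint8)),
            "y": IndividualEncoding("y", np.zeros(2, np.uint8),
                                    np.array([1, 1], np.uint8),
                                    np.array([1, 1], np.uint8)),
        }
        cohort = CohortSpec([("x", Role.OTHER), ("y", Role.OTHER)])
        res = _run("max", enc, cohort, cat)
        assert res.output["argmax_gene"] == 0

    def test_top_k(self):
        cat = VariantCatalog([("chr1", i, "A", "T") for i in (1, 2, 3)],
                             ["G0", "G1", "G2"], [0, 1, 2])
        gene_vecs = {"x": [1, 1, 0], "y": [0, 1, 1], "z": [0, 1, 0]}
        enc = {m: IndividualEncoding(m, np.zeros(3, np.uint8),
                                     np.array(v, np.uint8), np.array(v, np.uint8))
               for m, v in gene_vecs.items()}
        cohort = CohortSpec([(m, Role.OTHER) for m in enc])
        res = _run("max", enc, cohort, cat, k=3)
        assert res.output["top"] == oracle_max(enc, cohort, k=3) == [(3, 1), (1, 0), (1, 2)]


class TestOracleEquivalence:
    @pytest.mark.parametrize("op", ["recessive", "dominant", "comphet",
                                    "setdiff", "intersection", "max"])
    def test_random_cohorts(self, op):
        """Secure output equals the plaintext oracle across randomized
        family structures and carrier frequencies."""
        for seed in range(6):
            r = np.random.default_rng(seed)
            spec = SyntheticCohortSpec(
                n_genes=int(r.integers(3, 10)),
                variants_per_gene=int(r.integers(1, 5)),
                carrier_frequency=float(r.uniform(0.05, 0.5)),
                n_affected=int(r.integers(1, 4)),
                n_unaffected=int(r.integers(0, 3)),
                n_others=int(r.integers(0, 3)) + (1 if op == "setdiff" else 0),
                seed=seed * 37 + 5,
            )
            enc, cohort, cat = generate_cohort(spec)
            res = _run(op, enc, cohort, cat, seed=seed + 11)
            oracle = plaintext_oracle(op, enc, cohort, catalog=cat)
            if op == "comphet":
                assert np.array_equal(res.output["maternal"], oracle[0])
                assert np.array_equal(res.output["paternal"], oracle[1])
            elif op == "max":
                assert res.output["top"] == oracle
            else:
                assert np.array_equal(res.output["candidates"], oracle), seed


class TestMonotonicity:
    @pytest.mark.parametrize("op", ["recessive", "dominant", "setdiff"])
    def test_extra_control_only_clears_bits(self, op):
        """Adding an unaffected/control individual can clear output bits,
        never set new ones."""
        for seed in range(4):
            spec = SyntheticCohortSpec(n_genes=4, variants_per_gene=3,
                                       carrier_frequency=0.4, n_affected=2,
                                       n_unaffected=1, n_others=1, seed=seed)
            enc, cohort, cat = generate_cohort(spec)
            base = plaintext_oracle(op, enc, cohort, catalog=cat)
            r = np.random.default_rng(seed + 100)
            extra_het = (r.random(cat.n_variants) < 0.5).astype(np.uint8)
            enc2 = dict(enc)
            enc2["extra"] = IndividualEncoding.from_genotypes(
                "extra", np.zeros(cat.n_variants, np.uint8), extra_het, cat)
            cohort2 = CohortSpec(cohort.members + [("extra", Role.OTHER)])
            more = plaintext_oracle(op, enc2, cohort2, catalog=cat)
            assert not np.any(more & ~base)


class TestValidation:
    def test_role_requirements(self):
        trio_less = CohortSpec([("a", Role.AFFECTED_SIB)])
        with pytest.raises(ValueError, match="mother"):
            trio_less.validate_for("recessive")
        lone = CohortSpec([("a", Role.OTHER)])
        with pytest.raises(ValueError, match="two participants"):
            lone.validate_for("intersection")
        no_ctrl = CohortSpec([("a", Role.AFFECTED_SIB)])
        with pytest.raises(ValueError, match="control"):
            no_ctrl.validate_for("setdiff")

    def test_wraparound_guard(self):
        big = CohortSpec([(f"x{i}", Role.OTHER) for i in range(10)])
        with pytest.raises(ValueError, match="wraparound"):
            big.validate_for("intersection", l=4)


class TestProtectionQuotient:
    @pytest.mark.parametrize("revealed,total,expect", [
        (21, 3003, 99.3),    # trio, 7 candidates x 3 members
        (36, 2880, 98.7),    # truncation: 98.75 -> 98.7, not 98.8
        (4, 857, 99.5),      # single top gene in each of 4 patients
        (385, 2880, 86.6),   # proband-only disclosure
        (174, 5883, 97.0),   # 29 common variants x 6 members
        (336, 3003, 88.8),
        (0, 10, 100.0),
    ])
    def test_printed_values(self, revealed, total, expect):
        assert protection_quotient(revealed, total) == expect

    def test_validation(self):
        with pytest.raises(ValueError):
            protection_quotient(1, 0)
        with pytest.raises(ValueError):
            protection_quotient(5, 4)
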