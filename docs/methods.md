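# Methods

## Security and computation model

Two proxy servers S₀, S₁ hold complementary secret shares of every
patient's encoded genome; they are assumed non-colluding and semi-honest.
A researcher submits a query (participant ids, operation, pedigree roles);
the servers evaluate it jointly and each returns its share of the output,
which only the researcher can combine. A single server's view — its share
files plus the masked openings it receives during AND gates — is
marginally uniform, so it learns nothing about genotypes. This is an
operational property we test (chi-square uniformity of share histograms),
not a formal simulation proof.

Secret values live in Z_2^l with l = 32 by default (2 ≤ l ≤ 64 supported;
l = 4 is used for exhaustive enumeration in tests). Carrier-count sums
must not wrap around: cohort validation rejects n with 2n + 2 ≥ 2^l.

The offline phase is a **trusted dealer**: Boolean multiplication triples
(a, b, c = a∧b) are generated centrally, split at random, and streamed to
both parties before any private input is read. An OT-based offline phase
would produce identically distributed material; the dealer is a separate
component (`deal_bool_triples`) precisely so it could be swapped out. A
consequence is that no cryptographic security parameter appears in the
engine — the online protocol's correctness and communication pattern are
unaffected.

## The mixed-protocol recipe

Each filtering operation is an arithmetic phase (local), a conversion
(local), and a short Boolean circuit (interactive):

1. Sum the relevant shared bit vectors so that the positions satisfying
   the query hold the known constant (e.g. p + 2 for RECESSIVE: p affected
   hom bits + 2 parental het bits), then subtract that constant. Sought
   positions now hold arithmetic zero.
2. Convert with the local zero rule: party 0 keeps its share's bits,
   party 1 negates its share first. XOR-reconstruction is 0…0 iff the
   secret is 0; non-zero secrets give arbitrary non-zero strings, which is
   sufficient because only zeroness is tested downstream.
3. A Boolean equality-to-zero per converted vector produces indicator
   bits, combined with a few AND/INV/OR gates.

Exact gate compositions (counters tick once per SIMD invocation,
independent of vector length):

- **RECESSIVE / DOMINANT / SETDIFF**: 2 zero conversions, 2 EQ, 1 AND.
  Arithmetic adds: p+r+2s+1 and p+2r+2s−1 for the two family models, and
  2·cases + 2·controls − 1 for SETDIFF. An empty exclusion group is
  replaced by the canonical (0, 0) sharing, which costs no add.
- **INTERSECTION**: 1 conversion, 1 EQ, 0 AND; 2n adds.
- **COMPHET**: 3 conversions, 3 EQ, 2 INV, 2 OR (the per-gene
  reductions), 7 AND. The exclusivity terms are mZ ∧ ¬fZ ∧ oZ and
  fZ ∧ ¬mZ ∧ oZ; a gene passes iff both its maternal and paternal
  reductions are 1, and the output vectors are masked to passing genes.
  A 6-AND variant exists (computing mZ∧fZ once and XORing it out) but
  drops the two INV gates; we keep the INV-explicit construction because
  it reads exactly like the stated semantics.
- **MAX**: n−1 adds, one *full* interactive arithmetic-to-Boolean
  conversion of the count vector (each party Boolean-shares its own
  arithmetic share and a ripple adder is evaluated under sharing), then a
  tournament scan: g−1 GT and g−1 MUX, the (value, index) pair riding one
  selector. Ties break to the lowest gene index.

Internal circuits: EQ is an AND-halving tree over the inverted bits,
padded to a power of two with public ones (⌈log₂ l⌉ AND layers); GT is
computed as ¬carry-out of y + ¬x + 1 using the one-AND-per-bit carry
update c' = ((a⊕c) ∧ (b⊕c)) ⊕ c; MUX is y ⊕ (s ∧ (x⊕y)) with the shared
selector bit expanded locally. These compositions consume triples but
tick only their own unit counter, matching the vector-level accounting
convention of the operation ledger.

**Top-k MAX** repeats the tournament k times, opening each round's
(count, gene) winner and having both parties zero that position's count
share before the next round. The opened winners are exactly the disclosed
output, but note they become known to the servers, not only the
researcher; k = 1 discloses nothing beyond the researcher's answer.
Counters scale k-fold.

## Transports and determinism

Both parties run the same per-party program. In-process mode runs them as
lock-step threads over paired queues; socket mode runs party 1 in its own
process (`genoshare serve`) speaking identical length-prefixed,
sequence-tagged frames, so transcripts are bit-exact across transports
(asserted in tests). All randomness — sharing masks, dealer triples,
synthetic cohorts — flows from explicit seeds; given equal seeds, repeat
analyses are byte-identical.

## Encoding choices

- Multi-allelic VCF records are split into per-alt biallelic keys; the
  catalog is keyed by (chrom, 1-based pos, ref, alt).
- Missing genotypes (./.) contribute no bits — conservative for candidate
  discovery, since every operation requires presence.
- Hom-alt and het bits are mutually exclusive by construction; a violation
  raises at encoding time, never silently.
- Annotations (max sub-population AF, impact class) come from INFO fields
  or a sidecar TSV; variants lacking annotation are excluded with a
  warning. Computing annotations (VEP, gnomAD) is out of scope.
- Genes without catalog variants keep a (public, always-zero) slot so the
  gene-vector length is catalog-defined.

## Disclosure accounting

`protection_quotient(revealed, total) = 100 × (1 − revealed/total)`,
evaluated in integer arithmetic and truncated toward zero at one decimal,
so printed values are exactly reproducible (e.g. 36 of 2880 revealed →
98.7, not 98.8). Conventions for `revealed`: variant operations count each
candidate once per contributing member, except SETDIFF which discloses
the proband's candidates only; MAX counts k genes per patient. `total` is
the sum of members' rare-variant (or rare-gene) counts.

## Synthetic cohorts

The generator draws parental haplotypes as per-variant Bernoulli
(carrier_frequency, default 1%) alleles, transmits one uniformly chosen
allele per parent to each child (allele dropping), and draws unrelated
individuals independently. Defaults model a trio over 200 genes × 5
variants. Planted causal configurations overwrite the chosen site(s) with
the model's zygosity pattern (recessive: child 1/1, parents 0/1; dominant:
affected 0/1, others 0/0; compound het: one maternal and one paternal het
site in the same gene) and are idempotent.

What the generator does **not** model: linkage/recombination, realistic
site-frequency spectra, sequencing error, de novo mutation, consanguinity.
Passing tests therefore demonstrate protocol correctness and Mendelian
bookkeeping, not robustness to real-world data artefacts; real VCFs enter
through the same encoder and are subject to the same catalog/annotation
assumptions.

## Problem sizes

The test suite enumerates the l = 4 ring exhaustively (256 share pairs per
gate), checks secure-vs-oracle equivalence on 200 random cohorts per
operation at l = 32, and runs the RECESSIVE protocol over 10⁶ variants ×
5 members in-process to confirm counters are length-independent; the
acceptance script uses a 1000-variant, eight-member family per protocol.
These sizes were chosen to keep the full suite under a minute on one core
while still covering every code path the larger published workloads
exercise — runtimes on 28M-variant exome vectors scale linearly in memory
and vector length and are hardware-dependent, so they are not asserted.

## Known limitations

- Semi-honest, two-party only; no malicious security, no TLS on the
  socket transport, and authorization is a plain allow-list file.
- The trusted dealer is a real trust assumption in deployment; swap in an
  OT-based offline phase before any adversarial use.
- COMPHET assumes unphased data (exclusive parental origin is inferred
  from the parents' genotypes); X-linked, mitochondrial and de novo models
  are out of scope.
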