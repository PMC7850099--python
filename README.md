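# genoshare

Privacy-preserving rare-disease variant analysis via two-party secure
computation.

Rare-disease diagnosis routinely needs joint analysis of several genomes —
a trio (proband + parents), a sibship, or a cross-institutional cohort —
but every participant's exome is highly identifying. `genoshare` lets a
researcher run the standard Mendelian filtering queries **without any party
ever seeing a genotype**: each patient's data is split into two random
shares held by two non-colluding proxy servers, the servers evaluate the
query under secret sharing, and the researcher learns only the candidate
variants or genes the query returns.

## The model

Each individual *i* is encoded over a public variant catalog as three bit
vectors: V_i^H (homozygous-alternate sites), V_i^E (heterozygous sites, with
V^H ∧ V^E = 0), and V_i^G (genes carrying ≥ 1 rare functional variant).
Only variants with maximum sub-population allele frequency below a
threshold (1% or 5% depending on the analysis) and HIGH/MODERATE predicted
impact are encoded.

Vectors are **additively secret-shared** over Z_2^l (default l = 32):
⟨x⟩₀ + ⟨x⟩₁ ≡ x (mod 2^l). Addition, subtraction and public constants are
local. Boolean logic runs under **XOR sharing** with GMW-style AND gates
consuming pre-dealt Beaver triples (one communication round per gate,
SIMD over the whole vector).

The bridge between the two worlds is a *local zero-value conversion*:
party 0 reinterprets its arithmetic share as a bit string, party 1 negates
its share first; the XOR of the two strings is all-zero **iff** the secret
is zero (x = 0 ⟺ ⟨x⟩₀ = −⟨x⟩₁). Every query is arranged so the sought
positions hold an arithmetic zero, so no general (expensive, interactive)
arithmetic-to-Boolean conversion is ever needed — except in MAX, which
genuinely needs the full binary representation of the gene counts.

Six operations are provided, each with a plaintext oracle it must match
bit for bit:

| operation | finds | zero conversions |
|---|---|---|
| RECESSIVE | all affected sibs hom-alt, both parents het, no unaffected sib hom, no other carrier | 2 |
| DOMINANT | all affected sibs het, everyone else hom-ref | 2 |
| COMPHET | per gene, ≥ 2 het variants inherited from different parents | 3 |
| SETDIFF | carried by every case, absent from every control | 2 |
| INTERSECTION | carried by every participant | 1 |
| MAX | gene mutated in the most participants (top-k optional) | 0 (one full conversion) |

Disclosure is summarized by the **protection quotient**
100 × (1 − revealed/total): the fraction of variant or gene observations
*not* exposed to the researcher.

## Worked example

```
$ genoshare --seed 4 simulate --model recessive --seed 7 --n-genes 20 --variants-per-gene 3
{
  "operation": "recessive",
  "gate_stats": {
    "bool_and": 1,
    "bool_or": 0,
    "bool_inv": 0,
    "bool_eq": 2,
    "bool_mux": 0,
    "bool_gt": 0,
    "arith_add": 3,
    "zero_conversions": 2,
    "full_a2b_conversions": 0
  },
  "rounds": 11,
  "bytes_sent": 21296,
  "revealed": 3,
  "total": 3,
  "protection_quotient": 0.0,
  "candidates": [
    "chr1:944:C:T"
  ]
}
```

A 60-variant trio with a planted recessive site is generated, outsourced
as shares to two simulated servers, and analysed. The report shows the
candidate the researcher receives (`chr1:944:C:T`, the planted site), the
gate ledger of the run — 2 local zero conversions, 2 equality gates, 1 AND,
zero conversions via the expensive interactive route — and the disclosure
accounting (here every rare variant in this tiny noise-free cohort is part
of the answer, hence a protection quotient of 0.0; realistic cohorts carry
~1000 rare variants per member of which a handful are revealed).

The same pipeline runs step by step on real files:

```
genoshare encode sample.vcf --catalog catalog.tsv --out sample.tsv
genoshare outsource sample.vcf --catalog catalog.tsv --server0 s0/ --server1 s1/
genoshare analyze --op recessive --server0 s0/ --server1 s1/ --ped family.ped
genoshare serve --server1 s1/ --port 7001        # party 1 in its own process
genoshare analyze --op recessive --server0 s0/ --remote 127.0.0.1:7001 --ped family.ped
```

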