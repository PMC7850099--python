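"""Bit-vector encoding of annotated genotypes over a public variant catalog.

Each individual is represented by three bit vectors:

* ``V_H`` — homozygous-alternate sites (GT 1/1, 1|1),
* ``V_E`` — heterozygous sites (GT 0/1, 1/0, 0|1, 1|0),
* ``V_G`` — genes carrying at least one rare functional variant.

Only rare, functionally relevant variants are encoded: a variant passes
the filter when its maximum sub-population allele frequency is below the
chosen threshold (1% for MAX-style analyses, 5% for RECESSIVE/SETDIFF/
INTERSECTION-style analyses) and its predicted impact class is HIGH or
MODERATE.  The catalog (variant keys, gene assignment, ordering) is public
metadata; only the genotype bits are secret.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "VariantCatalog",
    "VariantAnnotation",
    "IndividualEncoding",
    "rare_functional_filter",
    "encode_individual",
    "decode_candidates",
]

VariantKey = Tuple[str, int, str, str]  # chrom, 1-based pos, ref, alt

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
DEFAULT_IMPACTS = frozenset({"HIGH", "MODERATE"})


@dataclass(frozen=True)
class VariantAnnotation:
    """Rarity/impact annotation for one biallelic variant.

    ``allele_frequency`` is the maximum AF across the stated
    sub-populations, in [0, 1].
    """

    allele_frequency: float
    impact: str

    def __post_init__(self):
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0, 1]")
        if self.impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact!r}")


def rare_functional_filter(
    ann: VariantAnnotation,
    af_threshold: float = 0.01,
    impacts: Iterable[str] = DEFAULT_IMPACTS,
) -> bool:
    """True iff AF strictly below threshold and impact in the allowed set."""
    if not (0.0 < af_threshold <= 1.0):
        raise ValueError(f"af_threshold must be in (0, 1], got {af_threshold}")
    impacts = set(impacts)
    unknown = impacts - set(IMPACT_CLASSES)
    if unknown:
        raise ValueError(f"unknown impact label(s): {sorted(unknown)}")
    return ann.allele_frequency < af_threshold and ann.impact in impacts


class VariantCatalog:
    """Public, ordered catalog of biallelic variants grouped into genes."""

    def __init__(self, variants: Sequence[VariantKey], genes: Sequence[str],
                 gene_of: Sequence[int]):
        self.variants: List[VariantKey] = [
            (str(c), int(p), str(r), str(a)) for c, p, r, a in variants
        ]
        self.genes: List[str] = list(genes)
        self.gene_of = np.asarray(gene_of, dtype=np.int64)
        if len(self.gene_of) != len(self.variants):
            raise ValueError("gene_of must map every variant")
        if len(self.variants) != len(set(self.variants)):
            raise ValueError("variant keys must be unique")
        if len(self.gene_of) and (self.gene_of.min() < 0 or self.gene_of.max() >= len(self.genes)):
            raise ValueError("gene_of index out of range")
        self._index: Dict[VariantKey, int] = {k: i for i, k in enumerate(self.variants)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def index_of(self, key: VariantKey) -> Optional[int]:
        return self._index.get(key)

    def gene_members(self) -> List[np.ndarray]:
        """Variant index arrays per gene (catalog order within each gene)."""
        members: List[List[int]] = [[] for _ in self.genes]
        for i, g in enumerate(self.gene_of):
            members[g].append(i)
        return [np.asarray(m, dtype=np.int64) for m in members]

    # -- TSV round trip (chrom, pos, ref, alt, gene) ------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.variants, columns=["chrom", "pos", "ref", "alt"]
        )
        df["gene"] = [self.genes[g] for g in self.gene_of]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VariantCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        genes: List[str] = []
        seen: Dict[str, int] = {}
        gene_of = []
        for g in df["gene"]:
            if g not in seen:
                seen[g] = len(genes)
                genes.append(g)
            gene_of.append(seen[g])
        variants = list(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))
        return cls(variants, genes, gene_of)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VariantCatalog":
        genes: List[str] = []
        seen: Dict[str, int] = {}
        gene_of = []
        for g in df["gene"]:
            if g not in seen:
                seen[g] = len(genes)
                genes.append(g)
            gene_of.append(seen[g])
        variants = list(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))
        return cls(variants, genes, gene_of)


@dataclass
class IndividualEncoding:
    """One individual's three bit vectors tied to a catalog.

    ``v_hom`` and ``v_het`` are mutually exclusive per site: a site is
    hom-alt or het, never both.  ``v_gene[g]`` is 1 iff some variant of
    gene ``g`` is carried (hom or het).
    """

    id: str
    v_hom: np.ndarray
    v_het: np.ndarray
    v_gene: np.ndarray

    def __post_init__(self):
        self.v_hom = np.asarray(self.v_hom, dtype=np.uint8)
        self.v_het = np.asarray(self.v_het, dtype=np.uint8)
        self.v_gene = np.asarray(self.v_gene, dtype=np.uint8)
        if len(self.v_hom) != len(self.v_het):
            raise ValueError("v_hom and v_het lengths differ")
        if np.any(self.v_hom & self.v_het):
            bad = int(np.flatnonzero(self.v_hom & self.v_het)[0])
            raise ValueError(
                f"individual {self.id}: site {bad} marked both hom-alt and het"
            )

    @classmethod
    def from_genotypes(cls, ind_id: str, v_hom, v_het, catalog: VariantCatalog) -> "IndividualEncoding":
        v_hom = np.asarray(v_hom, dtype=np.uint8)
        v_het = np.asarray(v_het, dtype=np.uint8)
        v_gene = derive_gene_vector(v_hom, v_het, catalog)
        return cls(ind_id, v_hom, v_het, v_gene)

    @property
    def n_rare_variants(self) -> int:
        """Number of rare variants carried (het or hom)."""
        return int(np.count_nonzero(self.v_hom | self.v_het))

    @property
    def n_rare_genes(self) -> int:
        return int(np.count_nonzero(self.v_gene))


def derive_gene_vector(v_hom: np.ndarray, v_het: np.ndarray,
                       catalog: VariantCatalog) -> np.ndarray:
    carried = (v_hom | v_het).astype(bool)
    v_gene = np.zeros(catalog.n_genes, dtype=np.uint8)
    if carried.any():
        np.maximum.at(v_gene, catalog.gene_of[carried], 1)
    return v_gene


class GenotypeError(ValueError):
    """Malformed genotype record, with position context."""


def _annotation_lookup(sidecar: Optional[pd.DataFrame]):
    if sidecar is None:
        return None
    table: Dict[VariantKey, VariantAnnotation] = {}
    for row in sidecar.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        table[key] = VariantAnnotation(float(row.AF), str(row.IMPACT))
    return table


def encode_individual(
    vcf_path,
    catalog: VariantCatalog,
    sample: Optional[str] = None,
    af_threshold: float = 0.01,
    impacts: Iterable[str] = DEFAULT_IMPACTS,
    annotations: Optional[pd.DataFrame] = None,
    af_key: str = "AF",
    impact_key: str = "IMPACT",
    individual_id: Optional[str] = None,
) -> IndividualEncoding:
    """Encode one sample of a VCF into the three bit vectors.

    Annotations come from INFO fields (``af_key``/``impact_key``, possibly
    comma-separated per alt) or from a sidecar TSV keyed by variant
    (columns chrom, pos, ref, alt, AF, IMPACT).  Multi-allelic records are
    split into per-alt biallelic keys.  Variants absent from the catalog
    are ignored with a logged warning; missing genotypes contribute no
    bits.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if sample is None:
        if len(samples) != 1:
            raise ValueError(
                f"{vcf_path}: multi-sample VCF, specify sample (have {samples})"
            )
        sample = samples[0]
    if sample not in samples:
        raise ValueError(f"sample {sample!r} not in {vcf_path}")
    si = samples.index(sample)

    sidecar = _annotation_lookup(annotations)

    v_hom = np.zeros(catalog.n_variants, dtype=np.uint8)
    v_het = np.zeros(catalog.n_variants, dtype=np.uint8)

    for rec in vcf:
        gt = rec.genotypes[si]
        alleles = gt[:-1]  # last entry is phasing flag
        if len(alleles) != 2:
            raise GenotypeError(
                f"{rec.CHROM}:{rec.POS}: expected diploid GT, got {gt}"
            )
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            key = (str(rec.CHROM), int(rec.POS), str(rec.REF), str(alt))
            k = catalog.index_of(key)
            if k is None:
                logger.warning("variant %s:%s %s>%s not in catalog; ignored",
                               rec.CHROM, rec.POS, rec.REF, alt)
                continue
            if sidecar is not None:
                ann = sidecar.get(key)
            else:
                ann = _info_annotation(rec, alt_idx, af_key, impact_key)
            if ann is None:
                logger.warning("variant %s:%s %s>%s lacks annotation; excluded",
                               rec.CHROM, rec.POS, rec.REF, alt)
                continue
            if not rare_functional_filter(ann, af_threshold, impacts):
                continue
            dose = sum(1 for a in alleles if a == alt_idx)
            if any(a < 0 for a in alleles):
                continue  # missing genotype -> absent
            if dose == 2:
                v_hom[k] = 1
            elif dose == 1:
                v_het[k] = 1
    return IndividualEncoding.from_genotypes(
        individual_id or sample, v_hom, v_het, catalog
    )


def _info_annotation(rec, alt_idx: int, af_key: str, impact_key: str):
    af = rec.INFO.get(af_key)
    impact = rec.INFO.get(impact_key)
    if af is None or impact is None:
        return None
    if isinstance(af, (tuple, list)):
        af = af[alt_idx - 1]
    if isinstance(impact, (tuple, list)):
        impact = impact[alt_idx - 1]
    elif isinstance(impact, str) and "," in impact:
        impact = impact.split(",")[alt_idx - 1]
    return VariantAnnotation(float(af), str(impact))


def decode_candidates(
    result_bits: np.ndarray,
    catalog: VariantCatalog,
    mode: str = "variant",
):
    """Map a reconstructed indicator vector back to keys, in catalog order."""
    bits = np.asarray(result_bits).astype(bool)
    if mode == "variant":
        if len(bits) != catalog.n_variants:
            raise ValueError(
                f"result length {len(bits)} != catalog variants {catalog.n_variants}"
            )
        return [catalog.variants[i] for i in np.flatnonzero(bits)]
    if mode == "gene":
        if len(bits) != catalog.n_genes:
            raise ValueError(
                f"result length {len(bits)} != catalog genes {catalog.n_genes}"
            )
        return [catalog.genes[i] for i in np.flatnonzero(bits)]
    raise ValueError(f"mode must be 'variant' or 'gene', got {mode!r}")
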