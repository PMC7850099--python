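"""Deterministic synthetic catalogs and Mendelian family cohorts.

The generator emulates the data regime the secure operations target:
biallelic rare variants grouped into genes, per-individual genotypes with
mutually exclusive het / hom-alt states, Mendelian allele transmission
inside a nuclear family (each child draws one allele from each parent),
and optionally a *planted* causal configuration for one of the three
inheritance models so that recovery can be checked against the plaintext
oracles.

Defaults describe a small but structurally realistic cohort: 200 genes ×
5 variants (1000 sites), per-allele carrier frequency 1% (rare), a trio
(two parents, one affected child).  It does not model linkage, realistic
site-frequency spectra or sequencing error; see the package docs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .encoding import IndividualEncoding, VariantCatalog, derive_gene_vector
from .protocols import CohortSpec, Role

__all__ = [
    "SyntheticCohortSpec",
    "generate_catalog",
    "generate_annotations",
    "generate_cohort",
    "plant_causal",
    "write_vcf",
    "write_ped",
    "read_ped",
]

_BASES = np.array(list("ACGT"))

PLANTABLE_MODELS = ("none", "recessive", "dominant", "comphet")


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_genes: int = 200
    variants_per_gene: int = 5
    carrier_frequency: float = 0.01  # per-allele Bernoulli rate
    n_affected: int = 1
    n_unaffected: int = 0
    n_others: int = 0
    planted_model: str = "none"
    planted_sites: Optional[Tuple[int, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0.0 <= self.carrier_frequency <= 1.0):
            raise ValueError("carrier_frequency must be in [0, 1]")
        if self.planted_model not in PLANTABLE_MODELS:
            raise ValueError(f"unknown planted model {self.planted_model!r}")

    @property
    def n_variants(self) -> int:
        return self.n_genes * self.variants_per_gene

    @classmethod
    def from_file(cls, path) -> "SyntheticCohortSpec":
        """Load a spec from a YAML (or JSON) mapping of field names."""
        import yaml

        with open(path) as fh:
            obj = yaml.safe_load(fh)
        if not isinstance(obj, dict):
            raise ValueError(f"{path}: expected a mapping of spec fields")
        if "planted_sites" in obj and obj["planted_sites"] is not None:
            obj["planted_sites"] = tuple(obj["planted_sites"])
        return cls(**obj)


def generate_catalog(n_genes: int, variants_per_gene: int, seed: int = 0) -> VariantCatalog:
    """Synthetic catalog: genes GENE0001..., variants chrN:pos:ref>alt."""
    rng = np.random.default_rng(seed)
    n = n_genes * variants_per_gene
    chroms = [f"chr{(g % 22) + 1}" for g in range(n_genes) for _ in range(variants_per_gene)]
    # strictly increasing positions per chromosome guarantee unique keys
    pos = np.zeros(n, dtype=np.int64)
    counters: Dict[str, int] = {}
    steps = rng.integers(1, 1000, size=n)
    for i, c in enumerate(chroms):
        counters[c] = counters.get(c, 0) + int(steps[i])
        pos[i] = counters[c]
    refs = _BASES[rng.integers(0, 4, size=n)]
    alt_off = rng.integers(1, 4, size=n)
    alts = _BASES[(np.searchsorted(_BASES, refs) + alt_off) % 4]
    genes = [f"GENE{g + 1:04d}" for g in range(n_genes)]
    gene_of = np.repeat(np.arange(n_genes), variants_per_gene)
    variants = list(zip(chroms, pos.tolist(), refs.tolist(), alts.tolist()))
    return VariantCatalog(variants, genes, gene_of)


def generate_annotations(
    catalog: VariantCatalog,
    seed: int = 0,
    af_range: Tuple[float, float] = (1e-5, 0.009),
    impacts: Sequence[str] = ("HIGH", "MODERATE"),
) -> pd.DataFrame:
    """Sidecar annotation table; defaults make every variant pass the
    1%-AF HIGH/MODERATE rare-functional filter."""
    rng = np.random.default_rng(seed)
    af = rng.uniform(af_range[0], af_range[1], size=catalog.n_variants)
    imp = rng.choice(list(impacts), size=catalog.n_variants)
    df = pd.DataFrame(catalog.variants, columns=["chrom", "pos", "ref", "alt"])
    df["AF"] = af
    df["IMPACT"] = imp
    df["GENE"] = [catalog.genes[g] for g in catalog.gene_of]
    return df


def _genotype_from_alleles(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    dose = a.astype(np.uint8) + b.astype(np.uint8)
    return (dose == 2).astype(np.uint8), (dose == 1).astype(np.uint8)


def generate_cohort(
    spec: SyntheticCohortSpec,
    catalog: Optional[VariantCatalog] = None,
) -> Tuple[Dict[str, IndividualEncoding], CohortSpec, VariantCatalog]:
    """Draw a family cohort with Mendelian transmission.

    Parents' haplotypes are per-variant Bernoulli(carrier_frequency)
    draws; every child (affected or unaffected sibling) inherits one
    uniformly chosen allele from each parent; unrelated "others" are drawn
    independently.  Returns encodings, the role assignment, the catalog.
    """
    if catalog is None:
        catalog = generate_catalog(spec.n_genes, spec.variants_per_gene, spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    n = catalog.n_variants
    f = spec.carrier_frequency

    def _haplos() -> Tuple[np.ndarray, np.ndarray]:
        return (rng.random(n) < f), (rng.random(n) < f)

    mother_h = _haplos()
    father_h = _haplos()
    genotypes: Dict[str, Tuple[np.ndarray, np.ndarray]] = {
        "mother": mother_h,
        "father": father_h,
    }
    members: List[Tuple[str, Role]] = [("mother", Role.MOTHER), ("father", Role.FATHER)]

    def _child() -> Tuple[np.ndarray, np.ndarray]:
        from_m = np.where(rng.random(n) < 0.5, mother_h[0], mother_h[1])
        from_f = np.where(rng.random(n) < 0.5, father_h[0], father_h[1])
        return from_m, from_f

    for i in range(spec.n_affected):
        mid = f"affected_{i + 1}"
        genotypes[mid] = _child()
        members.append((mid, Role.AFFECTED_SIB))
    for i in range(spec.n_unaffected):
        mid = f"unaffected_{i + 1}"
        genotypes[mid] = _child()
        members.append((mid, Role.UNAFFECTED_SIB))
    for i in range(spec.n_others):
        mid = f"other_{i + 1}"
        genotypes[mid] = _haplos()
        members.append((mid, Role.OTHER))

    cohort = CohortSpec(members)
    encodings: Dict[str, IndividualEncoding] = {}
    for mid, (a, b) in genotypes.items():
        v_hom, v_het = _genotype_from_alleles(a, b)
        encodings[mid] = IndividualEncoding.from_genotypes(mid, v_hom, v_het, catalog)

    if spec.planted_model != "none":
        sites = spec.planted_sites
        if sites is None:
            if spec.planted_model == "comphet":
                if catalog.gene_members()[0].size < 2:
                    raise ValueError("comphet planting needs a gene with >= 2 variants")
                g0 = catalog.gene_members()[0]
                sites = (int(g0[0]), int(g0[1]))
            else:
                sites = (0,)
        encodings = plant_causal(encodings, cohort, spec.planted_model, sites, catalog)
    return encodings, cohort, catalog


def plant_causal(
    encodings: Dict[str, IndividualEncoding],
    cohort: CohortSpec,
    model: str,
    sites: Sequence[int],
    catalog: VariantCatalog,
) -> Dict[str, IndividualEncoding]:
    """Overwrite genotypes at the chosen site(s) with a causal configuration.

    recessive: affected 1/1, parents 0/1, unaffected and others carry
    nothing at the site; dominant: affected 0/1, everyone else 0/0;
    comphet: mother het at site A only, father het at site B only,
    affected het at both, unaffected/others het at neither.  Idempotent.
    """
    model = model.lower()
    sites = tuple(int(s) for s in sites)
    for s in sites:
        if not (0 <= s < catalog.n_variants):
            raise ValueError(f"site {s} outside catalog")
    out: Dict[str, IndividualEncoding] = {}
    roles = dict(cohort.members)

    if model == "comphet":
        if len(sites) != 2:
            raise ValueError("comphet planting needs exactly two sites")
        a, b = sites
        if catalog.gene_of[a] != catalog.gene_of[b]:
            raise ValueError("comphet sites must lie in the same gene")

    for mid, enc in encodings.items():
        v_hom = enc.v_hom.copy()
        v_het = enc.v_het.copy()
        role = roles.get(mid, Role.OTHER)
        if model == "recessive":
            (s,) = sites[:1]
            if role == Role.AFFECTED_SIB:
                v_hom[s], v_het[s] = 1, 0
            elif role in (Role.MOTHER, Role.FATHER):
                v_hom[s], v_het[s] = 0, 1
            else:
                v_hom[s], v_het[s] = 0, 0
        elif model == "dominant":
            (s,) = sites[:1]
            if role == Role.AFFECTED_SIB:
                v_hom[s], v_het[s] = 0, 1
            else:
                v_hom[s], v_het[s] = 0, 0
        elif model == "comphet":
            a, b = sites
            if role == Role.MOTHER:
                v_hom[[a, b]] = 0
                v_het[a], v_het[b] = 1, 0
            elif role == Role.FATHER:
                v_hom[[a, b]] = 0
                v_het[a], v_het[b] = 0, 1
            elif role == Role.AFFECTED_SIB:
                v_hom[[a, b]] = 0
                v_het[a], v_het[b] = 1, 1
            else:
                v_hom[[a, b]] = 0
                v_het[[a, b]] = 0
        else:
            raise ValueError(f"cannot plant model {model!r}")
        out[mid] = IndividualEncoding.from_genotypes(mid, v_hom, v_het, catalog)
    return out


# ---------------------------------------------------------------------------
# VCF / PED output
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Max allele frequency across sub-populations">
##INFO=<ID=IMPACT,Number=A,Type=String,Description="Predicted impact class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    encodings: Dict[str, IndividualEncoding],
    catalog: VariantCatalog,
    annotations: pd.DataFrame,
    path,
) -> None:
    """Emit a multi-sample VCF v4.2 with GT and AF/IMPACT/GENE INFO fields.

    Round-trips with :func:`genoshare.encoding.encode_individual` when all
    annotations pass the rare-functional filter.
    """
    samples = list(encodings)
    ann = annotations.set_index(["chrom", "pos", "ref", "alt"])
    chroms = sorted({c for c, *_ in catalog.variants},
                    key=lambda c: (len(c), c))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for k, (chrom, pos, ref, alt) in enumerate(catalog.variants):
            if not any(encodings[s].v_hom[k] or encodings[s].v_het[k] for s in samples):
                continue  # sites nobody carries are left out entirely
            row = ann.loc[(chrom, pos, ref, alt)]
            info = f"AF={float(row.AF):.6g};IMPACT={row.IMPACT};GENE={row.GENE}"
            gts = []
            for s in samples:
                if encodings[s].v_hom[k]:
                    gts.append("1/1")
                elif encodings[s].v_het[k]:
                    gts.append("0/1")
                else:
                    gts.append("0/0")
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t"
                     + "\t".join(gts) + "\n")


_ROLE_TO_PED = {
    Role.MOTHER: ("2", "1"),
    Role.FATHER: ("1", "1"),
    Role.AFFECTED_SIB: ("0", "2"),
    Role.UNAFFECTED_SIB: ("0", "1"),
    Role.OTHER: ("0", "1"),
}


def write_ped(cohort: CohortSpec, path, fam_id: str = "FAM1") -> None:
    """PED-like role file: famID indID fatherID motherID sex affected role."""
    mother = cohort.mother or "0"
    father = cohort.father or "0"
    with open(path, "w") as fh:
        for mid, role in cohort.members:
            sex, aff = _ROLE_TO_PED[role]
            if role in (Role.AFFECTED_SIB, Role.UNAFFECTED_SIB):
                fa, mo = father, mother
            else:
                fa, mo = "0", "0"
            fam = fam_id if role != Role.OTHER else "0"
            fh.write(f"{fam}\t{mid}\t{fa}\t{mo}\t{sex}\t{aff}\t{role.value}\n")


def read_ped(path) -> CohortSpec:
    members: List[Tuple[str, Role]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"malformed PED line: {line!r}")
            members.append((fields[1], Role(fields[6])))
    return CohortSpec(members)
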