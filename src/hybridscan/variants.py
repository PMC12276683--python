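"""Core domain types shared by every pipeline stage.

Genotypes are stored as small integer codes per sample:
``0`` hom_ref, ``1`` het, ``2`` hom_alt, ``-1`` missing.  All internal
coordinates are 0-based half-open; the VCF/GFF boundary converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: variant type labels
SNP, INDEL, SV = "SNP", "INDEL", "SV"

_NUC = frozenset("ACGT")


class VariantDataError(ValueError):
    """Raised for malformed or inconsistent variant data."""


def classify_variant(ref: str, alt: str) -> str:
    """Classify a biallelic record as SNP, INDEL or SV by allele lengths.

    Length difference 1-49 bp is an INDEL; 50 bp or more is a structural
    variant (the conventional >=50 bp boundary).
    """
    if not ref or not alt:
        raise VariantDataError("empty allele")
    if not (_NUC.issuperset(ref) and _NUC.issuperset(alt)):
        raise VariantDataError(f"non-nucleotide allele: {ref!r}/{alt!r}")
    if ref == alt:
        raise VariantDataError(f"ref == alt ({ref!r})")
    if len(ref) == 1 and len(alt) == 1:
        return SNP
    size = abs(len(alt) - len(ref))
    if size == 0:
        # equal-length multi-nucleotide substitution; rare, treated as INDEL-class
        return INDEL
    return SV if size >= 50 else INDEL


@dataclass
class VariantRecord:
    """One biallelic site with per-sample genotype codes."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    genotypes: np.ndarray  # int8 codes, length == n_samples
    source: str = "SR"  # SR | Pan | Merged
    vtype: str = field(default="")
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantDataError(f"pos must be >= 1, got {self.pos}")
        if not self.vtype:
            self.vtype = classify_variant(self.ref, self.alt)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def copy(self) -> "VariantRecord":
        return VariantRecord(
            self.chrom, self.pos, self.ref, self.alt,
            self.genotypes.copy(), self.source, self.vtype, self.id,
        )


class VariantSet:
    """An ordered collection of biallelic records over one sample cohort.

    Records are kept sorted by ``(chrom, pos, ref, alt)`` and duplicate keys
    are forbidden; every record's genotype vector matches ``samples``.
    """

    def __init__(self, samples: Sequence[str], records: Iterable[VariantRecord],
                 sort: bool = True) -> None:
        self.samples = list(samples)
        recs = list(records)
        n = len(self.samples)
        for r in recs:
            if len(r.genotypes) != n:
                raise VariantDataError(
                    f"record {r.key}: {len(r.genotypes)} genotypes for {n} samples")
        if sort:
            recs.sort(key=lambda r: r.key)
        keys = [r.key for r in recs]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise VariantDataError(f"duplicate variant key {k}")
                seen.add(k)
        self.records = recs

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self) -> list[tuple[str, int, str, str]]:
        return [r.key for r in self.records]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def genotype_matrix(self) -> np.ndarray:
        """(n_records, n_samples) int8 matrix of genotype codes."""
        if not self.records:
            return np.zeros((0, len(self.samples)), dtype=np.int8)
        return np.vstack([r.genotypes for r in self.records])

    def vtypes(self) -> np.ndarray:
        return np.array([r.vtype for r in self.records])

    def positions(self) -> np.ndarray:
        return np.array([r.pos for r in self.records], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([r.chrom for r in self.records])

    def subset_records(self, mask: np.ndarray) -> "VariantSet":
        recs = [r for r, keep in zip(self.records, mask) if keep]
        return VariantSet(self.samples, recs, sort=False)

    def is_sorted(self) -> bool:
        ks = self.keys()
        return all(ks[i] <= ks[i + 1] for i in range(len(ks) - 1))


@dataclass
class PopMap:
    """sample -> population label mapping."""

    labels: dict[str, str]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.labels.values():
            seen.setdefault(v, None)
        return list(seen)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.labels.items() if p == pop]

    def indices_of(self, pop: str, samples: Sequence[str]) -> np.ndarray:
        return np.array([i for i, s in enumerate(samples)
                         if self.labels.get(s) == pop], dtype=np.intp)

    def validate(self, samples: Sequence[str]) -> None:
        missing = [s for s in samples if s not in self.labels]
        if missing:
            raise VariantDataError(f"samples without population label: {missing[:5]}")


@dataclass
class GeneModel:
    """A transcript with exon and CDS intervals, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int  # transcript span start
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for i in range(len(self.exons) - 1):
            if self.exons[i][1] > self.exons[i + 1][0]:
                raise VariantDataError(f"{self.gene_id}: overlapping exons")
        for s, e in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in self.exons):
                raise VariantDataError(f"{self.gene_id}: CDS [{s},{e}) outside exons")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end
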