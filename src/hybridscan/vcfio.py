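"""Reading and writing the standard formats the pipeline touches.

VCF 4.2 with a GT-only FORMAT is the interchange format for genotype call
sets; GFF3 or BED carries gene models; a two-column TSV carries the
sample -> population map.  Reading goes through cyvcf2 / gffutils; the
GT-only writer is a small text emitter whose output is round-trip checked
against third-party readers in the test-suite.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .variants import (
    MISSING, GeneModel, PopMap, VariantDataError, VariantRecord, VariantSet,
)

__version__ = "0.1.0"


@dataclass
class ReadReport:
    """Counts of records dropped while reading a VCF."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_symbolic: int = 0
    n_spanning_del: int = 0
    n_filtered: int = 0

    @property
    def n_dropped(self) -> int:
        return (self.n_multiallelic + self.n_symbolic + self.n_spanning_del
                + self.n_filtered)


def _code_genotypes(gts: list) -> np.ndarray:
    """cyvcf2 ``genotypes`` entries -> int8 codes; any half-missing call
    ('./1') is treated as missing."""
    out = np.empty(len(gts), dtype=np.int8)
    for i, g in enumerate(gts):
        alleles = g[:-1]
        if any(a < 0 for a in alleles) or len(alleles) != 2:
            out[i] = MISSING
        else:
            out[i] = alleles[0] + alleles[1]
    return out


def read_variant_table(path: str, allow_filter: bool = True,
                       expected_samples: Optional[Sequence[str]] = None,
                       source: str = "SR") -> tuple[VariantSet, ReadReport]:
    """Read a VCF into a :class:`VariantSet`, dropping multi-allelic,
    symbolic-ALT and spanning-deletion records (counted in the report).

    With ``allow_filter=False``, records whose FILTER is set and not PASS
    are dropped and counted too.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise VariantDataError(f"{path}: no samples / GT field")
    if expected_samples is not None and samples != list(expected_samples):
        raise VariantDataError(
            f"{path}: sample header mismatch (got {samples[:3]}..., "
            f"expected {list(expected_samples)[:3]}...)")
    report = ReadReport()
    records = []
    for lineno, v in enumerate(vcf, start=1):
        try:
            alts = v.ALT
            if len(alts) != 1:
                report.n_multiallelic += 1
                continue
            alt = alts[0]
            if alt is None or any(ch in alt for ch in "<>[]."):
                report.n_symbolic += 1
                continue
            if alt == "*" or "*" in alt:
                report.n_spanning_del += 1
                continue
            if not allow_filter and v.FILTER is not None:
                report.n_filtered += 1
                continue
            gt = _code_genotypes(v.genotypes)
            records.append(VariantRecord(v.CHROM, v.POS, v.REF, alt, gt,
                                         source=source,
                                         id=v.ID or "."))
        except VariantDataError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise VariantDataError(f"{path}: malformed record #{lineno}: {exc}")
    report.n_kept = len(records)
    return VariantSet(samples, records), report


def write_variant_table(vs: VariantSet, path: str, source_tag: str = "") -> None:
    """Write a GT-only VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=hybridscan-{__version__}\n")
        if source_tag:
            fh.write(f"##hybridscan_source={source_tag}\n")
        chroms: dict[str, None] = {}
        for r in vs.records:
            chroms.setdefault(r.chrom, None)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vs.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for r in vs.records:
            gts = "\t".join(gt_str[int(g)] for g in r.genotypes)
            fh.write(f"{r.chrom}\t{r.pos}\t{r.id}\t{r.ref}\t{r.alt}\t.\tPASS\t"
                     f".\tGT\t{gts}\n")


def read_popmap(path: str) -> PopMap:
    """Two-column TSV (sample, population), optional header."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "sample":
                continue
            if len(parts) < 2:
                raise VariantDataError(f"{path}: bad popmap line {line!r}")
            labels[parts[0]] = parts[1]
    return PopMap(labels)


def write_popmap(pm: PopMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, p in pm.labels.items():
            fh.write(f"{s}\t{p}\n")


def read_gene_models(path: str) -> list[GeneModel]:
    """Parse gene models from GFF3 (via gffutils) or BED12.

    GFF3 1-based inclusive coordinates become 0-based half-open internally.
    """
    if path.endswith((".bed", ".bed12")):
        return _read_bed12(path)
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    kinds = {f for f in db.featuretypes()}
    top = "gene" if "gene" in kinds else ("mRNA" if "mRNA" in kinds else None)
    if top is None:
        raise VariantDataError(f"{path}: no gene/mRNA features")
    for g in db.features_of_type(top, order_by="start"):
        exons = [(f.start - 1, f.end) for f in db.children(g, featuretype="exon",
                                                           order_by="start")]
        cds = [(f.start - 1, f.end) for f in db.children(g, featuretype="CDS",
                                                         order_by="start")]
        if not exons:
            exons = [(g.start - 1, g.end)]
        gid = g.attributes.get("ID", [g.id])[0]
        genes.append(GeneModel(gid, g.seqid, g.strand, g.start - 1, g.end,
                               exons=exons, cds=cds))
    return genes


def _read_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
            strand = f[5] if len(f) > 5 else "+"
            exons = [(start, end)]
            cds: list[tuple[int, int]] = []
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                thick_s, thick_e = int(f[6]), int(f[7])
                if thick_e > thick_s:
                    for xs, xe in exons:
                        s, e = max(xs, thick_s), min(xe, thick_e)
                        if e > s:
                            cds.append((s, e))
            genes.append(GeneModel(name, chrom, strand, start, end,
                                   exons=exons, cds=cds))
    return genes


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Emit gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\thybridscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{a}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\thybridscan\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\thybridscan\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mid}.exon{i};Parent={mid}\n")
            phase = 0
            cds = g.cds if g.strand == "+" else list(reversed(g.cds))
            for i, (s, e) in enumerate(cds, 1):
                fh.write(f"{g.chrom}\thybridscan\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t{phase}\tID={mid}.cds{i};Parent={mid}\n")
                phase = (3 - ((e - s - phase) % 3)) % 3
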