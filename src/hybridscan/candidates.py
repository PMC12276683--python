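"""Candidate-gene evidence integration and coding-consequence screening.

Selection-scan gene sets and a differential-expression gene list are
combined by exact set algebra (upset-style intersection counts); exonic
SNPs are screened for codon-level consequences against the reference
sequence; per-population genotype-class percentages and a region
dosage matrix support inspection of a focal locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .variants import (
    HET, HOM_ALT, HOM_REF, MISSING, GeneModel, PopMap, VariantRecord, VariantSet,
)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class ConsequenceCall:
    variant_key: tuple
    gene: str
    consequence: str
    codon_change: str = ""
    aa_change: str = ""


@dataclass
class CandidateTable:
    """Per-gene evidence flags and upset-style intersection counts."""

    genes: list
    flags: dict            # gene -> {evidence_name: bool}
    intersections: dict    # frozenset of evidence names -> count
    joint_candidates: list

    def to_rows(self) -> list[dict]:
        return [{"gene": g, **self.flags[g]} for g in self.genes]


def intersect_candidates(evidence_sets: dict[str, set], deg_set: set,
                         min_evidence: int = 1) -> CandidateTable:
    """Combine selection-evidence gene sets with the DEG list.

    Joint candidates are genes in the DEG set and in at least
    ``min_evidence`` selection-evidence sets.
    """
    import warnings

    all_sets = dict(evidence_sets)
    all_sets["DEG"] = set(deg_set)
    if not deg_set:
        warnings.warn("empty DEG set: no joint candidates possible")
    universe: dict[str, None] = {}
    for s in all_sets.values():
        for gid in sorted(s):
            universe.setdefault(gid, None)
    genes = list(universe)
    flags = {g: {name: g in s for name, s in all_sets.items()} for g in genes}
    # exact upset counts: genes grouped by their full membership pattern
    intersections: dict[frozenset, int] = {}
    for g in genes:
        pat = frozenset(name for name, v in flags[g].items() if v)
        intersections[pat] = intersections.get(pat, 0) + 1
    joint = [g for g in genes
             if flags[g]["DEG"]
             and sum(flags[g][n] for n in evidence_sets) >= min_evidence]
    return CandidateTable(genes, flags, intersections, joint)


def _cds_offset(gm: GeneModel, pos0: int) -> Optional[int]:
    """Offset of a genomic position within the spliced CDS (plus-strand order)."""
    off = 0
    for s, e in gm.cds:
        if s <= pos0 < e:
            return off + (pos0 - s)
        off += e - s
    return None


def spliced_cds(gm: GeneModel, seq: str) -> str:
    """The coding sequence of a gene model in translation order."""
    cds = "".join(seq[s:e] for s, e in gm.cds)
    return revcomp(cds) if gm.strand == "-" else cds


def translate(cds: str) -> str:
    return "".join(CODON_TABLE.get(cds[i:i + 3], "X")
                   for i in range(0, len(cds) - len(cds) % 3, 3))


def coding_consequence(v: VariantRecord, gm: GeneModel,
                       ref_seq: str, flank: int = 5_000) -> ConsequenceCall:
    """Classify one variant against one gene model.

    SNPs in CDS get codon-level calls (honoring strand and frame); other
    positions are classified positionally.  INDEL/SV records inside CDS are
    reported without frame analysis.
    """
    pos0 = v.pos - 1
    if ref_seq[pos0:pos0 + len(v.ref)].upper() != v.ref.upper():
        raise ValueError(f"{v.chrom}:{v.pos} REF disagrees with reference sequence")
    if not (gm.start - flank <= pos0 < gm.end + flank):
        return ConsequenceCall(v.key, gm.gene_id, "intergenic")
    if pos0 < gm.start or pos0 >= gm.end:
        before = pos0 < gm.start
        upstream = before if gm.strand == "+" else not before
        return ConsequenceCall(v.key, gm.gene_id,
                               "upstream" if upstream else "downstream")
    in_exon = any(s <= pos0 < e for s, e in gm.exons)
    if not in_exon:
        return ConsequenceCall(v.key, gm.gene_id, "intronic")
    off = _cds_offset(gm, pos0)
    if off is None:
        return ConsequenceCall(v.key, gm.gene_id, "exonic_noncoding")
    if v.vtype != "SNP":
        return ConsequenceCall(v.key, gm.gene_id, "coding_indel_unclassified")
    cds_seq = spliced_cds(gm, ref_seq)
    if gm.strand == "-":
        t_off = len(cds_seq) - 1 - off
        t_alt = revcomp(v.alt)
    else:
        t_off = off
        t_alt = v.alt
    codon_i = t_off // 3
    within = t_off % 3
    codon = cds_seq[3 * codon_i:3 * codon_i + 3]
    if len(codon) < 3:
        return ConsequenceCall(v.key, gm.gene_id, "exonic_noncoding")
    new_codon = codon[:within] + t_alt + codon[within + 1:]
    aa_ref = CODON_TABLE.get(codon, "X")
    aa_alt = CODON_TABLE.get(new_codon, "X")
    if aa_ref == aa_alt:
        cls = "synonymous"
    elif aa_alt == "*":
        cls = "stop_gained"
    elif aa_ref == "*":
        cls = "stop_lost"
    else:
        cls = "missense"
    return ConsequenceCall(v.key, gm.gene_id, cls,
                           codon_change=f"{codon}>{new_codon}",
                           aa_change=f"{aa_ref}{codon_i + 1}{aa_alt}")


def population_genotype_report(site_key: tuple, vs: VariantSet,
                               popmap: PopMap) -> dict[str, dict]:
    """Per-population genotype-class percentages (plus raw counts) at a site."""
    rec = next((r for r in vs.records if r.key == tuple(site_key)), None)
    if rec is None:
        raise KeyError(f"site {site_key} not present in the variant set")
    out = {}
    for pop in popmap.populations():
        idx = popmap.indices_of(pop, vs.samples)
        g = rec.genotypes[idx]
        n = len(g)
        counts = {"hom_ref": int((g == HOM_REF).sum()),
                  "het": int((g == HET).sum()),
                  "hom_alt": int((g == HOM_ALT).sum()),
                  "missing": int((g == MISSING).sum())}
        out[pop] = {"n": n, "counts": counts,
                    "percent": {k: 100.0 * v / n for k, v in counts.items()}}
    return out


def haplotype_matrix(region: tuple[str, int, int], vs: VariantSet,
                     popmap: PopMap, order_by_population: bool = True
                     ) -> tuple[np.ndarray, list, list]:
    """Dosage matrix (samples x sites) for a 0-based half-open region.

    Returns (matrix with -1 for missing, row sample names grouped by
    population, column site keys).
    """
    import warnings

    chrom, start, end = region
    recs = [r for r in vs.records
            if r.chrom == chrom and start <= r.pos - 1 < end]
    if order_by_population:
        rows: list[str] = []
        for pop in popmap.populations():
            rows.extend(s for s in vs.samples if popmap.labels.get(s) == pop)
        rows.extend(s for s in vs.samples if s not in set(rows))
    else:
        rows = list(vs.samples)
    if not recs:
        warnings.warn(f"no sites in region {chrom}:{start}-{end}")
        return np.zeros((len(rows), 0), dtype=np.int8), rows, []
    ridx = [vs.samples.index(s) for s in rows]
    mat = np.stack([r.genotypes[ridx] for r in recs], axis=1)
    return mat, rows, [r.key for r in recs]


def region_heterozygosity(mat: np.ndarray) -> float:
    """Mean column-wise heterozygote fraction of a dosage matrix."""
    if mat.size == 0:
        return float("nan")
    ok = mat != MISSING
    het = (mat == HET) & ok
    with np.errstate(invalid="ignore"):
        col = het.sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
    return float(col.mean())
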