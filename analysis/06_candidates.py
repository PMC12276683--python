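#!/usr/bin/env python
"""Integrate the selection evidence with expression to nominate candidates.

Joint candidates are differentially expressed genes that also fall in at
least one selection-evidence set (Fst, CLR or EigenGWAS).  For the gene
over the sweep locus the script screens exonic SNPs for coding
consequences, reports per-population genotype-class percentages at the
top exonic site, and exports the dosage matrix of the 150 kb flanking
region.
"""

import argparse
import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from hybridscan.candidates import (
    coding_consequence, haplotype_matrix, intersect_candidates,
    population_genotype_report,
)
from hybridscan.vcfio import read_gene_models, read_popmap, read_variant_table
from pyfaidx import Fasta


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim-dir", default="scratch/sim")
    args = ap.parse_args()

    vs, _ = read_variant_table(f"{args.sim_dir}/merged_qc.vcf")
    pm = read_popmap(f"{args.sim_dir}/popmap.tsv")
    genes = {g.gene_id: g for g in
             read_gene_models(f"{args.sim_dir}/genes.gff3")}
    ref = {k: str(v[:]) for k, v in Fasta(f"{args.sim_dir}/ref.fa").items()}
    truth = json.load(open(f"{args.sim_dir}/truth.json"))
    scan = json.load(open("results/04_scan.json"))
    egw = json.load(open("results/05_eigengwas.json"))

    deg = {gid for gid, flag in truth["deg"].items() if flag}
    evidence = {"fst": set(scan["fst_genes"]), "xpclr": set(scan["clr_genes"]),
                "eigengwas": set(egw["annotated_genes"])}
    table = intersect_candidates(evidence, deg)

    with open("results/06_candidates.tsv", "w") as fh:
        names = list(evidence) + ["DEG"]
        fh.write("gene\t" + "\t".join(names) + "\n")
        for row in table.to_rows():
            fh.write(row["gene"] + "\t"
                     + "\t".join(str(int(row[n])) for n in names) + "\n")
    with open("results/06_upset_counts.tsv", "w") as fh:
        fh.write("combination\tcount\n")
        for pat, cnt in sorted(table.intersections.items(),
                               key=lambda kv: -kv[1]):
            fh.write(("+".join(sorted(pat)) or "none") + f"\t{cnt}\n")

    # exonic screen of the gene over the sweep locus
    sweep = truth["sweep_loci"][0]
    sweep_gene = next(
        (g for g in genes.values()
         if g.chrom == sweep["chrom"] and g.start <= sweep["pos"] - 1 < g.end),
        None)
    focal_rows = []
    if sweep_gene is not None:
        for rec in vs.records:
            if rec.chrom != sweep_gene.chrom or rec.vtype != "SNP":
                continue
            pos0 = rec.pos - 1
            if not any(s <= pos0 < e for s, e in sweep_gene.exons):
                continue
            call = coding_consequence(rec, sweep_gene, ref[rec.chrom])
            focal_rows.append((rec, call))
        with open("results/06_exonic_consequences.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tgene\tconsequence\taa_change\n")
            for rec, call in focal_rows:
                fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t"
                         f"{call.gene}\t{call.consequence}\t"
                         f"{call.aa_change}\n")

    missense = [(rec, c) for rec, c in focal_rows
                if c.consequence == "missense"]
    focal = missense[0] if missense else (focal_rows[0] if focal_rows else None)
    report = None
    if focal is not None:
        rec = focal[0]
        report = population_genotype_report(rec.key, vs, pm)
        with open("results/06_focal_site.json", "w") as fh:
            json.dump({"site": list(rec.key[:2]) + [rec.ref, rec.alt],
                       "consequence": focal[1].consequence,
                       "by_population": report}, fh, indent=2)

    if sweep_gene is not None:
        mid = (sweep_gene.start + sweep_gene.end) // 2
        region = (sweep_gene.chrom, max(0, mid - 75_000), mid + 75_000)
        mat, rows, keys = haplotype_matrix(region, vs, pm)
        with open("results/06_haplotype_matrix.tsv", "w") as fh:
            fh.write("sample\tpopulation\t"
                     + "\t".join(str(k[1]) for k in keys) + "\n")
            for s, vals in zip(rows, mat):
                fh.write(f"{s}\t{pm.labels[s]}\t"
                         + "\t".join(str(int(v)) for v in vals) + "\n")

    print(f"{len(table.joint_candidates)} joint candidate genes "
          f"(DEG + >=1 selection evidence): "
          f"{', '.join(sorted(table.joint_candidates))}")
    if focal is not None and report is not None:
        rec = focal[0]
        qcb, dlw = report.get("QCB"), report.get("DLW")
        print(f"focal exonic site {rec.chrom}:{rec.pos} "
              f"({focal[1].consequence}): "
              f"QCB hom-ref {qcb['percent']['hom_ref']:.0f}% / "
              f"het {qcb['percent']['het']:.0f}% / "
              f"hom-alt {qcb['percent']['hom_alt']:.0f}%; "
              f"DLW hom-ref {dlw['percent']['hom_ref']:.0f}%")


if __name__ == "__main__":
    main()
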