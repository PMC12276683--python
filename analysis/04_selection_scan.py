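#!/usr/bin/env python
"""Windowed Fst and XP-CLR-style scans between the hybrid and DLW cohorts.

50 kb sliding windows with 25 kb steps; the top 5% of windows by each
statistic are candidate selection regions, and genes overlapping them are
candidate genes.  The configured sweep locus should surface in both scans.
"""

import argparse
import json
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from hybridscan.pipeline import SIM_RECOMB_CM_PER_MB
from hybridscan.scan import (
    SweepGrid, annotate_windows, gene_overlap_percent, make_windows,
    outlier_windows, windowed_fst, xpclr_scan,
)
from hybridscan.vcfio import read_gene_models, read_popmap, read_variant_table
from pyfaidx import Fasta


def write_windows(path, scores):
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_sites\tscore\n")
        for s in scores:
            w = s.window
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_sites}\t"
                     f"{s.score:.6g}\n")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim-dir", default="scratch/sim")
    ap.add_argument("--pop-obj", default="QCB")
    ap.add_argument("--pop-ref", default="DLW")
    args = ap.parse_args()

    vs, _ = read_variant_table(f"{args.sim_dir}/merged_qc.vcf")
    pm = read_popmap(f"{args.sim_dir}/popmap.tsv")
    genes = read_gene_models(f"{args.sim_dir}/genes.gff3")
    lens = {k: len(v) for k, v in Fasta(f"{args.sim_dir}/ref.fa").items()}
    truth = json.load(open(f"{args.sim_dir}/truth.json"))

    snps = vs.subset_records(vs.vtypes() == "SNP")
    idx_obj = pm.indices_of(args.pop_obj, vs.samples)
    idx_ref = pm.indices_of(args.pop_ref, vs.samples)
    windows = make_windows(lens)

    fst = windowed_fst(snps, idx_obj, idx_ref, windows)
    scale = SIM_RECOMB_CM_PER_MB
    grid = SweepGrid(s_values=np.concatenate(
        [[0.0], np.logspace(np.log10(1e-5 * scale), np.log10(1e-1 * scale),
                            15)]),
        recomb_cm_per_mb=scale)
    clr = xpclr_scan(snps, idx_ref, idx_obj, windows, grid)

    fst_out, fst_thr = outlier_windows(fst)
    clr_out, clr_thr = outlier_windows(clr)
    _, fst_genes = annotate_windows([s.window for s in fst_out], genes)
    _, clr_genes = annotate_windows([s.window for s in clr_out], genes)

    write_windows("results/04_fst_windows.tsv", fst)
    write_windows("results/04_clr_windows.tsv", clr)
    with open("results/04_candidate_genes.tsv", "w") as fh:
        fh.write("gene\tfst\txpclr\n")
        for gid in sorted(set(fst_genes) | set(clr_genes)):
            fh.write(f"{gid}\t{int(gid in fst_genes)}\t"
                     f"{int(gid in clr_genes)}\n")

    def hits_sweep(outliers):
        return any(w.window.chrom == sl["chrom"]
                   and w.window.start <= sl["pos"] - 1 < w.window.end
                   for w in outliers for sl in truth["sweep_loci"])

    summary = {
        "n_windows": len(fst), "fst_threshold": fst_thr,
        "clr_threshold": clr_thr,
        "n_fst_outliers": len(fst_out), "n_clr_outliers": len(clr_out),
        "fst_genes": list(fst_genes), "clr_genes": list(clr_genes),
        "gene_overlap": gene_overlap_percent(set(fst_genes), set(clr_genes)),
        "sweep_in_fst_top5": hits_sweep(fst_out),
        "sweep_in_clr_top5": hits_sweep(clr_out),
    }
    with open("results/04_scan.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"{len(fst_out)}/{len(fst)} Fst outlier windows "
          f"(threshold {fst_thr:.3f}) -> {len(fst_genes)} genes")
    print(f"{len(clr_out)}/{len(clr)} CLR outlier windows "
          f"(threshold {clr_thr:.2f}) -> {len(clr_genes)} genes")
    print(f"sweep window in Fst top 5%: {summary['sweep_in_fst_top5']}; "
          f"in CLR top 5%: {summary['sweep_in_clr_top5']}")


if __name__ == "__main__":
    main()
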