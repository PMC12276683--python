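#!/usr/bin/env python
"""Population structure of the merged cohort: PCA and K=2 admixture.

The three populations (GZB and DLW founders, QCB hybrids) should separate
on the top two principal components, and with two ancestry components the
founders should be near-pure while the hybrids carry roughly half of each.
"""

import argparse
import json
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from hybridscan.structure import (
    GenotypeMatrix, admixture_em, align_components, genotype_pca,
)
from hybridscan.vcfio import read_popmap, read_variant_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim-dir", default="scratch/sim")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--k", type=int, default=2)
    args = ap.parse_args()

    vs, _ = read_variant_table(f"{args.sim_dir}/merged_qc.vcf")
    pm = read_popmap(f"{args.sim_dir}/popmap.tsv")
    g = GenotypeMatrix.from_variant_set(vs, ["SNP"])
    pca = genotype_pca(g, n_pcs=5)

    sub = np.sort(np.random.default_rng(args.seed).choice(
        g.n_variants, min(4000, g.n_variants), replace=False))
    g_sub = GenotypeMatrix(g.samples, g.dosages[:, sub], g.chrom[sub],
                           g.pos[sub], g.vtype[sub])
    adm = admixture_em(g_sub, args.k, seed=args.seed, n_restarts=3,
                       max_iter=150)
    q = align_components(adm.q, pm.indices_of("GZB", vs.samples))

    with open("results/03_pcs.tsv", "w") as fh:
        fh.write("sample\tpopulation\t"
                 + "\t".join(f"PC{i+1}" for i in range(pca.pcs.shape[1]))
                 + "\n")
        for i, s in enumerate(vs.samples):
            fh.write(f"{s}\t{pm.labels[s]}\t"
                     + "\t".join(f"{x:.5f}" for x in pca.pcs[i]) + "\n")
    with open("results/03_q_matrix.tsv", "w") as fh:
        fh.write("sample\tpopulation\t"
                 + "\t".join(f"Q{k+1}" for k in range(q.shape[1])) + "\n")
        for i, s in enumerate(vs.samples):
            fh.write(f"{s}\t{pm.labels[s]}\t"
                     + "\t".join(f"{x:.5f}" for x in q[i]) + "\n")

    pops = {p: pm.indices_of(p, vs.samples) for p in pm.populations()}
    summary = {
        "explained_variance_pct": pca.explained_variance.tolist(),
        "mean_q1_by_population": {p: float(q[idx, 0].mean())
                                  for p, idx in pops.items()},
        "founder_max_q": float(np.concatenate(
            [q[pops["GZB"]].max(axis=1), q[pops["DLW"]].max(axis=1)]).mean()),
        "final_loglik": adm.loglik_trace[-1],
    }
    with open("results/03_structure.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("explained variance (top PCs): "
          + ", ".join(f"{v:.1f}%" for v in pca.explained_variance[:2]))
    for p, v in summary["mean_q1_by_population"].items():
        print(f"  mean GZB-component ancestry in {p}: {v:.3f}")


if __name__ == "__main__":
    main()
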