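"""End-to-end orchestration of the synthetic study.

One replicate runs: simulate cohort -> emulate SR and Pan call sets ->
merge under the concordance rule -> QC -> call-set comparisons ->
population structure -> selection scans (Fst, CLR) -> association scan ->
candidate-gene integration.  Returns a flat metric dictionary so drivers,
tests and the acceptance script share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .candidates import intersect_candidates
from .eigengwas import eigengwas_scan, significant_loci
from .merge import (
    MergeParams, genotype_class_frequencies, merge_callsets, uniformity_cv,
    window_density,
)
from .qc import QCThresholds, apply_qc_filters
from .scan import (
    SweepGrid, annotate_windows, make_windows, outlier_windows, windowed_fst,
    xpclr_scan,
)
from .simulate import SimConfig, TruthBundle, simulate_all
from .structure import GenotypeMatrix, genotype_pca
from .variants import VariantSet

#: simulator-consistent recombination rate for the CLR scan, in cM/Mb
SIM_RECOMB_CM_PER_MB = 200.0

#: density window sized to the desk-scale genome (20 windows per chromosome)
DENSITY_WINDOW = 50_000


@dataclass
class PipelineResult:
    truth: TruthBundle
    sr: VariantSet
    pan: VariantSet
    merged: VariantSet
    merged_qc: VariantSet
    sr_qc: VariantSet
    merge_report: object
    qc_report: object
    metrics: dict = field(default_factory=dict)


def _count_by_type(vs: VariantSet) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in vs.records:
        out[r.vtype] = out.get(r.vtype, 0) + 1
    return out


def sweep_window_rank(scores, truth: TruthBundle) -> dict[str, float]:
    """Best percentile rank (1 = top) of any window containing a sweep locus."""
    vals = np.array([s.score for s in scores])
    out = {}
    for sl in truth.sweep_loci:
        best = None
        for s in scores:
            w = s.window
            if w.chrom == sl.chrom and w.start <= sl.pos - 1 < w.end:
                pct = float(np.mean(vals <= s.score))
                best = pct if best is None else max(best, pct)
        out[f"{sl.chrom}:{sl.pos}"] = best if best is not None else np.nan
    return out


def run_pipeline(cfg: Optional[SimConfig] = None, seed: int = 0,
                 run_scans: bool = True) -> PipelineResult:
    cfg = cfg or SimConfig(seed=seed)
    truth, sr, pan = simulate_all(cfg)
    merged, mrep = merge_callsets(sr, pan, MergeParams())
    merged_qc, qrep = apply_qc_filters(merged, QCThresholds())
    sr_qc, _ = apply_qc_filters(sr, QCThresholds())

    m = {}
    sr_t, mg_t = _count_by_type(sr_qc), _count_by_type(merged_qc)
    for vt in ("SNP", "INDEL", "SV"):
        s, g = sr_t.get(vt, 0), mg_t.get(vt, 0)
        m[f"n_sr_{vt}"] = s
        m[f"n_merged_{vt}"] = g
        m[f"gain_pct_{vt}"] = 100.0 * (g - s) / s if s else float("inf")
    m["n_sr_total"] = len(sr_qc)
    m["n_merged_total"] = len(merged_qc)

    freqs_sr = genotype_class_frequencies(sr_qc)
    freqs_mg = genotype_class_frequencies(merged_qc)
    m["hom_alt_frac_sr"] = freqs_sr["ALL"]["hom_alt"]
    m["hom_alt_frac_merged"] = freqs_mg["ALL"]["hom_alt"]

    lens = truth.chrom_lengths
    # density uniformity is a per-type comparison (the variant classes tile
    # the genome differently by construction); SNPs carry the claim
    sr_snp = sr_qc.subset_records(sr_qc.vtypes() == "SNP")
    mg_snp = merged_qc.subset_records(merged_qc.vtypes() == "SNP")
    m["density_cv_sr"] = uniformity_cv(window_density(sr_snp, lens, DENSITY_WINDOW))
    m["density_cv_merged"] = uniformity_cv(
        window_density(mg_snp, lens, DENSITY_WINDOW))

    res = PipelineResult(truth, sr, pan, merged, merged_qc, sr_qc, mrep, qrep, m)
    if not run_scans:
        return res

    pm = truth.popmap
    samples = merged_qc.samples
    idx_obj = pm.indices_of("QCB", samples)   # hybrid (object) population
    idx_ref = pm.indices_of("DLW", samples)   # parental reference population
    windows = make_windows(lens)

    snps = merged_qc.subset_records(merged_qc.vtypes() == "SNP")
    fst_scores = windowed_fst(snps, idx_obj, idx_ref, windows)
    fst_out, m["fst_top5_threshold"] = outlier_windows(fst_scores)
    # the selection grid scales with the recombination rate: the escape
    # probability depends on r*d/s only, so the compressed genome keeps the
    # same dimensionless range as the defaults at 1 cM/Mb
    scale = SIM_RECOMB_CM_PER_MB / 1.0
    grid = SweepGrid(s_values=np.concatenate(
        [[0.0], np.logspace(np.log10(1e-5 * scale), np.log10(1e-1 * scale), 15)]),
        recomb_cm_per_mb=SIM_RECOMB_CM_PER_MB)
    clr_scores = xpclr_scan(snps, idx_ref, idx_obj, windows, grid)
    clr_out, m["clr_top5_threshold"] = outlier_windows(clr_scores)
    m["n_fst_windows"] = len(fst_scores)
    m["n_clr_windows"] = len(clr_scores)
    m["n_fst_outliers"] = len(fst_out)
    m["n_clr_outliers"] = len(clr_out)
    m["fst_sweep_rank"] = sweep_window_rank(fst_scores, truth)
    m["clr_sweep_rank"] = sweep_window_rank(clr_scores, truth)

    def _contains_sweep(outliers) -> bool:
        return any(w.window.chrom == sl.chrom
                   and w.window.start <= sl.pos - 1 < w.window.end
                   for w in outliers for sl in truth.sweep_loci)

    m["fst_sweep_in_top5"] = _contains_sweep(fst_out)
    m["clr_sweep_in_top5"] = _contains_sweep(clr_out)
    m["mean_windowed_fst"] = float(np.mean([s.score for s in fst_scores]))

    _, fst_genes = annotate_windows([s.window for s in fst_out], truth.genes)
    _, clr_genes = annotate_windows([s.window for s in clr_out], truth.genes)

    # association scan on the two contrasted populations
    both = np.concatenate([idx_obj, idx_ref])
    sub = snps.genotype_matrix()[:, both]
    gsub = GenotypeMatrix([samples[i] for i in both],
                          np.where(sub < 0, np.nan, sub).astype(float).T,
                          snps.chroms(), snps.positions(), snps.vtypes())
    pca = genotype_pca(gsub, n_pcs=2)
    egw = eigengwas_scan(gsub, pca.pcs[:, 0])
    m["lambda_gc"] = egw.lambda_gc
    sig = significant_loci(egw, truth.genes, chrom_lengths=lens)
    m["n_eigengwas_hits"] = len(sig)
    egw_genes = sorted({g for loc in sig for g in loc["genes"]})

    deg_set = {g for g, flag in truth.deg.items() if flag}
    table = intersect_candidates(
        {"fst": set(fst_genes), "xpclr": set(clr_genes),
         "eigengwas": set(egw_genes)}, deg_set)
    m["n_joint_candidates"] = len(table.joint_candidates)
    sweep_genes = {g.gene_id for g in truth.genes[:len(truth.sweep_loci)]}
    sweep_de = sweep_genes & deg_set
    m["sweep_de_recovered"] = bool(sweep_de
                                   and sweep_de <= set(table.joint_candidates))
    res.metrics.update(m)
    res.metrics["fst_genes"] = list(fst_genes)
    res.metrics["xpclr_genes"] = list(clr_genes)
    res.metrics["eigengwas_genes"] = egw_genes
    res.metrics["joint_candidates"] = list(table.joint_candidates)
    return res
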