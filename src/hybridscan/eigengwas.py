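"""Single-marker association against the leading principal component.

Each marker's dosage is regressed (OLS with intercept) on PC1 used as a
pseudo-phenotype; the Wald chi-square statistics are deflated by the
genomic-control factor lambda = median(chi2) / 0.4549364 (the median of a
1-df chi-square), and markers with adjusted p below the Bonferroni bar
0.05/n are called significant.  Drift-driven inflation is expected under
population differentiation; lambda_GC absorbs it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .structure import GenotypeMatrix
from .variants import GeneModel

CHI2_1_MEDIAN = 0.4549364


@dataclass
class EigenScanResult:
    chrom: np.ndarray
    pos: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    chi2_raw: np.ndarray
    chi2_adj: np.ndarray
    p_adj: np.ndarray
    lambda_gc: float
    n_markers: int
    n_skipped: int

    @property
    def bonferroni_threshold(self) -> float:
        return 0.05 / self.n_markers

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_adj < alpha / self.n_markers


def eigengwas_scan(g: GenotypeMatrix, pc1: np.ndarray) -> EigenScanResult:
    """Marker-by-marker OLS of pc1 on dosage with genomic control."""
    y_full = np.asarray(pc1, dtype=float)
    if len(y_full) != g.n_samples:
        raise ValueError("pc1 length does not match sample count")
    if np.allclose(y_full, y_full[0]):
        raise ValueError("pc1 is constant")
    X = g.dosages
    obs = ~np.isnan(X)
    # minor allele count >= 2 among observed calls required for a defined SE
    with np.errstate(invalid="ignore"):
        mac = np.minimum(np.nansum(X, axis=0),
                         np.nansum(2 * obs - np.where(obs, X, 0), axis=0))
    n_obs = obs.sum(axis=0)
    usable = (mac >= 2) & (n_obs >= 3)

    beta = np.full(g.n_variants, np.nan)
    se = np.full(g.n_variants, np.nan)
    Xz = np.where(obs, X, 0.0)
    y = np.where(obs, y_full[:, None], 0.0)
    nn = n_obs.astype(float)
    sx = Xz.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (Xz * Xz).sum(axis=0)
    sxy = (Xz * y).sum(axis=0)
    syy = (y * y).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssx = sxx - sx * sx / nn
        ssy = syy - sy * sy / nn
        ssxy = sxy - sx * sy / nn
        b = ssxy / ssx
        rss = ssy - b * ssxy
        sigma2 = rss / (nn - 2)
        s = np.sqrt(sigma2 / ssx)
    good = usable & np.isfinite(b) & np.isfinite(s) & (ssx > 0) & (s > 0)
    beta[good] = b[good]
    se[good] = s[good]

    chi2_raw = np.full(g.n_variants, np.nan)
    chi2_raw[good] = (beta[good] / se[good]) ** 2
    if not good.any():
        raise ValueError("no usable (polymorphic) markers")
    lam = float(np.median(chi2_raw[good]) / CHI2_1_MEDIAN)
    lam = max(lam, 1e-12)
    chi2_adj = chi2_raw / lam
    p_adj = np.full(g.n_variants, np.nan)
    p_adj[good] = chi2.sf(chi2_adj[good], df=1)
    return EigenScanResult(g.chrom, g.pos, beta, se, chi2_raw, chi2_adj,
                           p_adj, lam, n_markers=int(good.sum()),
                           n_skipped=int(g.n_variants - good.sum()))


def significant_loci(res: EigenScanResult, gene_models: Sequence[GeneModel],
                     alpha: float = 0.05, flank: int = 100_000,
                     chrom_lengths: dict | None = None) -> list[dict]:
    """Bonferroni-significant markers with genes within +/- flank bp."""
    out = []
    thr = alpha / res.n_markers
    for i in np.flatnonzero(np.isfinite(res.p_adj)):
        if not res.p_adj[i] < thr:
            continue
        chrom, pos = res.chrom[i], int(res.pos[i])
        lo = max(0, pos - 1 - flank)
        hi = pos - 1 + flank + 1
        if chrom_lengths and chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[chrom])
        genes = [gm.gene_id for gm in gene_models
                 if gm.chrom == chrom and gm.start < hi and gm.end > lo]
        out.append({"chrom": chrom, "pos": pos, "p_adj": float(res.p_adj[i]),
                    "chi2_adj": float(res.chi2_adj[i]), "genes": genes})
    return out
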