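"""Population-structure analyses: PCA and K-way admixture estimation.

PCA uses Patterson-style scaling: each variant column is centered by twice
its allele frequency and divided by sqrt(2p(1-p)); missing dosages are
mean-imputed.  Ancestry proportions are estimated by EM for the standard
binomial admixture likelihood P(alt copy | i, j) = sum_k q_ik f_kj, the
model behind the ADMIXTURE program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .variants import MISSING, VariantSet


@dataclass
class GenotypeMatrix:
    """samples x variants dosage matrix with NaN for missing calls."""

    samples: list
    dosages: np.ndarray  # float, (n_samples, n_variants), NaN = missing
    chrom: np.ndarray
    pos: np.ndarray
    vtype: np.ndarray

    @classmethod
    def from_variant_set(cls, vs: VariantSet,
                         vtypes: Optional[Sequence[str]] = None) -> "GenotypeMatrix":
        gm = vs.genotype_matrix().astype(float).T  # samples x variants
        gm[gm == MISSING] = np.nan
        chrom, pos, vt = vs.chroms(), vs.positions(), vs.vtypes()
        if vtypes is not None:
            keep = np.isin(vt, list(vtypes))
            gm, chrom, pos, vt = gm[:, keep], chrom[keep], pos[keep], vt[keep]
        return cls(list(vs.samples), gm, chrom, pos, vt)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class StructureResult:
    pcs: Optional[np.ndarray] = None              # samples x n_pcs
    explained_variance: Optional[np.ndarray] = None  # percentages
    q: Optional[np.ndarray] = None                # samples x K
    f: Optional[np.ndarray] = None                # K x variants
    loglik_trace: list = field(default_factory=list)
    samples: list = field(default_factory=list)


def genotype_pca(g: GenotypeMatrix, n_pcs: int = 10,
                 scale: bool = True) -> StructureResult:
    """Principal components of the standardized dosage matrix."""
    X = g.dosages.copy()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    p_hat = np.nanmean(X, axis=0) / 2.0
    col_mean = 2.0 * p_hat
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= col_mean
    sd = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    poly = sd > 0
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic variants")
    X = X[:, poly]
    if scale:
        X /= sd[poly]
    n = X.shape[0]
    cov = X @ X.T / X.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    n_pcs = min(n_pcs, n)
    pcs = vecs[:, :n_pcs] * np.sqrt(np.maximum(vals[:n_pcs], 0))
    # deterministic sign: the largest-magnitude coordinate is positive
    for k in range(pcs.shape[1]):
        j = np.argmax(np.abs(pcs[:, k]))
        if pcs[j, k] < 0:
            pcs[:, k] *= -1
    total = vals.sum()
    ev = 100.0 * vals[:n_pcs] / total if total > 0 else np.zeros(n_pcs)
    return StructureResult(pcs=pcs, explained_variance=ev, samples=list(g.samples))


def admixture_em(g: GenotypeMatrix, k: int, seed: int = 0,
                 max_iter: int = 300, tol: float = 1e-4,
                 n_restarts: int = 5) -> StructureResult:
    """EM for the binomial admixture model; best of ``n_restarts`` runs."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > g.n_samples:
        raise ValueError("K exceeds the number of samples")
    X = g.dosages
    obs = ~np.isnan(X)
    G = np.where(obs, X, 0.0)          # alt-allele copies
    H = np.where(obs, 2.0 - X, 0.0)    # ref-allele copies
    p_obs = np.nansum(X, axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))

    if k == 1:
        q = np.ones((g.n_samples, 1))
        f = np.clip(p_obs, 1e-6, 1 - 1e-6)[None, :]
        ll = _admixture_loglik(G, H, q, f)
        return StructureResult(q=q, f=f, loglik_trace=[ll], samples=list(g.samples))

    best: Optional[StructureResult] = None
    rng_master = np.random.default_rng(seed)
    for _ in range(n_restarts):
        rng = np.random.default_rng(rng_master.integers(2**31))
        q = rng.dirichlet(np.ones(k), size=g.n_samples)
        f = np.clip(p_obs[None, :] + rng.normal(0, 0.1, (k, g.n_variants)),
                    1e-6, 1 - 1e-6)
        trace = []
        prev = -np.inf
        for it in range(max_iter):
            pa = q @ f                      # P(alt copy) per (i, j)
            pb = q @ (1.0 - f)
            pa = np.clip(pa, 1e-12, None)
            pb = np.clip(pb, 1e-12, None)
            # expected copy counts attributed to each component
            A = np.einsum("ij,ik,kj->ikj", G / pa, q, f)
            B = np.einsum("ij,ik,kj->ikj", H / pb, q, 1.0 - f)
            denom_i = 2.0 * obs.sum(axis=1)
            q = (A.sum(axis=2) + B.sum(axis=2)) / denom_i[:, None]
            q = np.clip(q, 1e-9, None)
            q /= q.sum(axis=1, keepdims=True)
            num = A.sum(axis=0)
            f = num / np.clip(num + B.sum(axis=0), 1e-12, None)
            f = np.clip(f, 1e-6, 1 - 1e-6)
            ll = _admixture_loglik(G, H, q, f)
            if not np.isfinite(ll):
                raise FloatingPointError(f"non-finite likelihood at iteration {it}")
            trace.append(ll)
            if ll - prev < tol and it > 0:
                break
            prev = ll
        if best is None or trace[-1] > best.loglik_trace[-1]:
            best = StructureResult(q=q, f=f, loglik_trace=trace,
                                   samples=list(g.samples))
    return best


def _admixture_loglik(G: np.ndarray, H: np.ndarray, q: np.ndarray,
                      f: np.ndarray) -> float:
    pa = np.clip(q @ f, 1e-300, None)
    pb = np.clip(q @ (1.0 - f), 1e-300, None)
    return float(np.sum(G * np.log(pa)) + np.sum(H * np.log(pb)))


def align_components(q: np.ndarray, ref_indices: np.ndarray) -> np.ndarray:
    """Reorder components so component 0 maximizes mean ancestry among the
    given reference samples (fixed label-switching rule)."""
    lead = int(np.argmax(q[ref_indices].mean(axis=0)))
    order = [lead] + [k for k in range(q.shape[1]) if k != lead]
    return q[:, order]
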