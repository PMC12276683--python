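"""Site-level quality control.

Filters follow the strict-inequality reading of the thresholds: a site is
removed when missingness is *greater than* 10%, MAF is *lower than* 5%, or
the Hardy-Weinberg exact-test p-value is *below* 1e-6 (SNPs and INDELs
only; structural variants are exempt from the HWE filter).  Removal is
attributed in a fixed order (missingness, then MAF, then HWE) so report
counts reconcile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .variants import HET, HOM_ALT, HOM_REF, MISSING, SV, VariantSet


@dataclass
class QCThresholds:
    max_missing: float = 0.10
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    sv_min_len: int = 50

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.sv_min_len < 1:
            raise ValueError("sv_min_len must be >= 1")


@dataclass
class QCReport:
    n_input: int = 0
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_retained: int = 0
    by_type_before: dict = field(default_factory=dict)
    by_type_after: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_removed_missing + self.n_removed_maf + self.n_removed_hwe

    def validate(self) -> None:
        assert self.n_removed + self.n_retained == self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_hwe": self.n_removed_hwe,
            "n_retained": self.n_retained,
            "by_type_before": self.by_type_before,
            "by_type_after": self.by_type_after,
        }


def site_missingness(genotypes: np.ndarray) -> float:
    """Fraction of missing calls at a site."""
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("empty genotype vector")
    return float(np.mean(g == MISSING))


def minor_allele_freq(genotypes: np.ndarray) -> float:
    """min(p, 1-p) of the alt-allele frequency over non-missing calls."""
    g = np.asarray(genotypes)
    ok = g != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all genotypes missing")
    p = float(g[ok].sum()) / (2 * n)
    return min(p, 1.0 - p)


def genotype_counts(genotypes: np.ndarray) -> tuple[int, int, int]:
    g = np.asarray(genotypes)
    return (int(np.sum(g == HOM_REF)), int(np.sum(g == HET)),
            int(np.sum(g == HOM_ALT)))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the conditional probabilities of outcomes no more
    probable than the observed one (two-sided exact test).  Monomorphic
    sites return p = 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("no genotypes")
    n_alt = 2 * n_hom_alt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    # log P(h | n, n_rare) up to the shared normalizing constant
    logp = (hets * np.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def apply_qc_filters(vs: VariantSet, th: QCThresholds | None = None,
                     hwe_types: tuple = ("SNP", "INDEL")
                     ) -> tuple[VariantSet, QCReport]:
    """Apply missingness -> MAF -> HWE filters; SVs skip the HWE test."""
    th = th or QCThresholds()
    rep = QCReport(n_input=len(vs))
    for r in vs.records:
        rep.by_type_before[r.vtype] = rep.by_type_before.get(r.vtype, 0) + 1
    kept = []
    for r in vs.records:
        if site_missingness(r.genotypes) > th.max_missing:
            rep.n_removed_missing += 1
            continue
        ok = r.genotypes != MISSING
        if not ok.any():
            rep.n_removed_missing += 1
            continue
        if minor_allele_freq(r.genotypes) < th.min_maf:
            rep.n_removed_maf += 1
            continue
        if r.vtype in hwe_types and r.vtype != SV:
            if hwe_exact_p(*genotype_counts(r.genotypes)) < th.hwe_alpha:
                rep.n_removed_hwe += 1
                continue
        kept.append(r)
    out = VariantSet(vs.samples, kept, sort=False)
    rep.n_retained = len(out)
    for r in out.records:
        rep.by_type_after[r.vtype] = rep.by_type_after.get(r.vtype, 0) + 1
    rep.validate()
    return out, rep
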