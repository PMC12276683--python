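"""Shared builders for compact test fixtures."""

import numpy as np

from hybridscan.simulate import SimConfig, SweepLocus
from hybridscan.variants import VariantRecord, VariantSet


def small_config(seed: int = 0, **kw) -> SimConfig:
    """A scaled-down simulation for fast unit tests."""
    base = dict(chrom_len=600_000, n_snp=1200, n_indel=200, n_sv=12,
                cohort_size=60,
                sweep_loci=[SweepLocus("chr1", 300_001, 20.0)], seed=seed)
    base.update(kw)
    return SimConfig(**base)


def make_vs(geno_rows, samples=None, chrom="chr1", start_pos=100, spacing=10,
            ref="A", alt="T", source="SR"):
    """VariantSet from a list of genotype-code rows (one row per site)."""
    geno_rows = [np.asarray(r, dtype=np.int8) for r in geno_rows]
    n = len(geno_rows[0]) if geno_rows else 0
    samples = samples or [f"s{i}" for i in range(n)]
    recs = [VariantRecord(chrom, start_pos + i * spacing, ref, alt, g,
                          source=source)
            for i, g in enumerate(geno_rows)]
    return VariantSet(samples, recs)
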