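"""Forward-in-time simulation of a two-breed hybrid cohort.

Two founder breeds diverge from a common ancestral gene pool under the
Balding-Nichols model (breed allele frequencies Beta-distributed around an
ancestral frequency with divergence parameter F).  An F1 generation is
produced by crossing breed-A dams with breed-B sires; subsequent
generations inter-mate at random with Poisson-crossover recombination,
optionally with fitness weights at configured sweep loci.  The sampled
cohort mirrors a three-population design: two parental breed panels plus
the final-generation hybrids.

Two imperfect call sets are then emulated from the genotype truth:

* the single-reference ("SR") set drops variants unrepresentable on a
  linear reference (private loci) and miscalls heterozygotes as homozygous
  reference at an elevated rate inside bias regions flanking structural
  variants — the two mechanisms of reference bias;
* the panel ("Pan") set is restricted to the loci carried by one sampled
  diploid per breed (one assembly per parent) with a small symmetric
  genotyping error.

The genome is desk-scale: a compressed stand-in whose per-bp recombination
rate is correspondingly inflated so that linkage decays within a
chromosome.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .variants import (
    GeneModel, HET, HOM_ALT, HOM_REF, PopMap, VariantRecord, VariantSet,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child RNG of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())]))


def balding_nichols_freqs(p0: np.ndarray, f: float,
                          rng: np.random.Generator) -> np.ndarray:
    """One subpopulation's allele frequencies under the Balding-Nichols model.

    Frequencies are Beta(p0(1-F)/F, (1-p0)(1-F)/F): mean p0, variance
    F * p0 * (1 - p0).
    """
    if not 0 < f < 1:
        raise ValueError(f"divergence F must be in (0,1), got {f}")
    p0 = np.asarray(p0, dtype=float)
    return rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)


@dataclass
class SweepLocus:
    chrom: str
    pos: int  # 1-based
    s: float  # selection weight


@dataclass
class SimConfig:
    """Simulation parameters; defaults define the study conditions."""

    n_chrom: int = 2
    chrom_len: int = 4_000_000
    n_snp: int = 12000
    n_indel: int = 1800
    n_sv: int = 90
    divergence_f: float = 0.2
    n_founders_a: int = 200  # breed-A dams (sow stock)
    n_founders_b: int = 21   # breed-B sires (boar stock)
    cohort_size: int = 250
    n_generations: int = 5   # F1 .. F5
    n_a_out: int = 31
    n_b_out: int = 40
    n_hybrid_out: int = 37
    recomb_rate: float = 2e-6  # crossovers / bp / meiosis (compressed genome)
    sweep_loci: list = field(default_factory=lambda: [SweepLocus("chr1", 2_000_001, 20.0)])
    pi_priv: float = 0.05
    pi_priv_bias: float = 0.50
    sv_priv_prob: float = 0.80
    bias_half_width: int = 8_000
    indel_bias_frac: float = 0.6
    eps_base: float = 0.02
    eps_bias: float = 0.15
    mu_miss: float = 0.03
    eps_pan: float = 0.01
    # founder frequencies pinned at sweep loci: the favored allele starts on
    # few breed-A haplotypes and is absent from breed B (the focal missense
    # pattern: all hom-ref in the reference breed), so the sweep drags a
    # coherent haplotype and distorts local ancestry
    sweep_p_a: float = 0.02
    sweep_p_b: float = 0.0
    n_genes: int = 60
    deg_background_rate: float = 0.15
    deg_sweep_rate: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.divergence_f < 1:
            raise ValueError(f"divergence F must be in (0,1), got {self.divergence_f}")
        for name in ("pi_priv", "pi_priv_bias", "sv_priv_prob",
                     "sweep_p_a", "sweep_p_b", "indel_bias_frac", "eps_base",
                     "eps_bias", "mu_miss", "eps_pan", "deg_background_rate",
                     "deg_sweep_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.chrom_len < 10 * 50_000:
            raise ValueError("chrom_len must be at least 10 windows (500 kb)")
        if self.cohort_size < 2:
            raise ValueError("cohort_size must be >= 2")
        self.sweep_loci = [sl if isinstance(sl, SweepLocus) else SweepLocus(*sl)
                           for sl in self.sweep_loci]
        chroms = {f"chr{i + 1}" for i in range(self.n_chrom)}
        for sl in self.sweep_loci:
            if sl.chrom not in chroms or not 1 <= sl.pos <= self.chrom_len:
                raise ValueError(f"sweep locus {sl} outside simulated genome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_len for c in self.chrom_names}


@dataclass
class FounderPanel:
    """Loci, breed allele frequencies and founder haplotype pools."""

    chrom: np.ndarray        # per-locus chromosome name
    pos: np.ndarray          # 1-based positions
    ref: list
    alt: list
    vtype: np.ndarray
    p0: np.ndarray           # ancestral frequencies
    p_a: np.ndarray          # breed-A frequencies
    p_b: np.ndarray
    private: np.ndarray      # bool: unrepresentable on the linear reference
    in_bias: np.ndarray      # bool: inside a bias region
    bias_intervals: dict     # chrom -> list of (start0, end0)
    hap_a: np.ndarray        # (2*N_A, L) founder haplotypes, breed A
    hap_b: np.ndarray
    ref_seqs: dict           # chrom -> sequence string

    @property
    def n_loci(self) -> int:
        return len(self.pos)


@dataclass
class TruthBundle:
    """Ground truth for one simulated cohort."""

    truth: VariantSet
    popmap: PopMap
    panel: np.ndarray          # bool per locus: representable in the parental panel
    private: np.ndarray
    in_bias: np.ndarray
    bias_intervals: dict
    sweep_loci: list
    genes: list
    deg: dict                  # gene_id -> bool (differentially expressed)
    ref_seqs: dict
    chrom_lengths: dict
    ancestry_b_fraction: np.ndarray  # per hybrid sample, fraction of breed-B genome
    ancestry_b_by_locus: np.ndarray  # per locus, mean breed-B ancestry of hybrids
    cfg: SimConfig


def _draw_positions(rng: np.random.Generator, cfg: SimConfig) -> dict:
    """Draw unique variant positions per chromosome, per type."""
    chroms = cfg.chrom_names
    out = {"chrom": [], "pos": [], "vtype": []}
    margin = 600  # keep room for insertion alleles and left-extension
    # SVs first: their positions define bias regions
    per_chrom_used: dict[str, set] = {c: set() for c in chroms}

    def _add(chrom: str, pos: int, vtype: str) -> bool:
        if pos in per_chrom_used[chrom]:
            return False
        per_chrom_used[chrom].add(pos)
        out["chrom"].append(chrom)
        out["pos"].append(pos)
        out["vtype"].append(vtype)
        return True

    def _uniform(n: int, vtype: str) -> None:
        placed = 0
        while placed < n:
            c = chroms[rng.integers(len(chroms))]
            p = int(rng.integers(margin, cfg.chrom_len - margin))
            if _add(c, p, vtype):
                placed += 1

    _uniform(cfg.n_sv, "SV")
    sv_by_chrom: dict[str, list] = {c: [] for c in chroms}
    for c, p, vt in zip(out["chrom"], out["pos"], out["vtype"]):
        if vt == "SV":
            sv_by_chrom[c].append(p)
    bias_intervals = {
        c: sorted((max(0, p - 1 - cfg.bias_half_width),
                   min(cfg.chrom_len, p - 1 + cfg.bias_half_width))
                  for p in ps)
        for c, ps in sv_by_chrom.items()}

    _uniform(cfg.n_snp, "SNP")
    # a fraction of INDELs concentrated inside bias regions
    n_in_bias = int(round(cfg.n_indel * cfg.indel_bias_frac))
    flat_regions = [(c, s, e) for c, iv in bias_intervals.items() for s, e in iv]
    placed = 0
    while placed < n_in_bias and flat_regions:
        c, s, e = flat_regions[rng.integers(len(flat_regions))]
        p = int(rng.integers(max(s, margin), max(min(e, cfg.chrom_len - margin),
                                                 margin + 1)))
        if _add(c, p, "INDEL"):
            placed += 1
    _uniform(cfg.n_indel - placed, "INDEL")
    out["bias_intervals"] = bias_intervals
    return out


def _in_intervals(chrom: np.ndarray, pos: np.ndarray, intervals: dict) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for c, iv in intervals.items():
        if not iv:
            continue
        mask = chrom == c
        p0 = pos[mask] - 1
        h = np.zeros(p0.shape, dtype=bool)
        for s, e in iv:
            h |= (p0 >= s) & (p0 < e)
        hit[mask] = h
    return hit


def simulate_founders(cfg: SimConfig) -> FounderPanel:
    """Balding-Nichols divergence of two breeds plus founder haplotype pools."""
    rng_seq = substream(cfg.seed, "refseq")
    ref_seqs = {c: "".join(np.char.decode(
        _BASES[rng_seq.integers(0, 4, cfg.chrom_len)].astype("S1")).tolist())
        for c in cfg.chrom_names}

    rng_pos = substream(cfg.seed, "positions")
    drawn = _draw_positions(rng_pos, cfg)
    order = np.lexsort((np.array(drawn["pos"]), np.array(drawn["chrom"])))
    chrom = np.array(drawn["chrom"])[order]
    pos = np.array(drawn["pos"], dtype=np.int64)[order]
    vtype = np.array(drawn["vtype"])[order]
    bias_intervals = drawn["bias_intervals"]
    L = len(pos)

    rng_alle = substream(cfg.seed, "alleles")
    ref: list[str] = []
    alt: list[str] = []
    for c, p, vt in zip(chrom, pos, vtype):
        base = ref_seqs[c][p - 1]
        if vt == "SNP":
            others = [b for b in "ACGT" if b != base]
            ref.append(base)
            alt.append(others[rng_alle.integers(3)])
        else:
            ln = (int(rng_alle.integers(1, 30)) if vt == "INDEL"
                  else int(rng_alle.integers(50, 400)))
            ins = "".join(np.char.decode(
                _BASES[rng_alle.integers(0, 4, ln)].astype("S1")).tolist())
            ref.append(base)
            alt.append(base + ins)

    rng_freq = substream(cfg.seed, "frequencies")
    F = cfg.divergence_f
    p0 = rng_freq.uniform(0.05, 0.95, L)
    p_a = balding_nichols_freqs(p0, F, rng_freq)
    p_b = balding_nichols_freqs(p0, F, rng_freq)

    in_bias = _in_intervals(chrom, pos, bias_intervals)
    rng_priv = substream(cfg.seed, "private")
    priv_prob = np.where(in_bias, cfg.pi_priv_bias, cfg.pi_priv)
    # structural variants are the least representable on a linear reference
    priv_prob = np.where(vtype == "SV", cfg.sv_priv_prob, priv_prob)
    private = rng_priv.random(L) < priv_prob

    # pin founder frequencies at sweep loci: favored allele segregates in
    # breed A, (nearly) absent from breed B, and is reference-representable
    for sl in cfg.sweep_loci:
        sel = np.flatnonzero(chrom == sl.chrom)
        if sel.size:
            j = sel[np.argmin(np.abs(pos[sel] - sl.pos))]
            p_a[j], p_b[j] = cfg.sweep_p_a, cfg.sweep_p_b
            private[j] = False

    rng_hap = substream(cfg.seed, "founder_haplotypes")
    hap_a = (rng_hap.random((2 * cfg.n_founders_a, L)) < p_a).astype(np.int8)
    hap_b = (rng_hap.random((2 * cfg.n_founders_b, L)) < p_b).astype(np.int8)
    return FounderPanel(chrom, pos, ref, alt, vtype, p0, p_a, p_b, private,
                        in_bias, bias_intervals, hap_a, hap_b, ref_seqs)


def _meiosis_mask(rng: np.random.Generator, chrom: np.ndarray, pos: np.ndarray,
                  chrom_names: list, chrom_len: int, rate: float) -> np.ndarray:
    """Which parental haplotype (0/1) each locus of a gamete comes from."""
    mask = np.zeros(len(pos), dtype=np.int8)
    for c in chrom_names:
        sel = chrom == c
        if not sel.any():
            continue
        start = int(rng.integers(2))
        n_x = rng.poisson(rate * chrom_len)
        if n_x == 0:
            mask[sel] = start
            continue
        xpos = np.sort(rng.integers(1, chrom_len, n_x))
        # haplotype index flips at each crossover
        seg = np.searchsorted(xpos, pos[sel] - 1, side="right")
        mask[sel] = (start + seg) % 2
    return mask


def simulate_pedigree(founders: FounderPanel, cfg: SimConfig) -> TruthBundle:
    """Cross the breeds and propagate the hybrid cohort with recombination
    and optional sweep-locus selection; return full genotype truth."""
    L = founders.n_loci
    chrom, pos = founders.chrom, founders.pos
    rng = substream(cfg.seed, "pedigree")

    sweep_idx = []
    for sl in cfg.sweep_loci:
        # nearest simulated locus to the configured sweep position
        sel = np.flatnonzero(chrom == sl.chrom)
        if sel.size == 0:
            raise ValueError(f"sweep locus {sl}: chromosome not simulated")
        j = sel[np.argmin(np.abs(pos[sel] - sl.pos))]
        sweep_idx.append((int(j), sl.s))

    def gamete(individual: tuple[np.ndarray, np.ndarray],
               anc: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        m = _meiosis_mask(rng, chrom, pos, cfg.chrom_names, cfg.chrom_len,
                          cfg.recomb_rate)
        h = np.where(m == 0, individual[0], individual[1])
        a = np.where(m == 0, anc[0], anc[1])
        return h, a

    # F1: breed-A dam x breed-B sire
    n = cfg.cohort_size
    cohort = []
    for _ in range(n):
        dam = rng.integers(cfg.n_founders_a)
        sire = rng.integers(cfg.n_founders_b)
        dam_haps = (founders.hap_a[2 * dam], founders.hap_a[2 * dam + 1])
        sire_haps = (founders.hap_b[2 * sire], founders.hap_b[2 * sire + 1])
        zeros, ones = np.zeros(L, np.int8), np.ones(L, np.int8)
        h1, a1 = gamete(dam_haps, (zeros, zeros))
        h2, a2 = gamete(sire_haps, (ones, ones))
        cohort.append(((h1, h2), (a1, a2)))

    for _gen in range(2, cfg.n_generations + 1):
        if sweep_idx:
            w = np.ones(len(cohort))
            for j, s in sweep_idx:
                dosage = np.array([c[0][0][j] + c[0][1][j] for c in cohort])
                w *= 1.0 + s * dosage / 2.0
            w /= w.sum()
        else:
            w = None
        nxt = []
        for _ in range(n):
            p1 = rng.choice(len(cohort), p=w)
            p2 = p1
            while p2 == p1:
                p2 = rng.choice(len(cohort), p=w)
            h1, a1 = gamete(*cohort[p1])
            h2, a2 = gamete(*cohort[p2])
            nxt.append(((h1, h2), (a1, a2)))
        cohort = nxt

    rng_out = substream(cfg.seed, "sampling")
    # the sampled final-generation animals are themselves selected stock
    if sweep_idx:
        w_out = np.ones(len(cohort))
        for j, s in sweep_idx:
            dosage = np.array([c[0][0][j] + c[0][1][j] for c in cohort])
            w_out *= 1.0 + s * dosage / 2.0
        w_out /= w_out.sum()
        hybrid_ids = rng_out.choice(len(cohort), cfg.n_hybrid_out, replace=False,
                                    p=w_out)
    else:
        hybrid_ids = rng_out.choice(len(cohort), cfg.n_hybrid_out, replace=False)
    hyb_geno = np.array([cohort[i][0][0] + cohort[i][0][1] for i in hybrid_ids],
                        dtype=np.int8)
    anc_mat = np.array([(cohort[i][1][0] + cohort[i][1][1]) / 2.0
                        for i in hybrid_ids])
    anc_b = anc_mat.mean(axis=1)
    anc_b_locus = anc_mat.mean(axis=0)

    a_geno = ((rng_out.random((cfg.n_a_out, L)) < founders.p_a).astype(np.int8)
              + (rng_out.random((cfg.n_a_out, L)) < founders.p_a).astype(np.int8))
    b_geno = ((rng_out.random((cfg.n_b_out, L)) < founders.p_b).astype(np.int8)
              + (rng_out.random((cfg.n_b_out, L)) < founders.p_b).astype(np.int8))

    samples = ([f"GZB_{i + 1:03d}" for i in range(cfg.n_a_out)]
               + [f"DLW_{i + 1:03d}" for i in range(cfg.n_b_out)]
               + [f"QCB_{i + 1:03d}" for i in range(cfg.n_hybrid_out)])
    labels = {s: s.split("_")[0] for s in samples}
    geno = np.vstack([a_geno, b_geno, hyb_geno]).T  # (L, n_samples)

    records = [VariantRecord(c, int(p), r, a, geno[i], source="Truth", vtype=vt)
               for i, (c, p, r, a, vt) in enumerate(
                   zip(chrom, pos, founders.ref, founders.alt, founders.vtype))]
    truth = VariantSet(samples, records, sort=False)
    if not truth.is_sorted():
        truth = VariantSet(samples, records, sort=True)

    # parental panel: one sampled diploid per breed stands in for one assembly
    rng_panel = substream(cfg.seed, "panel")
    da = rng_panel.integers(cfg.n_founders_a)
    db = rng_panel.integers(cfg.n_founders_b)
    carried = (founders.hap_a[2 * da] + founders.hap_a[2 * da + 1]
               + founders.hap_b[2 * db] + founders.hap_b[2 * db + 1]) > 0
    panel = np.asarray(carried, dtype=bool)

    genes, deg = _simulate_genes(cfg, founders)
    return TruthBundle(truth, PopMap(labels), panel, founders.private,
                       founders.in_bias, founders.bias_intervals,
                       cfg.sweep_loci, genes, deg, founders.ref_seqs,
                       cfg.chrom_lengths, anc_b, anc_b_locus, cfg)


def _simulate_genes(cfg: SimConfig, founders: FounderPanel
                    ) -> tuple[list, dict]:
    """Random three-exon gene models; one gene pinned over each sweep locus."""
    rng = substream(cfg.seed, "genes")
    genes: list[GeneModel] = []

    def make_gene(gid: str, c: str, start: int, strand: str) -> GeneModel:
        e1 = (start, start + 300)
        e2 = (start + 800, start + 1400)
        e3 = (start + 2000, start + 2300)
        # CDS inside exons; total length 200 + 600 + 199 = 999, divisible by 3
        cds = [(start + 100, start + 300), (start + 800, start + 1400),
               (start + 2000, start + 2199)]
        return GeneModel(gid, c, strand, start, start + 2300,
                         exons=[e1, e2, e3], cds=cds)

    gi = 0
    for sl in cfg.sweep_loci:
        start = max(0, min(sl.pos - 1 - 1150, cfg.chrom_len - 2400))
        genes.append(make_gene(f"gene{gi + 1:03d}", sl.chrom, start,
                               "+" if rng.random() < 0.5 else "-"))
        gi += 1
    while gi < cfg.n_genes:
        c = cfg.chrom_names[rng.integers(cfg.n_chrom)]
        start = int(rng.integers(0, cfg.chrom_len - 2400))
        if any(g.chrom == c and not (start + 2300 <= g.start or start >= g.end)
               for g in genes):
            continue
        genes.append(make_gene(f"gene{gi + 1:03d}", c, start,
                               "+" if rng.random() < 0.5 else "-"))
        gi += 1

    sweep_gene_ids = {g.gene_id for g in genes[:len(cfg.sweep_loci)]}
    deg = {}
    for g in genes:
        p = cfg.deg_sweep_rate if g.gene_id in sweep_gene_ids else cfg.deg_background_rate
        deg[g.gene_id] = bool(rng.random() < p)
    return genes, deg


def emulate_callsets(truth: TruthBundle, cfg: SimConfig | None = None
                     ) -> tuple[VariantSet, VariantSet]:
    """Emulate the single-reference and panel call sets from genotype truth."""
    cfg = cfg or truth.cfg
    tvs = truth.truth
    gm = tvs.genotype_matrix()
    L, n = gm.shape

    rng_sr = substream(cfg.seed, "sr_errors")
    eps = np.where(truth.in_bias, cfg.eps_bias, cfg.eps_base)[:, None]
    u = rng_sr.random(gm.shape)
    sr_g = gm.copy()
    sr_g[(gm == HET) & (u < eps)] = HOM_REF
    sr_g[rng_sr.random(gm.shape) < cfg.mu_miss] = -1

    sr_records = []
    for i, r in enumerate(tvs.records):
        if truth.private[i]:
            continue
        sr_records.append(VariantRecord(r.chrom, r.pos, r.ref, r.alt,
                                        sr_g[i], source="SR", vtype=r.vtype))
    sr = VariantSet(tvs.samples, sr_records, sort=False)

    rng_pan = substream(cfg.seed, "pan_errors")
    pan_g = gm.copy()
    flip = rng_pan.random(gm.shape) < cfg.eps_pan
    shift = rng_pan.integers(1, 3, gm.shape)
    pan_g[flip] = ((pan_g[flip] + shift[flip]) % 3).astype(np.int8)
    pan_records = []
    for i, r in enumerate(tvs.records):
        if not truth.panel[i]:
            continue
        pan_records.append(VariantRecord(r.chrom, r.pos, r.ref, r.alt,
                                         pan_g[i], source="Pan", vtype=r.vtype))
    pan = VariantSet(tvs.samples, pan_records, sort=False)
    return sr, pan


def simulate_all(cfg: SimConfig) -> tuple[TruthBundle, VariantSet, VariantSet]:
    """Convenience wrapper: founders -> pedigree -> emulated call sets."""
    founders = simulate_founders(cfg)
    truth = simulate_pedigree(founders, cfg)
    sr, pan = emulate_callsets(truth, cfg)
    return truth, sr, pan


def write_truth_json(truth: TruthBundle, path: str) -> None:
    """Persist the non-genotype ground truth (sweeps, panel flags, bias)."""
    payload = {
        "sweep_loci": [asdict(s) for s in truth.sweep_loci],
        "panel": truth.panel.astype(int).tolist(),
        "private": truth.private.astype(int).tolist(),
        "bias_intervals": {c: [list(map(int, iv)) for iv in v]
                           for c, v in truth.bias_intervals.items()},
        "deg": truth.deg,
        "chrom_lengths": truth.chrom_lengths,
        "ancestry_b_fraction": truth.ancestry_b_fraction.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
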