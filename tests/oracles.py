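"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the Hardy-Weinberg test, a direct transcription of the
published variance-component formulas, and a whole-transcript build-and-
translate pipeline for coding consequences.
"""

from fractions import Fraction
from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def _fact(n: int) -> int:
    out = 1
    for i in range(2, n + 1):
        out *= i
    return out


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p-value via rational arithmetic.

    P(h | n, nA) = n! / (n_AA! h! n_aa!) * 2^h * nA! * na! / (2n)! for each
    heterozygote count h compatible with the allele counts; the two-sided p
    sums outcomes no more probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n - n_alt
    if min(n_alt, n_ref) == 0:
        return 1.0
    probs = {}
    denom = _fact(2 * n)
    for h in range(n_alt % 2, min(n_alt, n_ref) + 1, 2):
        hom_alt = (n_alt - h) // 2
        hom_ref = n - h - hom_alt
        if hom_ref < 0:
            continue
        num = (Fraction(_fact(n), _fact(hom_ref) * _fact(h) * _fact(hom_alt))
               * 2 ** h * _fact(n_alt) * _fact(n_ref))
        probs[h] = Fraction(num, denom)
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def wc84_components_oracle(c1, c2):
    """Direct transcription of the two-population diploid variance
    components from the published formulas, kept independent of the
    package's arrangement of terms."""
    n_i = np.array([sum(c1), sum(c2)], dtype=float)
    p_i = np.array([(2 * c1[2] + c1[1]) / (2 * n_i[0]),
                    (2 * c2[2] + c2[1]) / (2 * n_i[1])])
    h_i = np.array([c1[1] / n_i[0], c2[1] / n_i[1]])
    r = 2.0
    nbar = n_i.mean()
    c2_ = ((n_i ** 2).sum()) / (r * nbar)
    nc = (r * nbar - c2_) / (r - 1.0)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1.0) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    term = pbar * (1 - pbar) - ((r - 1.0) / r) * s2
    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1.0)) * (term - hbar / 4.0))
    b = (nbar / (nbar - 1.0)) * (term - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    return a, b, c


# ---------------------------------------------------------------------------
# whole-transcript consequence oracle

_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


def _translate(s: str) -> str:
    return "".join(_CODONS[s[i:i + 3]] for i in range(0, len(s) - len(s) % 3, 3))


def consequence_oracle(gm, pos0: int, alt_base: str, seq: str) -> str:
    """Classify a SNP against a gene model by rebuilding the full coding
    sequence before and after substitution and translating both."""
    in_cds = any(s <= pos0 < e for s, e in gm.cds)
    if not in_cds:
        if pos0 < gm.start or pos0 >= gm.end:
            within_flank = gm.start - 5000 <= pos0 < gm.end + 5000
            if not within_flank:
                return "intergenic"
            before = pos0 < gm.start
            upstream = before if gm.strand == "+" else not before
            return "upstream" if upstream else "downstream"
        if any(s <= pos0 < e for s, e in gm.exons):
            return "exonic_noncoding"
        return "intronic"
    mutated = seq[:pos0] + alt_base + seq[pos0 + 1:]
    cds_ref = "".join(seq[s:e] for s, e in gm.cds)
    cds_alt = "".join(mutated[s:e] for s, e in gm.cds)
    if gm.strand == "-":
        cds_ref, cds_alt = _revcomp(cds_ref), _revcomp(cds_alt)
    aa_ref, aa_alt = _translate(cds_ref), _translate(cds_alt)
    diffs = [(i, a, b) for i, (a, b) in enumerate(zip(aa_ref, aa_alt)) if a != b]
    if not diffs:
        return "synonymous"
    _, a, b = diffs[0]
    if b == "*":
        return "stop_gained"
    if a == "*":
        return "stop_lost"
    return "missense"


def random_gene_model(rng, chrom="chr1", genome_len=20000):
    """A random multi-exon gene model with a frame-consistent CDS."""
    from hybridscan.variants import GeneModel

    n_exons = int(rng.integers(1, 4))
    cursor = int(rng.integers(200, 2000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(90, 400))
        exons.append((cursor, cursor + length))
        cursor += length + int(rng.integers(50, 500))
    total = sum(e - s for s, e in exons)
    # trim the last exon's CDS so the total is a multiple of 3
    excess = total % 3
    cds = list(exons)
    if excess:
        s, e = cds[-1]
        cds[-1] = (s, e - excess)
    strand = "+" if rng.random() < 0.5 else "-"
    start, end = exons[0][0], exons[-1][1]
    return GeneModel(f"g{int(rng.integers(1e6))}", chrom, strand, start, end,
                     exons=exons, cds=cds)
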