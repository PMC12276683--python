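"""Integration of a single-reference call set with a parental-panel call set.

Sites private to either source pass through; overlapping sites (same
normalized ``chrom, pos, ref, alt`` key) are retained only when per-sample
genotype concordance strictly exceeds the 90% bar, keeping one source's
genotypes (the single-reference calls by default, since they derive from
per-sample reads).  Discordant overlaps are discarded.

Also provides the comparison summaries between call sets: genotype-class
frequency tables and windowed variant-density uniformity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .variants import (
    HET, HOM_ALT, HOM_REF, MISSING, VariantDataError, VariantRecord, VariantSet,
)


@dataclass
class MergeParams:
    min_concordance: float = 0.90
    # panel genotypes survive at retained overlaps: they come from the
    # graph-based caller and are free of reference-bias miscalls
    genotype_priority: str = "Pan"  # SR | Pan

    def __post_init__(self) -> None:
        if not 0 <= self.min_concordance <= 1:
            raise ValueError("min_concordance must be in [0,1]")
        if self.genotype_priority not in ("SR", "Pan"):
            raise ValueError("genotype_priority must be 'SR' or 'Pan'")


@dataclass
class MergeReport:
    n_sr_only: int = 0
    n_pan_only: int = 0
    n_overlap_retained: int = 0
    n_overlap_discarded: int = 0
    n_overlap_no_comparison: int = 0
    per_type: dict = field(default_factory=dict)

    @property
    def n_merged(self) -> int:
        return self.n_sr_only + self.n_pan_only + self.n_overlap_retained

    def to_dict(self) -> dict:
        return {
            "n_sr_only": self.n_sr_only,
            "n_pan_only": self.n_pan_only,
            "n_overlap_retained": self.n_overlap_retained,
            "n_overlap_discarded": self.n_overlap_discarded,
            "n_overlap_no_comparison": self.n_overlap_no_comparison,
            "n_merged": self.n_merged,
            "per_type": self.per_type,
        }


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_record(chrom: str, pos: int, ref: str, alt: str,
                     ref_seq: Optional[str] = None) -> tuple[str, int, str, str]:
    """Left-align and trim a variant to its minimal representation.

    ``ref_seq`` is the full chromosome sequence (0-based string); when given,
    the variant is shifted left while its right-trimmed alleles end with the
    same base, following the standard normalization algorithm.
    """
    if ref_seq is not None:
        seq = ref_seq
        if seq[pos - 1:pos - 1 + len(ref)].upper() != ref.upper():
            raise VariantDataError(
                f"{chrom}:{pos} REF {ref!r} disagrees with reference sequence")
        changed = True
        while changed:
            changed = False
            if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
                ref, alt = ref[:-1], alt[:-1]
                if not ref or not alt:
                    if pos == 1:
                        raise VariantDataError(
                            f"{chrom}:{pos} cannot left-extend past chromosome start")
                    base = seq[pos - 2].upper()
                    ref, alt = base + ref, base + alt
                    pos -= 1
                changed = True
            elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
                ref, alt = ref[1:], alt[1:]
                pos += 1
                changed = True
        return chrom, pos, ref, alt
    pos, ref, alt = _trim_alleles(pos, ref, alt)
    return chrom, pos, ref, alt


def normalize_and_key(vs: VariantSet, ref_seqs: Optional[dict] = None) -> VariantSet:
    """Normalize every record; collapse duplicates with identical genotypes.

    ``ref_seqs`` maps chromosome name to its full sequence string.
    """
    by_key: dict[tuple, VariantRecord] = {}
    for r in vs.records:
        seq = ref_seqs.get(r.chrom) if ref_seqs else None
        chrom, pos, ref, alt = normalize_record(r.chrom, r.pos, r.ref, r.alt, seq)
        rec = VariantRecord(chrom, pos, ref, alt, r.genotypes, r.source, id=r.id)
        if rec.key in by_key:
            if not np.array_equal(by_key[rec.key].genotypes, rec.genotypes):
                raise VariantDataError(
                    f"records collapse to {rec.key} with conflicting genotypes")
        else:
            by_key[rec.key] = rec
    return VariantSet(vs.samples, by_key.values())


def genotype_concordance(gA: np.ndarray, gB: np.ndarray) -> float:
    """Fraction of agreeing calls among pairs where both are non-missing.

    Returns NaN when there are no comparable pairs.
    """
    gA, gB = np.asarray(gA), np.asarray(gB)
    if gA.shape != gB.shape:
        raise ValueError("genotype vectors differ in length")
    both = (gA != MISSING) & (gB != MISSING)
    n = int(both.sum())
    if n == 0:
        return math.nan
    return float(np.sum(gA[both] == gB[both])) / n


def merge_callsets(sr: VariantSet, pan: VariantSet,
                   params: MergeParams | None = None
                   ) -> tuple[VariantSet, MergeReport]:
    """Integrate two call sets over the same cohort under the concordance rule."""
    params = params or MergeParams()
    if sr.samples != pan.samples:
        raise VariantDataError("sample lists differ between call sets")
    if not sr.is_sorted() or not pan.is_sorted():
        raise VariantDataError("input VariantSets must be sorted")
    sr_idx = {r.key: r for r in sr.records}
    pan_idx = {r.key: r for r in pan.records}
    rep = MergeReport()
    merged: list[VariantRecord] = []

    def _tally(kind: str, vtype: str) -> None:
        d = rep.per_type.setdefault(vtype, {"sr_only": 0, "pan_only": 0,
                                            "overlap_retained": 0,
                                            "overlap_discarded": 0})
        d[kind] += 1

    for key, r in sr_idx.items():
        if key not in pan_idx:
            out = r.copy()
            out.source = "Merged"
            merged.append(out)
            rep.n_sr_only += 1
            _tally("sr_only", r.vtype)
    for key, r in pan_idx.items():
        if key not in sr_idx:
            out = r.copy()
            out.source = "Merged"
            merged.append(out)
            rep.n_pan_only += 1
            _tally("pan_only", r.vtype)
    for key, r_sr in sr_idx.items():
        r_pan = pan_idx.get(key)
        if r_pan is None:
            continue
        conc = genotype_concordance(r_sr.genotypes, r_pan.genotypes)
        if math.isnan(conc):
            rep.n_overlap_no_comparison += 1
            rep.n_overlap_discarded += 1
            _tally("overlap_discarded", r_sr.vtype)
        elif conc > params.min_concordance:
            src = r_sr if params.genotype_priority == "SR" else r_pan
            out = src.copy()
            out.source = "Merged"
            merged.append(out)
            rep.n_overlap_retained += 1
            _tally("overlap_retained", r_sr.vtype)
        else:
            rep.n_overlap_discarded += 1
            _tally("overlap_discarded", r_sr.vtype)
    out_vs = VariantSet(sr.samples, merged)
    assert rep.n_merged == len(out_vs), "merge count identity violated"
    return out_vs, rep


def genotype_class_frequencies(vs: VariantSet, by_type: bool = True) -> dict:
    """Proportions of {hom_ref, het, hom_alt, missing} over sample x site calls.

    Returns ``{vtype: {class: fraction}}`` (plus an ``"ALL"`` row); each row
    sums to 1.
    """
    if len(vs) == 0:
        raise ValueError("empty VariantSet")
    gm = vs.genotype_matrix()
    vtypes = vs.vtypes()
    rows: dict[str, dict[str, float]] = {}
    groups = {"ALL": np.ones(len(vs), dtype=bool)}
    if by_type:
        for vt in np.unique(vtypes):
            groups[str(vt)] = vtypes == vt
    for name, mask in groups.items():
        sub = gm[mask]
        total = sub.size
        rows[name] = {
            "hom_ref": float(np.sum(sub == HOM_REF)) / total,
            "het": float(np.sum(sub == HET)) / total,
            "hom_alt": float(np.sum(sub == HOM_ALT)) / total,
            "missing": float(np.sum(sub == MISSING)) / total,
        }
    return rows


def window_density(vs: VariantSet, chrom_lengths: dict[str, int],
                   window_size: int = 500_000) -> dict[str, np.ndarray]:
    """Per-chromosome counts of variants in non-overlapping tiling windows."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-length // window_size))
        counts[chrom] = np.zeros(n_win, dtype=np.int64)
    for r in vs.records:
        if r.chrom in counts:
            i = (r.pos - 1) // window_size
            if i < len(counts[r.chrom]):
                counts[r.chrom][i] += 1
    return counts


def uniformity_cv(counts) -> float:
    """Coefficient of variation (population sd / mean) of window counts."""
    if isinstance(counts, dict):
        arr = np.concatenate([np.asarray(v, dtype=float) for v in counts.values()])
    else:
        arr = np.asarray(counts, dtype=float)
    m = arr.mean()
    if m == 0:
        return math.nan
    return float(arr.std() / m)
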