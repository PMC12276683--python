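"""Candidate-gene integration, coding consequences and focal-region reports."""

from itertools import combinations

import numpy as np
import pytest

from helpers import make_vs
from oracles import consequence_oracle, random_gene_model

from hybridscan.candidates import (
    coding_consequence, haplotype_matrix, intersect_candidates,
    population_genotype_report, region_heterozygosity,
)
from hybridscan.variants import GeneModel, PopMap, VariantRecord


class TestIntersect:
    def test_joint_candidates_example(self):
        table = intersect_candidates({"scan": {"A", "B", "C"}},
                                     {"B", "C", "D"})
        assert sorted(table.joint_candidates) == ["B", "C"]

    def test_disjoint_sets_empty(self):
        table = intersect_candidates({"scan": {"A"}}, {"B"})
        assert table.joint_candidates == []
        assert sum(table.intersections.values()) == 2  # universe size

    def test_empty_deg_warns(self):
        with pytest.warns(UserWarning):
            table = intersect_candidates({"scan": {"A"}}, set())
        assert table.joint_candidates == []

    def test_min_evidence_rule(self):
        ev = {"fst": {"A", "B"}, "xpclr": {"B"}, "eig": {"B", "C"}}
        deg = {"A", "B", "C"}
        assert sorted(intersect_candidates(ev, deg, 1).joint_candidates) == \
            ["A", "B", "C"]
        assert intersect_candidates(ev, deg, 3).joint_candidates == ["B"]

    def test_intersection_counts_match_powerset_enumeration(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        sets = {f"e{k}": {g for g in genes if rng.random() < 0.4}
                for k in range(5)}
        deg = {g for g in genes if rng.random() < 0.4}
        table = intersect_candidates(sets, deg)
        names = list(sets) + ["DEG"]
        all_sets = {**sets, "DEG": deg}
        universe = set().union(*all_sets.values())
        # brute force: count genes per exact membership pattern
        for r in range(len(names) + 1):
            for combo in combinations(names, r):
                expected = sum(
                    1 for g in universe
                    if all(g in all_sets[n] for n in combo)
                    and not any(g in all_sets[n] for n in names
                                if n not in combo))
                assert table.intersections.get(frozenset(combo), 0) == expected
        assert sum(table.intersections.values()) == len(universe)


def _plus_gene(seq_len=3000):
    # CDS 100..400 on the plus strand of a synthetic chromosome
    return GeneModel("g+", "chr1", "+", 50, 600, exons=[(50, 600)],
                     cds=[(100, 400)])


def _seq_with(codon_at_100="GGA", length=3000):
    seq = list("A" * length)
    seq[100:103] = list(codon_at_100)
    return "".join(seq)


class TestConsequence:
    def test_synonymous_third_position(self):
        seq = _seq_with("GGA")
        v = VariantRecord("chr1", 103, "A", "G", np.zeros(1, np.int8))
        call = coding_consequence(v, _plus_gene(), seq)
        assert call.consequence == "synonymous"
        assert call.codon_change == "GGA>GGG"

    def test_missense_met_to_ile(self):
        seq = _seq_with("ATG")
        v = VariantRecord("chr1", 103, "G", "A", np.zeros(1, np.int8))
        call = coding_consequence(v, _plus_gene(), seq)
        assert call.consequence == "missense"
        assert call.aa_change == "M1I"

    def test_positional_classes(self):
        gm = GeneModel("g", "chr1", "+", 1000, 3000,
                       exons=[(1000, 1400), (2000, 3000)],
                       cds=[(1100, 1400), (2000, 2300)])
        seq = "ACGT" * 3000
        def call_at(pos0, alt):
            ref = seq[pos0]
            alt = next(b for b in "ACGT" if b != ref)
            v = VariantRecord("chr1", pos0 + 1, ref, alt, np.zeros(1, np.int8))
            return coding_consequence(v, gm, seq).consequence
        assert call_at(500, "T") == "upstream"
        assert call_at(3500, "T") == "downstream"
        assert call_at(1700, "T") == "intronic"
        assert call_at(1050, "T") == "exonic_noncoding"
        assert call_at(9000, "T") == "intergenic"

    def test_minus_strand_upstream_side_flips(self):
        gm = GeneModel("g", "chr1", "-", 1000, 2000, exons=[(1000, 2000)])
        seq = "A" * 5000
        v = VariantRecord("chr1", 501, "A", "T", np.zeros(1, np.int8))
        assert coding_consequence(v, gm, seq).consequence == "downstream"

    def test_indel_in_cds_not_frame_analyzed(self):
        seq = _seq_with("ATG")
        v = VariantRecord("chr1", 101, "A", "ACC", np.zeros(1, np.int8))
        # place ref base consistent with sequence
        v = VariantRecord("chr1", 101, seq[100], seq[100] + "CC",
                          np.zeros(1, np.int8))
        call = coding_consequence(v, _plus_gene(), seq)
        assert call.consequence == "coding_indel_unclassified"

    def test_ref_mismatch_raises(self):
        seq = _seq_with("ATG")
        v = VariantRecord("chr1", 101, "C", "T", np.zeros(1, np.int8))
        with pytest.raises(ValueError):
            coding_consequence(v, _plus_gene(), seq)

    def test_randomized_models_match_full_transcript_oracle(self):
        """Both strands, multi-exon; classes agree with rebuilding and
        translating the whole coding sequence."""
        rng = np.random.default_rng(1)
        n_checked = 0
        while n_checked < 150:
            gm = random_gene_model(rng)
            seq = "".join(rng.choice(list("ACGT"), 20_000))
            pos0 = int(rng.integers(max(0, gm.start - 6000),
                                    min(20_000, gm.end + 6000) - 1))
            ref = seq[pos0]
            alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
            v = VariantRecord("chr1", pos0 + 1, ref, alt, np.zeros(1, np.int8))
            got = coding_consequence(v, gm, seq).consequence
            want = consequence_oracle(gm, pos0, alt, seq)
            assert got == want, (gm.gene_id, gm.strand, pos0, ref, alt)
            n_checked += 1


class TestPopulationReport:
    def _vs_and_popmap(self):
        g = np.array([0] * 40 + [0] * 21 + [1] * 15 + [2] * 1, dtype=np.int8)
        samples = [f"d{i}" for i in range(40)] + [f"q{i}" for i in range(37)]
        vs = make_vs([g], samples=samples)
        labels = {s: ("DLW" if s.startswith("d") else "QCB") for s in samples}
        return vs, PopMap(labels)

    def test_focal_site_percentages(self):
        vs, pm = self._vs_and_popmap()
        rep = population_genotype_report(vs.records[0].key, vs, pm)
        assert rep["DLW"]["percent"]["hom_ref"] == 100.0
        assert rep["QCB"]["percent"]["hom_ref"] == pytest.approx(56.76, abs=0.01)
        assert rep["QCB"]["percent"]["het"] == pytest.approx(40.54, abs=0.01)
        assert rep["QCB"]["percent"]["hom_alt"] == pytest.approx(2.70, abs=0.01)
        assert rep["QCB"]["counts"] == {"hom_ref": 21, "het": 15,
                                        "hom_alt": 1, "missing": 0}

    def test_percentages_sum_to_100(self):
        vs, pm = self._vs_and_popmap()
        rep = population_genotype_report(vs.records[0].key, vs, pm)
        for pop in rep.values():
            assert sum(pop["percent"].values()) == pytest.approx(100.0)

    def test_absent_site_raises_with_key(self):
        vs, pm = self._vs_and_popmap()
        with pytest.raises(KeyError):
            population_genotype_report(("chr9", 1, "A", "T"), vs, pm)


class TestHaplotypeMatrix:
    def _setup(self):
        rows = [np.array([0, 1, 2, 1], dtype=np.int8)] * 10
        vs = make_vs(rows, start_pos=100, spacing=100)
        pm = PopMap({"s0": "P1", "s1": "P1", "s2": "P2", "s3": "P2"})
        return vs, pm

    def test_region_subsets_columns(self):
        vs, pm = self._setup()
        mat, rows, keys = haplotype_matrix(("chr1", 99, 350), vs, pm)
        assert mat.shape == (4, 3)

    def test_half_open_region_boundary(self):
        vs, pm = self._setup()
        # site at 1-based pos 300 has 0-based position 299: excluded at end=299
        mat, _, keys = haplotype_matrix(("chr1", 99, 299), vs, pm)
        assert all(k[1] < 300 for k in keys)
        assert mat.shape[1] == 2

    def test_rows_grouped_by_population(self):
        vs, pm = self._setup()
        _, rows, _ = haplotype_matrix(("chr1", 0, 10_000), vs, pm)
        assert rows == ["s0", "s1", "s2", "s3"]

    def test_empty_region_warns(self):
        vs, pm = self._setup()
        with pytest.warns(UserWarning):
            mat, _, keys = haplotype_matrix(("chr1", 90_000, 91_000), vs, pm)
        assert mat.shape[1] == 0

    def test_sweep_region_loses_heterozygosity(self, small_pipeline):
        truth = small_pipeline.truth
        vs = small_pipeline.merged_qc
        pm = truth.popmap
        sweep = truth.sweep_loci[0]
        half = 50_000
        qcb = [s for s in vs.samples if pm.labels[s] == "QCB"]
        sub = PopMap({s: "QCB" for s in qcb})
        region = (sweep.chrom, sweep.pos - 1 - half, sweep.pos - 1 + half)
        control = ("chr2", 100_000, 100_000 + 2 * half)
        m_sweep, rows, _ = haplotype_matrix(region, vs, sub)
        m_ctrl, _, _ = haplotype_matrix(control, vs, sub)
        keep = [i for i, s in enumerate(rows) if s in qcb]
        assert region_heterozygosity(m_sweep[keep]) < \
            region_heterozygosity(m_ctrl[keep])
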