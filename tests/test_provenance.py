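import math

import numpy as np
import pytest

from conftest import roles_for
from paleonumt.mito_core import AnchoredSequence, NucSequence, codon_span
from paleonumt.phylo_placement import PanelAlignment
from paleonumt.provenance_tests import (
    CodonEdit,
    SubstitutionRecord,
    call_private_substitutions,
    codon_position_test,
    cpg_check,
    orf_integrity_scan,
    pathogenic_overlap,
    per_gene_report,
    provenance_verdict,
    repair_disruptions,
    tstv_summary,
)
from paleonumt.mito_core import project_position


def brute_force_multinomial_p(counts, weights):
    """Independent exact-test oracle: enumerate all outcomes."""
    n = sum(counts)
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()

    def pmf(o):
        coef = math.factorial(n) // math.prod(math.factorial(x) for x in o)
        return coef * math.prod(pi ** x for pi, x in zip(p, o))

    obs = pmf(counts)
    total = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            o = (a, b, n - a - b)
            q = pmf(o)
            if q <= obs * (1 + 1e-9):
                total += q
    return total


class TestCodonPositionTest:
    def test_exact_test_matches_enumeration_oracle(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    counts = (a, b, n - a - b)
                    got = codon_position_test(counts, (2, 1, 5))
                    assert got.method == "exact_multinomial"
                    want = brute_force_multinomial_p(counts, (2, 1, 5))
                    assert got.p_value == pytest.approx(want, rel=1e-9), counts

    def test_perfect_fit_gives_p_one(self):
        res = codon_position_test((20, 10, 50), (2, 1, 5))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_statistic_hand_computed(self):
        res = codon_position_test((23, 11, 67), (2, 1, 5), exact_threshold=50)
        assert res.method == "chi_square"
        assert res.statistic == pytest.approx(0.6476, abs=5e-4)

    def test_uniform_counts_fit_uniform_better_than_biased(self):
        p_biased = codon_position_test((5, 5, 5), (2, 1, 5)).p_value
        p_uniform = codon_position_test((5, 5, 5), (1, 1, 1)).p_value
        assert p_uniform > p_biased

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            codon_position_test((0, 0, 0))

    def test_method_switches_at_threshold(self):
        assert codon_position_test((60, 60, 90)).method == "chi_square"
        assert codon_position_test((10, 10, 10)).method == "exact_multinomial"


class TestTsTv:
    def _rec(self, ref, alt):
        site = type("S", (), {"category": "intergenic", "gene": None,
                              "codon": None, "incomplete_codon": False})()
        from paleonumt.provenance_tests import is_transition

        return SubstitutionRecord(
            position=1, site=site, ref_base=ref, alt_base=alt,
            is_transition=is_transition(ref, alt), cpg_context=False,
            privacy="private_to_focal",
        )

    def test_mixed_records(self):
        s = tstv_summary([self._rec("A", "G"), self._rec("C", "T"),
                          self._rec("A", "T")])
        assert (s.transitions, s.transversions, s.ratio) == (2, 1, 2.0)
        assert not s.infinite

    def test_all_transitions_flag_infinite(self):
        s = tstv_summary([self._rec("A", "G"), self._rec("G", "A")])
        assert s.transversions == 0 and s.ratio is None and s.infinite

    def test_empty(self):
        s = tstv_summary([])
        assert (s.transitions, s.transversions, s.infinite) == (0, 0, False)


def make_panel(reference, span, edits_by_label, labels=None):
    """Panel over ``span`` with per-label {position: base} edits."""
    lo, hi = span
    base = reference.residues[lo - 1 : hi]
    labels = labels or ["human_1", "human_2", "human_3", "neanderthal", "numt"]
    seqs = {}
    for label in labels:
        s = list(base)
        for pos, b in edits_by_label.get(label, {}).items():
            s[pos - lo] = b
        seqs[label] = NucSequence(label, "".join(s))
    return PanelAlignment.from_sequences(seqs, roles_for(labels), ref_start=lo)


class TestPrivateSubstitutions:
    SPAN = (12337, 14148)  # ND5

    def test_focal_identical_to_panel_gives_none(self, reference, gene_map):
        panel = make_panel(reference, self.SPAN, {})
        assert call_private_substitutions(panel, "numt", gene_map) == []

    def test_planted_private_change_recovered(self, reference, gene_map):
        pos = 12500
        ref_base = reference.residues[pos - 1]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        panel = make_panel(reference, self.SPAN, {"numt": {pos: alt}})
        (rec,) = call_private_substitutions(panel, "numt", gene_map)
        assert rec.position == pos
        assert (rec.ref_base, rec.alt_base) == (ref_base, alt)
        assert rec.is_transition
        assert rec.site.gene == "ND5"

    def test_change_shared_with_neanderthal_not_private(self, reference, gene_map):
        pos = 12500
        ref_base = reference.residues[pos - 1]
        alt = "A" if ref_base != "A" else "C"
        panel = make_panel(
            reference, self.SPAN, {"numt": {pos: alt}, "neanderthal": {pos: alt}}
        )
        assert call_private_substitutions(panel, "numt", gene_map) == []

    def test_syn_nonsyn_classified_against_consensus(self, reference, gene_map):
        # third codon position change in ND5 is usually synonymous
        gene = gene_map.gene("ND5")
        lo, hi = codon_span(gene, 10)
        pos3 = lo + 2
        ref_base = reference.residues[pos3 - 1]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        panel = make_panel(reference, self.SPAN, {"numt": {pos3: alt}})
        (rec,) = call_private_substitutions(panel, "numt", gene_map)
        assert rec.coding_class in ("synonymous", "nonsynonymous")
        assert rec.site.codon.codon_position == 3

    def test_missing_focal_rejected(self, reference, gene_map):
        panel = make_panel(reference, self.SPAN, {},
                           labels=["human_1", "human_2", "neanderthal"])
        with pytest.raises(ValueError, match="focal"):
            call_private_substitutions(panel, "numt", gene_map)


class TestOrfScan:
    def test_unmodified_reference_is_clean(self, reference, gene_map):
        anchored = AnchoredSequence.from_reference(reference)
        assert orf_integrity_scan(anchored, gene_map) == []

    def test_planted_disruptions_recovered(self, reference, gene_map):
        cols = list(reference.residues)
        nd5 = gene_map.gene("ND5")
        lo, _ = codon_span(nd5, 35)
        cols[lo - 1 : lo + 2] = list("TAA")
        nd3 = gene_map.gene("ND3")
        lo3, _ = codon_span(nd3, 108)
        cols[lo3 - 1 : lo3 + 2] = list("TAA")
        cox2 = gene_map.gene("COX2")
        lo2, _ = codon_span(cox2, 204)
        cols[lo2 - 1 : lo2 + 1] = ["-", "-"]  # 2-bp deletion
        anchored = AnchoredSequence(id="numt", ref_start=1, columns="".join(cols))
        found = {
            (d.gene, d.codon.codon_index, d.kind)
            for d in orf_integrity_scan(anchored, gene_map)
        }
        assert ("ND5", 35, "premature_stop") in found
        assert ("ND3", 108, "premature_stop") in found
        assert ("COX2", 204, "frameshift_indel") in found

    def test_in_frame_deletion_not_a_frameshift(self, reference, gene_map):
        cox2 = gene_map.gene("COX2")
        lo, hi = codon_span(cox2, 100)
        cols = list(reference.residues)
        cols[lo - 1 : hi] = ["-", "-", "-"]
        anchored = AnchoredSequence(id="x", ref_start=1, columns="".join(cols))
        kinds = {d.kind for d in orf_integrity_scan(anchored, gene_map)}
        assert "frameshift_indel" not in kinds


class TestRepair:
    def _stop_at(self, reference, gene_map, gene_name, codon_index):
        cols = list(reference.residues)
        gene = gene_map.gene(gene_name)
        lo, _ = codon_span(gene, codon_index)
        old = cols[lo - 1 : lo + 2]
        cols[lo - 1 : lo + 2] = list("TAA")
        return AnchoredSequence(id="numt", ref_start=1, columns="".join(cols)), \
            "".join(old), lo

    def test_premature_stop_replaced_with_panel_majority(self, reference, gene_map):
        focal, old_codon, lo = self._stop_at(reference, gene_map, "ND5", 35)
        panel_rows = [AnchoredSequence.from_reference(reference)] * 3
        disruptions = orf_integrity_scan(focal, gene_map)
        repaired, log = repair_disruptions(focal, disruptions, panel_rows, gene_map)
        assert repaired.columns[lo - 1 : lo + 2] == old_codon
        assert any(
            e.action == "replaced_with_panel_majority" and e.gene == "ND5"
            and e.codon_index == 35 for e in log
        )

    def test_frameshift_codon_excluded(self, reference, gene_map):
        cox2 = gene_map.gene("COX2")
        lo, _ = codon_span(cox2, 204)
        cols = list(reference.residues)
        cols[lo - 1 : lo + 1] = ["-", "-"]
        focal = AnchoredSequence(id="numt", ref_start=1, columns="".join(cols))
        disruptions = orf_integrity_scan(focal, gene_map)
        _, log = repair_disruptions(
            focal, disruptions, [AnchoredSequence.from_reference(reference)],
            gene_map,
        )
        assert CodonEdit("COX2", 204, "excluded_codon", "--" + cols[lo + 1], None) in log

    def test_no_disruptions_is_identity(self, reference, gene_map):
        focal = AnchoredSequence.from_reference(reference)
        repaired, log = repair_disruptions(focal, [], [], gene_map)
        assert repaired.columns == focal.columns and log == []

    def test_no_consensus_masks(self, reference, gene_map):
        focal, _, lo = self._stop_at(reference, gene_map, "ND5", 35)
        disruptions = orf_integrity_scan(focal, gene_map)
        repaired, log = repair_disruptions(focal, disruptions, [], gene_map)
        assert repaired.columns[lo - 1 : lo + 2] == "NNN"
        assert log[0].action == "masked"


class TestCpG:
    def _rec(self, ref, alt, cpg):
        site = type("S", (), {"category": "intergenic", "gene": None,
                              "codon": None, "incomplete_codon": False})()
        return SubstitutionRecord(1, site, ref, alt, True, cpg,
                                  "private_to_focal")

    def test_counts_flagged_and_unknown(self):
        recs = [self._rec("C", "T", True), self._rec("C", "T", False),
                self._rec("G", "A", None)]
        assert cpg_check(recs) == (1, 1)

    def test_context_from_consensus(self, reference, gene_map):
        # find a CG doublet inside ND5 and mutate its C -> T in the focal
        lo, hi = 12400, 14000
        idx = reference.residues.find("CG", lo)
        pos = idx + 1  # 1-based C of the doublet
        panel = make_panel(reference, (12337, 14148), {"numt": {pos: "T"}})
        (rec,) = call_private_substitutions(panel, "numt", gene_map)
        assert rec.cpg_context is True

    def test_non_cpg_transition_not_flagged(self, reference, gene_map):
        idx = reference.residues.find("CA", 12400)
        pos = idx + 1
        panel = make_panel(reference, (12337, 14148), {"numt": {pos: "T"}})
        (rec,) = call_private_substitutions(panel, "numt", gene_map)
        assert rec.cpg_context is False


class TestPathogenicOverlap:
    def _rec(self, pos, ref, alt):
        site = type("S", (), {"category": "coding", "gene": "ND3",
                              "codon": None, "incomplete_codon": False})()
        return SubstitutionRecord(pos, site, ref, alt, True, False,
                                  "private_to_focal")

    def test_matching_position_and_allele(self):
        hits = pathogenic_overlap(
            [self._rec(10398, "A", "G")],
            [(10398, "G", "Parkinson-protective")],
        )
        assert len(hits) == 1 and hits[0][1] == "Parkinson-protective"

    def test_empty_table(self):
        assert pathogenic_overlap([self._rec(10398, "A", "G")], []) == []

    def test_allele_mismatch_no_hit(self):
        assert pathogenic_overlap(
            [self._rec(10398, "A", "G")], [(10398, "T", "x")]
        ) == []

    def test_malformed_row_reports_line(self):
        with pytest.raises(ValueError, match="row 2"):
            pathogenic_overlap([], [(1, "A", "ok"), ("x", "A", "bad")])


class TestVerdict:
    def test_reference_as_focal_is_mitochondrial(self, reference, gene_map):
        panel = make_panel(reference, (12337, 14148), {})
        records = call_private_substitutions(panel, "numt", gene_map)
        report = provenance_verdict("numt", records)
        assert report.n_private == 0
        assert report.verdict == "mitochondrial-signature"

    def test_verdict_invariant_to_panel_row_order(self, reference, gene_map):
        edits = {"numt": {12500: "A" if reference.residues[12499] != "A" else "G"}}
        labels = ["human_1", "human_2", "human_3", "neanderthal", "numt"]
        p1 = make_panel(reference, (12337, 14148), edits, labels)
        p2 = make_panel(reference, (12337, 14148), edits, labels[::-1])
        r1 = provenance_verdict(
            "numt", call_private_substitutions(p1, "numt", gene_map))
        r2 = provenance_verdict(
            "numt", call_private_substitutions(p2, "numt", gene_map))
        assert r1.verdict == r2.verdict
        assert r1.codon_position_counts == r2.codon_position_counts

    def test_nuclear_pattern_flagged(self):
        # uniform codon positions, transversion-heavy: nuclear signature
        recs = []
        for i, (ref, alt) in enumerate([("A", "T"), ("C", "G"), ("A", "C")] * 20):
            codon = type("C", (), {"codon_position": i % 3 + 1})()
            site = type("S", (), {"category": "coding", "gene": "ND5",
                                  "codon": codon, "incomplete_codon": False})()
            recs.append(SubstitutionRecord(i + 1, site, ref, alt, False, False,
                                           "private_to_focal"))
        report = provenance_verdict("numt", recs)
        assert report.verdict in ("nuclear-signature", "mixed")
        assert report.bias_test_215.p_value < 0.05

    def test_per_gene_report_shape(self, reference, gene_map):
        pos = 12500
        alt = "A" if reference.residues[12499] != "A" else "G"
        panel = make_panel(reference, (12337, 14148), {"numt": {pos: alt}})
        records = call_private_substitutions(panel, "numt", gene_map)
        table = per_gene_report(records)
        assert list(table["gene"]) == ["ND5"]
        assert table.iloc[0][["pos1", "pos2", "pos3"]].sum() == 1
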