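import math

import numpy as np
import pytest

from paleonumt.clock_dating import Topology
from paleonumt.mito_core import translate_mito
from paleonumt.selection_tests import (
    BranchChangeSummary,
    ExcludedCodon,
    MKCounts,
    assign_changes_to_branches,
    branch_dnds,
    classify_change,
    fisher_exact_2x2,
    flag_heterogeneous_branches,
    mk_counts,
    mk_test,
    neutrality_index,
    ng86_sites,
    unique_amino_acids,
)
from paleonumt.synthetic_data import SimNode


def fisher_oracle(ds, ps, dn, pn):
    """Two-tailed Fisher by explicit hypergeometric enumeration."""
    r1, r2 = ds + ps, dn + pn
    c1 = ds + dn
    N = r1 + r2

    def p_of(a):
        c = c1 - a
        if not (0 <= c <= r2 and 0 <= r1 - a):
            return 0.0
        return math.comb(r1, a) * math.comb(r2, c) / math.comb(N, c1)

    obs = p_of(ds)
    return sum(p_of(a) for a in range(c1 + 1) if p_of(a) <= obs * (1 + 1e-12))


class TestClassifyChange:
    @pytest.mark.parametrize(
        "codon,pos,ref,alt,expected",
        [
            ("CTA", 3, "A", "G", "synonymous"),  # Leu -> Leu
            ("ATA", 2, "T", "C", "nonsynonymous"),  # Met -> Thr
            ("TAC", 3, "C", "A", "nonsense"),  # Tyr -> stop
            ("TGA", 3, "A", "G", "synonymous"),  # Trp -> Trp (TGA=TGG=W)
            ("AGC", 1, "A", "C", "nonsynonymous"),
        ],
    )
    def test_examples(self, codon, pos, ref, alt, expected):
        assert classify_change(codon, pos, ref, alt) == expected

    def test_gap_in_context_signals_exclusion(self):
        with pytest.raises(ExcludedCodon):
            classify_change("A-G", 1, "A", "G")


class TestFisher:
    def test_equals_enumeration_oracle_small_tables(self):
        for total in range(1, 19):
            for ds in range(total + 1):
                for ps in range(total - ds + 1):
                    for dn in range(total - ds - ps + 1):
                        pn = total - ds - ps - dn
                        got = fisher_exact_2x2(MKCounts("g", ds, dn, ps, pn))
                        want = fisher_oracle(ds, ps, dn, pn)
                        if min(ds + ps, dn + pn) == 0 or min(ds + dn, ps + pn) == 0:
                            assert got == 1.0
                        else:
                            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_equals_oracle_sampled_larger_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ds, ps, dn, pn = rng.integers(0, 11, size=4)
            if ds + ps + dn + pn > 40:
                continue
            got = fisher_exact_2x2(MKCounts("g", int(ds), int(dn), int(ps), int(pn)))
            want = fisher_oracle(int(ds), int(ps), int(dn), int(pn))
            if min(ds + ps, dn + pn) == 0 or min(ds + dn, ps + pn) == 0:
                assert got == 1.0
            else:
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestNeutralityIndex:
    def test_neutral_identity(self):
        assert neutrality_index(MKCounts("g", 10, 5, 20, 10)) == 1.0

    def test_undefined_cases(self):
        assert neutrality_index(MKCounts("g", 0, 5, 10, 10)) is None  # Ds=0
        assert neutrality_index(MKCounts("g", 10, 0, 10, 10)) is None  # Dn=0
        assert neutrality_index(MKCounts("g", 10, 5, 0, 10)) is None  # Ps=0

    def test_zero_pn_gives_zero_not_undefined(self):
        assert neutrality_index(MKCounts("g", 10, 5, 10, 0)) == 0.0

    def test_rounding_to_three_decimals(self):
        assert neutrality_index(MKCounts("g", 78, 30, 51, 23)) == 1.173


class TestMKCounts:
    def test_identical_rows_give_zero_counts(self):
        cds = "ATGCTACGATTC"
        c = mk_counts([cds, cds, cds], cds, "g")
        assert (c.ds, c.dn, c.ps, c.pn) == (0, 0, 0, 0)

    def test_divergent_synonymous_site(self):
        # humans fixed CTA (Leu); ancestor CTG (Leu): one Ds
        humans = ["ATGCTA", "ATGCTA", "ATGCTA"]
        c = mk_counts(humans, "ATGCTG", "g")
        assert (c.ds, c.dn, c.ps, c.pn) == (1, 0, 0, 0)

    def test_divergent_nonsynonymous_site(self):
        # ATA (Met) vs ACA (Thr) at codon 2
        humans = ["ATGATA", "ATGATA"]
        c = mk_counts(humans, "ATGACA", "g")
        assert (c.ds, c.dn) == (0, 1)

    def test_polymorphic_site_counts_each_derived_allele(self):
        humans = ["ATGCTA", "ATGCTG", "ATGCTA"]
        c = mk_counts(humans, "ATGCTA", "g")
        assert (c.ps, c.pn, c.ds, c.dn) == (1, 0, 0, 0)

    def test_site_both_polymorphic_and_divergent_is_polymorphism_only(self):
        humans = ["ATGCTA", "ATGCTG"]
        c = mk_counts(humans, "ATGCTC", "g")
        assert (c.ps, c.ds) == (1, 0)

    def test_excluded_codon_dropped(self):
        humans = ["ATGCTA", "ATGCTG"]
        c = mk_counts(humans, "ATGCTC", "g", excluded_codons={2})
        assert (c.ds, c.dn, c.ps, c.pn) == (0, 0, 0, 0)

    def test_conservation_polymorphism_total(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), size=300))
        # avoid stop-affected arithmetic by classifying everything the
        # same way mk_counts does: just check Ps+Pn equals the number of
        # classified derived alleles at variable sites
        humans = []
        for k in range(5):
            s = list(base)
            for i in rng.integers(0, 300, size=6):
                s[i] = rng.choice(list("ACGT"))
            humans.append("".join(s))
        c = mk_counts(humans, base, "g")
        from paleonumt.selection_tests import _consensus_codon

        expected = 0
        for ci in range(100):
            codons = [h[3 * ci : 3 * ci + 3] for h in humans]
            ctx = _consensus_codon(codons)
            for k in range(3):
                alleles = {cd[k] for cd in codons}
                if len(alleles) > 1:
                    expected += len(alleles - {ctx[k]})
        assert c.ps + c.pn == expected

    def test_neutral_simulation_pooled_ni_near_one(self):
        # equal-rate (neutral) changes in humans and ancestor: pooled NI -> 1
        rng = np.random.default_rng(7)
        tot = np.zeros(4)  # ds, dn, ps, pn
        for rep in range(150):
            base = "".join(rng.choice(list("ACGT"), size=120))
            humans = []
            for _ in range(4):
                s = list(base)
                for i in rng.integers(0, 120, size=3):
                    s[i] = rng.choice(list("ACGT"))
                humans.append("".join(s))
            anc = list(base)
            for i in rng.integers(0, 120, size=4):
                anc[i] = rng.choice(list("ACGT"))
            c = mk_counts(humans, "".join(anc), "g")
            tot += (c.ds, c.dn, c.ps, c.pn)
        ds, dn, ps, pn = tot
        ni = (pn / ps) / (dn / ds)
        assert 0.8 < ni < 1.25

    def test_mk_test_wraps_counts(self):
        res = mk_test(["ATGCTA", "ATGCTA"], "ATGCTG", "g")
        assert res.counts.ds == 1 and res.p_value == 1.0


class TestParsimonyAssignment:
    def _hominin_topo(self):
        tree = SimNode(
            "root", 4,
            [
                SimNode(
                    "homo", 3,
                    [
                        SimNode("hn", 2, [SimNode("human_1", 0),
                                          SimNode("neanderthal", 0)]),
                        SimNode("numt", 0),
                    ],
                ),
                SimNode("pan", 1, [SimNode("chimp", 0), SimNode("bonobo", 0)]),
            ],
        )
        return Topology.from_simnode(tree)

    def test_single_derived_residue_on_terminal_branch(self):
        topo = Topology.from_simnode(
            SimNode("r", 2, [SimNode("anc", 1, [SimNode("A", 0), SimNode("B", 0)]),
                             SimNode("C", 0)])
        )
        res = assign_changes_to_branches({"A": "M", "B": "V", "C": "V"}, topo)
        assert len(res) == 1
        assert res[0].branch == "A" and res[0].nonsynonymous == 1.0

    def test_shared_hominin_replacement_maps_to_stem(self):
        topo = self._hominin_topo()
        rows = {"human_1": "K", "neanderthal": "K", "numt": "K",
                "chimp": "R", "bonobo": "R"}
        res = assign_changes_to_branches(rows, topo)
        # exactly one change on the homo/pan stem edge; with an unrooted
        # ambiguity the fraction splits across the two root-adjacent
        # halves of that same edge
        assert all(s.branch in ("homo", "pan") for s in res)
        assert sum(s.nonsynonymous for s in res) == pytest.approx(1.0)

    def test_homoplasy_free_planted_counts_recovered_exactly(self):
        topo = self._hominin_topo()
        labels = topo.tip_labels()
        # plant: 2 changes on the human_1 branch, 1 on the numt branch,
        # 3 on the pan stem, at distinct columns
        n_cols = 6
        base = ["A"] * n_cols
        rows = {l: base[:] for l in labels}
        for col in (0, 1):
            rows["human_1"][col] = "S"
        rows["numt"][2] = "T"
        for col in (3, 4, 5):
            for l in ("chimp", "bonobo"):
                rows[l][col] = "W"
        rows = {l: "".join(v) for l, v in rows.items()}
        res = {s.branch: s.nonsynonymous for s in
               assign_changes_to_branches(rows, topo)}
        assert res.get("human_1") == 2.0
        assert res.get("numt") == 1.0
        assert sum(v for b, v in res.items() if b in ("pan", "homo")) == 3.0

    def test_ambiguous_site_counts_fractionally(self):
        # A/B vs C/D cherries with conflicting states: two equally
        # parsimonious placements share the single change
        topo = Topology.from_simnode(
            SimNode("r", 2, [
                SimNode("ab", 1, [SimNode("A", 0), SimNode("B", 0)]),
                SimNode("cd", 1, [SimNode("C", 0), SimNode("D", 0)]),
            ])
        )
        rows = {"A": "K", "B": "R", "C": "K", "D": "R"}
        res = assign_changes_to_branches(rows, topo)
        total = sum(s.nonsynonymous for s in res)
        assert total == pytest.approx(2.0)
        assert all(s.nonsynonymous < 2.0 for s in res)


class TestNG86AndBranchDnDs:
    def test_site_counts_hand_computed(self):
        # ATG (Met): only ATA at position 3 is synonymous
        n, s = ng86_sites("ATG")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(3 - 1 / 3)
        # CTA (Leu): pos1 TTA is Leu too (syn); pos3 fourfold... under the
        # mito code CTN all Leu -> pos3 fully synonymous
        n2, s2 = ng86_sites("CTA")
        assert s2 == pytest.approx(1 / 3 + 1)

    def test_gapped_codons_skipped(self):
        assert ng86_sites("AT-CTA") == pytest.approx(ng86_sites("CTA"))

    def _simulate(self, omega, seed, n_codons=800, subs_per_branch=60):
        """Evolve codon sequences with nonsyn changes accepted at rate
        omega; an unchanged outgroup keeps ancestral states identifiable."""
        rng = np.random.default_rng(seed)
        sense = [c for c in
                 (a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
                 if translate_mito(c) != "*"]
        root = "".join(rng.choice(sense, size=n_codons))
        tree = SimNode(
            "r", 2,
            [SimNode("xy", 1, [SimNode("x", 0), SimNode("y", 0)]),
             SimNode("z", 0)],
        )
        topo = Topology.from_simnode(tree)

        def evolve(seq):
            s = list(seq)
            done = 0
            while done < subs_per_branch:
                i = int(rng.integers(0, len(s)))
                old = s[i]
                new = rng.choice([b for b in "ACGT" if b != old])
                ci = i // 3
                codon = "".join(s[3 * ci : 3 * ci + 3])
                cand = codon[: i % 3] + new + codon[i % 3 + 1 :]
                if translate_mito(cand) == "*":
                    continue
                nonsyn = translate_mito(cand) != translate_mito(codon)
                if nonsyn and rng.random() > omega:
                    continue
                s[i] = new
                done += 1
            return "".join(s)

        rows = {"x": evolve(root), "y": evolve(root), "z": root}
        return rows, topo

    @staticmethod
    def _pooled_ratio(summaries):
        n = sum(s.nonsynonymous for s in summaries if s.branch in ("x", "y"))
        syn = sum(s.synonymous for s in summaries if s.branch in ("x", "y"))
        per = {s.branch: s for s in summaries}
        n_sites = 1 / (per["x"].dn / per["x"].nonsynonymous) \
            if per["x"].nonsynonymous else None
        s_sites = 1 / (per["x"].ds / per["x"].synonymous) \
            if per["x"].synonymous else None
        return (n / n_sites) / (syn / s_sites)

    def test_equal_rates_give_ratio_near_one(self):
        rows, topo = self._simulate(omega=1.0, seed=3, n_codons=1500,
                                    subs_per_branch=150)
        ratio = self._pooled_ratio(branch_dnds(rows, topo))
        assert 0.7 < ratio < 1.4

    def test_purifying_selection_lowers_ratio(self):
        rows, topo = self._simulate(omega=0.1, seed=2, n_codons=1500,
                                    subs_per_branch=150)
        ratio = self._pooled_ratio(branch_dnds(rows, topo))
        assert ratio < 0.3

    def test_zero_synonymous_changes_flag_undefined(self):
        s = BranchChangeSummary("b", nonsynonymous=3, synonymous=0, dn=0.1, ds=0.0)
        assert s.dnds is None

    def test_flagging_respects_level(self):
        summaries = [
            BranchChangeSummary("a", 50, 50),
            BranchChangeSummary("b", 5, 95),
        ]
        flagged = flag_heterogeneous_branches(summaries, level=0.004)
        assert "b" in flagged


class TestUniqueAminoAcids:
    ROWS = {"numt": "MKVL", "h1": "MKAL", "h2": "MKAL", "nea": "MKAL"}

    def test_focal_equal_to_panel_gives_empty(self):
        rows = dict(self.ROWS, numt="MKAL")
        assert unique_amino_acids(rows, "numt") == []

    def test_planted_unique_residue_recovered(self):
        (res,) = unique_amino_acids(self.ROWS, "numt")
        assert (res.position, res.focal_residue, res.panel_residues) == (3, "V", "A")

    def test_orthologue_presence_flagged(self):
        (res,) = unique_amino_acids(
            self.ROWS, "numt", orthologue_rows={"gorilla": "MKVL"}
        )
        assert res.known_in_other_species is True
        (res2,) = unique_amino_acids(
            self.ROWS, "numt", orthologue_rows={"gorilla": "MKAL"}
        )
        assert res2.known_in_other_species is False

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            unique_amino_acids({"numt": "MK", "h1": "MKA"}, "numt")
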