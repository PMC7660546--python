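"""Mutation screen: gene assembly, truncation rules, clinical-site
mapping oracle, pleiotropy scoring and the exact association test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from cryodrift.screen import (
    ClinicalSiteMatch,
    PleiotropyAnnotation,
    ScreenError,
    assemble_gene_sequence,
    call_truncations,
    classify_erythroid_bias,
    lof_pleiotropy_association,
    map_human_sites,
    pleiotropy_score,
    screen_pileups,
)
from cryodrift.simulate import SimulationConfig, simulate_pileups


class TestAssembly:
    def test_offsets_and_concatenation(self):
        recs = [("g", 0, "A" * 100), ("g", 1, "C" * 50), ("g", 2, "G" * 150)]
        gs = assemble_gene_sequence(recs)
        assert len(gs.sequence) == 300
        assert gs.offsets == [0, 100, 150]
        assert gs.missing_exons == []

    def test_isoform_duplicate_collapsed(self):
        recs = [("g", 0, "AAA"), ("g", 1, "CCC"), ("g", 1, "CCC")]
        gs = assemble_gene_sequence(recs)
        assert gs.sequence == "AAACCC"

    def test_conflicting_exon_rejected(self):
        with pytest.raises(ScreenError, match="conflicting"):
            assemble_gene_sequence([("g", 0, "AAA"), ("g", 0, "TTT")])

    def test_missing_exon_recorded(self):
        gs = assemble_gene_sequence([("g", 0, "AAA"), ("g", 2, "GGG")])
        assert gs.missing_exons == [1]
        assert gs.sequence == "AAAGGG"


def pileup_df(rows):
    return pd.DataFrame(
        rows, columns=["species", "gene", "exon", "pos", "ref", "alt", "support", "depth"]
    )


@pytest.fixture
def gene():
    # 10 codons incl. terminal stop; no internal stops
    seq = "ATGGCCGAAGTTCTGCGTACCGATAAGTAA"
    return assemble_gene_sequence([("g", 0, seq[:15]), ("g", 1, seq[15:])])


class TestCallTruncations:
    def test_min_support_rule(self, gene):
        rows = pileup_df(
            [
                ("sp", "g", 0, 0, ".", ".", 0, 10),
                ("sp", "g", 0, 4, "CCGAA", "C", 2, 10),  # 4-bp del, 2 reads
            ]
        )
        assert call_truncations(gene, rows) == []
        rows.loc[1, "support"] = 3
        calls = call_truncations(gene, rows)
        assert [c.kind for c in calls] == ["frameshift"]
        assert not calls[0].fixed  # 3/10 reads

    def test_frame_divisibility_rule(self, gene):
        inframe = pileup_df([("sp", "g", 0, 4, "CCGA", "C", 5, 5)])  # 3-bp del
        assert call_truncations(gene, inframe) == []
        frameshift = pileup_df([("sp", "g", 0, 4, "CCGAA", "C", 5, 5)])  # 4-bp del
        calls = call_truncations(gene, frameshift)
        assert [c.kind for c in calls] == ["frameshift"]
        assert calls[0].fixed

    def test_nonsense_before_terminal_codon_only(self, gene):
        # codon 7 'GAT' -> TAT is not stop; GAT pos 21 G->T gives TAT (missense)
        # use codon 5 'CGT': C->T at pos 15 gives TGT (Cys, missense);
        # craft a real stop: codon 4 'CTG': C->T -> TTG no. Use direct:
        # codon 6 'ACC' pos 18; no. Simplest real case: 'GAA' codon 2,
        # G->T at pos 6 gives TAA = stop.
        rows = pileup_df([("sp", "g", 0, 6, "G", "T", 4, 4)])
        calls = call_truncations(gene, rows)
        assert [c.kind for c in calls] == ["nonsense"]
        # the same substitution in the terminal codon is not nonsense:
        # terminal codon is TAA already; a change within it is ignored
        rows2 = pileup_df([("sp", "g", 1, 27, "T", "G", 4, 4)])
        assert all(c.kind != "nonsense" for c in call_truncations(gene, rows2))

    def test_whole_gene_deletion(self, gene):
        rows = pileup_df(
            [("sp", "g", 0, 0, ".", ".", 0, 0), ("sp", "g", 1, 15, ".", ".", 0, 0)]
        )
        calls = call_truncations(gene, rows, species_covered_elsewhere=True)
        assert [c.kind for c in calls] == ["whole_gene_deletion"]
        # without data elsewhere the zero coverage is not interpretable
        assert (
            call_truncations(gene, rows, species_covered_elsewhere=False) == []
        )

    def test_row_order_invariance(self, gene):
        rows = pileup_df(
            [
                ("sp", "g", 0, 6, "G", "T", 4, 4),
                ("sp", "g", 0, 4, "CCGAA", "C", 5, 5),
                ("sp", "g", 0, 0, ".", ".", 0, 10),
            ]
        )
        a = call_truncations(gene, rows)
        b = call_truncations(gene, rows.iloc[::-1].reset_index(drop=True))
        assert a == b

    def test_undefined_frame_rejected(self):
        gs = assemble_gene_sequence([("g", 0, "AAAA")])  # not a codon multiple
        with pytest.raises(ScreenError, match="frame"):
            call_truncations(gs, pileup_df([]))


class TestPlantedVariantRecovery:
    def test_calls_equal_planted_truncations(self):
        """Exact set equality: every planted fixed truncating variant with
        >= 3 supporting reads is called; nothing else is."""
        cfg = SimulationConfig(seed=21)
        pileups, exons, truth = simulate_pileups(cfg)
        calls = screen_pileups(pileups, exons)
        got = {
            (c.species, c.gene_id, c.kind, c.position)
            for c in calls
            if c.kind in ("frameshift", "nonsense", "whole_gene_deletion")
        }
        expected = set()
        for v in truth.planted_variants:
            if v["kind"] in ("frameshift", "nonsense") and v["support"] >= 3:
                expected.add((v["species"], v["gene_id"], v["kind"], v["position"]))
            elif v["kind"] == "whole_gene_deletion":
                expected.add((v["species"], v["gene_id"], v["kind"], None))
        assert got == expected

    def test_pileup_row_order_irrelevant(self):
        cfg = SimulationConfig(seed=22)
        pileups, exons, _ = simulate_pileups(cfg)
        a = screen_pileups(pileups, exons)
        shuffled = pileups.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = screen_pileups(shuffled, exons)
        assert sorted(a, key=repr) == sorted(b, key=repr)


class TestMapHumanSites:
    ALN = {
        "human":   "MR-KLV",
        "anc1":    "MRAKLV",
        "anc2":    "MRAKLV",
        "anc3":    "MRAKLI",
        "focal":   "MKAKLV",
    }

    def make_clinical(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "position", "variant_aa", "clinical_id"])

    def test_basic_match(self):
        clin = self.make_clinical([("g", 2, "K", "rs1")])
        out = map_human_sites(self.ALN, clin, "g", ["focal"], ["anc1", "anc2", "anc3"])
        assert len(out) == 1
        m = out[0]
        assert (m.human_position, m.species_residue, m.clinical_id) == (2, "K", "rs1")
        assert m.ancestral_residue == m.human_residue == "R"

    def test_ancestral_human_mismatch_excluded(self):
        aln = dict(self.ALN, human="MQ-KLV")  # human Q, ancestral R
        clin = self.make_clinical([("g", 2, "K", "rs1")])
        assert map_human_sites(aln, clin, "g", ["focal"], ["anc1", "anc2", "anc3"]) == []

    def test_position_outside_human_sequence_warns(self):
        clin = self.make_clinical([("g", 99, "K", "rs1")])
        with pytest.warns(UserWarning, match="outside"):
            out = map_human_sites(self.ALN, clin, "g", ["focal"], ["anc1", "anc2", "anc3"])
        assert out == []

    def test_matches_brute_force_scan(self, rng):
        """Random toy alignments: results equal a column-by-column oracle."""
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for rep in range(20):
            ncol = 30
            cols = rng.choice(aas, size=(6, ncol))
            species = ["human", "o1", "o2", "o3", "o4", "focal"]
            aln = {s: "".join(cols[i]) for i, s in enumerate(species)}
            clin_rows = [
                ("g", int(rng.integers(1, ncol + 1)), str(rng.choice(aas)), f"rs{k}")
                for k in range(10)
            ]
            clin = pd.DataFrame(
                clin_rows, columns=["gene_id", "position", "variant_aa", "clinical_id"]
            )
            got = map_human_sites(aln, clin, "g", ["focal"], ["o1", "o2", "o3", "o4"])
            # oracle
            expected = []
            for col in range(ncol):
                h = aln["human"][col]
                outres = [aln[o][col] for o in ["o1", "o2", "o3", "o4"]]
                vals, counts = np.unique(outres, return_counts=True)
                anc = vals[np.argmax(counts)] if counts.max() / 4 >= 2 / 3 else None
                if anc is None or anc != h:
                    continue
                res = aln["focal"][col]
                if res == anc:
                    continue
                for g, pos, va, cid in clin_rows:
                    if pos == col + 1 and va == res:
                        expected.append((col, cid))
            assert [(m.column, m.clinical_id) for m in got] == expected


CHILDREN = {
    "root": {"hemato", "cranio", "muscle", "size"},
    "hemato": {"anemia", "rbc"},
    "size": {"organ_size"},
}


class TestPleiotropy:
    def test_hematopoietic_only_scores_zero(self):
        a = pleiotropy_score("g", {"anemia", "rbc"}, CHILDREN, "hemato")
        assert a.score == 0

    def test_craniofacial_term_scores(self):
        a = pleiotropy_score("g", {"anemia", "cranio"}, CHILDREN, "hemato")
        assert a.score == 1

    def test_excluded_indirect_terms_ignored(self):
        a = pleiotropy_score(
            "g", {"organ_size"}, CHILDREN, "hemato", excluded_terms={"size"}
        )
        assert a.score == 0

    def test_unknown_terms_warn_and_ignored(self):
        with pytest.warns(UserWarning, match="absent"):
            a = pleiotropy_score("g", {"zzz", "muscle"}, CHILDREN, "hemato")
        assert a.score == 1

    def test_monotone_in_annotations(self):
        base = pleiotropy_score("g", {"cranio"}, CHILDREN, "hemato").score
        more = pleiotropy_score("g", {"cranio", "muscle"}, CHILDREN, "hemato").score
        assert more >= base


class TestErythroidBias:
    def _frames(self):
        lin = pd.DataFrame(
            {"erythrocyte": [100, 10, 0], "myeloid": [10, 10, 0], "lymphoid": [5, 10, 0]},
            index=["g1", "g2", "g3"],
        )
        org = pd.DataFrame(
            {"bone_marrow": [50, 5, 0], "liver": [10, 50, 0]},
            index=["g1", "g2", "g3"],
        )
        return lin, org

    def test_threshold_rule(self):
        lin, org = self._frames()
        with pytest.warns(UserWarning, match="all-zero"):
            out = classify_erythroid_bias(lin, org, fold=2.0)
        assert out.loc["g1", "erythroid_biased"]
        assert not out.loc["g2", "erythroid_biased"]
        assert not out.loc["g3", "erythroid_biased"]  # all-zero row
        assert out.loc["g1", "marrow_restricted"]
        assert not out.loc["g2", "marrow_restricted"]

    def test_fold_one_weak_maximum(self):
        lin = pd.DataFrame(
            {"erythrocyte": [10.0], "myeloid": [10.0], "lymphoid": [3.0]}, index=["g"]
        )
        org = pd.DataFrame({"bone_marrow": [1.0], "liver": [2.0]}, index=["g"])
        out = classify_erythroid_bias(lin, org, fold=1.0)
        assert out.loc["g", "erythroid_biased"]  # ties count at fold 1
        assert not out.loc["g", "marrow_restricted"]


def fisher_enumeration(table):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            comb(r1, x, exact=True)
            * comb(r2, c1 - x, exact=True)
            / comb(n, c1, exact=True)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestLofAssociation:
    def _annos(self, a, b, c, d):
        out = []
        out += [PleiotropyAnnotation(f"a{i}", 0, has_lof=True) for i in range(a)]
        out += [PleiotropyAnnotation(f"b{i}", 0, has_lof=False) for i in range(b)]
        out += [PleiotropyAnnotation(f"c{i}", 2, has_lof=True) for i in range(c)]
        out += [PleiotropyAnnotation(f"d{i}", 1, has_lof=False) for i in range(d)]
        return out

    def test_balanced_table(self):
        orr, p, table = lof_pleiotropy_association(self._annos(5, 5, 5, 5))
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation(self):
        orr, p, _ = lof_pleiotropy_association(self._annos(10, 0, 0, 10))
        assert p == pytest.approx(2 / comb(20, 10, exact=True))
        assert orr > 100  # Haldane-corrected, finite

    def test_matches_enumeration_for_small_tables(self, rng):
        """p equals full hypergeometric enumeration on all tables n <= 20."""
        checked = 0
        for n in range(4, 21):
            for _ in range(6):
                cells = rng.multinomial(n, [0.25] * 4)
                a, b, c, d = (int(x) for x in cells)
                if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                    continue
                _, p, table = lof_pleiotropy_association(self._annos(a, b, c, d))
                assert p == pytest.approx(fisher_enumeration(table), rel=1e-9)
                checked += 1
        assert checked > 50

    def test_empty_margin_rejected(self):
        with pytest.raises(ScreenError):
            lof_pleiotropy_association(self._annos(5, 5, 0, 0))
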