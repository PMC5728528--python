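import numpy as np
import pytest

from metapair.classify import (
    ClassifierParams,
    MODE_DUAL,
    MODE_LCA,
    MODE_SINGLE,
    MODE_UNASSIGNED,
    ReferenceIndex,
    categorize_motu,
    dual_read_assign,
    lca_assign,
    single_read_assign,
    standard_barcode_identify,
)
from metapair.lineage import Lineage
from metapair.seq_compare import revcomp
from metapair.synthetic import ReferenceRecord


def lineage(family, genus, species, order="Hymenoptera"):
    return Lineage(("Animalia", "Arthropoda", "Insecta", order,
                    family, family + "inae", genus, species))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng, seq, k):
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


def mates_of(amplicon, read_len=293):
    return amplicon[:read_len], revcomp(amplicon)[:read_len]


class TestDualReadAssign:
    def test_exact_pair_single_reference(self, rng):
        amp = random_dna(rng, 658)
        library = ReferenceIndex([
            ReferenceRecord("ref1", lineage("Fam1", "Gen1", "sp1"), amp),
            ReferenceRecord("other", lineage("Fam9", "Gen9", "sp9"),
                            random_dna(rng, 658)),
        ])
        fwd, rev = mates_of(amp)
        res = dual_read_assign(fwd, rev, library)
        assert res.mode == MODE_DUAL
        assert res.lineage == lineage("Fam1", "Gen1", "sp1")
        assert res.best_avg_identity_pct == pytest.approx(100.0)
        assert res.n_retained_hits == 1

    def test_three_hit_majority_species(self, rng):
        amp = random_dna(rng, 658)
        library = ReferenceIndex([
            ReferenceRecord("a", lineage("Fam1", "Gen1", "sp1"), amp),
            ReferenceRecord("b", lineage("Fam1", "Gen1", "sp1"), amp),
            ReferenceRecord("c", lineage("Fam1", "Gen1", "sp2"), amp),
        ])
        fwd, rev = mates_of(amp)
        res = dual_read_assign(fwd, rev, library)
        assert res.n_retained_hits == 3
        assert res.lineage.name_at("species") == "sp1"  # 2/3 >= 0.5

    def test_two_two_tie_backs_off_to_family(self, rng):
        amp = random_dna(rng, 658)
        library = ReferenceIndex([
            ReferenceRecord("a1", lineage("Fam1", "Gen1", "sp1"), amp),
            ReferenceRecord("a2", lineage("Fam1", "Gen1", "sp1"), amp),
            ReferenceRecord("b1", lineage("Fam1", "Gen2", "sp3"), amp),
            ReferenceRecord("b2", lineage("Fam1", "Gen2", "sp3"), amp),
        ])
        fwd, rev = mates_of(amp)
        res = dual_read_assign(fwd, rev, library)
        # species and genus tie at exactly 0.5/0.5 -> walk stops at family
        assert res.lineage.deepest_rank == "subfamily"
        assert res.lineage.name_at("family") == "Fam1"

    def test_single_read_fallback(self, rng):
        amp = random_dna(rng, 658)
        library = ReferenceIndex([
            ReferenceRecord("ref1", lineage("Fam1", "Gen1", "sp1"), amp),
        ])
        fwd = amp[:293]
        junk = random_dna(rng, 293)
        res = dual_read_assign(fwd, junk, library)
        assert res.mode == MODE_SINGLE
        assert res.lineage.name_at("species") == "sp1"

    def test_unassigned_when_nothing_matches(self, rng):
        library = ReferenceIndex([
            ReferenceRecord("ref1", lineage("Fam1", "Gen1", "sp1"),
                            random_dna(rng, 658)),
        ])
        res = dual_read_assign(random_dna(rng, 293), random_dna(rng, 293),
                               library)
        assert res.mode == MODE_UNASSIGNED
        assert not res.lineage

    def test_window_property(self, rng):
        params = ClassifierParams()
        refs = []
        base = random_dna(rng, 658)
        for i in range(6):
            refs.append(ReferenceRecord(
                f"r{i}", lineage("Fam1", "Gen1", f"sp{i}"),
                mutate(rng, base, 2 * i),
            ))
        library = ReferenceIndex(refs)
        fwd, rev = mates_of(base)
        res = dual_read_assign(fwd, rev, library, params)
        assert res.n_retained_hits >= 1
        top = max(ident for _, ident in res.retained)
        for _, ident in res.retained:
            assert ident >= top - params.identity_window

    def test_consensus_depth_monotone_in_fraction(self, rng):
        amp = random_dna(rng, 658)
        library = ReferenceIndex([
            ReferenceRecord("a", lineage("Fam1", "Gen1", "sp1"), amp),
            ReferenceRecord("b", lineage("Fam1", "Gen1", "sp1"), amp),
            ReferenceRecord("c", lineage("Fam1", "Gen1", "sp2"), amp),
            ReferenceRecord("d", lineage("Fam1", "Gen2", "sp3"), amp),
        ])
        fwd, rev = mates_of(amp)
        depths = []
        for fraction in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
            res = dual_read_assign(
                fwd, rev, library,
                ClassifierParams(consensus_fraction=fraction),
            )
            depths.append(res.lineage.depth)
        assert all(a >= b for a, b in zip(depths, depths[1:]))

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            ReferenceIndex([])


class TestDualVsSingleBenchmark:
    def test_dual_read_genus_accuracy_dominates(self, rng):
        # references paired with congeneric-family decoys that share the
        # 5' half but diverge 10% in the 3' half: forward-only evidence
        # cannot separate them, the reverse mate can
        refs = []
        truths = []
        for i in range(10):
            amp = random_dna(rng, 658)
            decoy = amp[:329] + mutate(rng, amp[329:], 33)
            refs.append(ReferenceRecord(
                f"true{i}", lineage("Fam%d" % i, f"GenA{i}", "sp1"), amp))
            refs.append(ReferenceRecord(
                f"decoy{i}", lineage("Fam%d" % i, f"GenB{i}", "sp1"), decoy))
            truths.append((amp, f"GenA{i}"))
        library = ReferenceIndex(refs)
        n_dual = n_single = 0
        for _ in range(4):
            for amp, genus in truths:
                read = mutate(rng, amp, 2)  # light sequencing error
                fwd, rev = mates_of(read)
                dual = dual_read_assign(fwd, rev, library)
                single = single_read_assign(fwd, library)
                n_dual += dual.lineage.name_at("genus") == genus
                n_single += single.lineage.name_at("genus") == genus
        assert n_dual >= n_single
        assert n_dual >= 30  # dual mode resolves nearly all queries


class TestLCA:
    def library(self, rng):
        seqs = [random_dna(rng, 658) for _ in range(3)]
        return ReferenceIndex([
            ReferenceRecord("x1", Lineage(("Bacteria", "Proteobacteria",
                                           "Alpha", "Rickettsiales", "FamR",
                                           "FamRinae", "Rickettsia", "sp1")),
                            seqs[0]),
            ReferenceRecord("x2", Lineage(("Bacteria", "Proteobacteria",
                                           "Alpha", "Rickettsiales", "FamR",
                                           "FamRinae", "Rickettsia", "sp2")),
                            mutate(rng, seqs[0], 6)),
            ReferenceRecord("y", Lineage(("Bacteria", "Proteobacteria",
                                          "Alpha", "Rickettsiales", "FamR",
                                          "FamRinae", "Wolbachia", "sp3")),
                            mutate(rng, seqs[0], 40)),
        ]), seqs[0]

    def test_same_genus_hits(self, rng):
        library, amp = self.library(rng)
        fwd, rev = mates_of(amp)
        res = lca_assign(fwd, rev, library,
                         ClassifierParams(lca_top_window=2.0))
        assert res.mode == MODE_LCA
        assert res.lineage.name_at("genus") == "Rickettsia"

    def test_two_genera_back_off_to_family(self, rng):
        library, amp = self.library(rng)
        fwd, rev = mates_of(amp)
        res = lca_assign(fwd, rev, library,
                         ClassifierParams(lca_top_window=15.0))
        assert res.lineage.name_at("genus") is None
        assert res.lineage.name_at("subfamily") == "FamRinae"

    def test_no_hits_unassigned(self, rng):
        library, _ = self.library(rng)
        res = lca_assign(random_dna(rng, 293), random_dna(rng, 293), library)
        assert res.mode == MODE_UNASSIGNED

    def test_lca_is_prefix_of_every_retained_hit(self, rng):
        library, amp = self.library(rng)
        fwd, rev = mates_of(amp)
        res = lca_assign(fwd, rev, library, ClassifierParams(lca_top_window=15.0))
        for rid, _ in res.retained:
            assert res.lineage.is_prefix_of(library.lineage(rid))


class TestStandardBarcode:
    def library(self, rng):
        amp = random_dna(rng, 658)
        return ReferenceIndex([
            ReferenceRecord("near", lineage("Fam1", "Gen1", "sp1"), amp),
            ReferenceRecord("far", lineage("Fam1", "Gen1", "sp2"),
                            mutate(rng, amp, 50)),
        ]), amp

    def test_identical_query(self, rng):
        library, amp = self.library(rng)
        res = standard_barcode_identify(amp, library)
        assert res.lineage.name_at("species") == "sp1"

    def test_divergence_under_3pct(self, rng):
        library, amp = self.library(rng)
        query = mutate(rng, amp, 19)  # 2.9% divergence
        res = standard_barcode_identify(query, library)
        assert res.lineage.name_at("species") == "sp1"

    def test_divergence_over_3pct_no_species(self, rng):
        library, amp = self.library(rng)
        query = mutate(rng, amp, 33)  # 5%
        res = standard_barcode_identify(query, library)
        assert res.lineage.name_at("species") is None


class TestCategorize:
    def result(self, names, mode=MODE_DUAL):
        from metapair.classify import AssignmentResult

        return AssignmentResult(Lineage(names), mode, 100.0, 1, (("r", 100.0),))

    def test_lepidoptera_is_host(self):
        res = self.result(("Animalia", "Arthropoda", "Insecta", "Lepidoptera"))
        assert categorize_motu(res) == "host"

    def test_bacteria_is_symbiont(self):
        res = self.result(("Bacteria", "Proteobacteria"), MODE_LCA)
        assert categorize_motu(res) == "putative_symbiont"

    def test_hymenoptera_is_parasitoid(self):
        res = self.result(("Animalia", "Arthropoda", "Insecta", "Hymenoptera"))
        assert categorize_motu(res) == "parasitoid"

    def test_plant_is_contaminant(self):
        res = self.result(("Viridiplantae", "Streptophyta"), MODE_LCA)
        assert categorize_motu(res) == "contaminant"

    def test_empty_lineage_unassigned(self):
        from metapair.classify import UNASSIGNED

        assert categorize_motu(UNASSIGNED) == "unassigned"
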