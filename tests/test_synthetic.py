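import io
import math

import numpy as np
import pytest

from metapair.io_formats import write_fasta
from metapair.seq_compare import align_identity, revcomp
from metapair.synthetic import (
    MockDesign,
    MockSample,
    Specimen,
    design_mock_community,
    generate_mids,
    generate_offtarget_library,
    generate_reference_library,
    load_fixture_tables,
    simulate_paired_reads,
)

from .oracles import hamming_identity_pct


class TestReferenceLibrary:
    def test_minimal_case(self):
        records = generate_reference_library(1, 1, 1, seed=1)
        assert len(records) == 1
        assert records[0].lineage.depth == 8
        assert len(records[0].sequence) == 658

    def test_2x2x2_strata_ordering(self):
        records = generate_reference_library(2, 2, 2, seed=1)
        assert len(records) == 8
        within, across = [], []
        for i in range(8):
            for j in range(i + 1, 8):
                a, b = records[i], records[j]
                ident = align_identity(a.sequence, b.sequence).identity_pct
                if a.lineage.name_at("genus") == b.lineage.name_at("genus"):
                    within.append(ident)
                else:
                    across.append(ident)
        assert min(within) >= max(across)

    def test_strata_bounds(self):
        records = generate_reference_library(2, 2, 3, seed=3,
                                             variants_per_species=2)
        by_species = {}
        for rec in records:
            by_species.setdefault(rec.lineage.name_at("species"), []).append(rec)
        for i, a in enumerate(records):
            for b in records[i + 1:]:
                div = 100.0 - hamming_identity_pct(a.sequence, b.sequence)
                same_sp = a.lineage.name_at("species") == b.lineage.name_at("species")
                same_gen = a.lineage.name_at("genus") == b.lineage.name_at("genus")
                if same_sp:
                    assert div < 1.0
                elif same_gen:
                    assert 5.0 <= div <= 12.0
                else:
                    assert div > 12.0

    def test_determinism_byte_identical_fasta(self):
        outs = []
        for _ in range(2):
            records = generate_reference_library(2, 2, 2, seed=42)
            sink = io.StringIO()
            write_fasta([(r.record_id, r.sequence) for r in records], sink)
            outs.append(sink.getvalue())
        assert outs[0] == outs[1]

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_reference_library(0, 1, 1, seed=1)

    def test_unsatisfiable_length_fails(self):
        with pytest.raises(ValueError, match="stratum"):
            generate_reference_library(1, 2, 2, seed=1, seq_len=12)


class TestMockDesign:
    def libraries(self):
        hosts = generate_reference_library(2, 2, 2, seed=1, prefix="H")
        paras = generate_reference_library(2, 2, 2, seed=2, prefix="P")
        off = generate_offtarget_library(2, 1, seed=3)
        return hosts, paras, off

    def test_design_valid(self):
        hosts, paras, off = self.libraries()
        design = design_mock_community(hosts, paras, off, n_samples=3,
                                       n_parasitoid_taxa=5, seed=9)
        assert len(design.samples) == 3
        roles = [sp.role for s in design.samples for sp in s.specimens]
        assert roles.count("host") == 3
        assert roles.count("parasitoid") == 5

    def test_mid_distance_enforced(self):
        mids = generate_mids(8, seed=0)
        for i, a in enumerate(mids):
            for b in mids[i + 1:]:
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_close_mids_rejected(self):
        from metapair.lineage import Lineage

        lin = Lineage(("Animalia",))
        mk = lambda sid, mid: MockSample(
            sid, mid, (Specimen(f"{sid}_h", "host", lin, 1.0, "r1"),)
        )
        with pytest.raises(ValueError, match="Hamming"):
            MockDesign((mk("S1", "AAAAAAA"), mk("S2", "AAAAAAC")))

    def test_abundances_must_sum_to_one(self):
        from metapair.lineage import Lineage

        lin = Lineage(("Animalia",))
        sp = Specimen("a", "host", lin, 0.5, "r1")
        with pytest.raises(ValueError, match="sum"):
            MockDesign((MockSample("S1", "AAAAAAA", (sp,)),))

    def test_host_required(self):
        from metapair.lineage import Lineage

        lin = Lineage(("Animalia",))
        sp = Specimen("a", "parasitoid", lin, 1.0, "r1")
        with pytest.raises(ValueError, match="host"):
            MockDesign((MockSample("S1", "AAAAAAA", (sp,)),))


class TestSimulateReads:
    def scenario(self, **kwargs):
        hosts = generate_reference_library(2, 2, 2, seed=1, prefix="H")
        paras = generate_reference_library(2, 2, 2, seed=2, prefix="P")
        off = generate_offtarget_library(2, 1, seed=3)
        design = design_mock_community(hosts, paras, off, n_samples=2,
                                       n_parasitoid_taxa=3, seed=9)
        return design, hosts + paras + off

    def test_no_noise_reads_are_exact_substrings(self):
        design, library = self.scenario()
        by_id = {r.record_id: r for r in library}
        fwd, rev, manifest = simulate_paired_reads(
            design, library, 50, error_rate=0.0, chimera_rate=0.0, seed=4
        )
        mids = design.mids
        spec_by_id = {
            sp.specimen_id: sp for s in design.samples for sp in s.specimens
        }
        for f, r in zip(fwd, rev):
            entry = manifest.entries[f.read_id]
            amplicon = by_id[spec_by_id[entry.specimen_id].record_id].sequence
            assert f.bases == (mids[entry.sample_id] + amplicon)[:300]
            assert r.bases == revcomp(amplicon)[:300]

    def test_chimera_rate_binomial(self):
        design, library = self.scenario()
        n = 1000
        fwd, rev, manifest = simulate_paired_reads(
            design, library, n // 2, error_rate=0.0, chimera_rate=0.05, seed=11
        )
        k = manifest.n_chimeras()
        expect = len(fwd) * 0.05
        sd = math.sqrt(len(fwd) * 0.05 * 0.95)
        assert abs(k - expect) <= 3 * sd

    def test_abundance_multinomial(self):
        design, library = self.scenario()
        fwd, _, manifest = simulate_paired_reads(
            design, library, 4000, error_rate=0.0, chimera_rate=0.0, seed=12
        )
        counts = manifest.reads_per_specimen()
        host = design.samples[0].specimens[0]
        assert host.role == "host" and host.relative_abundance == 0.8
        k = counts[host.specimen_id]
        sd = math.sqrt(4000 * 0.8 * 0.2)
        assert abs(k - 3200) <= 3 * sd

    def test_abundance_recovery_all_specimens(self):
        design, library = self.scenario()
        n = 10_000
        _, _, manifest = simulate_paired_reads(
            design, library, n, error_rate=0.0, chimera_rate=0.0, seed=13
        )
        counts = manifest.reads_per_specimen()
        for sample in design.samples:
            for sp in sample.specimens:
                p = sp.relative_abundance
                se = math.sqrt(n * p * (1 - p))
                assert abs(counts.get(sp.specimen_id, 0) - n * p) <= 3 * se

    def test_conservation_and_manifest_coverage(self):
        design, library = self.scenario()
        fwd, rev, manifest = simulate_paired_reads(
            design, library, 100, seed=5
        )
        assert len(fwd) == len(rev) == 100 * len(design.samples)
        assert {f.read_id for f in fwd} == set(manifest.entries)
        assert len(manifest) == len(fwd)

    def test_determinism(self):
        design, library = self.scenario()
        a = simulate_paired_reads(design, library, 60, error_rate=0.01,
                                  chimera_rate=0.05, seed=7)
        b = simulate_paired_reads(design, library, 60, error_rate=0.01,
                                  chimera_rate=0.05, seed=7)
        assert [r.bases for r in a[0]] == [r.bases for r in b[0]]
        assert [r.quals for r in a[1]] == [r.quals for r in b[1]]

    def test_zero_reads_rejected(self):
        design, library = self.scenario()
        with pytest.raises(ValueError):
            simulate_paired_reads(design, library, 0, seed=1)

    def test_overlapping_read_length_rejected(self):
        design, library = self.scenario()
        with pytest.raises(ValueError, match="overlap"):
            simulate_paired_reads(design, library, 10, read_len=400, seed=1)

    def test_quality_profile_decays(self):
        design, library = self.scenario()
        fwd, _, _ = simulate_paired_reads(design, library, 30, seed=8)
        quals = np.array([r.quals for r in fwd if len(r) == 300])
        mean = quals.mean(axis=0)
        assert mean[0] > 34
        assert mean[-1] < 24


class TestFixtureTables:
    def test_table1_morphological_family(self):
        df = load_fixture_tables("table1")
        row = df[(df.method == "morphological") & (df.level == "family")]
        assert float(row.pct_success.iloc[0]) == 100.0

    def test_table1_shape(self):
        df = load_fixture_tables("table1")
        assert len(df) == 9  # 3 methods x 3 levels
        assert set(df.n_total) == {22}

    def test_table2_exoristinae_bins(self):
        df = load_fixture_tables("table2")
        assert int(df[df.taxon_group == "Exoristinae"].n_bins.iloc[0]) == 12

    def test_table2_host_rows(self):
        df = load_fixture_tables("table2")
        assert (df.guild == "host").sum() == 19
        assert (df.guild == "parasitoid").sum() == 24

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            load_fixture_tables("table9")
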