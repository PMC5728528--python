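"""End-to-end orchestration: demux -> QC -> dereplicate -> chimera screen
-> cluster -> singleton filter -> dual-read classify -> LCA fallback ->
categorize -> MOTU table, with a conserved per-stage count ledger."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .classify import (
    AssignmentResult,
    ClassifierParams,
    MODE_UNASSIGNED,
    ReferenceIndex,
    categorize_motu,
    dual_read_assign,
    lca_assign,
)
from .clustering import (
    ChimeraCall,
    ChimeraParams,
    MOTUCluster,
    chimeric_sequences,
    detect_chimeras,
    dereplicate,
    greedy_cluster,
    remove_singletons,
)
from .io_formats import (
    MOTURow,
    MOTUTable,
    SequenceRead,
    read_fasta,
    read_fastq_pair,
    read_taxonomy_table,
    write_fasta,
    write_fastq,
    write_manifest,
    write_motu_table,
    write_taxonomy_table,
)
from .lineage import Lineage
from .preprocess import DemuxReport, QCParams, demultiplex
from .synthetic import (
    MockDesign,
    ReferenceRecord,
    design_mock_community,
    generate_offtarget_library,
    generate_reference_library,
    simulate_paired_reads,
)


def _strict_dataclass(cls, data: dict, context: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables; defaults match the published parameter census
    (Q<=20 bad, runs >3 truncate, 100-nt minimum, 97% clustering, 0.5-point
    identity window, 50% consensus, 97%/100-nt recovery, 3% Sanger
    divergence)."""

    seed: int = 0
    qc: QCParams = field(default_factory=QCParams)
    chimera: ChimeraParams = field(default_factory=ChimeraParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    cluster_threshold: float = 97.0
    singleton_mode: str = "per-sample"
    skip_chimera: bool = False
    recovery_min_identity: float = 97.0
    recovery_min_overlap: int = 100
    sanger_max_divergence: float = 3.0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for section, sub_cls in (("qc", QCParams), ("chimera", ChimeraParams),
                                 ("classifier", ClassifierParams)):
            if section in data:
                kwargs[section] = _strict_dataclass(
                    sub_cls, data.pop(section), section
                )
        allowed = {f.name for f in dc_fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config document must be a mapping")
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    motu_table: MOTUTable
    clusters: list[MOTUCluster]
    assignments: dict[str, AssignmentResult]
    categories: dict[str, str]
    demux_report: DemuxReport
    chimera_calls: list[ChimeraCall]
    stage_counts: dict[str, int]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_motu_table(self.motu_table, out / "motu_table.tsv")
        write_fasta(
            [(c.motu_id, c.centroid_fwd) for c in self.clusters],
            out / "centroids_R1.fasta",
        )
        write_fasta(
            [(c.motu_id, c.centroid_rev) for c in self.clusters if c.centroid_rev],
            out / "centroids_R2.fasta",
        )
        with open(out / "assignments.tsv", "w") as fh:
            fh.write("motu_id\tmode\tlineage\tavg_identity\tn_hits\tcategory\n")
            for motu_id, res in self.assignments.items():
                fh.write(
                    f"{motu_id}\t{res.mode}\t{res.lineage.to_string()}\t"
                    f"{res.best_avg_identity_pct:.2f}\t{res.n_retained_hits}\t"
                    f"{self.categories[motu_id]}\n"
                )
        with open(out / "demux_report.tsv", "w") as fh:
            fh.write("cell\tcount\n")
            for cell, n in self.demux_report.to_rows():
                fh.write(f"{cell}\t{n}\n")
        with open(out / "chimera_calls.tsv", "w") as fh:
            fh.write("query\tparent_a\tparent_b\tbreakpoint\tmodel_identity\t"
                     "single_identity\tverdict\n")
            for c in self.chimera_calls:
                fh.write(f"{c.query_id[:25]}...\t{c.parent_a[:25]}...\t"
                         f"{c.parent_b[:25]}...\t{c.breakpoint}\t"
                         f"{c.model_identity_pct:.2f}\t"
                         f"{c.best_single_identity_pct:.2f}\t{c.verdict}\n")
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(
                {"version": __version__, "stage_counts": self.stage_counts},
                fh, indent=2,
            )


def run_pipeline(
    pairs: Sequence[tuple[SequenceRead, SequenceRead]],
    mids: dict[str, str],
    references: Sequence[ReferenceRecord],
    config: PipelineConfig = PipelineConfig(),
    fallback_references: Optional[Sequence[ReferenceRecord]] = None,
) -> PipelineResult:
    """Run every stage on in-memory read pairs; see module docstring."""
    counts: dict[str, int] = {"input_pairs": len(pairs)}

    demuxed, report = demultiplex(pairs, mids, config.qc)
    assert report.n_input == len(pairs), "demux conservation violated"
    counts["accepted_pairs"] = report.n_accepted
    counts["rejected_pairs"] = report.n_rejected

    sample_by_read: dict[str, str] = {}
    mate_by_read: dict[str, str] = {}
    forward_reads: list[SequenceRead] = []
    for sample_id, sample_pairs in demuxed.items():
        for fwd, rev in sample_pairs:
            sample_by_read[fwd.read_id] = sample_id
            mate_by_read[fwd.read_id] = rev.bases
            forward_reads.append(fwd)

    uniques = dereplicate(forward_reads)
    counts["unique_sequences"] = len(uniques)

    calls: list[ChimeraCall] = []
    if not config.skip_chimera:
        calls = detect_chimeras(uniques, config.chimera)
        flagged = chimeric_sequences(calls)
        uniques = [u for u in uniques if u.sequence not in flagged]
        counts["chimeric_uniques"] = len(flagged)
    counts["uniques_after_chimera"] = len(uniques)

    clusters = greedy_cluster(
        uniques,
        config.cluster_threshold,
        sample_of=sample_by_read.__getitem__,
        mate_of=mate_by_read.get,
    )
    counts["clusters"] = len(clusters)
    clusters = remove_singletons(clusters, config.singleton_mode)
    counts["clusters_after_singletons"] = len(clusters)
    counts["reads_in_motus"] = sum(c.total for c in clusters)

    library = ReferenceIndex(list(references))
    fallback = (
        ReferenceIndex(list(fallback_references)) if fallback_references else None
    )
    assignments: dict[str, AssignmentResult] = {}
    categories: dict[str, str] = {}
    for cluster in clusters:
        if cluster.centroid_rev:
            res = dual_read_assign(cluster.centroid_fwd, cluster.centroid_rev,
                                   library, config.classifier)
        else:
            from .classify import single_read_assign

            res = single_read_assign(cluster.centroid_fwd, library,
                                     config.classifier)
        if res.mode == MODE_UNASSIGNED and fallback is not None:
            res = lca_assign(cluster.centroid_fwd, cluster.centroid_rev or None,
                             fallback, config.classifier)
        assignments[cluster.motu_id] = res
        categories[cluster.motu_id] = categorize_motu(res)
    counts["assigned_motus"] = sum(
        1 for r in assignments.values() if r.mode != MODE_UNASSIGNED
    )

    sample_order = list(mids)
    rows = [
        MOTURow(
            c.motu_id,
            [c.counts.get(s, 0) for s in sample_order],
            assignments[c.motu_id].lineage,
            categories[c.motu_id],
        )
        for c in clusters
    ]
    table = MOTUTable(samples=sample_order, rows=rows)
    return PipelineResult(
        motu_table=table,
        clusters=clusters,
        assignments=assignments,
        categories=categories,
        demux_report=report,
        chimera_calls=calls,
        stage_counts=counts,
    )


# ------------------------------------------------------------- simulate


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the packaged synthetic scenario (5 host-dominated samples,
    14 insect taxa, bacterial symbionts, plant contaminants)."""

    seed: int = 0
    n_samples: int = 5
    n_parasitoid_taxa: int = 9
    reads_per_sample: int = 4000
    read_len: int = 300
    error_rate: float = 0.001
    chimera_rate: float = 0.02
    host_share: float = 0.8
    symbiont_share: float = 0.05
    contaminant_share: float = 0.02

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return _strict_dataclass(cls, data, "simulation")


def build_scenario(
    sim: SimulationConfig,
) -> tuple[MockDesign, list[ReferenceRecord], list[ReferenceRecord]]:
    """Libraries plus a mock design for the packaged synthetic scenario."""
    if sim.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    hosts = generate_reference_library(
        max(2, (sim.n_samples + 1) // 2), 2, 2, seed=sim.seed + 11,
        order="Lepidoptera", prefix="HOST",
    )
    paras = generate_reference_library(
        max(2, (sim.n_parasitoid_taxa + 3) // 4), 2, 2, seed=sim.seed + 23,
        order="Hymenoptera", prefix="PARA",
    )
    offtargets = generate_offtarget_library(3, 2, seed=sim.seed + 37)
    design = design_mock_community(
        hosts, paras, offtargets,
        n_samples=sim.n_samples,
        n_parasitoid_taxa=sim.n_parasitoid_taxa,
        host_share=sim.host_share,
        symbiont_share=sim.symbiont_share,
        contaminant_share=sim.contaminant_share,
        seed=sim.seed + 41,
    )
    return design, hosts + paras, offtargets


def simulate_to_dir(out_dir, sim: SimulationConfig, overwrite: bool = False) -> dict:
    """Write a complete synthetic dataset (references, taxonomy, paired
    FASTQ, MIDs, truth manifest, specimen barcodes, design) to `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expected = ["references.fasta", "reads_R1.fastq", "reads_R2.fastq"]
    if not overwrite:
        clashes = [p for p in expected if (out / p).exists()]
        if clashes:
            raise FileExistsError(
                f"refusing to overwrite {clashes} (pass overwrite=True)"
            )
    design, references, offtargets = build_scenario(sim)
    fwd, rev, manifest = simulate_paired_reads(
        design, references + offtargets, sim.reads_per_sample,
        read_len=sim.read_len, error_rate=sim.error_rate,
        chimera_rate=sim.chimera_rate, seed=sim.seed,
    )
    write_fasta([(r.record_id, r.sequence) for r in references],
                out / "references.fasta")
    write_taxonomy_table({r.record_id: r.lineage for r in references},
                         out / "references.tax.tsv")
    write_fasta([(r.record_id, r.sequence) for r in offtargets],
                out / "fallback.fasta")
    write_taxonomy_table({r.record_id: r.lineage for r in offtargets},
                         out / "fallback.tax.tsv")
    write_fastq(fwd, out / "reads_R1.fastq")
    write_fastq(rev, out / "reads_R2.fastq")
    write_manifest(manifest.rows(), out / "manifest.tsv")
    with open(out / "mids.tsv", "w") as fh:
        for sample_id, mid in design.mids.items():
            fh.write(f"{sample_id}\t{mid}\n")
    by_id = {r.record_id: r for r in references + offtargets}
    barcodes = []
    for sample in design.samples:
        for sp in sample.specimens:
            if sp.role in {"host", "parasitoid"}:
                barcodes.append((f"{sp.specimen_id}|{sp.record_id}",
                                 by_id[sp.record_id].sequence))
    write_fasta(barcodes, out / "barcodes.fasta")
    doc = {
        "simulation": asdict(sim),
        "samples": [
            {
                "sample_id": s.sample_id,
                "mid": s.mid,
                "specimens": [
                    {"specimen_id": sp.specimen_id, "role": sp.role,
                     "record_id": sp.record_id,
                     "lineage": sp.lineage.to_string(),
                     "relative_abundance": sp.relative_abundance}
                    for sp in s.specimens
                ],
            }
            for s in design.samples
        ],
    }
    with open(out / "design.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return doc


def load_reference_records(fasta_path, tax_path) -> list[ReferenceRecord]:
    """Join a FASTA with its taxonomy TSV into reference records."""
    taxonomy = read_taxonomy_table(tax_path)
    records = []
    for rid, seq in read_fasta(fasta_path):
        lineage = taxonomy.get(rid)
        if lineage is None:
            raise ValueError(f"reference {rid!r} missing from taxonomy table")
        records.append(ReferenceRecord(rid, lineage, seq))
    return records


def run_from_files(
    r1, r2, mids_path, ref_fasta, ref_tax,
    config: PipelineConfig = PipelineConfig(),
    fallback_fasta=None, fallback_tax=None,
) -> PipelineResult:
    pairs, _orphans = read_fastq_pair(r1, r2)
    with open(mids_path) as fh:
        mids = dict(
            line.rstrip("\n").split("\t")[:2] for line in fh if line.strip()
        )
    references = load_reference_records(ref_fasta, ref_tax)
    fallback = (
        load_reference_records(fallback_fasta, fallback_tax)
        if fallback_fasta and fallback_tax else None
    )
    return run_pipeline(pairs, mids, references, config, fallback)
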