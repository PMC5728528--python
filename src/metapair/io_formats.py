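"""Readers and writers for the plain-text formats used across the pipeline.

FASTA, FASTQ (phred+33, gzip-transparent), the two-column taxonomy TSV,
the MOTU table TSV, and the read-truth manifest TSV.  Readers reject
malformed records with positional diagnostics instead of skipping them.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .lineage import Lineage, RANKS

Source = Union[str, Path, IO[str]]

CATEGORIES = ("host", "parasitoid", "putative_symbiont", "contaminant", "unassigned")

FORWARD = "forward"
REVERSE = "reverse"

_PHRED_OFFSET = 33


def _open_text(source: Source, mode: str = "rt"):
    """Open a path (gzip-transparent) or pass a file object through."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, mode)
        return open(path, mode)
    return _NonClosing(source)


class _NonClosing:
    """Context manager that leaves caller-owned file objects open."""

    def __init__(self, fh):
        self._fh = fh

    def __enter__(self):
        return self._fh

    def __exit__(self, *exc):
        return False


@dataclass
class SequenceRead:
    """One sequencing read: id, bases, per-base phred scores, mate tag."""

    read_id: str
    bases: str
    quals: list[int]
    mate: str = FORWARD

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def trimmed(self, start: int, end: int) -> "SequenceRead":
        return SequenceRead(
            self.read_id, self.bases[start:end], self.quals[start:end], self.mate
        )


def _decode_quals(qual_str: str, read_id: str, index: int) -> list[int]:
    quals = [ord(c) - _PHRED_OFFSET for c in qual_str]
    if any(q < 0 for q in quals):
        raise ValueError(
            f"record {index} ({read_id!r}): quality character below '!' — "
            "not phred+33"
        )
    if quals and min(quals) >= 31 and max(quals) > 62:
        raise ValueError(
            f"record {index} ({read_id!r}): quality string looks like "
            "phred+64; only phred+33 is supported"
        )
    return quals


def _clean_bases(bases: str) -> str:
    return bases.upper().replace("U", "T")


def strip_mate_suffix(title: str) -> str:
    """Read id without mate decorations (`/1`, `/2`, or whitespace tail)."""
    rid = title.split()[0] if title.split() else title
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


# ---------------------------------------------------------------- FASTQ


def read_fastq(source: Source, mate: str = FORWARD) -> Iterator[SequenceRead]:
    """Stream reads from a FASTQ file (phred+33; gzip-transparent)."""
    with _open_text(source) as fh:
        for index, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            rid = strip_mate_suffix(title)
            if len(seq) != len(qual):  # FastqGeneralIterator also guards this
                raise ValueError(
                    f"record {index} ({rid!r}): sequence and quality lengths differ"
                )
            yield SequenceRead(
                rid, _clean_bases(seq), _decode_quals(qual, rid, index), mate
            )


def read_fastq_pair(
    forward: Source, reverse: Source
) -> tuple[list[tuple[SequenceRead, SequenceRead]], list[str]]:
    """Pair up two FASTQ files by read id.

    Returns ``(pairs, orphan_ids)``; pairs follow forward-file order.
    """
    fwd_reads = list(read_fastq(forward, FORWARD))
    rev_by_id: dict[str, SequenceRead] = {}
    for read in read_fastq(reverse, REVERSE):
        if read.read_id in rev_by_id:
            raise ValueError(f"duplicate reverse read id {read.read_id!r}")
        rev_by_id[read.read_id] = read
    pairs = []
    orphans = []
    for fwd in fwd_reads:
        rev = rev_by_id.pop(fwd.read_id, None)
        if rev is None:
            orphans.append(fwd.read_id)
        else:
            pairs.append((fwd, rev))
    orphans.extend(rev_by_id)
    return pairs, orphans


def write_fastq(reads: Iterable[SequenceRead], sink: Source) -> None:
    with _open_text(sink, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + _PHRED_OFFSET) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------- FASTA


def read_fasta(source: Source) -> list[tuple[str, str]]:
    """Read FASTA as (id, uppercased sequence) tuples."""
    out = []
    with _open_text(source) as fh:
        for index, (title, seq) in enumerate(SimpleFastaParser(fh)):
            if not seq:
                raise ValueError(f"record {index} ({title!r}): empty sequence")
            out.append((title.split()[0], _clean_bases(seq)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], sink: Source, width: int = 70) -> None:
    with _open_text(sink, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


# ------------------------------------------------------------- taxonomy


def read_taxonomy_table(source: Source, sep: str = ";") -> dict[str, Lineage]:
    """Two-column TSV: record_id TAB semicolon-joined lineage (shallow→deep)."""
    mapping: dict[str, Lineage] = {}
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
            rid, lineage_str = parts
            if rid in mapping:
                raise ValueError(f"line {lineno}: duplicate record id {rid!r}")
            try:
                lineage = Lineage.from_string(lineage_str, sep=sep)
            except ValueError as exc:
                raise ValueError(f"line {lineno} ({rid!r}): {exc}") from exc
            if len(lineage) > len(RANKS):  # defensive; Lineage already checks
                raise ValueError(f"line {lineno} ({rid!r}): too many ranks")
            mapping[rid] = lineage
    return mapping


def write_taxonomy_table(
    mapping: dict[str, Lineage], sink: Source, rank_prefixes: bool = False
) -> None:
    with _open_text(sink, "wt") as fh:
        for rid, lineage in mapping.items():
            fh.write(f"{rid}\t{lineage.to_string(rank_prefixes=rank_prefixes)}\n")


# ------------------------------------------------------------ MOTU table


@dataclass
class MOTURow:
    motu_id: str
    counts: list[int]
    lineage: Lineage
    category: str

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError(f"MOTU {self.motu_id!r}: negative read count")
        if self.category not in CATEGORIES:
            raise ValueError(f"MOTU {self.motu_id!r}: unknown category {self.category!r}")


@dataclass
class MOTUTable:
    samples: list[str]
    rows: list[MOTURow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            if row.motu_id in seen:
                raise ValueError(f"duplicate MOTU id {row.motu_id!r}")
            seen.add(row.motu_id)
            if len(row.counts) != len(self.samples):
                raise ValueError(
                    f"MOTU {row.motu_id!r}: {len(row.counts)} counts for "
                    f"{len(self.samples)} samples"
                )

    def total_reads(self) -> int:
        return sum(sum(r.counts) for r in self.rows)


def write_motu_table(table: MOTUTable, sink: Source) -> None:
    with _open_text(sink, "wt") as fh:
        header = ["motu_id", *table.samples, "lineage", "category"]
        fh.write("\t".join(header) + "\n")
        for row in table.rows:
            cells = [row.motu_id, *map(str, row.counts),
                     row.lineage.to_string(), row.category]
            fh.write("\t".join(cells) + "\n")


def read_motu_table(source: Source) -> MOTUTable:
    with _open_text(source) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError("empty MOTU table")
    header = lines[0].split("\t")
    if header[0] != "motu_id" or header[-2:] != ["lineage", "category"]:
        raise ValueError("malformed MOTU table header")
    samples = header[1:-2]
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"line {lineno}: expected {len(header)} columns")
        counts = [int(c) for c in cells[1: 1 + len(samples)]]
        rows.append(
            MOTURow(cells[0], counts, Lineage.from_string(cells[-2]), cells[-1])
        )
    return MOTUTable(samples=samples, rows=rows)


# -------------------------------------------------------------- manifest


def write_manifest(entries: Iterable[tuple], sink: Source) -> None:
    """Entries: (read_id, specimen_id, sample_id, is_chimera, parent_ids)."""
    with _open_text(sink, "wt") as fh:
        fh.write("read_id\tspecimen_id\tsample_id\tis_chimera\tparents\n")
        for read_id, specimen_id, sample_id, is_chimera, parents in entries:
            fh.write(
                f"{read_id}\t{specimen_id}\t{sample_id}\t"
                f"{int(is_chimera)}\t{','.join(parents)}\n"
            )


def read_manifest(source: Source) -> dict[str, tuple[str, str, bool, tuple[str, ...]]]:
    mapping: dict[str, tuple[str, str, bool, tuple[str, ...]]] = {}
    with _open_text(source) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError("malformed manifest header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 5:
                raise ValueError(f"line {lineno}: expected 5 columns")
            rid, specimen, sample, chim, parents = cells
            if rid in mapping:
                raise ValueError(f"line {lineno}: duplicate read id {rid!r}")
            mapping[rid] = (
                specimen,
                sample,
                chim == "1",
                tuple(p for p in parents.split(",") if p),
            )
    return mapping
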